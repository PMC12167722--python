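"""Deterministic label/skeleton rasterization of polygonal tilings."""

from __future__ import annotations

import numpy as np
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon


def rasterize(tiling, pixel_size: float = 1.0, contour_width: int = 1,
              shape: tuple[int, int] | None = None,
              origin: tuple[float, float] | None = None) -> np.ndarray:
    """Render the tiling as an integer label image.

    Pixel centers sit at integer coordinates (origin top-left, x rightward
    = columns, y downward = rows, 0-based); world coordinates are divided by
    ``pixel_size``. Label ids equal tiling cell ids; contour pixels are 0.
    Contours are one-pixel lines drawn on the geometric cell edges (so
    pixel centroids are unbiased estimates of polygon centroids), plus a
    one-pixel frame at the image border.
    """
    areas = [tiling.cell_area(c) for c in tiling.cells]
    mean_diam = float(np.sqrt(np.mean(areas)) / pixel_size)
    if mean_diam < 8:
        raise ValueError("mean cell diameter < 8 px at this pixel size")
    xmin, ymin, xmax, ymax = tiling.box
    if origin is not None:
        xmin, ymin = origin
    if shape is None:
        shape = (int(np.ceil((ymax - ymin) / pixel_size)) + 1,
                 int(np.ceil((xmax - xmin) / pixel_size)) + 1)
    if 0 in tiling.cells:
        raise ValueError("cell id 0 is reserved for contour/background")
    label = np.zeros(shape, dtype=np.int32)
    for cid in sorted(tiling.cells):
        poly = tiling.cell_polygon(cid)
        rows = (poly[:, 1] - ymin) / pixel_size
        cols = (poly[:, 0] - xmin) / pixel_size
        rr, cc = draw_polygon(rows, cols, shape=shape)
        if rr.size == 0:
            raise ValueError(f"cell {cid} rasterizes to zero pixels")
        label[rr, cc] = cid
    # contour: one-pixel lines along the geometric edges
    contour = np.zeros(shape, dtype=bool)
    for (v1, v2), _cells in tiling.edge_map().items():
        r1 = int(round((tiling.points[v1][1] - ymin) / pixel_size))
        c1 = int(round((tiling.points[v1][0] - xmin) / pixel_size))
        r2 = int(round((tiling.points[v2][1] - ymin) / pixel_size))
        c2 = int(round((tiling.points[v2][0] - xmin) / pixel_size))
        rr, cc = draw_line(np.clip(r1, 0, shape[0] - 1),
                           np.clip(c1, 0, shape[1] - 1),
                           np.clip(r2, 0, shape[0] - 1),
                           np.clip(c2, 0, shape[1] - 1))
        contour[rr, cc] = True
    if contour_width > 1:
        for _ in range(contour_width - 1):
            grown = contour.copy()
            grown[1:, :] |= contour[:-1, :]
            grown[:, 1:] |= contour[:, :-1]
            contour = grown
    label[contour] = 0
    label[0, :] = label[-1, :] = 0
    label[:, 0] = label[:, -1] = 0
    return label


def skeleton_image(label: np.ndarray) -> np.ndarray:
    """8-bit contour (skeleton) image: 255 on cell outlines, 0 inside."""
    return np.where(label == 0, 255, 0).astype(np.uint8)
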