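"""Shared-vertex polygonal tilings used as synthetic epithelial tissue.

A :class:`Tiling` stores vertex coordinates once and each cell as a CCW loop
of vertex indices, so topological moves (T1, division, T2) act on shared
structure exactly, and adjacency (edge contacts vs vertex-only "fourfold"
contacts) can be read off without geometric tolerance games.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi


def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area of a closed loop given as an (n, 2) array."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cr = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cr)
    if abs(a) < 1e-12:  # degenerate: fall back to vertex mean
        return pts.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cr) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cr) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Tiling:
    """Confluent 2D tiling: shared vertices + per-cell CCW vertex loops."""

    points: np.ndarray                     # (V, 2) float, px
    cells: dict[int, list[int]]            # cell id -> CCW loop of vertex ids
    box: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    next_cell_id: int = field(default=0)

    def __post_init__(self) -> None:
        if self.next_cell_id == 0 and self.cells:
            self.next_cell_id = max(self.cells) + 1

    # -- geometry ---------------------------------------------------------
    def cell_polygon(self, cid: int) -> np.ndarray:
        return self.points[self.cells[cid]]

    def cell_area(self, cid: int) -> float:
        return polygon_area(self.cell_polygon(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return polygon_centroid(self.cell_polygon(cid))

    def centroids(self) -> dict[int, np.ndarray]:
        return {cid: self.cell_centroid(cid) for cid in self.cells}

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    # -- topology ---------------------------------------------------------
    def edge_map(self) -> dict[tuple[int, int], list[int]]:
        """Undirected vertex-pair edge -> list of incident cell ids."""
        em: dict[tuple[int, int], list[int]] = {}
        for cid, loop in self.cells.items():
            n = len(loop)
            for j in range(n):
                a, b = loop[j], loop[(j + 1) % n]
                key = (a, b) if a < b else (b, a)
                em.setdefault(key, []).append(cid)
        return em

    def adjacency(self) -> list[tuple[int, int, float, str]]:
        """Neighbor pairs ``(i, k, omega, kind)`` with i < k.

        Cells sharing an edge are edge contacts (omega = 1); cells sharing
        only a vertex (four or more cells meeting at a point) are
        vertex-only contacts (omega = 1/2).
        """
        em = self.edge_map()
        edge_pairs: set[tuple[int, int]] = set()
        for cells in em.values():
            if len(cells) == 2:
                i, k = sorted(cells)
                edge_pairs.add((i, k))
        # vertex-only contacts: pairs co-incident on a vertex but no edge
        vert_cells: dict[int, set[int]] = {}
        for cid, loop in self.cells.items():
            for v in loop:
                vert_cells.setdefault(v, set()).add(cid)
        vertex_pairs: set[tuple[int, int]] = set()
        for cells_at_v in vert_cells.values():
            if len(cells_at_v) >= 4:
                cl = sorted(cells_at_v)
                for a in range(len(cl)):
                    for b in range(a + 1, len(cl)):
                        pair = (cl[a], cl[b])
                        if pair not in edge_pairs:
                            vertex_pairs.add(pair)
        out = [(i, k, 1.0, "edge") for (i, k) in sorted(edge_pairs)]
        out += [(i, k, 0.5, "fourfold-vertex") for (i, k) in sorted(vertex_pairs)]
        return out

    def boundary_cells(self) -> set[int]:
        """Cells owning an edge not shared with any other cell."""
        em = self.edge_map()
        out: set[int] = set()
        for cells in em.values():
            if len(cells) == 1:
                out.add(cells[0])
        return out

    def vertex_cells(self, v: int) -> set[int]:
        return {cid for cid, loop in self.cells.items() if v in loop}

    def copy(self) -> "Tiling":
        return Tiling(
            points=self.points.copy(),
            cells={c: list(l) for c, l in self.cells.items()},
            box=self.box,
            next_cell_id=self.next_cell_id,
        )

    def add_vertex(self, xy: np.ndarray) -> int:
        self.points = np.vstack([self.points, np.asarray(xy, float)[None, :]])
        return len(self.points) - 1

    def validate(self) -> None:
        """Raise if any cell loop is degenerate or negatively oriented."""
        for cid, loop in self.cells.items():
            if len(loop) < 3:
                raise ValueError(f"cell {cid} has fewer than 3 vertices")
            if polygon_area(self.points[loop]) <= 0:
                raise ValueError(f"cell {cid} has non-positive area")


def make_hexagonal_tiling(n_rows: int, n_cols: int, spacing: float = 20.0,
                          margin: float = 4.0) -> Tiling:
    """Regular hexagonal tiling; cell centers on a triangular lattice.

    Nearest-neighbor center distance is ``spacing`` (px); interior cell area
    is (sqrt(3)/2) * spacing**2.
    """
    if n_rows < 3 or n_cols < 3:
        raise ValueError("n_rows and n_cols must be >= 3")
    if spacing < 6:
        raise ValueError("spacing too small to rasterize (need >= 6 px)")
    d = float(spacing)
    rh = d / np.sqrt(3.0)  # circumradius
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    hexv = np.stack([rh * np.cos(ang), rh * np.sin(ang)], axis=1)

    centers = []
    for r in range(n_rows):
        for c in range(n_cols):
            centers.append((c * d + (r % 2) * d / 2.0, r * d * np.sqrt(3.0) / 2.0))
    centers = np.asarray(centers) + margin + rh

    # deduplicate shared vertices on a fine grid
    key_of: dict[tuple[int, int], int] = {}
    pts: list[tuple[float, float]] = []
    cells: dict[int, list[int]] = {}
    for cid, ctr in enumerate(centers, start=1):
        loop = []
        for v in hexv + ctr:
            key = (round(v[0] * 1024), round(v[1] * 1024))
            if key not in key_of:
                key_of[key] = len(pts)
                pts.append((v[0], v[1]))
            loop.append(key_of[key])
        cells[cid] = loop
    p = np.asarray(pts)
    box = (0.0, 0.0, float(p[:, 0].max() + margin), float(p[:, 1].max() + margin))
    return Tiling(points=p, cells=cells, box=box)


def _mirrored(points: np.ndarray, box) -> np.ndarray:
    xmin, ymin, xmax, ymax = box
    refl = [
        np.column_stack([2 * xmin - points[:, 0], points[:, 1]]),
        np.column_stack([2 * xmax - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * ymin - points[:, 1]]),
        np.column_stack([points[:, 0], 2 * ymax - points[:, 1]]),
    ]
    return np.vstack([points] + refl)


def make_voronoi_tiling(n_cells: int, seed: int = 0, lloyd_steps: int = 5,
                        box: tuple[float, float, float, float] | None = None) -> Tiling:
    """Lloyd-relaxed Voronoi tiling of a rectangle.

    Generator points are mirrored across the four box edges so every Voronoi
    cell of an original point is bounded and the cells partition the
    rectangle exactly, with shared Voronoi vertices giving exact adjacency.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)
    if box is None:
        # target mean cell area ~ (20 px)^2 -> square box
        side = float(np.sqrt(n_cells) * 20.0)
        box = (0.0, 0.0, side, side)
    xmin, ymin, xmax, ymax = box
    pts = np.column_stack([
        rng.uniform(xmin, xmax, n_cells),
        rng.uniform(ymin, ymax, n_cells),
    ])
    for _ in range(lloyd_steps):
        vor = Voronoi(_mirrored(pts, box))
        new = np.empty_like(pts)
        for i in range(n_cells):
            region = vor.regions[vor.point_region[i]]
            new[i] = polygon_centroid(vor.vertices[region])
        pts = np.clip(new, [xmin, ymin], [xmax, ymax])

    vor = Voronoi(_mirrored(pts, box))
    # collect vertex ids actually used, reindex compactly
    used: dict[int, int] = {}
    coords: list[np.ndarray] = []
    cells: dict[int, list[int]] = {}
    for i in range(n_cells):
        region = vor.regions[vor.point_region[i]]
        loop = []
        for v in region:
            if v not in used:
                used[v] = len(coords)
                coords.append(vor.vertices[v])
            loop.append(used[v])
        if polygon_area(vor.vertices[region]) < 0:
            loop = loop[::-1]
        cells[i + 1] = loop
    return Tiling(points=np.asarray(coords), cells=cells, box=box)
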