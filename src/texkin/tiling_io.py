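"""Polygonal-tiling data model: frames, ROIs, half-links, and serialization.

A :class:`TissueFrame` is one time point of a confluent cell tiling: cell
centers, areas, the neighbor graph with contact weights (omega = 1 for edge
contacts, 1/2 for fourfold-vertex contacts), and outermost flags. Frames can
be built from integer label images, from the synthetic simulator's exact
geometry, or read back from CSV tables.

Half-links are directed center-to-center vectors l_ik = x_k - x_i; each
undirected neighbor pair inside a region of interest contributes two of
them, and links touching outermost cells are excluded from all tensor
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

VALID_OMEGA = {1.0: "edge", 0.5: "fourfold-vertex"}


class SchemaError(ValueError):
    """A frame table is missing a required column or violates an invariant."""


@dataclass
class TissueFrame:
    """One time point of the tiling."""

    frame_index: int
    time: float                                  # minutes
    ids: np.ndarray                              # (n,) int cell ids
    centers: np.ndarray                          # (n, 2) float, px (x, y)
    areas: np.ndarray                            # (n,) float, px^2
    outermost: np.ndarray                        # (n,) bool
    adjacency: list[tuple[int, int, float, str]]  # (i, k, omega, kind), i < k
    pixel_size: float = 1.0                      # um / px
    area_source: str = "polygon"                 # "polygon" | "pixel_count"
    label_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.outermost = np.asarray(self.outermost, dtype=bool)
        if np.any(self.areas <= 0):
            raise ValueError("cell areas must be strictly positive")
        self._index = {int(i): j for j, i in enumerate(self.ids)}
        self._neighbors: dict[int, list[tuple[int, float, str]]] = {
            int(i): [] for i in self.ids}
        seen: set[tuple[int, int]] = set()
        for i, k, omega, kind in self.adjacency:
            if i == k:
                raise ValueError("self-adjacency is not allowed")
            if omega not in VALID_OMEGA or VALID_OMEGA[omega] != kind:
                raise SchemaError(
                    f"omega {omega} inconsistent with contact kind {kind!r}")
            key = (min(i, k), max(i, k))
            if key in seen:
                continue
            seen.add(key)
            self._neighbors[int(i)].append((int(k), omega, kind))
            self._neighbors[int(k)].append((int(i), omega, kind))

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def center(self, cid: int) -> np.ndarray:
        return self.centers[self._index[cid]]

    def area(self, cid: int) -> float:
        return float(self.areas[self._index[cid]])

    def is_outermost(self, cid: int) -> bool:
        return bool(self.outermost[self._index[cid]])

    def neighbors(self, cid: int) -> list[tuple[int, float, str]]:
        """Neighbors of ``cid`` as (other id, omega, contact kind)."""
        return self._neighbors[cid]

    def has_cell(self, cid: int) -> bool:
        return cid in self._index


@dataclass
class ROISpec:
    """Lagrangian region of interest: per-frame member cell-id sets.

    Membership across frames changes only by lineage: identity, division
    (mother replaced by daughters) or apoptosis (removal) — no flux.
    """

    roi_id: int
    origin_tile: tuple[int, int]
    member_cells: list[set[int]] = field(default_factory=list)

    def members_at(self, frame: int) -> set[int]:
        return self.member_cells[frame]


@dataclass
class HalfLinkSet:
    """Weighted directed half-links of one ROI at one epoch."""

    roi_id: int
    frame_index: int
    i_ids: np.ndarray          # (m,) source cell ids
    k_ids: np.ndarray          # (m,) target cell ids
    omegas: np.ndarray         # (m,)
    vectors: np.ndarray        # (m, 2) l_ik = x_k - x_i
    n_c: int                   # cells in the ROI
    degenerate: bool = False

    @property
    def n_h(self) -> int:
        return len(self.i_ids)

    def texture_sum(self) -> np.ndarray:
        """Unnormalized tensor sum  sum (omega/2) l (x) l  (px^2)."""
        w = (self.omegas / 2.0)[:, None, None]
        outer = self.vectors[:, :, None] * self.vectors[:, None, :]
        return (w * outer).sum(axis=0)


def half_links(frame: TissueFrame, members, roi_id: int = 0) -> HalfLinkSet:
    """Emit all half-links from ROI members to their non-outermost neighbors.

    Links to and from outermost cells are excluded. The set is flagged
    degenerate when it has fewer than 3 non-collinear half-links; degenerate
    sets are rejected by every tensor operation downstream.
    """
    members = set(int(m) for m in members)
    for m in members:
        if not frame.has_cell(m):
            raise KeyError(f"ROI member {m} not present in frame")
    ii, kk, ww, vv = [], [], [], []
    for i in sorted(members):
        if frame.is_outermost(i):
            continue
        xi = frame.center(i)
        for k, omega, _kind in frame.neighbors(i):
            if frame.is_outermost(k):
                continue
            ii.append(i)
            kk.append(k)
            ww.append(omega)
            vv.append(frame.center(k) - xi)
    vectors = np.asarray(vv, float).reshape(-1, 2)
    degenerate = False
    if len(ii) < 3:
        degenerate = True
    else:
        # collinearity: rank of the link direction set
        s = np.linalg.svd(vectors, compute_uv=False)
        degenerate = s[-1] < 1e-9 * s[0]
    return HalfLinkSet(
        roi_id=roi_id, frame_index=frame.frame_index,
        i_ids=np.asarray(ii, int), k_ids=np.asarray(kk, int),
        omegas=np.asarray(ww, float), vectors=vectors,
        n_c=len(members), degenerate=degenerate)


# ---------------------------------------------------------------------------
# construction from label images
# ---------------------------------------------------------------------------

def _zero_pixel_neighbor_labels(label: np.ndarray):
    """For each contour (0) pixel, the labels in its 3x3 neighborhood."""
    padded = np.pad(label, 1, mode="constant")
    stacks = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            stacks.append(padded[1 + dr:padded.shape[0] - 1 + dr,
                                 1 + dc:padded.shape[1] - 1 + dc])
    stack = np.stack(stacks, axis=0)  # (9, H, W)
    rows, cols = np.nonzero(label == 0)
    return stack[:, rows, cols]  # (9, Z)


def build_frame_from_labels(label_image: np.ndarray, pixel_size: float = 1.0,
                            frame_index: int = 0, time: float = 0.0,
                            border_margin: int = 2) -> TissueFrame:
    """Build a TissueFrame from an integer label raster (0 = contour).

    Centers are means of member pixel coordinates (x = column, y = row,
    0-based). Adjacency comes from contour-pixel neighborhoods: a pair of
    labels co-occurring around a contour pixel with exactly two labels in
    its 3x3 neighborhood is an edge contact; a pair seen only at junction
    pixels where four or more labels meet is a fourfold-vertex contact
    (omega = 1/2). Cells with pixels within ``border_margin`` px of the
    image border are flagged outermost.
    """
    label = np.asarray(label_image)
    if not np.issubdtype(label.dtype, np.integer):
        raise TypeError("label image must have an integer dtype")
    ids = np.unique(label)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no cells")

    idx = ndimage.value_indices(label, ignore_value=0)
    # background = zero regions thicker than a contour line; cells adjacent
    # to background (or to the image border) are outermost
    zero = label == 0
    background = zero & (ndimage.distance_transform_edt(zero) > 2.0)
    near_background = ndimage.binary_dilation(background, iterations=3)
    centers = np.empty((ids.size, 2))
    areas = np.empty(ids.size)
    outermost = np.zeros(ids.size, dtype=bool)
    h, w = label.shape
    for j, cid in enumerate(ids):
        rows, cols = idx[cid]
        centers[j] = (cols.mean(), rows.mean())
        areas[j] = rows.size
        outermost[j] = (rows.min() < border_margin or cols.min() < border_margin
                        or rows.max() >= h - border_margin
                        or cols.max() >= w - border_margin
                        or bool(near_background[rows, cols].any()))

    neigh = _zero_pixel_neighbor_labels(label)  # (9, Z)
    srt = np.sort(neigh, axis=0)
    edge_evidence: set[tuple[int, int]] = set()
    junction_evidence: set[tuple[int, int]] = set()
    tri_counts: dict[tuple[int, int], int] = {}
    z = srt.shape[1]
    for col in range(z):
        vals = srt[:, col]
        uniq = np.unique(vals)
        uniq = uniq[uniq > 0]
        if uniq.size == 2:
            edge_evidence.add((int(uniq[0]), int(uniq[1])))
        elif uniq.size == 3:
            for a in range(3):
                for b in range(a + 1, 3):
                    key = (int(uniq[a]), int(uniq[b]))
                    tri_counts[key] = tri_counts.get(key, 0) + 1
        elif uniq.size >= 4:
            for a in range(uniq.size):
                for b in range(a + 1, uniq.size):
                    junction_evidence.add((int(uniq[a]), int(uniq[b])))

    adjacency: list[tuple[int, int, float, str]] = []
    all_pairs = edge_evidence | junction_evidence | set(tri_counts)
    for pair in sorted(all_pairs):
        if pair in edge_evidence:
            adjacency.append((*pair, 1.0, "edge"))
        elif pair in junction_evidence:
            adjacency.append((*pair, 0.5, "fourfold-vertex"))
        elif tri_counts.get(pair, 0) >= 2:
            adjacency.append((*pair, 1.0, "edge"))
        else:
            logger.debug("dropping ambiguous contact %s", pair)

    return TissueFrame(
        frame_index=frame_index, time=time, ids=ids, centers=centers,
        areas=areas, outermost=outermost, adjacency=adjacency,
        pixel_size=pixel_size, area_source="pixel_count", label_image=label)


def frame_from_tiling(tiling, frame_index: int = 0, time: float = 0.0,
                      pixel_size: float = 1.0) -> TissueFrame:
    """Exact TissueFrame from simulator geometry (centers = centroids)."""
    ids = np.asarray(sorted(tiling.cells), dtype=int)
    centers = np.array([tiling.cell_centroid(c) for c in ids])
    areas = np.array([tiling.cell_area(c) for c in ids])
    boundary = tiling.boundary_cells()
    outermost = np.array([c in boundary for c in ids])
    return TissueFrame(
        frame_index=frame_index, time=time, ids=ids, centers=centers,
        areas=areas, outermost=outermost, adjacency=tiling.adjacency(),
        pixel_size=pixel_size, area_source="polygon")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

CELL_COLUMNS = ["id", "x", "y", "area_px", "outermost"]
ADJ_COLUMNS = ["i", "k", "omega", "contact_kind"]


def write_frame_tables(frame: TissueFrame, path) -> None:
    """Write ``cells.csv`` and ``adjacency.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    order = np.argsort(frame.ids)
    cells = pd.DataFrame({
        "id": frame.ids[order],
        "x": frame.centers[order, 0],
        "y": frame.centers[order, 1],
        "area_px": frame.areas[order],
        "outermost": frame.outermost[order].astype(int),
    })
    cells.to_csv(path / "cells.csv", index=False)
    rows = []
    for i, k, om, kind in frame.adjacency:
        rows.append((i, k, om, kind))
        rows.append((k, i, om, kind))
    adj = pd.DataFrame(sorted(rows), columns=ADJ_COLUMNS)
    adj.to_csv(path / "adjacency.csv", index=False)


def read_frame_tables(path, frame_index: int = 0, time: float = 0.0,
                      pixel_size: float = 1.0) -> TissueFrame:
    path = Path(path)
    cells = pd.read_csv(path / "cells.csv")
    adj = pd.read_csv(path / "adjacency.csv")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise SchemaError(f"cells table is missing column {col!r}")
    for col in ADJ_COLUMNS:
        if col not in adj.columns:
            raise SchemaError(f"adjacency table is missing column {col!r}")
    bad = set(adj["omega"]) - set(VALID_OMEGA)
    if bad:
        raise SchemaError(f"omega values outside {{1, 0.5}}: {sorted(bad)}")
    # symmetrize: accept (i, k) without (k, i), warn
    seen: dict[tuple[int, int], tuple[float, str]] = {}
    directed: set[tuple[int, int]] = set()
    for row in adj.itertuples(index=False):
        i, k = int(row.i), int(row.k)
        directed.add((i, k))
        key = (min(i, k), max(i, k))
        if key not in seen:
            seen[key] = (float(row.omega), str(row.contact_kind))
    one_sided = sum(1 for (i, k) in directed if (k, i) not in directed)
    if one_sided:
        logger.warning("symmetrized %d one-sided adjacency rows", one_sided)
    adjacency = [(i, k, om, kind) for (i, k), (om, kind) in sorted(seen.items())]
    cells = cells.sort_values("id")
    return TissueFrame(
        frame_index=frame_index, time=time,
        ids=cells["id"].to_numpy(),
        centers=cells[["x", "y"]].to_numpy(float),
        areas=cells["area_px"].to_numpy(float),
        outermost=cells["outermost"].to_numpy().astype(bool),
        adjacency=adjacency, pixel_size=pixel_size,
        area_source="pixel_count")
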