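"""Cell tracking: PIV velocity estimation, center assignment, event
detection and Lagrangian ROI maintenance.

Cells are matched between consecutive frames by advecting frame-t centers
with a velocity field, then solving the global linear assignment problem
that minimizes total squared center distance (pairs beyond a cutoff are
forbidden). Appearing cells are resolved as division daughters — the
neighboring matched cell with the largest area decrease is the mother —
and disappearing interior cells as apoptoses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve

from .tiling_io import ROISpec, TissueFrame

logger = logging.getLogger(__name__)


@dataclass
class VelocityField:
    """2D velocity samples on a regular grid (px/min)."""

    origin: tuple[float, float]        # (x0, y0) of sample [0, 0]
    spacing: float                     # px between samples
    vectors: np.ndarray                # (ny, nx, 2)
    valid: np.ndarray                  # (ny, nx) bool mask
    source: str = "PIV"                # "PIV" | "ground-truth"
    interpolated: np.ndarray | None = None  # SD-filter replacements

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def sample_positions(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.vectors.shape[:2]
        gx = self.origin[0] + self.spacing * np.arange(nx)
        gy = self.origin[1] + self.spacing * np.arange(ny)
        return gx, gy

    def at(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear velocity at positions (n, 2); nearest valid fallback."""
        xy = np.atleast_2d(np.asarray(xy, float))
        gx, gy = self.sample_positions()
        fx = np.clip((xy[:, 0] - gx[0]) / self.spacing, 0, len(gx) - 1)
        fy = np.clip((xy[:, 1] - gy[0]) / self.spacing, 0, len(gy) - 1)
        x0 = np.clip(fx.astype(int), 0, len(gx) - 2)
        y0 = np.clip(fy.astype(int), 0, len(gy) - 2)
        tx = (fx - x0)[:, None]
        ty = (fy - y0)[:, None]
        v = self.vectors
        out = ((1 - tx) * (1 - ty) * v[y0, x0]
               + tx * (1 - ty) * v[y0, x0 + 1]
               + (1 - tx) * ty * v[y0 + 1, x0]
               + tx * ty * v[y0 + 1, x0 + 1])
        # fall back to the nearest valid sample where any corner is invalid
    # (masked vectors are never silently zero-filled)
        corner_ok = (self.valid[y0, x0] & self.valid[y0, x0 + 1]
                     & self.valid[y0 + 1, x0] & self.valid[y0 + 1, x0 + 1])
        if not np.all(corner_ok):
            vy, vx = np.nonzero(self.valid)
            if vy.size == 0:
                raise ValueError("velocity field has no valid vectors")
            pos_valid = np.column_stack([gx[vx], gy[vy]])
            for j in np.nonzero(~corner_ok)[0]:
                d2 = np.sum((pos_valid - xy[j]) ** 2, axis=1)
                out[j] = self.vectors[vy[np.argmin(d2)], vx[np.argmin(d2)]]
            logger.debug("velocity undefined at %d centers; used nearest "
                         "valid vector", int(np.sum(~corner_ok)))
        return out


@dataclass
class Lineage:
    """Frame-pair correspondence: id map + division/apoptosis records.

    ``mapping`` holds surviving cells only (injective); division mothers and
    daughters are kept separately so mother ids never appear as survivors.
    """

    frame_pair: tuple[int, int]
    mapping: dict[int, int]
    divisions: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    apoptoses: list[int] = field(default_factory=list)
    left_field: list[int] = field(default_factory=list)
    unresolved: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValueError("lineage id map must be injective")

    @property
    def mothers(self) -> set[int]:
        return {m for m, _ in self.divisions}

    @property
    def daughters(self) -> set[int]:
        return {d for _, ds in self.divisions for d in ds}

    def propagate(self, members: set[int]) -> set[int]:
        """ROI membership at the next frame (daughters replace mothers)."""
        out: set[int] = set()
        for c in members:
            if c in self.mapping:
                out.add(self.mapping[c])
        for m, (d1, d2) in self.divisions:
            if m in members:
                out.update((d1, d2))
        return out


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _subpixel_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """3-point Gaussian fit around the integer correlation peak."""
    r, c = peak
    out = [float(r), float(c)]
    for axis, j in ((0, r), (1, c)):
        if j <= 0 or j >= corr.shape[axis] - 1:
            continue
        if axis == 0:
            cm, c0, cp = corr[j - 1, c], corr[j, c], corr[j + 1, c]
        else:
            cm, c0, cp = corr[r, j - 1], corr[r, j], corr[r, j + 1]
        if min(cm, c0, cp) <= 0:
            denom = cm - 2 * c0 + cp
            if denom != 0:
                out[axis] = j + 0.5 * (cm - cp) / denom
            continue
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2 * l0 + lp
        if denom != 0:
            out[axis] = j + 0.5 * (lm - lp) / denom
    return out[0], out[1]


def piv(image_t: np.ndarray, image_t1: np.ndarray, window: int = 64,
        step: int = 16, sd_filter_n: float = 3.0, dt: float = 1.0
        ) -> VelocityField:
    """Single-pass cross-correlation PIV on an image pair.

    Per interrogation window the displacement is the (sub-pixel) peak of the
    normalized FFT cross-correlation with the same window in the second
    image. Vectors beyond ``sd_filter_n`` standard deviations from the field
    mean are replaced by the local median of their valid neighbors and
    flagged interpolated. Velocities are displacement / dt.
    """
    a = np.asarray(image_t, float)
    b = np.asarray(image_t1, float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if min(a.shape) < 2 * window:
        raise ValueError("images must be at least 2x the window size")
    h, w = a.shape
    rows = np.arange(0, h - window + 1, step)
    cols = np.arange(0, w - window + 1, step)
    ny, nx = len(rows), len(cols)
    disp = np.zeros((ny, nx, 2))
    valid = np.zeros((ny, nx), bool)
    for iy, r0 in enumerate(rows):
        for ix, c0 in enumerate(cols):
            wa = a[r0:r0 + window, c0:c0 + window]
            wb = b[r0:r0 + window, c0:c0 + window]
            sa, sb = wa.std(), wb.std()
            if sa == 0 or sb == 0:
                continue  # flat window: masked invalid
            wa = (wa - wa.mean()) / sa
            wb = (wb - wb.mean()) / sb
            corr = fftconvolve(wb, wa[::-1, ::-1], mode="full")
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            pr, pc = _subpixel_peak(corr, pk)
            dy = pr - (window - 1)
            dx = pc - (window - 1)
            if abs(dx) > window / 2 or abs(dy) > window / 2:
                continue
            disp[iy, ix] = (dx, dy)
            valid[iy, ix] = True

    interpolated = np.zeros((ny, nx), bool)
    if valid.sum() >= 4:
        mean = disp[valid].mean(axis=0)
        std = disp[valid].std(axis=0)
        outlier = valid & np.any(
            np.abs(disp - mean) > sd_filter_n * np.maximum(std, 1e-12), axis=2)
        for iy, ix in zip(*np.nonzero(outlier)):
            y0, y1 = max(0, iy - 1), min(ny, iy + 2)
            x0, x1 = max(0, ix - 1), min(nx, ix + 2)
            block_ok = valid[y0:y1, x0:x1] & ~outlier[y0:y1, x0:x1]
            if block_ok.any():
                disp[iy, ix] = np.median(
                    disp[y0:y1, x0:x1][block_ok], axis=0)
            else:
                disp[iy, ix] = mean
            interpolated[iy, ix] = True

    center_off = (window - 1) / 2.0
    return VelocityField(
        origin=(float(cols[0] + center_off), float(rows[0] + center_off)),
        spacing=float(step), vectors=disp / dt, valid=valid,
        source="PIV", interpolated=interpolated)


# ---------------------------------------------------------------------------
# assignment and event detection
# ---------------------------------------------------------------------------

def match_cells(frame_t: TissueFrame, frame_t1: TissueFrame,
                velocity: VelocityField | None = None,
                max_dist: float = 400.0, dt: float | None = None) -> Lineage:
    """Globally optimal one-to-one center assignment (squared distance).

    Frame-t centers are first advected by the velocity field; pairs farther
    apart than ``max_dist`` px get infinite cost. Returns a partial lineage:
    unmatched cells are recorded but not yet resolved into events.
    """
    if frame_t.n_cells == 0 or frame_t1.n_cells == 0:
        raise ValueError("frames must be nonempty")
    if dt is None:
        dt = frame_t1.time - frame_t.time
        if dt <= 0:
            dt = 1.0
    pts_t = frame_t.centers.copy()
    if velocity is not None:
        pts_t = pts_t + velocity.at(pts_t) * dt
    pts_t1 = frame_t1.centers
    n, m = len(pts_t), len(pts_t1)
    d2 = np.sum((pts_t[:, None, :] - pts_t1[None, :, :]) ** 2, axis=2)
    big = 1e12
    cost = np.where(d2 > max_dist ** 2, big, d2)
    # dummy column per old cell at the cutoff penalty: leaving a cell
    # unmatched must beat any far-fetched pairing
    dummies = np.full((n, n), big)
    np.fill_diagonal(dummies, max_dist ** 2)
    rows, cols = linear_sum_assignment(np.hstack([cost, dummies]))
    mapping: dict[int, int] = {}
    for r, c in zip(rows, cols):
        if c < m and cost[r, c] < big:
            mapping[int(frame_t.ids[r])] = int(frame_t1.ids[c])
    lin = Lineage(frame_pair=(frame_t.frame_index, frame_t1.frame_index),
                  mapping=mapping)
    matched_t = set(mapping)
    matched_t1 = set(mapping.values())
    for cid in frame_t.ids:
        if int(cid) not in matched_t:
            lin.unresolved.append((int(cid), "unmatched-old"))
    for cid in frame_t1.ids:
        if int(cid) not in matched_t1:
            lin.unresolved.append((int(cid), "unmatched-new"))
    return lin


def detect_events(lineage: Lineage, frame_t: TissueFrame,
                  frame_t1: TissueFrame) -> Lineage:
    """Resolve unmatched cells into divisions, apoptoses or departures.

    Each unmatched-new cell's mother is the neighboring matched cell with
    the largest area decrease over the interval (ties: smallest center
    distance, then lowest id). Unmatched-old interior cells are apoptoses;
    unmatched-old outermost cells left the field.
    """
    inv = {v: k for k, v in lineage.mapping.items()}
    unresolved_left: list[tuple[int, str]] = []
    for cid, reason in lineage.unresolved:
        if reason != "unmatched-new":
            continue
        best = None  # (area_decrease, -distance, -id) maximized
        for k, _w, _kind in frame_t1.neighbors(cid):
            if k not in inv:
                continue
            prev = inv[k]
            decrease = frame_t.area(prev) - frame_t1.area(k)
            dist = float(np.linalg.norm(frame_t1.center(cid) - frame_t1.center(k)))
            cand = (decrease, -dist, -prev)
            if best is None or cand > best[0]:
                best = (cand, prev, k)
        if best is None:
            logger.warning("new cell %d has no matched neighbor; unresolved", cid)
            unresolved_left.append((cid, "no-matched-neighbor"))
            continue
        _, mother, sibling = best
        lineage.mapping.pop(mother)
        inv.pop(sibling)
        lineage.divisions.append((mother, (min(sibling, cid), max(sibling, cid))))
    for cid, reason in lineage.unresolved:
        if reason != "unmatched-old":
            continue
        if cid in lineage.mothers:
            continue
        if frame_t.is_outermost(cid):
            lineage.left_field.append(cid)
        else:
            lineage.apoptoses.append(cid)
    lineage.unresolved = unresolved_left
    return lineage


def track_cells(frames: list[TissueFrame],
                velocities: list[VelocityField] | None = None,
                max_dist: float = 400.0) -> list[Lineage]:
    """Match + event detection over a whole frame sequence."""
    out = []
    for j in range(len(frames) - 1):
        vel = velocities[j] if velocities is not None else None
        lin = match_cells(frames[j], frames[j + 1], velocity=vel,
                          max_dist=max_dist)
        out.append(detect_events(lin, frames[j], frames[j + 1]))
    return out


def track_rois(initial: TissueFrame, lineages: list[Lineage],
               tile: float = 120.0) -> list[ROISpec]:
    """Lagrangian ROIs from a square tiling of the initial frame.

    Initial membership = cells whose centers fall inside each tile; later
    membership follows the lineage only (daughters replace mothers,
    apoptotic cells drop out) so cells never transfer between ROIs.
    """
    xmin, ymin = initial.centers.min(axis=0)
    tiles: dict[tuple[int, int], set[int]] = {}
    for cid, ctr in zip(initial.ids, initial.centers):
        key = (int((ctr[1] - ymin) // tile), int((ctr[0] - xmin) // tile))
        tiles.setdefault(key, set()).add(int(cid))
    rois = []
    for roi_id, key in enumerate(sorted(tiles)):
        members = [tiles[key]]
        for lin in lineages:
            members.append(lin.propagate(members[-1]))
        if not members[-1]:
            logger.info("ROI %d emptied; closed", roi_id)
        rois.append(ROISpec(roi_id=roi_id, origin_tile=key,
                            member_cells=members))
    return rois
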