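"""Flow advection and topological events (T1, division, T2) on tilings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._tiling import Tiling, polygon_area, polygon_centroid


@dataclass
class FlowSpec:
    """Prescribed smooth tissue flow.

    kind "affine": v(x) = gradient @ x + translation, with ``gradient`` the
    velocity-gradient matrix (1/min) and ``translation`` in px/min.
    ``gradient`` may be a (2, 2) array or a callable t -> (2, 2) array.
    kind "smooth-grid": velocity sampled on a coarse grid, bilinearly
    interpolated; ``grid_x``/``grid_y`` are 1D sample coordinates and
    ``grid_v`` has shape (ny, nx, 2) in px/min.
    """

    kind: str = "affine"
    gradient: np.ndarray | Callable[[float], np.ndarray] | None = None
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    grid_v: np.ndarray | None = None

    def gradient_at(self, t: float) -> np.ndarray:
        if self.kind != "affine":
            raise ValueError("gradient_at is defined for affine flows only")
        g = self.gradient
        if g is None:
            return np.zeros((2, 2))
        return np.asarray(g(t) if callable(g) else g, float)

    def velocity(self, xy: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Velocity (px/min) at positions ``xy`` of shape (n, 2)."""
        xy = np.atleast_2d(np.asarray(xy, float))
        if self.kind == "affine":
            gv = self.gradient_at(t)
            return xy @ gv.T + self.translation
        interp = RegularGridInterpolator(
            (self.grid_y, self.grid_x), self.grid_v,
            bounds_error=False, fill_value=None)
        return interp(np.column_stack([xy[:, 1], xy[:, 0]]))


@dataclass
class EventRecord:
    """One logged topological event between frames ``frame`` and ``frame+1``."""

    frame: int
    kind: str                         # "T1" | "division" | "apoptosis"
    cells: tuple[int, ...]            # participants at the event's start
    mother: int | None = None
    daughters: tuple[int, int] | None = None
    axis_angle: float | None = None
    lost_pair: tuple[int, int] | None = None    # T1: neighbors losing contact
    gained_pair: tuple[int, int] | None = None  # T1: neighbors gaining contact


def advect(tiling: Tiling, flow: FlowSpec, dt: float, t: float = 0.0) -> Tiling:
    """Move every vertex by its local velocity * dt; adjacency unchanged.

    For affine flows this is the exact map x -> (I + grad_v dt) x + u dt,
    so every center-to-center link transforms by F = I + grad_v dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = tiling.copy()
    if flow.kind == "affine":
        gv = flow.gradient_at(t)
        f = np.eye(2) + gv * dt
        out.points = tiling.points @ f.T + flow.translation * dt
    else:
        out.points = tiling.points + flow.velocity(tiling.points, t) * dt
    xmin, ymin, xmax, ymax = tiling.box
    corners = np.array([[xmin, ymin], [xmax, ymin], [xmin, ymax],
                        [xmax, ymax]], float)
    moved = corners + flow.velocity(corners, t) * dt
    out.box = (float(moved[:, 0].min()), float(moved[:, 1].min()),
               float(moved[:, 0].max()), float(moved[:, 1].max()))
    for cid, loop in out.cells.items():
        if polygon_area(out.points[loop]) <= 0:
            raise ValueError("flow too strong for dt: cell inversion")
    return out


def _third_cell(tiling: Tiling, v: int, exclude: tuple[int, int]) -> int | None:
    cells = tiling.vertex_cells(v) - set(exclude)
    if len(cells) != 1:
        return None
    return cells.pop()


def t1_candidates_with_cells(tiling: Tiling
                             ) -> list[tuple[tuple[int, int], tuple[int, int, int, int]]]:
    """Interior trivalent edges eligible for a T1 flip.

    Returns ``[((v1, v2), (a, b, c, d)), ...]`` where a, b lose contact and
    c, d gain it.
    """
    em = tiling.edge_map()
    boundary = tiling.boundary_cells()
    vert_cells: dict[int, set[int]] = {}
    for cid, loop in tiling.cells.items():
        for v in loop:
            vert_cells.setdefault(v, set()).add(cid)
    out = []
    for (v1, v2), cells in em.items():
        if len(cells) != 2:
            continue
        a, b = cells
        if a in boundary or b in boundary:
            continue
        cc = vert_cells[v1] - {a, b}
        dd = vert_cells[v2] - {a, b}
        if len(cc) != 1 or len(dd) != 1:
            continue
        c, d = cc.pop(), dd.pop()
        if c == d or c in boundary or d in boundary:
            continue
        out.append(((v1, v2), (a, b, c, d)))
    return out


def t1_candidates(tiling: Tiling) -> list[tuple[int, int]]:
    """Interior trivalent edges eligible for a T1 flip (vertex-id pairs)."""
    return [edge for edge, _cells in t1_candidates_with_cells(tiling)]


def apply_t1(tiling: Tiling, edge: tuple[int, int], frame: int = 0,
             new_length: float | None = None,
             relax_area: bool = False,
             target_length: float | None = None,
             metric: np.ndarray | None = None) -> tuple[Tiling, EventRecord]:
    """Flip the edge ``(v1, v2)``: cells A,B lose contact, C,D gain it.

    With ``relax_area`` the tissue around the gaining cells is locally
    relaxed until the gained center-to-center link x_C - x_D has the same
    norm as the lost link x_A - x_B (measured before the flip), so the
    rearrangement changes no area and its texture-trace contribution
    vanishes (Tr R = 0). ``metric`` optionally supplies an SPD matrix W
    (typically the inverse of the tissue's texture tensor) defining the
    norm |l|_W = sqrt(l^T W l): matching links in the texture metric rather
    than the Euclidean one is what keeps Tr(M^-1 DeltaM) = 0 exactly even
    in anisotropic tissue. ``target_length`` overrides the lost-link norm
    (in the same metric).
    """
    v1, v2 = edge
    em = tiling.edge_map()
    key = (v1, v2) if v1 < v2 else (v2, v1)
    cells = em.get(key)
    if cells is None or len(cells) != 2:
        raise ValueError("T1 requires an interior edge shared by two cells")
    a, b = cells
    c = _third_cell(tiling, v1, (a, b))
    d = _third_cell(tiling, v2, (a, b))
    if c is None or d is None or c == d:
        raise ValueError("T1 endpoints must be trivalent with distinct third cells")

    w_metric = np.eye(2) if metric is None else np.asarray(metric, float)

    def wnorm(vec: np.ndarray) -> float:
        return float(np.sqrt(vec @ w_metric @ vec))

    target = (float(target_length) if target_length is not None else
              wnorm(tiling.cell_centroid(a) - tiling.cell_centroid(b)))

    p1, p2 = tiling.points[v1], tiling.points[v2]
    m = 0.5 * (p1 + p2)
    ev = p2 - p1
    ell0 = float(np.linalg.norm(ev))
    perp = np.array([-ev[1], ev[0]]) / ell0
    # v1 stays with cell A: orient perp toward A's centroid
    if np.dot(perp, tiling.cell_centroid(a) - m) < 0:
        perp = -perp

    def build(ell: float) -> Tiling:
        out = tiling.copy()
        out.points[v1] = m + 0.5 * ell * perp
        out.points[v2] = m - 0.5 * ell * perp
        # topology: membership checks against the *pre-flip* loops
        set_a = set(tiling.cells[a])
        set_b = set(tiling.cells[b])
        out.cells[a] = [v for v in out.cells[a] if v != v2]
        out.cells[b] = [v for v in out.cells[b] if v != v1]
        # C gains v2 next to v1 on the B side
        loop_c = out.cells[c]
        j = loop_c.index(v1)
        prev = loop_c[j - 1]
        if prev in set_b:
            loop_c.insert(j, v2)          # ... prev, v2, v1 ...
        else:
            loop_c.insert(j + 1, v2)      # ... v1, v2, next ...
        # D gains v1 next to v2 on the A side
        loop_d = out.cells[d]
        j = loop_d.index(v2)
        prev = loop_d[j - 1]
        if prev in set_a:
            loop_d.insert(j, v1)
        else:
            loop_d.insert(j + 1, v1)
        return out

    ell = float(new_length) if new_length is not None else ell0
    out = build(ell)
    out.validate()
    if relax_area:
        out = relax_gained_link(out, c, d, (v1, v2), target, metric=metric)
    rec = EventRecord(frame=frame, kind="T1", cells=(a, b, c, d),
                      lost_pair=(min(a, b), max(a, b)),
                      gained_pair=(min(c, d), max(c, d)))
    return out, rec


def relax_gained_link(tiling: Tiling, c: int, d: int,
                      pinned: tuple[int, int], target: float,
                      metric: np.ndarray | None = None) -> Tiling:
    """Translate the vertex sets of cells ``c`` and ``d`` toward or away
    from each other until their center-to-center link has norm ``target``.

    The two ``pinned`` vertices (the shared new edge) stay put; surrounding
    cells deform slightly, which is cell shape change, not rearrangement.
    The norm is |l|_W = sqrt(l^T W l) with W = ``metric`` (identity if not
    given). Raises if the target is unreachable within the locality bounds
    (total travel <= 40% of the current separation; no affected cell may
    lose more than 70% of its area).
    """
    w_metric = np.eye(2) if metric is None else np.asarray(metric, float)

    def wnorm(vec: np.ndarray) -> float:
        return float(np.sqrt(vec @ w_metric @ vec))

    out = tiling
    verts_c = [v for v in out.cells[c] if v not in pinned]
    verts_d = [v for v in out.cells[d] if v not in pinned]
    moved = set(verts_c) | set(verts_d)
    affected = [cid for cid, lp in out.cells.items() if moved & set(lp)]
    area0 = {cid: out.cell_area(cid) for cid in affected}

    def acceptable(tl: Tiling) -> bool:
        try:
            tl.validate()
        except ValueError:
            return False
        return all(tl.cell_area(cid) > 0.3 * area0[cid] for cid in affected)

    scale = float(np.linalg.norm(out.cell_centroid(c) - out.cell_centroid(d)))
    damp = 0.4
    travel = 0.0
    max_travel = 0.4 * scale  # keep the relaxation local (px)
    converged = False
    for _ in range(200):
        sep = out.cell_centroid(c) - out.cell_centroid(d)
        gapval = wnorm(sep) - target
        if abs(gapval) < 1e-9 * target:
            converged = True
            break
        u = sep / np.linalg.norm(sep)
        step = float(np.clip(damp * gapval * scale / target,
                             -0.1 * scale, 0.1 * scale))
        if travel + abs(step) > max_travel:
            break
        trial = out.copy()
        trial.points[verts_c] -= step * u
        trial.points[verts_d] += step * u
        if not acceptable(trial):
            damp *= 0.5
            if damp < 1e-4:
                break
            continue
        new_gap = wnorm(trial.cell_centroid(c)
                        - trial.cell_centroid(d)) - target
        if abs(new_gap) >= abs(gapval):
            damp *= 0.5
            if damp < 1e-4:
                break
            continue
        out = trial
        travel += abs(step)
    if not converged:
        raise ValueError("link relaxation did not converge")
    out.validate()
    return out


def _segment_crossings(poly: np.ndarray, point: np.ndarray, direction: np.ndarray):
    """Intersections of an infinite line with polygon edges.

    Returns list of (edge_index, s, xy) with s the fractional position along
    the edge, excluding near-vertex hits.
    """
    n = len(poly)
    hits = []
    d = direction / np.linalg.norm(direction)
    nrm = np.array([-d[1], d[0]])
    sd = (poly - point) @ nrm  # signed distance of each vertex to the line
    for j in range(n):
        s0, s1 = sd[j], sd[(j + 1) % n]
        if s0 == s1:
            continue
        s = s0 / (s0 - s1)
        if 0.02 <= s <= 0.98 and (s0 > 0) != (s1 > 0):
            xy = poly[j] + s * (poly[(j + 1) % n] - poly[j])
            hits.append((j, float(s), xy))
    return hits


def apply_division(tiling: Tiling, cell: int, axis_angle: float | None = None,
                   frame: int = 0, rng: np.random.Generator | None = None
                   ) -> tuple[Tiling, EventRecord]:
    """Split ``cell`` by a line through its centroid.

    ``axis_angle`` is the angle of the *division plane* (the cut line); by
    default the cut runs perpendicular to the cell's long axis. Two daughter
    cells with fresh ids share the new edge; neighbors sharing the two cut
    edges receive the new vertices. Total area is conserved exactly.
    """
    if cell not in tiling.cells:
        raise ValueError(f"no such cell: {cell}")
    poly = tiling.cell_polygon(cell)
    ctr = polygon_centroid(poly)
    if axis_angle is None:
        # long axis from the loop's second moment; cut perpendicular to it
        q = poly - ctr
        cov = q.T @ q
        w, v = np.linalg.eigh(cov)
        long_axis = v[:, int(np.argmax(w))]
        axis_angle = float(np.arctan2(long_axis[1], long_axis[0]) + np.pi / 2)

    em = tiling.edge_map()
    loop = tiling.cells[cell]
    n = len(loop)
    for attempt in range(12):
        ang = axis_angle + attempt * np.deg2rad(5.0)
        d = np.array([np.cos(ang), np.sin(ang)])
        hits = _segment_crossings(poly, ctr, d)
        if len(hits) == 2:
            break
    else:
        raise ValueError(f"cannot find a valid division line for cell {cell}")

    out = tiling.copy()
    (j1, _, xy1), (j2, _, xy2) = hits
    w1 = out.add_vertex(xy1)
    w2 = out.add_vertex(xy2)
    # daughter loops: w1 -> (j1+1 .. j2) -> w2 and w2 -> (j2+1 .. j1) -> w1
    def arc(fr: int, to: int) -> list[int]:
        idx = []
        j = (fr + 1) % n
        while True:
            idx.append(loop[j])
            if j == to:
                break
            j = (j + 1) % n
        return idx

    d1_loop = [w1] + arc(j1, j2) + [w2]
    d2_loop = [w2] + arc(j2, j1) + [w1]
    d1 = out.next_cell_id
    d2 = out.next_cell_id + 1
    out.next_cell_id += 2
    del out.cells[cell]
    out.cells[d1] = d1_loop
    out.cells[d2] = d2_loop

    # insert the new vertices into the neighbors sharing the cut edges
    for (j, w) in ((j1, w1), (j2, w2)):
        va, vb = loop[j], loop[(j + 1) % n]
        key = (va, vb) if va < vb else (vb, va)
        for nb in em.get(key, []):
            if nb == cell:
                continue
            lp = out.cells[nb]
            # in the neighbor the edge runs vb -> va; insert between them
            for jj in range(len(lp)):
                a0, b0 = lp[jj], lp[(jj + 1) % len(lp)]
                if {a0, b0} == {va, vb}:
                    lp.insert(jj + 1, w)
                    break
    out.validate()
    rec = EventRecord(frame=frame, kind="division", cells=(cell,),
                      mother=cell, daughters=(d1, d2), axis_angle=axis_angle)
    return out, rec


def apply_t2(tiling: Tiling, cell: int, frame: int = 0) -> tuple[Tiling, EventRecord]:
    """Remove ``cell`` (apoptosis/T2): its loop collapses to its centroid.

    Neighbors absorb the vacated area exactly; all former neighbors share
    the collapsed vertex, so non-consecutive ring neighbors become
    vertex-only (omega = 1/2) contacts.
    """
    if cell not in tiling.cells:
        raise ValueError(f"no such cell: {cell}")
    if cell in tiling.boundary_cells():
        raise ValueError("T2 on a boundary cell is not supported")
    out = tiling.copy()
    victim = set(tiling.cells[cell])
    w = out.add_vertex(tiling.cell_centroid(cell))
    neighbors = sorted({
        cid for v in victim for cid in tiling.vertex_cells(v) if cid != cell
    })
    del out.cells[cell]
    for nb in neighbors:
        lp = [w if v in victim else v for v in out.cells[nb]]
        dedup: list[int] = []
        for v in lp:
            if not dedup or dedup[-1] != v:
                dedup.append(v)
        while len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            raise ValueError(f"T2 would degenerate neighbor cell {nb}")
        out.cells[nb] = dedup
    out.validate()
    rec = EventRecord(frame=frame, kind="apoptosis", cells=(cell,))
    return out, rec
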