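"""Ground-truth synthetic tissue movies: flow + seeded topological events.

A scene is a sequence of tilings produced by advecting an initial tiling
with a prescribed smooth flow and applying T1 transitions, divisions and
T2 removals between frames, with every event logged exactly. The scene is
fully reproducible from (config, seed) and provides the ground truth a
tracking/strain pipeline is validated against: the true lineage, the true
velocity field, and the true per-interval deformation gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..tiling_io import TissueFrame, frame_from_tiling, half_links
from ._tiling import Tiling, make_hexagonal_tiling, make_voronoi_tiling
from .events import EventRecord, FlowSpec, advect, apply_division, apply_t1, \
    apply_t2, relax_gained_link, t1_candidates_with_cells
from .raster import rasterize, skeleton_image


@dataclass
class SceneConfig:
    tiling_kind: str = "voronoi"            # "voronoi" | "hexagonal"
    n_cells: int = 200                       # voronoi
    lloyd_steps: int = 5
    n_rows: int = 9                          # hexagonal
    n_cols: int = 9
    spacing: float = 20.0
    flow: FlowSpec = field(default_factory=FlowSpec)
    n_intervals: int = 5
    dt: float = 1.0                          # minutes
    t1_per_interval: int = 0
    divisions_per_interval: int = 0
    t2_per_interval: int = 0
    t1_relax: bool = True                    # area-preserving rearrangements
    division_axis: str = "long_axis"         # or "random"
    pixel_size: float = 1.0


@dataclass
class SyntheticScene:
    config: SceneConfig
    seed: int
    tilings: list[Tiling]
    frames: list[TissueFrame]
    events: list[EventRecord]
    grad_v: list[np.ndarray]                 # truth velocity gradient / interval

    @property
    def n_frames(self) -> int:
        return len(self.tilings)

    @property
    def dt(self) -> float:
        return self.config.dt

    def true_deformation_gradient(self, interval: int) -> np.ndarray:
        """Exact F for the advection step of ``interval`` (affine flows)."""
        return np.eye(2) + self.grad_v[interval] * self.config.dt

    def events_in(self, interval: int) -> list[EventRecord]:
        return [e for e in self.events if e.frame == interval]

    def true_lineage(self, interval: int):
        from ..tracking import Lineage  # local import: no module cycle
        frame_t = self.frames[interval]
        mapping = {int(c): int(c) for c in frame_t.ids}
        divisions, apoptoses = [], []
        for ev in self.events_in(interval):
            if ev.kind == "division":
                mapping.pop(ev.mother, None)
                divisions.append((ev.mother, ev.daughters))
            elif ev.kind == "apoptosis":
                mapping.pop(ev.cells[0], None)
                apoptoses.append(ev.cells[0])
        return Lineage(frame_pair=(interval, interval + 1), mapping=mapping,
                       divisions=divisions, apoptoses=apoptoses)

    def movie_frame(self) -> tuple[tuple[float, float], tuple[int, int]]:
        """Common camera frame (origin, raster shape) covering all frames."""
        boxes = np.array([t.box for t in self.tilings])
        xmin, ymin = boxes[:, 0].min(), boxes[:, 1].min()
        xmax, ymax = boxes[:, 2].max(), boxes[:, 3].max()
        px = self.config.pixel_size
        shape = (int(np.ceil((ymax - ymin) / px)) + 1,
                 int(np.ceil((xmax - xmin) / px)) + 1)
        return (float(xmin), float(ymin)), shape

    def label_image(self, frame: int) -> np.ndarray:
        origin, shape = self.movie_frame()
        return rasterize(self.tilings[frame], self.config.pixel_size,
                         shape=shape, origin=origin)

    def skeleton(self, frame: int) -> np.ndarray:
        return skeleton_image(self.label_image(frame))

    def truth_velocity(self, interval: int, step: float = 16.0):
        """Sampled ground-truth velocity grid for one interval."""
        from ..tracking import VelocityField
        xmin, ymin, xmax, ymax = self.tilings[interval].box
        gx = np.arange(xmin, xmax + step, step)
        gy = np.arange(ymin, ymax + step, step)
        xx, yy = np.meshgrid(gx, gy)
        pos = np.column_stack([xx.ravel(), yy.ravel()])
        flow = replace(self.config.flow)
        if flow.kind == "affine":
            flow = replace(flow, gradient=self.grad_v[interval])
        v = flow.velocity(pos, t=interval * self.config.dt)
        vec = v.reshape(len(gy), len(gx), 2)
        return VelocityField(origin=(float(gx[0]), float(gy[0])), spacing=float(step),
                             vectors=vec, valid=np.ones(vec.shape[:2], bool),
                             source="ground-truth")


def _initial_tiling(config: SceneConfig, seed: int) -> Tiling:
    if config.tiling_kind == "hexagonal":
        return make_hexagonal_tiling(config.n_rows, config.n_cols, config.spacing)
    if config.tiling_kind == "voronoi":
        return make_voronoi_tiling(config.n_cells, seed=seed,
                                   lloyd_steps=config.lloyd_steps)
    raise ValueError(f"unknown tiling kind {config.tiling_kind!r}")


def _deep_interior(tiling: Tiling) -> set[int]:
    """Cells that are neither boundary nor adjacent to a boundary cell."""
    boundary = tiling.boundary_cells()
    neighbor_of_boundary: set[int] = set()
    for i, k, _w, _kind in tiling.adjacency():
        if i in boundary:
            neighbor_of_boundary.add(k)
        if k in boundary:
            neighbor_of_boundary.add(i)
    return set(tiling.cells) - boundary - neighbor_of_boundary


def simulate(config: SceneConfig, seed: int = 0) -> SyntheticScene:
    """Run the scene: per interval, advect then apply the seeded events.

    Events are instantaneous, applied after advection, at most one per cell
    per interval. Frame t+1 is exactly frame t advected by the flow plus
    the logged events.
    """
    rng = np.random.default_rng(seed)
    tiling = _initial_tiling(config, seed)
    tilings = [tiling]
    events: list[EventRecord] = []
    grad_v: list[np.ndarray] = []

    for it in range(config.n_intervals):
        t = it * config.dt
        if config.flow.kind == "affine":
            gv = config.flow.gradient_at(t)
        else:
            gv = np.zeros((2, 2))
        grad_v.append(gv)
        pre = tiling  # epoch-t geometry, before advection
        cur = advect(tiling, config.flow, config.dt, t=t)

        metric = None
        if config.t1_per_interval and config.t1_relax:
            # mid-interval texture metric: relaxing gained links to the lost
            # link's norm in this metric zeroes Tr(M_mid^-1 DeltaM_R), the
            # trace the strain decomposition attributes to rearrangement
            fr_pre = frame_from_tiling(pre)
            hl_pre = half_links(fr_pre, {int(cc) for cc in fr_pre.ids})
            fr_adv = frame_from_tiling(cur)
            hl_adv = half_links(fr_adv, {int(cc) for cc in fr_adv.ids})
            if not hl_pre.degenerate and not hl_adv.degenerate:
                m_mid = 0.5 * (hl_pre.texture_sum() / hl_pre.n_h
                               + hl_adv.texture_sum() / hl_adv.n_h)
                metric = np.linalg.inv(m_mid)

        # events are kept >= 2 cells apart within an interval so that one
        # event's local relaxation cannot disturb another's link bookkeeping
        used: set[int] = set()
        interval_t1s: list[tuple[tuple[int, int], tuple[int, int],
                                 np.ndarray]] = []

        def mark_used(cells) -> None:
            used.update(cells)
            for i, k, _w, _kind in cur.adjacency():
                if i in cells:
                    used.add(k)
                if k in cells:
                    used.add(i)

        for _ in range(config.t1_per_interval):
            deep = _deep_interior(cur)
            cand = [(edge, cells) for edge, cells in t1_candidates_with_cells(cur)
                    if not (set(cells) & used) and set(cells) <= deep]
            if not cand:
                break
            # T1s occur on short junctions; short edges also keep the
            # gained link close to the lost one, so the relaxation converges
            lengths = np.array([np.linalg.norm(cur.points[e[0]] - cur.points[e[1]])
                                for e, _cells in cand])
            cut = np.quantile(lengths, 0.3)
            short = [cd for cd, ln in zip(cand, lengths) if ln <= cut]
            edge, abcd = short[rng.integers(len(short))]
            a, b = abcd[0], abcd[1]
            # relaxation target: the lost link at epoch t (the vector the
            # strain decomposition will debit), in the texture metric
            lost = pre.cell_centroid(a) - pre.cell_centroid(b)
            w = metric if metric is not None else np.eye(2)
            target = float(np.sqrt(lost @ w @ lost))
            try:
                cur, rec = apply_t1(cur, edge, frame=it,
                                    relax_area=config.t1_relax,
                                    target_length=target, metric=metric)
            except ValueError:
                continue
            events.append(rec)
            interval_t1s.append((rec.gained_pair, edge, lost))
            mark_used(set(rec.cells))

        for _ in range(config.divisions_per_interval):
            deep = sorted(_deep_interior(cur) - used)
            if not deep:
                break
            cell = int(deep[rng.integers(len(deep))])
            angle = None
            if config.division_axis == "random":
                angle = float(rng.uniform(0, np.pi))
            try:
                cur, rec = apply_division(cur, cell, axis_angle=angle, frame=it)
            except ValueError:
                continue
            events.append(rec)
            mark_used({cell, *rec.daughters})

        for _ in range(config.t2_per_interval):
            deep = sorted(_deep_interior(cur) - used)
            if not deep:
                break
            # favor small cells, as T2 does in real tissue
            areas = np.array([cur.cell_area(c) for c in deep])
            cell = int(deep[int(np.argmin(areas))])
            try:
                cur, rec = apply_t2(cur, cell, frame=it)
            except ValueError:
                continue
            events.append(rec)
            mark_used({cell, *rec.cells})

        if interval_t1s and config.t1_relax:
            # fixed-point refinement: the events themselves shift the
            # end-of-interval texture, so re-relax each gained link in the
            # actual mid-interval metric (two passes suffice)
            hl_pre2 = half_links(frame_from_tiling(pre),
                                 {int(cc) for cc in pre.cells})
            m1_pre = hl_pre2.texture_sum() / hl_pre2.n_h
            for _pass in range(2):
                hl_end = half_links(frame_from_tiling(cur),
                                    {int(cc) for cc in cur.cells})
                if hl_end.degenerate:
                    break
                m_mid = 0.5 * (m1_pre + hl_end.texture_sum() / hl_end.n_h)
                w_mid = np.linalg.inv(m_mid)
                for (cpair, pinned, lost) in interval_t1s:
                    tgt = float(np.sqrt(lost @ w_mid @ lost))
                    try:
                        cur = relax_gained_link(cur, cpair[0], cpair[1],
                                                pinned, tgt, metric=w_mid)
                    except ValueError:
                        pass  # keep the first-pass geometry for this event

        tilings.append(cur)
        tiling = cur

    frames = [frame_from_tiling(tl, frame_index=j, time=j * config.dt,
                                pixel_size=config.pixel_size)
              for j, tl in enumerate(tilings)]
    return SyntheticScene(config=config, seed=seed, tilings=tilings,
                          frames=frames, events=events, grad_v=grad_v)
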