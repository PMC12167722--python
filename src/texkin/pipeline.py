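"""End-to-end analysis of a frame sequence: ROIs, link classification,
strain decomposition and validation-ready tidy tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import strain as strain_mod
from .kinematics import KinematicsReport, density_balance, kinematic_check
from .texture import density as texture_density
from .tiling_io import ROISpec, TissueFrame, half_links
from .tracking import Lineage, VelocityField, piv, track_cells, track_rois


@dataclass
class IntervalResult:
    roi_id: int
    interval: int
    rates: strain_mod.StrainRates
    rho_t: float
    rho_t1: float
    div_v: dict[str, float] = field(default_factory=dict)
    topology_free: bool = True
    n_divisions: int = 0
    grad_v_truth: np.ndarray | None = None


@dataclass
class SceneAnalysis:
    results: list[IntervalResult]
    rois: list[ROISpec]
    lineages: list[Lineage]
    dt: float
    variant: str

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "roi": r.roi_id, "interval": r.interval,
                "rho_t": r.rho_t, "rho_t1": r.rho_t1,
                "topology_free": r.topology_free,
                "n_divisions": r.n_divisions,
                "n_c": r.rates.n_c_t, "n_h": r.rates.n_h_t,
                "residual": float(np.linalg.norm(r.rates.residual)),
            }
            for name, t in (("F", r.rates.F), ("G", r.rates.G),
                            ("S", r.rates.S), ("R", r.rates.R),
                            ("D", r.rates.D), ("A", r.rates.A),
                            ("DT", r.rates.D_T)):
                row[f"{name}_xx"] = t[0, 0]
                row[f"{name}_xy"] = t[0, 1]
                row[f"{name}_yx"] = t[1, 0]
                row[f"{name}_yy"] = t[1, 1]
            for route, v in r.div_v.items():
                row[f"divv_{route}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    # -- aligned series for the validation checks -------------------------
    def kinematic_report(self, use_grad_v: str = "texture",
                         tensor_variant: str | None = None
                         ) -> KinematicsReport:
        """Kinematic-equation check for the chosen texture normalization.

        The strain rates grad v and D_T are always the physically measured
        ones (from this analysis's decomposition); ``tensor_variant``
        selects which texture series is inserted into the equation — "M0"
        exposes the unnormalized tensor's failure on dividing ROIs, since
        its growth with cell number cannot be produced by intensive rates.
        ``use_grad_v``: 'texture' (deformation-gradient route) or 'truth'.
        """
        if tensor_variant is None:
            tensor_variant = self.variant
        if tensor_variant == self.variant:
            m_t = [r.rates.M_t for r in self.results]
            m_t1 = [r.rates.M_t1 for r in self.results]
        elif tensor_variant == "M0" and self.variant == "M1":
            m_t = [r.rates.M_t * r.rates.n_h_t for r in self.results]
            m_t1 = [r.rates.M_t1 * r.rates.n_h_t1 for r in self.results]
        else:
            raise ValueError(
                f"cannot derive {tensor_variant} series from {self.variant}")
        if use_grad_v == "texture":
            gv = [(r.rates.F - np.eye(2)) / self.dt for r in self.results]
        elif use_grad_v == "truth":
            gv = [r.grad_v_truth for r in self.results]
        else:
            raise ValueError(use_grad_v)
        d_t = [r.rates.D_T for r in self.results]
        return kinematic_check(
            m_t, m_t1, gv, d_t, self.dt,
            topology_free=[r.topology_free for r in self.results],
            division_counts=[r.n_divisions for r in self.results])

    def density_report(self, routes=("TrG",)) -> KinematicsReport:
        div_routes = {}
        for route in routes:
            if route == "TrG":
                div_routes[route] = np.array(
                    [float(np.trace(r.rates.G)) for r in self.results])
            else:
                div_routes[route] = np.array(
                    [r.div_v.get(route, np.nan) for r in self.results])
        keep = np.all(np.isfinite(np.vstack(list(div_routes.values()))), axis=0)
        return density_balance(
            np.array([r.rho_t for r in self.results])[keep],
            np.array([r.rho_t1 for r in self.results])[keep],
            {k: v[keep] for k, v in div_routes.items()},
            np.array([float(np.trace(r.rates.D_T))
                      for r in self.results])[keep],
            self.dt)


def analyze_frames(frames: list[TissueFrame], lineages: list[Lineage],
                   rois: list[ROISpec] | None = None, dt: float | None = None,
                   variant: str = "M1", rule: str = "division-priority",
                   closure: str = "raw", tile: float = 120.0,
                   velocity_fields: dict[str, list[VelocityField]] | None = None,
                   grad_v_truth: list[np.ndarray] | None = None
                   ) -> SceneAnalysis:
    """Classify links and decompose strain for every (ROI, interval).

    ``velocity_fields`` maps route names (e.g. "PIV", "truth") to one
    velocity field per interval; the ROI-fitted divergence of each route is
    attached to the results. Degenerate ROIs are skipped.
    """
    if dt is None:
        dt = frames[1].time - frames[0].time
    if rois is None:
        rois = track_rois(frames[0], lineages, tile=tile)
    results: list[IntervalResult] = []
    for roi in rois:
        for j in range(len(frames) - 1):
            members_t = roi.members_at(j)
            members_t1 = roi.members_at(j + 1)
            if not members_t or not members_t1:
                continue
            hl_t = half_links(frames[j], members_t, roi_id=roi.roi_id)
            hl_t1 = half_links(frames[j + 1], members_t1, roi_id=roi.roi_id)
            if hl_t.degenerate or hl_t1.degenerate:
                continue
            cls = strain_mod.classify_links(
                hl_t, hl_t1, lineages[j], frames[j], frames[j + 1], rule=rule)
            if len(cls.cons_pairs) < 3:
                continue
            gv_truth = grad_v_truth[j] if grad_v_truth is not None else None
            rates = strain_mod.decompose(cls, dt, variant=variant,
                                         closure=closure, grad_v=gv_truth)
            n_div = sum(1 for m, _d in lineages[j].divisions
                        if m in members_t)
            div_v = {}
            if velocity_fields:
                pts = np.array([frames[j].center(c) for c in members_t])
                bbox = (pts[:, 0].min(), pts[:, 1].min(),
                        pts[:, 0].max(), pts[:, 1].max())
                for route, fields in velocity_fields.items():
                    try:
                        gv, _ = strain_mod.grad_v_from_field(fields[j], bbox)
                        div_v[route] = float(np.trace(gv))
                    except ValueError:
                        div_v[route] = float("nan")
            # densities always from the half-link-normalized tensor
            m1_t = hl_t.texture_sum() / hl_t.n_h
            m1_t1 = hl_t1.texture_sum() / hl_t1.n_h
            results.append(IntervalResult(
                roi_id=roi.roi_id, interval=j, rates=rates,
                rho_t=texture_density(m1_t), rho_t1=texture_density(m1_t1),
                div_v=div_v, topology_free=cls.topology_free(),
                n_divisions=n_div, grad_v_truth=gv_truth))
    return SceneAnalysis(results=results, rois=rois, lineages=lineages,
                         dt=dt, variant=variant)


def analyze_scene(scene, variant: str = "M1", rule: str = "division-priority",
                  closure: str = "raw", tile: float = 120.0,
                  lineage_source: str = "truth", run_piv: bool = False,
                  truth_velocity: bool = True) -> SceneAnalysis:
    """Analyze a synthetic scene against its own ground truth.

    ``lineage_source``: "truth" uses the logged events; "detected" runs the
    tracking pipeline (assignment + division/apoptosis detection).
    """
    frames = scene.frames
    if lineage_source == "truth":
        lineages = [scene.true_lineage(j) for j in range(scene.n_frames - 1)]
    elif lineage_source == "detected":
        vels = [scene.truth_velocity(j) for j in range(scene.n_frames - 1)]
        # no-match cutoff below the neighbor spacing: a chain of
        # neighbor-to-neighbor mismatches must cost more than leaving a
        # divided/dying cell unmatched
        diam = float(np.sqrt(np.mean(frames[0].areas)))
        lineages = track_cells(frames, vels, max_dist=0.8 * diam)
    else:
        raise ValueError(lineage_source)
    velocity_fields: dict[str, list[VelocityField]] = {}
    if truth_velocity:
        velocity_fields["truth"] = [scene.truth_velocity(j)
                                    for j in range(scene.n_frames - 1)]
    if run_piv:
        skels = [scene.skeleton(j) for j in range(scene.n_frames)]
        (ox, oy), _shape = scene.movie_frame()
        fields = []
        for j in range(scene.n_frames - 1):
            vf = piv(skels[j], skels[j + 1], dt=scene.dt)
            vf.origin = (vf.origin[0] + ox, vf.origin[1] + oy)
            fields.append(vf)
        velocity_fields["PIV"] = fields
    return analyze_frames(
        frames, lineages, dt=scene.dt, variant=variant, rule=rule,
        closure=closure, tile=tile,
        velocity_fields=velocity_fields or None,
        grad_v_truth=scene.grad_v)
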