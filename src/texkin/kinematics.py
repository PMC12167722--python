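"""Validation of the cell-shape-tensor kinematic equation and the
cell-number-density balance across measurement routes.

The kinematic equation states that, following a Lagrangian cell group, the
coarse-grained cell shape tensor M evolves as

    dM/dt = (grad v - D_T) M + M (grad v - D_T)^T,

and taking determinants yields the density balance

    d rho / dt + rho div v = (Tr D_T) rho.

Both contain no mechanical parameters, so a correct measurement pipeline
must satisfy them up to O(dt^2) discretization. These checks are the
package's figure-of-merit computations: per-ROI, per-interval left/right
sides, residuals, component-wise regressions and moving-average time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPONENTS = {"xx": (0, 0), "xy": (0, 1), "yy": (1, 1)}


@dataclass
class RegressionStats:
    slope: float
    intercept: float
    r2: float
    rmse: float


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionStats:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        return RegressionStats(np.nan, np.nan, np.nan,
                               float(np.sqrt(np.mean((y - x) ** 2))))
    coef = np.polyfit(x, y, 1)
    pred = np.polyval(coef, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionStats(float(coef[0]), float(coef[1]), r2,
                           float(np.sqrt(np.mean((y - x) ** 2))))


def compare_tensor_series(series_a, series_b) -> dict[str, RegressionStats]:
    """Per-component OLS of series_b against series_a.

    Accepts sequences of 2x2 tensors (keys xx, xy, yy) or of scalars
    (single key "value").
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal shapes")
    if a.ndim == 1:
        return {"value": _ols(a, b)}
    return {name: _ols(a[:, i, j], b[:, i, j])
            for name, (i, j) in COMPONENTS.items()}


@dataclass
class KinematicsReport:
    """LHS/RHS pairs of a kinematic identity plus comparison statistics."""

    lhs: np.ndarray                      # (n, 2, 2) or (n,)
    rhs: np.ndarray
    residual_norm: np.ndarray            # (n,)
    topology_free: np.ndarray            # (n,) bool
    division_counts: np.ndarray          # (n,) int
    stats: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def stats_subset(self, mask) -> dict[str, RegressionStats]:
        mask = np.asarray(mask, bool)
        return compare_tensor_series(self.lhs[mask], self.rhs[mask])


def kinematic_check(m_t, m_t1, grad_v, d_t, dt: float,
                    topology_free=None, division_counts=None
                    ) -> KinematicsReport:
    """Check  DeltaM = [(grad v - D_T) M + M (grad v - D_T)^T] dt  per item.

    ``m_t``/``m_t1`` are aligned per-(ROI, interval) texture tensors under
    Lagrangian correspondence; ``grad_v`` and ``d_t`` the matching velocity
    gradients and topological strain rates. The RHS uses the epoch-t tensor;
    the neglected term is O(dt^2).
    """
    m_t = np.asarray(m_t, float)
    m_t1 = np.asarray(m_t1, float)
    grad_v = np.asarray(grad_v, float)
    d_t = np.asarray(d_t, float)
    if not (m_t.shape == m_t1.shape == grad_v.shape == d_t.shape):
        raise ValueError("misaligned input series")
    n = len(m_t)
    lhs = m_t1 - m_t
    eff = grad_v - d_t
    rhs = (np.einsum("nij,njk->nik", eff, m_t)
           + np.einsum("nij,nkj->nik", m_t, eff)) * dt
    res = np.linalg.norm(lhs - rhs, axis=(1, 2))
    tf = (np.ones(n, bool) if topology_free is None
          else np.asarray(topology_free, bool))
    dc = (np.zeros(n, int) if division_counts is None
          else np.asarray(division_counts, int))
    rep = KinematicsReport(lhs=lhs, rhs=rhs, residual_norm=res,
                           topology_free=tf, division_counts=dc)
    if n >= 3:
        rep.stats["all"] = compare_tensor_series(lhs, rhs)
    if tf.sum() >= 3 and (~tf).sum() >= 3:
        rep.stats["topology_free"] = rep.stats_subset(tf)
        rep.stats["with_events"] = rep.stats_subset(~tf)
    return rep


def density_balance(rho_t, rho_t1, div_v_routes: dict, tr_d_t, dt: float
                    ) -> KinematicsReport:
    """Check  (Delta rho / rho) / dt + div v = Tr D_T  per route.

    ``div_v_routes`` maps route name ("TrG", "PIV", "truth", ...) to the
    per-item velocity divergence; the Lagrangian density change uses the
    mid-interval density. Reports LHS-vs-RHS regressions per route and
    route-vs-route agreement.
    """
    rho_t = np.asarray(rho_t, float)
    rho_t1 = np.asarray(rho_t1, float)
    tr_d_t = np.asarray(tr_d_t, float)
    rho_mid = 0.5 * (rho_t + rho_t1)
    dlog = (rho_t1 - rho_t) / (rho_mid * dt)
    lhs_by_route = {}
    stats = {}
    for name, divv in div_v_routes.items():
        divv = np.asarray(divv, float)
        if divv.shape != rho_t.shape:
            raise ValueError(f"misaligned div v series for route {name!r}")
        lhs = dlog + divv
        lhs_by_route[name] = lhs
        stats[name] = compare_tensor_series(tr_d_t, lhs)["value"]
    routes = sorted(div_v_routes)
    for a in range(len(routes)):
        for b in range(a + 1, len(routes)):
            stats[f"{routes[a]}-vs-{routes[b]}"] = compare_tensor_series(
                np.asarray(div_v_routes[routes[a]], float),
                np.asarray(div_v_routes[routes[b]], float))["value"]
    first = next(iter(lhs_by_route.values()))
    return KinematicsReport(
        lhs=first, rhs=tr_d_t,
        residual_norm=np.abs(first - tr_d_t),
        topology_free=np.zeros(len(rho_t), bool),
        division_counts=np.zeros(len(rho_t), int),
        stats=stats, extra={"lhs_by_route": lhs_by_route, "dlog_rho": dlog})


def moving_average(values, times, window: float) -> np.ndarray:
    """Centered moving average over a time window (same length as input)."""
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    out = np.empty_like(values)
    for j, t in enumerate(times):
        sel = np.abs(times - t) <= window / 2.0
        out[j] = values[sel].mean()
    return out


def kymograph(positions, frames, quantities: dict, axis_extent=None,
              window_px: float = 200.0, step_px: float = 50.0,
              coherence_from: str | None = None) -> pd.DataFrame:
    """Space-time table of moving-window averages along one axis.

    ``positions`` are per-observation coordinates along the chosen axis,
    ``frames`` the per-observation frame indices, and ``quantities`` maps
    column name -> per-observation values (angles may be None and are
    dropped). If ``coherence_from`` names an angle column, a "coherence"
    column |< exp(2 i theta) >| is added per window (1 = aligned cells).
    Windows without data yield NaN, never zero.
    """
    positions = np.asarray(positions, float)
    frames = np.asarray(frames)
    if axis_extent is None:
        axis_extent = (float(positions.min()), float(positions.max()))
    grid = np.arange(axis_extent[0], axis_extent[1] + step_px / 2, step_px)
    rows = []
    for fr in np.unique(frames):
        fsel = frames == fr
        for x0 in grid:
            sel = fsel & (np.abs(positions - x0) <= window_px / 2.0)
            row = {"frame": fr, "position": float(x0), "n": int(sel.sum())}
            for name, vals in quantities.items():
                arr = np.asarray(
                    [v for v, s in zip(vals, sel) if s and v is not None],
                    float)
                if name == coherence_from:
                    row["coherence"] = (
                        float(np.abs(np.mean(np.exp(2j * arr))))
                        if arr.size else np.nan)
                else:
                    row[name] = float(arr.mean()) if arr.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
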