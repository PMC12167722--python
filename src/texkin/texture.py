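"""Texture tensors, pixel second moments and cell-shape summaries.

The texture tensor is a 2x2 symmetric positive tensor built from outer
products of cell-center-to-cell-center half-links; its eigenstructure
approximates the coarse-grained cell shape as an ellipse with area
A = pi |M|^(1/2). Variants differ only in normalization:

    M0 = sum_i (1/2) sum_k w_ik l_ik (x) l_ik   (unnormalized; grows with N_c)
    M1 = M0 / N_h                               (per half-link; ROI-intensive)
    M2 = M0 / N_c                               (per cell)

M3 and M4 are an extension point: they can be registered as callables but
no formula ships by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .tiling_io import HalfLinkSet


class DegenerateROIError(ValueError):
    """The half-link set cannot support a positive-definite tensor."""


class VariantNotConfigured(KeyError):
    """Requested texture variant has no registered formula."""


# extension point: name -> f(m0, n_c, n_h, halflinks) -> (2, 2) array
_VARIANT_REGISTRY: dict[str, Callable] = {}


def register_variant(name: str, func: Callable) -> None:
    _VARIANT_REGISTRY[name] = func


@dataclass
class TextureTensor:
    variant: str
    components: np.ndarray        # (2, 2) symmetric, px^2 (or um^2)
    n_c: int
    n_h: int
    roi_id: int = 0
    frame_index: int = 0

    @property
    def eigenvalues(self) -> np.ndarray:
        """(lambda1, lambda2) with lambda1 >= lambda2."""
        w = np.linalg.eigvalsh(self.components)
        return w[::-1]


def texture(halflinks: HalfLinkSet, variant: str = "M1") -> TextureTensor:
    """Texture tensor of one ROI under the chosen normalization."""
    if halflinks.degenerate:
        raise DegenerateROIError(
            f"ROI {halflinks.roi_id} is degenerate (insufficient half-links)")
    m0 = halflinks.texture_sum()
    n_c, n_h = halflinks.n_c, halflinks.n_h
    if variant == "M0":
        comp = m0
    elif variant == "M1":
        comp = m0 / n_h
    elif variant == "M2":
        comp = m0 / n_c
    elif variant in _VARIANT_REGISTRY:
        comp = np.asarray(_VARIANT_REGISTRY[variant](m0, n_c, n_h, halflinks))
    elif variant in ("M3", "M4"):
        raise VariantNotConfigured(
            f"variant {variant} not configured; register a formula with "
            "register_variant()")
    else:
        raise VariantNotConfigured(f"unknown texture variant {variant!r}")
    return TextureTensor(variant=variant, components=comp, n_c=n_c, n_h=n_h,
                         roi_id=halflinks.roi_id,
                         frame_index=halflinks.frame_index)


def _components(m) -> np.ndarray:
    return m.components if isinstance(m, TextureTensor) else np.asarray(m, float)


def texture_area(m) -> float:
    """Ellipse area A = pi |M|^(1/2)."""
    comp = _components(m)
    det = float(np.linalg.det(comp))
    if det <= 0:
        raise DegenerateROIError("degenerate tensor: |M| <= 0")
    return float(np.pi * np.sqrt(det))


def density(m) -> float:
    """Cell number density rho = 1 / (pi |M|^(1/2))."""
    return 1.0 / texture_area(m)


@dataclass
class ShapeSummary:
    area: float
    aspect_ratio: float
    orientation: float | None     # angle of the major eigenvector, (-pi/2, pi/2]
    isotropic: bool


def shape_summary(m, isotropy_rtol: float = 1e-12) -> ShapeSummary:
    """Ellipse area, aspect ratio sqrt(l1/l2) and major-axis angle."""
    comp = _components(m)
    w, v = np.linalg.eigh(comp)
    l2, l1 = float(w[0]), float(w[1])
    if l2 <= 0:
        raise DegenerateROIError("tensor not positive definite")
    area = float(np.pi * np.sqrt(l1 * l2))
    aspect = float(np.sqrt(l1 / l2))
    if (l1 - l2) <= isotropy_rtol * l1:
        return ShapeSummary(area=area, aspect_ratio=1.0, orientation=None,
                            isotropic=True)
    e1 = v[:, 1]
    theta = float(np.arctan2(e1[1], e1[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return ShapeSummary(area=area, aspect_ratio=aspect, orientation=theta,
                        isotropic=False)


def orientation_coherence(thetas) -> float:
    """| < exp(2 i theta) > | : 1 for aligned cells, ~0 for random ones."""
    th = np.asarray([t for t in thetas if t is not None], float)
    if th.size == 0:
        raise ValueError("orientation_coherence needs at least one angle")
    return float(np.abs(np.mean(np.exp(2j * th))))


# ---------------------------------------------------------------------------
# pixel-based second moments
# ---------------------------------------------------------------------------

@dataclass
class PixelMoments:
    """Pixel-counting shape measures of an ROI's cells.

    ``m2_mean`` is (4/N_c) sum_c m2c: the factor 4 makes the per-cell second
    moment of a filled ellipse with radii (r_a, r_b) equal diag(r_a^2, r_b^2),
    so pi |m2_mean|^(1/2) is directly comparable to the texture area.
    """

    cell_ids: np.ndarray
    m2_cells: np.ndarray          # (n, 2, 2) per-cell second moments, px^2
    areas_excl: np.ndarray        # contour-excluded pixel counts
    areas_half: np.ndarray        # + half of the adjacent contour pixels
    m2_mean: np.ndarray           # (2, 2): (4 / N_c) * sum m2c
    n_c: int

    def density_px(self, convention: str = "half") -> float:
        """1 / mean pixel area; 'half' includes half the outline pixels."""
        areas = self.areas_half if convention == "half" else self.areas_excl
        return 1.0 / float(np.mean(areas))


def pixel_moments(label_image: np.ndarray, cells=None,
                  min_pixels: int = 4) -> PixelMoments:
    """Per-cell pixel second moments (about the pixel centroid) and areas."""
    label = np.asarray(label_image)
    if cells is None:
        ids = np.unique(label)
        ids = ids[ids > 0]
    else:
        ids = np.asarray(sorted(int(c) for c in cells))
    idx = ndimage.value_indices(label, ignore_value=0)

    # contour pixels adjacent to each cell, for the half-outline convention
    contour = label == 0
    neighbor_counts: dict[int, float] = {int(c): 0.0 for c in ids}
    padded = np.pad(label, 1, mode="constant")
    rows, cols = np.nonzero(contour)
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    neigh = np.stack([padded[1 + dr + rows, 1 + dc + cols] for dr, dc in shifts])
    for z in range(rows.size):
        uniq = np.unique(neigh[:, z])
        uniq = uniq[uniq > 0]
        if uniq.size == 0:
            continue
        share = 1.0 / uniq.size  # outline pixel split among adjacent cells
        for c in uniq:
            if int(c) in neighbor_counts:
                neighbor_counts[int(c)] += share

    keep, m2s, a_ex, a_half = [], [], [], []
    for cid in ids:
        if int(cid) not in idx and cid not in idx:
            continue
        rr, cc = idx[cid]
        if rr.size < min_pixels:
            continue
        x = cc.astype(float)
        y = rr.astype(float)
        xc, yc = x.mean(), y.mean()
        a = float(rr.size)
        m2 = np.array([
            [np.sum((x - xc) ** 2), np.sum((x - xc) * (y - yc))],
            [np.sum((x - xc) * (y - yc)), np.sum((y - yc) ** 2)],
        ]) / a
        keep.append(int(cid))
        m2s.append(m2)
        a_ex.append(a)
        a_half.append(a + neighbor_counts[int(cid)])
    if not keep:
        raise ValueError("no usable cells (all below the pixel minimum)")
    m2s = np.asarray(m2s)
    n_c = len(keep)
    m2_mean = 4.0 / n_c * m2s.sum(axis=0)
    return PixelMoments(cell_ids=np.asarray(keep), m2_cells=m2s,
                        areas_excl=np.asarray(a_ex),
                        areas_half=np.asarray(a_half),
                        m2_mean=m2_mean, n_c=n_c)


# ---------------------------------------------------------------------------
# texture variant vs pixel-moment comparison
# ---------------------------------------------------------------------------

@dataclass
class VariantFit:
    alpha: float
    slope: dict[str, float]
    intercept: dict[str, float]
    r2: dict[str, float]


def variant_vs_moments(textures: list[TextureTensor],
                       moments: list[np.ndarray]) -> VariantFit:
    """Compare a texture-variant series against 4x pixel second moments.

    alpha rescales the moment series so both have the same mean ellipse
    area; for the N_h-normalized variant M1 no fitting is needed and alpha
    is fixed at 1. Per-component ordinary least squares of M against
    alpha * m2 quantifies the agreement.
    """
    if len(textures) != len(moments) or len(textures) < 3:
        raise ValueError("need >= 3 paired (texture, moment) observations")
    variant = textures[0].variant
    mt = np.asarray([t.components for t in textures])
    mm = np.asarray([np.asarray(m, float) for m in moments])
    if variant == "M1":
        alpha = 1.0
    else:
        area_t = np.array([texture_area(c) for c in mt])
        area_m = np.array([texture_area(c) for c in mm])
        alpha = float(np.mean(area_t) / np.mean(area_m))
    comp_idx = {"xx": (0, 0), "xy": (0, 1), "yy": (1, 1)}
    slope, intercept, r2 = {}, {}, {}
    for name, (a, b) in comp_idx.items():
        x = alpha * mm[:, a, b]
        y = mt[:, a, b]
        if np.ptp(x) <= 1e-12 * max(1.0, float(np.abs(x).max())):
            slope[name] = np.nan
            intercept[name] = np.nan
            r2[name] = np.nan
            continue
        coef = np.polyfit(x, y, 1)
        pred = np.polyval(coef, x)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        slope[name] = float(coef[0])
        intercept[name] = float(coef[1])
        r2[name] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VariantFit(alpha=alpha, slope=slope, intercept=intercept, r2=r2)
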