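"""Texture tensors, pixel moments, shape summaries and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texkin.texture import DegenerateROIError, VariantNotConfigured, \
    density, orientation_coherence, pixel_moments, register_variant, \
    shape_summary, texture, texture_area, variant_vs_moments
from texkin.tiling_io import HalfLinkSet, frame_from_tiling, half_links


def _linkset(vectors, omegas=None, n_c=1):
    vectors = np.asarray(vectors, float)
    m = len(vectors)
    if omegas is None:
        omegas = np.ones(m)
    return HalfLinkSet(roi_id=0, frame_index=0,
                       i_ids=np.zeros(m, int), k_ids=np.arange(1, m + 1),
                       omegas=np.asarray(omegas, float), vectors=vectors,
                       n_c=n_c)


class TestTextureVariants:
    def test_two_link_cell(self):
        """Two opposed links (+-d, 0): M0 = diag(d^2, 0), M1 halves it."""
        d = 3.0
        hl = _linkset([[d, 0.0], [-d, 0.0], [0.0, 1e-9], [0.0, -1e-9]])
        # the tiny y-links avoid the collinearity guard without moving M
        m0 = texture(hl, "M0")
        np.testing.assert_allclose(m0.components, [[d * d, 0], [0, 0]],
                                   atol=1e-12)
        m1 = texture(hl, "M1")
        np.testing.assert_allclose(m1.components, m0.components / hl.n_h)

    def test_hexagonal_interior_cell(self, hex_tiling, hex_frame):
        """Ideal hexagonal 1-cell ROI: M1 = (d^2 / 4) I."""
        boundary = hex_tiling.boundary_cells()
        deep = [int(c) for c in hex_frame.ids
                if not hex_frame.is_outermost(int(c))
                and all(k not in boundary
                        for k, _w, _kind in hex_frame.neighbors(int(c)))]
        m1 = texture(half_links(hex_frame, [deep[0]]), "M1")
        np.testing.assert_allclose(m1.components, (20.0 ** 2 / 4) * np.eye(2),
                                   atol=1e-9)

    def test_m1_is_m0_over_nh(self, hex_frame):
        interior = [int(c) for c in hex_frame.ids
                    if not hex_frame.is_outermost(int(c))]
        hl = half_links(hex_frame, interior)
        np.testing.assert_allclose(texture(hl, "M1").components * hl.n_h,
                                   texture(hl, "M0").components)

    def test_roi_doubling_scales_m0_not_m1(self, hex_tiling, hex_frame):
        """On a homogeneous tiling M0 is extensive, M1 intensive."""
        boundary = hex_tiling.boundary_cells()
        deep = sorted(int(c) for c in hex_frame.ids
                      if not hex_frame.is_outermost(int(c))
                      and all(k not in boundary
                              for k, _w, _kind in
                              hex_frame.neighbors(int(c))))
        half = deep[:len(deep) // 2]
        m0_half = texture(half_links(hex_frame, half), "M0").components
        m0_full = texture(half_links(hex_frame, deep), "M0").components
        m1_half = texture(half_links(hex_frame, half), "M1").components
        m1_full = texture(half_links(hex_frame, deep), "M1").components
        assert np.trace(m0_full) > 1.5 * np.trace(m0_half)
        np.testing.assert_allclose(m1_half, m1_full, rtol=0.05, atol=1e-9)

    def test_unconfigured_variants_raise(self, hex_frame):
        interior = [int(c) for c in hex_frame.ids
                    if not hex_frame.is_outermost(int(c))]
        hl = half_links(hex_frame, interior)
        with pytest.raises(VariantNotConfigured):
            texture(hl, "M3")
        register_variant("M3", lambda m0, n_c, n_h, links: m0 / (n_c * 6))
        try:
            m3 = texture(hl, "M3")
            assert m3.components.shape == (2, 2)
        finally:
            from texkin.texture import _VARIANT_REGISTRY
            _VARIANT_REGISTRY.pop("M3", None)

    def test_degenerate_roi_rejected(self):
        hl = _linkset([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0]])
        assert not hl.degenerate  # constructed directly; mark manually
        hl.degenerate = True
        with pytest.raises(DegenerateROIError):
            texture(hl, "M1")


class TestAreaDensity:
    def test_arithmetic(self):
        m = np.diag([4.0, 1.0])
        assert texture_area(m) == pytest.approx(2 * np.pi)
        assert density(m) == pytest.approx(1 / (2 * np.pi))

    def test_circle_limit(self):
        assert texture_area(3.0 * np.eye(2)) == pytest.approx(3 * np.pi)

    def test_hexagon_systematic_offset(self, hex_tiling, hex_frame):
        """Texture area pi d^2/4 vs true hexagon area (sqrt(3)/2) d^2:
        ratio pi / (2 sqrt(3)) ~ 0.907 for regular hexagons."""
        boundary = hex_tiling.boundary_cells()
        deep = [int(c) for c in hex_frame.ids
                if not hex_frame.is_outermost(int(c))
                and all(k not in boundary
                        for k, _w, _kind in hex_frame.neighbors(int(c)))]
        m1 = texture(half_links(hex_frame, [deep[0]]), "M1")
        ratio = texture_area(m1) / hex_tiling.cell_area(deep[0])
        assert ratio == pytest.approx(np.pi / (2 * np.sqrt(3)), rel=1e-9)

    def test_degenerate_tensor_rejected(self):
        with pytest.raises(DegenerateROIError):
            texture_area(np.diag([1.0, 0.0]))


class TestShapeSummary:
    def test_diagonal(self):
        s = shape_summary(np.diag([4.0, 1.0]))
        assert s.area == pytest.approx(2 * np.pi)
        assert s.aspect_ratio == pytest.approx(2.0)
        assert s.orientation == pytest.approx(0.0)

    def test_rotation_equivariance(self):
        phi = np.deg2rad(45)
        r = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        s = shape_summary(r @ np.diag([4.0, 1.0]) @ r.T)
        assert s.aspect_ratio == pytest.approx(2.0)
        assert s.orientation == pytest.approx(phi)

    def test_isotropic_flag(self):
        s = shape_summary(2.5 * np.eye(2))
        assert s.isotropic
        assert s.orientation is None
        assert s.aspect_ratio == 1.0


class TestOrientationCoherence:
    def test_aligned(self):
        assert orientation_coherence([0.3] * 10) == pytest.approx(1.0)

    def test_perpendicular_pair_cancels(self):
        assert orientation_coherence([0.0, np.pi / 2]) == pytest.approx(
            0.0, abs=1e-12)

    def test_uniform_random_is_incoherent(self):
        rng = np.random.default_rng(0)
        assert orientation_coherence(
            rng.uniform(-np.pi / 2, np.pi / 2, 10_000)) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            orientation_coherence([])


class TestPixelMoments:
    def test_two_by_two_square(self):
        img = np.zeros((10, 10), dtype=np.int32)
        img[4:6, 4:6] = 1
        pm = pixel_moments(img)
        np.testing.assert_allclose(pm.m2_cells[0],
                                   [[0.25, 0.0], [0.0, 0.25]])

    def test_translation_invariance(self):
        img = np.zeros((40, 40), dtype=np.int32)
        img[5:12, 6:16] = 2
        pm1 = pixel_moments(img)
        pm2 = pixel_moments(np.roll(np.roll(img, 9, axis=0), 7, axis=1))
        np.testing.assert_allclose(pm1.m2_cells, pm2.m2_cells)

    def test_ellipse_second_moment_factor(self):
        """Filled ellipse with semi-axes (r_a, r_b): r_a^2 / m_xx -> 4."""
        from skimage.draw import ellipse
        img = np.zeros((140, 260), dtype=np.int32)
        rr, cc = ellipse(70, 130, 50, 110)
        img[rr, cc] = 1
        pm = pixel_moments(img)
        assert 110.0 ** 2 / pm.m2_cells[0][0, 0] == pytest.approx(4.0,
                                                                  rel=0.01)

    def test_tiny_cells_excluded(self):
        img = np.zeros((20, 20), dtype=np.int32)
        img[3, 3] = 1          # single pixel: excluded
        img[8:12, 8:12] = 2
        pm = pixel_moments(img)
        assert list(pm.cell_ids) == [2]


class TestVariantVsMoments:
    def test_m2_alpha_is_link_ratio_on_hexagons(self, hex_tiling, hex_frame):
        """M2 = M1 * (N_h / N_c): on ideal hexagonal ROIs alpha -> 6."""
        boundary = hex_tiling.boundary_cells()
        deep = sorted(int(c) for c in hex_frame.ids
                      if not hex_frame.is_outermost(int(c))
                      and all(k not in boundary for k, _w, _kind in
                              hex_frame.neighbors(int(c))))
        textures, moments = [], []
        for k in range(3, len(deep) + 1):
            hl = half_links(hex_frame, deep[:k])
            textures.append(texture(hl, "M2"))
            moments.append(texture(hl, "M1").components)  # stand-in pairing
        fit = variant_vs_moments(textures, moments)
        assert fit.alpha == pytest.approx(6.0, rel=1e-6)

    def test_proportional_series_r2_one(self):
        rng = np.random.default_rng(1)
        base = [np.diag([4 + x, 2 + 0.5 * x]) for x in rng.random(8)]
        hls = [_linkset([[2, 0], [-2, 0], [0, 1], [0, -1]]) for _ in base]
        textures = [texture(h, "M1") for h in hls]
        for t, b in zip(textures, base):
            t.components = 2.0 * np.asarray(b)
        fit = variant_vs_moments(textures, base)
        for comp in ("xx", "yy"):
            assert fit.r2[comp] == pytest.approx(1.0)

    def test_m1_tracks_pixel_moments_on_random_tissue(self, voronoi_tiling):
        """M1 vs 4x pixel second moments across differently stretched
        tissues: close to the identity line (slope within 15%), and
        component-wise deviation |M1 - m2| / tr(m2) <= 0.15 per ROI."""
        from texkin.synthetic import FlowSpec, advect, rasterize
        textures, moments = [], []
        for s in (-0.15, -0.08, 0.0, 0.08, 0.15, 0.22):
            gv = np.array([[s, 0.0], [0.0, -s / (1 + s)]])
            tiling = advect(voronoi_tiling, FlowSpec(kind="affine",
                                                     gradient=gv), dt=1.0)
            label = rasterize(tiling)
            geo = frame_from_tiling(tiling)
            interior = sorted(int(c) for c in geo.ids
                              if not geo.is_outermost(int(c)))
            hl = half_links(geo, interior)
            textures.append(texture(hl, "M1"))
            moments.append(pixel_moments(label, cells=interior).m2_mean)
        fit = variant_vs_moments(textures, moments)
        assert fit.alpha == 1.0
        assert 0.85 <= fit.slope["xx"] <= 1.15
        assert 0.85 <= fit.slope["yy"] <= 1.15
        tdev = [np.abs(t.components - m).max() / np.trace(m)
                for t, m in zip(textures, moments)]
        assert max(tdev) <= 0.15


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(0.0, 2 * np.pi), st.floats(0.2, 5.0))
def test_texture_rotation_equivariance_and_scaling(phi, s):
    """texture(R x) = R texture(x) R^T and texture(s x) = s^2 texture(x)."""
    rng = np.random.default_rng(12345)
    vecs = rng.normal(scale=5.0, size=(12, 2))
    hl = _linkset(vecs)
    base = texture(hl, "M1").components
    r = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    rotated = texture(_linkset(vecs @ r.T), "M1").components
    np.testing.assert_allclose(rotated, r @ base @ r.T, atol=1e-9)
    scaled = texture(_linkset(s * vecs), "M1").components
    np.testing.assert_allclose(scaled, s * s * base, rtol=1e-9)
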