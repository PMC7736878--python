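"""Spectral index arithmetic, continuum-removal geometry and the NDI
wavelength-pair optimisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from icealgae import indices as idx
from icealgae.cube import SpectralCube

WL11 = np.arange(650.0, 701.0, 5.0)  # 11 bands across the feature window


def seg_from(values, wl=WL11, **kwargs):
    return idx.continuum_remove(np.asarray(values, float), wl, **kwargs)


def v_spectrum():
    """Chord at 1.0, dip to 0.5x chord at the window midpoint (675 nm)."""
    depth = np.interp(WL11, [650, 675, 700], [0.0, 0.5, 0.0])
    return 1.0 - depth


class TestNdi:
    def test_equal_bands_give_zero(self):
        wl = np.linspace(400, 700, 31)
        assert idx.ndi(np.full(31, 0.4), wl, 450, 670) == 0.0

    def test_arithmetic(self):
        wl = np.array([500.0, 600.0])
        spec = np.array([0.2, 0.1])
        assert idx.ndi(spec, wl, 500, 600) == pytest.approx(1.0 / 3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        wl = np.linspace(400, 700, 20)
        spec = rng.uniform(0.01, 1.0, 20)
        l1, l2 = rng.choice(wl, 2, replace=False)
        a = idx.ndi(spec, wl, l1, l2)
        b = idx.ndi(spec, wl, l2, l1)
        assert a == pytest.approx(-b, abs=1e-12)
        assert -1.0 <= a <= 1.0

    def test_zero_denominator_marks_undefined(self):
        wl = np.array([500.0, 600.0, 700.0])
        assert math.isnan(idx.ndi(np.zeros(3), wl, 500, 600))


class TestContinuumRemoval:
    def test_linear_spectrum_has_no_feature(self):
        seg = seg_from(np.linspace(0.3, 0.5, 11))
        np.testing.assert_allclose(seg.rho, 1.0, rtol=1e-12)
        np.testing.assert_array_equal(seg.depth, 0.0)

    def test_endpoints_exactly_unity(self):
        rng = np.random.default_rng(2)
        seg = seg_from(rng.uniform(0.2, 0.8, 11))
        assert seg.rho[0] == pytest.approx(1.0, abs=1e-12)
        assert seg.rho[-1] == pytest.approx(1.0, abs=1e-12)

    def test_v_spectrum_mid_depth(self):
        seg = seg_from(v_spectrum())
        mid = np.argmin(np.abs(seg.wavelengths - 675.0))
        assert seg.depth[mid] == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        spec = rng.uniform(0.2, 0.8, 11)
        a = seg_from(spec)
        b = seg_from(7.3 * spec)
        np.testing.assert_allclose(a.rho, b.rho, rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_chord_rho_never_exceeds_hull_rho(self, seed):
        """The upper hull lies on or above the chord, so hull-normalised
        transmittance is <= chord-normalised at every band (brute-force
        hull oracle)."""
        rng = np.random.default_rng(seed)
        wl = np.sort(rng.uniform(650, 700, 10))
        spec = rng.uniform(0.1, 1.0, 10)
        chord = np.interp(wl, [wl[0], wl[-1]], [spec[0], spec[-1]])
        # oracle: brute-force upper hull by pairwise chord enumeration
        hull = chord.copy()
        for i in range(10):
            for j in range(i + 1, 10):
                line = np.interp(wl, [wl[i], wl[j]], [spec[i], spec[j]])
                sel = (wl >= wl[i]) & (wl <= wl[j])
                if np.all(spec[sel] <= line[sel] + 1e-12):
                    hull[sel] = np.maximum(hull[sel], line[sel])
        assert np.all(hull >= chord - 1e-12)
        assert np.all(spec / hull <= spec / chord + 1e-9)
        # implementation's hull mode agrees with the oracle
        seg = idx.continuum_remove(spec, wl, window=(wl[0], wl[-1]),
                                   mode="hull")
        np.testing.assert_allclose(seg.continuum, hull, rtol=1e-9)

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError, match="3 bands"):
            idx.continuum_remove(np.array([1.0, 1.0]),
                                 np.array([650.0, 700.0]))


class TestAreaIndices:
    def test_zero_depth_zero_area(self):
        assert idx.auc(seg_from(np.linspace(0.3, 0.5, 11))) == 0.0

    def test_triangular_depth_area(self):
        # depth rises linearly to 0.5 at mid-window: area = 0.5*50*0.5/... = 12.5
        assert idx.auc(seg_from(v_spectrum())) == pytest.approx(12.5)

    def test_gaussian_dip_matches_quadrature(self):
        wl = np.arange(650.0, 700.5, 0.5)
        depth_fn = lambda x: 0.6 * np.exp(-0.5 * ((x - 677.0) / 6.0) ** 2)
        seg = seg_from(1.0 - depth_fn(wl), wl=wl)
        exact, _ = quad(depth_fn, 650, 700)
        # trapezoid error bound: (b-a) h^2 max|f''| / 12
        h = 0.5
        bound = 50 * h**2 * (0.6 / 6.0**2) / 12
        assert abs(idx.auc(seg) - exact) <= bound

    def test_literal_mode_integrates_rho(self):
        seg = seg_from(v_spectrum())
        assert idx.auc(seg, mode="literal") == pytest.approx(50.0 - 12.5)

    def test_cbd_and_mbd_geometry(self):
        flat = seg_from(np.linspace(0.3, 0.5, 11))
        assert idx.cbd(flat) == 0.0
        assert idx.mbd(flat) == 0.0
        vee = seg_from(v_spectrum())
        assert idx.cbd(vee, 675.0) == pytest.approx(0.5)
        assert idx.mbd(vee) == pytest.approx(0.5)

    def test_mbd_dominates_cbd(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            seg = seg_from(rng.uniform(0.1, 1.0, 11))
            assert idx.mbd(seg) >= idx.cbd(seg) - 1e-12

    def test_cbd_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            idx.cbd(seg_from(v_spectrum()), 620.0)

    def test_normalised_indices_arithmetic(self):
        seg = seg_from(v_spectrum())
        # AUC 12.5, CBD(677->675 band) 0.5, MBD 0.5
        assert idx.ancb(seg, 675.0) == pytest.approx(25.0)
        assert idx.anmb(seg) == pytest.approx(25.0)

    def test_anmb_never_exceeds_ancb(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seg = seg_from(rng.uniform(0.1, 1.0, 11))
            a_ncb, a_nmb = idx.ancb(seg), idx.anmb(seg)
            if not (math.isnan(a_ncb) or math.isnan(a_nmb)):
                assert a_nmb <= a_ncb + 1e-9

    def test_degenerate_divisors_marked_undefined(self):
        flat = seg_from(np.linspace(0.3, 0.5, 11))
        assert math.isnan(idx.ancb(flat))
        assert math.isnan(idx.anmb(flat))
        assert math.isnan(idx.lauc(flat))

    def test_lauc_log_identities_and_monotonicity(self):
        vee = seg_from(v_spectrum())  # AUC 12.5
        assert idx.lauc(vee) == pytest.approx(math.log(12.5))
        shallow = seg_from(1.0 - 0.4 * (1.0 - v_spectrum()))
        assert idx.auc(shallow) < idx.auc(vee)
        assert idx.lauc(shallow) < idx.lauc(vee)
        assert idx.lauc(vee, log_base=10) == pytest.approx(math.log10(12.5))


class TestPerPixel:
    def wl(self):
        return np.arange(640.0, 706.0, 5.0)

    def cube_of(self, spectra):
        data = np.asarray(spectra, float)
        return SpectralCube(data, self.wl(), units="transmittance")

    def test_constant_cube_constant_map(self):
        spec = 1.0 - np.interp(self.wl(), [650, 675, 700], [0, 0.5, 0])
        cube = self.cube_of(np.tile(spec, (3, 3, 1)))
        cfg = idx.IndexConfig("AUC")
        m = idx.index_map(cube, cfg)
        seg = idx.continuum_remove(spec, self.wl())
        np.testing.assert_allclose(m, idx.auc(seg), rtol=1e-12)

    @pytest.mark.parametrize("label", ["AUC", "ANCB", "ANMB", "LAUC",
                                       "NDI(660:695)"])
    def test_map_agrees_with_scalar_loop_oracle(self, label):
        rng = np.random.default_rng(6)
        cube = self.cube_of(rng.uniform(0.2, 1.0, (5, 5, self.wl().size)))
        cfg = idx.IndexConfig.from_label(label)
        m = idx.index_map(cube, cfg)
        for y in range(5):
            for x in range(5):
                spec = cube.data[y, x]
                if cfg.name == "NDI":
                    want = idx.ndi(spec, self.wl(), cfg.lambda1, cfg.lambda2)
                else:
                    seg = idx.continuum_remove(spec, self.wl())
                    want = {"AUC": idx.auc, "ANCB": idx.ancb,
                            "ANMB": idx.anmb, "LAUC": idx.lauc}[cfg.name](seg)
                if math.isnan(want):
                    assert math.isnan(m[y, x])  # undefined on both routes
                else:
                    assert m[y, x] == pytest.approx(want, rel=1e-9)

    def test_map_mean_equals_method_two(self):
        rng = np.random.default_rng(7)
        cube = self.cube_of(rng.uniform(0.2, 1.0, (4, 4, self.wl().size)))
        cfg = idx.IndexConfig("ANMB")
        m = idx.index_map(cube, cfg)
        sec = idx.section_index(cube, cfg, method=2)
        assert np.nanmean(m) == pytest.approx(sec.value, rel=1e-12)
        assert sec.method == 2

    def test_methods_agree_on_homogeneous_cube(self):
        spec = 1.0 - np.interp(self.wl(), [650, 677, 700], [0, 0.3, 0])
        cube = self.cube_of(np.tile(spec, (3, 3, 1)))
        cfg = idx.IndexConfig("LAUC")
        m1 = idx.section_index(cube, cfg, method=1).value
        m2 = idx.section_index(cube, cfg, method=2).value
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_two_pixel_jensen_gap(self):
        wl = np.array([500.0, 600.0])
        a, b = np.array([0.2, 0.1]), np.array([0.4, 0.1])
        cube = SpectralCube(np.stack([a, b])[None, :, :], wl,
                            units="transmittance")
        cfg = idx.IndexConfig("NDI", lambda1=500, lambda2=600)
        m1 = idx.section_index(cube, cfg, method=1).value
        m2 = idx.section_index(cube, cfg, method=2).value
        # hand computation: mean spectrum (0.3, 0.1) -> 0.5;
        # per-pixel (1/3 + 3/5)/2 = 7/15
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(7.0 / 15.0)

    def test_wrong_units_rejected(self):
        cube = self.cube_of(np.ones((2, 2, self.wl().size)))
        radiance = cube.copy_with(units="radiance")
        with pytest.raises(ValueError, match="transmittance"):
            idx.index_map(radiance, idx.IndexConfig("AUC"))


class TestCorrelationSurface:
    def make_sections(self, n=8, seed=0, link=True):
        """Sections whose transmittance at 670 nm falls exponentially
        with Chl a, flat elsewhere: NDI(650, 670) tracks log Chl a."""
        rng = np.random.default_rng(seed)
        wl = np.arange(640.0, 701.0, 10.0)
        sections = []
        for _ in range(n):
            chla = float(rng.uniform(2.0, 80.0))
            spec = np.full(wl.size, 0.5)
            if link:
                spec[wl == 670.0] = 0.5 * math.exp(-0.02 * chla)
            else:
                spec = rng.uniform(0.2, 0.8, wl.size)
            data = np.tile(spec, (3, 3, 1)) * rng.normal(1, 1e-3, (3, 3, 1))
            sections.append((SpectralCube(data, wl, units="transmittance"),
                             chla))
        return sections, wl

    def test_antisymmetric_with_nan_diagonal(self):
        sections, _ = self.make_sections()
        surf = idx.ndi_correlation_surface(sections)
        off = ~np.eye(surf.r.shape[0], dtype=bool)
        np.testing.assert_allclose(surf.r[off], -surf.r.T[off], atol=1e-10)
        assert np.isnan(np.diag(surf.r)).all()

    def test_constructed_link_detected(self):
        sections, wl = self.make_sections()
        surf = idx.ndi_correlation_surface(sections)
        i, j = int(np.where(wl == 650)[0][0]), int(np.where(wl == 670)[0][0])
        assert abs(surf.r[i, j]) > 0.9

    def test_shuffled_labels_break_the_link(self):
        rng = np.random.default_rng(1)
        sections, wl = self.make_sections(n=10)
        i, j = int(np.where(wl == 650)[0][0]), int(np.where(wl == 670)[0][0])
        hits = 0
        for _ in range(5):
            chlas = [c for _, c in sections]
            rng.shuffle(chlas)
            shuffled = [(cube, c) for (cube, _), c in zip(sections, chlas)]
            surf = idx.ndi_correlation_surface(shuffled)
            if abs(surf.r[i, j]) > 0.99:
                hits += 1
        assert hits <= 1

    def test_too_few_sections_rejected(self):
        sections, _ = self.make_sections(n=2)
        with pytest.raises(ValueError, match="3 sections"):
            idx.ndi_correlation_surface(sections)


class TestPairSelection:
    def surface(self, wl, strong):
        r = np.zeros((wl.size, wl.size))
        for (i, j), v in strong.items():
            r[i, j], r[j, i] = v, -v
        np.fill_diagonal(r, np.nan)
        return idx.CorrelationSurface(wl, r, 10)

    def test_single_qualifying_pair_returned(self):
        wl = np.array([440.0, 530.0, 655.0, 680.0])
        surf = self.surface(wl, {(0, 2): 0.9})
        out = idx.select_ndi_pairs(surf)
        assert len(out) == 1
        assert (out.lambda1[0], out.lambda2[0]) == (440.0, 655.0)

    def test_close_pair_excluded_despite_high_r(self):
        wl = np.array([440.0, 655.0, 663.0])
        surf = self.surface(wl, {(1, 2): 0.99})
        assert len(idx.select_ndi_pairs(surf)) == 0

    def test_region_requirement(self):
        wl = np.array([500.0, 560.0, 655.0])
        surf = self.surface(wl, {(0, 1): 0.95, (0, 2): 0.8})
        out = idx.select_ndi_pairs(surf)
        # 500/560 excluded (no chlorophyll-region band), 500/655 kept
        assert len(out) == 1
        assert out.lambda2[0] == 655.0

    def test_label_format_round_trip(self):
        cfg = idx.IndexConfig.from_label("NDI(587:621)")
        assert (cfg.lambda1, cfg.lambda2) == (587.0, 621.0)
        assert cfg.label == "NDI(587:621)"
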