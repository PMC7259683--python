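import numpy as np
import pytest

from fernet.initialization import (
    EPS_F,
    InitParams,
    compute_initialization,
    corrected_tensor_init,
    f_b0_map,
    f_b0_raw,
    f_bounds,
    f_md_map,
    interpolated_init,
    reference_signals,
)
from fernet.simulator import simulate_dwi, simulate_s0
from fernet.tensor import compute_attenuation, from_lower_tri

B = 800.0
PARAMS = InitParams()


class TestReferenceSignals:
    def test_constant_wm(self):
        s0 = np.concatenate([np.full(21, 100.0), [500.0] * 5])
        wm = np.arange(26) < 21
        s_t, s_w = reference_signals(s0, wm, ~wm)
        assert s_t == 100.0

    def test_percentiles_linear_interpolation(self):
        # WM {90,...,190}: 5th percentile by sort-and-interpolate = 95
        # CSF {300,400,500}: 95th percentile = 490
        s0 = np.concatenate([np.arange(90.0, 191.0, 10.0), [300.0, 400.0, 500.0]])
        wm = np.arange(14) < 11
        s_t, s_w = reference_signals(s0, wm, ~wm)
        assert s_t == pytest.approx(95.0)
        assert s_w == pytest.approx(490.0)

    def test_empty_mask_rejected(self):
        s0 = np.ones(10)
        with pytest.raises(ValueError, match="empty"):
            reference_signals(s0, np.zeros(10, bool), np.ones(10, bool))

    def test_inverted_references_rejected(self):
        s0 = np.concatenate([np.full(5, 900.0), np.full(5, 100.0)])
        wm = np.arange(10) < 5
        with pytest.raises(ValueError, match="S_t"):
            reference_signals(s0, wm, ~wm)


class TestFB0:
    def test_limits(self):
        assert f_b0_raw(400.0, 400.0, 1200.0) == pytest.approx(1.0)
        assert f_b0_raw(1200.0, 400.0, 1200.0) == pytest.approx(0.0)
        # logarithmic midpoint
        assert f_b0_raw(np.sqrt(400.0 * 1200.0), 400.0, 1200.0) == pytest.approx(0.5)

    def test_clamped_to_nearest_bound(self):
        f = f_b0_map(np.array([400.0, 1200.0]), 400.0, 1200.0,
                     f_min_map=0.2, f_max_map=0.8)
        np.testing.assert_allclose(f, [0.8, 0.2])

    def test_monotone_decreasing_in_s0(self):
        s0 = np.linspace(300.0, 1400.0, 50)
        f = f_b0_raw(s0, 400.0, 1200.0)
        assert np.all(np.diff(f) < 0)


class TestFBounds:
    def test_derived_example(self):
        # oracle: direct evaluation with e^-2, e^-2.4, e^-0.08
        att = np.array([[0.12, 0.5, 0.80]])
        lo, hi = f_bounds(att, B, PARAMS)
        assert lo[0] == pytest.approx(0.656, abs=5e-4)
        assert hi[0] == pytest.approx(0.852, abs=5e-4)

    def test_degenerate_edges(self):
        e_d = np.exp(-B * PARAMS.d)
        att = np.array([[e_d, np.exp(-B * PARAMS.lambda_min)]])
        lo, hi = f_bounds(att, B, PARAMS)
        assert lo[0] == pytest.approx(EPS_F)       # zero numerator clamped up
        assert hi[0] == pytest.approx(1.0)

    def test_ordering_enforced(self):
        rng = np.random.default_rng(11)
        att = rng.uniform(0.05, 1.0, size=(40, 12))
        lo, hi = f_bounds(att, B, PARAMS)
        assert np.all(lo <= hi)
        assert np.all((lo >= EPS_F) & (hi <= 1.0))


class TestFMD:
    def test_limits(self):
        assert f_md_map(PARAMS.md_tissue, B, PARAMS) == pytest.approx(1.0)
        assert f_md_map(PARAMS.d, B, PARAMS) == pytest.approx(EPS_F)

    def test_derived_value(self):
        # oracle: (e^-1.2 - e^-2.4) / (e^-0.48 - e^-2.4)
        assert f_md_map(1.5e-3, B, PARAMS) == pytest.approx(0.3986, abs=5e-5)

    def test_monotone_decreasing_in_md(self):
        md = np.linspace(0.1e-3, 2.9e-3, 60)
        f = f_md_map(md, B, PARAMS)
        assert np.all(np.diff(f) <= 0)


class TestInterpolation:
    def test_exponent_collapse(self):
        assert interpolated_init(0.4, 0.9, 0.0) == pytest.approx(0.4)
        assert interpolated_init(0.4, 0.9, 1.0) == pytest.approx(0.9)

    def test_geometric_mean(self):
        assert interpolated_init(0.4, 0.9, 0.5) == pytest.approx(0.6)

    def test_bracketing(self):
        rng = np.random.default_rng(5)
        fb0 = rng.uniform(EPS_F, 1, 100)
        fmd = rng.uniform(EPS_F, 1, 100)
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            f = interpolated_init(fb0, fmd, alpha)
            assert np.all(f >= np.minimum(fb0, fmd) - 1e-12)
            assert np.all(f <= np.maximum(fb0, fmd) + 1e-12)


class TestCorrectedTensorInit:
    def test_identity_at_full_tissue(self, scheme, wm_tensor):
        signals = simulate_dwi(wm_tensor, 1.0, 400.0, scheme)
        att = compute_attenuation(signals[None], scheme)
        d6 = corrected_tensor_init(att, np.array([1.0]), scheme)
        assert np.abs(from_lower_tri(d6[0]) - wm_tensor).max() < 1e-9

    def test_true_fraction_recovers_tensor(self, scheme, wm_tensor):
        f = 0.6
        signals = simulate_dwi(wm_tensor, f, simulate_s0(f, 400, 1200), scheme)
        att = compute_attenuation(signals[None], scheme)
        d6 = corrected_tensor_init(att, np.array([f]), scheme)
        assert np.abs(from_lower_tri(d6[0]) - wm_tensor).max() < 1e-9

    def test_wrong_fraction_leaves_residual(self, scheme, wm_tensor):
        from fernet.fitting import voxel_objective

        f = 0.6
        signals = simulate_dwi(wm_tensor, f, simulate_s0(f, 400, 1200), scheme)
        att = compute_attenuation(signals[None], scheme)
        f_wrong = 0.45
        d6 = corrected_tensor_init(att, np.array([f_wrong]), scheme)
        assert voxel_objective(att[0], scheme, f_wrong, d6[0]) > 1e-8


class TestPipeline:
    def _signals(self, scheme, wm_tensor, f):
        return simulate_dwi(wm_tensor, f, simulate_s0(f, 400, 1200), scheme)

    def test_limiting_alpha_behavior(self, scheme, wm_tensor):
        """S0 = S_t gives alpha=1 (trust f_MD); S0 = S_w gives alpha=0."""
        sig_wm = self._signals(scheme, wm_tensor, 1.0)   # S0 = 400 = S_t
        maps, _ = compute_initialization(sig_wm[None], scheme, 400.0, 1200.0)
        assert maps.alpha[0] == pytest.approx(1.0)

        sig_csf = self._signals(scheme, wm_tensor, 0.0)  # S0 = 1200 = S_w
        maps, _ = compute_initialization(sig_csf[None], scheme, 400.0, 1200.0)
        assert maps.alpha[0] == pytest.approx(0.0)

    def test_feasibility_of_all_maps(self, scheme, wm_tensor):
        rng = np.random.default_rng(2)
        f_true = rng.uniform(0.1, 1.0, 30)
        signals = np.stack([self._signals(scheme, wm_tensor, f) for f in f_true])
        signals *= rng.normal(1.0, 0.02, signals.shape).clip(0.5)
        for mode in ("fernet", "b0"):
            maps, _ = compute_initialization(signals, scheme, 400.0, 1200.0,
                                             mode=mode)
            assert np.all(maps.f_min <= maps.f_max)
            assert np.all((maps.alpha >= 0) & (maps.alpha <= 1))
            assert np.all(maps.f_init >= maps.f_min - 1e-12)
            assert np.all(maps.f_init <= maps.f_max + 1e-12)

    def test_b0_mode_midpoint_replacement(self, scheme, wm_tensor):
        """Out-of-range raw f_b0 falls back to the bound midpoint."""
        sig = self._signals(scheme, wm_tensor, 1.0)  # raw f_b0 = 1
        maps, _ = compute_initialization(sig[None], scheme, 400.0, 1200.0,
                                         mode="b0")
        if maps.f_max[0] < 1.0:  # raw value above f_max -> midpoint
            assert maps.f_init[0] == pytest.approx(
                0.5 * (maps.f_min[0] + maps.f_max[0])
            )

    def test_global_rescaling_invariance(self, scheme, wm_tensor):
        signals = np.stack([self._signals(scheme, wm_tensor, f)
                            for f in (0.3, 0.6, 0.9)])
        a, _ = compute_initialization(signals, scheme, 400.0, 1200.0)
        bmaps, _ = compute_initialization(
            7.5 * signals, scheme, 7.5 * 400.0, 7.5 * 1200.0
        )
        for field in ("f_b0", "f_md", "alpha", "f_min", "f_max", "f_init"):
            np.testing.assert_allclose(
                getattr(a, field), getattr(bmaps, field), atol=1e-12
            )

    def test_unknown_mode_rejected(self, scheme, wm_tensor):
        with pytest.raises(ValueError, match="mode"):
            compute_initialization(
                self._signals(scheme, wm_tensor, 0.5)[None],
                scheme, 400.0, 1200.0, mode="magic",
            )
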