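"""Phantom construction oracle and the full pipeline against it."""

import numpy as np
import pytest

from lvind import analyze_subject
from lvind.phantom import PhantomSpec, generate_phantom, simulate_observers
from lvind.stats import bland_altman


def run_pipeline(spec):
    cs, truth = generate_phantom(spec)
    res = analyze_subject(cs, compute_metrics=False)
    return res.bullseye, truth


class TestPairedOracle:
    @pytest.mark.parametrize("s", [0.1, 0.33, 0.5])
    def test_uniform_contraction_machine_precision(self, s):
        b, truth = run_pipeline(PhantomSpec(contraction=s, mode="paired"))
        assert np.allclose(b.seg_pct, 100.0 * s, atol=1e-9)
        assert np.allclose(truth.seg_ind_pct, 100.0 * s, atol=1e-12)

    def test_zero_contraction_is_akinetic(self):
        cs, truth = generate_phantom(PhantomSpec(contraction=0.0, mode="paired"))
        res = analyze_subject(cs)
        assert np.allclose(res.bullseye.seg_pct, 0.0, atol=1e-12)
        assert res.metrics.ef_pct == pytest.approx(0.0, abs=1e-9)
        assert res.metrics.gls_pct == pytest.approx(0.0, abs=1e-9)

    def test_negative_contraction_is_dyskinetic(self):
        contraction = {k: 0.3 for k in range(1, 18)}
        contraction[10] = -0.1
        b, truth = run_pipeline(PhantomSpec(contraction=contraction, mode="paired"))
        assert b[10] < 0.0
        assert truth.seg_ind_pct[9] < 0.0
        assert all(b[k] > 0 for k in range(1, 18) if k != 10)

    def test_single_segment_elevation_recovered(self):
        contraction = {k: 0.3 for k in range(1, 18)}
        contraction[10] = 0.484
        b, truth = run_pipeline(PhantomSpec(contraction=contraction, mode="paired"))
        # exact recovery of the construction truth ...
        assert np.allclose(b.seg_pct, truth.seg_ind_pct, atol=1e-9)
        # ... whose segment-10 mean sits within 1 pp of 48.4 (boundary
        # smoothing pulls it slightly toward the neighbouring 30 %)
        assert b[10] == pytest.approx(48.4, abs=1.0)
        assert b[4] == pytest.approx(30.0, abs=0.5)

    def test_pipeline_matches_truth_with_annular_descent(self):
        b, truth = run_pipeline(PhantomSpec(annular_descent_mm=4.0, mode="paired"))
        assert np.allclose(b.seg_pct, truth.seg_ind_pct, atol=1e-9)


class TestResampledMode:
    def test_tracking_substitution_error_below_one_point(self):
        b, truth = run_pipeline(PhantomSpec(mode="resampled", n_points=200))
        assert np.max(np.abs(b.seg_pct - truth.seg_ind_pct)) < 1.0

    def test_truth_independent_of_output_mode(self):
        _, t_paired = generate_phantom(PhantomSpec(mode="paired", seed=3))
        _, t_resampled = generate_phantom(PhantomSpec(mode="resampled", seed=3))
        assert np.allclose(t_paired.seg_ind_pct, t_resampled.seg_ind_pct)


class TestVolumesAndStrain:
    def test_ef_matches_analytic_affine_ratio(self):
        """Uniform contraction toward the sliding centre is an affine map
        (x -> (1-s) x, y -> b y + const with b = (1-s) + s/6), so the
        true volume ratio is (1-s)^2 b."""
        s = 0.33
        cs, truth = generate_phantom(PhantomSpec(contraction=s, mode="paired"))
        a = 1.0 - s
        bscale = (1.0 - s) + s * (2.0 / 3.0 - 0.5)
        ef_analytic = 100.0 * (1.0 - a * a * bscale)
        assert truth.ef_pct == pytest.approx(ef_analytic, rel=0.015)
        res = analyze_subject(cs)
        assert res.metrics.ef_pct == pytest.approx(ef_analytic, rel=0.015)

    def test_gls_negative_under_contraction(self):
        _, truth = generate_phantom(PhantomSpec(contraction=0.33))
        assert truth.gls_pct < -10.0


class TestDeterminismAndNoise:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(noise_sd_mm=0.8, seed=9)
        cs1, t1 = generate_phantom(spec)
        cs2, t2 = generate_phantom(spec)
        for key in cs1.contours:
            assert np.array_equal(cs1.contours[key].points, cs2.contours[key].points)
        assert np.array_equal(t1.seg_ind_pct, t2.seg_ind_pct)

    def test_different_seed_differs_under_noise(self):
        cs1, _ = generate_phantom(PhantomSpec(noise_sd_mm=0.8, seed=9))
        cs2, _ = generate_phantom(PhantomSpec(noise_sd_mm=0.8, seed=10))
        key = next(iter(cs1.contours))
        some_differ = any(
            not np.array_equal(cs1.contours[k].points, cs2.contours[k].points)
            for k in cs1.contours
        )
        assert some_differ
        del key

    def test_contraction_crossing_center_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            PhantomSpec(contraction=1.2)


class TestSimulateObservers:
    def test_zero_jitter_identity_and_zero_bias(self):
        cs, _ = generate_phantom(PhantomSpec(seed=2))
        cs2 = simulate_observers(cs, jitter_sd_mm=0.0, seed=5)
        b1 = analyze_subject(cs, compute_metrics=False).bullseye
        b2 = analyze_subject(cs2, compute_metrics=False).bullseye
        res = bland_altman(b1.seg_pct, b2.seg_pct)
        assert res.bias == 0.0 and res.loa_low == 0.0

    def test_deterministic_per_seed(self):
        cs, _ = generate_phantom(PhantomSpec(seed=2))
        a = simulate_observers(cs, 1.0, seed=7)
        b = simulate_observers(cs, 1.0, seed=7)
        for k in a.contours:
            assert np.array_equal(a.contours[k].points, b.contours[k].points)

    def test_jitter_keeps_strong_interobserver_correlation(self):
        """1 mm contour jitter across phantoms with varied regional
        function keeps segmental InD correlation well above 0.7."""
        rng = np.random.default_rng(21)
        orig, reread = [], []
        for i in range(12):
            contraction = {k: float(np.clip(rng.normal(0.33, 0.08), 0.05, 0.6)) for k in range(1, 18)}
            cs, _ = generate_phantom(PhantomSpec(contraction=contraction, seed=100 + i))
            cs_obs = simulate_observers(cs, jitter_sd_mm=1.0, seed=200 + i)
            orig.extend(analyze_subject(cs, compute_metrics=False).bullseye.seg_pct)
            reread.extend(analyze_subject(cs_obs, compute_metrics=False).bullseye.seg_pct)
        res = bland_altman(np.array(orig), np.array(reread))
        assert res.pearson_r > 0.7
        assert abs(res.bias) < 2.0
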