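"""Slow-binding inference: curve fitting, kobs regressions, modality calls,
microscopic constants."""

import math

import numpy as np
import pytest

from inhibkit.errors import (
    InconsistentDataError,
    InsufficientDesignError,
    InvalidInputError,
)
from inhibkit.models import KobsRegression, ProgressCurve, slow_binding_progress
from inhibkit.progress import (
    ProgressCurveFitter,
    SlowBindingAnalyzer,
    classify_slow_binding_modality,
    derive_microscopic_constants,
    fit_progress_curve,
    regress_kobs_vs_inhibitor,
)
from inhibkit.simulate import (
    LEAD_CYTC_SLOW_DESIGN,
    LEAD_CYTC_SLOW_TRUTH,
    GeneratorSpec,
    generate_progress_curves,
)

from conftest import make_noisy_curve


def _curve(v0, vs, kobs, duration=600.0, n=60, S=6e-5, I=2e-8):
    t = np.linspace(0.0, duration, n)
    return ProgressCurve(times=t, signal=slow_binding_progress(t, v0, vs, kobs),
                         S=S, I=I)


class TestProgressCurveFitter:
    def test_noiseless_recovery(self):
        truth = (1e-8, 2e-9, 0.02)
        f = fit_progress_curve(_curve(*truth))
        assert f.slow_binding and f.converged
        assert f.v0 == pytest.approx(truth[0], rel=1e-6)
        assert f.vs == pytest.approx(truth[1], rel=1e-6)
        assert f.kobs == pytest.approx(truth[2], rel=1e-6)

    def test_straight_line_yields_sentinel(self):
        t = np.linspace(0.0, 600.0, 60)
        c = ProgressCurve(times=t, signal=3e-9 * t, S=6e-5, I=0.0)
        f = fit_progress_curve(c)
        assert not f.slow_binding
        assert f.v0 == f.vs == pytest.approx(3e-9, rel=1e-9)
        assert math.isnan(f.kobs)

    def test_noisy_line_yields_sentinel(self):
        t = np.linspace(0.0, 600.0, 60)
        rng = np.random.default_rng(5)
        y = 3e-9 * t + rng.normal(0, 0.02 * 3e-9 * 600, 60)
        f = fit_progress_curve(ProgressCurve(times=t, signal=y, S=6e-5, I=0.0))
        assert not f.slow_binding
        assert f.v0 == pytest.approx(3e-9, rel=0.05)

    def test_input_validation(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(InvalidInputError):
            ProgressCurveFitter().fit(t, 2.0 * t)  # too few points
        t = np.linspace(0, 10, 10)
        with pytest.raises(InvalidInputError):
            ProgressCurveFitter().fit(t, np.zeros_like(t))  # constant signal

    def test_noisy_replicates_unbiased(self):
        """Mean estimates over 100 noisy replicates stay within 5% of truth."""
        truth = (1e-8, 2e-9, 0.02)
        est = np.array([
            [f.v0, f.vs, f.kobs]
            for seed in range(100)
            for f in [fit_progress_curve(make_noisy_curve(*truth, sigma=0.02, seed=seed))]
        ])
        rel = np.abs(est.mean(axis=0) / np.array(truth) - 1)
        assert np.all(rel < 0.05), rel

    def test_interval_coverage(self):
        """~95% of kobs +/- 1.96*SE intervals cover the truth (allow 90-99%)."""
        truth = (1e-8, 2e-9, 0.02)
        hits = 0
        n = 300
        for seed in range(n):
            f = fit_progress_curve(make_noisy_curve(*truth, sigma=0.02, seed=1000 + seed))
            hits += abs(f.kobs - truth[2]) <= 1.96 * f.se_kobs
        assert 0.90 <= hits / n <= 0.99

    def test_matches_grid_search_oracle(self):
        """The multistart optimum matches an exhaustive shrinking-grid search
        over (v0, vs, kobs) on a small noisy instance."""
        truth = (1e-8, 2e-9, 0.02)
        c = make_noisy_curve(*truth, sigma=0.03, n=40, seed=11)
        f = fit_progress_curve(c)

        def sse(p):
            return float(np.sum((slow_binding_progress(c.times, *p) - c.signal) ** 2))

        # coarse grid around data-driven ranges, refined by repeated shrinking
        lo = np.array([1e-9, 1e-10, 1e-4])
        hi = np.array([5e-8, 1e-8, 0.5])
        center, width = np.sqrt(lo * hi), np.sqrt(hi / lo)
        for _ in range(12):
            grids = [np.geomspace(c / w, c * w, 11) for c, w in zip(center, width)]
            best = min(
                ((v0, vs, k) for v0 in grids[0] for vs in grids[1] for k in grids[2]),
                key=sse,
            )
            center = np.array(best)
            width = width ** 0.6
        assert f.sse <= sse(tuple(center)) * (1 + 1e-9)
        np.testing.assert_allclose([f.v0, f.vs, f.kobs], center, rtol=np.max(width) - 1)


class TestKobsRegression:
    def test_exact_line_recovered(self):
        # points on kobs = 0.00271 + 0.00066*I(nM): slope/intercept exact
        I = np.array([15, 20, 30, 40, 50]) * 1e-9
        k = 0.00271 + 0.00066e9 * I
        r = regress_kobs_vs_inhibitor(I, k)
        assert r.A * 1e-9 == pytest.approx(0.00066, rel=1e-12)
        assert r.B == pytest.approx(0.00271, rel=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_levels_rejected(self):
        with pytest.raises(InsufficientDesignError):
            regress_kobs_vs_inhibitor([1e-8, 2e-8], [0.01, 0.02])

    def test_noisy_slope_unbiased(self):
        """Mean slope over 200 seeded 5%-noise titrations within 5% of truth."""
        I = np.array([10, 20, 30, 40, 50]) * 1e-9
        k_true = 0.00271 + 0.00066e9 * I
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            k = k_true * (1 + rng.normal(0, 0.05, I.size))
            slopes.append(regress_kobs_vs_inhibitor(I, k).A * 1e-9)
        assert np.mean(slopes) == pytest.approx(0.00066, rel=0.05)


def _regressions_from_pattern(S_levels, A_fn, B_fn):
    return {
        S: KobsRegression(A=A_fn(S), B=B_fn(S), se_A=0.0, se_B=0.0,
                          r_squared=1.0, n=5, S=S)
        for S in S_levels
    }


class TestModalityClassifier:
    S_levels = (20e-6, 40e-6, 80e-6, 120e-6)

    def test_competitive_pattern(self):
        # A = k+0/(1+S/Km) falls with S while B stays flat
        regs = _regressions_from_pattern(
            self.S_levels, lambda S: 3.8e5 / (1 + S / 80e-6), lambda S: 0.00509)
        ev = classify_slow_binding_modality(regs)
        assert ev.modality == "competitive"
        assert ev.inv_A_slope > 0

    def test_noncompetitive_pattern(self):
        regs = _regressions_from_pattern(
            self.S_levels, lambda S: 6.6e5, lambda S: 0.00271)
        ev = classify_slow_binding_modality(regs)
        assert ev.modality == "noncompetitive"

    def test_null_noise_mostly_classified_noncompetitive(self):
        # flat A and B with pure noise: S-dependence should rarely be detected
        # (false "competitive" calls are bounded by the test's alpha level)
        calls = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            regs = _regressions_from_pattern(
                self.S_levels,
                lambda S: 6.6e5 * (1 + 0.05 * rng.standard_normal()),
                lambda S: 0.00271 * (1 + 0.05 * rng.standard_normal()))
            calls.append(classify_slow_binding_modality(regs).modality)
        assert calls.count("noncompetitive") >= 0.85 * len(calls)

    def test_insufficient_levels_undetermined(self):
        regs = _regressions_from_pattern((20e-6, 120e-6), lambda S: 6.6e5,
                                         lambda S: 0.00271)
        ev = classify_slow_binding_modality(regs)
        assert ev.modality == "undetermined"
        assert "need >= 3" in ev.reason


class TestMicroscopicConstants:
    def test_noncompetitive_published_constants(self):
        # A = 0.00066 1/s/nM, B = 0.00271 1/s -> Ki = 4.106 nM, reported 4.1
        regs = {6e-5: KobsRegression(A=0.00066e9, B=0.00271, se_A=1e-5 * 1e9,
                                     se_B=3e-4, r_squared=0.99, n=5, S=6e-5)}
        c = derive_microscopic_constants(regs, "noncompetitive")
        assert c.Ki_nM == pytest.approx(4.106, abs=5e-4)
        assert round(c.Ki_nM, 1) == 4.1

    def test_competitive_published_constants(self):
        # k+0 = 0.00038, k-0 = 0.00509 -> Ki = 13.39 nM, reported 13.4
        S_levels = (20e-6, 40e-6, 80e-6, 120e-6)
        regs = _regressions_from_pattern(
            S_levels, lambda S: 0.00038e9 / (1 + S / 80e-6), lambda S: 0.00509)
        c = derive_microscopic_constants(regs, "competitive", Km=80e-6)
        assert c.k_plus0_per_nM == pytest.approx(0.00038, rel=1e-9)
        assert c.Ki_nM == pytest.approx(13.395, abs=5e-3)
        assert round(c.Ki_nM, 1) == 13.4

    def test_competitive_km_coestimated(self):
        S_levels = (20e-6, 40e-6, 80e-6, 120e-6)
        regs = _regressions_from_pattern(
            S_levels, lambda S: 0.00038e9 / (1 + S / 80e-6), lambda S: 0.00509)
        c = derive_microscopic_constants(regs, "competitive", Km=None)
        assert c.k_plus0_per_nM == pytest.approx(0.00038, rel=1e-6)

    def test_ratio_identity(self):
        regs = {6e-5: KobsRegression(A=0.007, B=0.007, se_A=0, se_B=0,
                                     r_squared=1, n=4, S=6e-5)}
        c = derive_microscopic_constants(regs, "noncompetitive")
        assert c.Ki == pytest.approx(1.0)  # in the unit of I used

    def test_ki_invariant_to_inhibitor_unit(self):
        """Deriving from a titration expressed in molar vs in nanomolar gives
        the same Ki after unit conversion."""
        I_nM = np.array([15, 20, 30, 40, 50], dtype=float)
        k = 0.00271 + 0.00066 * I_nM
        r_nM = regress_kobs_vs_inhibitor(I_nM, k)     # I in nM
        r_M = regress_kobs_vs_inhibitor(I_nM * 1e-9, k)  # I in molar
        c_nM = derive_microscopic_constants({6e-5: r_nM}, "noncompetitive")
        c_M = derive_microscopic_constants({6e-5: r_M}, "noncompetitive")
        assert c_nM.Ki * 1e-9 == pytest.approx(c_M.Ki, rel=1e-9)

    def test_inconsistent_constants_rejected(self):
        regs = {6e-5: KobsRegression(A=6.6e5, B=-0.001, se_A=0, se_B=0,
                                     r_squared=1, n=4, S=6e-5)}
        with pytest.raises(InconsistentDataError):
            derive_microscopic_constants(regs, "noncompetitive")


class TestSlowBindingAnalyzer:
    def test_noiseless_end_to_end(self):
        spec = GeneratorSpec("slow-binding-noncompetitive", LEAD_CYTC_SLOW_TRUTH,
                             LEAD_CYTC_SLOW_DESIGN, "additive", 0.0, 0)
        curves, _ = generate_progress_curves(spec)
        an = SlowBindingAnalyzer(modality="noncompetitive").fit(curves)
        assert an.constants_.k_plus0_per_nM == pytest.approx(0.00066, rel=1e-6)
        assert an.k_minus0_ == pytest.approx(0.00271, rel=1e-6)
        assert an.Ki_ * 1e9 == pytest.approx(4.106, abs=1e-3)

    def test_zero_inhibitor_curves_are_linear_sentinels(self):
        spec = GeneratorSpec("slow-binding-noncompetitive", LEAD_CYTC_SLOW_TRUTH,
                             LEAD_CYTC_SLOW_DESIGN, "additive", 0.0, 0)
        curves, _ = generate_progress_curves(spec)
        an = SlowBindingAnalyzer(modality="noncompetitive").fit(curves)
        for c, f in zip(curves, an.fits_):
            if c.I == 0:
                assert not f.slow_binding

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            SlowBindingAnalyzer().fit([])
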