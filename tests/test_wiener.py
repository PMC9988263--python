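"""First-passage density: series correctness, symmetry, simulation, drift maps."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from rlddm import (
    DDMParams,
    drift_linear,
    drift_sigmoid,
    simulate_ddm,
    wiener_choice_prob,
    wiener_logpdf,
    wiener_logpdf_grad,
)

PARAM_SETS = [
    DDMParams(alpha=2.0, tau=0.3, beta=0.5, nu=1.0),
    DDMParams(alpha=1.2, tau=0.2, beta=0.35, nu=-0.8),
    DDMParams(alpha=0.8, tau=0.1, beta=0.6, nu=2.5),
    DDMParams(alpha=1.6, tau=0.25, beta=0.7, nu=0.4),
    DDMParams(alpha=3.0, tau=0.4, beta=0.5, nu=1e-4),
]


class TestDriftMaps:
    def test_linear_examples(self):
        assert drift_linear(0.4, 0.4, 2.0) == 0.0
        assert drift_linear(0.6, 0.2, 2.0) == pytest.approx(0.8)

    def test_linear_antisymmetric(self, rng):
        qh, ql = rng.normal(size=50), rng.normal(size=50)
        np.testing.assert_allclose(
            drift_linear(qh, ql, 1.7), -drift_linear(ql, qh, 1.7)
        )
        assert np.all(np.sign(drift_linear(qh, ql, 1.7)) == np.sign(qh - ql))

    def test_sigmoid_midpoint_and_limits(self):
        assert drift_sigmoid(0.3, 0.3, 1.0, 2.0) == 0.0
        assert drift_sigmoid(1e9, 0.0, 1.0, 2.0) == pytest.approx(2.0)
        assert drift_sigmoid(0.0, 1e9, 1.0, 2.0) == pytest.approx(-2.0)

    def test_sigmoid_analytic_point(self):
        # nu_max = 1 and scaled difference ln 3: 2 * (3/4) - 1 = 1/2
        assert drift_sigmoid(math.log(3.0), 0.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_sigmoid_strictly_increasing_and_bounded(self, rng):
        x = np.sort(rng.normal(scale=3, size=100))
        y = drift_sigmoid(x, 0.0, 1.3, 0.9)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.abs(y) < 0.9)


class TestLogpdf:
    def test_no_decision_time_is_log_zero(self):
        p = PARAM_SETS[0]
        assert wiener_logpdf(p.tau, "upper", p) == -np.inf
        assert wiener_logpdf(p.tau - 0.05, "lower", p) == -np.inf

    def test_strict_mode_raises(self):
        p = PARAM_SETS[0]
        with pytest.raises(ValueError, match="non-decision"):
            wiener_logpdf(p.tau, "upper", p, strict=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            wiener_logpdf(1.0, "upper", DDMParams(-1.0, 0.2, 0.5, 1.0))
        with pytest.raises(ValueError):
            wiener_logpdf(1.0, "upper", DDMParams(1.0, 0.2, 1.2, 1.0))
        with pytest.raises(ValueError):
            wiener_logpdf(1.0, "sideways", PARAM_SETS[0])

    def test_mirror_symmetry(self, rng):
        """Upper density at (nu, beta) = lower density at (-nu, 1-beta)."""
        for _ in range(25):
            a = rng.uniform(0.5, 3.0)
            t = rng.uniform(0.0, 0.5)
            b = rng.uniform(0.15, 0.85)
            v = rng.uniform(-2.5, 2.5)
            rt = t + rng.uniform(0.02, 3.0)
            up = wiener_logpdf(rt, "upper", DDMParams(a, t, b, v))
            lo = wiener_logpdf(rt, "lower", DDMParams(a, t, 1 - b, -v))
            assert up == pytest.approx(lo, rel=1e-12)

    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_joint_normalization(self, p):
        """Upper + lower first-passage densities integrate to 1 within 1e-4."""
        iu = quad(lambda r: np.exp(wiener_logpdf(float(r), "upper", p)),
                  p.tau, p.tau + 100, limit=300)[0]
        il = quad(lambda r: np.exp(wiener_logpdf(float(r), "lower", p)),
                  p.tau, p.tau + 100, limit=300)[0]
        assert iu + il == pytest.approx(1.0, abs=1e-4)
        assert iu == pytest.approx(wiener_choice_prob(p), abs=1e-4)

    def test_matches_reference_series_across_switch(self):
        """Both long-K series agree with the adaptive evaluation (< 1e-6),
        including around the small-time/large-time switch."""
        a, t0, b, v = 1.5, 0.2, 0.4, 0.8

        def reference(rt):
            # independent implementation, fixed K = 60 terms for both series
            t = rt - t0
            u = t / a**2
            w = b
            small = sum(
                (w + 2 * k) * math.exp(-((w + 2 * k) ** 2) / (2 * u))
                for k in range(-60, 61)
            ) / math.sqrt(2 * math.pi * u**3)
            large = sum(
                math.pi * k * math.exp(-(k**2) * math.pi**2 * u / 2)
                * math.sin(k * math.pi * w)
                for k in range(1, 61)
            )
            f0 = small if u < 1.0 else large
            return math.exp(-v * a * w - v**2 * t / 2) / a**2 * f0

        for rt in np.linspace(t0 + 0.01, t0 + 6.0, 120):
            ours = np.exp(wiener_logpdf(float(rt), "lower", DDMParams(a, t0, b, v)))
            assert ours == pytest.approx(reference(rt), abs=1e-6)

    def test_continuity_at_series_switch(self):
        """Density is continuous (< 1e-6 jump) where the evaluation switches
        between the small-time and large-time series."""
        from rlddm.wiener import _n_terms_large, _n_terms_small

        p = DDMParams(1.5, 0.2, 0.45, 0.6)
        us = np.linspace(0.05, 3.0, 20000)
        ks = np.array([_n_terms_small(u, 1e-7) for u in us])
        kl = np.array([_n_terms_large(u, 1e-7) for u in us])
        crossings = np.where(np.diff((ks < kl).astype(int)) != 0)[0]
        assert len(crossings) >= 1

        def reference(u, w):
            # both series with generous K = 80; they agree to ~1e-12 here
            small = sum(
                (w + 2 * k) * math.exp(-((w + 2 * k) ** 2) / (2 * u))
                for k in range(-80, 81)
            ) / math.sqrt(2 * math.pi * u**3)
            large = sum(
                math.pi * k * math.exp(-(k**2) * math.pi**2 * u / 2)
                * math.sin(k * math.pi * w)
                for k in range(1, 81)
            )
            assert abs(small - large) < 1e-10
            return 0.5 * (small + large)

        w = 1 - p.beta  # upper boundary maps to the mirrored lower density
        for c in crossings:
            for u in (us[c], us[c + 1]):  # one on each side of the switch
                rt = p.tau + u * p.alpha**2
                ours = np.exp(wiener_logpdf(float(rt), "upper", p))
                exact = (
                    math.exp(p.nu * p.alpha * w - p.nu**2 * (rt - p.tau) / 2)
                    / p.alpha**2 * reference(u, w)
                )
                assert ours == pytest.approx(exact, abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(15):
            a = rng.uniform(0.7, 2.5)
            t = rng.uniform(0.05, 0.5)
            b = rng.uniform(0.2, 0.8)
            v = rng.uniform(-2, 2)
            rt = t + rng.uniform(0.05, 2.0)
            bd = "upper" if rng.random() < 0.5 else "lower"
            _, g = wiener_logpdf_grad(rt, bd, DDMParams(a, t, b, v))
            for i, (da, dt, db, dv) in enumerate(
                [(0, 0, 0, 1), (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0)]
            ):
                lp1 = wiener_logpdf(rt, bd, DDMParams(a + h * da, t + h * dt, b + h * db, v + h * dv))
                lp2 = wiener_logpdf(rt, bd, DDMParams(a - h * da, t - h * dt, b - h * db, v - h * dv))
                assert (lp1 - lp2) / (2 * h) == pytest.approx(g[i], rel=1e-4, abs=1e-6)


class TestChoiceProb:
    def test_zero_drift_returns_bias(self):
        assert wiener_choice_prob(DDMParams(1.5, 0.2, 0.5, 0.0)) == pytest.approx(0.5)
        assert wiener_choice_prob(DDMParams(1.5, 0.2, 0.3, 0.0)) == pytest.approx(0.3)

    def test_closed_form_continuity_near_zero_drift(self):
        lo = wiener_choice_prob(DDMParams(1.5, 0.2, 0.4, 1e-7))
        assert lo == pytest.approx(0.4, abs=1e-5)

    def test_simulation_matches_closed_form(self):
        p = DDMParams(alpha=1.5, tau=0.2, beta=0.4, nu=0.8)
        n = 20000
        _, up = simulate_ddm(p, n, seed=11, dt=1e-4)
        target = wiener_choice_prob(p)
        se = math.sqrt(target * (1 - target) / n)
        assert abs(up.mean() - target) < 3 * se + 2e-3


class TestSimulate:
    def test_rts_exceed_nondecision_time(self):
        p = DDMParams(1.2, 0.35, 0.5, 0.5)
        rts, _ = simulate_ddm(p, 500, seed=1)
        assert np.all(rts > p.tau)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError, match="step size"):
            simulate_ddm(PARAM_SETS[0], 10, seed=0, dt=0.0)
        with pytest.raises(ValueError, match="paths"):
            simulate_ddm(PARAM_SETS[0], 0, seed=0)

    def test_seeded_determinism(self):
        p = PARAM_SETS[1]
        r1 = simulate_ddm(p, 200, seed=5)
        r2 = simulate_ddm(p, 200, seed=5)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])

    def test_higher_drift_faster_and_more_accurate(self):
        slow = DDMParams(1.5, 0.2, 0.5, 0.4)
        fast = DDMParams(1.5, 0.2, 0.5, 2.0)
        rts_s, up_s = simulate_ddm(slow, 4000, seed=2)
        rts_f, up_f = simulate_ddm(fast, 4000, seed=3)
        assert up_f.mean() > up_s.mean()
        assert rts_f[up_f == 1].mean() < rts_s[up_s == 1].mean()

    def test_likelihood_peaks_near_generating_parameters(self):
        """Grid over (nu, alpha) with tau/beta fixed at truth."""
        true = DDMParams(alpha=1.4, tau=0.25, beta=0.5, nu=0.7)
        rts, up = simulate_ddm(true, 4000, seed=21, dt=2e-4)
        nus = np.linspace(0.1, 1.3, 7)
        alphas = np.linspace(0.8, 2.0, 7)
        ll = np.empty((7, 7))
        for i, v in enumerate(nus):
            for j, a in enumerate(alphas):
                p = DDMParams(a, true.tau, true.beta, v)
                up_lp = wiener_logpdf(rts[up == 1], "upper", p)
                lo_lp = wiener_logpdf(rts[up == 0], "lower", p)
                ll[i, j] = up_lp.sum() + lo_lp.sum()
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(nus[i] - true.nu) <= 0.2 + 1e-9
        assert abs(alphas[j] - true.alpha) <= 0.2 + 1e-9
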