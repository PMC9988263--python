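"""Hierarchical model: transforms, likelihood composition, priors, gradients."""

import numpy as np
import pytest
from rlddm import MODEL_SPECS, RLDDM, DDMParams, SubjectParams, run_sequence
from rlddm import drift_sigmoid, wiener_logpdf
from rlddm.hierarchical import (
    PRIORS,
    HierarchicalRLDDM,
    free_params,
    prepare_sessions,
    transform_to_native,
    transform_to_unconstrained,
)
from rlddm.params import PARAM_NAMES


class TestTransforms:
    def test_identities_at_zero(self):
        p = transform_to_native({nm: 0.0 for nm in PARAM_NAMES}, min_rt=0.8)
        assert p.eta_pos == 0.5 and p.beta == 0.5
        assert p.rho == 1.0 and p.alpha == 1.0 and p.nu == 1.0
        assert p.tau == pytest.approx(0.4)  # logistic(0) * min RT

    def test_tau_always_below_min_rt(self, rng):
        for raw in rng.normal(scale=5, size=50):
            p = transform_to_native({nm: raw for nm in PARAM_NAMES}, min_rt=0.6)
            assert 0 < p.tau < 0.6

    def test_round_trip_identity(self, rng):
        for _ in range(20):
            raw = {nm: rng.normal() for nm in PARAM_NAMES}
            p = transform_to_native(raw, min_rt=0.73)
            back = transform_to_unconstrained(p, min_rt=0.73)
            for nm in PARAM_NAMES:
                assert back[nm] == pytest.approx(raw[nm], abs=1e-12)

    def test_missing_min_rt(self):
        with pytest.raises(ValueError, match="minimum reaction time"):
            transform_to_native({nm: 0.0 for nm in PARAM_NAMES}, min_rt=0.0)


class TestDataPreparation:
    def test_empty_data_rejected(self, small_multidrug_cohort):
        _, df = small_multidrug_cohort
        with pytest.raises(ValueError, match="no completed test trials"):
            prepare_sessions(df[df.trial_type == "control"])

    def test_nonpositive_rt_rejected(self, small_multidrug_cohort):
        _, df = small_multidrug_cohort
        bad = df.copy()
        i = bad.index[(bad.trial_type == "test") & (bad.choice != "none")][0]
        bad.loc[i, "rt_s"] = -0.1
        with pytest.raises(ValueError, match="non-positive reaction"):
            prepare_sessions(bad)

    def test_reference_drug_leads(self, small_multidrug_cohort):
        _, df = small_multidrug_cohort
        tb = prepare_sessions(df, drug_reference="placebo")
        assert tb.drugs[0] == "placebo"
        assert tb.n_sessions == tb.n_subjects * 3


class TestLikelihood:
    def test_decomposition_oracle(self, small_single_cohort):
        """Model log likelihood of a session equals the independent composition
        of value recursion -> drift mapping -> Wiener density per trial."""
        _, _, df = small_single_cohort
        m = RLDDM(df, spec=4)
        h = m.hierarchical
        tb = h.table
        rng = np.random.default_rng(0)
        x = h.sample_prior(rng)
        nat = h.native_sessions(x)
        lls = h.loglike_sessions(x)
        for i in range(tb.n_sessions):
            a, b = tb.ptr[i], tb.ptr[i + 1]
            p = SubjectParams(**{nm: nat[i, j] for j, nm in enumerate(PARAM_NAMES)})
            choices = np.where(tb.choices[a:b] == 1, "high", "low")
            series = run_sequence(choices, tb.outcomes[a:b], p, MODEL_SPECS[4])
            ref = 0.0
            for t in range(b - a):
                vt = drift_sigmoid(series.q_high[t], series.q_low[t], p.nu, p.nu_max)
                bd = "upper" if tb.choices[a + t] == 1 else "lower"
                ref += wiener_logpdf(
                    tb.rts[a + t], bd, DDMParams(p.alpha, p.tau, p.beta, float(vt))
                )
            assert lls[i] == pytest.approx(ref, rel=1e-10)

    def test_rho_one_nesting_exact(self, small_single_cohort):
        """rho -> 1 collapses model 2 onto 1 and model 4 onto 3 (<= 1e-10)."""
        _, _, df = small_single_cohort
        for full_id, nested_id in ((2, 1), (4, 3)):
            m_full = RLDDM(df, spec=full_id)
            m_nested = RLDDM(df, spec=nested_id)
            hf, hn = m_full.hierarchical, m_nested.hierarchical
            rng = np.random.default_rng(1)
            xn = hn.sample_prior(rng)
            # embed the nested draw into the full model with rho pinned at 1
            xf = np.zeros(hf.n_dim)
            for nm in hn.names:
                pf, pn = hf.names.index(nm), hn.names.index(nm)
                of, on = hf._offsets(pf), hn._offsets(pn)
                xf[of["mu"]] = xn[on["mu"]]
                xf[of["log_sigma"]] = xn[on["log_sigma"]]
                S = hn.table.n_subjects
                xf[of["z"]: of["z"] + S] = xn[on["z"]: on["z"] + S]
            orho = hf._offsets(hf.names.index("rho"))
            xf[orho["mu"]] = 0.0          # exp(0) = 1
            xf[orho["log_sigma"]] = -40.0  # scale ~ 0: all subjects at rho = 1
            ll_full = np.sum(hf.loglike_sessions(xf))
            ll_nested = np.sum(hn.loglike_sessions(xn))
            assert abs(ll_full - ll_nested) < 1e-10

    def test_free_params_per_variant(self):
        assert "rho" not in free_params(MODEL_SPECS[1])
        assert "nu_max" not in free_params(MODEL_SPECS[2])
        assert set(free_params(MODEL_SPECS[4])) == set(PARAM_NAMES)


class TestGradient:
    @pytest.mark.parametrize("spec", [1, 4])
    def test_matches_finite_differences_multidrug(self, spec, small_multidrug_cohort):
        _, df = small_multidrug_cohort
        h = RLDDM(df, spec=spec).hierarchical
        rng = np.random.default_rng(3)
        x = h.initial_point(rng) + 0.1 * rng.standard_normal(h.n_dim)
        lp, g = h.logpost_and_grad(x)
        assert np.isfinite(lp)
        for i in rng.choice(h.n_dim, size=20, replace=False):
            e = np.zeros(h.n_dim)
            e[i] = 1e-6
            fd = (h.logpost_and_grad(x + e)[0] - h.logpost_and_grad(x - e)[0]) / 2e-6
            assert fd == pytest.approx(g[i], rel=1e-4, abs=1e-5)


class TestPriors:
    def test_prior_catalog_values(self):
        assert PRIORS["eta_pos"]["mu"] == (0.0, 1.0) and PRIORS["eta_pos"]["sigma"] == 1.0
        assert PRIORS["beta"]["mu"] == (0.0, 0.5) and PRIORS["beta"]["sigma"] == 0.1
        assert PRIORS["rho"]["mu"] == (0.1, 0.1)
        assert PRIORS["alpha"]["mu"] == (0.0, 0.1)
        assert PRIORS["nu"]["mu"] == (0.2, 0.2)
        assert PRIORS["nu_max"]["mu"] == (0.5, 0.2)
        for nm in PARAM_NAMES:
            assert PRIORS[nm]["d_scale"] == 0.1

    def test_prior_predictive_moments(self, small_multidrug_cohort):
        """Sampled prior draws reproduce the catalog's locations and scales."""
        _, df = small_multidrug_cohort
        h = RLDDM(df, spec=4).hierarchical
        rng = np.random.default_rng(11)
        draws = np.array([h.sample_prior(rng) for _ in range(4000)])
        for nm, tol in (("eta_pos", 0.06), ("beta", 0.03), ("nu", 0.012)):
            off = h._offsets(h.names.index(nm))
            mus = draws[:, off["mu"]]
            m0, s0 = PRIORS[nm]["mu"]
            assert mus.mean() == pytest.approx(m0, abs=tol)
            assert mus.std() == pytest.approx(s0, rel=0.08)
            sig = np.exp(draws[:, off["log_sigma"]])
            # |N(0, s)| has mean s * sqrt(2/pi)
            assert sig.mean() == pytest.approx(
                PRIORS[nm]["sigma"] * np.sqrt(2 / np.pi), rel=0.1
            )
            z = draws[:, off["z"]: off["z"] + h.table.n_subjects]
            assert z.mean() == pytest.approx(0.0, abs=0.05)
            assert z.std() == pytest.approx(1.0, rel=0.05)

    def test_zero_scale_collapses_subjects_to_intercept(self, small_multidrug_cohort):
        """Non-centered degenerate limit: scale -> 0 pins every subject to the
        group intercept."""
        _, df = small_multidrug_cohort
        h = RLDDM(df, spec=4).hierarchical
        x = np.zeros(h.n_dim)
        rng = np.random.default_rng(5)
        for p, nm in enumerate(h.names):
            off = h._offsets(p)
            x[off["mu"]] = PRIORS[nm]["mu"][0]
            x[off["log_sigma"]] = -40.0
            S = h.table.n_subjects
            x[off["z"]: off["z"] + S] = rng.standard_normal(S)  # irrelevant at scale 0
            D = h.n_drug_eff
            x[off["d_log_scale"]: off["d_log_scale"] + D] = -40.0
            x[off["z_d"]: off["z_d"] + S * D] = rng.standard_normal(S * D)
        nat = h.native_sessions(x)
        ref = nat[h.table.drug_idx == 0]
        # within the reference drug all sessions share identical natives
        for col, nm in enumerate(PARAM_NAMES):
            if nm == "tau":
                continue  # scaled by session-specific minimum RT by design
            assert np.ptp(ref[:, col]) < 1e-12


class TestFit:
    def test_empty_data_is_an_error(self):
        import pandas as pd

        from rlddm.tasks import COLUMNS

        with pytest.raises(ValueError):
            RLDDM(pd.DataFrame(columns=COLUMNS), spec=4)

    def test_seeded_fit_reproducible(self, small_single_cohort):
        _, _, df = small_single_cohort
        sub = df[df.subject_id.isin(sorted(df.subject_id.unique())[:3])]
        a = RLDDM(sub, spec=1).fit(profile="smoke", seed=9)
        b = RLDDM(sub, spec=1).fit(profile="smoke", seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_warmup_must_be_below_iterations(self, small_single_cohort):
        _, _, df = small_single_cohort
        with pytest.raises(ValueError, match="warmup"):
            RLDDM(df, spec=1).fit(iterations=100, warmup=100, profile=None)
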