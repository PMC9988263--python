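"""Endogenous pain modulation and its link to prediction errors.

Trial-wise modulation is the test-trial value minus the mean of the
session's passive control trials with the *matching* outcome (wins against
relief controls, losses against increase controls), separately for the VAS
intensity rating and the behaviourally self-adjusted temperature; negative
values mean pain inhibition.  The modulation records are regressed on the
model-derived prediction errors with drug as a factor (linear mixed model,
random subject intercept), and choice preference for the high-contingency
colour in the late task blocks is summarized with a mixed-effects logistic
intercept test against chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "compute_modulation",
    "fit_pe_model",
    "choice_preference",
    "PEModelResult",
    "ChoicePreference",
]


def compute_modulation(trials: pd.DataFrame) -> pd.DataFrame:
    """Test-minus-control modulation per completed test trial.

    For every subject-session, the mean VAS rating and behavioural
    temperature change of the win controls (respectively lose controls) is
    subtracted from each winning (losing) test trial.  Test trials without a
    matching-outcome control in their session are kept but flagged
    ``missing_controls`` with NaN modulation, never zero-filled.
    """
    test = trials[
        (trials["trial_type"] == "test") & (trials["outcome"].isin(["win", "lose"]))
    ].copy()
    ctrl = trials[trials["trial_type"] == "control"]
    cm = (
        ctrl.groupby(["subject_id", "drug", "outcome"])[["vas_rating", "beh_delta_c"]]
        .mean()
        .rename(columns={"vas_rating": "ctrl_vas", "beh_delta_c": "ctrl_beh"})
        .reset_index()
    )
    out = test.merge(cm, on=["subject_id", "drug", "outcome"], how="left")
    out["vas_modulation"] = out["vas_rating"] - out["ctrl_vas"]
    out["beh_modulation"] = out["beh_delta_c"] - out["ctrl_beh"]
    out["missing_controls"] = out["ctrl_vas"].isna()
    cols = [
        "subject_id", "drug", "session_order", "block", "trial_index",
        "outcome", "vas_modulation", "beh_modulation", "missing_controls",
    ]
    return out[cols]


@dataclass
class PEModelResult:
    """Coefficient table and fitted mixed model of one outcome measure."""

    outcome_measure: str
    table: pd.DataFrame  # coef, se, z, p, ci lower/upper per fixed effect
    fitted: object

    @property
    def pe_slope(self) -> float:
        return float(self.table.loc["pe", "coef"])

    @property
    def pe_ci(self) -> tuple:
        return (
            float(self.table.loc["pe", "ci_lower"]),
            float(self.table.loc["pe", "ci_upper"]),
        )


def fit_pe_model(
    records: pd.DataFrame,
    include_drug: bool = True,
    outcome_measure: str = "vas",
    include_order: bool = False,
    reference_drug: str = "placebo",
) -> PEModelResult:
    """Mixed-effects regression of modulation on prediction error.

    ``records`` must carry a ``pe`` column (modulation records joined with
    the extracted PE series) plus the modulation columns from
    :func:`compute_modulation`.  Fixed effects: PE, drug, and their
    interaction (drug terms only when ``include_drug`` and several levels are
    present); random intercept per subject.  A negative PE slope means that
    unexpected relief enhances pain inhibition.
    """
    ycol = {"vas": "vas_modulation", "beh": "beh_modulation"}[outcome_measure]
    df = records.dropna(subset=[ycol, "pe"]).copy()
    if df["subject_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    terms = ["pe"]
    if include_drug and df["drug"].nunique() > 1:
        lev = f"C(drug, Treatment('{reference_drug}'))"
        terms += [lev, f"pe:{lev}"]
    if include_order and df["session_order"].nunique() > 1:
        terms.append("C(session_order)")
    formula = f"{ycol} ~ " + " + ".join(terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=True)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular design in PE model ({formula}): {e}") from e
    fe = fit.fe_params
    ci = fit.conf_int().loc[fe.index]
    table = pd.DataFrame(
        {
            "coef": fe,
            "se": fit.bse.loc[fe.index],
            "z": fit.tvalues.loc[fe.index],
            "p": fit.pvalues.loc[fe.index],
            "ci_lower": ci[0],
            "ci_upper": ci[1],
        }
    )
    table.index = [_clean_term(t) for t in table.index]
    return PEModelResult(outcome_measure=outcome_measure, table=table, fitted=fit)


def _clean_term(term: str) -> str:
    return (
        term.replace("C(drug, Treatment('placebo'))", "drug")
        .replace("C(session_order)", "order")
        .replace("[T.", "[")
    )


@dataclass
class ChoicePreference:
    """High-contingency choice proportions in the selected blocks."""

    per_subject: pd.Series
    mean: float
    sd: float
    intercept_logit: float
    intercept_ci: tuple
    above_chance: bool

    def __str__(self) -> str:
        lo, hi = self.intercept_ci
        return (
            f"choice preference {self.mean:.1%} (SD {self.sd:.1%}); "
            f"logit intercept {self.intercept_logit:.3f} "
            f"[{lo:.3f}, {hi:.3f}] -> above chance: {self.above_chance}"
        )


def choice_preference(
    trials: pd.DataFrame,
    blocks=(4, 5),
    drug: str | None = None,
) -> ChoicePreference:
    """Preference for the high-contingency option in the stated blocks.

    Uses completed test trials only; subjects with no eligible trials are
    excluded with a warning.  The above-chance test is a random-intercept
    logistic regression of the choice indicator on an intercept (fit by
    variational Bayes); 'above chance' means the interval of the group
    intercept lies entirely above 0 on the logit scale.
    """
    df = trials[
        (trials["trial_type"] == "test")
        & trials["choice"].isin(["high", "low"])
        & trials["block"].isin(list(blocks))
    ]
    if drug is not None:
        df = df[df["drug"] == drug]
    if len(df) == 0:
        raise ValueError("no completed test trials in the selected blocks")
    eligible = df.groupby("subject_id").size()
    dropped = set(trials["subject_id"].unique()) - set(eligible.index)
    if dropped:
        warnings.warn(f"subjects without eligible trials excluded: {sorted(dropped)}")
    per_subject = df.groupby("subject_id")["choice"].apply(lambda c: (c == "high").mean())

    y = (df["choice"] == "high").astype(float).to_numpy()
    exog = np.ones((len(y), 1))
    groups = df["subject_id"].astype("category").cat.codes.to_numpy()
    n_grp = groups.max() + 1
    exog_vc = np.zeros((len(y), n_grp))
    exog_vc[np.arange(len(y)), groups] = 1.0
    if len(per_subject) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glmm = sm.BinomialBayesMixedGLM(
                y, exog, exog_vc, ident=np.zeros(n_grp, dtype=int)
            ).fit_vb()
        mean = float(glmm.fe_mean[0])
        sd = float(glmm.fe_sd[0])
    else:  # single subject: plain logistic intercept
        fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        mean = float(fit.params[0])
        sd = float(fit.bse[0])
    ci = (mean - 1.96 * sd, mean + 1.96 * sd)
    return ChoicePreference(
        per_subject=per_subject,
        mean=float(per_subject.mean()),
        sd=float(per_subject.std(ddof=1)) if len(per_subject) > 1 else 0.0,
        intercept_logit=mean,
        intercept_ci=ci,
        above_chance=ci[0] > 0.0,
    )
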