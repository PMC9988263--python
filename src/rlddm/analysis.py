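"""Posterior summaries: HDIs, drug contrasts, predictive checks, PE series.

Free functions operating on :class:`rlddm.model.RLDDMResults`; the results
object exposes them as methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, SubjectParams
from .rl import run_sequence
from .tasks import TaskConfig, generate_schedule, simulate_agent

__all__ = ["HDInterval", "hdi", "contrast_drug", "posterior_predict", "extract_pe", "PPCResult"]


@dataclass(frozen=True)
class HDInterval:
    """Narrowest contiguous interval holding ``mass`` of the draws."""

    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def hdi(samples, mass: float = 0.95) -> HDInterval:
    """Highest density interval by the sorted-window method.

    Scans all windows of ``ceil(mass * n)`` consecutive order statistics and
    returns the narrowest; constant samples give a zero-width interval.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 samples for an HDI, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must lie in (0, 1], got {mass}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return HDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return HDInterval(float(x[i]), float(x[i + k]), mass)


def contrast_drug(results, parameter: str, drug_a: str, drug_b: str, mass: float = 0.95):
    """HDI of the group-level difference of a parameter's drug effect.

    The difference ``effect(drug_a) - effect(drug_b)`` is computed draw-wise
    on the unconstrained scale (the reference drug's effect is zero) before
    summarizing.  Returns ``(HDInterval, encloses_zero)``.
    """
    model = results.model
    if parameter not in model.hierarchical.names:
        raise KeyError(
            f"parameter {parameter!r} is not sampled by model {model.spec.id}; "
            f"available: {model.hierarchical.names}"
        )
    eff_a = results.drug_effect_draws(parameter, drug_a)
    eff_b = results.drug_effect_draws(parameter, drug_b)
    diff = eff_a - eff_b
    interval = hdi(diff, mass)
    return interval, interval.contains(0.0)


@dataclass
class PPCResult:
    """Posterior predictive distribution of the choice-preference statistic."""

    samples: np.ndarray
    observed: float
    mean: float
    interval: HDInterval
    p_value_one_sided: float  # P(replicate >= observed)
    p_value_two_sided: float


def posterior_predict(
    results,
    task: TaskConfig = TaskConfig(),
    n_rep: int = 200,
    seed: int = 0,
    drug: str | None = None,
    last_blocks: int = 2,
) -> PPCResult:
    """Replicate the task from posterior draws and score choice preference.

    For each replicate one posterior draw is selected, every session of the
    requested drug condition is re-played by an agent with that draw's
    subject-session parameters on a fresh schedule, and the group-mean
    proportion of high-contingency choices in the last ``last_blocks`` blocks
    is recorded.  Returns the replicate distribution, its mean and HDI, and
    posterior p-values of the observed statistic (one-sided ``P(rep >= obs)``
    and two-sided ``2 * min(p, 1 - p)``).
    """
    model = results.model
    tb = model.hierarchical.table
    rng = np.random.default_rng(seed)
    if drug is None:
        drug = tb.drugs[0]
    if drug not in tb.drugs:
        raise KeyError(f"drug {drug!r} not in fitted conditions {tb.drugs}")
    d_idx = tb.drugs.index(drug)
    sess_ids = np.where(tb.drug_idx == d_idx)[0]

    blocks_sel = list(range(task.n_blocks - last_blocks + 1, task.n_blocks + 1))
    observed = _observed_preference(tb, sess_ids, blocks_sel)

    flat = results.draws.reshape(-1, results.draws.shape[-1])
    stats = np.empty(n_rep)
    for r in range(n_rep):
        x = flat[rng.integers(flat.shape[0])]
        nat = model.hierarchical.native_sessions(x)
        props = []
        for i in sess_ids:
            p = SubjectParams(**{nm: nat[i, j] for j, nm in enumerate(PARAM_NAMES)})
            sched = generate_schedule(task, int(rng.integers(2**31)))
            played = simulate_agent(
                p, sched, model.spec, int(rng.integers(2**31)), task
            )
            late = played[played["block"].isin(blocks_sel)]
            done = late[late["choice"] != "none"]
            if len(done):
                props.append((done["choice"] == "high").mean())
        stats[r] = np.mean(props) if props else np.nan
    stats = stats[np.isfinite(stats)]
    p_one = float(np.mean(stats >= observed))
    return PPCResult(
        samples=stats,
        observed=observed,
        mean=float(np.mean(stats)),
        interval=hdi(stats),
        p_value_one_sided=p_one,
        p_value_two_sided=float(2.0 * min(p_one, 1.0 - p_one)),
    )


def _observed_preference(tb, sess_ids, blocks_sel) -> float:
    props = []
    sel = np.asarray(blocks_sel)
    for i in sess_ids:
        a, b = tb.ptr[i], tb.ptr[i + 1]
        m = np.isin(tb.blocks[a:b], sel)
        if m.any():
            props.append(float(np.mean(tb.choices[a:b][m])))
    if not props:
        warnings.warn("no completed trials in the selected blocks")
        return np.nan
    return float(np.mean(props))


def extract_pe(results) -> pd.DataFrame:
    """Trial-wise prediction errors from subject-level posterior means.

    The posterior mean of each subject-session's native parameters is plugged
    into the value recursion over that session's realized choice/outcome
    sequence (condition-specific means: each drug session uses its own
    parameter set).  Returns one row per completed test trial with the
    decision-time expected values and the prediction error.
    """
    model = results.model
    tb = model.hierarchical.table
    nat = results.posterior_mean_natives()
    rows = []
    for i in range(tb.n_sessions):
        a, b = tb.ptr[i], tb.ptr[i + 1]
        choices = np.where(tb.choices[a:b] == 1, "high", "low")
        p = SubjectParams(**{nm: nat[i, j] for j, nm in enumerate(PARAM_NAMES)})
        series = run_sequence(choices, tb.outcomes[a:b], p, model.spec)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": tb.subjects[tb.subj_idx[i]],
                    "drug": tb.drugs[tb.drug_idx[i]],
                    "block": tb.blocks[a:b],
                    "trial_index": tb.trial_index[a:b],
                    "choice": choices,
                    "outcome": np.where(tb.outcomes[a:b] > 0, "win", "lose"),
                    "q_high": series.q_high,
                    "q_low": series.q_low,
                    "pe": series.delta,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
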