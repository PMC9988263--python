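"""Simple summary plots for predictive checks and pain modulation."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_ppc", "plot_modulation_by_outcome"]


def plot_ppc(ppc, ax=None):
    """Histogram of replicated choice-preference statistics with the observed
    value and the 95% HDI marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(ppc.samples, bins=25, color="steelblue", alpha=0.75, density=True)
    ax.axvline(ppc.observed, color="black", ls="--", lw=1.5,
               label=f"observed {ppc.observed:.3f}")
    ax.axvspan(ppc.interval.lower, ppc.interval.upper, color="steelblue",
               alpha=0.15, label="95% HDI")
    ax.set_xlabel("high-contingency choice proportion (last 2 blocks)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_modulation_by_outcome(records, measure: str = "vas", ax=None):
    """Mean ± SD of trial-wise modulation per drug and outcome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    col = {"vas": "vas_modulation", "beh": "beh_modulation"}[measure]
    summary = records.groupby(["drug", "outcome"])[col].agg(["mean", "std"])
    drugs = summary.index.get_level_values(0).unique()
    width = 0.35
    xs = np.arange(len(drugs))
    for k, outcome in enumerate(("win", "lose")):
        means = [summary.loc[(d, outcome), "mean"] for d in drugs]
        sds = [summary.loc[(d, outcome), "std"] for d in drugs]
        ax.bar(xs + (k - 0.5) * width, means, width, yerr=sds, capsize=3,
               label=outcome, alpha=0.8)
    ax.axhline(0, color="gray", lw=0.8)
    ax.set_xticks(xs, drugs)
    unit = "VAS" if measure == "vas" else "°C"
    ax.set_ylabel(f"modulation ({unit}; negative = inhibition)")
    ax.legend(frameon=False, fontsize=8)
    return ax
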