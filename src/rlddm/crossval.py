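"""K-fold cross-validated predictive accuracy (ELPD) across model variants.

Folds partition *subjects*; for each fold the model is re-fit on the
remaining subjects and the held-out subjects' (choice, RT) pairs are scored
by their expected log pointwise predictive density.  Held-out subjects have
no subject-level posterior, so their parameters are simulated from the
group-level distribution of each posterior draw ("new-subject" prediction);
a plug-in alternative using the group means is available for sensitivity
analysis.  A model is decisively better when the ELPD difference is at least
twice its standard error (computed from the pointwise difference vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hierarchical import HierarchicalRLDDM, prepare_sessions
from .rl import ModelSpec

__all__ = ["ELPDResult", "kfold_split", "kfold_elpd", "compare", "is_decisive"]


@dataclass
class ELPDResult:
    """Total and pointwise predictive density of one model over the folds."""

    model_id: int
    elpd: float
    pointwise: np.ndarray          # per held-out trial, aligned to trial_key
    trial_key: pd.DataFrame        # subject_id, drug, block, trial_index
    folds: list
    per_fold: list = field(default_factory=list)


def kfold_split(subject_ids, k: int = 10, seed: int = 0) -> list:
    """Disjoint subject folds with sizes differing by at most one."""
    subjects = list(subject_ids)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(subjects[idx])
    return [sorted(f) for f in folds]


def kfold_elpd(
    spec,
    data: pd.DataFrame,
    folds: list,
    fit_profile: str = "desk",
    seed: int = 0,
    method: str = "new_subject",
    n_posterior: int = 40,
    n_sim: int = 10,
    drug_reference: str = "placebo",
) -> ELPDResult:
    """Score one model variant over pre-computed subject folds.

    ``method='new_subject'`` marginalizes held-out subjects over the
    group-level distribution with ``n_sim`` simulated parameter sets per
    retained posterior draw (``n_posterior`` thinned draws per fold);
    ``method='group_mean'`` plugs in the group-level location instead.
    """
    from .model import RLDDM

    spec = spec if isinstance(spec, ModelSpec) else ModelSpec.from_id(spec)
    if method not in ("new_subject", "group_mean"):
        raise ValueError(f"unknown held-out prediction method {method!r}")
    all_subjects = set(data["subject_id"].unique())
    flat = [s for f in folds for s in f]
    if len(flat) != len(set(flat)) or set(flat) != all_subjects:
        raise ValueError("folds must partition the subject set")
    for i, fold in enumerate(folds):
        if set(fold) == all_subjects:
            raise ValueError(f"fold {i} leaves no training subjects")

    keys, points, per_fold = [], [], []
    for i, fold in enumerate(folds):
        train = data[~data["subject_id"].isin(fold)]
        held = data[data["subject_id"].isin(fold)]
        res = RLDDM(train, spec=spec, drug_reference=drug_reference).fit(
            profile=fit_profile, seed=seed + 7919 * i
        )
        ll = _heldout_pointwise(
            res, held, method, n_posterior, n_sim, seed + 104729 * i, drug_reference
        )
        keys.append(ll[0])
        points.append(ll[1])
        per_fold.append(float(np.sum(ll[1])))
    key = pd.concat(keys, ignore_index=True)
    pointwise = np.concatenate(points)
    return ELPDResult(
        model_id=spec.id,
        elpd=float(np.sum(pointwise)),
        pointwise=pointwise,
        trial_key=key,
        folds=[list(f) for f in folds],
        per_fold=per_fold,
    )


def _heldout_pointwise(res, held, method, n_posterior, n_sim, seed, drug_reference):
    h_train = res.model.hierarchical
    table = prepare_sessions(held, drug_reference)
    if table.drugs != h_train.table.drugs:
        # a held-out fold may lack a drug level; require label compatibility
        if not set(table.drugs) <= set(h_train.table.drugs):
            raise ValueError("held-out data contain drug levels absent from training")
    h_held = HierarchicalRLDDM(res.model.spec, table)
    rng = np.random.default_rng(seed)
    flat = res.draws.reshape(-1, res.draws.shape[-1])
    idx = np.linspace(0, len(flat) - 1, min(n_posterior, len(flat))).astype(int)

    n_rep = len(idx) * (n_sim if method == "new_subject" else 1)
    lls = np.empty((n_rep, table.n_trials))
    r = 0
    drug_map = np.array(
        [h_train.table.drugs.index(d) for d in table.drugs], dtype=int
    )
    for di in idx:
        blocks = h_train.unpack(flat[di])
        reps = n_sim if method == "new_subject" else 1
        for _ in range(reps):
            lp = _new_session_linpred(h_train, table, blocks, drug_map, rng, method)
            nat = _natives(h_held, lp)
            lls[r] = h_held.trial_loglike(nat)
            r += 1
    pointwise = logsumexp(lls, axis=0) - np.log(n_rep)
    key = pd.DataFrame(
        {
            "subject_id": np.repeat(
                [table.subjects[s] for s in table.subj_idx],
                np.diff(table.ptr),
            ),
            "drug": np.repeat(
                [table.drugs[d] for d in table.drug_idx], np.diff(table.ptr)
            ),
            "block": table.blocks,
            "trial_index": table.trial_index,
        }
    )
    return key, pointwise


def _new_session_linpred(h_train, table, blocks, drug_map, rng, method):
    """Unconstrained session values for unseen subjects under one draw."""
    S = table.n_subjects
    D = h_train.n_drug_eff
    lp = np.empty((table.n_sessions, len(h_train.names)))
    for p, nm in enumerate(h_train.names):
        b = blocks[nm]
        if method == "new_subject":
            z = rng.standard_normal(S)
            v = b["mu"] + b["sigma"] * z[table.subj_idx]
        else:
            v = np.full(table.n_sessions, b["mu"])
        if D > 0:
            if method == "new_subject":
                zd = rng.standard_normal((S, D))
                if D == 2:
                    w = np.empty_like(zd)
                    w[:, 0] = zd[:, 0]
                    w[:, 1] = b["r"] * zd[:, 0] + np.sqrt(1 - b["r"] ** 2) * zd[:, 1]
                else:
                    w = zd
                eff = b["d_loc"][None, :] + b["d_scale"][None, :] * w
            else:
                eff = np.broadcast_to(b["d_loc"], (S, D))
            train_didx = drug_map[table.drug_idx]
            mask = train_didx > 0
            v = v.copy()
            v[mask] += eff[table.subj_idx[mask], train_didx[mask] - 1]
        lp[:, p] = v
    return lp


def _natives(h_held, lp):
    nat, _ = h_held._natives_from_linpred(lp)
    return nat


def is_decisive(elpd_diff: float, se_diff: float) -> bool:
    """Difference rule: decisive when ``|diff| >= 2 * se(diff)``.

    A zero difference (identical predictive performance) is never decisive.
    """
    if elpd_diff == 0.0:
        return False
    return abs(elpd_diff) >= 2.0 * se_diff


def compare(results: list) -> pd.DataFrame:
    """Rank scored models; differences are relative to the best model.

    All results must be scored on identical folds and trials.  ``se_diff``
    is computed from the pointwise difference vector; the best model's
    difference is 0 with se 0.
    """
    if len(results) < 2:
        raise ValueError("need at least two scored models to compare")
    ref = results[0]
    for r in results[1:]:
        if r.folds != ref.folds or len(r.pointwise) != len(ref.pointwise):
            raise ValueError("results were not scored on identical folds")
    best = max(results, key=lambda r: r.elpd)
    rows = []
    for r in sorted(results, key=lambda r: -r.elpd):
        if r is best:
            diff, se = 0.0, 0.0
        else:
            d = r.pointwise - best.pointwise
            diff = float(np.sum(d))
            se = float(np.sqrt(len(d) * np.var(d, ddof=1)))
        rows.append((f"Model {r.model_id}", r.elpd, diff, se, is_decisive(diff, se) if r is not best else False))
    return pd.DataFrame(
        rows, columns=["model", "elpd", "elpd_diff", "se_diff", "decisively_worse"]
    ).set_index("model")
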