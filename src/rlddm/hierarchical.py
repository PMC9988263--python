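"""Hierarchical Bayesian specification of the RL-DDM variants.

Every native parameter (learning rates, outcome sensitivity, boundary
separation, non-decision time, bias, drift scaling, drift bound) gets a
group-level intercept (location + scale), a main effect per non-reference
drug (location + scale), and standardized per-subject deviates for both,
combined on the unconstrained scale (non-centered parameterization):

    raw[subject, drug] = mu + sigma * z[subject]
                       + 1[drug != ref] * (d_loc[drug] + d_scale[drug] * w[subject, drug])

where the per-subject drug deviates ``w`` share a correlation matrix with an
LKJ(1) prior (uniform over correlations), and the native value is the
logistic / exponential transform of ``raw`` (non-decision time additionally
scaled by the subject-session minimum RT, keeping it below every observed
reaction time).

The likelihood of each completed test trial is the Wiener first-passage
density of its (choice, RT) pair with a trial drift computed from the
Q-value trajectory.  ``logpost_and_grad`` returns the joint log posterior
and its exact gradient (analytic through the likelihood series, the value
recursion and all transforms), which drives the HMC sampler in
:mod:`rlddm.sampling`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .params import PARAM_NAMES, SubjectParams, to_native, to_unconstrained
from .rl import ModelSpec
from .wiener import _wiener_logpdf_grad

__all__ = [
    "PRIORS",
    "HierarchicalRLDDM",
    "SessionTable",
    "prepare_sessions",
    "transform_to_native",
]


# prior catalog: intercept location (mean, sd); intercept scale HN(sd);
# drug-effect location (mean, sd); drug-effect scale HN(sd)
PRIORS = {
    "eta_pos": {"mu": (0.0, 1.0), "sigma": 1.0, "d_loc": (0.0, 1.0), "d_scale": 0.1},
    "eta_neg": {"mu": (0.0, 1.0), "sigma": 1.0, "d_loc": (0.0, 1.0), "d_scale": 0.1},
    "tau": {"mu": (0.0, 1.0), "sigma": 1.0, "d_loc": (0.0, 1.0), "d_scale": 0.1},
    "beta": {"mu": (0.0, 0.5), "sigma": 0.1, "d_loc": (0.0, 0.5), "d_scale": 0.1},
    "rho": {"mu": (0.1, 0.1), "sigma": 0.1, "d_loc": (0.0, 0.5), "d_scale": 0.1},
    "alpha": {"mu": (0.0, 0.1), "sigma": 0.1, "d_loc": (0.0, 0.5), "d_scale": 0.1},
    "nu": {"mu": (0.2, 0.2), "sigma": 0.1, "d_loc": (0.0, 0.5), "d_scale": 0.1},
    "nu_max": {"mu": (0.5, 0.2), "sigma": 0.1, "d_loc": (0.0, 0.5), "d_scale": 0.1},
}


def free_params(spec: ModelSpec) -> list[str]:
    """Native parameters actually sampled under a model variant."""
    names = ["eta_pos", "eta_neg"]
    if spec.scaled:
        names.append("rho")
    names += ["alpha", "tau", "beta", "nu"]
    if spec.sigmoid:
        names.append("nu_max")
    return names


def transform_to_native(raw: dict, min_rt: float) -> SubjectParams:
    """Unconstrained draws -> native subject parameters (tau scaled by min RT)."""
    if min_rt is None or not min_rt > 0:
        raise ValueError(f"minimum reaction time must be > 0, got {min_rt}")
    vals = {}
    for nm in PARAM_NAMES:
        if nm not in raw:
            raise KeyError(f"missing unconstrained value for {nm!r}")
        vals[nm] = float(to_native(nm, raw[nm], min_rt if nm == "tau" else 1.0))
    return SubjectParams(**vals)


def transform_to_unconstrained(params: SubjectParams, min_rt: float) -> dict:
    """Inverse of :func:`transform_to_native`."""
    return {
        nm: float(to_unconstrained(nm, getattr(params, nm), min_rt if nm == "tau" else 1.0))
        for nm in PARAM_NAMES
    }


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class SessionTable:
    """Completed test trials stacked across subject-drug sessions."""

    choices: np.ndarray      # 1 = high option (upper boundary), 0 = low
    outcomes: np.ndarray     # +1 win, -1 lose
    rts: np.ndarray          # seconds
    blocks: np.ndarray       # task block of each trial
    trial_index: np.ndarray  # within-session trial index of each trial
    ptr: np.ndarray          # session i owns trials ptr[i]:ptr[i+1]
    subj_idx: np.ndarray     # session -> subject index
    drug_idx: np.ndarray     # session -> drug index (0 = reference)
    min_rt: np.ndarray       # session -> minimum observed RT
    subjects: list
    drugs: list              # reference drug first

    @property
    def n_sessions(self) -> int:
        return len(self.subj_idx)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return len(self.rts)


def prepare_sessions(data: pd.DataFrame, drug_reference: str = "placebo") -> SessionTable:
    """Index completed test trials by (subject, drug) session.

    Rows with no recorded button press are dropped; a session must have at
    least one completed trial with a positive RT.
    """
    df = data[(data["trial_type"] == "test") & (data["choice"].isin(["high", "low"]))]
    df = df.assign(rt_s=pd.to_numeric(df["rt_s"], errors="coerce"))
    df = df[np.isfinite(df["rt_s"])]
    if len(df) == 0:
        raise ValueError("no completed test trials in the data")
    if (df["rt_s"] <= 0).any():
        bad = df.index[df["rt_s"] <= 0].tolist()
        raise ValueError(f"non-positive reaction times at rows {bad}")
    subjects = sorted(df["subject_id"].unique())
    drugs_present = list(df["drug"].unique())
    if drug_reference in drugs_present:
        drugs = [drug_reference] + sorted(d for d in drugs_present if d != drug_reference)
    else:
        drugs = sorted(drugs_present)
    smap = {s: i for i, s in enumerate(subjects)}
    dmap = {d: i for i, d in enumerate(drugs)}

    ch, oc, rt, bl, ti, ptr, sidx, didx, mrt = [], [], [], [], [], [0], [], [], []
    for (s, d), g in df.groupby(["subject_id", "drug"], sort=True):
        g = g.sort_values(["block", "trial_index"])
        ch.append((g["choice"] == "high").to_numpy(np.int64))
        oc.append(np.where(g["outcome"] == "win", 1.0, -1.0))
        rt.append(g["rt_s"].to_numpy(float))
        bl.append(g["block"].to_numpy(np.int64))
        ti.append(g["trial_index"].to_numpy(np.int64))
        ptr.append(ptr[-1] + len(g))
        sidx.append(smap[s])
        didx.append(dmap[d])
        mrt.append(float(g["rt_s"].min()))
    return SessionTable(
        choices=np.concatenate(ch),
        outcomes=np.concatenate(oc),
        rts=np.concatenate(rt),
        blocks=np.concatenate(bl),
        trial_index=np.concatenate(ti),
        ptr=np.asarray(ptr, dtype=np.int64),
        subj_idx=np.asarray(sidx, dtype=np.int64),
        drug_idx=np.asarray(didx, dtype=np.int64),
        min_rt=np.asarray(mrt, dtype=float),
        subjects=subjects,
        drugs=drugs,
    )


# ---------------------------------------------------------------------------
# likelihood kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _session_ll_grad(nat, choices, outcomes, rts, use_sigmoid):
    """Log likelihood of one session and gradient wrt the 8 native params.

    ``nat`` order follows PARAM_NAMES: eta_pos, eta_neg, rho, alpha, tau,
    beta, nu, nu_max.  Static variants pass rho = 1; linear variants ignore
    the nu_max slot.
    """
    eta_p, eta_n, rho, alpha, tau, beta, nu, nu_max = (
        nat[0], nat[1], nat[2], nat[3], nat[4], nat[5], nat[6], nat[7],
    )
    qh, ql = 0.0, 0.0
    # sensitivities of (qh, ql) wrt (eta_pos, eta_neg, rho)
    dqh = np.zeros(3)
    dql = np.zeros(3)
    ll = 0.0
    g = np.zeros(8)
    for t in range(choices.shape[0]):
        dq = qh - ql
        x = dq * nu
        if use_sigmoid:
            sig = 1.0 / (1.0 + np.exp(-x))
            vt = nu_max * (2.0 * sig - 1.0)
            dvt_dx = 2.0 * nu_max * sig * (1.0 - sig)
            dvt_dnumax = 2.0 * sig - 1.0
        else:
            vt = x
            dvt_dx = 1.0
            dvt_dnumax = 0.0
        upper = choices[t]
        lp, d_v, d_a, d_tau, d_w = _wiener_logpdf_grad(rts[t], upper, alpha, tau, beta, vt)
        if not np.isfinite(lp):
            return -np.inf, g
        ll += lp
        g[3] += d_a
        g[4] += d_tau
        g[5] += d_w
        g[6] += d_v * dvt_dx * dq
        g[7] += d_v * dvt_dnumax
        coeff = d_v * dvt_dx * nu
        g[0] += coeff * (dqh[0] - dql[0])
        g[1] += coeff * (dqh[1] - dql[1])
        g[2] += coeff * (dqh[2] - dql[2])
        # learning update of the chosen option and its sensitivities
        r = outcomes[t]
        if upper == 1:
            q, dq0, dq1, dq2 = qh, dqh[0], dqh[1], dqh[2]
        else:
            q, dq0, dq1, dq2 = ql, dql[0], dql[1], dql[2]
        delta = rho * r - q
        pos_err = delta > 0.0
        eta = eta_p if pos_err else eta_n
        n0 = dq0 + (delta if pos_err else 0.0) - eta * dq0
        n1 = dq1 + (0.0 if pos_err else delta) - eta * dq1
        n2 = dq2 + eta * (r - dq2)
        qn = q + eta * delta
        if upper == 1:
            qh = qn
            dqh[0], dqh[1], dqh[2] = n0, n1, n2
        else:
            ql = qn
            dql[0], dql[1], dql[2] = n0, n1, n2
    return ll, g


@njit(cache=True)
def _all_sessions_ll_grad(nat_sess, choices, outcomes, rts, ptr, use_sigmoid):
    n_sess = nat_sess.shape[0]
    lls = np.empty(n_sess)
    grads = np.zeros((n_sess, 8))
    for i in range(n_sess):
        a, b = ptr[i], ptr[i + 1]
        ll, g = _session_ll_grad(nat_sess[i], choices[a:b], outcomes[a:b], rts[a:b], use_sigmoid)
        lls[i] = ll
        grads[i] = g
    return lls, grads


@njit(cache=True)
def _session_trial_ll(nat, choices, outcomes, rts, use_sigmoid, out):
    eta_p, eta_n, rho, alpha, tau, beta, nu, nu_max = (
        nat[0], nat[1], nat[2], nat[3], nat[4], nat[5], nat[6], nat[7],
    )
    qh, ql = 0.0, 0.0
    for t in range(choices.shape[0]):
        x = (qh - ql) * nu
        if use_sigmoid:
            vt = 2.0 * nu_max / (1.0 + np.exp(-x)) - nu_max
        else:
            vt = x
        lp, _, _, _, _ = _wiener_logpdf_grad(rts[t], choices[t], alpha, tau, beta, vt)
        out[t] = lp
        r = outcomes[t]
        q = qh if choices[t] == 1 else ql
        delta = rho * r - q
        eta = eta_p if delta > 0.0 else eta_n
        if choices[t] == 1:
            qh = q + eta * delta
        else:
            ql = q + eta * delta


@njit(cache=True)
def _all_sessions_trial_ll(nat_sess, choices, outcomes, rts, ptr, use_sigmoid):
    out = np.empty(rts.shape[0])
    for i in range(nat_sess.shape[0]):
        a, b = ptr[i], ptr[i + 1]
        _session_trial_ll(nat_sess[i], choices[a:b], outcomes[a:b], rts[a:b], use_sigmoid, out[a:b])
    return out


# ---------------------------------------------------------------------------
# the hierarchical model
# ---------------------------------------------------------------------------


class HierarchicalRLDDM:
    """Joint posterior over group and subject parameters of one variant.

    Parameters are packed into a flat unconstrained vector ``x`` as, per
    native parameter: intercept location, log intercept scale, S subject
    deviates, then (multi-drug data) D drug-effect locations, D log
    drug-effect scales, one correlation angle when D == 2, and S*D subject
    drug deviates.
    """

    def __init__(self, spec: ModelSpec, table: SessionTable):
        self.spec = spec if isinstance(spec, ModelSpec) else ModelSpec.from_id(spec)
        self.table = table
        self.names = free_params(self.spec)
        self.n_drug_eff = max(len(table.drugs) - 1, 0)
        if self.n_drug_eff > 2:
            raise NotImplementedError("at most two non-reference drug levels supported")
        S, D = table.n_subjects, self.n_drug_eff
        self._block = 2 + S + (2 * D + S * D + (1 if D == 2 else 0) if D > 0 else 0)
        self.n_dim = self._block * len(self.names)
        self._nat_idx = np.array([PARAM_NAMES.index(nm) for nm in self.names])

    # ---- packing helpers -------------------------------------------------

    def _offsets(self, p: int):
        S, D = self.table.n_subjects, self.n_drug_eff
        o = p * self._block
        off = {"mu": o, "log_sigma": o + 1, "z": o + 2}
        o2 = o + 2 + S
        if D > 0:
            off["d_loc"] = o2
            off["d_log_scale"] = o2 + D
            o3 = o2 + 2 * D
            if D == 2:
                off["corr"] = o3
                o3 += 1
            off["z_d"] = o3
        return off

    def unpack(self, x: np.ndarray) -> dict:
        """Flat vector -> named blocks per native parameter."""
        S, D = self.table.n_subjects, self.n_drug_eff
        out = {}
        for p, nm in enumerate(self.names):
            off = self._offsets(p)
            b = {
                "mu": x[off["mu"]],
                "sigma": np.exp(x[off["log_sigma"]]),
                "z": x[off["z"]: off["z"] + S],
            }
            if D > 0:
                b["d_loc"] = x[off["d_loc"]: off["d_loc"] + D]
                b["d_scale"] = np.exp(x[off["d_log_scale"]: off["d_log_scale"] + D])
                b["r"] = np.tanh(x[off["corr"]]) if D == 2 else None
                b["z_d"] = x[off["z_d"]: off["z_d"] + S * D].reshape(S, D)
            out[nm] = b
        return out

    # ---- linear predictors and natives -----------------------------------

    def _linpred(self, blocks: dict) -> np.ndarray:
        """Unconstrained session-level values, shape (n_sessions, n_free)."""
        tb = self.table
        D = self.n_drug_eff
        lp = np.empty((tb.n_sessions, len(self.names)))
        for p, nm in enumerate(self.names):
            b = blocks[nm]
            v = b["mu"] + b["sigma"] * b["z"][tb.subj_idx]
            if D > 0:
                w = _correlate(b["z_d"], b["r"]) if D == 2 else b["z_d"]
                eff = b["d_loc"][None, :] + b["d_scale"][None, :] * w  # (S, D)
                mask = tb.drug_idx > 0
                v = v.copy()
                v[mask] += eff[tb.subj_idx[mask], tb.drug_idx[mask] - 1]
            lp[:, p] = v
        return lp

    def native_sessions(self, x: np.ndarray) -> np.ndarray:
        """Native parameter matrix (n_sessions, 8) implied by ``x``.

        Unsampled slots are fixed: rho = 1 (static), nu_max = 1 (unused under
        a linear mapping).
        """
        blocks = self.unpack(np.asarray(x, dtype=float))
        lp = self._linpred(blocks)
        return self._natives_from_linpred(lp)[0]

    def _natives_from_linpred(self, lp: np.ndarray):
        tb = self.table
        nat = np.ones((tb.n_sessions, 8))
        jac = np.empty_like(lp)
        for p, nm in enumerate(self.names):
            col = self._nat_idx[p]
            if nm in ("eta_pos", "eta_neg", "beta"):
                s = expit(lp[:, p])
                nat[:, col] = s
                jac[:, p] = s * (1.0 - s)
            elif nm == "tau":
                s = expit(lp[:, p])
                nat[:, col] = s * tb.min_rt
                jac[:, p] = s * (1.0 - s) * tb.min_rt
            else:
                e = np.exp(np.minimum(lp[:, p], 50.0))  # overflow guard; kernel rejects
                nat[:, col] = e
                jac[:, p] = e
        return nat, jac

    # ---- log posterior ----------------------------------------------------

    def loglike_sessions(self, x: np.ndarray) -> np.ndarray:
        """Per-session log likelihood at ``x`` (no priors)."""
        tb = self.table
        nat = self.native_sessions(x)
        lls, _ = _all_sessions_ll_grad(
            nat, tb.choices, tb.outcomes, tb.rts, tb.ptr, self.spec.sigmoid
        )
        return lls

    def trial_loglike(self, nat_sessions: np.ndarray) -> np.ndarray:
        """Per-trial log likelihood for explicit native session parameters."""
        tb = self.table
        return _all_sessions_trial_ll(
            np.ascontiguousarray(nat_sessions), tb.choices, tb.outcomes, tb.rts,
            tb.ptr, self.spec.sigmoid,
        )

    def logpost_and_grad(self, x: np.ndarray):
        """Joint log posterior and its gradient at the unconstrained ``x``."""
        x = np.asarray(x, dtype=float)
        tb = self.table
        S, D = tb.n_subjects, self.n_drug_eff
        blocks = self.unpack(x)
        lp_lin = self._linpred(blocks)
        nat, jac = self._natives_from_linpred(lp_lin)
        lls, grads = _all_sessions_ll_grad(
            nat, tb.choices, tb.outcomes, tb.rts, tb.ptr, self.spec.sigmoid
        )
        grad = np.zeros_like(x)
        if not np.all(np.isfinite(lls)):
            return -np.inf, grad
        logp = float(np.sum(lls))
        g_lin = grads[:, self._nat_idx] * jac  # (n_sessions, n_free)

        for p, nm in enumerate(self.names):
            off = self._offsets(p)
            b = blocks[nm]
            gp = g_lin[:, p]
            grad[off["mu"]] += gp.sum()
            grad[off["log_sigma"]] += np.dot(gp, b["z"][tb.subj_idx]) * b["sigma"]
            gz = np.bincount(tb.subj_idx, weights=gp, minlength=S) * b["sigma"]
            grad[off["z"]: off["z"] + S] += gz
            if D > 0:
                mask = tb.drug_idx > 0
                di = tb.drug_idx[mask] - 1
                si = tb.subj_idx[mask]
                gm = gp[mask]
                g_dloc = np.zeros(D)
                np.add.at(g_dloc, di, gm)
                grad[off["d_loc"]: off["d_loc"] + D] += g_dloc
                w = _correlate(b["z_d"], b["r"]) if D == 2 else b["z_d"]
                g_w = np.zeros((S, D))
                np.add.at(g_w, (si, di), gm * b["d_scale"][di])
                g_dls = np.zeros(D)
                np.add.at(g_dls, di, gm * w[si, di] * b["d_scale"][di])
                grad[off["d_log_scale"]: off["d_log_scale"] + D] += g_dls
                if D == 2:
                    r = b["r"]
                    rt_ = np.sqrt(1.0 - r * r)
                    zd = b["z_d"]
                    g_zd = np.empty_like(zd)
                    g_zd[:, 0] = g_w[:, 0] + r * g_w[:, 1]
                    g_zd[:, 1] = rt_ * g_w[:, 1]
                    dw1_dr = zd[:, 0] - (r / rt_) * zd[:, 1]
                    grad[off["corr"]] += np.dot(g_w[:, 1], dw1_dr) * (1.0 - r * r)
                    grad[off["z_d"]: off["z_d"] + S * D] += g_zd.ravel()
                else:
                    grad[off["z_d"]: off["z_d"] + S * D] += g_w.ravel()

        logp += self._logprior_and_grad(x, blocks, grad)
        return logp, grad

    def _logprior_and_grad(self, x, blocks, grad):
        S, D = self.table.n_subjects, self.n_drug_eff
        lp = 0.0
        for p, nm in enumerate(self.names):
            off = self._offsets(p)
            pr = PRIORS[nm]
            b = blocks[nm]
            m0, s0 = pr["mu"]
            lp += -0.5 * ((b["mu"] - m0) / s0) ** 2
            grad[off["mu"]] += -(b["mu"] - m0) / s0**2
            # half-normal on sigma, sampled as log sigma (Jacobian included)
            sc = pr["sigma"]
            lp += -0.5 * (b["sigma"] / sc) ** 2 + x[off["log_sigma"]]
            grad[off["log_sigma"]] += -(b["sigma"] / sc) ** 2 + 1.0
            z = b["z"]
            lp += -0.5 * np.dot(z, z)
            grad[off["z"]: off["z"] + S] += -z
            if D > 0:
                dm, ds = pr["d_loc"]
                dl = b["d_loc"]
                lp += float(np.sum(-0.5 * ((dl - dm) / ds) ** 2))
                grad[off["d_loc"]: off["d_loc"] + D] += -(dl - dm) / ds**2
                dsc = pr["d_scale"]
                lsd = x[off["d_log_scale"]: off["d_log_scale"] + D]
                lp += float(np.sum(-0.5 * (b["d_scale"] / dsc) ** 2 + lsd))
                grad[off["d_log_scale"]: off["d_log_scale"] + D] += (
                    -((b["d_scale"] / dsc) ** 2) + 1.0
                )
                zd = b["z_d"].ravel()
                lp += -0.5 * np.dot(zd, zd)
                grad[off["z_d"]: off["z_d"] + S * D] += -zd
                if D == 2:
                    # LKJ(1) is uniform in r; only the tanh Jacobian remains
                    r = b["r"]
                    lp += np.log1p(-r * r)
                    grad[off["corr"]] += -2.0 * r
        return lp

    # ---- starting points --------------------------------------------------

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.05) -> np.ndarray:
        """Prior-location start with small jitter (deviates near zero)."""
        x = np.zeros(self.n_dim)
        for p, nm in enumerate(self.names):
            off = self._offsets(p)
            x[off["mu"]] = PRIORS[nm]["mu"][0]
            x[off["log_sigma"]] = np.log(0.5 * PRIORS[nm]["sigma"] + 1e-3)
            if self.n_drug_eff > 0:
                x[off["d_log_scale"]: off["d_log_scale"] + self.n_drug_eff] = np.log(0.05)
        return x + jitter * rng.standard_normal(self.n_dim)

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the full unconstrained vector from the priors."""
        S, D = self.table.n_subjects, self.n_drug_eff
        x = np.zeros(self.n_dim)
        for p, nm in enumerate(self.names):
            off = self._offsets(p)
            pr = PRIORS[nm]
            x[off["mu"]] = rng.normal(*pr["mu"])
            x[off["log_sigma"]] = np.log(np.abs(rng.normal(0.0, pr["sigma"])) + 1e-12)
            x[off["z"]: off["z"] + S] = rng.standard_normal(S)
            if D > 0:
                x[off["d_loc"]: off["d_loc"] + D] = rng.normal(*pr["d_loc"], size=D)
                x[off["d_log_scale"]: off["d_log_scale"] + D] = np.log(
                    np.abs(rng.normal(0.0, pr["d_scale"], size=D)) + 1e-12
                )
                if D == 2:
                    x[off["corr"]] = np.arctanh(rng.uniform(-1.0, 1.0) * 0.999999)
                x[off["z_d"]: off["z_d"] + S * D] = rng.standard_normal(S * D)
        return x


def _correlate(z_d: np.ndarray, r: float) -> np.ndarray:
    """Apply the 2x2 correlation Cholesky factor to standardized deviates."""
    w = np.empty_like(z_d)
    w[:, 0] = z_d[:, 0]
    w[:, 1] = r * z_d[:, 0] + np.sqrt(1.0 - r * r) * z_d[:, 1]
    return w
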