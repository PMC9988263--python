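"""Model/Results facade over the hierarchical RL-DDM machinery.

``RLDDM`` is built from a canonical trial table and a model variant;
``fit()`` runs adaptive HMC and returns an ``RLDDMResults`` carrying the
posterior draws, convergence diagnostics, and the downstream analyses
(summaries, drug contrasts, posterior predictive checks, prediction-error
extraction).
"""

from __future__ import annotations

import json
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

from . import analysis
from .hierarchical import HierarchicalRLDDM, prepare_sessions
from .rl import ModelSpec
from .sampling import sample_chains
from .tasks import TaskConfig

__all__ = ["RLDDM", "RLDDMResults", "FIT_PROFILES"]

#: named fit profiles: (chains, total iterations per chain, warmup iterations)
FIT_PROFILES = {
    "paper": {"chains": 4, "iterations": 4000, "warmup": 1000, "max_leapfrog": 48},
    "desk": {"chains": 2, "iterations": 800, "warmup": 400, "max_leapfrog": 32},
    "smoke": {"chains": 1, "iterations": 300, "warmup": 150, "max_leapfrog": 16},
}


class RLDDM:
    """Hierarchical RL-DDM of choices and reaction times.

    Parameters
    ----------
    data : trial table in the canonical schema (see :mod:`rlddm.tasks`);
        only completed test trials enter the likelihood.
    spec : model variant, 1-4 or a :class:`rlddm.rl.ModelSpec`.
    drug_reference : condition coded as the intercept; the other drug levels
        get main-effect columns.
    """

    def __init__(self, data: pd.DataFrame, spec=4, drug_reference: str = "placebo"):
        self.data = data
        self.spec = spec if isinstance(spec, ModelSpec) else ModelSpec.from_id(spec)
        self.drug_reference = drug_reference
        self.table = prepare_sessions(data, drug_reference)
        self.hierarchical = HierarchicalRLDDM(self.spec, self.table)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec=4, drug_reference: str = "placebo"):
        return cls(data, spec, drug_reference)

    @classmethod
    def from_csv(cls, path, spec=4, drug_reference: str = "placebo", **kwargs):
        from .io import read_trials

        return cls(read_trials(path), spec, drug_reference, **kwargs)

    def loglike(self, x: np.ndarray) -> float:
        """Total data log likelihood at an unconstrained parameter vector."""
        return float(np.sum(self.hierarchical.loglike_sessions(x)))

    def logpost(self, x: np.ndarray) -> float:
        return self.hierarchical.logpost_and_grad(x)[0]

    def fit(
        self,
        chains: int | None = None,
        iterations: int | None = None,
        warmup: int | None = None,
        seed: int = 0,
        profile: str | None = "desk",
        target_accept: float = 0.85,
        max_leapfrog: int | None = None,
    ) -> "RLDDMResults":
        """Sample the posterior with adaptive HMC.

        Explicit ``chains``/``iterations``/``warmup`` override the chosen
        profile ("paper" = 4 chains x 4000 iterations with the first 1000
        discarded; "desk" = 2 x 800/400).
        """
        prof = dict(FIT_PROFILES[profile]) if profile else {}
        chains = chains or prof.get("chains", 4)
        iterations = iterations or prof.get("iterations", 4000)
        warmup = warmup if warmup is not None else prof.get("warmup", 1000)
        max_leapfrog = max_leapfrog or prof.get("max_leapfrog", 32)
        if warmup >= iterations:
            raise ValueError(f"warmup ({warmup}) must be below iterations ({iterations})")
        rng = np.random.default_rng(seed)
        inits = [self.hierarchical.initial_point(rng) for _ in range(chains)]
        draws, stats = sample_chains(
            self.hierarchical.logpost_and_grad,
            inits,
            n_iter=iterations,
            n_warmup=warmup,
            seed=seed,
            target_accept=target_accept,
            max_leapfrog=max_leapfrog,
        )
        return RLDDMResults(self, draws, stats, seed=seed)


class RLDDMResults:
    """Posterior draws of a fitted RL-DDM with diagnostics and analyses."""

    def __init__(self, model: RLDDM, draws: np.ndarray, stats, seed: int = 0):
        self.model = model
        self.draws = draws  # (chains, draws, dim) unconstrained
        self.stats = stats
        self.seed = seed
        self._idata = None

    # ---- posterior views --------------------------------------------------

    def to_inferencedata(self) -> az.InferenceData:
        """Group-level posterior as an arviz InferenceData."""
        if self._idata is not None:
            return self._idata
        h = self.model.hierarchical
        C, N, _ = self.draws.shape
        data_vars = {}
        drugs = h.table.drugs[1:]
        for nm in h.names:
            mu = np.empty((C, N))
            sigma = np.empty((C, N))
            dloc = np.empty((C, N, h.n_drug_eff)) if h.n_drug_eff else None
            for c in range(C):
                for i in range(N):
                    b = h.unpack(self.draws[c, i])[nm]
                    mu[c, i] = b["mu"]
                    sigma[c, i] = b["sigma"]
                    if h.n_drug_eff:
                        dloc[c, i] = b["d_loc"]
            data_vars[f"mu_{nm}"] = (("chain", "draw"), mu)
            data_vars[f"sigma_{nm}"] = (("chain", "draw"), sigma)
            if h.n_drug_eff:
                data_vars[f"d_loc_{nm}"] = (("chain", "draw", "drug_effect"), dloc)
        coords = {"chain": np.arange(C), "draw": np.arange(N)}
        if h.n_drug_eff:
            coords["drug_effect"] = drugs
        self._idata = az.InferenceData(posterior=xr.Dataset(data_vars, coords=coords))
        return self._idata

    def group_draws(self, var: str) -> np.ndarray:
        """Flattened draws of a group-level variable, e.g. ``mu_eta_pos``."""
        da = self.to_inferencedata().posterior[var]
        return da.values.reshape(-1, *da.values.shape[2:])

    def drug_effect_draws(self, parameter: str, drug: str) -> np.ndarray:
        """Group-level drug-effect draws (zero vector for the reference)."""
        h = self.model.hierarchical
        if drug == h.table.drugs[0]:
            return np.zeros(self.draws.shape[0] * self.draws.shape[1])
        if drug not in h.table.drugs:
            raise KeyError(f"unknown drug {drug!r}; fitted: {h.table.drugs}")
        j = h.table.drugs[1:].index(drug)
        return self.group_draws(f"d_loc_{parameter}")[:, j]

    def posterior_mean_natives(self) -> np.ndarray:
        """Posterior-mean native parameters per subject-session, (n_sess, 8).

        Means are taken on the native scale (transform applied draw-wise).
        """
        h = self.model.hierarchical
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        acc = np.zeros((h.table.n_sessions, 8))
        step = max(len(flat) // 500, 1)  # cap the averaging cost
        used = 0
        for i in range(0, len(flat), step):
            acc += h.native_sessions(flat[i])
            used += 1
        return acc / used

    # ---- diagnostics ------------------------------------------------------

    def rhat(self) -> pd.Series:
        idata = self.to_inferencedata()
        post = idata.posterior
        if post.sizes["chain"] == 1:  # split the chain for a usable diagnostic
            n = post.sizes["draw"] // 2
            halves = [
                post.isel(draw=slice(i * n, (i + 1) * n)).assign_coords(draw=np.arange(n))
                for i in (0, 1)
            ]
            post = xr.concat(halves, dim="chain").assign_coords(chain=[0, 1])
        ds = az.rhat(post)
        return ds.to_dataframe().max().rename("rhat")

    def ess(self) -> pd.Series:
        ds = az.ess(self.to_inferencedata())
        return ds.to_dataframe().min().rename("ess")

    def convergence_report(self, warn: float = 1.01, fail: float = 1.1) -> dict:
        """R-hat screen over all group-level quantities plus divergences."""
        r = self.rhat()
        n_div = int(sum(s.n_divergent for s in self.stats))
        max_r = float(r.max())
        status = "ok"
        if max_r > fail:
            status = "fail"
        elif max_r > warn:
            status = "warn"
        return {
            "max_rhat": max_r,
            "status": status,
            "n_divergent": n_div,
            "rhat_warn_threshold": warn,
            "rhat_fail_threshold": fail,
            "flagged": sorted(r.index[r > warn].tolist()),
        }

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """Group-level posterior summary table (mean, sd, HDI, R-hat, ESS)."""
        post = self.to_inferencedata().posterior
        rh = az.rhat(self.to_inferencedata())
        es = az.ess(self.to_inferencedata())
        rows = []
        for var in post.data_vars:
            da = post[var]
            if "drug_effect" in da.dims:
                for d in da.coords["drug_effect"].values:
                    v = da.sel(drug_effect=d).values.ravel()
                    iv = analysis.hdi(v, mass)
                    rows.append(
                        (f"{var}[{d}]", v.mean(), v.std(), iv.lower, iv.upper,
                         float(rh[var].sel(drug_effect=d)), float(es[var].sel(drug_effect=d)))
                    )
            else:
                v = da.values.ravel()
                iv = analysis.hdi(v, mass)
                rows.append(
                    (var, v.mean(), v.std(), iv.lower, iv.upper,
                     float(rh[var]), float(es[var]))
                )
        lo = f"hdi_{100 * (1 - mass) / 2:g}%"
        hi = f"hdi_{100 * (1 + mass) / 2:g}%"
        return pd.DataFrame(
            rows, columns=["parameter", "mean", "sd", lo, hi, "rhat", "ess"]
        ).set_index("parameter")

    # ---- analyses ---------------------------------------------------------

    def hdi(self, var: str, mass: float = 0.95) -> analysis.HDInterval:
        return analysis.hdi(self.group_draws(var).ravel(), mass)

    def contrast_drug(self, parameter: str, drug_a: str, drug_b: str, mass: float = 0.95):
        return analysis.contrast_drug(self, parameter, drug_a, drug_b, mass)

    def posterior_predict(self, task: TaskConfig = TaskConfig(), n_rep: int = 200,
                          seed: int = 0, drug: str | None = None):
        return analysis.posterior_predict(self, task, n_rep, seed, drug)

    def extract_pe(self) -> pd.DataFrame:
        return analysis.extract_pe(self)

    # ---- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Draws + metadata to an .npz next to a .json sidecar."""
        path = Path(path)
        np.savez_compressed(path, draws=self.draws)
        meta = {
            "spec_id": self.model.spec.id,
            "drug_reference": self.model.drug_reference,
            "seed": self.seed,
            "subjects": self.model.table.subjects,
            "drugs": self.model.table.drugs,
            "accept_rates": [s.accept_rate for s in self.stats],
            "n_divergent": [s.n_divergent for s in self.stats],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path, data: pd.DataFrame) -> "RLDDMResults":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = RLDDM(data, spec=meta["spec_id"], drug_reference=meta["drug_reference"])
        draws = np.load(path if path.suffix else path.with_suffix(".npz"))["draws"]
        return cls(model, draws, stats=[], seed=meta["seed"])
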