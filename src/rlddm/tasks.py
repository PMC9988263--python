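"""Synthetic wheel-of-fortune cohorts: schedules, agents, pain outcomes.

The task is a two-option gambling game played on top of a tonic painful heat
stimulus: in *test* trials the subject picks one of two colours, one of which
wins (a -3 degC relief) with probability 0.75 and the other with 0.25; losing
raises the temperature by +1 degC.  *Control* trials deliver the same relief
or increase passively, with win/lose counts matched to the realized test
outcomes of the session, and *neutral* trials change nothing.  A session is
five blocks of 4 test + 4 control trials in shuffled order followed by one
neutral trial (45 trials; 20 test).

Choices and reaction times come from a reinforcement-learning agent whose
drift-diffusion choice rule uses the learned value difference as drift
(:mod:`rlddm.rl`, :mod:`rlddm.wiener`).  Trial-wise VAS and behavioural pain
modulation are generated as a linear function of the agent's prediction
errors plus a per-drug offset and Gaussian noise, so the full analysis
pipeline can be exercised without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .params import PARAM_NAMES, SubjectParams, to_native
from .rl import ModelSpec, MODEL_SPECS

__all__ = [
    "TaskConfig",
    "GenerativeConfig",
    "generate_schedule",
    "simulate_agent",
    "simulate_pain",
    "generate_cohort",
    "COLUMNS",
]

#: canonical trial-table schema (one row per trial)
COLUMNS = [
    "subject_id",
    "drug",
    "session_order",
    "block",
    "trial_index",
    "trial_type",
    "choice",
    "outcome",
    "rt_s",
    "vas_rating",
    "beh_delta_c",
]


@dataclass(frozen=True)
class TaskConfig:
    """Structure and contingencies of one session of the game."""

    n_blocks: int = 5
    tests_per_block: int = 4
    controls_per_block: int = 4
    neutrals_per_block: int = 1
    p_win_high: float = 0.75
    p_win_low: float = 0.25
    relief_delta: float = -3.0
    increase_delta: float = 1.0

    def __post_init__(self):
        for nm in ("n_blocks", "tests_per_block", "controls_per_block", "neutrals_per_block"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be a positive count, got {getattr(self, nm)}")
        for nm in ("p_win_high", "p_win_low"):
            p = getattr(self, nm)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1], got {p}")

    @property
    def trials_per_block(self) -> int:
        return self.tests_per_block + self.controls_per_block + self.neutrals_per_block

    @property
    def trials_per_session(self) -> int:
        return self.n_blocks * self.trials_per_block


# Table-1-style dispersion of trial-wise modulation (VAS units, degC) and the
# per-drug offsets implied by the across-outcome session means.
_DEFAULT_VAS_OFFSETS = {"placebo": 2.4, "levodopa": 0.2, "naltrexone": 1.1}
_DEFAULT_BEH_OFFSETS = {"placebo": -0.03, "levodopa": -0.055, "naltrexone": 0.005}

#: unconstrained-scale group locations/scales of the generative population
DEFAULT_GROUP_PARAMS = {
    "eta_pos": (-1.6, 0.5),
    "eta_neg": (-1.6, 0.5),
    "rho": (0.1, 0.1),
    "alpha": (0.3, 0.1),
    "tau": (0.0, 0.3),
    "beta": (0.0, 0.1),
    "nu": (0.1, 0.15),
    "nu_max": (0.1, 0.15),
}

#: population preset for model- and parameter-recovery experiments: strong
#: learning and a saturating drift regime, where the four variants make
#: clearly distinct predictions (for weak value signals the sigmoid mapping
#: degenerates to the linear one, S(x) ~ nu_max*x/2, and variants are not
#: identifiable from behaviour)
RECOVERY_GROUP_PARAMS = {
    **DEFAULT_GROUP_PARAMS,
    "eta_pos": (-0.4, 0.3),
    "eta_neg": (-0.4, 0.3),
    "rho": (0.6, 0.1),
    "nu": (1.2, 0.15),
    "nu_max": (0.3, 0.15),
}

#: additive unconstrained shifts per non-reference drug (weaker value-driven
#: drift under both active compounds, matching the flat learning curves
#: observed under levodopa and naltrexone)
DEFAULT_DRUG_SHIFTS = {
    "levodopa": {"nu": -1.6, "nu_max": -0.8},
    "naltrexone": {"nu": -2.2, "nu_max": -1.0},
}


@dataclass(frozen=True)
class GenerativeConfig:
    """Population and pain-coupling settings of the synthetic cohort."""

    n_subjects: int = 28
    drugs: tuple = ("placebo", "levodopa", "naltrexone")
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    drug_shifts: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DRUG_SHIFTS.items()})
    beta_pe_vas: float = -0.36
    beta_pe_beh: float = -0.06
    noise_sd_vas: float = 21.51
    noise_sd_beh: float = 0.64
    vas_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_VAS_OFFSETS))
    beh_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_BEH_OFFSETS))
    tau_ref: float = 0.6
    miss_rate: float = 0.0
    model_id: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError(f"drug labels must be unique, got {self.drugs}")
        if self.noise_sd_vas < 0 or self.noise_sd_beh < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError(f"miss_rate must lie in [0, 1), got {self.miss_rate}")


def generate_schedule(config: TaskConfig, seed: int) -> pd.DataFrame:
    """Trial skeletons of one session: block, type, and the win lottery draw.

    Test/control interleaving within a block is a seeded shuffle of the exact
    block composition, with the neutral trial(s) closing the block.  Each test
    trial carries a pre-drawn uniform ``u_win``: the trial is won iff
    ``u_win < p_win(chosen colour)``, so the same schedule is playable by any
    agent while holding the lottery fixed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(1, config.n_blocks + 1):
        kinds = ["test"] * config.tests_per_block + ["control"] * config.controls_per_block
        rng.shuffle(kinds)
        kinds += ["neutral"] * config.neutrals_per_block
        rows += [(b, k) for k in kinds]
    df = pd.DataFrame(rows, columns=["block", "trial_type"])
    df.insert(1, "trial_index", np.arange(1, len(df) + 1))
    df["u_win"] = np.where(df["trial_type"] == "test", rng.random(len(df)), np.nan)
    return df


@njit(cache=True)
def _agent_core(
    u_wins, eta_pos, eta_neg, rho, alpha, tau, beta, nu, nu_max,
    use_sigmoid, p_win_high, p_win_low, dt, miss_rate, seed,
):
    np.random.seed(seed)
    n = u_wins.shape[0]
    choices = np.empty(n, np.int64)   # 1 high, 0 low, -1 missed
    outcomes = np.empty(n, np.int64)  # +1 win, -1 lose, 0 none
    rts = np.empty(n)
    qh, ql = 0.0, 0.0
    sdt = math.sqrt(dt)
    for t in range(n):
        if miss_rate > 0.0 and np.random.random() < miss_rate:
            choices[t] = -1
            outcomes[t] = 0
            rts[t] = np.nan
            continue
        x = (qh - ql) * nu
        if use_sigmoid:
            v = 2.0 * nu_max / (1.0 + math.exp(-x)) - nu_max
        else:
            v = x
        pos = beta * alpha
        steps = 0
        while 0.0 < pos < alpha:
            pos += v * dt + sdt * np.random.normal()
            steps += 1
        ch = 1 if pos >= alpha else 0
        rts[t] = tau + steps * dt
        pwin = p_win_high if ch == 1 else p_win_low
        r = 1 if u_wins[t] < pwin else -1
        q = qh if ch == 1 else ql
        delta = rho * r - q
        eta = eta_pos if delta > 0.0 else eta_neg
        if ch == 1:
            qh = q + eta * delta
        else:
            ql = q + eta * delta
        choices[t] = ch
        outcomes[t] = r
    return choices, outcomes, rts


def simulate_agent(
    params: SubjectParams,
    schedule: pd.DataFrame,
    spec: ModelSpec = MODEL_SPECS[4],
    seed: int = 0,
    task: TaskConfig = TaskConfig(),
    dt: float = 1e-3,
    miss_rate: float = 0.0,
) -> pd.DataFrame:
    """Play the schedule's test trials with an RL-DDM agent.

    Returns the test-trial rows with ``choice`` ('high'/'low'/'none'),
    ``outcome`` ('win'/'lose'/'neutral') and ``rt_s`` columns appended.  The
    Q-value trajectory implied by the returned choice/outcome sequence is, by
    construction, the one :func:`rlddm.rl.run_sequence` recomputes.
    """
    params.validate()
    tests = schedule[schedule["trial_type"] == "test"]
    rho = params.rho if spec.scaled else 1.0
    choices, outcomes, rts = _agent_core(
        tests["u_win"].to_numpy(float),
        params.eta_pos, params.eta_neg, rho, params.alpha, params.tau,
        params.beta, params.nu, params.nu_max,
        spec.sigmoid, task.p_win_high, task.p_win_low, dt, miss_rate, seed,
    )
    out = tests.copy()
    out["choice"] = np.where(choices == 1, "high", np.where(choices == 0, "low", "none"))
    out["outcome"] = np.where(outcomes == 1, "win", np.where(outcomes == -1, "lose", "neutral"))
    out["rt_s"] = rts
    return out


def simulate_pain(
    pe: np.ndarray,
    gen: GenerativeConfig,
    seed: int,
    drug: str = "placebo",
):
    """PE-coupled trial-wise modulation: ``slope * PE + drug offset + noise``.

    Returns ``(vas_mod, beh_mod)`` arrays, one value per test trial; negative
    values mean pain inhibition.
    """
    pe = np.asarray(pe, dtype=float)
    rng = np.random.default_rng(seed)
    vas = gen.beta_pe_vas * pe + gen.vas_offsets.get(drug, 0.0)
    beh = gen.beta_pe_beh * pe + gen.beh_offsets.get(drug, 0.0)
    vas = vas + rng.normal(0.0, gen.noise_sd_vas, size=pe.shape)
    beh = beh + rng.normal(0.0, gen.noise_sd_beh, size=pe.shape)
    return vas, beh


def draw_subject_params(gen: GenerativeConfig, rng: np.random.Generator):
    """Unconstrained per-subject draws: ``loc + scale * z`` per parameter.

    Returns ``(n_subjects, 8)`` of unconstrained intercept values (before any
    drug shift) in :data:`rlddm.params.PARAM_NAMES` order.
    """
    raw = np.empty((gen.n_subjects, len(PARAM_NAMES)))
    for j, nm in enumerate(PARAM_NAMES):
        loc, scale = gen.group_params[nm]
        raw[:, j] = loc + scale * rng.standard_normal(gen.n_subjects)
    return raw


def _native_params(raw_row: np.ndarray, gen: GenerativeConfig) -> SubjectParams:
    vals = {}
    for j, nm in enumerate(PARAM_NAMES):
        t_ref = gen.tau_ref if nm == "tau" else 1.0
        vals[nm] = float(to_native(nm, raw_row[j], t_ref))
    return SubjectParams(**vals)


def generate_cohort(
    gen: GenerativeConfig,
    task: TaskConfig = TaskConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Full synthetic cohort in the canonical trial-table schema.

    Each subject plays one session per drug (order counterbalanced by a latin
    square).  Control-trial outcomes copy the session's realized test
    outcomes in shuffled order; VAS ratings embed the PE-coupled modulation on
    top of outcome-conditioned control levels so the downstream
    test-minus-control computation recovers it.
    """
    if seed is None:
        seed = gen.seed
    rng = np.random.default_rng(seed)
    spec = ModelSpec.from_id(gen.model_id)
    raw_int = draw_subject_params(gen, rng)
    n_drugs = len(gen.drugs)
    orders = [tuple(np.roll(np.arange(n_drugs), -i)) for i in range(n_drugs)]

    from .rl import run_sequence  # cycle-free local import

    frames = []
    for s in range(gen.n_subjects):
        subj = f"S{s + 1:03d}"
        order = orders[s % n_drugs]
        for pos, di in enumerate(order):
            drug = gen.drugs[di]
            raw = raw_int[s].copy()
            for nm, shift in gen.drug_shifts.get(drug, {}).items():
                raw[PARAM_NAMES.index(nm)] += shift
            params = _native_params(raw, gen)
            sched = generate_schedule(task, int(rng.integers(2**31)))
            played = simulate_agent(
                params, sched, spec, int(rng.integers(2**31)), task,
                miss_rate=gen.miss_rate,
            )
            frames.append(
                _assemble_session(subj, drug, pos + 1, sched, played, params, gen, spec, task, rng, run_sequence)
            )
    df = pd.concat(frames, ignore_index=True)
    return df[COLUMNS]


def _assemble_session(subj, drug, session_order, sched, played, params, gen, spec, task, rng, run_sequence):
    df = sched.drop(columns="u_win").copy()
    df["choice"] = "none"
    df["outcome"] = "neutral"
    df["rt_s"] = np.nan
    df.loc[played.index, "choice"] = played["choice"].to_numpy()
    df.loc[played.index, "outcome"] = played["outcome"].to_numpy()
    df.loc[played.index, "rt_s"] = played["rt_s"].to_numpy()

    # passive controls mirror the realized test outcomes, shuffled
    done = played[played["choice"] != "none"]
    pool = list(done["outcome"])
    ctrl_idx = df.index[df["trial_type"] == "control"]
    if pool:
        assigned = [pool[i % len(pool)] for i in range(len(ctrl_idx))]
        rng.shuffle(assigned)
        df.loc[ctrl_idx, "outcome"] = assigned
    df.loc[ctrl_idx, "rt_s"] = np.exp(rng.normal(np.log(0.5), 0.2, size=len(ctrl_idx)))
    neut_idx = df.index[df["trial_type"] == "neutral"]
    df.loc[neut_idx, "rt_s"] = np.exp(rng.normal(np.log(0.5), 0.2, size=len(neut_idx)))

    # prediction errors of the completed test trials drive the pain coupling
    pes = run_sequence(
        done["choice"], np.where(done["outcome"] == "win", 1.0, -1.0), params, spec
    )
    vas_mod, beh_mod = simulate_pain(pes.delta, gen, int(rng.integers(2**31)), drug)

    baseline = rng.normal(150.0, 8.0)
    df["vas_rating"] = np.nan
    df["beh_delta_c"] = np.nan
    ctrl = df.loc[ctrl_idx]
    level = {"win": baseline - 30.0, "lose": baseline + 15.0}
    ctrl_vas = np.array([level.get(o, baseline) for o in ctrl["outcome"]])
    df.loc[ctrl_idx, "vas_rating"] = ctrl_vas + rng.normal(0.0, 8.0, size=len(ctrl_idx))
    df.loc[ctrl_idx, "beh_delta_c"] = rng.normal(0.05, 0.3, size=len(ctrl_idx))
    df.loc[neut_idx, "vas_rating"] = baseline + rng.normal(0.0, 8.0, size=len(neut_idx))
    df.loc[neut_idx, "beh_delta_c"] = rng.normal(0.0, 0.3, size=len(neut_idx))

    # test ratings = outcome-matched control mean + simulated modulation, so
    # the downstream test-minus-control difference returns the modulation
    for outcome in ("win", "lose"):
        cm_vas = df.loc[ctrl_idx][df.loc[ctrl_idx, "outcome"] == outcome]["vas_rating"].mean()
        cm_beh = df.loc[ctrl_idx][df.loc[ctrl_idx, "outcome"] == outcome]["beh_delta_c"].mean()
        sel = done.index[done["outcome"] == outcome]
        pos_in_done = [done.index.get_loc(i) for i in sel]
        if np.isnan(cm_vas):
            continue
        df.loc[sel, "vas_rating"] = cm_vas + vas_mod[pos_in_done]
        df.loc[sel, "beh_delta_c"] = cm_beh + beh_mod[pos_in_done]

    df["vas_rating"] = df["vas_rating"].clip(0.0, 200.0)
    df.insert(0, "session_order", session_order)
    df.insert(0, "drug", drug)
    df.insert(0, "subject_id", subj)
    return df
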