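"""Trial-by-trial value learning with dual learning rates.

Expected values (Q) for the two wheel colours — the option with the high win
contingency and the option with the low one — start at zero and are updated
after every completed test trial from the signed outcome R (+1 win, -1 loss):

    delta = rho * R - Q_chosen
    Q_chosen <- Q_chosen + eta_plus * delta   if delta > 0
    Q_chosen <- Q_chosen + eta_minus * delta  if delta <= 0

``rho`` is an individual outcome-sensitivity scaling; the *static* variant
fixes rho = 1, the *scaled* variant estimates it.  The tie delta == 0 uses the
negative-error learning rate.  The unchosen option carries its value forward
unchanged, and passive (control/neutral) or unanswered trials never update Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "MODEL_SPECS", "QState", "PESeries", "update_q", "run_sequence"]

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model variants: outcome sensitivity x drift mapping.

    ======  ===================  =============
    id      outcome_sensitivity  drift_mapping
    ======  ===================  =============
    1       static               linear
    2       scaled               linear
    3       static               sigmoid
    4       scaled               sigmoid
    ======  ===================  =============
    """

    outcome_sensitivity: str
    drift_mapping: str

    def __post_init__(self):
        if self.outcome_sensitivity not in ("static", "scaled"):
            raise ValueError(f"unknown outcome sensitivity {self.outcome_sensitivity!r}")
        if self.drift_mapping not in ("linear", "sigmoid"):
            raise ValueError(f"unknown drift mapping {self.drift_mapping!r}")

    @property
    def id(self) -> int:
        return {
            ("static", "linear"): 1,
            ("scaled", "linear"): 2,
            ("static", "sigmoid"): 3,
            ("scaled", "sigmoid"): 4,
        }[(self.outcome_sensitivity, self.drift_mapping)]

    @property
    def scaled(self) -> bool:
        return self.outcome_sensitivity == "scaled"

    @property
    def sigmoid(self) -> bool:
        return self.drift_mapping == "sigmoid"

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        try:
            return MODEL_SPECS[int(model_id)]
        except KeyError:
            raise ValueError(f"model id must be 1..4, got {model_id}") from None


MODEL_SPECS = {
    1: ModelSpec("static", "linear"),
    2: ModelSpec("scaled", "linear"),
    3: ModelSpec("static", "sigmoid"),
    4: ModelSpec("scaled", "sigmoid"),
}


@dataclass
class QState:
    """Expected values of the two options; both start at zero."""

    q_high: float = 0.0
    q_low: float = 0.0

    def get(self, choice: str) -> float:
        return self.q_high if choice == HIGH else self.q_low


@dataclass
class PESeries:
    """Per-test-trial prediction errors and decision-time expected values.

    ``q_high``/``q_low`` are the values *before* that trial's update — the
    quantities feeding the drift rate — and ``delta`` the prediction error of
    the realized (choice, outcome) pair.
    """

    delta: np.ndarray = field(default_factory=lambda: np.empty(0))
    q_high: np.ndarray = field(default_factory=lambda: np.empty(0))
    q_low: np.ndarray = field(default_factory=lambda: np.empty(0))
    choice: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    outcome: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta": self.delta,
                "q_high": self.q_high,
                "q_low": self.q_low,
                "choice": self.choice,
                "outcome": self.outcome,
            }
        )


def _check_rates(eta_pos: float, eta_neg: float) -> None:
    if not (0.0 < eta_pos < 1.0 and 0.0 < eta_neg < 1.0):
        raise ValueError(
            f"learning rates must lie in (0, 1), got eta_pos={eta_pos}, eta_neg={eta_neg}"
        )


def update_q(
    state: QState,
    choice: str,
    reward: float,
    eta_pos: float,
    eta_neg: float,
    rho: float = 1.0,
    spec: ModelSpec = MODEL_SPECS[1],
):
    """One learning step; returns (new QState, prediction error delta).

    ``reward`` is the signed unit outcome (+1 win, -1 loss); under a static
    spec rho is forced to 1 regardless of the argument.
    """
    _check_rates(eta_pos, eta_neg)
    if choice not in (HIGH, LOW):
        raise ValueError(f"choice must be '{HIGH}' or '{LOW}', got {choice!r}")
    if spec.scaled:
        if not rho > 0:
            raise ValueError(f"outcome sensitivity must be > 0, got {rho}")
    else:
        rho = 1.0
    q = state.get(choice)
    delta = rho * reward - q
    eta = eta_pos if delta > 0 else eta_neg
    q_new = q + eta * delta
    if choice == HIGH:
        return QState(q_new, state.q_low), delta
    return QState(state.q_high, q_new), delta


def run_sequence(choices, outcomes, params, spec: ModelSpec) -> PESeries:
    """Run the update over an aligned (choices, outcomes) sequence.

    ``params`` needs attributes ``eta_pos``, ``eta_neg`` and (scaled variant)
    ``rho``.  Outcomes are signed units (+1/-1).  Returns the PESeries with
    decision-time Q values; an empty sequence leaves Q at (0, 0).
    """
    choices = list(choices)
    outcomes = list(outcomes)
    if len(choices) != len(outcomes):
        raise ValueError(
            f"misaligned inputs: {len(choices)} choices vs {len(outcomes)} outcomes"
        )
    rho = getattr(params, "rho", 1.0) if spec.scaled else 1.0
    state = QState()
    n = len(choices)
    delta = np.empty(n)
    qh = np.empty(n)
    ql = np.empty(n)
    for t, (c, r) in enumerate(zip(choices, outcomes)):
        qh[t] = state.q_high
        ql[t] = state.q_low
        state, delta[t] = update_q(state, c, r, params.eta_pos, params.eta_neg, rho, spec)
    return PESeries(
        delta=delta,
        q_high=qh,
        q_low=ql,
        choice=np.asarray(choices, dtype=object),
        outcome=np.asarray(outcomes, dtype=float),
    )
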