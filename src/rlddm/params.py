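"""Native-scale subject parameters and the unconstrained-scale transforms.

Eight native parameters describe one subject in one drug session:

====== ======================== ============= ====================
name   meaning                  native range  transform from raw
====== ======================== ============= ====================
eta_pos learning rate, delta>0  (0, 1)        logistic
eta_neg learning rate, delta<=0 (0, 1)        logistic
rho    outcome sensitivity      (0, inf)      exp
alpha  boundary separation      (0, inf)      exp
tau    non-decision time (s)    (0, t_ref)    logistic * t_ref
beta   a-priori bias            (0, 1)        logistic
nu     drift scaling            (0, inf)      exp
nu_max drift bound (sigmoid)    (0, inf)      exp
====== ======================== ============= ====================

``t_ref`` for tau is the subject-session minimum reaction time during
inference (so tau sits strictly below every observed RT) and a fixed
reference time when generating synthetic subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

PARAM_NAMES = ("eta_pos", "eta_neg", "rho", "alpha", "tau", "beta", "nu", "nu_max")

#: parameters mapped through the logistic function (tau additionally scaled)
LOGISTIC_PARAMS = ("eta_pos", "eta_neg", "tau", "beta")
EXP_PARAMS = ("rho", "alpha", "nu", "nu_max")


@dataclass(frozen=True)
class SubjectParams:
    """Native-scale parameter set of one subject-session."""

    eta_pos: float
    eta_neg: float
    rho: float
    alpha: float
    tau: float
    beta: float
    nu: float
    nu_max: float

    def validate(self) -> None:
        for nm in ("eta_pos", "eta_neg", "beta"):
            v = getattr(self, nm)
            if not 0 < v < 1:
                raise ValueError(f"{nm} must lie in (0, 1), got {v}")
        for nm in ("rho", "alpha", "nu", "nu_max"):
            v = getattr(self, nm)
            if not v > 0:
                raise ValueError(f"{nm} must be > 0, got {v}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in PARAM_NAMES])


def to_native(name: str, raw, t_ref: float = 1.0):
    """Unconstrained draw -> native scale (tau scaled by ``t_ref``)."""
    raw = np.asarray(raw, dtype=float)
    if name == "tau":
        return expit(raw) * t_ref
    if name in LOGISTIC_PARAMS:
        return expit(raw)
    if name in EXP_PARAMS:
        return np.exp(raw)
    raise KeyError(name)


def to_unconstrained(name: str, native, t_ref: float = 1.0):
    """Inverse of :func:`to_native`."""
    native = np.asarray(native, dtype=float)
    if name == "tau":
        return logit(native / t_ref)
    if name in LOGISTIC_PARAMS:
        return logit(native)
    if name in EXP_PARAMS:
        return np.log(native)
    raise KeyError(name)


def native_jacobian(name: str, raw, t_ref: float = 1.0):
    """d native / d raw, evaluated at the unconstrained value."""
    raw = np.asarray(raw, dtype=float)
    if name == "tau":
        p = expit(raw)
        return p * (1.0 - p) * t_ref
    if name in LOGISTIC_PARAMS:
        p = expit(raw)
        return p * (1.0 - p)
    if name in EXP_PARAMS:
        return np.exp(raw)
    raise KeyError(name)
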