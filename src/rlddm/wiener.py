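"""Wiener first-passage-time distribution and drift-rate mappings.

The two-boundary Wiener diffusion (drift ``v``, boundary separation ``alpha``,
relative start point ``beta``, non-decision time ``tau``, diffusion coefficient
fixed to 1) is the choice rule of every model variant in this package: the
likelihood of a (choice, reaction time) pair is the first-passage density of
the accumulator through the boundary mapped to that choice.  The *upper*
boundary is, by convention, the high-contingency option, so ``beta > 0.5``
means an a-priori bias toward it and positive drift pushes toward it.

The density is evaluated through the classic dual series representation:
a small-time expansion (sum over mirrored start points) and a large-time
expansion (sine series), with the cheaper of the two chosen per evaluation
from the number of terms each needs for an absolute truncation error of
1e-7 on the unit-boundary density.  Analytic partial derivatives with
respect to (v, alpha, tau, beta) are provided for gradient-based sampling.

Note on conventions: the diffusion coefficient is 1 (the Stan/``rtdists``
scale).  Some of the older literature uses 0.1; parameters differ by a
factor of 10 between the two conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "drift_linear",
    "drift_sigmoid",
    "wiener_logpdf",
    "wiener_logpdf_grad",
    "wiener_choice_prob",
    "simulate_ddm",
]

_TRUNC_EPS = 1e-7  # absolute truncation tolerance of the dimensionless series


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a single Wiener first-passage evaluation.

    alpha : boundary separation (> 0, evidence units)
    tau   : non-decision time (>= 0, seconds)
    beta  : relative start point in (0, 1); 0.5 is unbiased
    nu    : drift rate (evidence per second, toward the upper boundary)
    """

    alpha: float
    tau: float
    beta: float
    nu: float

    def validate(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"boundary separation must be > 0, got {self.alpha}")
        if self.tau < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.tau}")
        if not 0 < self.beta < 1:
            raise ValueError(f"start-point bias must lie in (0, 1), got {self.beta}")


def drift_linear(q_high: float, q_low: float, nu: float):
    """Trial drift as the scaled value difference: ``nu_t = (q_high - q_low) * nu``."""
    return (np.asarray(q_high) - np.asarray(q_low)) * nu


def drift_sigmoid(q_high: float, q_low: float, nu: float, nu_max: float):
    """Trial drift through a saturating mapping bounded at ``±nu_max``.

    ``S(x) = 2*nu_max / (1 + exp(-x)) - nu_max`` applied to the scaled value
    difference ``x = (q_high - q_low) * nu``; strictly increasing, S(0) = 0.
    """
    from scipy.special import expit

    x = (np.asarray(q_high) - np.asarray(q_low)) * nu
    return nu_max * (2.0 * expit(x) - 1.0)


# ---------------------------------------------------------------------------
# dimensionless density f(u | w): first passage through the LOWER boundary of
# a zero-drift unit-boundary diffusion started at w, at scaled time u = t/a^2
# ---------------------------------------------------------------------------


@njit(cache=True)
def _n_terms_small(u, eps):
    # number of terms the small-time series needs for absolute error eps
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    return int(math.ceil(ks))


@njit(cache=True)
def _n_terms_large(u, eps):
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    return int(math.ceil(kl))


@njit(cache=True)
def _f0_and_derivs(u, w):
    """Dimensionless lower-boundary density F(u, w) and dF/du, dF/dw.

    Chooses the series (small- vs large-time) needing fewer terms; both are
    truncated to an absolute tolerance of ``_TRUNC_EPS``.
    """
    ks = _n_terms_small(u, _TRUNC_EPS)
    kl = _n_terms_large(u, _TRUNC_EPS)
    f = 0.0
    fu = 0.0
    fw = 0.0
    if ks < kl:
        c = 1.0 / math.sqrt(2.0 * math.pi * u * u * u)
        for k in range(-ks, ks + 1):
            s = w + 2.0 * k
            e = math.exp(-s * s / (2.0 * u))
            f += s * e
            fu += s * e * (-1.5 / u + s * s / (2.0 * u * u))
            fw += (1.0 - s * s / u) * e
        f *= c
        fu *= c
        fw *= c
    else:
        for k in range(1, kl + 1):
            kp = k * math.pi
            e = math.exp(-kp * kp * u / 2.0)
            sn = math.sin(kp * w)
            f += math.pi * k * e * sn
            fu += math.pi * k * e * sn * (-kp * kp / 2.0)
            fw += math.pi * kp * k * e * math.cos(kp * w)
    return f, fu, fw


@njit(cache=True)
def _logpdf_grad_lower(t, v, a, w):
    """Log density of hitting the LOWER boundary at decision time t, with
    partial derivatives wrt (v, a, t, w).  Returns (-inf, 0,0,0,0) when the
    truncated series underflows."""
    # reject degenerate/overflowing parameter regions outright (zero density)
    if not (t > 0.0 and 0.0 < w < 1.0):
        return -np.inf, 0.0, 0.0, 0.0, 0.0
    if not (1e-6 < a < 1e6) or not (abs(v) < 1e8) or not (t < 1e8):
        return -np.inf, 0.0, 0.0, 0.0, 0.0
    u = t / (a * a)
    if not np.isfinite(u) or u <= 1e-12:
        return -np.inf, 0.0, 0.0, 0.0, 0.0
    f, fu, fw = _f0_and_derivs(u, w)
    if f < 1e-290:
        return -np.inf, 0.0, 0.0, 0.0, 0.0
    lp = -2.0 * math.log(a) - v * a * w - v * v * t / 2.0 + math.log(f)
    gu = fu / f
    gw_ = fw / f
    d_v = -a * w - v * t
    d_t = -v * v / 2.0 + gu / (a * a)  # derivative wrt decision time t
    d_a = -2.0 / a - v * w + gu * (-2.0 * t / (a * a * a))
    d_w = -v * a + gw_
    return lp, d_v, d_a, d_t, d_w


@njit(cache=True)
def _wiener_logpdf_grad(rt, upper, alpha, tau, beta, nu):
    """Log density of (boundary, rt) and gradient wrt (nu, alpha, tau, beta).

    ``upper`` is 1 if the upper boundary was hit, else 0.  Upper-boundary
    density equals the lower-boundary density under (nu, beta) -> (-nu, 1-beta).
    """
    t = rt - tau
    if t <= 0.0:
        return -np.inf, 0.0, 0.0, 0.0, 0.0
    if upper == 1:
        lp, d_v, d_a, d_t, d_w = _logpdf_grad_lower(t, -nu, alpha, 1.0 - beta)
        d_v = -d_v
        d_w = -d_w
    else:
        lp, d_v, d_a, d_t, d_w = _logpdf_grad_lower(t, nu, alpha, beta)
    # d/dtau = -d/dt
    return lp, d_v, d_a, -d_t, d_w


def wiener_logpdf(rt, boundary, params: DDMParams, strict: bool = False):
    """Joint log density of hitting ``boundary`` ("upper"/"lower") at ``rt``.

    ``rt <= tau`` yields ``-inf`` (or raises when ``strict=True``): no decision
    time is available below the non-decision time.  Vectorized over ``rt``.
    """
    params.validate()
    up = _boundary_flag(boundary)
    rts = np.atleast_1d(np.asarray(rt, dtype=float))
    if strict and np.any(rts <= params.tau):
        raise ValueError("rt <= tau: reaction time below the non-decision time")
    out = np.empty(rts.shape)
    for i, r in enumerate(rts):
        out[i] = _wiener_logpdf_grad(r, up, params.alpha, params.tau, params.beta, params.nu)[0]
    return out[0] if np.isscalar(rt) else out


def wiener_logpdf_grad(rt: float, boundary, params: DDMParams):
    """Log density and its gradient wrt (nu, alpha, tau, beta) at a scalar rt."""
    params.validate()
    up = _boundary_flag(boundary)
    lp, d_v, d_a, d_tau, d_w = _wiener_logpdf_grad(
        float(rt), up, params.alpha, params.tau, params.beta, params.nu
    )
    return lp, np.array([d_v, d_a, d_tau, d_w])


def _boundary_flag(boundary) -> int:
    if boundary in (1, "upper", "high"):
        return 1
    if boundary in (0, "lower", "low"):
        return 0
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def wiener_choice_prob(params: DDMParams) -> float:
    """Probability that the accumulator is absorbed at the upper boundary.

    Closed form ``(1 - exp(-2 nu beta alpha)) / (1 - exp(-2 nu alpha))`` for
    nonzero drift; ``beta`` at zero drift.
    """
    params.validate()
    v, a, w = params.nu, params.alpha, params.beta
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return w
    # expm1 keeps the ratio stable for small |x|
    return math.expm1(-x * w) / math.expm1(-x)


# leading-order boundary-layer correction for discrete-time first passage:
# absorb at boundaries pulled in by c = zeta(1/2)/sqrt(2pi) * sigma * sqrt(dt)
_BOUNDARY_SHIFT = 0.5826


@njit(cache=True)
def _advance_block(pos, steps, z, m, drift, sdt, lo, hi, abs_steps, abs_sign):
    """Advance surviving paths through m pre-drawn steps each.

    Survivors are compacted to the front of ``pos``/``steps``; absorbed
    paths append their crossing step count and boundary sign to
    ``abs_steps``/``abs_sign``.  Returns (n_surviving, n_absorbed).
    """
    n = pos.shape[0]
    keep = 0
    nabs = 0
    for i in range(n):
        x = pos[i]
        s = steps[i]
        hit = 0
        for j in range(m):
            x += drift + sdt * z[i * m + j]
            s += 1
            if x >= hi:
                hit = 1
                break
            if x <= lo:
                hit = -1
                break
        if hit == 0:
            pos[keep] = x
            steps[keep] = s
            keep += 1
        else:
            abs_steps[nabs] = s
            abs_sign[nabs] = hit
            nabs += 1
    return keep, nabs


def _simulate_paths(n, alpha, tau, beta, nu, dt, seed):
    rng = np.random.default_rng(seed)
    sdt = math.sqrt(dt)
    c = _BOUNDARY_SHIFT * sdt
    lo, hi = min(c, alpha / 2), max(alpha - c, alpha / 2)
    pos = np.full(n, beta * alpha)
    steps = np.zeros(n, dtype=np.int64)
    out_rts = []
    out_up = []
    while pos.size:
        k = pos.size
        # block of m pre-drawn steps per path, capped at ~64 MB
        m = int(min(256, max(8, 8_000_000 // k)))
        z = rng.standard_normal(k * m)
        abs_steps = np.empty(k, dtype=np.int64)
        abs_sign = np.empty(k, dtype=np.int64)
        keep, nabs = _advance_block(
            pos, steps, z, m, nu * dt, sdt, lo, hi, abs_steps, abs_sign
        )
        if nabs:
            out_rts.append(tau + abs_steps[:nabs] * dt)
            out_up.append((abs_sign[:nabs] > 0).astype(np.int64))
            pos = pos[:keep].copy()
            steps = steps[:keep].copy()
    rts = np.concatenate(out_rts) if out_rts else np.empty(0)
    upper = np.concatenate(out_up) if out_up else np.empty(0, dtype=np.int64)
    return rts, upper


def simulate_ddm(params: DDMParams, n: int, seed: int, dt: float = 1e-3):
    """Euler–Maruyama simulation of the diffusion; returns (rts, upper_flags).

    Every sampled RT exceeds ``tau``.  The step size biases hitting times by
    O(sqrt(dt)); use small ``dt`` when validating against the analytic density.
    """
    params.validate()
    if dt <= 0:
        raise ValueError(f"step size must be > 0, got {dt}")
    if n < 1:
        raise ValueError(f"need n >= 1 paths, got {n}")
    return _simulate_paths(int(n), params.alpha, params.tau, params.beta, params.nu, dt, seed)
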