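"""Cumulative prospect theory primitives.

The model combines a sign-dependent power value function, a two-parameter
probability weighting function that is linear in log-odds, and a logistic
choice rule mapping the utility difference between two gambles onto a
choice probability.  All functions accept scalars or numpy arrays and are
pure: the tunable quantities live in :class:`CPTParams`.

Parameters
----------
alpha : value discrimination, the shared curvature exponent of the value
    function in the gain and loss domains (0 < alpha; alpha < 1 gives the
    classic concave-for-gains / convex-for-losses shape).
lam : loss aversion, the multiplicative weight on the disutility of losses
    (lam > 1 means losses loom larger than equivalent gains).
gamma : curvature of the probability weighting function (gamma < 1 gives
    the inverse-S shape that overweights small probabilities).
delta : elevation of the probability weighting function.
k : choice sensitivity of the logistic rule; held at 1 so that no
    parameter outside the prospect-theory quartet is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "CPTParams",
    "value",
    "weight",
    "utility",
    "choice_probability",
    "expected_value",
    "PROB_CLIP_EPS",
]

#: choice probabilities are clipped to [eps, 1 - eps] before any log is
#: taken; with k = 1 on raw point values up to 200 the logistic saturates
#: far beyond double precision, and clipping keeps likelihoods finite.
PROB_CLIP_EPS = 1e-12

ArrayLike = Union[float, int, np.ndarray]


@dataclass(frozen=True)
class CPTParams:
    """Parameter quartet (alpha, lambda, gamma, delta) with fixed k."""

    alpha: float = 1.0
    lam: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    k: float = field(default=1.0)

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "gamma", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"CPT parameter {name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.gamma, self.delta], dtype=float)

    @classmethod
    def from_array(cls, arr, k: float = 1.0) -> "CPTParams":
        a, l, g, d = (float(v) for v in arr)
        return cls(alpha=a, lam=l, gamma=g, delta=d, k=k)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "lam": self.lam, "gamma": self.gamma,
                "delta": self.delta, "k": self.k}

    @classmethod
    def from_dict(cls, d: dict) -> "CPTParams":
        return cls(alpha=d["alpha"], lam=d["lam"], gamma=d["gamma"],
                   delta=d["delta"], k=d.get("k", 1.0))


def value(x: ArrayLike, params: CPTParams) -> ArrayLike:
    """Subjective value of an outcome.

    ``v(x) = x**alpha`` for gains and ``v(x) = -lam * (-x)**alpha`` for
    losses, so the function is odd up to the loss-aversion weight and
    passes through the reference point v(0) = 0.
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x) ** params.alpha
    out = np.where(x >= 0, ax, -params.lam * ax)
    return out if out.ndim else float(out)


def weight(p: ArrayLike, params: CPTParams) -> ArrayLike:
    """Decision weight ``w(p) = delta*p**gamma / (delta*p**gamma + (1-p)**gamma)``.

    Endpoints are preserved exactly (w(0)=0, w(1)=1) and the function is
    strictly increasing for any positive gamma, delta.
    """
    scalar = np.ndim(p) == 0
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    g, d = params.gamma, params.delta
    out = np.zeros_like(p)
    out[p == 1] = 1.0
    interior = (p > 0) & (p < 1)
    pi = p[interior]
    # evaluated in log space (the weight is linear in log odds); p**g can
    # underflow for small p and large g if formed directly
    out[interior] = expit(np.log(d) + g * (np.log(pi) - np.log1p(-pi)))
    return float(out[0]) if scalar else out


def _check_sign_pattern(x, y, trial_type: str) -> None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if trial_type == "GAIN_ONLY":
        ok = (x >= 0) & (y >= 0)
    elif trial_type == "LOSS_ONLY":
        ok = (x <= 0) & (y <= 0)
    elif trial_type == "MIXED":
        ok = x * y < 0
    else:
        raise ValueError(f"unknown trial type {trial_type!r}")
    if not np.all(ok):
        raise ValueError(f"outcome sign pattern inconsistent with trial type {trial_type}")


def utility(gamble, trial_type: str, params: CPTParams) -> float:
    """CPT utility of a two-outcome gamble ``(x, y, p)``.

    Single-domain gambles use complementary weights,
    ``f = w(p) v(x) + (1 - w(p)) v(y)``; mixed gambles weight the gain and
    the loss separately, ``f = w(p) v(x) + w(1-p) v(y)``.  With all four
    parameters at 1 both branches reduce to the expected value.
    """
    x, y, p = gamble
    _check_sign_pattern(x, y, trial_type)
    wp = weight(p, params)
    if trial_type == "MIXED":
        wy = weight(1.0 - np.asarray(p, dtype=float), params)
    else:
        wy = 1.0 - wp
    out = wp * value(x, params) + wy * value(y, params)
    return float(out) if np.ndim(out) == 0 else out


def choice_probability(f_a: ArrayLike, f_b: ArrayLike, params: CPTParams,
                       eps: float = PROB_CLIP_EPS) -> ArrayLike:
    """Probability of choosing gamble A over B.

    Logistic rule ``P(A) = 1 / (1 + exp(k (f_B - f_A)))`` with the
    sensitivity k fixed at 1 by default; the result is clipped to
    ``[eps, 1 - eps]`` so downstream log-likelihoods stay finite.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    out = np.clip(expit(params.k * (f_a - f_b)), eps, 1.0 - eps)
    return out if out.ndim else float(out)


def expected_value(gamble) -> ArrayLike:
    """Expected value ``EV = p*x + (1-p)*y`` of a gamble ``(x, y, p)``."""
    x, y, p = gamble
    x = np.asarray(x, dtype=float)
    out = p * x + (1.0 - np.asarray(p, dtype=float)) * np.asarray(y, dtype=float)
    return out if out.ndim else float(out)
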