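"""Domain growth functions rho(t) for uniform isotropic growth x(t) = rho(t) x(0).

Every family satisfies rho(0) = 1 exactly and provides the analytic derivative
rho_dot. The degree-4 polynomial family (three free coefficients; the
order-0 and order-4 coefficients are fixed by rho(0) = 1 and rho(T) = rho_T)
is the finite-dimensional parameterization used when the growth function is
itself the unknown of the inverse problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthFunction",
    "constant_growth",
    "exponential_growth",
    "logistic_growth",
    "polynomial_growth",
    "eval_growth",
    "NonPositiveGrowthError",
]

#: Default logistic carrying capacity: matches the exponential family's final
#: size exp(0.6) at rate 0.001 and horizon 600, so both reference growth
#: profiles end at the same domain size.
DEFAULT_LOGISTIC_K = math.exp(0.6)


class NonPositiveGrowthError(ValueError):
    """A growth curve became non-positive on the requested time range."""


@dataclass(frozen=True)
class GrowthFunction:
    """A named growth family with its parameters.

    family : one of ``constant``, ``exponential``, ``logistic``, ``polynomial``
    params : family-specific parameters (see the factory functions)
    """

    family: str
    params: dict = field(default_factory=dict)

    def __call__(self, t):
        return eval_growth(self, t)


def constant_growth() -> GrowthFunction:
    """Stationary domain: rho = 1, rho_dot = 0."""
    return GrowthFunction("constant")


def exponential_growth(r: float = 0.001) -> GrowthFunction:
    """rho(t) = exp(r t)."""
    return GrowthFunction("exponential", {"r": float(r)})


def logistic_growth(r: float = 0.01, K: float = DEFAULT_LOGISTIC_K) -> GrowthFunction:
    """rho(t) = exp(r t) / (1 + (exp(r t) - 1)/K); saturates at K."""
    if K <= 0:
        raise ValueError("carrying capacity K must be positive")
    return GrowthFunction("logistic", {"r": float(r), "K": float(K)})


def polynomial_growth(dof, T: float, rho_T: float) -> GrowthFunction:
    """Degree-4 polynomial growth in scaled time s = t/T with 3 free coefficients.

    rho(sT) = 1 + c1 s + c2 s^2 + c3 s^3 + c4 s^4, with
    c4 = rho_T - 1 - c1 - c2 - c3 so that rho(0) = 1 and rho(T) = rho_T hold
    exactly. Positivity of rho is not guaranteed by construction and is
    checked at evaluation time.
    """
    if T <= 0 or rho_T <= 0:
        raise ValueError("T and rho_T must be positive")
    c1, c2, c3 = (float(c) for c in dof)
    c4 = rho_T - 1.0 - c1 - c2 - c3
    return GrowthFunction(
        "polynomial",
        {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "T": float(T), "rho_T": float(rho_T)},
    )


def eval_growth(g: GrowthFunction, t):
    """Evaluate (rho(t), rho_dot(t)) for scalar or array t.

    Raises
    ------
    NonPositiveGrowthError
        If a polynomial-family curve is non-positive at any requested time.
    """
    t_arr = np.asarray(t, dtype=float)
    p = g.params
    if g.family == "constant":
        rho = np.ones_like(t_arr)
        rho_dot = np.zeros_like(t_arr)
    elif g.family == "exponential":
        rho = np.exp(p["r"] * t_arr)
        rho_dot = p["r"] * rho
    elif g.family == "logistic":
        r, K = p["r"], p["K"]
        E = np.exp(r * t_arr)
        denom = 1.0 + (E - 1.0) / K
        rho = E / denom
        rho_dot = r * E * (1.0 - 1.0 / K) / (denom * denom)
    elif g.family == "polynomial":
        s = t_arr / p["T"]
        c1, c2, c3, c4 = p["c1"], p["c2"], p["c3"], p["c4"]
        rho = 1.0 + s * (c1 + s * (c2 + s * (c3 + s * c4)))
        rho_dot = (c1 + s * (2 * c2 + s * (3 * c3 + s * 4 * c4))) / p["T"]
        if np.any(rho <= 0):
            raise NonPositiveGrowthError(
                f"polynomial growth non-positive (min rho = {float(np.min(rho)):.4g})"
            )
    else:
        raise ValueError(f"unknown growth family {g.family!r}")
    if t_arr.ndim == 0:
        return float(rho), float(rho_dot)
    return rho, rho_dot


def positive_on_grid(g: GrowthFunction, T: float, n: int = 200) -> bool:
    """Check rho > 0 on a uniform grid of n+1 points over [0, T]."""
    try:
        rho, _ = eval_growth(g, np.linspace(0.0, T, n + 1))
    except NonPositiveGrowthError:
        return False
    return bool(np.all(rho > 0))


def project_to_polynomial(
    g: GrowthFunction, T: float, rho_T: float, n: int = 401
) -> GrowthFunction:
    """Least-squares projection of an arbitrary growth curve onto the 3-DOF family.

    Fits c1, c2, c3 so that the constrained quartic best matches ``g`` on a
    uniform grid over [0, T] (the endpoint values rho(0)=1, rho(T)=rho_T are
    enforced by construction). Used to express reference exponential/logistic
    curves in the polynomial parameter space.
    """
    t = np.linspace(0.0, T, n)
    s = t / T
    rho, _ = eval_growth(g, t)
    # rho - 1 - (rho_T - 1) s^4 = c1 (s - s^4) + c2 (s^2 - s^4) + c3 (s^3 - s^4)
    target = rho - 1.0 - (rho_T - 1.0) * s**4
    basis = np.stack([s - s**4, s**2 - s**4, s**3 - s**4], axis=1)
    dof, *_ = np.linalg.lstsq(basis, target, rcond=None)
    return polynomial_growth(dof, T, rho_T)
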