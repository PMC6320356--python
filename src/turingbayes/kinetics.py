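"""Schnakenberg (activator-depleted) reaction kinetics and the Turing space.

The kinetics are

    f(u, v) = a - u + u^2 v,        g(u, v) = b - u^2 v,

where ``u`` is the activator and ``v`` the depleted substrate. This module
provides the reaction terms, the spatially homogeneous steady state, its
linearization, and the Turing space: the set of parameters ``(a, b, d)`` for
which diffusion destabilizes the homogeneous steady state and stationary
spatial patterns can form (diffusion-driven instability).

All quantities are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParameters",
    "reaction_terms",
    "homogeneous_steady_state",
    "steady_state_jacobian",
    "turing_conditions",
    "sample_turing_space",
    "turing_space_area",
    "TuringSampleError",
]


class TuringSampleError(RuntimeError):
    """Rejection sampling of the Turing space exhausted its draw budget."""

    def __init__(self, attempts: int, accepted: int, requested: int):
        self.attempts = attempts
        self.accepted = accepted
        self.requested = requested
        super().__init__(
            f"rejection sampling produced {accepted}/{requested} points "
            f"after {attempts} draws; the box may not intersect the Turing space"
        )


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic and diffusion constants of the Schnakenberg system.

    Parameters
    ----------
    a, b
        Production rates of activator ``u`` and substrate ``v``; both > 0.
    d
        Ratio of the substrate to activator diffusion coefficients; > 0.
        Turing instability requires ``d > 1`` (long-range inhibition).
    gamma
        Reaction scaling; > 0. Larger ``gamma`` acts like a larger domain,
        selecting shorter pattern wavelengths.
    m
        Spatial dimension, 1 or 2.
    """

    a: float
    b: float
    d: float
    gamma: float
    m: int = 1

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "gamma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.m not in (1, 2):
            raise ValueError(f"spatial dimension m must be 1 or 2, got {self.m!r}")


def reaction_terms(u, v, params: ModelParameters):
    """Evaluate f(u,v) = a - u + u^2 v and g(u,v) = b - u^2 v elementwise."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uuv = u * u * v
    return params.a - u + uuv, params.b - uuv


def homogeneous_steady_state(a: float, b: float) -> tuple[float, float]:
    """Spatially homogeneous steady state (u*, v*) = (a+b, b/(a+b)^2).

    Raises
    ------
    ValueError
        If ``a + b <= 0`` (the steady state is undefined).
    """
    s = a + b
    if s <= 0:
        raise ValueError(f"steady state requires a + b > 0, got a={a}, b={b}")
    return s, b / (s * s)


def steady_state_jacobian(a: float, b: float) -> tuple[float, float, float, float]:
    """Partial derivatives (f_u, f_v, g_u, g_v) at the homogeneous steady state.

    Analytically: f_u = (b-a)/(b+a), f_v = (a+b)^2, g_u = -2b/(a+b),
    g_v = -(a+b)^2, with determinant f_u g_v - f_v g_u = (a+b)^2.
    """
    s = a + b
    if s <= 0:
        raise ValueError(f"Jacobian requires a + b > 0, got a={a}, b={b}")
    f_u = (b - a) / s
    f_v = s * s
    g_u = -2.0 * b / s
    g_v = -(s * s)
    return f_u, f_v, g_u, g_v


def turing_conditions(a, b, d):
    """The four diffusion-driven-instability conditions for Schnakenberg kinetics.

    Returns ``(values, in_space)`` where ``values`` stacks the four left-hand
    sides, in order:

    1. trace:            f_u + g_v                       (< 0)
    2. determinant:      f_u g_v - f_v g_u = (a+b)^2     (> 0)
    3. d-weighted trace: d f_u + g_v                     (> 0)
    4. discriminant:     (d f_u + g_v)^2 - 4 d (f_u g_v - f_v g_u)  (> 0)

    ``in_space`` is True where all four strict inequalities hold. Boundary
    points (any condition exactly zero) count as outside. Accepts scalars or
    broadcastable arrays; positivity of inputs is required for scalars and
    assumed elementwise for arrays (non-positive a+b yields in_space False).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    scalar = a.ndim == 0 and b.ndim == 0 and d_arr.ndim == 0
    if scalar:
        if a + b <= 0:
            raise ValueError(f"turing_conditions requires a + b > 0, got a={a}, b={b}")
        if d_arr <= 0:
            raise ValueError(f"turing_conditions requires d > 0, got d={d}")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = a + b
        f_u = (b - a) / s
        det = s * s
        trace = f_u - det
        d_trace = d_arr * f_u - det
        disc = d_trace * d_trace - 4.0 * d_arr * det
    values = np.stack(np.broadcast_arrays(trace, det, d_trace, disc))
    in_space = (trace < 0) & (det > 0) & (d_trace > 0) & (disc > 0)
    if not scalar:
        in_space &= (s > 0) & (d_arr > 0)
    if scalar:
        return tuple(float(x) for x in values), bool(in_space)
    return values, in_space


def sample_turing_space(
    n: int,
    d: float,
    box: tuple[tuple[float, float], tuple[float, float]] = ((0.1, 10.0), (0.1, 10.0)),
    seed: int | np.random.Generator = 0,
    max_draws: int = 10_000_000,
) -> np.ndarray:
    """Draw ``n`` points uniformly from the Turing space intersected with a box.

    Uses rejection sampling: uniform draws on the ``(a, b)`` box, keeping
    points that satisfy all four instability conditions. For the default
    ``[0.1, 10]^2`` box at ``d = 10`` the acceptance rate is about 1%, hence
    the generous default draw budget.

    Returns an ``(n, 2)`` array of accepted ``(a, b)`` points.

    Raises
    ------
    TuringSampleError
        If the budget is exhausted before ``n`` acceptances.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    (a_lo, a_hi), (b_lo, b_hi) = box
    if not (a_hi > a_lo and b_hi > b_lo):
        raise ValueError(f"box must have positive area, got {box!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = np.empty((n, 2))
    accepted = 0
    attempts = 0
    batch = max(1024, min(4 * n, 262_144))
    while accepted < n:
        if attempts >= max_draws:
            raise TuringSampleError(attempts, accepted, n)
        k = min(batch, max_draws - attempts)
        ab = rng.uniform((a_lo, b_lo), (a_hi, b_hi), size=(k, 2))
        attempts += k
        _, keep = turing_conditions(ab[:, 0], ab[:, 1], d)
        hits = ab[keep]
        take = min(len(hits), n - accepted)
        out[accepted : accepted + take] = hits[:take]
        accepted += take
    return out


def turing_space_area(
    d: float,
    box: tuple[tuple[float, float], tuple[float, float]] = ((0.1, 10.0), (0.1, 10.0)),
    resolution: int = 400,
) -> tuple[float, float]:
    """Estimate the area of the Turing space inside a box by midpoint counting.

    The box is split into ``resolution`` cells per axis; a cell counts toward
    the area when its midpoint satisfies the instability conditions. Returns
    ``(area, ratio_to_box)`` where ``ratio_to_box = box_area / area`` (how many
    times larger the box is than the Turing space it contains).
    """
    if resolution < 100:
        raise ValueError("resolution must be >= 100 cells per axis")
    (a_lo, a_hi), (b_lo, b_hi) = box
    da = (a_hi - a_lo) / resolution
    db = (b_hi - b_lo) / resolution
    a_mid = a_lo + da * (np.arange(resolution) + 0.5)
    b_mid = b_lo + db * (np.arange(resolution) + 0.5)
    A, B = np.meshgrid(a_mid, b_mid, indexing="ij")
    _, inside = turing_conditions(A, B, d)
    area = float(inside.sum()) * da * db
    box_area = (a_hi - a_lo) * (b_hi - b_lo)
    ratio = box_area / area if area > 0 else float("inf")
    return area, ratio
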