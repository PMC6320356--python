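"""Synthetic observations (Gaussian noise model) and the misfit potential.

The data model is ``y = G(p) + eta`` with ``eta`` zero-mean Gaussian,
independent across nodes and components, with per-component standard
deviation equal to a fixed fraction of that component's spatial range. The
potential used by all samplers is the covariance-weighted squared misfit

    Phi(p; y) = sum_c sum_i (G(p)_{c,i} - y_{c,i})^2 / sigma_c^2

with no 1/2 factor (fixed project-wide; it sets the posterior temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .growth import NonPositiveGrowthError
from .solver import BlowUpError, FieldPair, SteadyStateError

__all__ = ["Observation", "make_synthetic_data", "potential"]


@dataclass
class Observation:
    """Noisy final-time fields plus the (known) noise standard deviations.

    sigma_u, sigma_v are in concentration units; the likelihood covariance is
    diagonal, sigma_c^2 * I per component.
    """

    data: FieldPair
    sigma_u: float
    sigma_v: float
    meta: dict = field(default_factory=dict)

    @property
    def n_observed(self) -> int:
        return self.data.u.size + self.data.v.size


def make_synthetic_data(
    solution: FieldPair,
    noise_fraction: float,
    seed: int | np.random.Generator,
    meta: dict | None = None,
) -> Observation:
    """Perturb a noiseless solution with Gaussian noise scaled to its range.

    Each component independently receives i.i.d. zero-mean Gaussian noise with
    standard deviation ``noise_fraction * (max - min)`` of that component's
    noiseless values (u and v have their own scales).

    Raises
    ------
    ValueError
        If ``noise_fraction > 0`` but a component has zero spatial range
        (degenerate, unpatterned solution).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranges = {}
    for name, vals in (("u", solution.u), ("v", solution.v)):
        r = float(np.max(vals) - np.min(vals))
        if noise_fraction > 0 and r == 0.0:
            raise ValueError(f"component {name} has zero range; cannot scale noise")
        ranges[name] = r
    sigma_u = noise_fraction * ranges["u"]
    sigma_v = noise_fraction * ranges["v"]
    u = solution.u + sigma_u * rng.standard_normal(solution.u.shape)
    v = solution.v + sigma_v * rng.standard_normal(solution.v.shape)
    info = {"noise_fraction": noise_fraction}
    if meta:
        info.update(meta)
    return Observation(FieldPair(u, v, solution.t), sigma_u, sigma_v, info)


def potential(
    p: np.ndarray,
    obs: Observation,
    forward: Callable[[np.ndarray], FieldPair],
) -> float:
    """Sigma-weighted squared misfit between the model prediction and the data.

    ``forward`` maps a parameter vector to the predicted final-time fields.
    Failures of the forward model (scheme blow-up, non-positive growth,
    failed steady-state seeking) yield ``+inf`` so that samplers reject the
    proposal rather than aborting.
    """
    if obs.sigma_u <= 0 or obs.sigma_v <= 0:
        raise ValueError("potential requires strictly positive noise sigmas")
    try:
        pred = forward(np.asarray(p, dtype=float))
    except (BlowUpError, NonPositiveGrowthError, SteadyStateError, ValueError):
        return float("inf")
    ru = (pred.u - obs.data.u) / obs.sigma_u
    rv = (pred.v - obs.data.v) / obs.sigma_v
    phi = float(np.sum(ru * ru) + np.sum(rv * rv))
    return phi if np.isfinite(phi) else float("inf")
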