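"""Reference study configurations and synthetic-data generators.

Two synthetic studies define the package's benchmark conditions:

* a 1-D pattern on a uniformly growing domain, integrated to T = 600 from
  fixed perturbed-steady-state initial conditions, with exponential
  (rate 0.001) or logistic (rate 0.01, carrying capacity e^0.6) growth, and
  5% Gaussian noise -- used to identify the growth function itself;
* a 2-D steady-state pattern on the stationary unit square at the reference
  kinetic parameters (a = 0.126779, b = 0.792366, d = 10, gamma = 1000),
  with 5% or 10% Gaussian noise -- used to identify kinetic parameters.

The ``paper``-scale solver settings (h = 1e-2, tau = 1e-4, steady-state
threshold 1e-5) are the generators' reference conditions; coarser presets
are provided because full-scale runs need long wall-clock times.

This module also defines picklable forward operators G(p) for the samplers.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .growth import (
    GrowthFunction,
    eval_growth,
    exponential_growth,
    logistic_growth,
    polynomial_growth,
    NonPositiveGrowthError,
)
from .kinetics import ModelParameters
from .observation import Observation, make_synthetic_data
from .solver import (
    FieldPair,
    SolverConfig,
    initial_condition_1d,
    initial_condition_2d,
    solve_forward,
    solve_to_steady_state,
)

__all__ = [
    "EXAMPLE1_PARAMS",
    "TABLE1_PARAMS",
    "SOLVER_PRESETS",
    "growing_domain_observation",
    "steady_state_observation",
    "PolynomialGrowthForward",
    "StationaryKineticsForward",
]

#: 1-D growing-domain study: standard Schnakenberg values from the literature.
EXAMPLE1_PARAMS = ModelParameters(a=0.1, b=0.9, d=10.0, gamma=1000.0, m=1)

#: 2-D stationary-domain study: exact parameter values used to generate the data.
TABLE1_PARAMS = ModelParameters(a=0.126779, b=0.792366, d=10.0, gamma=1000.0, m=2)

#: Solver presets. "paper" is the reference resolution; "test" and "tiny" are
#: coarser settings for desk-scale runs and the automated test suite.
SOLVER_PRESETS = {
    "paper": SolverConfig(h=1e-2, tau=1e-4, T=600.0, tol=1e-5, max_time=1200.0),
    "test": SolverConfig(h=1.0 / 32, tau=1e-3, T=600.0, tol=1e-5, max_time=600.0),
    "tiny": SolverConfig(h=1.0 / 16, tau=2e-3, T=600.0, tol=1e-4, max_time=300.0),
}


def growing_domain_observation(
    growth: str | GrowthFunction = "exponential",
    cfg: SolverConfig | str = "paper",
    noise_fraction: float = 0.05,
    seed: int = 0,
    params: ModelParameters = EXAMPLE1_PARAMS,
) -> Observation:
    """Generate the 1-D growing-domain dataset: solve to T and add noise.

    ``growth`` may be "exponential", "logistic", or any GrowthFunction.
    """
    if isinstance(cfg, str):
        cfg = SOLVER_PRESETS[cfg]
    if isinstance(growth, str):
        growth = {"exponential": exponential_growth, "logistic": logistic_growth}[
            growth
        ]()
    grid = cfg.grid(1)
    ic = initial_condition_1d(grid)
    final = solve_forward(params, growth, ic, cfg)
    rho_T, _ = eval_growth(growth, cfg.T)
    meta = {
        "study": "growing_domain_1d",
        "growth": growth.family,
        "growth_params": dict(growth.params),
        "rho_T": rho_T,
        "params": {"a": params.a, "b": params.b, "d": params.d, "gamma": params.gamma},
        "h": cfg.h,
        "tau": cfg.tau,
        "T": cfg.T,
        "seed": seed,
    }
    return make_synthetic_data(final, noise_fraction, seed, meta=meta)


def steady_state_observation(
    cfg: SolverConfig | str = "paper",
    noise_fraction: float = 0.05,
    seed: int = 0,
    params: ModelParameters = TABLE1_PARAMS,
    verify: bool = True,
) -> Observation:
    """Generate the 2-D stationary-domain dataset: run to the patterned
    steady state (with the 2T stationarity check) and add noise."""
    if isinstance(cfg, str):
        cfg = SOLVER_PRESETS[cfg]
    grid = cfg.grid(2)
    ic = initial_condition_2d(grid, params.a, params.b)
    state, T = solve_to_steady_state(params, ic, cfg, verify=verify)
    meta = {
        "study": "steady_state_2d",
        "params": {"a": params.a, "b": params.b, "d": params.d, "gamma": params.gamma},
        "h": cfg.h,
        "tau": cfg.tau,
        "tol": cfg.tol,
        "T_steady": T,
        "seed": seed,
    }
    return make_synthetic_data(state, noise_fraction, seed, meta=meta)


class PolynomialGrowthForward:
    """Observation operator for growth identification: DOF vector -> final fields.

    The kinetic parameters are fixed and known; the parameter vector is the
    three free coefficients of the degree-4 polynomial growth family, with
    the final size rho_T treated as known. Curves that become non-positive
    on the evaluation grid raise NonPositiveGrowthError (mapped to an
    infinite potential by the caller).
    """

    def __init__(
        self,
        cfg: SolverConfig,
        rho_T: float,
        params: ModelParameters = EXAMPLE1_PARAMS,
        positivity_grid: int = 200,
    ):
        self.cfg = cfg
        self.rho_T = float(rho_T)
        self.params = params
        self.positivity_grid = positivity_grid
        self._ic = initial_condition_1d(cfg.grid(1))

    def __call__(self, dof: np.ndarray) -> FieldPair:
        g = polynomial_growth(dof, self.cfg.T, self.rho_T)
        # positivity screen before paying for the PDE solve
        rho, _ = eval_growth(g, np.linspace(0.0, self.cfg.T, self.positivity_grid + 1))
        if np.any(rho <= 0):
            raise NonPositiveGrowthError("candidate growth curve non-positive")
        return solve_forward(self.params, g, self._ic, self.cfg)


class StationaryKineticsForward:
    """Observation operator for kinetic-parameter identification on the
    stationary unit square.

    ``infer`` names the components of the parameter vector, in order, out of
    ("a", "b", "d", "gamma"); the rest are fixed at ``base``. The initial
    condition is the fixed, known perturbation of the reference steady state
    (it does not change with the candidate parameters). ``mode="fixed"``
    integrates to the horizon ``T`` (typically the steady-state time recorded
    when the data were generated); ``mode="steady_state"`` re-runs the
    steady-state stopping rule per candidate (without the 2T verification).
    """

    def __init__(
        self,
        cfg: SolverConfig,
        infer: tuple[str, ...] = ("a", "b"),
        base: ModelParameters = TABLE1_PARAMS,
        mode: str = "fixed",
        T: float | None = None,
    ):
        if mode not in ("fixed", "steady_state"):
            raise ValueError(f"unknown mode {mode!r}")
        unknown = set(infer) - {"a", "b", "d", "gamma"}
        if unknown:
            raise ValueError(f"cannot infer {sorted(unknown)}")
        self.cfg = cfg if T is None else replace(cfg, T=T)
        self.infer = tuple(infer)
        self.base = base
        self.mode = mode
        self._ic = initial_condition_2d(self.cfg.grid(2), base.a, base.b)

    def __call__(self, p: np.ndarray) -> FieldPair:
        values = {"a": self.base.a, "b": self.base.b, "d": self.base.d, "gamma": self.base.gamma}
        for name, value in zip(self.infer, np.atleast_1d(p)):
            values[name] = float(value)
        params = ModelParameters(m=2, **values)
        if self.mode == "fixed":
            return solve_forward(params, GrowthFunction("constant"), self._ic, self.cfg)
        state, _ = solve_to_steady_state(params, self._ic, self.cfg, verify=False)
        return state
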