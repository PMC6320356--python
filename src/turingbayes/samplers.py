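"""Metropolis-Hastings samplers for the misfit potential Phi.

Implements the acceptance rule a(x, x') = min{1, exp(Phi(x) - Phi(x'))}, two
proposal kernels valid for function-space targets (the independence sampler,
which redraws from the prior, and the preconditioned Crank-Nicolson kernel),
and a multi-proposal parallel Metropolis-Hastings step: N proposals are
drawn, their potentials evaluated concurrently, and N new states are
resampled from the stationary distribution of the (N+1)-state transition
matrix A(i, j) = a(x^i, x^j)/N (off-diagonal). For this acceptance rule the
stationary distribution has the closed form softmax(-Phi), since
pi_i A(i,j) = min(e^{-Phi_i}, e^{-Phi_j})/N is symmetric (detailed balance).

Determinism contract: all proposal randomness is consumed on the
coordinating generator before any potential is evaluated, so chains are
bit-identical for any worker count.
"""

from __future__ import annotations

import functools
import math
import multiprocessing
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChainState",
    "Chain",
    "acceptance_probability",
    "independence_propose",
    "pcn_propose",
    "PCNKernel",
    "IndependenceKernel",
    "transition_matrix",
    "stationary_distribution",
    "stationary_from_matrix",
    "parallel_mh_step",
    "run_chain",
]


@dataclass
class ChainState:
    """A parameter vector with its potential value."""

    p: np.ndarray
    phi: float


@dataclass
class Chain:
    """Ordered samples from one MCMC run (N recorded states per step)."""

    samples: np.ndarray  # (steps * N, dim)
    phis: np.ndarray  # (steps * N,)
    step_index: np.ndarray  # (steps * N,)
    seed: int
    n_proposals: int
    names: list[str] = field(default_factory=list)
    accept_fraction: float = 0.0
    n_failed_forward: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)


def acceptance_probability(phi_current: float, phi_proposed: float) -> float:
    """min{1, exp(phi_current - phi_proposed)} with infinite-potential handling.

    An infinite proposed potential (failed forward solve) is never accepted;
    an infinite current potential with a finite proposal is always left.
    """
    if math.isinf(phi_proposed) and phi_proposed > 0:
        return 0.0
    if math.isinf(phi_current) and phi_current > 0:
        return 1.0
    return min(1.0, math.exp(min(0.0, phi_current - phi_proposed)))


def independence_propose(prior, rng: np.random.Generator) -> np.ndarray:
    """A fresh prior draw, independent of the current state."""
    return prior.sample(1, rng)[0]


def pcn_propose(
    x: np.ndarray,
    beta: float,
    Gamma: np.ndarray,
    rng: np.random.Generator,
    mean: np.ndarray | None = None,
    mean_scaling: str = "prior_preserving",
) -> np.ndarray:
    """Preconditioned Crank-Nicolson proposal around the current state.

    With ``mean_scaling="prior_preserving"`` (default) the proposal is

        m + sqrt(1 - beta^2) (x - m) + beta * xi,   xi ~ N(0, Gamma),

    which leaves the Gaussian prior N(m, Gamma) invariant, so the acceptance
    rule min{1, exp(Phi(x) - Phi(x'))} targets the correct posterior. At
    beta = 1 this reduces to the independence sampler on N(m, Gamma); at
    beta = 0 the proposal equals the current state. ``mean_scaling="printed"``
    uses the factor sqrt(1 - beta) instead (kept selectable for comparison;
    it does not preserve the prior except at the endpoints).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    x = np.asarray(x, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.ndim == 1:
        Gamma = np.diag(Gamma)
    if not np.allclose(Gamma, Gamma.T):
        raise ValueError("Gamma must be symmetric")
    try:
        L = np.linalg.cholesky(Gamma)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(Gamma)
        if np.any(eigval < -1e-10 * max(1.0, float(np.max(np.abs(eigval))))):
            raise ValueError("Gamma must be positive semi-definite") from None
        L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    m = np.zeros_like(x) if mean is None else np.asarray(mean, dtype=float)
    if mean_scaling == "prior_preserving":
        factor = math.sqrt(1.0 - beta * beta)
    elif mean_scaling == "printed":
        factor = math.sqrt(1.0 - beta)
    else:
        raise ValueError(f"unknown mean_scaling {mean_scaling!r}")
    xi = L @ rng.standard_normal(len(x))
    return m + factor * (x - m) + beta * xi


class IndependenceKernel:
    """Proposal kernel drawing fresh prior samples."""

    def __init__(self, prior):
        self.prior = prior

    def __call__(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return independence_propose(self.prior, rng)

    def describe(self) -> dict:
        return {"kind": "independence"}


class PCNKernel:
    """pCN kernel with fixed step size beta and covariance Gamma."""

    def __init__(self, beta, Gamma, mean=None, mean_scaling="prior_preserving"):
        self.beta = float(beta)
        self.Gamma = np.asarray(Gamma, dtype=float)
        self.mean = mean
        self.mean_scaling = mean_scaling
        # validate eagerly
        pcn_propose(
            np.zeros(self.Gamma.shape[0] if self.Gamma.ndim == 2 else len(np.atleast_1d(self.Gamma))),
            self.beta,
            self.Gamma,
            np.random.default_rng(0),
            mean=self.mean,
            mean_scaling=self.mean_scaling,
        )

    def __call__(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return pcn_propose(
            x, self.beta, self.Gamma, rng, mean=self.mean, mean_scaling=self.mean_scaling
        )

    def describe(self) -> dict:
        return {"kind": "pcn", "beta": self.beta, "mean_scaling": self.mean_scaling}


def transition_matrix(phis: Sequence[float]) -> np.ndarray:
    """(N+1)x(N+1) parallel-MH transition matrix from the potential values."""
    phis = np.asarray(phis, dtype=float)
    n1 = len(phis)
    N = n1 - 1
    A = np.zeros((n1, n1))
    for i in range(n1):
        for j in range(n1):
            if j != i:
                A[i, j] = acceptance_probability(phis[i], phis[j]) / N
        A[i, i] = 1.0 - np.sum(A[i]) + A[i, i]
    return A


def stationary_distribution(phis: Sequence[float]) -> np.ndarray:
    """Stationary distribution of the parallel-MH transition matrix.

    Closed form softmax(-Phi) with log-sum-exp stabilization; states with
    infinite potential get zero mass. If every potential is infinite, all
    mass stays on state 0 (the chain holds its current position).
    """
    phis = np.asarray(phis, dtype=float)
    finite = np.isfinite(phis)
    if not np.any(finite):
        pi = np.zeros(len(phis))
        pi[0] = 1.0
        return pi
    weights = np.zeros(len(phis))
    shift = np.min(phis[finite])
    weights[finite] = np.exp(-(phis[finite] - shift))
    return weights / np.sum(weights)


def stationary_from_matrix(A: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a stochastic matrix (generic oracle)."""
    eigval, eigvec = np.linalg.eig(A.T)
    idx = int(np.argmin(np.abs(eigval - 1.0)))
    pi = np.real(eigvec[:, idx])
    pi = np.abs(pi)
    return pi / np.sum(pi)


def _screened_potential(potential_fn, prior, p) -> float:
    if math.isinf(prior.logpdf(p)):
        return math.inf
    return potential_fn(p)


def _evaluate_serial(potential_fn, proposals):
    return [potential_fn(p) for p in proposals]


def parallel_mh_step(
    x_current: ChainState,
    N: int,
    propose: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    evaluate: Callable[[list[np.ndarray]], list[float]],
    rng: np.random.Generator,
) -> list[ChainState]:
    """One multi-proposal step: returns N states resampled from the
    stationary distribution over {current} + {N proposals}."""
    if N < 1:
        raise ValueError("N must be >= 1")
    proposals = [propose(x_current.p, rng) for _ in range(N)]
    # indices are drawn after the potentials, but the random draw for them is
    # taken from the coordinating stream; evaluation consumes no randomness
    phis = [x_current.phi] + list(evaluate(proposals))
    states = [x_current] + [ChainState(p, phi) for p, phi in zip(proposals, phis[1:])]
    pi = stationary_distribution(phis)
    indices = rng.choice(N + 1, size=N, p=pi)
    return [states[i] for i in indices]


def run_chain(
    potential_fn: Callable[[np.ndarray], float],
    prior,
    kernel,
    steps: int,
    N: int = 8,
    seed: int = 0,
    workers: int = 1,
    init: np.ndarray | ChainState | None = None,
    names: list[str] | None = None,
) -> Chain:
    """Run a parallel-MH chain against a potential function.

    The initial state is drawn from the prior unless ``init`` is given. Each
    step draws N proposals from ``kernel`` (a callable ``(x, rng) -> x'``),
    evaluates their potentials (optionally across ``workers`` processes), and
    records the N resampled states; the last recorded state becomes the next
    reference state. Fixed seed gives identical chains for any worker count.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)

    if prior is not None and hasattr(prior, "logpdf"):
        # screen proposals outside the prior support before paying for a
        # forward solve; zero prior density means zero posterior density
        potential_fn = functools.partial(_screened_potential, potential_fn, prior)

    pool = None
    try:
        if workers > 1:
            pool = multiprocessing.get_context("fork").Pool(workers)

            def evaluate(props):
                return pool.map(potential_fn, props)

        else:

            def evaluate(props):
                return _evaluate_serial(potential_fn, props)

        if init is None:
            p0 = prior.sample(1, rng)[0]
            current = ChainState(p0, potential_fn(p0))
        elif isinstance(init, ChainState):
            current = init
        else:
            p0 = np.asarray(init, dtype=float)
            current = ChainState(p0, potential_fn(p0))

        dim = len(current.p)
        samples = np.empty((steps * N, dim))
        phis = np.empty(steps * N)
        step_index = np.empty(steps * N, dtype=int)
        n_new = 0
        n_failed = 0
        for k in range(steps):
            out = parallel_mh_step(current, N, kernel, evaluate, rng)
            for j, st in enumerate(out):
                samples[k * N + j] = st.p
                phis[k * N + j] = st.phi
                step_index[k * N + j] = k
            n_new += sum(1 for st in out if st is not current)
            n_failed += sum(
                1 for st in out if math.isinf(st.phi) and st.phi > 0
            )
            current = out[-1]
    finally:
        if pool is not None:
            pool.close()
            pool.join()

    describe = kernel.describe() if hasattr(kernel, "describe") else {"kind": "custom"}
    return Chain(
        samples=samples,
        phis=phis,
        step_index=step_index,
        seed=seed,
        n_proposals=N,
        names=list(names) if names else list(getattr(prior, "names", [])) or [f"p{i}" for i in range(dim)],
        accept_fraction=n_new / (steps * N),
        n_failed_forward=n_failed,
        meta={"kernel": describe, "steps": steps, "workers": workers},
    )
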