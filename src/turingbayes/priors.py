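"""Prior distributions over model parameters and growth coefficients.

Four kinds are provided, matching the inference studies this package targets:

* uniform on a rectangular box (vague knowledge of order of magnitude only),
* uniform on the Turing space intersected with a box (informed by linear
  instability theory),
* log-normal (positivity-preserving, e.g. for the diffusion ratio d and the
  reaction scaling gamma),
* Gaussian (e.g. on the three polynomial growth coefficients), including a
  calibration routine that scales the standard deviations so that 95% of
  sampled growth curves lie inside a prescribed envelope.

Each prior exposes ``sample(n, rng)`` and ``logpdf(p)``; log-densities are
normalized where cheap and ``-inf`` outside the support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kinetics

__all__ = [
    "UniformBoxPrior",
    "UniformTuringPrior",
    "LogNormalPrior",
    "GaussianPrior",
    "ProductPrior",
    "prior_sample",
    "prior_logdensity",
    "default_growth_envelope",
    "calibrate_growth_prior",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Growth-prior calibration could not reach the target in-band fraction."""


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


class UniformBoxPrior:
    """Uniform distribution on an axis-aligned box.

    ``bounds`` is a sequence of (lo, hi) pairs, one per coordinate.
    """

    kind = "uniform_box"

    def __init__(self, bounds, names=None):
        self.bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("each bound pair must satisfy hi > lo")
        self.dim = len(self.bounds)
        self.names = list(names) if names else [f"p{i}" for i in range(self.dim)]
        self._log_vol = float(np.sum(np.log(self.bounds[:, 1] - self.bounds[:, 0])))

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _as_rng(rng)
        return rng.uniform(self.bounds[:, 0], self.bounds[:, 1], size=(n, self.dim))

    def logpdf(self, p) -> float:
        p = np.asarray(p, dtype=float)
        inside = np.all((p >= self.bounds[:, 0]) & (p <= self.bounds[:, 1]))
        return -self._log_vol if inside else -math.inf

    def covariance(self) -> np.ndarray:
        widths = self.bounds[:, 1] - self.bounds[:, 0]
        return np.diag(widths**2 / 12.0)


class UniformTuringPrior:
    """Uniform distribution on the Turing space of (a, b) at fixed d, within a box."""

    kind = "uniform_turing"

    def __init__(self, d: float, box=((0.1, 10.0), (0.1, 10.0)), names=("a", "b")):
        self.d = float(d)
        self.box = tuple(tuple(map(float, pair)) for pair in box)
        self.dim = 2
        self.names = list(names)
        self._log_area: float | None = None

    def sample(self, n: int, rng) -> np.ndarray:
        return kinetics.sample_turing_space(n, self.d, self.box, _as_rng(rng))

    def logpdf(self, p) -> float:
        a, b = np.asarray(p, dtype=float)
        (a_lo, a_hi), (b_lo, b_hi) = self.box
        if not (a_lo <= a <= a_hi and b_lo <= b <= b_hi):
            return -math.inf
        _, inside = kinetics.turing_conditions(float(a), float(b), self.d)
        if not inside:
            return -math.inf
        if self._log_area is None:
            area, _ = kinetics.turing_space_area(self.d, self.box, resolution=400)
            self._log_area = math.log(area)
        return -self._log_area


class LogNormalPrior:
    """Independent log-normal components.

    Parameterized by the medians (the scale parameters exp(mu)) and a common
    or per-component standard deviation of the underlying normal in log
    space. A log-sd near 1 spreads each component over about one order of
    magnitude, and the support is the positive orthant, which keeps the
    diffusion ratio and reaction scaling strictly positive.
    """

    kind = "lognormal"

    def __init__(self, medians, sigma_log, names=None):
        self.medians = np.atleast_1d(np.asarray(medians, dtype=float))
        if np.any(self.medians <= 0):
            raise ValueError("log-normal medians must be positive")
        self.dim = len(self.medians)
        self.sigma_log = np.broadcast_to(
            np.asarray(sigma_log, dtype=float), (self.dim,)
        ).copy()
        if np.any(self.sigma_log <= 0):
            raise ValueError("sigma_log must be positive")
        self.mu = np.log(self.medians)
        self.names = list(names) if names else [f"p{i}" for i in range(self.dim)]

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _as_rng(rng)
        z = rng.standard_normal((n, self.dim))
        return np.exp(self.mu + self.sigma_log * z)

    def logpdf(self, p) -> float:
        p = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any(p <= 0):
            return -math.inf
        z = (np.log(p) - self.mu) / self.sigma_log
        return float(
            np.sum(-np.log(p) - np.log(self.sigma_log) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z)
        )


class GaussianPrior:
    """Multivariate Gaussian, possibly degenerate (zero covariance allowed)."""

    kind = "gaussian"

    def __init__(self, mean, cov, names=None):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.dim = len(self.mean)
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (self.dim, self.dim):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        self.cov = cov
        self.names = list(names) if names else [f"c{i + 1}" for i in range(self.dim)]
        eigval, eigvec = np.linalg.eigh(cov)
        if np.any(eigval < -1e-12 * max(1.0, float(np.max(np.abs(eigval))))):
            raise ValueError("covariance must be positive semi-definite")
        eigval = np.clip(eigval, 0.0, None)
        self._factor = eigvec * np.sqrt(eigval)  # cov = factor @ factor.T
        self._pos = eigval > 0
        with np.errstate(divide="ignore"):
            self._inv_eig = np.where(self._pos, 1.0 / np.where(self._pos, eigval, 1.0), 0.0)
        self._eigvec = eigvec
        self._logdet = float(np.sum(np.log(eigval[self._pos]))) if np.any(self._pos) else 0.0

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _as_rng(rng)
        z = rng.standard_normal((n, self.dim))
        return self.mean + z @ self._factor.T

    def logpdf(self, p) -> float:
        p = np.atleast_1d(np.asarray(p, dtype=float))
        y = self._eigvec.T @ (p - self.mean)
        # components in the null space must match the mean exactly
        if np.any(~self._pos) and not np.allclose(y[~self._pos], 0.0, atol=1e-12):
            return -math.inf
        k = int(np.sum(self._pos))
        quad = float(np.sum(y * y * self._inv_eig))
        return -0.5 * (quad + k * math.log(2 * math.pi) + self._logdet)


class ProductPrior:
    """Independent product of priors over consecutive coordinate blocks."""

    kind = "product"

    def __init__(self, parts):
        self.parts = list(parts)
        self.dim = sum(p.dim for p in self.parts)
        self.names = [name for p in self.parts for name in p.names]

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _as_rng(rng)
        return np.concatenate([p.sample(n, rng) for p in self.parts], axis=1)

    def logpdf(self, p) -> float:
        p = np.atleast_1d(np.asarray(p, dtype=float))
        total = 0.0
        i = 0
        for part in self.parts:
            total += part.logpdf(p[i : i + part.dim])
            i += part.dim
        return total


def prior_sample(spec, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. samples from a prior (functional facade)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return spec.sample(n, _as_rng(seed))


def prior_logdensity(spec, p) -> float:
    """Log-density of a prior at p; -inf outside the support."""
    return spec.logpdf(p)


def default_growth_envelope(T: float, rho_T: float, n_t: int = 101):
    """Default admissible band for growth curves on [0, T].

    Centered on the prior-mean curve of the polynomial family (all free
    coefficients zero, i.e. rho(t) = 1 + (rho_T - 1)(t/T)^4) with constant
    half-width equal to the net growth rho_T - 1. This band contains both
    the exponential and the saturating logistic reference profiles ending at
    rho_T.
    Returns (t_grid, lower, upper).
    """
    t = np.linspace(0.0, T, n_t)
    s = t / T
    center = 1.0 + (rho_T - 1.0) * s**4
    half = (rho_T - 1.0) * np.ones_like(t)
    return t, center - half, center + half


def calibrate_growth_prior(
    envelope,
    T: float,
    rho_T: float,
    base_sd=None,
    n: int = 10_000,
    seed: int = 0,
    target: tuple[float, float] = (0.94, 0.96),
    max_iter: int = 80,
) -> GaussianPrior:
    """Scale a zero-mean diagonal Gaussian prior on (c1, c2, c3) so that the
    fraction of sampled growth curves lying entirely inside ``envelope`` is
    within ``target`` (default [0.94, 0.96]) at ``n`` Monte Carlo samples.

    ``envelope`` is a (t_grid, lower, upper) triple; the common multiplier of
    the base standard deviations is found by bisection.
    """
    t_grid, lower, upper = (np.asarray(a, dtype=float) for a in envelope)
    if np.any(upper <= lower):
        raise CalibrationError("envelope must have positive width everywhere")
    if base_sd is None:
        base_sd = np.full(3, max(rho_T - 1.0, 0.1))
    base_sd = np.asarray(base_sd, dtype=float)
    s_grid = t_grid / T

    # design matrix mapping (c1,c2,c3) to curve values; c4 absorbs the
    # endpoint constraint rho(T) = rho_T
    B = np.stack([s_grid - s_grid**4, s_grid**2 - s_grid**4, s_grid**3 - s_grid**4], axis=1)
    mean_curve = 1.0 + (rho_T - 1.0) * s_grid**4

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3))

    def in_band_fraction(scale: float) -> float:
        curves = mean_curve + (z * (scale * base_sd)) @ B.T
        ok = np.all((curves >= lower) & (curves <= upper), axis=1)
        return float(np.mean(ok))

    lo_target, hi_target = target
    if in_band_fraction(1e-9) < hi_target:
        raise CalibrationError(
            "envelope does not contain the prior mean curve; calibration impossible"
        )
    lo, hi = 1e-9, 1.0
    while in_band_fraction(hi) > lo_target:
        hi *= 2.0
        if hi > 1e9:
            # effectively unbounded envelope: any spread stays in band
            sd = hi * base_sd
            return GaussianPrior(np.zeros(3), np.diag(sd**2), names=("c1", "c2", "c3"))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        frac = in_band_fraction(mid)
        if lo_target <= frac <= hi_target:
            sd = mid * base_sd
            return GaussianPrior(np.zeros(3), np.diag(sd**2), names=("c1", "c2", "c3"))
        if frac > hi_target:
            lo = mid
        else:
            hi = mid
    # fall out: check the bracket edges
    for scale in (0.5 * (lo + hi), lo, hi):
        if lo_target <= in_band_fraction(scale) <= hi_target:
            sd = scale * base_sd
            return GaussianPrior(np.zeros(3), np.diag(sd**2), names=("c1", "c2", "c3"))
    raise CalibrationError("bisection failed to reach the target in-band fraction")


def growth_curves(dof_samples, T: float, rho_T: float, t_grid) -> np.ndarray:
    """Evaluate the polynomial growth curve for each DOF row on t_grid."""
    dof_samples = np.atleast_2d(np.asarray(dof_samples, dtype=float))
    s = np.asarray(t_grid, dtype=float) / T
    B = np.stack([s - s**4, s**2 - s**4, s**3 - s**4], axis=1)
    return 1.0 + (rho_T - 1.0) * s**4 + dof_samples @ B.T
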