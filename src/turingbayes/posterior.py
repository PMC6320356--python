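"""Chain post-processing: burn-in, merging, highest-posterior-density
credible regions, and pointwise bands for function-valued posteriors.

HPD regions are computed from a Gaussian kernel density estimate evaluated
on a rectangular lattice: the region is the smallest superlevel set of the
estimated density holding at least the requested posterior mass. For
function-valued posteriors (growth curves) the credible band is the
pointwise quantile band over a time grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .priors import growth_curves
from .samplers import Chain

__all__ = [
    "HPDRegion",
    "GrowthBand",
    "detect_burn_in",
    "merge_chains",
    "hpd_region",
    "pairwise_hpd",
    "growth_band",
    "bands_separated",
]


@dataclass
class HPDRegion:
    """Smallest lattice superlevel set holding >= level of the estimated mass."""

    level: float
    axes: list[np.ndarray]  # lattice coordinates per dimension
    mask: np.ndarray  # boolean, shape = lattice shape
    density_threshold: float
    mass: float  # estimated mass inside the mask
    names: list[str] = field(default_factory=list)

    def bounding_box(self) -> np.ndarray:
        """(dim, 2) array of [min, max] lattice coordinates of masked cells."""
        idx = np.argwhere(self.mask)
        if len(idx) == 0:
            return np.full((len(self.axes), 2), np.nan)
        out = np.empty((len(self.axes), 2))
        for k, ax in enumerate(self.axes):
            out[k, 0] = ax[idx[:, k].min()]
            out[k, 1] = ax[idx[:, k].max()]
        return out

    def side_lengths(self) -> np.ndarray:
        box = self.bounding_box()
        return box[:, 1] - box[:, 0]

    def contains(self, point) -> bool:
        """True if the lattice cell nearest to ``point`` is in the region."""
        point = np.atleast_1d(np.asarray(point, dtype=float))
        idx = []
        for k, ax in enumerate(self.axes):
            if point[k] < ax[0] or point[k] > ax[-1]:
                return False
            idx.append(int(np.argmin(np.abs(ax - point[k]))))
        return bool(self.mask[tuple(idx)])

    def area(self) -> float:
        """Total measure (length/area) of the masked cells."""
        cell = 1.0
        for ax in self.axes:
            cell *= ax[1] - ax[0]
        return float(self.mask.sum()) * cell


@dataclass
class GrowthBand:
    """Pointwise credible band for growth curves over a time grid."""

    t: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean_curve: np.ndarray
    level: float


def _chain_samples(chain) -> np.ndarray:
    return chain.samples if isinstance(chain, Chain) else np.asarray(chain, dtype=float)


def detect_burn_in(chain, grid_fraction: float = 0.05) -> int:
    """Burn-in cut by convergence of the running mean.

    Searches cut indices B over a 5% grid of the chain length and returns the
    smallest B such that for every coordinate the mean over samples[B:] and
    the mean over the second half of samples[B:] agree within 0.1 of the
    post-cut standard deviation. Falls back to half the chain when no cut
    passes.
    """
    samples = _chain_samples(chain)
    samples = samples.reshape(len(samples), -1)
    n = len(samples)
    if n < 100:
        raise ValueError(f"chain too short for burn-in detection (n={n} < 100)")
    step = max(1, int(round(grid_fraction * n)))
    for B in range(0, n // 2 + 1, step):
        tail = samples[B:]
        half = tail[len(tail) // 2 :]
        sd = tail.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        if np.all(np.abs(tail.mean(axis=0) - half.mean(axis=0)) < 0.1 * sd):
            return B
    return n // 2


def merge_chains(chains: list) -> pd.DataFrame:
    """Concatenate post-burn-in samples of several chains.

    Returns a DataFrame with one column per parameter plus a ``chain``
    provenance column. All chains must share the same parameter names.
    """
    if not chains:
        raise ValueError("no chains to merge")
    names = None
    frames = []
    for i, chain in enumerate(chains):
        samples = _chain_samples(chain)
        cur_names = (
            list(chain.names)
            if isinstance(chain, Chain) and chain.names
            else [f"p{k}" for k in range(samples.shape[1])]
        )
        if names is None:
            names = cur_names
        elif cur_names != names:
            raise ValueError(f"parameter names mismatch: {cur_names} vs {names}")
        B = detect_burn_in(samples)
        df = pd.DataFrame(samples[B:], columns=names)
        df["chain"] = i
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def hpd_region(
    samples,
    level: float = 0.95,
    grid_resolution: int = 200,
    names: list[str] | None = None,
) -> HPDRegion:
    """Highest-posterior-density region from samples (1-D or 2-D).

    A Gaussian KDE (Scott's rule bandwidth) is evaluated on a rectangular
    lattice extending three bandwidths beyond the sample range; the density
    threshold is the largest value whose superlevel set carries at least
    ``level`` of the estimated mass.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, dim = samples.shape
    if dim > 2:
        raise ValueError("hpd_region supports 1-D or 2-D samples; use pairwise_hpd")
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = samples.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate samples: zero variance in some coordinate")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")

    kde = gaussian_kde(samples.T)
    bw = sd * n ** (-1.0 / (dim + 4))  # Scott's rule per axis
    axes = []
    for k in range(dim):
        lo = samples[:, k].min() - 3 * bw[k]
        hi = samples[:, k].max() + 3 * bw[k]
        axes.append(np.linspace(lo, hi, grid_resolution))
    if dim == 1:
        dens = kde(axes[0][None, :])
        shape = (grid_resolution,)
    else:
        X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
        dens = kde(np.vstack([X.ravel(), Y.ravel()]))
        shape = (grid_resolution, grid_resolution)
    cell = np.prod([ax[1] - ax[0] for ax in axes])
    masses = dens * cell
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(masses[order])
    total = cum[-1]
    k_needed = int(np.searchsorted(cum, level * total)) if total > 0 else len(dens) - 1
    k_needed = min(k_needed, len(dens) - 1)
    threshold = dens[order[k_needed]]
    mask = (dens >= threshold).reshape(shape)
    mass = float(masses[dens >= threshold].sum() / total)
    return HPDRegion(
        level=level,
        axes=axes,
        mask=mask,
        density_threshold=float(threshold),
        mass=mass,
        names=list(names) if names else [f"p{k}" for k in range(dim)],
    )


def pairwise_hpd(
    samples,
    level: float = 0.95,
    grid_resolution: int = 200,
    names: list[str] | None = None,
) -> dict[tuple[int, int], HPDRegion]:
    """HPD region of every 2-D coordinate projection of the samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    dim = samples.shape[1]
    names = list(names) if names else [f"p{k}" for k in range(dim)]
    if dim == 1:
        return {(0, 0): hpd_region(samples, level, grid_resolution, names)}
    out = {}
    for i, j in itertools.combinations(range(dim), 2):
        out[(i, j)] = hpd_region(
            samples[:, [i, j]], level, grid_resolution, [names[i], names[j]]
        )
    return out


def growth_band(
    dof_samples,
    T: float,
    rho_T: float,
    level: float = 0.95,
    n_t: int = 101,
) -> GrowthBand:
    """Pointwise quantile band of sampled polynomial growth curves.

    Each DOF sample is decoded to its curve on a uniform time grid; the band
    is the pointwise [(1-level)/2, (1+level)/2] quantile envelope, along with
    the curve at the posterior-mean coefficients.
    """
    dof_samples = np.atleast_2d(np.asarray(dof_samples, dtype=float))
    t = np.linspace(0.0, T, n_t)
    curves = growth_curves(dof_samples, T, rho_T, t)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    mean_curve = growth_curves(dof_samples.mean(axis=0), T, rho_T, t)[0]
    return GrowthBand(t=t, lower=lower, upper=upper, mean_curve=mean_curve, level=level)


def bands_separated(band1: GrowthBand, band2: GrowthBand, min_fraction: float = 0.05) -> bool:
    """True if the bands' vertical intervals are disjoint over a contiguous
    sub-interval covering at least ``min_fraction`` of the common time grid."""
    if len(band1.t) != len(band2.t) or not np.allclose(band1.t, band2.t):
        raise ValueError("bands must share a common time grid")
    disjoint = (band1.upper < band2.lower) | (band2.upper < band1.lower)
    needed = max(1, int(np.ceil(min_fraction * len(band1.t))))
    run = 0
    for flag in disjoint:
        run = run + 1 if flag else 0
        if run >= needed:
            return True
    return False


def curve_in_band(band: GrowthBand, curve: np.ndarray) -> bool:
    """True if a curve on the band's time grid lies inside the band pointwise."""
    curve = np.asarray(curve, dtype=float)
    return bool(np.all((curve >= band.lower) & (curve <= band.upper)))
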