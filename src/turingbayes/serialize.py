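"""Plain-text persistence for fields, observations, chains, regions and bands.

Fields are stored as delimited text (1-D: node index, u, v; 2-D: row index,
column index, u, v) with a JSON metadata sidecar (``<path>.meta.json``)
holding the grid spacing, time stamp, generating parameters and a hash of
the resolved configuration. Chains are stored as CSV with one row per
recorded sample. Every artifact can be reloaded bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observation import Observation
from .posterior import GrowthBand, HPDRegion
from .samplers import Chain
from .solver import FieldPair

__all__ = [
    "config_hash",
    "save_field",
    "load_field",
    "save_observation",
    "load_observation",
    "save_chain",
    "load_chain",
    "save_region",
    "save_band",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=float)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_meta(path: Path, meta: dict) -> None:
    payload = dict(meta)
    payload["config_hash"] = config_hash(payload)
    _sidecar(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _read_meta(path: Path) -> dict:
    sc = _sidecar(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def save_field(path, field: FieldPair, meta: dict | None = None) -> None:
    path = Path(path)
    u, v = field.u, field.v
    if u.ndim == 1:
        df = pd.DataFrame({"i": np.arange(u.size), "u": u, "v": v})
    else:
        ii, jj = np.meshgrid(np.arange(u.shape[0]), np.arange(u.shape[1]), indexing="ij")
        df = pd.DataFrame(
            {"i": ii.ravel(), "j": jj.ravel(), "u": u.ravel(), "v": v.ravel()}
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    info = {"t": field.t, "ndim": u.ndim, "shape": list(u.shape)}
    if meta:
        info.update(meta)
    _write_meta(path, info)


def load_field(path) -> tuple[FieldPair, dict]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = _read_meta(path)
    if "j" in df.columns:
        n_i = int(df["i"].max()) + 1
        n_j = int(df["j"].max()) + 1
        u = df["u"].to_numpy().reshape(n_i, n_j)
        v = df["v"].to_numpy().reshape(n_i, n_j)
    else:
        u = df["u"].to_numpy()
        v = df["v"].to_numpy()
    return FieldPair(u, v, float(meta.get("t", 0.0))), meta


def save_observation(path, obs: Observation) -> None:
    meta = dict(obs.meta)
    meta.update({"sigma_u": obs.sigma_u, "sigma_v": obs.sigma_v})
    save_field(path, obs.data, meta=meta)


def load_observation(path) -> Observation:
    data, meta = load_field(path)
    sigma_u = float(meta.pop("sigma_u"))
    sigma_v = float(meta.pop("sigma_v"))
    for key in ("config_hash", "t", "ndim", "shape"):
        meta.pop(key, None)
    return Observation(data, sigma_u, sigma_v, meta)


def save_chain(path, chain: Chain) -> None:
    path = Path(path)
    df = pd.DataFrame(chain.samples, columns=chain.names)
    df["phi"] = chain.phis
    df["step"] = chain.step_index
    df.to_csv(path, index=False, float_format="%.17g")
    _write_meta(
        path,
        {
            "seed": chain.seed,
            "n_proposals": chain.n_proposals,
            "names": chain.names,
            "accept_fraction": chain.accept_fraction,
            "n_failed_forward": chain.n_failed_forward,
            **chain.meta,
        },
    )


def load_chain(path) -> Chain:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = _read_meta(path)
    names = meta.get("names") or [c for c in df.columns if c not in ("phi", "step")]
    extra = {
        k: v
        for k, v in meta.items()
        if k
        not in (
            "seed",
            "n_proposals",
            "names",
            "accept_fraction",
            "n_failed_forward",
            "config_hash",
        )
    }
    return Chain(
        samples=df[names].to_numpy(),
        phis=df["phi"].to_numpy(),
        step_index=df["step"].to_numpy(dtype=int),
        seed=int(meta.get("seed", 0)),
        n_proposals=int(meta.get("n_proposals", 1)),
        names=list(names),
        accept_fraction=float(meta.get("accept_fraction", 0.0)),
        n_failed_forward=int(meta.get("n_failed_forward", 0)),
        meta=extra,
    )


def save_region(path, region: HPDRegion) -> None:
    """Lattice coordinates + mask as TSV (1-D: x, in_region; 2-D adds y)."""
    path = Path(path)
    if len(region.axes) == 1:
        df = pd.DataFrame({"x": region.axes[0], "in_region": region.mask.astype(int)})
    else:
        X, Y = np.meshgrid(region.axes[0], region.axes[1], indexing="ij")
        df = pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "in_region": region.mask.ravel().astype(int)}
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _write_meta(
        path,
        {
            "level": region.level,
            "names": region.names,
            "density_threshold": region.density_threshold,
            "mass": region.mass,
        },
    )


def save_band(path, band: GrowthBand) -> None:
    path = Path(path)
    pd.DataFrame(
        {"t": band.t, "lower": band.lower, "upper": band.upper, "mean": band.mean_curve}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    _write_meta(path, {"level": band.level})
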