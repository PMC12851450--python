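"""Experiment orchestration: ABC fitting pipelines, the synthetic benchmark
study, model comparison, and provenance records.

The benchmark study mirrors the method-validation design: 16 ground-truth
parameter sets (every low/high combination of the four parameters) are each
used to simulate an observed virtual histology slice, and three estimation
methods are compared by the mean absolute relative parameter error E —
rejection ABC with the Jaccard distance, with the geometric summary
distance, and with the geometric distance plus regression adjustment. The
study runs at a reduced scale (small synthetic atlas, hundreds of prior
simulations) chosen to preserve the methods' ordering rather than the
absolute error magnitudes, which depend on the atlas and simulation size.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .abm import SimulationParams, run_simulation
from .anatomy import AnatomyAtlas, default_atlas
from .inference import (
    AbcResult,
    PriorSpec,
    estimation_error,
    model_support,
    posterior_point_estimate,
    regression_adjust,
    rejection_select,
    sample_prior,
    PARAM_NAMES,
)
from .morphometrics import extract_slice, jaccard, mad_scale, summary_distance, summary_statistics

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationProtocol",
    "ExperimentConfig",
    "ground_truth_grid",
    "simulate_observation",
    "simulate_pool",
    "fit_abc",
    "compare_models",
    "run_benchmark_study",
    "provenance_record",
    "verify_provenance",
]

#: low/high values of the four parameters spanning the 2^4 benchmark grid
BENCHMARK_LEVELS = {
    "p_m": (0.2, 1.0),
    "p_p": (0.0005, 0.005),
    "w_wm": (0.1, 0.45),
    "w_bv": (0.1, 0.45),
}


@dataclass(frozen=True)
class SimulationProtocol:
    """How one simulation is run and read out for fitting: lattice steps,
    seeding geometry, carrying capacity, sensing radius, and which plane of
    the final lattice becomes the virtual histology slice."""

    T: int = 200
    init_radius: float = 6.0
    cells_per_voxel: int = 3
    K: int = 3
    d: int = 5
    slice_axis: int = 2
    slice_index: int | None = None  # None -> through the seeding center
    center: tuple | None = None  # None -> grid center

    def resolve(self, atlas: AnatomyAtlas):
        center = self.center or tuple(n // 2 for n in atlas.shape)
        index = self.slice_index if self.slice_index is not None else center[self.slice_axis]
        return center, index


@dataclass
class ExperimentConfig:
    """Configuration of a benchmark / fitting experiment."""

    atlas_shape: tuple = (64, 64, 64)
    atlas_seed: int = 0
    n_sims: int = 1000
    accept_frac: float = 0.05
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    prior: PriorSpec = field(default_factory=PriorSpec)
    seed: int = 0
    variant: str = "full"

    def __post_init__(self):
        if self.n_sims * self.accept_frac < 1:
            raise ValueError("n_sims * accept_frac must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["atlas_shape"] = list(self.atlas_shape)
        return d


def ground_truth_grid(levels: dict | None = None) -> np.ndarray:
    """All low/high combinations of the four parameters: a (16, 4) array in
    (p_m, p_p, w_wm, w_bv) order."""
    levels = levels or BENCHMARK_LEVELS
    combos = itertools.product(*(levels[name] for name in PARAM_NAMES))
    return np.array(list(combos), dtype=float)


def _params_from_theta(theta, protocol: SimulationProtocol, seed: int,
                       variant: str = "full") -> SimulationParams:
    p_m, p_p, w_wm, w_bv = (float(v) for v in theta)
    return SimulationParams(
        p_m=p_m, p_p=p_p, w_wm=w_wm, w_bv=w_bv,
        K=protocol.K, T=protocol.T, d=protocol.d, seed=int(seed), variant=variant,
    )


def simulate_observation(theta, atlas: AnatomyAtlas, protocol: SimulationProtocol,
                         seed: int, variant: str = "full"):
    """Run one simulation and return its virtual histology slice and
    summary-statistic vector."""
    center, index = protocol.resolve(atlas)
    params = _params_from_theta(theta, protocol, seed, variant)
    res = run_simulation(
        params, atlas,
        {"center": center, "radius": protocol.init_radius,
         "cells_per_voxel": protocol.cells_per_voxel},
    )
    sl = extract_slice(res.state, protocol.slice_axis, index, spacing_um=atlas.spacing_um)
    return sl, summary_statistics(sl)


def simulate_pool(thetas, atlas, protocol, seeds, variant: str = "full"):
    """Simulate one run per parameter set; returns (slices, stats (n, 8))."""
    slices, stats = [], []
    for theta, seed in zip(thetas, seeds):
        sl, s = simulate_observation(theta, atlas, protocol, int(seed), variant)
        slices.append(sl)
        stats.append(s)
    return slices, np.asarray(stats)


def _child_seeds(seed, n):
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def fit_abc(
    observed_slice,
    atlas: AnatomyAtlas,
    config: ExperimentConfig,
    method: str = "geometric",
    adjust: bool = True,
) -> AbcResult:
    """Full rejection-ABC fit of the four parameters to an observed slice.

    ``method`` selects the distance: ``"geometric"`` (MAD-standardized
    Euclidean distance between summary vectors) or ``"jaccard"`` (1 - J,
    so larger overlap means closer). Regression adjustment applies only to
    the geometric method.
    """
    rng_seed, *sim_seeds = _child_seeds(config.seed, config.n_sims + 1)
    thetas = sample_prior(config.n_sims, config.prior, config.variant,
                          rng=np.random.default_rng(rng_seed))
    slices, stats = simulate_pool(thetas, atlas, config.protocol, sim_seeds, config.variant)
    s_obs = summary_statistics(observed_slice)

    if method == "geometric":
        scale = mad_scale(stats)
        distances = np.array([summary_distance(s, s_obs, scale) for s in stats])
    elif method == "jaccard":
        scale = None
        distances = np.array([1.0 - jaccard(sl, observed_slice) for sl in slices])
    else:
        raise ValueError(f"unknown method {method!r}")

    accepted_idx, delta = rejection_select(distances, config.accept_frac)
    accepted = thetas[accepted_idx]
    acc_dist = distances[accepted_idx]
    if adjust and method == "geometric":
        adjusted = regression_adjust(accepted, stats[accepted_idx], s_obs,
                                     acc_dist, delta, config.prior)
    else:
        adjusted = accepted.copy()

    estimates = {}
    percentiles = {}
    for j, name in enumerate(PARAM_NAMES):
        rng_j = getattr(config.prior, name)
        if config.variant == "white-matter-only" and name == "w_bv":
            estimates[name] = (0.0, 0.0, 0.0)
        else:
            estimates[name] = posterior_point_estimate(adjusted[:, j], rng_j)
        percentiles[name] = tuple(np.percentile(adjusted[:, j], [10, 90]))
    return AbcResult(
        accepted=accepted,
        distances=acc_dist,
        delta=delta,
        adjusted=adjusted,
        point_estimates=estimates,
        scale=scale,
        sample_percentiles=percentiles,
    )


def compare_models(observed_slice, atlas, config: ExperimentConfig,
                   accept_frac: float | None = None) -> dict:
    """Support for the full vs white-matter-only model by pooled ABC.

    Equal-size simulation pools are drawn under each model, pooled with one
    common distance scale, and the better-supported model is the one
    over-represented among the accepted parameter sets.
    """
    s_obs = summary_statistics(observed_slice)
    all_stats, labels = [], []
    for k, variant in enumerate(("full", "white-matter-only")):
        seeds = _child_seeds(config.seed + 7919 * (k + 1), config.n_sims + 1)
        thetas = sample_prior(config.n_sims, config.prior, variant,
                              rng=np.random.default_rng(seeds[0]))
        _, stats = simulate_pool(thetas, atlas, config.protocol, seeds[1:], variant)
        all_stats.append(stats)
        labels.extend([variant] * config.n_sims)
    pooled = np.vstack(all_stats)
    scale = mad_scale(pooled)
    distances = np.array([summary_distance(s, s_obs, scale) for s in pooled])
    frac = accept_frac if accept_frac is not None else config.accept_frac / 2.0
    return model_support(distances, np.array(labels), frac)


def run_benchmark_study(config: ExperimentConfig | None = None,
                        atlas: AnatomyAtlas | None = None) -> pd.DataFrame:
    """The scaled-down 16-case synthetic recovery study.

    For each ground-truth corner: simulate an observed slice, draw a fresh
    prior pool, and estimate the parameters with the three methods. Returns
    a per-case table with columns (case, p_m, p_p, w_wm, w_bv, E_jaccard,
    E_geometric, E_geom_regression) plus the per-method means in
    ``df.attrs["mean_errors"]``.
    """
    config = config or ExperimentConfig()
    if atlas is None:
        atlas = default_atlas(config.atlas_shape, seed=config.atlas_seed)
    truths = ground_truth_grid()

    # one prior simulation pool serves every case and all three methods,
    # as one pool of prior simulations serves every tumor in a full fit
    seeds = _child_seeds(config.seed, config.n_sims + len(truths) + 1)
    thetas = sample_prior(config.n_sims, config.prior, "full",
                          rng=np.random.default_rng(int(seeds[0])))
    slices, stats = simulate_pool(thetas, atlas, config.protocol,
                                  seeds[1 : config.n_sims + 1])
    scale = mad_scale(stats)

    rows = []
    for case, theta_true in enumerate(truths):
        obs_seed = int(seeds[config.n_sims + 1 + case])
        obs_slice, s_obs = simulate_observation(theta_true, atlas, config.protocol, obs_seed)
        d_geom = np.array([summary_distance(s, s_obs, scale) for s in stats])
        d_jac = np.array([1.0 - jaccard(sl, obs_slice) for sl in slices])

        acc_j, _ = rejection_select(d_jac, config.accept_frac)
        acc_g, delta_g = rejection_select(d_geom, config.accept_frac)
        _, E_jac = estimation_error(theta_true, thetas[acc_j])
        _, E_geom = estimation_error(theta_true, thetas[acc_g])
        adjusted = regression_adjust(thetas[acc_g], stats[acc_g], s_obs,
                                     d_geom[acc_g], delta_g, config.prior)
        _, E_reg = estimation_error(theta_true, adjusted)
        rows.append(
            dict(case=case, **dict(zip(PARAM_NAMES, theta_true)),
                 E_jaccard=E_jac, E_geometric=E_geom, E_geom_regression=E_reg,
                 delta=delta_g)
        )
        logger.info("case %2d: E_jac=%.3f E_geom=%.3f E_reg=%.3f", case, E_jac, E_geom, E_reg)

    df = pd.DataFrame(rows)
    df.attrs["mean_errors"] = {
        "jaccard": float(df["E_jaccard"].mean()),
        "geometric": float(df["E_geometric"].mean()),
        "geom_regression": float(df["E_geom_regression"].mean()),
    }
    return df


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_config(config: dict) -> str:
    return _hash_bytes(json.dumps(config, sort_keys=True, default=str).encode())


def _hash_atlas(atlas: AnatomyAtlas) -> str:
    h = hashlib.sha256()
    for mask in (atlas.brain_mask, atlas.wm_mask, atlas.bv_mask):
        h.update(np.packbits(mask).tobytes())
    h.update(np.float64(atlas.spacing_um).tobytes())
    return h.hexdigest()


def provenance_record(config: dict, seeds, atlas: AnatomyAtlas | None = None,
                      outputs: dict | None = None) -> dict:
    """JSON-serializable sidecar pinning a run: seeds, config hash, package
    version, atlas hash, and hashes of any output arrays. Re-running with
    the same config and seeds must reproduce the output hashes."""
    record = {
        "package": "gliomalatt",
        "version": __version__,
        "seeds": [int(s) for s in np.atleast_1d(seeds)],
        "config": config,
        "config_hash": _hash_config(config),
    }
    if atlas is not None:
        record["atlas_hash"] = _hash_atlas(atlas)
    if outputs:
        record["output_hashes"] = {
            name: _hash_bytes(np.ascontiguousarray(arr).tobytes())
            for name, arr in outputs.items()
        }
    return record


def verify_provenance(record: dict, config: dict | None = None,
                      atlas: AnatomyAtlas | None = None) -> bool:
    """Check a sidecar against the current config/atlas; raises on tamper."""
    if _hash_config(record["config"]) != record["config_hash"]:
        raise ValueError("provenance mismatch: config hash does not match record")
    if config is not None and _hash_config(config) != record["config_hash"]:
        raise ValueError("provenance mismatch: supplied config differs from record")
    if atlas is not None and record.get("atlas_hash") not in (None, _hash_atlas(atlas)):
        raise ValueError("provenance mismatch: atlas differs from record")
    return True
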