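"""In-silico drug-combination experiments.

A hypothetical drug mix blocks, for each cell at each time step, either its
migration (with probability ``q_mig``, the anti-migration fraction of the
mix) or — otherwise — its proliferation. A tumor grows untreated for
``pre_days``, is treated for ``treat_days``, and is compared to an
untreated control grown for the full horizon; the readouts are the treated
tumor's total cell count and convex-hull volume relative to the control.
The mix is swept from 100%/0% (pure anti-migration) to 0%/100% (pure
anti-proliferation) in steps of 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .abm import LatticeState, SimulationParams, SimulationResult, _run, initialize_tumor
from .anatomy import AnatomyAtlas

__all__ = [
    "TreatmentSchedule",
    "treated_step",
    "run_growth_with_treatment",
    "convex_hull_volume",
    "run_treatment_sweep",
]

#: 1800 steps correspond to a 90-day horizon
STEPS_PER_DAY = 20


@dataclass(frozen=True)
class TreatmentSchedule:
    """30 days of unhindered growth, 60 days of treatment, against a 90-day
    untreated control (defaults; all in days at 20 steps/day)."""

    pre_days: float = 30.0
    treat_days: float = 60.0
    control_days: float = 90.0
    steps_per_day: int = STEPS_PER_DAY
    mix_grid: tuple = tuple(np.round(np.arange(1.0, -0.01, -0.1), 1))

    def __post_init__(self):
        if abs(self.pre_days + self.treat_days - self.control_days) > 1e-9:
            raise ValueError("pre_days + treat_days must equal control_days")
        if any(not 0.0 <= q <= 1.0 for q in self.mix_grid):
            raise ValueError("mix fractions must lie in [0, 1]")

    @property
    def pre_steps(self) -> int:
        return int(round(self.pre_days * self.steps_per_day))

    @property
    def treat_steps(self) -> int:
        return int(round(self.treat_days * self.steps_per_day))

    @property
    def control_steps(self) -> int:
        return int(round(self.control_days * self.steps_per_day))


def treated_step(state: LatticeState, params: SimulationParams, q_mig: float,
                 atlas: AnatomyAtlas, rng) -> LatticeState:
    """One time step under treatment: each acting cell independently has its
    migration suppressed with probability ``q_mig`` and its proliferation
    suppressed otherwise; all other dynamics follow the untreated model."""
    if not 0.0 <= q_mig <= 1.0:
        raise ValueError("q_mig must lie in [0, 1]")
    seed = int(rng.integers(0, 2**31))
    return _run(state, params, atlas, T=1, seed=seed, treat=True, q_mig=q_mig).state


def run_growth_with_treatment(
    params: SimulationParams,
    atlas: AnatomyAtlas,
    schedule: TreatmentSchedule,
    q_mig: float | None,
    init_spec: dict | None = None,
):
    """Grow untreated for the pre-phase, then treated (or untreated when
    ``q_mig`` is None) for the treatment phase, continuing one RNG stream.

    Returns ``(state_at_treatment_start, final_state)``. The whole horizon
    runs as one seeded stream with the drug switching on at the treatment
    step, so with ``q_mig=None`` (no drug at all) the run is bit-identical
    to a control simulation over the full horizon with the same seed.
    """
    spec = dict(init_spec or {})
    center = spec.get("center", tuple(n // 2 for n in atlas.shape))
    state0 = initialize_tumor(
        atlas, center,
        radius_voxels=spec.get("radius", 8),
        cells_per_voxel=spec.get("cells_per_voxel", 3),
        K=params.K,
    )
    res = _run(
        state0, params, atlas, T=schedule.control_steps, seed=params.seed,
        treat=q_mig is not None, q_mig=float(q_mig or 0.0),
        treat_from=schedule.pre_steps, record_steps=[schedule.pre_steps],
    )
    pre_state = LatticeState(counts=res.snapshots[0], t=schedule.pre_steps)
    return pre_state, res.state


def convex_hull_volume(occupied) -> float:
    """Volume (voxel^3) of the convex hull of occupied voxel centers.

    ``occupied`` is either an (n, 3) array of voxel coordinates or a count
    lattice (voxels with at least one cell are occupied). Degenerate sets —
    fewer than four points, or coplanar/colinear points — enclose no volume
    and report 0. An empty tumor is an error.
    """
    pts = np.asarray(getattr(occupied, "counts", occupied))
    if pts.ndim == 3:
        pts = np.argwhere(pts > 0)
    pts = np.asarray(pts, dtype=float)
    if pts.size == 0:
        raise ValueError("empty tumor has no convex hull")
    if pts.shape[0] < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0


def _ratio(treated: float, control: float) -> float:
    if control > 0:
        return treated / control
    return 1.0 if treated == control else float("inf")


def run_treatment_sweep(
    params: SimulationParams,
    atlas: AnatomyAtlas,
    schedule: TreatmentSchedule | None = None,
    seeds=(0, 1, 2, 3, 4),
    init_spec: dict | None = None,
) -> pd.DataFrame:
    """Sweep the anti-migration/anti-proliferation mix over the schedule grid.

    For every mix fraction and seed the treated tumor (pre-phase untreated,
    treatment phase treated) is compared to an untreated control grown to
    the full horizon with its own seed stream. Returns a tidy table with
    columns (mix, seed, cells_treated, cells_control, hull_treated,
    hull_control, rel_cells, rel_hull).
    """
    schedule = schedule or TreatmentSchedule()
    rows = []
    for seed in seeds:
        control_params = replace(params, seed=int(seed) + 2**20)
        spec = dict(init_spec or {})
        center = spec.get("center", tuple(n // 2 for n in atlas.shape))
        control0 = initialize_tumor(
            atlas, center,
            radius_voxels=spec.get("radius", 8),
            cells_per_voxel=spec.get("cells_per_voxel", 3),
            K=params.K,
        )
        control = _run(control0, control_params, atlas,
                       T=schedule.control_steps, seed=control_params.seed).state
        cells_c = control.n_cells
        hull_c = convex_hull_volume(control.counts)
        for q in schedule.mix_grid:
            run_params = replace(params, seed=int(seed))
            _, treated = run_growth_with_treatment(
                run_params, atlas, schedule, q_mig=float(q), init_spec=init_spec
            )
            cells_t = treated.n_cells
            hull_t = convex_hull_volume(treated.counts)
            rows.append(
                dict(
                    mix=float(q),
                    seed=int(seed),
                    cells_treated=cells_t,
                    cells_control=cells_c,
                    hull_treated=hull_t,
                    hull_control=hull_c,
                    rel_cells=_ratio(cells_t, cells_c),
                    rel_hull=_ratio(hull_t, hull_c),
                )
            )
    return pd.DataFrame(rows)
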