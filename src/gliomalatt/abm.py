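"""Stochastic lattice agent-based model of glioma growth.

Cells live on a 3D lattice with carrying capacity ``K`` per voxel. At each
discrete time step every cell alive at the start of the step is processed
once, in uniformly random order: it first proliferates with probability
``p_p`` (offspring placed in the same voxel, ineligible to act until the
next step, and only if the voxel holds fewer than ``K`` cells), then
attempts to move with probability ``p_m`` to one of its six von Neumann
neighbors. The move direction is drawn from a mixture of an isotropic term
and two anatomy-attraction terms::

    P = (1/6) (1 - w_wm - w_bv) 1  +  w_wm P_wm  +  w_bv P_bv

where ``P_wm`` (and analogously ``P_bv``) is built by summing, over every
white-matter voxel within Euclidean sensing distance ``d`` of the cell, the
unit vector toward that voxel folded onto the six lattice axes, and
L1-normalizing. Moves into full voxels or off the brain mask are aborted.

The per-cell loop is compiled with numba; the attraction fields depend only
on voxel position, so they are precomputed once per atlas by FFT
correlation (:func:`direction_field`) and looked up during the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import signal

from .anatomy import AnatomyAtlas

__all__ = [
    "SimulationParams",
    "LatticeState",
    "SimulationResult",
    "initialize_tumor",
    "unit_direction",
    "direction_to_axis_weights",
    "structure_attraction",
    "mixed_migration_distribution",
    "direction_field",
    "step",
    "run_simulation",
    "DIRECTIONS",
]

#: the six von Neumann offsets, in slot order (+x, -x, +y, -y, +z, -z)
DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

UNIFORM6 = np.full(6, 1.0 / 6.0)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulation run.

    p_m, p_p : per-step migration and proliferation probabilities.
    w_wm, w_bv : attraction strengths toward white matter and vessels,
        with ``w_wm + w_bv <= 1`` (the remainder is isotropic motion).
    K : voxel carrying capacity (cells per voxel).
    T : number of time steps.
    d : sensing radius in voxels.
    variant : ``"full"`` or ``"white-matter-only"`` (forces ``w_bv = 0``).
    """

    p_m: float
    p_p: float
    w_wm: float = 0.0
    w_bv: float = 0.0
    K: int = 3
    T: int = 1800
    d: int = 5
    seed: int = 0
    variant: str = "full"

    def __post_init__(self):
        if not 0.0 <= self.p_m <= 1.0 or not 0.0 <= self.p_p <= 1.0:
            raise ValueError("p_m and p_p must lie in [0, 1]")
        if self.variant not in ("full", "white-matter-only"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "white-matter-only" and self.w_bv != 0.0:
            object.__setattr__(self, "w_bv", 0.0)
        if self.w_wm < 0 or self.w_bv < 0 or self.w_wm + self.w_bv > 1.0 + 1e-12:
            raise ValueError("need w_wm, w_bv >= 0 and w_wm + w_bv <= 1")
        if self.K < 1 or self.T < 0 or self.d < 1:
            raise ValueError("need K >= 1, T >= 0, d >= 1")
        if not 0 <= int(self.seed) < 2**32:
            raise ValueError("seed must lie in [0, 2^32)")


@dataclass
class LatticeState:
    """Per-voxel cell counts at one instant.

    ``newborn_counts`` marks cells born within the current step (ineligible
    to act); it is all-zero between steps because newborn flags are cleared
    when a step completes.
    """

    counts: np.ndarray
    newborn_counts: np.ndarray = None
    t: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int32)
        if self.newborn_counts is None:
            self.newborn_counts = np.zeros_like(self.counts)
        else:
            self.newborn_counts = np.asarray(self.newborn_counts, dtype=np.int32)

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())


@dataclass
class SimulationResult:
    state: LatticeState
    n_trajectory: np.ndarray  # N_t for t = 0..T
    snapshots: np.ndarray | None = None  # (n_snap, *shape) when recorded
    snapshot_steps: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Direction machinery (reference implementations)
# ---------------------------------------------------------------------------


def unit_direction(cell_voxel, target_voxel) -> np.ndarray:
    """Unit vector pointing from the cell's voxel toward a target voxel."""
    v = np.asarray(target_voxel, dtype=float) - np.asarray(cell_voxel, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("cell and target voxel coincide; direction undefined")
    return v / norm


def direction_to_axis_weights(v) -> np.ndarray:
    """Fold a unit direction vector onto the six lattice axes.

    Slot order (+x, -x, +y, -y, +z, -z); the positive slot of an axis gets
    ``max(component, 0)`` and the negative slot the magnitude
    ``|min(component, 0)|``, so at most three slots are nonzero and opposing
    slots are never both nonzero.
    """
    v = np.asarray(v, dtype=float)
    u = np.empty(6)
    u[0::2] = np.maximum(v, 0.0)
    u[1::2] = -np.minimum(v, 0.0)
    return u


def structure_attraction(state_pos, mask, d) -> np.ndarray:
    """Attraction distribution from one structure mask at one voxel.

    Sums the axis-folded unit vectors toward every mask voxel within
    Euclidean distance ``d`` (excluding the cell's own voxel) and
    L1-normalizes. With no structure in range the distribution falls back
    to uniform (1/6 per direction), i.e. the term behaves isotropically.
    """
    mask = np.asarray(mask, dtype=bool)
    pos = np.asarray(state_pos, dtype=int)
    d = int(d)
    lo = np.maximum(pos - d, 0)
    hi = np.minimum(pos + d + 1, mask.shape)
    window = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    offsets = np.argwhere(window) + lo - pos
    if offsets.size:
        norms = np.linalg.norm(offsets, axis=1)
        keep = (norms > 0) & (norms <= d)
        offsets, norms = offsets[keep], norms[keep]
    if offsets.size == 0:
        return UNIFORM6.copy()
    v = offsets / norms[:, None]
    u = np.zeros(6)
    u[0::2] = np.maximum(v, 0.0).sum(axis=0)
    u[1::2] = (-np.minimum(v, 0.0)).sum(axis=0)
    total = u.sum()
    if total <= 0.0:
        return UNIFORM6.copy()
    return u / total


def mixed_migration_distribution(P_wm, P_bv, w_wm, w_bv) -> np.ndarray:
    """Mix the isotropic, white-matter and vessel terms into one distribution."""
    if w_wm < 0 or w_bv < 0 or w_wm + w_bv > 1.0 + 1e-12:
        raise ValueError("need w_wm, w_bv >= 0 and w_wm + w_bv <= 1")
    P_wm = np.asarray(P_wm, dtype=float)
    P_bv = np.asarray(P_bv, dtype=float)
    out = (1.0 - w_wm - w_bv) / 6.0 + w_wm * P_wm + w_bv * P_bv
    return out


def direction_field(mask, d) -> np.ndarray:
    """Precompute :func:`structure_attraction` for every voxel at once.

    The attraction at voxel x is a sum over fixed offsets o (0 < |o| <= d)
    of axis-folded unit vectors weighted by ``mask[x + o]`` — a
    cross-correlation of the mask with six fixed kernels, evaluated here by
    FFT. Voxels sensing no structure get the uniform fallback. Returns a
    C-contiguous float32 array of shape ``(*mask.shape, 6)`` whose rows sum
    to 1.
    """
    mask = np.asarray(mask, dtype=np.float64)
    d = int(d)
    rng = np.arange(-d, d + 1, dtype=float)
    OX, OY, OZ = np.meshgrid(rng, rng, rng, indexing="ij")
    norm = np.sqrt(OX**2 + OY**2 + OZ**2)
    valid = (norm > 0) & (norm <= d)
    safe = np.where(valid, norm, 1.0)
    comps = [OX / safe, OY / safe, OZ / safe]
    slots = np.empty((6,) + OX.shape)
    for axis in range(3):
        slots[2 * axis] = np.where(valid, np.maximum(comps[axis], 0.0), 0.0)
        slots[2 * axis + 1] = np.where(valid, -np.minimum(comps[axis], 0.0), 0.0)

    out = np.empty(mask.shape + (6,), dtype=np.float64)
    if mask.any():
        for k in range(6):
            out[..., k] = signal.correlate(mask, slots[k], mode="same", method="fft")
        np.clip(out, 0.0, None, out=out)
        total = out.sum(axis=-1)
        empty = total < 1e-6  # true sums are >= 1 per sensed voxel; this is FFT noise
        total[empty] = 1.0
        out /= total[..., None]
        out[empty] = 1.0 / 6.0
    else:
        out[:] = 1.0 / 6.0
    return np.ascontiguousarray(out, dtype=np.float32)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize_tumor(
    atlas: AnatomyAtlas,
    center_voxel,
    radius_voxels: float = 8,
    cells_per_voxel: int = 3,
    K: int = 3,
) -> LatticeState:
    """Seed a spherical bolus of cells around the injection site.

    Every lattice site within Euclidean distance ``radius_voxels``
    (inclusive) of the center receives ``cells_per_voxel`` cells; with the
    defaults (radius 8, 3 cells/voxel) this is 2109 voxels and 6327 cells.
    """
    center = np.asarray(center_voxel, dtype=int)
    shape = atlas.shape
    if cells_per_voxel > K:
        raise ValueError("cells_per_voxel exceeds carrying capacity")
    if not atlas.brain_mask[tuple(center)]:
        raise ValueError("injection center lies outside the brain mask")
    r = int(np.floor(radius_voxels))
    if np.any(center - r < 0) or np.any(center + r >= shape):
        raise ValueError("seeding sphere exceeds the lattice bounds")
    g = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    sphere = (X**2 + Y**2 + Z**2) <= radius_voxels**2
    sites = np.argwhere(sphere) + center - r
    off_brain = ~atlas.brain_mask[sites[:, 0], sites[:, 1], sites[:, 2]]
    if off_brain.any():
        raise ValueError(
            f"{int(off_brain.sum())} seeding-sphere voxels lie outside the brain mask"
        )
    counts = np.zeros(shape, dtype=np.int32)
    counts[sites[:, 0], sites[:, 1], sites[:, 2]] = cells_per_voxel
    return LatticeState(counts=counts)


# ---------------------------------------------------------------------------
# Compiled per-cell dynamics
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    coords,
    n0,
    counts,
    brain,
    Pwm,
    Pbv,
    w_wm,
    w_bv,
    p_m,
    p_p,
    K,
    T,
    seed,
    treat,
    treat_from,
    q_mig,
    perm,
    n_traj,
    snapshots,
    snap_steps,
):
    """Run T steps in place. Returns the final cell count, or -1 if the
    coordinate buffer overflowed (caller retries with a larger buffer)."""
    if seed >= 0:
        np.random.seed(seed)
    nx, ny, nz = counts.shape
    cap = coords.shape[0]
    base = (1.0 - w_wm - w_bv) / 6.0
    n = n0
    snap_i = 0
    if snapshots.shape[0] > 0 and snap_steps[snap_i] == 0:
        snapshots[snap_i] = counts
        snap_i += 1
    n_traj[0] = n
    for t in range(T):
        N_t = n
        treating = treat and t >= treat_from
        # Fisher-Yates permutation of the cells alive at step start
        for i in range(N_t):
            perm[i] = i
        for i in range(N_t - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = perm[i]
            perm[i] = perm[j]
            perm[j] = tmp
        for i in range(N_t):
            c = perm[i]
            x = coords[c, 0]
            y = coords[c, 1]
            z = coords[c, 2]
            mig_ok = True
            pro_ok = True
            if treating:
                # drug action: each step the cell's migration is suppressed
                # with probability q_mig, otherwise its proliferation is
                if np.random.random() < q_mig:
                    mig_ok = False
                else:
                    pro_ok = False
            u = np.random.random()
            if pro_ok and counts[x, y, z] < K and u < p_p:
                if n >= cap:
                    return -1
                coords[n, 0] = x
                coords[n, 1] = y
                coords[n, 2] = z
                counts[x, y, z] += 1
                n += 1
            u = np.random.random()
            if mig_ok and u < p_m:
                r = np.random.random()
                acc = 0.0
                k = 5
                for kk in range(6):
                    acc += base + w_wm * Pwm[x, y, z, kk] + w_bv * Pbv[x, y, z, kk]
                    if r < acc:
                        k = kk
                        break
                if k == 0:
                    tx, ty, tz = x + 1, y, z
                elif k == 1:
                    tx, ty, tz = x - 1, y, z
                elif k == 2:
                    tx, ty, tz = x, y + 1, z
                elif k == 3:
                    tx, ty, tz = x, y - 1, z
                elif k == 4:
                    tx, ty, tz = x, y, z + 1
                else:
                    tx, ty, tz = x, y, z - 1
                if (
                    0 <= tx < nx
                    and 0 <= ty < ny
                    and 0 <= tz < nz
                    and brain[tx, ty, tz]
                    and counts[tx, ty, tz] < K
                ):
                    counts[x, y, z] -= 1
                    counts[tx, ty, tz] += 1
                    coords[c, 0] = tx
                    coords[c, 1] = ty
                    coords[c, 2] = tz
        n_traj[t + 1] = n
        if snap_i < snapshots.shape[0] and snap_steps[snap_i] == t + 1:
            snapshots[snap_i] = counts
            snap_i += 1
    return n


def _coords_from_counts(counts, cap):
    sites = np.argwhere(counts > 0)
    reps = counts[sites[:, 0], sites[:, 1], sites[:, 2]]
    coords = np.zeros((cap, 3), dtype=np.int32)
    flat = np.repeat(sites, reps, axis=0).astype(np.int32)
    coords[: flat.shape[0]] = flat
    return coords, flat.shape[0]


def _capacity_guess(n0, params):
    growth = min((1.0 + params.p_p) ** params.T * 4.0, 2.0**62)
    return int(min(growth * max(n0, 1), 2.0**31)) + 64


def _run(state, params, atlas, T, seed, treat=False, q_mig=0.0, treat_from=0,
         record_steps=None):
    """Shared driver: prepares buffers, retries on coordinate overflow."""
    Pwm, Pbv = atlas.migration_fields(params.d)
    counts0 = state.counts
    brain = np.ascontiguousarray(atlas.brain_mask, dtype=np.uint8)
    cap_limit = int(params.K) * int(atlas.brain_mask.sum())
    n0 = int(counts0.sum())
    cap = min(_capacity_guess(n0, replace(params, T=T)), max(cap_limit, n0) + 64)
    if record_steps is None:
        snap_steps = np.empty(0, dtype=np.int64)
    else:
        snap_steps = np.asarray(sorted(set(int(s) for s in record_steps)), dtype=np.int64)
    while True:
        coords, n0_ = _coords_from_counts(counts0, cap)
        counts = counts0.copy()
        n_traj = np.zeros(T + 1, dtype=np.int64)
        snapshots = np.zeros((len(snap_steps),) + counts.shape, dtype=np.int32)
        perm = np.empty(cap, dtype=np.int64)
        n = _run_kernel(
            coords,
            n0_,
            counts,
            brain,
            Pwm,
            Pbv,
            float(params.w_wm),
            float(params.w_bv),
            float(params.p_m),
            float(params.p_p),
            int(params.K),
            int(T),
            int(seed),
            treat,
            int(treat_from),
            float(q_mig),
            perm,
            n_traj,
            snapshots,
            snap_steps,
        )
        if n >= 0:
            break
        cap = min(cap * 4, max(cap_limit, cap + 1) + 64)
    new_state = LatticeState(counts=counts, t=state.t + T)
    return SimulationResult(
        state=new_state,
        n_trajectory=n_traj,
        snapshots=snapshots if record_steps is not None else None,
        snapshot_steps=snap_steps if record_steps is not None else None,
    )


def step(state: LatticeState, params: SimulationParams, atlas: AnatomyAtlas, rng) -> LatticeState:
    """Advance the lattice by one time step (seed drawn from ``rng``)."""
    seed = int(rng.integers(0, 2**31))
    return _run(state, params, atlas, T=1, seed=seed).state


def run_simulation(
    params: SimulationParams,
    atlas: AnatomyAtlas,
    init_spec: dict | LatticeState | None = None,
    record_steps=None,
) -> SimulationResult:
    """Run ``params.T`` steps from a spherical seed (or a given state).

    ``init_spec`` is either an existing :class:`LatticeState`, or a dict with
    keys ``center`` (default: grid center), ``radius`` (default 8) and
    ``cells_per_voxel`` (default 3). Bit-reproducible for a fixed
    ``params.seed``. ``record_steps`` optionally lists step indices at which
    to snapshot the full count lattice.
    """
    if isinstance(init_spec, LatticeState):
        state = init_spec
    else:
        spec = dict(init_spec or {})
        center = spec.get("center", tuple(n // 2 for n in atlas.shape))
        state = initialize_tumor(
            atlas,
            center,
            radius_voxels=spec.get("radius", 8),
            cells_per_voxel=spec.get("cells_per_voxel", 3),
            K=params.K,
        )
    return _run(state, params, atlas, T=params.T, seed=params.seed, record_steps=record_steps)
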