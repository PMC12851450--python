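"""Anatomical scaffolds for lattice tumor simulation.

The simulator reads three co-registered 3D binary masks of the mouse brain:
the brain outline, the white-matter tracts, and the blood vasculature. Real
scaffolds come from diffusion-tensor imaging (white matter is obtained by
thresholding the fractional-anisotropy map) and from tissue-clearing
microscopy of the vasculature. This module represents such volumes, reads
and writes them as NIfTI or compressed arrays, and synthesizes stand-in
anatomy (slab/arc-like tracts, branching tubular vessel trees) for testing
and benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "AnatomyAtlas",
    "threshold_fa",
    "generate_synthetic_atlas",
    "default_atlas",
    "load_volume",
    "save_volume",
    "save_mask",
    "load_mask",
    "save_atlas",
    "load_atlas",
]

#: default voxel edge length, micrometres (resolution of the DTI scaffold)
DEFAULT_SPACING_UM = 43.0


@dataclass
class ScalarVolume:
    """A 3D scalar image with isotropic or anisotropic voxel spacing in um."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("volume must be a 3D array with all dimensions >= 1")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume contains non-finite values")
        s = np.asarray(self.spacing_um, dtype=float)
        if s.ndim == 0:
            s = np.repeat(s, 3)
        if s.shape != (3,) or np.any(s <= 0):
            raise ValueError("spacing_um must be a positive scalar or 3-vector")
        self.spacing_um = tuple(float(x) for x in s)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class AnatomyAtlas:
    """Three co-registered binary masks: brain outline, white matter, vessels.

    Invariants enforced on construction: identical shapes, white matter and
    vessels are subsets of the brain, and the brain is nonempty.
    """

    brain_mask: np.ndarray
    wm_mask: np.ndarray
    bv_mask: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM
    _field_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        self.bv_mask = np.asarray(self.bv_mask, dtype=bool)
        if not (
            self.brain_mask.shape == self.wm_mask.shape == self.bv_mask.shape
        ):
            raise ValueError("atlas masks must share one shape")
        if self.brain_mask.ndim != 3:
            raise ValueError("atlas masks must be 3D")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")
        if np.any(self.wm_mask & ~self.brain_mask):
            raise ValueError("white-matter mask extends outside the brain mask")
        if np.any(self.bv_mask & ~self.brain_mask):
            raise ValueError("vessel mask extends outside the brain mask")
        self.spacing_um = float(self.spacing_um)
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    def migration_fields(self, d: int):
        """Per-voxel 6-direction attraction fields, cached per sensing radius.

        Returns ``(P_wm, P_bv)`` as float32 arrays of shape ``(*shape, 6)``;
        see :func:`gliomalatt.abm.direction_field`.
        """
        if d not in self._field_cache:
            from .abm import direction_field

            self._field_cache[d] = (
                direction_field(self.wm_mask, d),
                direction_field(self.bv_mask, d),
            )
        return self._field_cache[d]


def threshold_fa(vol: ScalarVolume, threshold: float) -> np.ndarray:
    """Binarize a fractional-anisotropy volume at ``threshold`` (inclusive >=).

    FA quantifies how directionally constrained water diffusion is in a
    voxel (0 = free, 1 = a single direction); voxels at or above the
    threshold are taken to be white matter.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("FA threshold must lie in [0, 1]")
    values = np.asarray(vol.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("FA volume contains non-finite values")
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("FA values must lie in [0, 1]")
    return values >= threshold


# ---------------------------------------------------------------------------
# Synthetic anatomy
# ---------------------------------------------------------------------------


def _grid_coords(shape):
    ax = [np.arange(n, dtype=float) for n in shape]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid_mask(shape, margin: float = 1.0) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid (a convex 'brain')."""
    X, Y, Z = _grid_coords(shape)
    c = [(n - 1) / 2.0 for n in shape]
    a = [max(n / 2.0 - margin, 0.5) for n in shape]
    return (
        ((X - c[0]) / a[0]) ** 2
        + ((Y - c[1]) / a[1]) ** 2
        + ((Z - c[2]) / a[2]) ** 2
    ) <= 1.0


def _slab_mask(shape, axis: int, start: int, thickness: int) -> np.ndarray:
    if thickness < 1:
        raise ValueError("slab thickness must be >= 1")
    n = shape[axis]
    lo, hi = start, start + thickness
    if lo < 0 or hi > n:
        logger.warning("slab [%d, %d) clipped to grid axis %d (size %d)", lo, hi, axis, n)
    lo, hi = max(lo, 0), min(hi, n)
    mask = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, hi)
    mask[tuple(sl)] = True
    return mask


def _shell_mask(shape, center, radius: float, thickness: float, bounds=None) -> np.ndarray:
    """Spherical shell |r - radius| <= thickness/2, optionally boxed to an arc."""
    X, Y, Z = _grid_coords(shape)
    r = np.sqrt(
        (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    )
    mask = np.abs(r - radius) <= thickness / 2.0
    if bounds is not None:
        for axis, (lo, hi) in enumerate(bounds):
            idx = [X, Y, Z][axis]
            mask &= (idx >= lo) & (idx <= hi)
    if center[0] - radius < 0 or center[0] + radius >= shape[0]:
        logger.warning("shell extends beyond grid; clipped")
    return mask


def _capsule_mask(shape, p0, p1, radius: float) -> np.ndarray:
    """Voxels whose centers lie within ``radius`` of the segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.floor(np.minimum(p0, p1) - radius).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        logger.warning("tube [%s -> %s, r=%.2f] clipped to grid", p0, p1, radius)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ax = [np.arange(lo[k], hi[k], dtype=float) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    seg = p1 - p0
    L2 = float(seg @ seg)
    if L2 == 0.0:
        dist = np.linalg.norm(P - p0, axis=-1)
    else:
        t = np.clip((P - p0) @ seg / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * seg
        dist = np.linalg.norm(P - proj, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist <= radius
    return mask


def _vessel_tree(shape, spec, rng) -> np.ndarray:
    """Recursive branching tube network (arterial-tree-like stand-in).

    Each segment spawns two children rotated away from its axis; radii and
    lengths shrink geometrically so the tree terminates at capillary-scale
    tubes.
    """
    mask = np.zeros(shape, dtype=bool)
    root = np.asarray(spec["root"], dtype=float)
    direction = np.asarray(spec.get("direction", (0.0, 0.0, 1.0)), dtype=float)
    direction = direction / np.linalg.norm(direction)
    length = float(spec.get("length", min(shape) / 3.0))
    radius = float(spec.get("radius", 2.0))
    levels = int(spec.get("levels", 4))
    angle = np.deg2rad(float(spec.get("branch_angle_deg", 35.0)))
    r_decay = float(spec.get("radius_decay", 0.7))
    l_decay = float(spec.get("length_decay", 0.8))
    min_radius = float(spec.get("min_radius", 0.6))

    stack = [(root, direction, length, radius, levels)]
    while stack:
        p0, u, L, r, lev = stack.pop()
        p1 = p0 + u * L
        mask |= _capsule_mask(shape, p0, p1, r)
        if lev <= 0 or r * r_decay < min_radius:
            continue
        for _ in range(2):
            # random unit vector perpendicular to u
            w = rng.standard_normal(3)
            w -= (w @ u) * u
            n = np.linalg.norm(w)
            if n < 1e-12:
                w = np.array([1.0, 0.0, 0.0])
                n = 1.0
            w /= n
            child = np.cos(angle) * u + np.sin(angle) * w
            stack.append((p1, child, L * l_decay, r * r_decay, lev - 1))
    return mask


def generate_synthetic_atlas(
    shape=(120, 120, 120),
    spacing_um: float = DEFAULT_SPACING_UM,
    tract_specs=(),
    vessel_specs=(),
    seed: int = 0,
    brain: str | np.ndarray = "ellipsoid",
) -> AnatomyAtlas:
    """Build a synthetic :class:`AnatomyAtlas` from geometric primitives.

    Parameters
    ----------
    tract_specs
        White-matter primitives, dicts with ``kind`` in {"slab", "shell"}:
        ``{"kind": "slab", "axis": 2, "start": 40, "thickness": 4}`` or
        ``{"kind": "shell", "center": (..), "radius": R, "thickness": t,
        "bounds": [(lo, hi), ...] or None}``.
    vessel_specs
        Vessel primitives, ``{"kind": "tube", "p0": .., "p1": .., "radius": r}``
        or ``{"kind": "tree", "root": .., "direction": .., "length": ..,
        "radius": .., "levels": ..}``.
    brain
        ``"ellipsoid"`` (inscribed in the grid), ``"full"`` (whole grid), or an
        explicit boolean mask.

    The result is deterministic for a fixed ``seed`` (only vessel trees draw
    random numbers). Primitives extending beyond the grid are clipped with a
    logged warning.
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 1:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)

    if isinstance(brain, str):
        if brain == "ellipsoid":
            brain_mask = _ellipsoid_mask(shape)
        elif brain == "full":
            brain_mask = np.ones(shape, dtype=bool)
        else:
            raise ValueError(f"unknown brain spec {brain!r}")
    else:
        brain_mask = np.asarray(brain, dtype=bool)
        if brain_mask.shape != shape:
            raise ValueError("explicit brain mask shape mismatch")

    wm = np.zeros(shape, dtype=bool)
    for spec in tract_specs:
        kind = spec.get("kind", "slab")
        if kind == "slab":
            wm |= _slab_mask(shape, int(spec["axis"]), int(spec["start"]), int(spec["thickness"]))
        elif kind == "shell":
            wm |= _shell_mask(
                shape,
                spec["center"],
                float(spec["radius"]),
                float(spec["thickness"]),
                spec.get("bounds"),
            )
        else:
            raise ValueError(f"unknown tract kind {kind!r}")

    bv = np.zeros(shape, dtype=bool)
    for spec in vessel_specs:
        kind = spec.get("kind", "tube")
        if kind == "tube":
            bv |= _capsule_mask(shape, spec["p0"], spec["p1"], float(spec["radius"]))
        elif kind == "tree":
            bv |= _vessel_tree(shape, spec, rng)
        else:
            raise ValueError(f"unknown vessel kind {kind!r}")

    return AnatomyAtlas(
        brain_mask=brain_mask,
        wm_mask=wm & brain_mask,
        bv_mask=bv & brain_mask,
        spacing_um=spacing_um,
    )


def default_atlas(shape=(64, 64, 64), spacing_um=DEFAULT_SPACING_UM, seed: int = 0) -> AnatomyAtlas:
    """A small default brain phantom: one arc-like tract (corpus-callosum
    stand-in), one straight slab, and two branching vessel trees reaching
    toward the center, inside an ellipsoidal brain."""
    sx, sy, sz = (int(n) for n in shape)
    c = [(n - 1) / 2.0 for n in (sx, sy, sz)]
    tracts = [
        {"kind": "slab", "axis": 2, "start": int(0.62 * sz), "thickness": max(2, sz // 20)},
        {
            "kind": "shell",
            "center": (c[0], c[1], 0.15 * sz),
            "radius": 0.45 * sz,
            "thickness": max(2.0, sz / 18),
            "bounds": [(0, sx - 1), (0.2 * sy, 0.8 * sy), (0.3 * sz, sz - 1)],
        },
    ]
    vessels = [
        {
            "kind": "tree",
            "root": (0.2 * sx, 0.2 * sy, 0.2 * sz),
            "direction": (0.5, 0.5, 0.7),
            "length": 0.3 * min(shape),
            "radius": max(1.5, sx / 40),
            "levels": 4,
        },
        {
            "kind": "tree",
            "root": (0.85 * sx, 0.5 * sy, 0.3 * sz),
            "direction": (-0.7, 0.1, 0.7),
            "length": 0.28 * min(shape),
            "radius": max(1.2, sx / 48),
            "levels": 4,
        },
    ]
    return generate_synthetic_atlas(shape, spacing_um, tracts, vessels, seed=seed)


# ---------------------------------------------------------------------------
# I/O: NIfTI and compressed-array dialects
# ---------------------------------------------------------------------------


def save_volume(vol: ScalarVolume, path) -> None:
    """Write a scalar volume to ``.nii``/``.nii.gz`` (spacing in the header
    zooms, micron units) or to a ``.npz`` with ``values`` and ``spacing_um``."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, values=vol.values, spacing_um=np.asarray(vol.spacing_um))
        return
    affine = np.diag([*vol.spacing_um, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_zooms(vol.spacing_um)
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(path))


def load_volume(path) -> ScalarVolume:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return ScalarVolume(values=data["values"], spacing_um=tuple(data["spacing_um"]))
    img = nib.load(str(path))
    values = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return ScalarVolume(values=values, spacing_um=tuple(float(z) for z in zooms))


def save_mask(mask: np.ndarray, path, spacing_um=DEFAULT_SPACING_UM) -> None:
    s = np.broadcast_to(np.asarray(spacing_um, dtype=float), (3,))
    save_volume(ScalarVolume(np.asarray(mask, dtype=np.uint8), tuple(s)), path)


def load_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    vol = load_volume(path)
    return np.asarray(vol.values) > 0, vol.spacing_um


_ATLAS_FILES = {"brain": "brain_mask", "wm": "wm_mask", "bv": "bv_mask"}


def save_atlas(atlas: AnatomyAtlas, directory, fmt: str = ".nii.gz") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, stem in _ATLAS_FILES.items():
        mask = getattr(atlas, f"{key}_mask")
        save_mask(mask, directory / f"{stem}{fmt}", spacing_um=atlas.spacing_um)


def load_atlas(directory) -> AnatomyAtlas:
    """Load an atlas directory; members must agree in shape and spacing."""
    directory = Path(directory)
    masks, spacings = {}, {}
    for key, stem in _ATLAS_FILES.items():
        candidates = sorted(directory.glob(f"{stem}.*"))
        if not candidates:
            raise FileNotFoundError(f"missing {stem} in {directory}")
        masks[key], spacings[key] = load_mask(candidates[0])
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"atlas member shapes differ: {shapes}")
    if len({s for s in spacings.values()}) > 1:
        raise ValueError(f"atlas member spacings differ: {spacings}")
    return AnatomyAtlas(
        brain_mask=masks["brain"],
        wm_mask=masks["wm"],
        bv_mask=masks["bv"],
        spacing_um=spacings["brain"][0],
    )
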