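"""Synthetic head phantoms and cohorts for the posterior circulation.

The phantom is stylized anatomy: the nine posterior-circulation structures are
voxelized ellipsoids at plausible posterior-fossa positions — a midline
brainstem stack (medulla, pons, midbrain), paired cerebellar hemispheres,
paired occipital lobes and paired thalami, mirror-symmetric across the
midsagittal plane — inside an ellipsoidal brain.  No anatomical fidelity is
claimed; the downstream volumetrics, scale and evaluation math only need nine
disjoint labeled regions with left/right symmetry.

Ischemic lesions are grown voxel-by-voxel by seeded region growing inside a
target structure until a requested volume fraction is reached, giving
connected, irregular shapes.  A cohort generator draws per-visit lesion
burdens and an outcome from a stated logistic link between the ten burden
features and poor prognosis, so model-recovery experiments have a known truth.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from . import scale as _scale
from .volumetry import (
    LABELS,
    STRUCTURES,
    FeatureVector,
    LabelVolume,
    LesionMask,
    lesion_features,
)


class AtlasConfigError(ValueError):
    """Raised when a grid cannot host the stylized anatomy."""


# Canonical geometry in fractions of the grid's physical extent per axis
# (slice/inferior->superior, row/anterior->posterior, col/right->left... the
# mirror plane is the col-extent midline).  (center_z, center_y, center_x),
# (semi_z, semi_y, semi_x).  Right-sided structures are the col-mirror of the
# left ones.
_CANONICAL: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "left_cerebellum": ((0.22, 0.68, 0.34), (0.13, 0.14, 0.13)),
    "left_occipital": ((0.55, 0.72, 0.36), (0.10, 0.10, 0.11)),
    "left_thalamus": ((0.55, 0.42, 0.43), (0.050, 0.045, 0.045)),
    "medulla": ((0.15, 0.45, 0.50), (0.060, 0.040, 0.035)),
    "pons": ((0.28, 0.45, 0.50), (0.070, 0.055, 0.060)),
    "midbrain": ((0.42, 0.45, 0.50), (0.055, 0.050, 0.050)),
}
_BRAIN = ((0.50, 0.50, 0.50), (0.49, 0.47, 0.47))

DEFAULT_GRID = (40, 256, 256)
DEFAULT_SPACING = (5.0, 0.5, 0.5)


def _primitives() -> dict[str, tuple[tuple[float, ...], tuple[float, ...]]]:
    prims = {}
    for name in STRUCTURES:
        if name.startswith("right_"):
            (cz, cy, cx), semi = _CANONICAL[name.replace("right_", "left_")]
            prims[name] = ((cz, cy, 1.0 - cx), semi)
        else:
            prims[name] = _CANONICAL[name]
    return prims


@dataclass
class StructureAtlas:
    """Voxelized stylized anatomy of the nine structures.

    ``labels`` holds the voxel grid (0 = non-structure, 1-9 = canonical
    structure order); ``primitives`` maps each structure name to its ellipsoid
    (center_mm, semi_axes_mm).  ``brain_mask`` marks intracranial voxels.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    labels: np.ndarray
    brain_mask: np.ndarray
    primitives: dict[str, tuple[np.ndarray, np.ndarray]]
    structure_names: tuple[str, ...] = STRUCTURES

    def label_volume(self) -> LabelVolume:
        return LabelVolume(self.labels, self.spacing, brain_mask=self.brain_mask)

    def structure_mask(self, name: str) -> np.ndarray:
        if name == "other":
            return self.brain_mask & (self.labels == 0)
        if name not in LABELS:
            raise KeyError(f"unknown structure {name!r}")
        return self.labels == LABELS[name]


def _ellipsoid_mask(coords, center_mm, semi_mm) -> np.ndarray:
    zz, yy, xx = coords
    d = (
        ((zz - center_mm[0]) / semi_mm[0]) ** 2
        + ((yy - center_mm[1]) / semi_mm[1]) ** 2
        + ((xx - center_mm[2]) / semi_mm[2]) ** 2
    )
    return d <= 1.0


def build_atlas(
    grid_shape=DEFAULT_GRID,
    spacing=DEFAULT_SPACING,
) -> StructureAtlas:
    """Voxelize the stylized anatomy onto a grid.

    Voxel centers sit at ``(i + 0.5) * spacing``; left/right pairs mirror
    exactly across the midsagittal (col) plane, so on any grid their voxel
    counts are equal.  Raises :class:`AtlasConfigError` naming the first
    structure that gets no voxels or collides with an earlier one.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    if len(grid_shape) != 3 or any(g < 1 for g in grid_shape):
        raise AtlasConfigError(f"invalid grid shape {grid_shape}")
    if any(s <= 0 for s in spacing):
        raise AtlasConfigError(f"spacing must be positive, got {spacing}")

    extent = np.array([g * s for g, s in zip(grid_shape, spacing)])
    axes = [
        (np.arange(g) + 0.5) * s for g, s in zip(grid_shape, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)

    labels = np.zeros(grid_shape, dtype=np.int64)
    prims_mm: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (cfrac, sfrac) in _primitives().items():
        center_mm = np.asarray(cfrac) * extent
        semi_mm = np.asarray(sfrac) * extent
        mask = _ellipsoid_mask(coords, center_mm, semi_mm)
        if not mask.any():
            raise AtlasConfigError(
                f"grid {grid_shape} at spacing {spacing} too small: "
                f"structure {name!r} has no voxels"
            )
        clash = labels[mask]
        if (clash != 0).any():
            other = STRUCTURES[int(clash[clash != 0][0]) - 1]
            raise AtlasConfigError(f"structure {name!r} overlaps {other!r} on this grid")
        labels[mask] = LABELS[name]
        prims_mm[name] = (center_mm, semi_mm)

    brain = _ellipsoid_mask(coords, np.asarray(_BRAIN[0]) * extent, np.asarray(_BRAIN[1]) * extent)
    brain |= labels > 0
    return StructureAtlas(grid_shape, spacing, labels, brain, prims_mm)


# ---------------------------------------------------------------------------
# lesion placement
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_region(region: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Randomized 6-connected region growing to exactly ``n_target`` voxels."""
    out = np.zeros(region.shape, dtype=bool)
    if n_target == 0:
        return out
    idx = np.argwhere(region)
    start = idx[rng.integers(len(idx))]
    shape = region.shape
    visited = np.zeros(region.shape, dtype=bool)
    heap = [(0.0, tuple(start))]
    visited[tuple(start)] = True
    grown = 0
    while heap and grown < n_target:
        _, vox = heapq.heappop(heap)
        out[vox] = True
        grown += 1
        for off in _NEIGHBOR_OFFSETS:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and not visited[nb]
                and region[nb]
            ):
                visited[nb] = True
                heapq.heappush(heap, (float(rng.random()), nb))
    if grown < n_target:
        raise ValueError(
            f"requested {n_target} voxels but only {grown} reachable from the seed "
            f"(region disconnected); achieved maximum fraction "
            f"{grown / region.sum():.4f}"
        )
    return out


def place_lesion(atlas: StructureAtlas, lesion_spec, seed=None) -> LesionMask:
    """Grow an ischemic lesion with requested per-structure volume fractions.

    ``lesion_spec`` maps a structure name (or ``"other"`` for brain tissue
    outside the nine structures) to a target fraction of that region's volume
    in [0, 1].  Each target is grown independently by seeded 6-connected
    region growing from a random interior point, so the achieved fraction
    matches the request to within one voxel.  Deterministic under a fixed
    seed; targets are processed in canonical structure order regardless of
    the ordering of ``lesion_spec``.
    """
    if isinstance(lesion_spec, dict):
        spec = dict(lesion_spec)
    else:
        spec = {name: frac for name, frac in lesion_spec}
    valid = set(STRUCTURES) | {"other"}
    unknown = set(spec) - valid
    if unknown:
        raise ValueError(f"unknown lesion targets: {sorted(unknown)}")
    for name, frac in spec.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"lesion fraction for {name!r} must be in [0, 1], got {frac}")

    rng = np.random.default_rng(seed)
    mask = np.zeros(atlas.grid_shape, dtype=bool)
    for name in list(STRUCTURES) + ["other"]:
        if name not in spec:
            continue
        region = atlas.structure_mask(name)
        n_region = int(region.sum())
        n_target = int(round(spec[name] * n_region))
        mask |= _grow_region(region, n_target, rng)
    return LesionMask(mask, atlas.spacing)


# ---------------------------------------------------------------------------
# CT rendering
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Grid geometry, tissue intensities (HU) and noise for one phantom."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    hu_background: float = -1000.0  # outside the cranium
    hu_parenchyma: float = 35.0  # brain tissue outside the nine structures
    hu_structures: dict[str, float] = field(
        default_factory=lambda: {
            "left_cerebellum": 38.0,
            "right_cerebellum": 38.0,
            "left_occipital": 36.0,
            "right_occipital": 36.0,
            "left_thalamus": 33.0,
            "right_thalamus": 33.0,
            "medulla": 31.0,
            "midbrain": 31.0,
            "pons": 31.0,
        }
    )
    hu_lesion_offset: float = -20.0  # lesion relative to parenchyma (hypodense)
    noise_sd: float = 2.0
    lesion_spec: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        for name, frac in dict(self.lesion_spec).items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"lesion fraction for {name!r} must be in [0, 1]")


def render_ct(
    atlas: StructureAtlas,
    lesion: LesionMask | None = None,
    config: PhantomConfig | None = None,
) -> np.ndarray:
    """Noncontrast-CT-like intensity volume for a phantom.

    Each voxel gets its tissue-class mean (background / parenchyma /
    per-structure HU), lesion voxels are set hypodense relative to
    parenchyma, then Gaussian noise of the configured SD is added.
    Deterministic under the config seed.
    """
    config = config or PhantomConfig(grid_shape=atlas.grid_shape, spacing=atlas.spacing)
    vol = np.full(atlas.grid_shape, config.hu_background, dtype=np.float64)
    vol[atlas.brain_mask] = config.hu_parenchyma
    for name, hu in config.hu_structures.items():
        vol[atlas.labels == LABELS[name]] = hu
    if lesion is not None:
        if lesion.data.shape != atlas.grid_shape:
            raise ValueError(
                f"lesion shape {lesion.data.shape} != atlas grid {atlas.grid_shape}"
            )
        vol[lesion.data] = config.hu_parenchyma + config.hu_lesion_offset
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        vol += rng.normal(0.0, config.noise_sd, size=vol.shape)
    return vol


def make_phantom(config: PhantomConfig | None = None):
    """Convenience: atlas + lesion + CT volume from one config."""
    config = config or PhantomConfig()
    atlas = build_atlas(config.grid_shape, config.spacing)
    lesion = place_lesion(atlas, config.lesion_spec, seed=config.seed)
    image = render_ct(atlas, lesion, config)
    return atlas, lesion, image


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: generative outcome weights: brainstem burden weighted heaviest, mirroring
#: the clinical gravity of midbrain/pons involvement
DEFAULT_BETA = np.array([1.0, 1.0, 0.8, 0.8, 1.2, 1.2, 2.0, 5.0, 3.0, 1.0])
DEFAULT_BETA0 = -1.6


@dataclass
class CohortConfig:
    """Generative model for a synthetic cohort of visits.

    Per visit, each of the ten regions is independently involved with
    probability ``involvement_prob``; an involved region's lesion fraction is
    drawn Beta(frac_alpha, frac_beta).  Poor prognosis is Bernoulli with
    Pr(poor) = logistic(beta0 + beta·x); the mRS is then drawn uniformly from
    the matching range (0-2 good, 3-6 poor).  Visits are partitioned into
    ``k`` subsets whose sizes differ by at most one.

    With ``include_masks`` the lesion is actually grown on a phantom grid and
    the features recomputed from the voxel masks (slower; meant for small n);
    otherwise the sampled fractions are used directly.
    """

    n: int = 36
    k: int = 5
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    beta0: float = DEFAULT_BETA0
    involvement_prob: float = 0.35
    frac_alpha: float = 1.2
    frac_beta: float = 3.0
    include_masks: bool = False
    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing: tuple[float, float, float] = (5.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (10,):
            raise ValueError("beta must have length 10")
        if self.n < self.k:
            raise ValueError(f"n={self.n} visits cannot fill k={self.k} subsets")
        if not 0.0 < self.involvement_prob < 1.0:
            raise ValueError("involvement_prob must be in (0, 1)")
        if self.frac_alpha <= 0 or self.frac_beta <= 0:
            raise ValueError("Beta distribution parameters must be positive")


def sample_features(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one visit's true lesion-burden feature vector."""
    involved = rng.random(10) < config.involvement_prob
    fracs = rng.beta(config.frac_alpha, config.frac_beta, size=10)
    return np.where(involved, fracs, 0.0)


def simulate_cohort(config: CohortConfig):
    """Generate a cohort of :class:`~pcscale.scale.PatientRecord` visits.

    Deterministic under the config seed.  Returns records carrying the true
    feature vector, mRS, prognosis, subset id and pc-ASPECTS (computed from
    masks when ``include_masks``, else from the feature vector with
    any-overlap involvement).
    """
    rng = np.random.default_rng(config.seed)
    subsets = _scale.assign_subsets(config.n, config.k, seed=rng.integers(2**31))

    atlas = None
    if config.include_masks:
        atlas = build_atlas(config.grid_shape, config.spacing)
        labels = atlas.label_volume()

    records = []
    for i in range(config.n):
        x = sample_features(config, rng)
        lesion = None
        if config.include_masks:
            spec = {name: float(x[j]) for j, name in enumerate(STRUCTURES) if x[j] > 0}
            if x[9] > 0:
                spec["other"] = float(x[9])
            lesion = place_lesion(atlas, spec, seed=rng.integers(2**31))
            x = lesion_features(labels, lesion).values
            pca = _scale.pc_aspects(labels, lesion)
        else:
            pca = _scale.pc_aspects_from_features(x)
        p_poor = 1.0 / (1.0 + np.exp(-(config.beta0 + config.beta @ x)))
        poor = rng.random() < p_poor
        mrs = int(rng.integers(3, 7)) if poor else int(rng.integers(0, 3))
        records.append(
            _scale.PatientRecord(
                visit_id=i + 1,
                features=FeatureVector(x),
                mrs=mrs,
                subset=int(subsets[i]),
                pc_aspects=pca,
                label_volume=labels if config.include_masks else None,
                lesion_mask=lesion,
            )
        )
    return records


def synthetic_slices(n: int = 10, size: int = 96, seed: int = 0, lesion_spec=None):
    """Axial CT slices with per-pixel structure labels for segmenter training.

    Builds a phantom on a (20, size, size) grid, renders the CT volume, and
    returns the ``n`` slices richest in structure voxels as
    (images (n, size, size), labels (n, size, size), z (n,)) where z is each
    slice's normalized through-plane position.
    """
    atlas = build_atlas((20, size, size), (5.0, 1.0, 1.0))
    cfg = PhantomConfig(grid_shape=atlas.grid_shape, spacing=atlas.spacing, seed=seed)
    lesion = place_lesion(atlas, lesion_spec or {}, seed=seed)
    image = render_ct(atlas, lesion, cfg)
    richness = (atlas.labels > 0).sum(axis=(1, 2))
    keep = np.sort(np.argsort(richness)[::-1][:n])
    z = (keep + 0.5) / atlas.grid_shape[0]
    return image[keep], atlas.labels[keep], z


def generative_auc(records, config: CohortConfig) -> float:
    """AUC of the true linear predictor beta0 + beta·x against the drawn
    outcomes — the ceiling an estimated score can approach on this cohort."""
    from .evalstats import auc

    X = np.vstack([r.features.values for r in records])
    y = np.array([1 if r.prognosis == "poor" else 0 for r in records])
    eta = config.beta0 + X @ config.beta
    return auc(eta, y)
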