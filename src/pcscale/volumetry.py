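"""Structure volumetrics and the 10-parameter lesion-burden feature vector.

A labeled noncontrast-CT volume assigns each voxel one of nine posterior
circulation structures (labels 1-9) or non-structure tissue (label 0).  Given
a paired binary ischemic-lesion mask, the lesion burden of a visit is summarized
by ten dimensionless proportions: for each structure, the fraction of its
volume that is lesioned, and a tenth parameter for lesion burden in brain
tissue outside the nine structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical structure enumeration; list index + 1 is the voxel label.
STRUCTURES: tuple[str, ...] = (
    "left_cerebellum",
    "right_cerebellum",
    "left_occipital",
    "right_occipital",
    "left_thalamus",
    "right_thalamus",
    "medulla",
    "midbrain",
    "pons",
)

FEATURE_NAMES: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 11))

#: label value for each structure name
LABELS: dict[str, int] = {name: i + 1 for i, name in enumerate(STRUCTURES)}


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class LabelVolume:
    """3D integer atlas of the nine structures.

    Parameters
    ----------
    data : (S, R, C) integer array with values in {0, ..., 9}.
    spacing : voxel size in mm per axis (slice, row, col).
    brain_mask : optional boolean array marking intracranial voxels; used as
        the denominator region for the "other regions" lesion proportion.
        When absent the whole grid is treated as brain.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > 9:
            raise ValueError(f"labels must lie in 0..9, found range [{lo}, {hi}]")
        self.spacing = _check_spacing(self.spacing)
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape:
                raise ValueError("brain mask shape differs from label volume shape")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def brain(self) -> np.ndarray:
        """Brain region used for the f10 denominator (whole grid if no mask)."""
        if self.brain_mask is not None:
            return self.brain_mask
        return np.ones(self.data.shape, dtype=bool)


@dataclass
class LesionMask:
    """Binary ischemic-lesion mask aligned to a :class:`LabelVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"lesion mask must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)


def _check_pair(labels: LabelVolume, lesion: LesionMask) -> None:
    if lesion.data.shape != labels.data.shape:
        raise ValueError(
            f"lesion shape {lesion.data.shape} != label volume shape {labels.data.shape}"
        )
    if not np.allclose(lesion.spacing, labels.spacing):
        raise ValueError(f"lesion spacing {lesion.spacing} != label spacing {labels.spacing}")


@dataclass
class FeatureVector:
    """The ten lesion-proportion parameters of one visit.

    ``values[i]`` for i in 0..8 is vol(lesion ∩ structure_i) / vol(structure_i)
    in the canonical structure order; ``values[9]`` is the lesion proportion of
    brain tissue outside the nine structures.  All entries are dimensionless
    fractions in [0, 1].
    """

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (10,):
            raise ValueError(f"feature vector must have exactly 10 components, got {self.values.shape}")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("features must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __len__(self) -> int:
        return 10

    def __getitem__(self, i):
        return self.values[i]


def structure_volumes(labels: LabelVolume) -> pd.Series:
    """Volume of each of the nine structures in mL.

    A structure with no voxels is reported as 0.0 mL with a warning.
    """
    counts = np.bincount(labels.data.ravel(), minlength=10)
    vols = counts[1:10] * labels.voxel_volume_mm3 / 1000.0
    absent = [STRUCTURES[i] for i in range(9) if counts[i + 1] == 0]
    if absent:
        warnings.warn(f"structures absent from label volume (0 mL): {', '.join(absent)}")
    return pd.Series(vols, index=list(STRUCTURES), name="volume_ml")


def lesion_volume(labels: LabelVolume, lesion: LesionMask) -> float:
    """Total lesion volume in mL."""
    _check_pair(labels, lesion)
    return float(lesion.data.sum()) * labels.voxel_volume_mm3 / 1000.0


def lesion_features(
    labels: LabelVolume,
    lesion: LesionMask,
    other_denominator: str = "region",
) -> FeatureVector:
    """Compute the 10-parameter lesion-proportion feature vector.

    Parameters
    ----------
    other_denominator : {"region", "lesion"}
        How the tenth parameter is normalized.  ``"region"`` (default) divides
        the lesion volume outside the nine structures by the volume of brain
        tissue outside the structures, so all ten features share the
        "fraction of region lesioned" semantics.  ``"lesion"`` divides by the
        total lesion volume instead (fraction of the lesion falling outside
        the structures).

    Structures with zero volume contribute a 0 feature with a warning; the
    result is independent of voxel spacing.
    """
    _check_pair(labels, lesion)
    if other_denominator not in ("region", "lesion"):
        raise ValueError(f"unknown other_denominator {other_denominator!r}")

    lab = labels.data
    les = lesion.data
    feats = np.zeros(10)
    struct_counts = np.bincount(lab.ravel(), minlength=10)[1:10]
    overlap_counts = np.bincount(lab[les].ravel(), minlength=10)
    for i in range(9):
        if struct_counts[i] == 0:
            warnings.warn(f"structure {STRUCTURES[i]} has zero volume; feature set to 0")
            feats[i] = 0.0
        else:
            feats[i] = overlap_counts[i + 1] / struct_counts[i]

    other_region = labels.brain() & (lab == 0)
    lesion_other = int((les & other_region).sum())
    if other_denominator == "region":
        denom = int(other_region.sum())
        if denom == 0:
            warnings.warn("no brain tissue outside the nine structures; f10 set to 0")
            feats[9] = 0.0
        else:
            feats[9] = lesion_other / denom
    else:
        total = int(les.sum())
        feats[9] = 0.0 if total == 0 else lesion_other / total
    return FeatureVector(feats)


def masks_from_slices(
    label_slices,
    spacing,
    lesion_slices=None,
) -> tuple[LabelVolume, LesionMask]:
    """Stack per-slice 2D annotations into aligned 3D volumes.

    ``label_slices`` (and ``lesion_slices`` if given) are sequences of equal
    shaped 2D arrays in slice order; an inconsistent shape raises an error
    naming the slice index.
    """
    label_slices = [np.asarray(s) for s in label_slices]
    if not label_slices:
        raise ValueError("no slices given")
    shape0 = label_slices[0].shape
    for i, s in enumerate(label_slices):
        if s.shape != shape0:
            raise ValueError(f"label slice {i} has shape {s.shape}, expected {shape0}")
    labels = LabelVolume(np.stack(label_slices).astype(np.int64), spacing)

    if lesion_slices is None:
        lesion = LesionMask(np.zeros(labels.data.shape, dtype=bool), spacing)
    else:
        lesion_slices = [np.asarray(s) for s in lesion_slices]
        if len(lesion_slices) != len(label_slices):
            raise ValueError(
                f"{len(lesion_slices)} lesion slices vs {len(label_slices)} label slices"
            )
        for i, s in enumerate(lesion_slices):
            if s.shape != shape0:
                raise ValueError(f"lesion slice {i} has shape {s.shape}, expected {shape0}")
        lesion = LesionMask(np.stack(lesion_slices) > 0, spacing)
    return labels, lesion


def features_frame(records) -> pd.DataFrame:
    """Tabulate feature vectors as a visit_id, f1..f10 DataFrame."""
    rows = []
    for rec in records:
        fv = rec.features if isinstance(rec.features, FeatureVector) else FeatureVector(rec.features)
        rows.append({"visit_id": rec.visit_id, **dict(zip(FEATURE_NAMES, fv.values))})
    return pd.DataFrame(rows)
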