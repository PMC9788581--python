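"""Eight threshold-defined volumes of interest (VOIs) per patient.

All masks are strict-inequality thresholds and boolean intersections; there
is no morphological cleanup, so mask volumes follow directly from the voxel
predicates:

* ``Skeleton``          : CT HU > 150
* ``Skeleton600``       : CT HU > 600 (sclerotic / dense bone)
* ``PSMA_PET_3``        : PSMA SUV > 3.0, inside Skeleton
* ``NaF_PET_10``        : NaF SUV > 10, inside Skeleton
* ``NaF10_PSMA3``       : pathological on both tracers
* ``Scl_PSMA3``         : PSMA-pathological sclerotic bone
* ``Scl_NaF10``         : NaF-pathological sclerotic bone
* ``Scl_NaF10_PSMA3``   : pathological on both tracers within sclerosis
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .volumes import ImageVolume, StudyPair

VOI_NAMES = (
    "Skeleton",
    "Skeleton600",
    "PSMA_PET_3",
    "NaF_PET_10",
    "NaF10_PSMA3",
    "Scl_PSMA3",
    "Scl_NaF10",
    "Scl_NaF10_PSMA3",
)

#: VOIs defined on each PET tracer (pathological masks)
PSMA_VOIS = ("PSMA_PET_3", "Scl_PSMA3")
NAF_VOIS = ("NaF_PET_10", "Scl_NaF10")


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold set defining the eight VOIs.

    Defaults are the clinical operating points: skeleton HU > 150, sclerosis
    HU > 600, pathological PSMA SUV > 3.0, pathological NaF SUV > 10.
    """

    hu_skeleton: float = 150.0
    hu_sclerosis: float = 600.0
    suv_psma: float = 3.0
    suv_naf: float = 10.0

    def __post_init__(self) -> None:
        if not self.hu_sclerosis > self.hu_skeleton:
            raise ValueError("hu_sclerosis must exceed hu_skeleton")
        if not (self.suv_psma > 0 and self.suv_naf > 0):
            raise ValueError("SUV thresholds must be positive")

    def to_dict(self) -> dict:
        return {
            "hu_skeleton": self.hu_skeleton,
            "hu_sclerosis": self.hu_sclerosis,
            "suv_psma": self.suv_psma,
            "suv_naf": self.suv_naf,
        }


def threshold_mask(vol: ImageVolume, threshold: float) -> np.ndarray:
    """Binary mask of voxels strictly above ``threshold`` (in the volume's units).

    NaN voxels are rejected: upstream must sanitise, a NaN compared against a
    threshold would silently drop voxels.
    """
    values = vol.values
    if np.isnan(values).any():
        raise ValueError("volume contains NaN voxels; sanitise before thresholding")
    return values > threshold


@dataclass(frozen=True)
class VOISet:
    """The eight binary masks of one patient on a shared grid."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    config: SegmentationConfig

    def __post_init__(self) -> None:
        missing = set(VOI_NAMES) - set(self.masks)
        if missing:
            raise ValueError(f"VOISet missing masks: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def voxel_counts(self) -> dict[str, int]:
        return {name: int(self.masks[name].sum()) for name in VOI_NAMES}

    def write(self, out_dir: str | os.PathLike, prefix: str = "") -> None:
        """Write masks as uint8 NIfTI plus a JSON sidecar with the config."""
        from .volumes import Modality, ValueKind, write_volume

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in VOI_NAMES:
            vol = ImageVolume(
                self.masks[name].astype(np.uint8),
                self.spacing,
                self.origin,
                Modality.CT,
                ValueKind.HU,
            )
            write_volume(vol, out / f"{prefix}{name}.nii.gz")
        sidecar = {"config": self.config.to_dict(), "voxel_counts": self.voxel_counts()}
        (out / f"{prefix}voiset.json").write_text(json.dumps(sidecar, indent=2))


def build_voiset(study: StudyPair, config: SegmentationConfig | None = None) -> VOISet:
    """Build the eight VOIs from a coregistered study.

    PET-pathological masks are restricted to the skeleton (SUV > threshold
    AND HU > 150): pathological volumes are reported *in the skeleton*.
    """
    config = config or SegmentationConfig()
    study.validate_grid()

    skeleton = threshold_mask(study.ct, config.hu_skeleton)
    sclerosis = threshold_mask(study.ct, config.hu_sclerosis)
    psma_path = threshold_mask(study.psma, config.suv_psma) & skeleton
    naf_path = threshold_mask(study.naf, config.suv_naf) & skeleton

    masks = {
        "Skeleton": skeleton,
        "Skeleton600": sclerosis,
        "PSMA_PET_3": psma_path,
        "NaF_PET_10": naf_path,
        "NaF10_PSMA3": psma_path & naf_path,
        "Scl_PSMA3": psma_path & sclerosis,
        "Scl_NaF10": naf_path & sclerosis,
        "Scl_NaF10_PSMA3": psma_path & naf_path & sclerosis,
    }
    return VOISet(masks, study.ct.spacing, study.ct.origin, config)


class VOISegmenter(BaseEstimator):
    """Transformer building a :class:`VOISet` from a coregistered StudyPair.

    Stateless (thresholds are hyperparameters, nothing is learned); ``fit``
    exists for pipeline compatibility.
    """

    def __init__(
        self,
        hu_skeleton: float = 150.0,
        hu_sclerosis: float = 600.0,
        suv_psma: float = 3.0,
        suv_naf: float = 10.0,
    ) -> None:
        self.hu_skeleton = hu_skeleton
        self.hu_sclerosis = hu_sclerosis
        self.suv_psma = suv_psma
        self.suv_naf = suv_naf

    @property
    def config(self) -> SegmentationConfig:
        return SegmentationConfig(self.hu_skeleton, self.hu_sclerosis, self.suv_psma, self.suv_naf)

    def fit(self, X=None, y=None) -> "VOISegmenter":
        return self

    def transform(self, study: StudyPair) -> VOISet:
        return build_voiset(study, self.config)

    def fit_transform(self, study: StudyPair, y=None) -> VOISet:
        return self.fit().transform(study)
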