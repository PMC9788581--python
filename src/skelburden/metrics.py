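"""Per-patient VOI metrics: volumes, mean SUV, TEA/TBA burden scores, percentages.

TEA (total enzyme activity, PSMA) and TBA (total bone demineralisation
activity, NaF) are TLG-analogues: VOI volume in litres times the mean SUV_bw
over the VOI, hence identical to the per-voxel sum of SUV x voxel volume (L).
An empty VOI has undefined mean SUV (NaN marker) and a burden score of 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import NAF_VOIS, PSMA_VOIS, VOI_NAMES, VOISet
from .volumes import ImageVolume, StudyPair


def mask_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in mL: voxel count x spacing product / 1000."""
    sx, sy, sz = spacing
    if not (sx > 0 and sy > 0 and sz > 0):
        raise ValueError("spacing must be strictly positive")
    return float(np.count_nonzero(mask)) * (sx * sy * sz) / 1000.0


def mean_suv(pet: ImageVolume, mask: np.ndarray) -> float:
    """Arithmetic mean SUV over the mask; NaN marker when the mask is empty."""
    if pet.shape != mask.shape:
        raise ValueError(f"grid mismatch: PET {pet.shape} vs mask {mask.shape}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    return float(pet.values[mask].mean())


def burden_score(pet: ImageVolume, mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """TLG-analogue burden score in L.SUV: volume (L) x mean SUV; 0 for empty VOI."""
    volume_l = mask_volume(mask, spacing) / 1000.0
    mean = mean_suv(pet, mask)
    if math.isnan(mean):
        return 0.0
    return volume_l * mean


def percentage_volume(numerator_ml: float, denominator_ml: float) -> float:
    """100 x numerator/denominator; NaN with a warning for a zero denominator."""
    if denominator_ml <= 0:
        warnings.warn(
            f"percentage_volume: nonpositive denominator {denominator_ml} mL; undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return 100.0 * numerator_ml / denominator_ml


# percentage families: numerator VOIs per denominator
_PCT_OF_SKELETON = ("Skeleton600", "PSMA_PET_3", "NaF_PET_10", "NaF10_PSMA3")
_PCT_OF_SCLEROSIS = ("Scl_PSMA3", "Scl_NaF10", "Scl_NaF10_PSMA3")
_PCT_PATH_VS_SCLEROSIS = ("PSMA_PET_3", "NaF_PET_10")  # non-nested, may exceed 100%


@dataclass(frozen=True)
class VOIMetrics:
    """All per-patient quantitative outputs for one VOISet."""

    patient_id: str
    volume_ml: dict[str, float]
    mean_suv: dict[str, float]
    tea: dict[str, float]  # PSMA_PET_3, Scl_PSMA3 (L.SUV)
    tba: dict[str, float]  # NaF_PET_10, Scl_NaF10 (L.SUV)
    pct_of_skeleton: dict[str, float]
    pct_of_sclerosis: dict[str, float]
    pct_path_vs_sclerosis: dict[str, float]

    def to_row(self) -> dict[str, float | str]:
        """Flatten into one tidy row keyed by metric family + VOI name."""
        row: dict[str, float | str] = {"patient_id": self.patient_id}
        for name in VOI_NAMES:
            row[f"volume_ml_{name}"] = self.volume_ml[name]
        for name, v in self.mean_suv.items():
            row[f"mean_suv_{name}"] = v
        for name, v in self.tea.items():
            row[f"tea_{name}"] = v
        for name, v in self.tba.items():
            row[f"tba_{name}"] = v
        for name, v in self.pct_of_skeleton.items():
            row[f"pct_skeleton_{name}"] = v
        for name, v in self.pct_of_sclerosis.items():
            row[f"pct_sclerosis_{name}"] = v
        for name, v in self.pct_path_vs_sclerosis.items():
            row[f"pct_path_vs_sclerosis_{name}"] = v
        return row


def compute_voi_metrics(study: StudyPair, voiset: VOISet) -> VOIMetrics:
    """Compute volumes, mean SUVs, TEA/TBA, and all three percentage families."""
    spacing = voiset.spacing
    volume_ml = {name: mask_volume(voiset[name], spacing) for name in VOI_NAMES}

    suv_means: dict[str, float] = {}
    for name in PSMA_VOIS:
        suv_means[name] = mean_suv(study.psma, voiset[name])
    for name in NAF_VOIS:
        suv_means[name] = mean_suv(study.naf, voiset[name])

    tea = {name: burden_score(study.psma, voiset[name], spacing) for name in PSMA_VOIS}
    tba = {name: burden_score(study.naf, voiset[name], spacing) for name in NAF_VOIS}

    skel = volume_ml["Skeleton"]
    scl = volume_ml["Skeleton600"]
    pct_of_skeleton = {n: percentage_volume(volume_ml[n], skel) for n in _PCT_OF_SKELETON}
    pct_of_sclerosis = {n: percentage_volume(volume_ml[n], scl) for n in _PCT_OF_SCLEROSIS}
    pct_path_vs_sclerosis = {n: percentage_volume(volume_ml[n], scl) for n in _PCT_PATH_VS_SCLEROSIS}

    return VOIMetrics(
        patient_id=study.patient_id,
        volume_ml=volume_ml,
        mean_suv=suv_means,
        tea=tea,
        tba=tba,
        pct_of_skeleton=pct_of_skeleton,
        pct_of_sclerosis=pct_of_sclerosis,
        pct_path_vs_sclerosis=pct_path_vs_sclerosis,
    )
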