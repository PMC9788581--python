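"""Synthetic dual-tracer phantoms and M/N cohorts with exact ground truth.

No patient scans are distributable, so every pipeline stage is exercised on
stylised digital phantoms: a scaled-down skeleton (a vertebral column of
stacked cylinders, a pelvic torus segment, and paired long-bone tubes with
cortical shells) carrying nested HU compartments, focal spherical lesions
with partially overlapping pathological PSMA / NaF uptake, truncated-Gaussian
texture noise, and an optional planted rigid misalignment of the NaF study.

Design points that matter downstream:

* Noise is truncated at +/-4 sd, so HU compartments and sub-threshold SUV
  backgrounds can never cross the segmentation thresholds: control (N)
  patients have *exactly* zero pathological volume by construction.
* The cortical shell is rendered at 500 HU — at a 4 mm grid a thin cortical
  shell partial-volumes well below its intrinsic density — so the dense-bone
  (HU > 600) compartment is driven by discrete sclerotic patches and
  sclerotic lesions, keeping the sclerosis/skeleton volume ratio near the
  clinically observed ~15%.
* All randomness flows from one `numpy` Generator seeded by the spec; equal
  specs give bit-identical volumes.
* The ground-truth record contains the generator's own per-voxel predicate
  masks and volumes, the planted transform, and the moving-study CT, so the
  pipeline can be checked against it without re-deriving anything.

The ``misalignment`` transform moves the anatomy of the NaF study: the NaF
volumes show the scene displaced by T, i.e. they are rendered at
``T.inverse()``-mapped points.  Bone-guided registration of the NaF CT onto
the PSMA CT therefore recovers T itself (in the resampling convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .registration import RigidTransform
from .segmentation import VOI_NAMES
from .volumes import AcquisitionMeta, ImageVolume, Modality, StudyPair, ValueKind

#: half-lives (min) used for the default acquisition metadata
HALF_LIFE_GA68_MIN = 67.71
HALF_LIFE_F18_MIN = 109.77

DEFAULT_META_PSMA = AcquisitionMeta(280.0, 80.0, 60.0, HALF_LIFE_GA68_MIN)
DEFAULT_META_NAF = AcquisitionMeta(220.0, 80.0, 60.0, HALF_LIFE_F18_MIN)


class GenerationError(RuntimeError):
    """Raised when a phantom cannot satisfy its placement constraints."""


@dataclass(frozen=True)
class HULevels:
    """Mean HU per tissue compartment plus texture noise sd."""

    background: float = 20.0
    trabecular: float = 300.0
    cortical: float = 500.0
    sclerotic: float = 800.0
    noise_sd: float = 25.0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines one synthetic study pair.

    ``concordance`` is the probability that a lesion is pathological on both
    tracers; the remainder splits evenly into PSMA-only and NaF-only lesions.
    Lesion SUVs are log-normal around medians (8 PSMA, 25 NaF) so maxima span
    the clinically observed range; sub-threshold assignments keep the lesion
    visible but non-pathological on that tracer.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    skeleton_fraction: float | None = None
    sclerosis_fraction: float = 0.12
    hu_levels: HULevels = field(default_factory=HULevels)
    lesion_count: int = 0
    lesion_radius_mm: tuple[float, float] = (6.0, 14.0)
    concordance: float = 0.6
    lesion_psma_suv_median: float = 8.0
    lesion_naf_suv_median: float = 25.0
    lesion_suv_log_sigma: float = 0.4
    lesion_sclerotic_prob: float = 0.5
    background_suv_psma: float = 1.0
    background_suv_naf: float = 4.0
    suv_noise_sd: float = 0.3
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("grid_shape and spacing must be positive")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        if self.skeleton_fraction is not None and not 0.0 < self.skeleton_fraction < 1.0:
            raise ValueError("skeleton_fraction must lie in (0, 1)")
        if not 0.0 <= self.sclerosis_fraction < 1.0:
            raise ValueError("sclerosis_fraction must lie in [0, 1)")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be non-negative")
        lo, hi = self.lesion_radius_mm
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_mm must be an ascending positive range")


@dataclass(frozen=True)
class Lesion:
    center_mm: tuple[float, float, float]
    radius_mm: float
    psma_suv: float
    naf_suv: float
    pathological_psma: bool
    pathological_naf: bool
    sclerotic: bool


@dataclass(frozen=True)
class PhantomTruth:
    """Generator-side ground truth for one phantom.

    ``masks``/``volumes_ml`` describe the *aligned* anatomy (the NaF fields
    as they would appear without the planted misalignment).  ``naf_ct`` is
    the moving-study CT (misaligned with the NaF PET) used to drive
    registration; ``naf_aligned`` is the alignment reference.
    """

    lesions: tuple[Lesion, ...]
    planted_transform: RigidTransform
    masks: dict[str, np.ndarray]
    volumes_ml: dict[str, float]
    naf_ct: ImageVolume
    naf_aligned: ImageVolume
    skeleton_fraction: float
    sclerosis_fraction: float


# ---------------------------------------------------------------------------
# Stylised skeleton geometry


@dataclass(frozen=True)
class _Geometry:
    spine_xy: tuple[float, float]
    spine_radius: float
    vertebra_height: float
    vertebra_gap: float
    spine_z: tuple[float, float]
    pelvis_center: tuple[float, float, float]
    pelvis_major: float
    pelvis_minor: float
    femur_x_offset: float
    femur_radius: float
    femur_z: tuple[float, float]
    shell_mm: float


def _make_geometry(spec: PhantomSpec, radius_scale: float = 1.0) -> _Geometry:
    ext = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    lx, ly, lz = (float(v) for v in ext)
    cx, cy = lx / 2.0, ly / 2.0
    s = radius_scale
    return _Geometry(
        spine_xy=(cx, cy + 0.12 * ly),
        spine_radius=0.09 * min(lx, ly) * s,
        vertebra_height=20.0,
        vertebra_gap=4.0,
        spine_z=(0.28 * lz, 0.98 * lz),
        pelvis_center=(cx, cy, 0.22 * lz),
        pelvis_major=0.28 * min(lx, ly),
        pelvis_minor=9.0 * s,
        femur_x_offset=0.28 * min(lx, ly),
        femur_radius=10.0 * s,
        femur_z=(0.02 * lz, 0.20 * lz),
        shell_mm=4.0,
    )


def _skeleton_labels(points: np.ndarray, geom: _Geometry) -> np.ndarray:
    """0 = background, 1 = trabecular interior, 2 = cortical shell."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    interior = np.zeros(len(points), dtype=bool)
    shell = np.zeros(len(points), dtype=bool)

    def add_tube(depth: np.ndarray, inside_extra: np.ndarray | None = None) -> None:
        # depth: distance inward from the primitive surface (positive inside)
        nonlocal interior, shell
        inside = depth > 0
        if inside_extra is not None:
            inside &= inside_extra
        deep = depth > geom.shell_mm
        interior |= inside & deep
        shell |= inside & ~deep

    # vertebral column: stacked cylinders with gaps
    sx, sy = geom.spine_xy
    rho = np.hypot(x - sx, y - sy)
    z_lo, z_hi = geom.spine_z
    period = geom.vertebra_height + geom.vertebra_gap
    in_band = ((z - z_lo) % period < geom.vertebra_height) & (z >= z_lo) & (z <= z_hi)
    add_tube(geom.spine_radius - rho, in_band)

    # pelvis: torus segment
    px, py, pz = geom.pelvis_center
    ring = np.hypot(np.hypot(x - px, y - py) - geom.pelvis_major, z - pz)
    add_tube(geom.pelvis_minor - ring)

    # paired long bones
    for sign in (-1.0, 1.0):
        fx = geom.pelvis_center[0] + sign * geom.femur_x_offset
        rho_f = np.hypot(x - fx, y - py)
        in_f = (z >= geom.femur_z[0]) & (z <= geom.femur_z[1])
        add_tube(geom.femur_radius - rho_f, in_f)

    labels = np.zeros(len(points), dtype=np.uint8)
    labels[shell] = 2
    labels[interior] = 1  # interior wins where primitives overlap
    return labels


def _truncated_normal(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Gaussian noise clipped at +/-4 sd (keeps compartments threshold-safe)."""
    return np.clip(rng.standard_normal(shape), -4.0, 4.0) * sd


def _sphere_hits(points: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d2 = np.sum((points - center) ** 2, axis=1)
    return d2 < radius * radius


# ---------------------------------------------------------------------------
# Scene rendering


def _render_study(
    points: np.ndarray,
    geom: _Geometry,
    patches: Sequence[tuple[np.ndarray, float]],
    lesions: Sequence[Lesion],
    spec: PhantomSpec,
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    suv_noise: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (ct, psma_suv, naf_suv) arrays for the scene sampled at ``points``.

    CT noise is drawn from ``rng`` (differs between the two studies of one
    patient — separate acquisitions); the PET noise fields are passed in so
    the aligned and misaligned renders of one PET study share a realisation.
    """
    lv = spec.hu_levels
    labels = _skeleton_labels(points, geom)
    hu = np.full(len(points), lv.background)
    hu[labels == 1] = lv.trabecular
    hu[labels == 2] = lv.cortical
    in_bone = labels > 0

    for center, radius in patches:
        hit = _sphere_hits(points, center, radius) & in_bone
        hu[hit] = lv.sclerotic

    psma = np.full(len(points), spec.background_suv_psma)
    naf = np.full(len(points), spec.background_suv_naf)
    for lesion in lesions:
        hit = _sphere_hits(points, np.asarray(lesion.center_mm), lesion.radius_mm)
        psma[hit] = np.maximum(psma[hit], lesion.psma_suv)
        naf[hit] = np.maximum(naf[hit], lesion.naf_suv)
        if lesion.sclerotic:
            hu[hit & in_bone] = lv.sclerotic

    ct = hu + _truncated_normal(rng, len(points), lv.noise_sd)
    psma = np.maximum(psma + suv_noise["psma"], 0.0)
    naf = np.maximum(naf + suv_noise["naf"], 0.0)
    return (ct.reshape(shape), psma.reshape(shape), naf.reshape(shape))


def _predicate_masks(ct: np.ndarray, psma: np.ndarray, naf: np.ndarray) -> dict[str, np.ndarray]:
    """Generator-side per-voxel VOI predicates at the default thresholds."""
    skeleton = ct > 150.0
    sclerosis = ct > 600.0
    psma_path = (psma > 3.0) & skeleton
    naf_path = (naf > 10.0) & skeleton
    return {
        "Skeleton": skeleton,
        "Skeleton600": sclerosis,
        "PSMA_PET_3": psma_path,
        "NaF_PET_10": naf_path,
        "NaF10_PSMA3": psma_path & naf_path,
        "Scl_PSMA3": psma_path & sclerosis,
        "Scl_NaF10": naf_path & sclerosis,
        "Scl_NaF10_PSMA3": psma_path & naf_path & sclerosis,
    }


_MAX_PATCHES = 400


def make_phantom(
    spec: PhantomSpec,
    patient_id: str = "P00",
    group: str = "M",
    psa: float = 0.0,
) -> tuple[StudyPair, PhantomTruth]:
    """Generate one dual-tracer study pair plus its ground-truth record.

    The PSMA study defines the reference grid; the NaF study (PET and its own
    CT) is rendered with the anatomy displaced by ``spec.misalignment``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)

    grid = ImageVolume(np.zeros(shape), spacing, modality=Modality.CT)
    points = grid.physical_points()

    geom = _make_geometry(spec)
    labels = _skeleton_labels(points, geom)
    n_bone = int((labels > 0).sum())
    if n_bone == 0:
        raise GenerationError("skeleton geometry produced no bone voxels on this grid")
    if spec.skeleton_fraction is not None:
        achieved = n_bone / len(points)
        scale = float(np.clip(math.sqrt(spec.skeleton_fraction / achieved), 0.5, 2.0))
        geom = _make_geometry(spec, radius_scale=scale)
        labels = _skeleton_labels(points, geom)
        n_bone = int((labels > 0).sum())
        if n_bone == 0:
            raise GenerationError("skeleton_fraction rescaling removed all bone voxels")

    bone_points = points[labels > 0]

    # sclerotic patches until the target fraction of skeleton voxels is dense
    patches: list[tuple[np.ndarray, float]] = []
    target = spec.sclerosis_fraction * n_bone
    sclerotic_hit = np.zeros(len(bone_points), dtype=bool)
    while sclerotic_hit.sum() < target:
        if len(patches) >= _MAX_PATCHES:
            raise GenerationError(
                f"could not reach sclerosis_fraction={spec.sclerosis_fraction} "
                f"within {_MAX_PATCHES} patches"
            )
        center = bone_points[rng.integers(len(bone_points))]
        radius = float(rng.uniform(6.0, 12.0))
        patches.append((center, radius))
        sclerotic_hit |= _sphere_hits(bone_points, center, radius)

    # lesions: centers inside skeleton voxels
    lesions: list[Lesion] = []
    lo, hi = spec.lesion_radius_mm
    for _ in range(spec.lesion_count):
        center = bone_points[rng.integers(len(bone_points))]
        radius = float(rng.uniform(lo, hi))
        u = rng.random()
        path_psma = u < spec.concordance or u < spec.concordance + (1 - spec.concordance) / 2
        path_naf = u < spec.concordance or u >= spec.concordance + (1 - spec.concordance) / 2
        sigma = spec.lesion_suv_log_sigma
        if path_psma:
            psma_suv = max(spec.lesion_psma_suv_median * math.exp(sigma * rng.standard_normal()), 3.5)
        else:
            psma_suv = float(rng.uniform(1.5, 2.5))
        if path_naf:
            naf_suv = max(spec.lesion_naf_suv_median * math.exp(sigma * rng.standard_normal()), 11.0)
        else:
            naf_suv = float(rng.uniform(5.0, 8.0))
        lesions.append(
            Lesion(
                center_mm=tuple(float(c) for c in center),
                radius_mm=radius,
                psma_suv=psma_suv,
                naf_suv=naf_suv,
                pathological_psma=bool(path_psma),
                pathological_naf=bool(path_naf),
                sclerotic=bool(rng.random() < spec.lesion_sclerotic_prob),
            )
        )

    # shared PET noise realisations (aligned and misaligned renders agree)
    psma_noise = _truncated_normal(rng, len(points), spec.suv_noise_sd)
    naf_noise = _truncated_normal(rng, len(points), spec.suv_noise_sd)
    noise = {"psma": psma_noise, "naf": naf_noise}

    ct_arr, psma_arr, naf_aligned_arr = _render_study(
        points, geom, patches, lesions, spec, rng, shape, noise
    )

    identity = (
        np.allclose(spec.misalignment.rotation_deg, 0.0)
        and np.allclose(spec.misalignment.translation_mm, 0.0)
    )
    # NaF study: own CT acquisition noise; PET noise field shared with the
    # aligned render so identity misalignment reproduces it bit-for-bit.
    moved = points if identity else spec.misalignment.inverse().apply(points)
    naf_ct_arr, _, naf_arr = _render_study(moved, geom, patches, lesions, spec, rng, shape, noise)

    study = StudyPair(
        ct=ImageVolume(ct_arr, spacing, modality=Modality.CT, value_kind=ValueKind.HU),
        psma=ImageVolume(psma_arr, spacing, modality=Modality.PET_PSMA, value_kind=ValueKind.SUV),
        naf=ImageVolume(naf_arr, spacing, modality=Modality.PET_NAF, value_kind=ValueKind.SUV),
        meta_psma=DEFAULT_META_PSMA,
        meta_naf=DEFAULT_META_NAF,
        psa=psa,
        group=group,
        patient_id=patient_id,
    )

    masks = _predicate_masks(ct_arr, psma_arr, naf_aligned_arr)
    voxel_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    volumes_ml = {name: float(mask.sum()) * voxel_ml for name, mask in masks.items()}
    truth = PhantomTruth(
        lesions=tuple(lesions),
        planted_transform=spec.misalignment,
        masks=masks,
        volumes_ml=volumes_ml,
        naf_ct=ImageVolume(naf_ct_arr, spacing, modality=Modality.CT, value_kind=ValueKind.HU),
        naf_aligned=ImageVolume(
            naf_aligned_arr, spacing, modality=Modality.PET_NAF, value_kind=ValueKind.SUV
        ),
        skeleton_fraction=n_bone / len(points),
        sclerosis_fraction=float(masks["Skeleton600"].sum()) / max(n_bone, 1),
    )
    return study, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """A full M/N cohort: group sizes, per-patient lesion burden, PSA model.

    Serum PSA in the M group follows ``psa = alpha * V + multiplicative
    log-normal noise`` with V the true pathological PSMA volume (mL); as the
    noise sd -> 0 the volume-PSA correlation approaches 1 exactly.  N-group
    PSA is drawn independently of burden (log-normal around ``n_psa_median``).

    ``burden_scale_log_sigma`` is a per-patient log-normal factor on lesion
    radii: metastatic burden in this disease is heavily skewed across
    patients (reported volume dispersions have CV > 2), and lesion count
    alone cannot reproduce that spread.
    """

    n_m: int = 14
    n_n: int = 12
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    lesion_count_range: tuple[int, int] = (6, 30)
    burden_scale_log_sigma: float = 0.45
    psa_alpha: float = 1.0
    psa_log_sigma: float = 0.3
    n_psa_median: float = 5.0
    n_psa_log_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_m < 1 or self.n_n < 1:
            raise ValueError("group sizes must be >= 1")
        if not self.psa_alpha > 0:
            raise ValueError("psa_alpha must be positive")
        lo, hi = self.lesion_count_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_count_range must be an ascending positive range")


@dataclass(frozen=True)
class SyntheticCohort:
    studies: tuple[StudyPair, ...]
    truths: tuple[PhantomTruth, ...]
    clinical: pd.DataFrame


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full M/N cohort (studies, ground truths, clinical table)."""
    rng = np.random.default_rng(spec.seed)
    studies: list[StudyPair] = []
    truths: list[PhantomTruth] = []
    rows: list[dict] = []

    for i in range(spec.n_m + spec.n_n):
        is_m = i < spec.n_m
        group = "M" if is_m else "N"
        pid = f"{group}{(i if is_m else i - spec.n_m) + 1:02d}"
        lo, hi = spec.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1)) if is_m else 0
        child_seed = int(rng.integers(2**31))
        scale = math.exp(spec.burden_scale_log_sigma * rng.standard_normal())
        r_lo, r_hi = spec.phantom.lesion_radius_mm
        radii = (max(r_lo * scale, 3.0), min(max(r_hi * scale, 4.0), 30.0))
        pspec = replace(
            spec.phantom, lesion_count=n_lesions, seed=child_seed, lesion_radius_mm=radii
        )
        study, truth = make_phantom(pspec, patient_id=pid, group=group)

        if is_m:
            vol = truth.volumes_ml["PSMA_PET_3"]
            psa = spec.psa_alpha * vol * math.exp(spec.psa_log_sigma * rng.standard_normal())
        else:
            psa = spec.n_psa_median * math.exp(spec.n_psa_log_sigma * rng.standard_normal())
        age = float(np.clip(rng.normal(66.0 if is_m else 68.0, 9.0), 45, 88))

        study = replace(study, psa=float(psa))
        studies.append(study)
        truths.append(truth)
        rows.append(
            {"patient_id": pid, "group": group, "psa": float(psa), "age": round(age, 1),
             "n_lesions": n_lesions}
        )

    return SyntheticCohort(tuple(studies), tuple(truths), pd.DataFrame(rows))
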