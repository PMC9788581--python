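"""End-to-end orchestration: register -> segment -> metrics -> cohort statistics.

Per-patient runs are deterministic given inputs and config, and every output
directory carries a provenance record (config hash, package version, input
checksums).  Failures are isolated at patient granularity: a failing patient
yields a structured error record and the cohort statistics are computed on
the surviving subset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortAnalyzer, CohortResult, threshold_sweep
from .metrics import VOIMetrics, compute_voi_metrics
from .registration import BoneGuidedRegistration, resample_to
from .segmentation import SegmentationConfig, build_voiset
from .volumes import ImageVolume, StudyPair

logger = logging.getLogger("skelburden")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run (YAML-serialisable, versioned schema)."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sweep_thresholds: tuple[float, ...] = (3.0, 4.0, 6.0, 10.0)
    register: bool = True
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"] = self.segmentation.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        raw["sweep_thresholds"] = tuple(raw.get("sweep_thresholds", (3.0, 4.0, 6.0, 10.0)))
        return cls(segmentation=seg, **raw)


def _volume_checksum(vol: ImageVolume) -> str:
    return hashlib.sha256(np.ascontiguousarray(vol.values).tobytes()).hexdigest()[:16]


def _provenance(config: RunConfig, study: StudyPair) -> dict:
    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "software_version": __version__,
        "patient_id": study.patient_id,
        "input_checksums": {
            "ct": _volume_checksum(study.ct),
            "psma": _volume_checksum(study.psma),
            "naf": _volume_checksum(study.naf),
        },
    }


def run_patient(
    config: RunConfig,
    study: StudyPair,
    naf_ct: ImageVolume | None = None,
) -> VOIMetrics:
    """Process one patient: optional bone-guided realignment, VOIs, metrics.

    ``naf_ct`` is the CT of the NaF study; when given and ``config.register``
    is on, the NaF PET is realigned onto the reference (PSMA-study) grid via
    the CT bone compartment before segmentation.  With registration off the
    inputs are taken as pre-registered (identity bypass).
    """
    if config.register and naf_ct is not None:
        reg = BoneGuidedRegistration(hu_threshold=config.segmentation.hu_skeleton)
        reg.fit(study.ct, naf_ct)
        logger.info(
            "%s: registered NaF study (dice %.3f -> %.3f)",
            study.patient_id, reg.dice_before_, reg.dice_after_,
        )
        naf = resample_to(study.naf, reg.transform_, study.ct, "linear")
        study = replace(study, naf=naf)

    voiset = build_voiset(study, config.segmentation)
    metrics = compute_voi_metrics(study, voiset)

    if config.out_dir is not None:
        out = Path(config.out_dir) / (study.patient_id or "patient")
        out.mkdir(parents=True, exist_ok=True)
        voiset.write(out)
        row = metrics.to_row()
        (out / "metrics.json").write_text(json.dumps(row, indent=2, default=float))
        (out / "provenance.json").write_text(json.dumps(_provenance(config, study), indent=2))
    return metrics


@dataclass(frozen=True)
class PatientStatus:
    patient_id: str
    ok: bool
    error: str = ""


def run_cohort(
    config: RunConfig,
    studies: list[StudyPair],
    clinical: pd.DataFrame | None = None,
    naf_cts: list[ImageVolume | None] | None = None,
) -> tuple[CohortResult, pd.DataFrame, list[PatientStatus]]:
    """Process a cohort with per-patient failure isolation.

    Returns the cohort statistics (group summaries, Mann-Whitney tests,
    PSA correlations, SUV_PSMA threshold sweep), the tidy per-patient metrics
    table, and per-patient status records.  ``clinical`` may override/extend
    group and PSA from a table keyed by ``patient_id``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    naf_cts = naf_cts or [None] * len(studies)

    rows: list[dict] = []
    statuses: list[PatientStatus] = []
    surviving: list[StudyPair] = []
    for study, naf_ct in zip(studies, naf_cts):
        try:
            metrics = run_patient(config, study, naf_ct)
        except Exception as exc:  # isolate the patient, keep the cohort
            logger.error("%s failed: %s", study.patient_id, exc)
            statuses.append(PatientStatus(study.patient_id, False, f"{type(exc).__name__}: {exc}"))
            continue
        row = metrics.to_row()
        row["group"] = study.group
        row["psa"] = study.psa
        rows.append(row)
        statuses.append(PatientStatus(study.patient_id, True))
        surviving.append(study)

    table = pd.DataFrame(rows)
    if clinical is not None and len(table):
        override = clinical.set_index("patient_id")
        for col in ("group", "psa"):
            if col in override.columns:
                table[col] = table["patient_id"].map(override[col]).fillna(table[col])

    if table.empty:
        raise RuntimeError(
            "no patient succeeded; statuses: "
            + "; ".join(f"{s.patient_id}: {s.error}" for s in statuses)
        )
    analyzer = CohortAnalyzer().fit(table)
    for notice in analyzer.notices_:
        logger.warning(notice)
    sweep = threshold_sweep(surviving, config.sweep_thresholds, config.segmentation)
    result = analyzer.result(sweep=sweep)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        result.summary.to_csv(out / "summary.csv", index=False)
        result.tests.to_csv(out / "tests.csv", index=False)
        sweep.volumes.to_csv(out / "sweep_volumes.csv")
        sweep.to_frame().to_csv(out / "sweep_correlations.csv", index=False)
        result.correlations.to_csv(out / "correlations.csv", index=False)
        report = {
            "config_hash": config.config_hash(),
            "n_patients": len(studies),
            "n_ok": sum(s.ok for s in statuses),
            "statuses": [dataclasses.asdict(s) for s in statuses],
            "notices": list(result.notices),
        }
        (out / "cohort_provenance.json").write_text(json.dumps(report, indent=2))
    return result, table, statuses
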