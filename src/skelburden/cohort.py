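"""Cohort-level statistics: group summaries, Mann-Whitney tests, PSA correlations, threshold sweep.

The metastatic (M) and control (N) groups are compared metric-by-metric with
a two-sided Mann-Whitney U test (exact permutation distribution for small
tie-free samples, normal approximation with tie and continuity corrections
otherwise).  Correlations against serum PSA are Pearson r on raw values,
computed within each group.  The SUV_PSMA threshold sweep rebuilds the
pathological PSMA mask at each threshold and tracks both the per-patient
volume and the within-M correlation with PSA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .segmentation import SegmentationConfig, threshold_mask
from .metrics import mask_volume
from .volumes import StudyPair


class GroupSummary(NamedTuple):
    mean: float
    sd: float
    min: float
    max: float


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean, population standard deviation (divisor n), min and max.

    The population form is the convention used throughout the reported
    summaries (e.g. group ages quoted as mean +/- sd).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires a non-empty list")
    return GroupSummary(
        float(arr.mean()), float(arr.std(ddof=0)), float(arr.min()), float(arr.max())
    )


#: sample-size cap under which the exact permutation distribution is used
_EXACT_MAX_N = 25


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U, p)`` where U counts pairs (a, b) with a > b (+0.5 per tie).
    The p-value is exact (full permutation distribution) when
    n1 + n2 <= 25 and there are no ties, else the normal approximation with
    tie and continuity corrections.  Two groups with all values identical
    have no separation at all: p = 1 with a warning.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all values identical in both groups; p = 1", RuntimeWarning, stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "asymptotic" if has_ties or combined.size > _EXACT_MAX_N else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN marker for degenerate input."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Threshold sweep


@dataclass(frozen=True)
class SweepResult:
    """Per-patient pathological PSMA volumes and within-M PSA correlation per threshold."""

    volumes: pd.DataFrame  # index patient_id, one column per threshold (mL)
    pearson_r_m: dict[float, float]  # threshold -> r(volume, PSA) within group M
    thresholds: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"suv_psma_threshold": t, "pearson_r_m": self.pearson_r_m[t]} for t in self.thresholds
        ]
        return pd.DataFrame(rows)


def threshold_sweep(
    cohort: Sequence[StudyPair],
    thresholds: Sequence[float] = (3.0, 4.0, 6.0, 10.0),
    config: SegmentationConfig | None = None,
) -> SweepResult:
    """Rebuild the pathological PSMA mask at each SUV threshold.

    For each threshold the skeletal pathological PSMA volume is recomputed
    per patient and Pearson r between that volume and serum PSA is evaluated
    within group M.  Volumes are non-increasing in the threshold by
    construction of the strict-> predicate.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be positive and ascending")
    config = config or SegmentationConfig()

    records: dict[str, dict[float, float]] = {}
    m_psa: list[float] = []
    m_ids: list[str] = []
    for study in cohort:
        study.validate_grid()
        skeleton = threshold_mask(study.ct, config.hu_skeleton)
        pid = study.patient_id
        records[pid] = {}
        for t in thresholds:
            mask = threshold_mask(study.psma, t) & skeleton
            records[pid][t] = mask_volume(mask, study.ct.spacing)
        if study.group == "M":
            m_psa.append(study.psa)
            m_ids.append(pid)

    if records:
        volumes = pd.DataFrame.from_dict(records, orient="index")[list(thresholds)]
    else:
        volumes = pd.DataFrame(columns=list(thresholds))
    r_by_threshold: dict[float, float] = {}
    for t in thresholds:
        if len(m_ids) >= 3:
            vols = volumes.loc[m_ids, t].to_numpy()
            r_by_threshold[t] = pearson_r(vols, m_psa) if np.std(vols) > 0 else float("nan")
        else:
            r_by_threshold[t] = float("nan")
    return SweepResult(volumes, r_by_threshold, thresholds)


# ---------------------------------------------------------------------------
# Cohort analyzer

#: volume metrics correlated against PSA per group (PSMA, NaF, CT sclerosis)
CORRELATION_METRICS = ("volume_ml_PSMA_PET_3", "volume_ml_NaF_PET_10", "volume_ml_Skeleton600")


@dataclass(frozen=True)
class CohortResult:
    """Fitted cohort statistics bundled for reporting."""

    summary: pd.DataFrame
    tests: pd.DataFrame
    ratio_of_means: pd.Series
    correlations: pd.DataFrame
    sweep: SweepResult | None = None
    n_m: int = 0
    n_n: int = 0
    notices: tuple[str, ...] = ()


class CohortAnalyzer(BaseEstimator):
    """Aggregate a tidy per-patient metrics table into cohort statistics.

    ``fit`` expects a DataFrame with ``patient_id``, ``group`` (M/N), ``psa``
    and numeric metric columns (the flattened :class:`~skelburden.metrics.VOIMetrics`
    rows).  Fitted attributes:

    summary_
        (metric, group) rows with mean / population sd / min / max.
    tests_
        Mann-Whitney U and two-sided p per metric, M vs N.
    ratio_of_means_
        M-mean over N-mean per percentage-volume metric.
    correlations_
        Pearson r against PSA per (volume metric, group).
    """

    def __init__(self, metrics: Sequence[str] | None = None) -> None:
        self.metrics = metrics

    def _metric_columns(self, table: pd.DataFrame) -> list[str]:
        if self.metrics is not None:
            return list(self.metrics)
        prefixes = ("volume_ml_", "tea_", "tba_", "pct_")
        return [
            c
            for c in table.columns
            if c.startswith(prefixes) and pd.api.types.is_numeric_dtype(table[c])
        ]

    def fit(self, table: pd.DataFrame, y=None) -> "CohortAnalyzer":
        required = {"group", "psa"}
        if missing := required - set(table.columns):
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        bad = set(table["group"]) - {"M", "N"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

        metrics = self._metric_columns(table)
        groups = {g: table[table["group"] == g] for g in ("M", "N")}
        self.n_m_, self.n_n_ = len(groups["M"]), len(groups["N"])
        notices: list[str] = []

        rows = []
        for metric in metrics:
            for g, sub in groups.items():
                vals = sub[metric].dropna()
                if len(vals) == 0:
                    continue
                s = group_summary(vals)
                rows.append(
                    {"metric": metric, "group": g, "n": len(vals), "mean": s.mean,
                     "sd": s.sd, "min": s.min, "max": s.max}
                )
        self.summary_ = pd.DataFrame(rows)

        test_rows = []
        both_groups = self.n_m_ >= 1 and self.n_n_ >= 1
        comparable = self.n_m_ >= 2 and self.n_n_ >= 2
        if not comparable:
            notices.append(
                f"Mann-Whitney comparisons skipped: group sizes M={self.n_m_}, N={self.n_n_}"
            )
        for metric in metrics:
            if not comparable:
                continue
            a = groups["M"][metric].dropna().to_numpy()
            b = groups["N"][metric].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                u, p = mann_whitney_u(a, b)
            test_rows.append({"metric": metric, "U": u, "p": p, "n_m": len(a), "n_n": len(b)})
        self.tests_ = pd.DataFrame(test_rows)

        ratios = {}
        if both_groups:
            for metric in metrics:
                if not metric.startswith("pct_"):
                    continue
                m_mean = groups["M"][metric].dropna().mean()
                n_mean = groups["N"][metric].dropna().mean()
                ratios[metric] = float(m_mean / n_mean) if n_mean else float("nan")
        self.ratio_of_means_ = pd.Series(ratios, dtype=float)

        corr_rows = []
        for metric in CORRELATION_METRICS:
            if metric not in table.columns:
                continue
            for g, sub in groups.items():
                valid = sub[[metric, "psa"]].dropna()
                if len(valid) < 3:
                    continue
                vols = valid[metric].to_numpy()
                if np.std(vols) == 0 or np.std(valid["psa"].to_numpy()) == 0:
                    r = float("nan")
                else:
                    r = pearson_r(vols, valid["psa"].to_numpy())
                corr_rows.append({"metric": metric, "group": g, "r": r, "n": len(valid)})
        self.correlations_ = pd.DataFrame(corr_rows)
        self.notices_ = tuple(notices)
        return self

    def result(self, sweep: SweepResult | None = None) -> CohortResult:
        if not hasattr(self, "summary_"):
            raise RuntimeError("CohortAnalyzer is not fitted; call fit() first")
        return CohortResult(
            summary=self.summary_,
            tests=self.tests_,
            ratio_of_means=self.ratio_of_means_,
            correlations=self.correlations_,
            sweep=sweep,
            n_m=self.n_m_,
            n_n=self.n_n_,
            notices=self.notices_,
        )
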