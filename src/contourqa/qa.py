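"""Statistical pass criteria and contour-error detection evaluation.

Per-organ criteria come from the validation set: with mean and SD of the
slice-wise DSC and HD distributions, a test contour passes when

    DSC > mean_DSC - k * sd_DSC      or      HD < mean_HD + k * sd_HD

with k = 1.96 (the two-sided 95% normal band).  The either-criterion rule
exists because small structures legitimately score low DSC while keeping a
tight HD.  A contour failing both criteria is flagged as erroneous.

Detection quality against ground-truth error labels is summarized per organ
by the confusion counts (positive class = error-containing contour), balanced
accuracy BA = (sensitivity + specificity) / 2, and an ROC AUC.  The pass/fail
decision itself is binary, so for the ROC a continuous conformity score is
defined: the max of the two criterion margins in SD units,

    conformity = max((DSC - thr_DSC) / sd_DSC, (thr_HD - HD) / sd_HD);

sweeping its threshold traces the ROC (the hard decision corresponds to
threshold 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .metrics import SliceMetrics, ValidationStats

DEFAULT_K = 1.96
_SD_FLOOR = 1e-9  # keeps conformity finite for degenerate (sd = 0) criteria


@dataclass
class PassCriteria:
    """Per-organ thresholds derived from validation statistics."""

    organ: str
    dsc_threshold: float  # pass when DSC strictly above
    hd_threshold: float  # pass when HD strictly below (pixels)
    k: float
    source_stats: ValidationStats

    @property
    def dsc_threshold_display(self) -> float:
        """DSC threshold at the 2-decimal display precision."""
        return round(self.dsc_threshold, 2)

    @property
    def hd_threshold_display(self) -> float:
        """HD threshold at the 1-decimal display precision."""
        return round(self.hd_threshold, 1)


@dataclass
class QADecision:
    case_id: str
    slice_index: int
    organ: str
    dsc_pass: bool
    hd_pass: bool
    verdict: str  # "pass" | "fail"
    conformity_score: float


@dataclass
class DetectionReport:
    organ: str
    tp: int
    fp: int
    tn: int
    fn: int
    ba: float
    sensitivity: float
    specificity: float
    auc: float  # nan when truth is single-class

    @property
    def n_samples(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def fit_criteria(stats: ValidationStats, k: float = DEFAULT_K) -> PassCriteria:
    """Thresholds mean_DSC - k*sd_DSC and mean_HD + k*sd_HD for one organ."""
    if k <= 0:
        raise ValueError("k must be positive")
    if stats.dsc_sd == 0 or stats.hd_sd == 0:
        warnings.warn(
            f"zero validation SD for organ '{stats.organ}': degenerate criteria",
            stacklevel=2,
        )
    return PassCriteria(
        organ=stats.organ,
        dsc_threshold=stats.dsc_mean - k * stats.dsc_sd,
        hd_threshold=stats.hd_mean + k * stats.hd_sd,
        k=k,
        source_stats=stats,
    )


def fit_all_criteria(
    stats: Mapping[str, ValidationStats], k: float = DEFAULT_K
) -> dict[str, PassCriteria]:
    return {organ: fit_criteria(s, k) for organ, s in stats.items()}


def conformity_score(metrics: SliceMetrics, criteria: PassCriteria) -> float:
    """Signed margin to the nearer-passed criterion, in SD units.

    Positive iff the slice passes at least one criterion; monotone in both
    metrics, so sweeping a threshold over it traces a full ROC.
    """
    dsc_sd = max(criteria.source_stats.dsc_sd, _SD_FLOOR)
    hd_sd = max(criteria.source_stats.hd_sd, _SD_FLOOR)
    dsc_margin = (metrics.dsc - criteria.dsc_threshold) / dsc_sd
    if np.isinf(metrics.hd_pixels):
        hd_margin = -np.inf
    else:
        hd_margin = (criteria.hd_threshold - metrics.hd_pixels) / hd_sd
    return float(max(dsc_margin, hd_margin))


def decide(metrics: SliceMetrics, criteria: PassCriteria) -> QADecision:
    """Apply the either-criterion rule to one (slice, organ) sample.

    Strict inequalities; an infinite HD (missing contour on one side) can
    never satisfy the HD criterion.
    """
    if metrics.organ != criteria.organ:
        raise ValueError(
            f"organ mismatch: metrics for '{metrics.organ}', criteria for "
            f"'{criteria.organ}'"
        )
    dsc_pass = metrics.dsc > criteria.dsc_threshold
    hd_pass = bool(np.isfinite(metrics.hd_pixels)) and (
        metrics.hd_pixels < criteria.hd_threshold
    )
    return QADecision(
        case_id=metrics.case_id,
        slice_index=metrics.slice_index,
        organ=metrics.organ,
        dsc_pass=dsc_pass,
        hd_pass=hd_pass,
        verdict="pass" if (dsc_pass or hd_pass) else "fail",
        conformity_score=conformity_score(metrics, criteria),
    )


def decide_all(
    records: Iterable[SliceMetrics], criteria: Mapping[str, PassCriteria]
) -> list[QADecision]:
    return [decide(rec, criteria[rec.organ]) for rec in records if rec.organ in criteria]


def _roc_auc(error: np.ndarray, suspicion: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(error, suspicion))


def evaluate_detection(
    decisions: Sequence[QADecision],
    truth: Mapping[tuple[str, int, str], bool],
    per_organ: bool = True,
) -> dict[str, DetectionReport]:
    """Confusion counts, BA, sensitivity, specificity and AUC per organ.

    ``truth`` maps (case_id, slice_index, organ) to True when the sample
    contains a contour error (the positive class).  A "fail" verdict is a
    positive prediction.  The AUC sweeps the continuous conformity score
    (higher suspicion = lower conformity); with single-class truth the AUC is
    NaN and rates with zero denominators are NaN.

    Returns one report per organ plus an "overall" pooled report.
    """
    missing = [
        (d.case_id, d.slice_index, d.organ)
        for d in decisions
        if (d.case_id, d.slice_index, d.organ) not in truth
    ]
    if missing:
        raise ValueError(f"{len(missing)} decisions without a truth label, e.g. {missing[0]}")
    groups: dict[str, list[QADecision]] = {"overall": list(decisions)}
    if per_organ:
        for d in decisions:
            groups.setdefault(d.organ, []).append(d)
    reports: dict[str, DetectionReport] = {}
    for name, group in groups.items():
        is_error = np.array(
            [truth[(d.case_id, d.slice_index, d.organ)] for d in group], dtype=bool
        )
        flagged = np.array([d.verdict == "fail" for d in group], dtype=bool)
        tp = int((is_error & flagged).sum())
        fn = int((is_error & ~flagged).sum())
        fp = int((~is_error & flagged).sum())
        tn = int((~is_error & ~flagged).sum())
        sen = tp / (tp + fn) if (tp + fn) else float("nan")
        spe = tn / (tn + fp) if (tn + fp) else float("nan")
        ba = (
            0.5 * (sen + spe)
            if np.isfinite(sen) and np.isfinite(spe)
            else float("nan")
        )
        if is_error.any() and not is_error.all():
            suspicion = -np.array(
                [
                    np.nan_to_num(d.conformity_score, neginf=-1e12, posinf=1e12)
                    for d in group
                ]
            )
            auc = _roc_auc(is_error, suspicion)
        else:
            auc = float("nan")
        reports[name] = DetectionReport(
            organ=name, tp=tp, fp=fp, tn=tn, fn=fn,
            ba=ba, sensitivity=sen, specificity=spe, auc=auc,
        )
    return reports
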