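"""End-to-end orchestration of the contour-QA strategy.

The five-step strategy: (1) split the data into gold / candidate /
validation / test sets, (2) train a segmentation backend on the gold set,
(3) enrich it by active-learning fine-tuning on the candidate pool,
(4) derive per-organ statistical pass criteria from the validation set,
(5) apply model + criteria to the test set and score error detection.

Two entry points:

* :func:`run_all` — the full strategy on a synthetic phantom dataset with a
  trainable backend, writing every artifact (criteria, per-slice metrics,
  decisions, detection report, selection audit trail, run manifest) into a
  run directory;
* :func:`detection_benchmark` — the QA half only (metrics → criteria →
  decisions → detection), driven by synthetic probability maps of fixed
  confidence instead of a trained model, which isolates the decision
  machinery from segmentation quality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .active_learning import CandidateImage, SelectionRound, run_loop
from .io_rtstruct import rasterize_structure_set
from .metrics import (
    SliceMetrics,
    evaluate_case,
    metrics_dataframe,
    summarize_validation,
)
from .phantom import (
    PhantomCase,
    PhantomConfig,
    error_truth_table,
    generate_case,
    inject_errors,
    observer_contours,
    synth_probmaps,
)
from .qa import DetectionReport, decide_all, evaluate_detection, fit_all_criteria
from .segmentation import ReferenceBackend, TrainConfig


@dataclass
class RunConfig:
    """Configuration of a full phantom run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_gold: int = 4
    n_candidate: int = 8
    n_validation: int = 4
    n_test: int = 4
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=8))
    loop_fraction: float = 0.3
    loop_iterations: int = 2
    k: float = 1.96
    seed: int = 0
    out_dir: str | Path = "runs/phantom"

    def __post_init__(self) -> None:
        if self.n_validation < 1:
            raise ValueError(
                "missing validation set: n_validation must be >= 1 because the "
                "pass criteria are fitted on validation statistics"
            )
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1 to evaluate detection")


def split_assign(
    cases: Sequence[str],
    n_validation: int,
    n_test: int,
    rng: np.random.Generator,
    n_candidate: int | None = None,
) -> pd.DataFrame:
    """Assign cases to candidate / validation / test sets.

    The candidate set is the first-enrolled block (list order is enrollment
    order); the remaining cases are split uniformly at random, without
    replacement, into validation and test.
    """
    cases = list(cases)
    if n_candidate is None:
        n_candidate = len(cases) - n_validation - n_test
    if n_candidate < 0 or n_candidate + n_validation + n_test > len(cases):
        raise ValueError(
            f"cannot split {len(cases)} cases into {n_candidate} candidate + "
            f"{n_validation} validation + {n_test} test"
        )
    candidate = cases[:n_candidate]
    rest = cases[n_candidate:]
    perm = rng.permutation(len(rest))
    validation = [rest[i] for i in perm[:n_validation]]
    test = [rest[i] for i in perm[n_validation : n_validation + n_test]]
    rows = (
        [{"case_id": c, "set_assignment": "candidate"} for c in candidate]
        + [{"case_id": c, "set_assignment": "validation"} for c in validation]
        + [{"case_id": c, "set_assignment": "test"} for c in test]
    )
    frame = pd.DataFrame(rows)
    if frame["case_id"].duplicated().any():
        raise ValueError("set assignments are not disjoint by case_id")
    return frame


# ---------------------------------------------------------------------------
# Helpers shared by both entry points
# ---------------------------------------------------------------------------


def _manual_masks_for_case(
    case: PhantomCase,
    jitter_sd: float,
    rng: np.random.Generator,
    cfg: PhantomConfig,
    with_errors: bool,
):
    """Observer-quality manual masks, optionally corrupted with gross errors."""
    observed = observer_contours(
        case.truth_structures, jitter_sd, rng, cfg.pixel_spacing_mm
    )
    labels = []
    if with_errors:
        observed, labels = inject_errors(observed, cfg, rng, case)
    masks = rasterize_structure_set(observed, case.series, organs=list(cfg.priors))
    return masks, labels


def _predicted_masks_from_probmaps(
    probmaps: Mapping[str, Sequence[np.ndarray]], threshold: float = 0.5
) -> dict[str, list[np.ndarray]]:
    return {
        organ: [np.asarray(p) > threshold for p in maps]
        for organ, maps in probmaps.items()
    }


def _qa_phase(
    validation_cases: Sequence[PhantomCase],
    test_cases: Sequence[PhantomCase],
    predict_masks,
    cfg: PhantomConfig,
    k: float,
    rng: np.random.Generator,
):
    """Fit criteria on clean validation cases, decide and score the test set.

    ``predict_masks(case) -> {organ: [mask, ...]}`` supplies the model side.
    Validation manual contours are observer-quality but error-free (the
    workflow assumption: validation contours were rechecked and error slices
    excluded); test manual contours carry injected gross errors.
    """
    val_records: list[SliceMetrics] = []
    for case in validation_cases:
        manual, _ = _manual_masks_for_case(case, cfg.observer_jitter_sd, rng, cfg, False)
        val_records.extend(evaluate_case(manual, predict_masks(case), case.case_id))
    stats = summarize_validation(val_records)
    criteria = fit_all_criteria(stats, k)

    test_records: list[SliceMetrics] = []
    truth: dict[tuple[str, int, str], bool] = {}
    all_labels = []
    for case in test_cases:
        manual, labels = _manual_masks_for_case(
            case, cfg.observer_jitter_sd, rng, cfg, True
        )
        test_records.extend(evaluate_case(manual, predict_masks(case), case.case_id))
        truth.update(error_truth_table(case, labels, organs=list(cfg.priors)))
        all_labels.extend(labels)
    decisions = decide_all(test_records, criteria)
    reports = evaluate_detection(decisions, truth)
    return {
        "validation_records": val_records,
        "stats": stats,
        "criteria": criteria,
        "test_records": test_records,
        "decisions": decisions,
        "truth": truth,
        "labels": all_labels,
        "reports": reports,
    }


def sensitivity_for_kind(
    decisions, labels, kind: str
) -> float:
    """Detection sensitivity restricted to one injected-error kind."""
    keys = {(l.case_id, l.slice_index, l.organ) for l in labels if l.kind == kind}
    relevant = [d for d in decisions if (d.case_id, d.slice_index, d.organ) in keys]
    if not relevant:
        return float("nan")
    return sum(d.verdict == "fail" for d in relevant) / len(relevant)


# ---------------------------------------------------------------------------
# Probability-map-driven benchmark (QA half only)
# ---------------------------------------------------------------------------


def detection_benchmark(
    cfg: PhantomConfig | None = None,
    n_validation: int = 20,
    n_test: int = 20,
    confidence: float = 0.95,
    blur_px: float = 0.5,
    k: float = 1.96,
    seed: int = 0,
) -> dict:
    """Phantom error-detection benchmark with synthetic probability maps.

    Generates clean validation cases and error-injected test cases, derives
    predicted contours from confidence-``confidence`` probability maps of the
    truth, fits per-organ criteria, and scores detection.  Returns the dict
    from the QA phase plus per-kind sensitivities.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    validation = [
        generate_case(cfg, rng, case_id=f"val-{i:03d}") for i in range(n_validation)
    ]
    test = [generate_case(cfg, rng, case_id=f"test-{i:03d}") for i in range(n_test)]

    prob_cache = {
        case.case_id: synth_probmaps(case.truth_masks, confidence, blur_px)
        for case in validation + test
    }

    def predict_masks(case: PhantomCase):
        return _predicted_masks_from_probmaps(prob_cache[case.case_id])

    result = _qa_phase(validation, test, predict_masks, cfg, k, rng)
    result["probmaps"] = prob_cache
    result["sensitivity_by_kind"] = {
        kind: sensitivity_for_kind(result["decisions"], result["labels"], kind)
        for kind in ("missing", "shifted", "deformed", "spurious")
    }
    return result


# ---------------------------------------------------------------------------
# Full phantom run with a trainable backend
# ---------------------------------------------------------------------------


def _cases_to_candidates(
    cases: Sequence[PhantomCase],
    masks_by_case: Mapping[str, Mapping[str, Sequence]],
) -> list[CandidateImage]:
    out = []
    for case in cases:
        masks = masks_by_case[case.case_id]
        for i, sl in enumerate(case.series):
            organ_masks = {
                organ: (m[i].grid if hasattr(m[i], "grid") else np.asarray(m[i], bool))
                for organ, m in masks.items()
            }
            out.append(CandidateImage(case.case_id, i, sl.pixel_grid, organ_masks))
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the full phantom strategy and write artifacts to ``cfg.out_dir``.

    Returns a dict with the trained model, criteria, decisions, detection
    reports, and the selection audit trail.  Non-training stages are
    bit-reproducible for a fixed config; training is seed-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    pcfg = cfg.phantom
    n_total = cfg.n_gold + cfg.n_candidate + cfg.n_validation + cfg.n_test
    cases = [generate_case(pcfg, rng, case_id=f"case-{i:03d}") for i in range(n_total)]
    gold = cases[: cfg.n_gold]
    trial = [c.case_id for c in cases[cfg.n_gold :]]
    manifest = split_assign(
        trial, cfg.n_validation, cfg.n_test, rng, n_candidate=cfg.n_candidate
    )
    manifest = pd.concat(
        [
            pd.DataFrame(
                [{"case_id": c.case_id, "set_assignment": "gold"} for c in gold]
            ),
            manifest,
        ],
        ignore_index=True,
    )
    if manifest["case_id"].duplicated().any():
        raise ValueError("set assignments are not disjoint by case_id")
    by_id = {c.case_id: c for c in cases}
    assign = dict(zip(manifest["case_id"], manifest["set_assignment"]))
    candidates = [by_id[c] for c in assign if assign[c] == "candidate"]
    validation = [by_id[c] for c in assign if assign[c] == "validation"]
    test = [by_id[c] for c in assign if assign[c] == "test"]

    # Step 2: initial model on the gold atlas (expert truth annotations).
    backend = ReferenceBackend(organs=list(pcfg.priors))
    gold_masks = {c.case_id: c.truth_masks for c in gold}
    gold_images = _cases_to_candidates(gold, gold_masks)
    model = backend.train(gold_images, cfg.train)

    # Step 3: active-learning fine-tuning on noisy candidate annotations.
    cand_masks = {}
    for case in candidates:
        masks, _ = _manual_masks_for_case(
            case, pcfg.observer_jitter_sd, rng, pcfg, with_errors=True
        )
        cand_masks[case.case_id] = masks
    pool = _cases_to_candidates(candidates, cand_masks)
    model, trail = run_loop(
        model, gold_images, pool, cfg.loop_iterations, cfg.loop_fraction, backend
    )

    # Steps 4-5: criteria from validation, detection on test.
    def predict_masks(case: PhantomCase):
        per_organ: dict[str, list[np.ndarray]] = {o: [] for o in pcfg.priors}
        for sl in case.series:
            maps = backend.predict(model, sl.pixel_grid)
            for organ in per_organ:
                per_organ[organ].append(np.asarray(maps[organ]) > 0.5)
        return per_organ

    qa_result = _qa_phase(validation, test, predict_masks, pcfg, cfg.k, rng)
    qa_result["sensitivity_by_kind"] = {
        kind: sensitivity_for_kind(qa_result["decisions"], qa_result["labels"], kind)
        for kind in ("missing", "shifted", "deformed", "spurious")
    }
    out = Path(cfg.out_dir)
    _write_artifacts(out, cfg, manifest, qa_result, trail)
    qa_result.update({"model": model, "audit_trail": trail, "manifest": manifest})
    return qa_result


# ---------------------------------------------------------------------------
# Artifact serialization
# ---------------------------------------------------------------------------


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def criteria_to_json(criteria) -> dict:
    return {
        organ: {
            "dsc_threshold": c.dsc_threshold,
            "hd_threshold": c.hd_threshold,
            "dsc_threshold_display": c.dsc_threshold_display,
            "hd_threshold_display": c.hd_threshold_display,
            "k": c.k,
            "n_slices": c.source_stats.n_slices,
            "dsc_mean": c.source_stats.dsc_mean,
            "dsc_sd": c.source_stats.dsc_sd,
            "hd_mean": c.source_stats.hd_mean,
            "hd_sd": c.source_stats.hd_sd,
        }
        for organ, c in criteria.items()
    }


def report_to_json(reports: Mapping[str, DetectionReport]) -> dict:
    return {
        name: {
            "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
            "ba": r.ba, "sensitivity": r.sensitivity,
            "specificity": r.specificity, "auc": r.auc,
        }
        for name, r in reports.items()
    }


def _write_artifacts(
    out: Path,
    cfg: RunConfig,
    manifest: pd.DataFrame,
    qa_result: dict,
    trail: list[SelectionRound],
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    metrics_dataframe(qa_result["validation_records"]).to_csv(
        out / "validation_metrics.csv", index=False
    )
    metrics_dataframe(qa_result["test_records"]).to_csv(
        out / "test_metrics.csv", index=False
    )
    (out / "criteria.json").write_text(
        json.dumps(criteria_to_json(qa_result["criteria"]), indent=1)
    )
    pd.DataFrame(
        [
            {
                "case_id": d.case_id,
                "slice_index": d.slice_index,
                "organ": d.organ,
                "dsc_pass": d.dsc_pass,
                "hd_pass": d.hd_pass,
                "verdict": d.verdict,
                "conformity_score": d.conformity_score,
            }
            for d in qa_result["decisions"]
        ]
    ).to_csv(out / "decisions.csv", index=False)
    (out / "detection_report.json").write_text(
        json.dumps(report_to_json(qa_result["reports"]), indent=1)
    )
    pd.DataFrame(
        [
            {
                "round": r.round_index,
                "image_id": s.image_id,
                "u": s.u,
                "dsc": s.dsc,
                "hd": s.hd,
                "has_contour": s.has_contour,
                "r": s.r,
                "selected": s.image_id in r.selected,
            }
            for r in trail
            for s in r.scores
        ]
    ).to_csv(out / "selection_audit.csv", index=False)
    run_manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "contourqa_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "rounds": [
            {
                "round": r.round_index,
                "selected": r.selected,
                "pool_before": r.pool_size_before,
                "pool_after": r.pool_size_after,
            }
            for r in trail
        ],
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
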