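"""Active-learning candidate scoring and the iterative fine-tuning loop.

Candidate slices from a clinical trial carry annotations of mixed quality, so
the loop must pick slices that are informative (high model uncertainty U) yet
reliably annotated.  The representativeness score combines both:

    R = U * DSC / HD,

where DSC and HD compare the model's prediction with the candidate's manual
annotation — a proxy for annotation quality given current model competence.
Slices without any contours (manual or predicted) take DSC = 1 and HD = 1,
so they are ranked purely by uncertainty.

Each round the remaining pool is stratified into slices with and without
manual contours, the top ``fraction`` of each stratum (by R) is moved into
the training set (contour-free picks become explicit all-background negative
examples), and the model is fine-tuned.  Two rounds at 30% consume about half
the pool (0.3 + 0.7 * 0.3 = 0.51).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .metrics import dice, hausdorff
from .uncertainty import image_uncertainty

#: Floor applied to HD in the representativeness ratio.  A perfect contour has
#: HD 0; flooring at one pixel keeps R finite and is consistent with the
#: HD = 1 convention used for contour-free images.
HD_EPSILON = 1.0


class LoopAborted(RuntimeError):
    """Trainer failure inside :func:`run_loop`; carries ``audit_trail``."""

    audit_trail: list["SelectionRound"]


@dataclass
class CandidateImage:
    """One candidate slice: the image plus its (possibly absent) annotation.

    ``manual_masks`` maps organ -> boolean mask; an empty dict or all-empty
    masks mean the slice carries no manual contours.
    """

    case_id: str
    slice_index: int
    image: np.ndarray
    manual_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def image_id(self) -> str:
        return f"{self.case_id}/{self.slice_index:04d}"

    @property
    def has_contour(self) -> bool:
        return any(np.asarray(m).any() for m in self.manual_masks.values())


@dataclass
class CandidateScore:
    case_id: str
    slice_index: int
    u: float
    dsc: float
    hd: float
    has_contour: bool
    r: float

    @property
    def image_id(self) -> str:
        return f"{self.case_id}/{self.slice_index:04d}"


@dataclass
class SelectionRound:
    round_index: int
    selected: list[str]
    fraction: float
    pool_size_before: int
    pool_size_after: int
    scores: list[CandidateScore] = field(default_factory=list)


def representativeness(
    u: float, dsc: float, hd: float, hd_epsilon: float = HD_EPSILON
) -> float:
    """R = U * DSC / max(HD, eps); all inputs must be non-negative."""
    if u < 0 or dsc < 0 or hd < 0:
        raise ValueError(f"negative input to representativeness: u={u}, dsc={dsc}, hd={hd}")
    if u > 0.5 + 1e-12 or dsc > 1.0 + 1e-12:
        raise ValueError(f"u must be in [0, 0.5] and dsc in [0, 1]; got u={u}, dsc={dsc}")
    return u * dsc / max(hd, hd_epsilon)


def score_candidate(
    candidate: CandidateImage,
    probability_maps: dict[str, np.ndarray],
    threshold: float = 0.5,
    hd_epsilon: float = HD_EPSILON,
) -> CandidateScore:
    """Score one candidate slice against the current model's prediction.

    Uncertainty is the mean of the per-organ-channel image uncertainties.
    Image-level DSC is the mean over organs where either mask is non-empty;
    image-level HD is the mean over the same organs with infinite per-organ
    values capped at the image diagonal, so a single missing organ degrades
    but does not annihilate the score.  If no organ has any contour in either
    the manual annotation or the prediction, DSC = HD = 1 by convention.
    """
    organs = list(probability_maps)
    u = float(np.mean([image_uncertainty(probability_maps[o]).u for o in organs]))
    diag = math.hypot(*candidate.image.shape)
    dscs, hds = [], []
    for organ in organs:
        pred = np.asarray(probability_maps[organ]) > threshold
        man = np.asarray(
            candidate.manual_masks.get(organ, np.zeros_like(pred)), dtype=bool
        )
        if not man.any() and not pred.any():
            continue
        dscs.append(dice(man, pred))
        hds.append(min(hausdorff(man, pred), diag))
    if dscs:
        dsc_img, hd_img = float(np.mean(dscs)), float(np.mean(hds))
    else:
        dsc_img, hd_img = 1.0, 1.0  # no contours anywhere: rank by uncertainty
    return CandidateScore(
        case_id=candidate.case_id,
        slice_index=candidate.slice_index,
        u=u,
        dsc=dsc_img,
        hd=hd_img,
        has_contour=candidate.has_contour,
        r=representativeness(u, dsc_img, hd_img, hd_epsilon),
    )


def select_round(
    pool: Sequence[CandidateScore], fraction: float, round_index: int = 0
) -> SelectionRound:
    """Pick the top ``fraction`` of each stratum (with/without contours) by R.

    Ties on R break by higher uncertainty, then by stable image-id order.
    Selected counts are ``floor(fraction * stratum size)`` per stratum; an
    empty stratum simply contributes nothing.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    selected: list[str] = []
    for stratum_flag in (True, False):
        stratum = [s for s in pool if s.has_contour is stratum_flag]
        stratum.sort(key=lambda s: (-s.r, -s.u, s.image_id))
        n_take = int(math.floor(fraction * len(stratum)))
        selected.extend(s.image_id for s in stratum[:n_take])
    return SelectionRound(
        round_index=round_index,
        selected=selected,
        fraction=fraction,
        pool_size_before=len(pool),
        pool_size_after=len(pool) - len(selected),
        scores=list(pool),
    )


def run_loop(
    initial_model,
    gold_set: Sequence[CandidateImage],
    candidate_pool: Sequence[CandidateImage],
    iterations: int,
    fraction: float,
    trainer,
    predict: Callable | None = None,
) -> tuple[object, list[SelectionRound]]:
    """Iterative select-and-fine-tune loop over a candidate pool.

    ``trainer`` implements the segmentation-backend contract
    (``predict(model, image) -> {organ: probability map}`` and
    ``fine_tune(model, extra, cfg) -> model``).  Per iteration: predict on the
    remaining pool, score every slice, select the top fraction per stratum,
    move the picks into the training set (with their manual annotations for
    the with-contour stratum, as all-background negatives otherwise) and
    fine-tune.  The audit trail records every score and selection; the loop
    is deterministic given the trainer's seed.  A trainer failure aborts the
    loop but preserves the trail gathered so far.
    """
    model = initial_model
    pool = list(candidate_pool)
    trail: list[SelectionRound] = []
    predict_fn = predict or trainer.predict
    for round_index in range(iterations):
        if not pool:
            break
        scores = []
        for cand in pool:
            maps = predict_fn(model, cand.image)
            grids = {o: (m.grid if hasattr(m, "grid") else m) for o, m in maps.items()}
            scores.append(score_candidate(cand, grids))
        round_result = select_round(scores, fraction, round_index)
        trail.append(round_result)
        chosen_ids = set(round_result.selected)
        chosen = [c for c in pool if c.image_id in chosen_ids]
        pool = [c for c in pool if c.image_id not in chosen_ids]
        extra = []
        for cand in chosen:
            if cand.has_contour:
                extra.append(cand)
            else:
                shape = cand.image.shape
                extra.append(
                    CandidateImage(
                        case_id=cand.case_id,
                        slice_index=cand.slice_index,
                        image=cand.image,
                        manual_masks={o: np.zeros(shape, dtype=bool) for o in cand.manual_masks} or {},
                    )
                )
        try:
            model = trainer.fine_tune(model, extra)
        except Exception as exc:
            err = LoopAborted(
                f"trainer failed in round {round_index}; audit trail preserved"
            )
            err.audit_trail = trail
            raise err from exc
    return model, trail
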