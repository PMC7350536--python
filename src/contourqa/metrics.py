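"""Slice-wise contour-accuracy metrics: Dice coefficient and Hausdorff distance.

Both metrics compare a manually drawn contour with a model-predicted one on a
single slice, as binary masks on the same pixel grid.

Empty-set conventions (fixed here, used everywhere downstream):

* both masks empty — the slice is trivially correct: DSC 1.0, HD 0.0;
* exactly one mask empty — a missing (or spurious) contour: DSC 0.0, HD
  ``inf``, so such slices can never satisfy a pass criterion.

The Hausdorff distance is the classical symmetric 100th-percentile variant,
computed between boundary-pixel centers in isotropic pixel-index units (no
spacing scaling), matching how per-organ thresholds are reported in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .io_rtstruct import BinaryMask


@dataclass
class SliceMetrics:
    """DSC and HD for one (slice, organ) pair."""

    case_id: str
    slice_index: int
    organ: str
    dsc: float
    hd_pixels: float
    manual_empty: bool
    predicted_empty: bool

    @property
    def trivially_correct(self) -> bool:
        return self.manual_empty and self.predicted_empty


@dataclass
class ValidationStats:
    """Per-organ sample mean and SD of the two metrics over validation slices."""

    organ: str
    dsc_mean: float
    dsc_sd: float
    hd_mean: float
    hd_sd: float
    n_slices: int


def _as_grid(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.grid
    return np.asarray(mask, dtype=bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``.

    Symmetric, in [0, 1].  Both masks empty returns 1.0 (trivially identical);
    exactly one empty returns 0.0.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    _check_shapes(ga, gb)
    na, nb = int(ga.sum()), int(gb.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (na + nb)


def boundary_pixels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """(row, col) coordinates of boundary pixels.

    A true pixel is boundary when at least one 4-neighbor is false or lies
    off the grid edge.
    """
    g = _as_grid(mask)
    if not g.any():
        return np.empty((0, 2), dtype=int)
    padded = np.pad(g, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(g & ~interior)


def hausdorff(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Symmetric Hausdorff distance between boundary-pixel centers, in pixels.

    Euclidean distance in index space.  Both masks empty returns 0.0; exactly
    one empty returns ``inf``.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    _check_shapes(ga, gb)
    ea, eb = not ga.any(), not gb.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return math.inf
    pa = boundary_pixels(ga).astype(float)
    pb = boundary_pixels(gb).astype(float)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def slice_metrics(
    manual: BinaryMask | np.ndarray,
    predicted: BinaryMask | np.ndarray,
    case_id: str = "",
    slice_index: int = 0,
    organ: str = "",
) -> SliceMetrics:
    """Compute both metrics and the empty-set flags for one slice."""
    gm, gp = _as_grid(manual), _as_grid(predicted)
    return SliceMetrics(
        case_id=case_id,
        slice_index=slice_index,
        organ=organ,
        dsc=dice(gm, gp),
        hd_pixels=hausdorff(gm, gp),
        manual_empty=not gm.any(),
        predicted_empty=not gp.any(),
    )


def evaluate_case(
    manual: Mapping[str, Sequence[BinaryMask | np.ndarray]],
    predicted: Mapping[str, Sequence[BinaryMask | np.ndarray]],
    case_id: str = "",
) -> list[SliceMetrics]:
    """Slice-by-slice metrics for every (slice, organ) of one case.

    ``manual`` and ``predicted`` map organ label to a per-slice sequence of
    masks.  An organ present in only one mapping is scored against empty
    masks.  Both-empty slices are kept, flagged as trivially correct.
    """
    organs = list(dict.fromkeys(list(manual) + list(predicted)))
    records: list[SliceMetrics] = []
    for organ in organs:
        man = manual.get(organ, [])
        pred = predicted.get(organ, [])
        n = max(len(man), len(pred))
        for idx in range(n):
            m = _as_grid(man[idx]) if idx < len(man) else None
            p = _as_grid(pred[idx]) if idx < len(pred) else None
            if m is None and p is not None:
                m = np.zeros_like(p)
            if p is None and m is not None:
                p = np.zeros_like(m)
            assert m is not None and p is not None
            records.append(slice_metrics(m, p, case_id, idx, organ))
    return records


def summarize_validation(
    records: Iterable[SliceMetrics], min_slices: int = 2
) -> dict[str, ValidationStats]:
    """Per-organ mean and sample SD of DSC and of the finite HD values.

    Only slices with a manual contour contribute (empty-manual slices carry
    no information about annotation accuracy).  Sample (n-1) SD.  Fewer than
    ``min_slices`` usable slices for an organ is an error naming the organ.
    """
    by_organ: dict[str, list[SliceMetrics]] = {}
    for rec in records:
        if rec.manual_empty:
            continue
        by_organ.setdefault(rec.organ, []).append(rec)
    stats: dict[str, ValidationStats] = {}
    for organ, recs in by_organ.items():
        if len(recs) < min_slices:
            raise ValueError(
                f"organ '{organ}' has only {len(recs)} usable validation "
                f"slice(s); at least {min_slices} required"
            )
        dscs = np.array([r.dsc for r in recs])
        hds = np.array([r.hd_pixels for r in recs])
        hds = hds[np.isfinite(hds)]
        if len(hds) < min_slices:
            raise ValueError(
                f"organ '{organ}' has fewer than {min_slices} finite HD values"
            )
        stats[organ] = ValidationStats(
            organ=organ,
            dsc_mean=float(dscs.mean()),
            dsc_sd=float(dscs.std(ddof=1)),
            hd_mean=float(hds.mean()),
            hd_sd=float(hds.std(ddof=1)),
            n_slices=len(recs),
        )
    if not stats:
        raise ValueError("no organ with manual contours in the records")
    return stats


def metrics_dataframe(records: Iterable[SliceMetrics]):
    """Tidy per-slice table (case, slice, organ, dsc, hd, flags)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "slice_index": r.slice_index,
                "organ": r.organ,
                "dsc": r.dsc,
                "hd_pixels": r.hd_pixels,
                "manual_empty": r.manual_empty,
                "predicted_empty": r.predicted_empty,
            }
            for r in records
        ]
    )
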