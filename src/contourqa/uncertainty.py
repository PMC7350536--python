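"""Image-level segmentation uncertainty from foreground-probability maps.

For a binary probability map the per-pixel confidence margin is
``max(p, 1 - p)``; the image uncertainty is the mean shortfall of that margin,

    U = (1/m) * sum_i (1 - max(p_i, 1 - p_i)),

over all m pixels.  U is 0 for a fully binarized map, 0.5 when every pixel
sits at p = 0.5 (the decision boundary), and is invariant under p -> 1 - p.
Images with high U are the ones the model is least confident about and hence
the most informative candidates for active-learning fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass
class ProbabilityMap:
    """Per-slice, per-organ foreground probability grid in [0, 1]."""

    grid: np.ndarray
    organ: str
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("probability grid must be 2D")
        _validate_probabilities(self.grid)


@dataclass
class UncertaintyScore:
    case_id: str
    slice_index: int
    organ: str
    u: float


def _validate_probabilities(grid: np.ndarray) -> None:
    if grid.size == 0:
        raise ValueError("empty probability map")
    lo, hi = float(grid.min()), float(grid.max())
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"probabilities outside [0, 1]: min={lo:g}, max={hi:g}")


def image_uncertainty(p: ProbabilityMap | np.ndarray) -> UncertaintyScore:
    """Mean per-pixel confidence shortfall of one probability map."""
    if isinstance(p, ProbabilityMap):
        grid, organ, case_id, idx = p.grid, p.organ, p.case_id, p.slice_index
    else:
        grid = np.asarray(p, dtype=float)
        _validate_probabilities(grid)
        organ, case_id, idx = "", "", 0
    u = float(np.mean(1.0 - np.maximum(grid, 1.0 - grid)))
    return UncertaintyScore(case_id=case_id, slice_index=idx, organ=organ, u=u)


def case_uncertainty(
    maps: Sequence[ProbabilityMap] | Mapping[str, Sequence[ProbabilityMap]],
    reduction: str = "mean",
) -> tuple[list[UncertaintyScore], float]:
    """Per-map uncertainty scores plus a case-level aggregate.

    ``maps`` may be a flat sequence or an organ -> per-slice mapping.
    ``reduction`` is the aggregate policy: "mean" (default) or "max".
    """
    if isinstance(maps, Mapping):
        flat = [m for per_organ in maps.values() for m in per_organ]
    else:
        flat = list(maps)
    if not flat:
        raise ValueError("case_uncertainty needs at least one probability map")
    scores = [image_uncertainty(m) for m in flat]
    values = np.array([s.u for s in scores])
    if reduction == "mean":
        aggregate = float(values.mean())
    elif reduction == "max":
        aggregate = float(values.max())
    else:
        raise ValueError(f"unknown reduction policy '{reduction}'")
    return scores, aggregate
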