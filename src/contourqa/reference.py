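"""Published per-organ validation statistics for thoracic OAR contour QA.

Reference slice-wise DSC and HD (pixel) statistics reported for a
multicenter lung-trial QA system, with the pass criteria printed alongside
them (DSC threshold at 2 decimals, HD threshold at 1 decimal).  They serve
as a worked input for the threshold arithmetic: criteria derived as
mean ∓ 1.96σ from the statistics should reproduce the printed thresholds at
display precision.

One documented discrepancy: the printed spinal-cord DSC criterion is 0.75,
whereas 0.86 − 1.96·0.06 = 0.7424 rounds to 0.74.  Every other printed
threshold matches the formula; this package always applies the formula and
never hard-codes the 0.75.
"""

from __future__ import annotations

from .metrics import ValidationStats

#: Slice-wise validation statistics per organ: (DSC mean, DSC SD, HD mean,
#: HD SD), HD in pixels.  The number of validation slices behind them was
#: not published (n_slices = 0 below marks it unknown).
REFERENCE_VALIDATION_STATS: dict[str, ValidationStats] = {
    "heart": ValidationStats("heart", 0.95, 0.03, 7.2, 4.1, 0),
    "esophagus": ValidationStats("esophagus", 0.69, 0.13, 4.6, 2.4, 0),
    "spinal_cord": ValidationStats("spinal_cord", 0.86, 0.06, 2.0, 0.7, 0),
    "lung_left": ValidationStats("lung_left", 0.96, 0.04, 7.3, 6.1, 0),
    "lung_right": ValidationStats("lung_right", 0.96, 0.04, 7.3, 4.7, 0),
}

#: Pass criteria as printed: organ -> (DSC lower bound, HD upper bound in px).
REFERENCE_PASS_CRITERIA: dict[str, tuple[float, float]] = {
    "heart": (0.89, 15.2),
    "esophagus": (0.44, 9.3),
    "spinal_cord": (0.75, 3.4),  # DSC value is the documented discrepancy
    "lung_left": (0.88, 19.3),
    "lung_right": (0.88, 16.5),
}
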