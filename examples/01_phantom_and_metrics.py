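"""Generate a synthetic thorax case and score an observer's contours.

Builds one phantom case (CT-like slices + ground-truth organ contours),
simulates a human observer's delineation with boundary jitter, and computes
the two slice-wise contour-accuracy metrics: Dice similarity coefficient
(DSC, overlap; 1 = identical) and Hausdorff distance (HD, worst boundary
deviation, in pixels).
"""

import numpy as np

from contourqa import (
    PhantomConfig,
    evaluate_case,
    generate_case,
    observer_contours,
    rasterize_structure_set,
)

cfg = PhantomConfig(slices_per_case=6)
rng = np.random.default_rng(0)
case = generate_case(cfg, rng, case_id="demo-000")

observed = observer_contours(case.truth_structures, jitter_sd=2.0, rng=rng)
manual = rasterize_structure_set(observed, case.series, organs=list(cfg.priors))
truth = {o: [m.grid for m in case.truth_masks[o]] for o in cfg.priors}

records = evaluate_case(manual, truth, case_id=case.case_id)
print(f"{'organ':<12} {'slice':>5} {'DSC':>6} {'HD(px)':>7}")
for rec in records:
    if rec.slice_index == 3:  # mid-thorax slice
        print(f"{rec.organ:<12} {rec.slice_index:>5} {rec.dsc:>6.3f} {rec.hd_pixels:>7.2f}")

# Large organs (lungs, heart) keep DSC near 1 under observer jitter; small
# organs (esophagus, cord) lose more overlap per pixel of boundary noise but
# keep a tight HD — the reason the QA pass rule accepts either criterion.
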