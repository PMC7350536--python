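"""Rank candidate slices by uncertainty-weighted representativeness.

Scores a pool of candidate slices the way the active-learning loop does:
each slice gets an uncertainty U (mean confidence shortfall of the model's
probability maps), a DSC/HD agreement between model prediction and the
slice's manual annotation, and the composite representativeness
R = U * DSC / HD.  The top 30% of each stratum (with / without contours) is
selected.  Slices with corrupted annotations get low R, so selection favors
informative AND well-annotated slices.
"""

import numpy as np

from contourqa import PhantomConfig, generate_case, select_round, synth_probmaps
from contourqa.active_learning import CandidateImage, score_candidate

cfg = PhantomConfig(slices_per_case=8)
rng = np.random.default_rng(1)
case = generate_case(cfg, rng, "pool-000")

scores = []
for i in range(case.n_slices):
    manual = {o: case.truth_masks[o][i].grid.copy() for o in cfg.priors}
    corrupted = i % 3 == 2
    if corrupted:  # every third slice: heart annotation shifted grossly
        manual["heart"] = np.roll(manual["heart"], 9, axis=1)
    maps = synth_probmaps(
        {o: [case.truth_masks[o][i]] for o in cfg.priors},
        confidence=0.85,
        blur_px=1.0,
    )
    cand = CandidateImage(case.case_id, i, case.series[i].pixel_grid, manual)
    s = score_candidate(cand, {o: maps[o][0] for o in cfg.priors})
    scores.append(s)
    tag = "corrupted" if corrupted else ""
    print(
        f"slice {i}: U={s.u:.3f}  DSC={s.dsc:.3f}  HD={s.hd:5.2f}  "
        f"R={s.r:.4f}  {tag}"
    )

chosen = select_round(scores, fraction=0.3)
print("selected for fine-tuning:", chosen.selected)
# The selected slices are the highest-R ones; corrupted annotations rank low
# because the model's prediction disagrees with them (low DSC, high HD).
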