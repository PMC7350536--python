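"""End-to-end phantom run: train, actively fine-tune, fit criteria, detect.

The full five-step strategy with the trainable reference backend: (1) split
phantom cases into gold / candidate / validation / test sets, (2) train on
the gold set, (3) run two 30% active-learning selection rounds over the
candidate pool (noisy annotations), (4) fit per-organ pass criteria on the
validation set, (5) flag erroneous test contours and score the detection.
Artifacts (criteria, metrics, decisions, audit trail) land in the run
directory.
"""

from contourqa import PhantomConfig, RunConfig, run_all
from contourqa.segmentation import TrainConfig

cfg = RunConfig(
    phantom=PhantomConfig(slices_per_case=6),
    n_gold=4,
    n_candidate=8,
    n_validation=4,
    n_test=4,
    train=TrainConfig(epochs=8, seed=0),
    loop_fraction=0.3,
    loop_iterations=2,
    seed=7,
    out_dir="scratch/example_run",
)
result = run_all(cfg)

for r in result["audit_trail"]:
    print(
        f"selection round {r.round_index}: picked {len(r.selected)} of "
        f"{r.pool_size_before} pool slices"
    )
overall = result["reports"]["overall"]
print(
    f"test-set error detection: BA={overall.ba:.3f} "
    f"SEN={overall.sensitivity:.3f} SPE={overall.specificity:.3f}"
)
print("artifacts written to", cfg.out_dir)
# Two rounds at 30% of the remaining pool consume about half the candidates;
# the audit trail in selection_audit.csv records every score behind them.
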