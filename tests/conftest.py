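from __future__ import annotations

import numpy as np
import pytest

from contourqa.active_learning import CandidateImage
from contourqa.phantom import PhantomConfig, generate_case, generate_cases
from contourqa.segmentation import ReferenceBackend, TrainConfig


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    return PhantomConfig(n_cases=2, slices_per_case=6, seed=11)


@pytest.fixture(scope="session")
def phantom_case(small_cfg) -> object:
    return generate_case(small_cfg, np.random.default_rng(small_cfg.seed), "fix-000")


def cases_to_candidates(cases, organs) -> list[CandidateImage]:
    out = []
    for case in cases:
        for i, sl in enumerate(case.series):
            out.append(
                CandidateImage(
                    case.case_id,
                    i,
                    sl.pixel_grid,
                    {o: case.truth_masks[o][i].grid for o in organs},
                )
            )
    return out


@pytest.fixture(scope="session")
def trained_backend(small_cfg):
    """A reference backend trained on 48 phantom slices (shared across tests)."""
    cfg = PhantomConfig(n_cases=8, slices_per_case=8, seed=3)
    cases = generate_cases(cfg)
    organs = list(cfg.priors)
    train = cases_to_candidates(cases[:6], organs)[:48]
    held_out = cases_to_candidates(cases[6:], organs)
    backend = ReferenceBackend(organs=organs)
    model = backend.train(train, TrainConfig(epochs=20, seed=0))
    return backend, model, held_out
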