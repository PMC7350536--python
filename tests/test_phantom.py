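"""Phantom generator: geometry invariants, observer noise, error injection."""

from __future__ import annotations

import math

import numpy as np
import pytest

from contourqa.io_rtstruct import rasterize_structure_set
from contourqa.metrics import dice, evaluate_case
from contourqa.phantom import (
    ErrorLabel,
    PhantomConfig,
    generate_case,
    inject_errors,
    observer_contours,
    synth_probmaps,
)
from contourqa.uncertainty import image_uncertainty


class TestGenerateCase:
    def test_organ_masks_never_overlap(self, phantom_case, small_cfg):
        organs = list(small_cfg.priors)
        for i in range(phantom_case.n_slices):
            total = sum(phantom_case.truth_masks[o][i].grid.sum() for o in organs)
            union = np.zeros_like(phantom_case.truth_masks[organs[0]][i].grid)
            for o in organs:
                union |= phantom_case.truth_masks[o][i].grid
            assert union.sum() == total

    def test_same_seed_identical_output(self, small_cfg):
        a = generate_case(small_cfg, np.random.default_rng(9), "x")
        b = generate_case(small_cfg, np.random.default_rng(9), "x")
        for sa, sb in zip(a.series, b.series):
            np.testing.assert_array_equal(sa.pixel_grid, sb.pixel_grid)
        for o in small_cfg.priors:
            for ma, mb in zip(a.truth_masks[o], b.truth_masks[o]):
                np.testing.assert_array_equal(ma.grid, mb.grid)

    def test_esophagus_smaller_than_heart_where_both_present(self, phantom_case):
        for eso, heart in zip(
            phantom_case.truth_masks["esophagus"], phantom_case.truth_masks["heart"]
        ):
            if heart.area_pixels() and eso.area_pixels():
                assert eso.area_pixels() < heart.area_pixels()

    def test_forced_overlap_raises(self, rng):
        from contourqa.phantom import DEFAULT_PRIORS, OrganPrior

        priors = dict(DEFAULT_PRIORS)
        priors["heart"] = OrganPrior((64.0, 58.0), (40.0, 40.0), hu=90.0)
        with pytest.raises(ValueError, match="force overlap"):
            generate_case(PhantomConfig(priors=priors), rng, "bad")


class TestObserverContours:
    def test_zero_jitter_reproduces_truth_exactly(self, phantom_case, rng, small_cfg):
        observed = observer_contours(phantom_case.truth_structures, 0.0, rng)
        masks = rasterize_structure_set(
            observed, phantom_case.series, organs=list(small_cfg.priors)
        )
        for organ in small_cfg.priors:
            for got, truth in zip(masks[organ], phantom_case.truth_masks[organ]):
                assert dice(got, truth) == 1.0

    def test_one_pixel_jitter_keeps_lung_dsc_high(self, phantom_case, rng, small_cfg):
        observed = observer_contours(phantom_case.truth_structures, 1.0, rng)
        masks = rasterize_structure_set(
            observed, phantom_case.series, organs=["lung_left", "lung_right"]
        )
        for organ in ("lung_left", "lung_right"):
            for got, truth in zip(masks[organ], phantom_case.truth_masks[organ]):
                if truth.area_pixels():
                    assert dice(got, truth) > 0.95

    def test_mean_dsc_non_increasing_in_jitter(self, phantom_case, small_cfg):
        means = []
        for jitter in (0.0, 1.0, 2.5, 5.0):
            observed = observer_contours(
                phantom_case.truth_structures, jitter, np.random.default_rng(4)
            )
            masks = rasterize_structure_set(
                observed, phantom_case.series, organs=list(small_cfg.priors)
            )
            scores = [
                dice(got, truth)
                for organ in small_cfg.priors
                for got, truth in zip(masks[organ], phantom_case.truth_masks[organ])
                if truth.area_pixels()
            ]
            means.append(float(np.mean(scores)))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestInjectErrors:
    def test_zero_rate_is_identity(self, phantom_case, rng, small_cfg):
        cfg = PhantomConfig(error_rate=0.0)
        corrupted, labels = inject_errors(
            phantom_case.truth_structures, cfg, rng, phantom_case
        )
        assert labels == []
        for organ, polys in phantom_case.truth_structures.contours.items():
            assert len(corrupted.contours[organ]) == len(polys)
            for a, b in zip(polys, corrupted.contours[organ]):
                np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_seeded_error_count_is_binomial_scale(self):
        # ~10% of (slice, organ) samples over many cases
        cfg = PhantomConfig(n_cases=20, slices_per_case=10, error_rate=0.1, seed=2)
        rng = np.random.default_rng(99)
        total_samples = 0
        total_errors = 0
        for i in range(cfg.n_cases):
            case = generate_case(cfg, rng, f"e-{i}")
            _, labels = inject_errors(case.truth_structures, cfg, rng, case)
            # samples eligible for corruption: populated plus heart-absent slices
            total_samples += sum(
                len(case.truth_structures.polygons_on(o, sl.z_position_mm, 1.5)) > 0
                or o == "heart"
                for o in cfg.priors
                for sl in case.series
            )
            total_errors += len(labels)
        rate = total_errors / total_samples
        assert 0.07 < rate < 0.13

    def test_labels_consistent_with_corruption(self, phantom_case, small_cfg):
        cfg = PhantomConfig(error_rate=0.3)
        corrupted, labels = inject_errors(
            phantom_case.truth_structures, cfg, np.random.default_rng(1), phantom_case
        )
        labeled = {(l.slice_index, l.organ) for l in labels}
        man = rasterize_structure_set(
            corrupted, phantom_case.series, organs=list(small_cfg.priors)
        )
        for organ in small_cfg.priors:
            for i in range(phantom_case.n_slices):
                same = np.array_equal(
                    man[organ][i].grid, phantom_case.truth_masks[organ][i].grid
                )
                if (i, organ) in labeled:
                    assert not same, (i, organ)
                else:
                    assert same, (i, organ)

    def test_missing_error_yields_zero_dsc_infinite_hd(self, phantom_case, small_cfg):
        cfg = PhantomConfig(error_rate=1.0, error_mix={"missing": 1.0})
        corrupted, labels = inject_errors(
            phantom_case.truth_structures, cfg, np.random.default_rng(0), phantom_case
        )
        assert all(l.kind in ("missing",) for l in labels)
        man = rasterize_structure_set(
            corrupted, phantom_case.series, organs=list(small_cfg.priors)
        )
        truth = {
            o: [m.grid for m in phantom_case.truth_masks[o]] for o in small_cfg.priors
        }
        records = evaluate_case(man, truth, "c")
        flagged = {(l.slice_index, l.organ) for l in labels}
        for r in records:
            if (r.slice_index, r.organ) in flagged:
                assert r.dsc == 0.0 and math.isinf(r.hd_pixels)

    def test_spurious_contour_lands_on_empty_truth_slice(self, phantom_case):
        cfg = PhantomConfig(error_rate=1.0, error_mix={"spurious": 1.0})
        corrupted, labels = inject_errors(
            phantom_case.truth_structures, cfg, np.random.default_rng(0), phantom_case
        )
        assert labels, "heart is absent on edge slices, so spurious must occur"
        for l in labels:
            assert l.kind == "spurious"
            truth = phantom_case.truth_masks[l.organ][l.slice_index]
            assert truth.area_pixels() == 0
            z = phantom_case.series[l.slice_index].z_position_mm
            assert corrupted.polygons_on(l.organ, z, 1.5)

    def test_label_invariant_none_iff_zero_magnitude(self):
        with pytest.raises(ValueError):
            ErrorLabel("c", 0, "heart", "none", 1.0)
        with pytest.raises(ValueError):
            ErrorLabel("c", 0, "heart", "missing", 0.0)


class TestSynthProbmaps:
    def test_full_confidence_no_blur_gives_zero_uncertainty(self, phantom_case):
        maps = synth_probmaps(phantom_case.truth_masks, confidence=1.0, blur_px=0.0)
        u = image_uncertainty(maps["heart"][2]).u
        assert u == 0.0

    def test_uniform_margin_confidence_gives_exact_uncertainty(self, phantom_case):
        maps = synth_probmaps(phantom_case.truth_masks, confidence=0.9, blur_px=0.0)
        for organ_maps in maps.values():
            for grid in organ_maps:
                assert image_uncertainty(grid).u == pytest.approx(0.1)

    def test_uncertainty_decreases_with_confidence(self, phantom_case):
        us = []
        for conf in (0.7, 0.8, 0.95):
            maps = synth_probmaps(phantom_case.truth_masks, conf, blur_px=0.5)
            us.append(image_uncertainty(maps["lung_left"][2]).u)
        assert us[0] > us[1] > us[2]

    def test_half_confidence_rejected(self, phantom_case):
        with pytest.raises(ValueError, match="confidence"):
            synth_probmaps(phantom_case.truth_masks, confidence=0.5)
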