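"""Slow-conduction classification, 4-connected components, region outcomes."""

import numpy as np
import pytest

from ommap.preprocess import PixelMask
from ommap.regions import (
    SLOW,
    ScMap,
    classify_slow,
    connected_components,
    region_report,
    run_pipeline,
)
from ommap.velocity import CvMap


def _cv_from_speeds(speed):
    """Build a CvMap directly from a speed grid (NaN = invalid)."""
    speed = np.asarray(speed, dtype=float)
    valid = np.isfinite(speed)
    with np.errstate(invalid="ignore"):
        vx = np.where(valid, speed, np.nan)
    vy = np.zeros_like(speed)
    vy[~valid] = np.nan
    reason = np.where(valid, 0, 1).astype(np.uint8)
    return CvMap(vx=vx, vy=vy, speed=speed.copy(), valid=valid, reason=reason)


def _sc_from_bool(slow):
    slow = np.asarray(slow, dtype=bool)
    state = np.where(slow, SLOW, 1).astype(np.int8)
    return ScMap(state=state, threshold_mps=0.2, pixel_size_mm=0.17)


def brute_force_components(slow):
    """Exhaustive 4-connectivity flood fill, for cross-checking."""
    slow = np.asarray(slow, dtype=bool)
    labels = np.zeros(slow.shape, dtype=int)
    sizes = []
    nxt = 0
    for r0, c0 in np.argwhere(slow):
        if labels[r0, c0]:
            continue
        nxt += 1
        stack, count = [(int(r0), int(c0))], 0
        labels[r0, c0] = nxt
        while stack:
            r, c = stack.pop()
            count += 1
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < slow.shape[0]
                    and 0 <= cc < slow.shape[1]
                    and slow[rr, cc]
                    and not labels[rr, cc]
                ):
                    labels[rr, cc] = nxt
                    stack.append((rr, cc))
        sizes.append(count)
    return labels, sizes


class TestClassifySlow:
    def test_strict_threshold_boundary(self):
        cv = _cv_from_speeds([[0.19, 0.20], [0.21, 0.1999999]])
        sc = classify_slow(cv, 0.2)
        assert bool(sc.slow[0, 0]) and bool(sc.slow[1, 1])
        assert bool(sc.normal[0, 1]) and bool(sc.normal[1, 0])

    def test_uniform_fast_map_has_no_slow_pixels(self):
        sc = classify_slow(_cv_from_speeds(np.full((10, 10), 0.5)), 0.2)
        assert not sc.slow.any()

    def test_invalid_pixels_excluded(self):
        speed = np.full((5, 5), 0.5)
        speed[2, 2] = np.nan
        sc = classify_slow(_cv_from_speeds(speed), 0.2)
        assert bool(sc.excluded[2, 2])

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            classify_slow(_cv_from_speeds(np.full((4, 4), np.nan)), 0.2)

    def test_percent_sc_monotone_in_threshold(self, rng):
        speed = rng.uniform(0.05, 0.6, size=(30, 30))
        cv = _cv_from_speeds(speed)
        fractions = []
        for thr in (0.1, 0.2, 0.3, 0.4):
            sc = classify_slow(cv, thr)
            labels, _ = connected_components(sc)
            fractions.append(region_report(labels).percent_sc)
        assert (np.diff(fractions) >= 0).all()


class TestConnectedComponents:
    def test_documented_example_grid(self):
        slow = np.zeros((4, 4), dtype=bool)
        for rc in [(0, 0), (0, 1), (1, 1), (0, 3), (1, 3), (3, 0), (3, 3)]:
            slow[rc] = True
        _, sizes = connected_components(_sc_from_bool(slow))
        assert sorted(sizes) == [1, 1, 2, 3]
        _, oracle_sizes = brute_force_components(slow)
        assert sorted(oracle_sizes) == sorted(sizes)

    def test_diagonal_touch_is_two_components(self):
        slow = np.zeros((3, 3), dtype=bool)
        slow[0, 0] = slow[1, 1] = True
        _, sizes = connected_components(_sc_from_bool(slow))
        assert sizes == [1, 1]

    def test_all_slow_grid_is_one_component(self):
        _, sizes = connected_components(_sc_from_bool(np.ones((7, 9), dtype=bool)))
        assert sizes == [63]

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(200):
            slow = rng.random((20, 20)) < rng.uniform(0.2, 0.7)
            labels, sizes = connected_components(_sc_from_bool(slow))
            oracle_labels, oracle_sizes = brute_force_components(slow)
            assert sorted(sizes) == sorted(oracle_sizes)
            # identical partition, independent of label numbering
            assert (labels > 0).sum() == (oracle_labels > 0).sum()
            for lab in range(1, max(sizes, default=0) and labels.max() + 1):
                members = labels == lab
                if members.any():
                    assert len(np.unique(oracle_labels[members])) == 1


class TestRegionReport:
    def test_ten_pixel_component_area(self):
        slow = np.zeros((10, 10), dtype=bool)
        slow[2, 0:10] = True  # one 10-pixel strip
        labels, _ = connected_components(_sc_from_bool(slow))
        rep = region_report(labels, pixel_area_mm2=0.0289)
        assert rep.component_areas_mm2 == [pytest.approx(0.289)]

    def test_counting_rule_and_mean_area(self):
        # components of sizes 3, 2, 1, 1: only the first two are counted
        slow = np.zeros((4, 4), dtype=bool)
        for rc in [(0, 0), (0, 1), (1, 1), (0, 3), (1, 3), (3, 0), (3, 3)]:
            slow[rc] = True
        labels, _ = connected_components(_sc_from_bool(slow))
        rep = region_report(labels, pixel_area_mm2=0.0289)
        assert rep.n_components == 2
        assert sorted(rep.component_areas_mm2) == [
            pytest.approx(2 * 0.0289),
            pytest.approx(3 * 0.0289),
        ]
        assert rep.mean_area_mm2 == pytest.approx(2.5 * 0.0289)
        # single-pixel components still count toward the SC percentage
        assert rep.percent_sc == pytest.approx(100.0 * 7 / 16)

    def test_no_slow_pixels_mean_area_undefined(self):
        labels = np.zeros((5, 5), dtype=int)
        rep = region_report(labels)
        assert rep.percent_sc == 0.0
        assert rep.n_components == 0
        assert np.isnan(rep.mean_area_mm2)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            region_report(np.zeros((4, 4), dtype=int), roi=np.zeros((4, 4), dtype=bool))

    def test_label_permutation_invariance(self, rng):
        slow = rng.random((15, 15)) < 0.4
        labels, _ = connected_components(_sc_from_bool(slow))
        perm = np.concatenate([[0], rng.permutation(np.arange(1, labels.max() + 1))])
        relabeled = perm[labels]
        rep1 = region_report(labels)
        rep2 = region_report(relabeled)
        assert rep1.percent_sc == rep2.percent_sc
        assert rep1.n_components == rep2.n_components
        assert sorted(rep1.component_areas_mm2) == sorted(rep2.component_areas_mm2)


class TestRunPipeline:
    def test_two_disjoint_slow_patches_found(self, small_config):
        from ommap.synthetic import Patch, SceneSpec, make_movie

        spec = SceneSpec(
            grid_rows=40, grid_cols=40, n_frames=600, noise_sd=0.0, drift_per_s=0.0,
            patches=(
                Patch(kind="rect", speed_mps=0.08, r0=6, r1=16, c0=14, c1=26),
                Patch(kind="rect", speed_mps=0.08, r0=26, r1=36, c0=14, c1=26),
            ),
            source="left", seed=1,
        )
        movie, truth = make_movie(spec)
        assert truth.component_count == 2
        res = run_pipeline(movie, small_config)
        assert res.report.n_components == 2

    def test_pipeline_deterministic(self, patch_movie, small_config):
        movie, _ = patch_movie
        rep1 = run_pipeline(movie, small_config).report
        rep2 = run_pipeline(movie, small_config).report
        assert rep1.to_dict() == rep2.to_dict()

    def test_plane_wave_has_zero_percent_sc(self, plane_movie, small_config):
        movie, _ = plane_movie
        assert run_pipeline(movie, small_config).report.percent_sc == 0.0
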