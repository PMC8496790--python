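"""Synthetic scene generator: front propagation, ground truth, study tables."""

import numpy as np
import pandas as pd
import pytest

from ommap.config import default_config
from ommap.regions import run_pipeline
from ommap.study_stats import estimate_icc
from ommap.synthetic import (
    EffectSpec,
    Patch,
    SceneSpec,
    StudyDesign,
    eikonal_travel_time,
    make_movie,
    make_study_table,
)


class TestFrontPropagation:
    def test_plane_wave_lat_linear_in_column(self, plane_movie, plane_scene):
        _, truth = plane_movie
        lat = truth.lat_ms
        # every column activates simultaneously; consecutive columns are
        # pixel_size / speed apart
        step = plane_scene.pixel_size_mm / plane_scene.base_speed_mps
        col_times = lat[:, 1:] - lat[:, :-1]
        np.testing.assert_allclose(col_times, step, atol=1e-9)
        np.testing.assert_allclose(lat.std(axis=0), 0.0, atol=1e-9)

    def test_point_source_matches_euclidean_oracle(self):
        # uniform medium: first-arrival time is distance / speed exactly;
        # the discrete front may lag by at most ~1 pixel of travel time
        speed = np.full((50, 50), 0.4)
        src = np.zeros((50, 50), dtype=bool)
        src[25, 25] = True
        t = eikonal_travel_time(speed, 0.17, src)
        rr, cc = np.mgrid[0:50, 0:50]
        exact = np.hypot(rr - 25, cc - 25) * 0.17 / 0.4
        one_px_ms = 0.17 / 0.4
        assert np.abs(t - exact).max() < one_px_ms

    def test_lat_monotone_with_distance_in_uniform_scene(self):
        speed = np.full((40, 40), 0.5)
        src = np.zeros((40, 40), dtype=bool)
        src[20, 20] = True
        t = eikonal_travel_time(speed, 0.17, src)
        # exactly monotone along rays from the source
        assert (np.diff(t[20, 20:]) > 0).all()
        assert (np.diff(t[20:, 20]) > 0).all()
        assert (np.diff(np.diagonal(t)[20:]) > 0).all()
        # monotone with Euclidean distance up to sub-pixel discretization
        rr, cc = np.mgrid[0:40, 0:40]
        d = np.hypot(rr - 20, cc - 20)
        order = np.argsort(d.ravel())
        binned = pd.Series(t.ravel()[order]).groupby(np.round(d.ravel()[order], 3)).mean()
        step_ms = 0.17 / 0.5
        assert (np.diff(binned.values) > -0.5 * step_ms).all()

    def test_block_line_forces_detour(self):
        spec_open = SceneSpec(grid_rows=30, grid_cols=30, n_frames=400, noise_sd=0.0,
                              drift_per_s=0.0, source="left", seed=0)
        # vertical block at column 15 with a gap at the bottom rows
        block = (((-0.5, 15.5), (24.5, 15.5)),)
        spec_blocked = SceneSpec(grid_rows=30, grid_cols=30, n_frames=400, noise_sd=0.0,
                                 drift_per_s=0.0, source="left", seed=0,
                                 block_segments=block)
        _, t_open = make_movie(spec_open)
        _, t_blk = make_movie(spec_blocked)
        behind = t_blk.lat_ms[2:10, 20:28]
        assert np.isfinite(behind).all()
        assert (behind > t_open.lat_ms[2:10, 20:28] + 1.0).all()

    def test_full_block_flags_unreached_pixels(self):
        block = (((-0.5, 15.5), (29.5, 15.5)),)  # spans the whole grid
        spec = SceneSpec(grid_rows=30, grid_cols=30, n_frames=400, noise_sd=0.0,
                         drift_per_s=0.0, source="left", block_segments=block)
        _, truth = make_movie(spec)
        assert truth.flagged[:, 20:].all()
        assert not truth.flagged[:, :10].any()

    def test_short_movie_flags_late_pixels_instead_of_truncating(self):
        spec = SceneSpec(grid_rows=40, grid_cols=40, n_frames=30,
                         base_speed_mps=0.05, noise_sd=0.0, drift_per_s=0.0, source="left")
        movie, truth = make_movie(spec)
        assert truth.flagged.any()
        assert movie.n_frames == 30

    def test_source_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(source=(200, 200)).validate()
        with pytest.raises(ValueError):
            SceneSpec(source="northwest").validate()


class TestGroundTruth:
    def test_sc_mask_is_exactly_thresholded_speed(self, rng):
        for _ in range(5):
            r0, c0 = rng.integers(0, 20, 2)
            spec = SceneSpec(
                grid_rows=32, grid_cols=32, n_frames=300, noise_sd=0.0, drift_per_s=0.0,
                patches=(
                    Patch(kind="rect", speed_mps=float(rng.uniform(0.05, 0.4)),
                          r0=int(r0), r1=int(r0 + 8), c0=int(c0), c1=int(c0 + 8)),
                ),
                source="top", seed=int(rng.integers(1 << 16)),
            )
            _, truth = make_movie(spec)
            expected = truth.tissue & (truth.speed_mps < truth.sc_threshold_mps)
            np.testing.assert_array_equal(truth.sc_mask, expected)

    def test_quarter_area_slow_patch_fraction(self):
        spec = SceneSpec(grid_rows=40, grid_cols=40, n_frames=300,
                         patches=(Patch(kind="rect", speed_mps=0.1, r0=10, r1=30, c0=10, c1=30),),
                         noise_sd=0.0, drift_per_s=0.0)
        _, truth = make_movie(spec)
        assert truth.sc_mask.mean() == pytest.approx(0.25)

    def test_component_areas_are_pixel_multiples(self, patch_movie, patch_scene):
        _, truth = patch_movie
        px_area = patch_scene.pixel_size_mm**2
        for a in truth.component_areas_mm2:
            assert a > 0
            assert (a / px_area) == pytest.approx(round(a / px_area))

    def test_same_seed_reproduces_movie(self):
        spec = SceneSpec(grid_rows=16, grid_cols=16, n_frames=100, noise_sd=0.1, seed=42)
        m1, _ = make_movie(spec)
        m2, _ = make_movie(spec)
        np.testing.assert_array_equal(m1.data, m2.data)


def test_noise_free_round_trip_recovers_plane_speed(plane_movie, plane_scene, small_config):
    """Full pipeline on a noise-free plane wave recovers the interior speed."""
    movie, _ = plane_movie
    res = run_pipeline(movie, small_config)
    interior = res.cv.speed[8:-8, 8:-8]
    assert np.isfinite(interior).all()
    assert abs(np.nanmean(interior) - plane_scene.base_speed_mps) / plane_scene.base_speed_mps < 0.05


class TestStudyTable:
    def test_default_design_with_one_missing_cell_yields_55_rows(self):
        design = StudyDesign(missing=(("persistentAF_2", "right", "S2"),))
        table = make_study_table(design)
        assert len(table) == 55
        assert table["animal"].nunique() == 7
        assert set(table["train"]) == {"S1", "S2"}

    def test_same_seed_gives_identical_tables(self):
        design = StudyDesign(seed=9)
        pd.testing.assert_frame_equal(make_study_table(design), make_study_table(design))

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            make_study_table(StudyDesign(n_animals_per_class={}))

    def test_unknown_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            make_study_table(StudyDesign(missing=(("animal_99", "top", "S1"),)))

    def test_icc_recovery_monte_carlo(self):
        """With animal_sd^2/(animal_sd^2+resid_sd^2) = 0.42, the mixed-model
        ICC estimate should average close to 0.42 over many tables."""
        total = 100.0
        animal_sd = float(np.sqrt(0.42 * total))
        resid_sd = float(np.sqrt(0.58 * total))
        iccs = []
        for rep in range(200):
            design = StudyDesign(animal_sd=animal_sd, resid_sd=resid_sd, seed=1000 + rep)
            iccs.append(estimate_icc(make_study_table(design), "percent_sc"))
        assert abs(np.mean(iccs) - 0.42) < 0.05
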