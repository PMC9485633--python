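"""Dictionary construction and two-stage matching tests."""

import numpy as np
import pytest

from multimapping.dictionary_matching import (
    Dictionary,
    DictionaryGrid,
    build_dictionary,
    estimate_global_b1,
    match_fine,
    match_pixel_matrix,
    match_signals,
)
from multimapping.sequence_model import TissueParams, simulate_multimapping_series

from conftest import MYO


@pytest.fixture(scope="module")
def small_dict(params_mm, schedule_mm):
    grid = DictionaryGrid(
        t1_values=(900.0, 1100.0, 1300.0),
        t2_values=(40.0, 50.0),
        b1_values=(1.0,),
    )
    return build_dictionary(grid, params_mm, schedule_mm)


@pytest.fixture(scope="module")
def b1_dict(params_mm, schedule_mm):
    grid = DictionaryGrid(
        t1_values=tuple(np.arange(900.0, 1700.0 + 1, 50.0)),
        t2_values=tuple(np.arange(30.0, 260.0 + 1, 10.0)),
        b1_values=(0.8, 0.85, 0.9, 0.95, 1.0, 1.05, 1.1),
    )
    return build_dictionary(grid, params_mm, schedule_mm)


class TestGridAndBuild:
    def test_non_increasing_axis_rejected(self):
        with pytest.raises(ValueError):
            DictionaryGrid((1000.0, 900.0), (50.0,), (1.0,))

    def test_entry_count_and_unit_norms(self, small_dict):
        assert small_dict.entries.shape[0] == 6
        np.testing.assert_allclose(
            np.linalg.norm(small_dict.entries, axis=1), 1.0, atol=1e-12
        )

    def test_entries_proportional_to_sequence_model(self, small_dict, params_mm, schedule_mm):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO).samples
        i = np.flatnonzero((small_dict.t1 == 1100.0) & (small_dict.t2 == 50.0))[0]
        np.testing.assert_allclose(
            small_dict.entries[i], series / np.linalg.norm(series), rtol=1e-12
        )

    def test_schedule_fingerprint_changes_with_rr(self, params_mm, schedule_mm):
        from multimapping.sequence_model import multimapping_schedule

        other = multimapping_schedule(
            (1000.0,) * 9 + (990.0,), params=params_mm
        )
        assert other.fingerprint() != schedule_mm.fingerprint()


class TestMatchSignals:
    def test_self_match_recovers_scale_and_score(self, small_dict):
        i = 3
        series = 2.7 * small_dict.entries[i] * small_dict.norms[i]
        res = match_signals(series, small_dict)
        assert (res.t1, res.t2, res.b1) == (
            small_dict.t1[i], small_dict.t2[i], small_dict.b1[i]
        )
        assert res.scale == pytest.approx(2.7, rel=1e-9)
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_positive_scaling_invariance(self, small_dict, params_mm, schedule_mm):
        rng = np.random.default_rng(3)
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO).samples
        noisy = series + rng.normal(0, 0.01, series.shape)
        base = match_signals(noisy, small_dict)
        for scale in (0.1, 7.3, 1234.0):
            res = match_signals(scale * noisy, small_dict)
            assert (res.t1, res.t2) == (base.t1, base.t2)

    def test_off_grid_t1_matches_nearest_millisecond(self, params_mm, schedule_mm):
        grid = DictionaryGrid(
            t1_values=tuple(np.arange(1095.0, 1106.0, 1.0)),
            t2_values=(50.0,),
        )
        d = build_dictionary(grid, params_mm, schedule_mm)
        series = simulate_multimapping_series(
            params_mm, schedule_mm, TissueParams(1100.4, 50.0)
        ).samples
        res = match_signals(series, d)
        assert res.t1 in (1100.0, 1101.0)

    def test_all_zero_pixel_flagged(self, small_dict):
        res = match_signals(np.zeros(10), small_dict)
        assert res.flagged and res.score == 0.0

    def test_exhaustive_scan_oracle_equality(self, params_mm, schedule_mm):
        """Optimized (chunked/deduplicated) matching equals a naive O(N) scan."""
        grid = DictionaryGrid(
            t1_values=tuple(np.linspace(300.0, 1900.0, 20)),
            t2_values=tuple(np.linspace(20.0, 280.0, 20)),
            b1_values=(0.8, 0.9, 1.0, 1.1, 1.2),
        )
        d = build_dictionary(grid, params_mm, schedule_mm)
        rng = np.random.default_rng(11)
        picks = rng.integers(0, d.entries.shape[0], 100)
        pixels = d.entries[picks] * d.norms[picks, None]
        pixels = pixels + rng.normal(0, 0.01, pixels.shape)
        idx, scores = match_pixel_matrix(pixels, d, chunk=517)  # odd chunk on purpose
        # naive oracle: full score matrix, first-occurrence argmax
        unit = pixels / np.linalg.norm(pixels, axis=1)[:, None]
        full = unit @ d.entries.T
        naive_idx = np.argmax(full, axis=1)
        np.testing.assert_array_equal(idx, naive_idx)
        np.testing.assert_allclose(scores, full[np.arange(100), naive_idx], rtol=1e-12)


class TestGlobalB1:
    def test_round_trip_b1_estimate(self, b1_dict, params_mm, schedule_mm):
        from multimapping.phantom import PhantomDefinition, make_phantom, septal_roi, simulate_acquisition
        from multimapping.psir import restore_polarity

        d = PhantomDefinition(b1=0.9)
        maps = make_phantom(d)
        series, sch = simulate_acquisition(
            maps, "multimapping", schedule=schedule_mm, params=params_mm, noise_sd=0.0
        )
        signed = restore_polarity(series)
        est = estimate_global_b1(signed.frames, septal_roi(d), b1_dict)
        assert abs(est - 0.9) <= 0.05 + 1e-9  # within one grid step

    def test_single_pixel_roi_returns_that_pixels_b1(self, b1_dict, params_mm, schedule_mm):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO, b1=0.85).samples
        frames = np.tile(series[:, None, None], (1, 3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        est = estimate_global_b1(frames, mask, b1_dict)
        single = match_signals(series, b1_dict)
        assert est == single.b1

    def test_degenerate_b1_grid_returns_unity(self, small_dict, params_mm, schedule_mm):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO).samples
        frames = series[:, None, None] * np.ones((1, 2, 2))
        est = estimate_global_b1(frames, np.ones((2, 2), bool), small_dict)
        assert est == 1.0

    def test_empty_roi_rejected(self, small_dict):
        with pytest.raises(ValueError):
            estimate_global_b1(np.zeros((10, 2, 2)), np.zeros((2, 2), bool), small_dict)


class TestMatchFine:
    def test_coarse_t1_step_rejected_without_override(self, params_mm, schedule_mm):
        grid = DictionaryGrid((1000.0, 1010.0), (50.0, 51.0))
        frames = np.zeros((10, 2, 2))
        with pytest.raises(ValueError, match="1 ms"):
            match_fine(frames, 1.0, grid, params_mm, schedule_mm)
        # explicit override allowed
        match_fine(frames, 1.0, grid, params_mm, schedule_mm, allow_coarse=True)

    def test_nonpositive_b1_rejected(self, params_mm, schedule_mm):
        grid = DictionaryGrid((1000.0, 1001.0), (50.0,))
        with pytest.raises(ValueError):
            match_fine(np.zeros((10, 2, 2)), 0.0, grid, params_mm, schedule_mm)

    def test_noiseless_on_grid_recovery_and_determinism(
        self, params_mm, schedule_mm, fine_dict_b1_1, fine_grid_reduced
    ):
        tissues = [(1100.0, 50.0), (1600.0, 250.0), (1400.0, 70.0)]
        frames = np.zeros((10, 1, 3))
        for j, (t1, t2) in enumerate(tissues):
            frames[:, 0, j] = simulate_multimapping_series(
                params_mm, schedule_mm, TissueParams(t1, t2)
            ).samples
        out1 = match_fine(frames, 1.0, fine_grid_reduced, params_mm, schedule_mm,
                          dictionary=fine_dict_b1_1)
        out2 = match_fine(frames, 1.0, fine_grid_reduced, params_mm, schedule_mm,
                          dictionary=fine_dict_b1_1)
        for j, (t1, t2) in enumerate(tissues):
            assert out1[0].data[0, j] == t1
            assert out1[1].data[0, j] == t2
        np.testing.assert_array_equal(out1[0].data, out2[0].data)
        np.testing.assert_array_equal(out1[1].data, out2[1].data)

    def test_masked_pixels_are_nan(self, params_mm, schedule_mm, fine_dict_b1_1, fine_grid_reduced):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO).samples
        frames = np.tile(series[:, None, None], (1, 2, 2))
        mask = np.array([[True, False], [False, False]])
        t1_map, _ = match_fine(frames, 1.0, fine_grid_reduced, params_mm, schedule_mm,
                               mask=mask, dictionary=fine_dict_b1_1)
        assert t1_map.data[0, 0] == 1100.0
        assert np.isnan(t1_map.data[1, 1])
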