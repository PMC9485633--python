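"""Bloch-simulation unit and property tests for the sequence engine."""

import numpy as np
import pytest

from multimapping.sequence_model import (
    AdiabaticPulseParams,
    MagnetizationState,
    PulseSequenceParams,
    TissueParams,
    apply_inversion,
    apply_t2prep,
    molli_schedule,
    multimapping_schedule,
    relax,
    simulate_bssfp_shot,
    simulate_hs_inversion,
    simulate_molli_series,
    simulate_multimapping_series,
    simulate_series,
    simulate_series_bulk,
    simulate_t2bssfp_series,
    t2bssfp_schedule,
)
from multimapping.reference_fitting import fit_molli

from conftest import MYO, naive_series_oracle


class TestElementaryOperators:
    @pytest.mark.parametrize(
        "mz, t1, duration, expected",
        [
            (-1.0, 1000.0, 693.1, 0.0),          # half-life of recovery from -1
            (1.0, 1000.0, 0.0, 1.0),             # zero duration is the identity
            (0.0, 500.0, 500.0, 1.0 - np.exp(-1.0)),
        ],
    )
    def test_relax_mz(self, mz, t1, duration, expected):
        state = MagnetizationState(mz=mz)
        out = relax(state, duration, TissueParams(t1, t1 / 10.0))
        assert out.mz == pytest.approx(expected, abs=1e-3)

    def test_relax_mxy_decay(self):
        state = MagnetizationState(mz=0.0, mxy=1.0)
        out = relax(state, 50.0, TissueParams(1000.0, 50.0))
        assert out.mxy == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_relax_rejects_negative_duration(self):
        with pytest.raises(ValueError):
            relax(MagnetizationState(mz=1.0), -1.0, MYO)

    @pytest.mark.parametrize(
        "mz, eff, expected",
        [(1.0, 1.0, -1.0), (1.0, 0.89, -0.89), (0.5, 0.89, -0.445)],
    )
    def test_inversion(self, mz, eff, expected):
        out = apply_inversion(MagnetizationState(mz=mz, mxy=0.3), eff)
        assert out.mz == pytest.approx(expected, rel=1e-12)
        assert out.mxy == 0.0

    @pytest.mark.parametrize("eff", [0.0, -0.5, 1.5])
    def test_inversion_rejects_bad_efficiency(self, eff):
        with pytest.raises(ValueError):
            apply_inversion(MagnetizationState(mz=1.0), eff)

    @pytest.mark.parametrize(
        "te, t2, expected",
        [(70.0, 70.0, np.exp(-1.0)), (0.0, 50.0, 1.0), (30.0, 50.0, np.exp(-0.6))],
    )
    def test_t2prep(self, te, t2, expected):
        out = apply_t2prep(MagnetizationState(mz=1.0), te, TissueParams(1100.0, t2))
        assert out.mz == pytest.approx(expected, rel=1e-12)
        assert out.mxy == 0.0

    def test_t2_longer_than_t1_warns_not_raises(self):
        with pytest.warns(UserWarning):
            TissueParams(50.0, 100.0)


class TestBssfpShot:
    def test_long_shot_reaches_closed_form_steady_state(self):
        # echo after ~600 pulses so the transient has decayed
        params = PulseSequenceParams(n_readout_lines=1200, flip_angle_deg=50.0)
        tissue = TissueParams(1000.0, 50.0)
        sample, _ = simulate_bssfp_shot(MagnetizationState.equilibrium(), params, tissue)
        alpha = np.deg2rad(50.0)
        ratio = tissue.t1 / tissue.t2
        closed = np.sin(alpha) / ((ratio + 1) - np.cos(alpha) * (ratio - 1))
        assert sample == pytest.approx(closed, rel=0.01)

    def test_driven_saturation_between_consecutive_shots(self, params_mm):
        state = MagnetizationState.equilibrium()
        s1, state = simulate_bssfp_shot(state, params_mm, MYO)
        s2, _ = simulate_bssfp_shot(state, params_mm, MYO)
        assert 0 < s2 < s1

    def test_shot_preserves_sign_of_entering_mz(self, params_mm):
        neg = MagnetizationState(mz=-0.8)
        sample, out = simulate_bssfp_shot(neg, params_mm, MYO)
        assert sample < 0
        assert out.mxy == 0.0

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            simulate_bssfp_shot(
                MagnetizationState.equilibrium(),
                PulseSequenceParams(n_readout_lines=1),
                MYO,
            )


class TestMultimappingSeries:
    def test_ten_samples_with_negative_inversion_beats(self, params_mm, schedule_mm):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO)
        assert len(series.samples) == 10
        assert series.samples[0] < 0 and series.samples[4] < 0
        assert np.all(np.diff(series.sample_times_ms) > 0)

    def test_t2prep_samples_strictly_decreasing(self, params_mm, schedule_mm):
        series = simulate_multimapping_series(params_mm, schedule_mm, MYO)
        s8, s9, s10 = series.samples[7:]
        assert s8 > s9 > s10 > 0

    def test_samples_scale_linearly_with_m0(self, params_mm, schedule_mm):
        s1 = simulate_multimapping_series(params_mm, schedule_mm, MYO, m0=1.0)
        s3 = simulate_multimapping_series(params_mm, schedule_mm, MYO, m0=3.0)
        np.testing.assert_allclose(s3.samples, 3.0 * s1.samples, rtol=1e-12)

    def test_samples_bounded_by_m0(self, params_mm, schedule_mm):
        for t1, t2 in [(300, 40), (1100, 50), (2000, 250)]:
            s = simulate_multimapping_series(params_mm, schedule_mm, TissueParams(t1, t2))
            assert np.all(np.abs(s.samples) <= 1.0)

    def test_wrong_event_pattern_rejected(self, params_mm):
        bad = t2bssfp_schedule(1000.0, params=params_mm)
        with pytest.raises(ValueError):
            simulate_multimapping_series(params_mm, bad, MYO)


class TestOracleEquivalence:
    """The vectorized engine must agree with a naive scalar per-TR loop."""

    @pytest.mark.parametrize("protocol", ["multimapping", "molli", "t2bssfp"])
    def test_engine_matches_naive_bloch_loop(self, protocol, params_mm, params_ref):
        rng = np.random.default_rng(42)
        for _ in range(7):
            t1 = rng.uniform(300.0, 2000.0)
            t2 = rng.uniform(20.0, min(300.0, t1))
            b1 = rng.uniform(0.6, 1.2)
            rr = rng.uniform(600.0, 1200.0)
            if protocol == "multimapping":
                params, sch = params_mm, multimapping_schedule(rr, params=params_mm)
            elif protocol == "molli":
                params, sch = params_ref, molli_schedule(rr, params=params_ref)
            else:
                params, sch = params_ref, t2bssfp_schedule(rr, params=params_ref)
            got = simulate_series(params, sch, TissueParams(t1, t2), b1=b1).samples
            want = naive_series_oracle(params, sch, t1, t2, b1)
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_bulk_engine_matches_single_tissue_calls(self, params_mm, schedule_mm):
        t1s = np.array([400.0, 1100.0, 1600.0])
        t2s = np.array([45.0, 50.0, 250.0])
        bulk = simulate_series_bulk(t1s, t2s, 0.9, params_mm, schedule_mm)
        for i in range(3):
            single = simulate_series(
                params_mm, schedule_mm, TissueParams(t1s[i], t2s[i]), b1=0.9
            ).samples
            np.testing.assert_allclose(bulk[i], single, rtol=1e-12)


class TestMolliSeries:
    def test_eight_samples_and_ti_structure(self, params_ref):
        sch = molli_schedule(1000.0, params=params_ref)
        series, tis = simulate_molli_series(params_ref, sch, MYO)
        assert len(series.samples) == 8
        # within each Look-Locker block TIs step by one R-R interval
        np.testing.assert_allclose(np.diff(tis[:5]), 1000.0, rtol=1e-9)
        np.testing.assert_allclose(np.diff(tis[5:]), 1000.0, rtol=1e-9)

    def test_apparent_t1_star_underestimates_t1(self, params_ref):
        sch = molli_schedule(1000.0, params=params_ref)
        series, tis = simulate_molli_series(params_ref, sch, MYO)
        fit = fit_molli(np.abs(series.samples), tis)
        assert fit.converged
        assert fit.t1_star < MYO.t1


class TestT2BssfpSeries:
    def test_te_labels(self, params_ref):
        sch = t2bssfp_schedule(1000.0, params=params_ref)
        series = simulate_t2bssfp_series(params_ref, sch, MYO)
        assert series.prep_labels == [
            "t2prep(0)", "t2prep(23)", "t2prep(46)", "t2prep(70)"
        ]
        assert len(series.samples) == 4

    def test_full_recovery_limit_is_pure_t2_decay(self):
        # the samples reflect pure T2prep decay in the limit where the shot
        # neither perturbs nor delays the prepared magnetization: weak
        # readout (1 deg), centre of k-space acquired first, no startup
        # ramp, and 16 s pauses so each image starts from equilibrium
        params = PulseSequenceParams.reference(
            flip_angle_deg=1.0, profile_order="low-high", n_startup=0
        )
        sch = t2bssfp_schedule(16000.0, params=params)
        series = simulate_t2bssfp_series(params, sch, MYO)
        ratio = series.samples[3] / series.samples[0]
        assert ratio == pytest.approx(np.exp(-70.0 / MYO.t2), rel=0.01)

    @pytest.mark.filterwarnings("ignore:T2=.*exceeds T1")
    def test_infinite_t2_gives_equal_samples(self):
        # long pauses remove saturation history; with no T2prep decay the
        # four samples are then identical
        params = PulseSequenceParams.reference()
        sch = t2bssfp_schedule(16000.0, params=params)
        tissue = TissueParams(1100.0, 1e9)
        series = simulate_t2bssfp_series(params, sch, tissue)
        assert np.ptp(series.samples) / np.abs(series.samples).max() < 1e-3


class TestAdiabaticInversion:
    def test_lossless_limit_approaches_unity(self):
        eff = simulate_hs_inversion(AdiabaticPulseParams(), TissueParams(1e9, 1e9))
        assert eff == pytest.approx(1.0, abs=0.01)

    def test_relaxation_during_pulse_lowers_efficiency(self):
        lossless = simulate_hs_inversion(AdiabaticPulseParams(), TissueParams(1e9, 1e9))
        myocardial = simulate_hs_inversion(AdiabaticPulseParams(), MYO)
        assert myocardial < lossless

    def test_sub_adiabatic_b1_degrades_inversion(self):
        full = simulate_hs_inversion(AdiabaticPulseParams(), MYO)
        half = simulate_hs_inversion(
            AdiabaticPulseParams(peak_b1_ut=13.5 / 2.0), MYO
        )
        assert half < full

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            AdiabaticPulseParams(duration_ms=0.0)
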