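"""Intrinsic electrophysiology feature extraction."""
import math

import numpy as np
import pytest

from pvseq.ephys import (
    AUX_NAMES,
    FEATURE_NAMES,
    FICurve,
    SweepSet,
    VoltageClampStep,
    ap_shape,
    attenuation,
    capacitance,
    chord_threshold,
    detect_aps,
    df_di,
    extract_features,
    firing_threshold,
    fit_logistic_fi,
    input_resistance,
    sag,
    series_resistance,
)
from pvseq.io import read_sweeps, write_sweeps
from pvseq.simulate import EphysSpec, SimulationConfig, simulate_sweeps

LN4 = math.log(4.0)


def _sweeps(**kwargs):
    cfg = SimulationConfig(ephys_spec=EphysSpec(**kwargs), seed=0)
    return simulate_sweeps(cfg, "cell"), cfg.ephys_spec


class TestPassive:
    def test_ohms_law_values(self):
        sweeps, _ = _sweeps(r_s_mohm=10.0, r_in_mohm=90.0, c_pf=100.0)
        assert series_resistance(sweeps) == pytest.approx(10.0, rel=0.02)
        assert input_resistance(sweeps) == pytest.approx(90.0, rel=0.02)

    @pytest.mark.parametrize("r_s,r_in,c", [
        (5.0, 60.0, 80.0), (10.0, 90.0, 100.0), (15.0, 200.0, 150.0), (20.0, 120.0, 250.0)])
    def test_rc_round_trip_grid(self, r_s, r_in, c):
        sweeps, _ = _sweeps(r_s_mohm=r_s, r_in_mohm=r_in, c_pf=c)
        assert series_resistance(sweeps) == pytest.approx(r_s, rel=0.02)
        assert input_resistance(sweeps) == pytest.approx(r_in, rel=0.02)
        assert capacitance(sweeps) == pytest.approx(c, rel=0.02)

    def test_raw_charge_closed_form(self):
        # synthetic transient: amplitude 500 pA, tau 2 ms -> Q = 1 pC; C_raw = Q/dV = 200 pF
        dt = 0.02
        t = np.arange(0, 120, dt)
        current = np.zeros_like(t)
        in_step = (t >= 10) & (t < 110)
        current[in_step] = 500.0 * np.exp(-(t[in_step] - 10) / 2.0)
        step = VoltageClampStep(5.0, 10.0, 110.0, t, current)
        sweeps = SweepSet(sampling_rate_hz=50_000.0, vc_step=step)
        assert capacitance(sweeps, correct_for_series=False) == pytest.approx(200.0, rel=0.01)

    def test_flat_trace_flagged(self):
        t = np.arange(0, 100, 0.05)
        step = VoltageClampStep(5.0, 10.0, 90.0, t, np.zeros_like(t))
        sweeps = SweepSet(sampling_rate_hz=20_000.0, vc_step=step)
        assert math.isnan(input_resistance(sweeps))


class TestSpikes:
    def test_template_spikes_all_detected(self):
        sweeps, spec = _sweeps(fmax_hz=80.0)
        step = sweeps.cc_steps[-1]
        aps = detect_aps(step.time_ms, step.voltage_mv)
        expected = round(spec.fmax_hz / (1 + math.exp(-(600 - spec.i0_pa) / spec.s_pa)) * 1.5)
        assert len(aps["onset_idx"]) == expected

    def test_flat_and_sag_traces_have_no_detections(self):
        sweeps, _ = _sweeps()
        for step in sweeps.cc_steps:
            if step.i_inj_pa <= 0:
                aps = detect_aps(step.time_ms, step.voltage_mv)
                assert len(aps["onset_idx"]) == 0


class TestFICurve:
    def test_chord_threshold_matches_closed_form(self):
        for fmax, i0, s in [(100.0, 200.0, 40.0), (150.0, 250.0, 60.0), (60.0, 80.0, 15.0)]:
            analytic = i0 - (5.0 / 3.0) * LN4 * s
            assert chord_threshold(fmax, i0, s) == pytest.approx(analytic, abs=1e-6)

    def test_exact_logistic_data_recovers_threshold(self):
        fmax, i0, s = 120.0, 220.0, 45.0
        i = np.arange(-100, 601, 25, dtype=float)
        f = fmax / (1 + np.exp(-(i - i0) / s))
        thr = firing_threshold(FICurve(i, f))
        assert thr == pytest.approx(i0 - (5 / 3) * LN4 * s, abs=0.1)

    def test_all_zero_frequencies_flagged(self):
        fi = FICurve(np.arange(5, dtype=float), np.zeros(5))
        assert math.isnan(firing_threshold(fi))

    def test_step_function_threshold_near_jump(self):
        i = np.arange(0, 501, 50, dtype=float)
        f = np.where(i >= 250, 90.0, 0.0)
        thr = firing_threshold(FICurve(i, f))
        assert 200.0 <= thr <= 300.0

    def test_df_di_on_exact_line(self):
        i = np.arange(0, 501, 50, dtype=float)
        f = np.maximum(0.0, 0.3 * (i - 50))
        assert df_di(FICurve(i, f)) == pytest.approx(0.3)

    def test_df_di_saturated_is_zero(self):
        i = np.arange(0, 501, 50, dtype=float)
        f = np.where(i >= 50, 70.0, 0.0)  # constant inside the window
        assert df_di(FICurve(i, f)) == pytest.approx(0.0)

    def test_df_di_from_sweeps_matches_exact_logistic_curve(self):
        # spike-count quantization must not distort the window slope much
        fmax, i0, s = 200.0, 260.0, 50.0
        sweeps, _ = _sweeps(fmax_hz=fmax, i0_pa=i0, s_pa=s)
        from pvseq.ephys import fi_curve
        measured = df_di(fi_curve(sweeps))
        i = np.arange(-150, 601, 50, dtype=float)
        exact = fmax / (1 + np.exp(-(i - i0) / s))
        counts = np.round(np.where(i > 0, exact, 0.0) * 1.5)  # spikes per 1.5 s step
        reference = df_di(FICurve(i, counts / 1.5))
        assert measured == pytest.approx(reference, rel=0.02)


class TestTrainAndShape:
    def test_attenuation_recovers_configured_decay(self):
        sweeps, _ = _sweeps(attenuation=1.25)
        assert attenuation(sweeps) == pytest.approx(1.25, rel=0.05)

    def test_equal_amplitudes_give_unity(self):
        sweeps, _ = _sweeps(attenuation=1.0)
        assert attenuation(sweeps) == pytest.approx(1.0, rel=0.02)

    def test_sag_round_trip(self):
        sweeps, _ = _sweeps(sag_mv=7.0)
        assert sag(sweeps) == pytest.approx(7.0, abs=0.5)

    def test_symmetric_triangle_shape_metrics(self):
        # symmetric template with trough at baseline: half-width = rise,
        # symmetry = 1/2, amplitude = configured peak height
        sweeps, _ = _sweeps(ap_rise_ms=0.4, ap_fall_ms=0.4, ap_trough_mv=0.0,
                            attenuation=1.0, ap_amp_mv=60.0)
        shape = ap_shape(sweeps)
        assert shape["ap_half_width_ms"] == pytest.approx(0.4, abs=0.06)
        assert shape["ap_symmetry"] == pytest.approx(0.5, abs=0.05)
        assert shape["ap_amplitude_mv"] == pytest.approx(60.0, rel=0.05)

    def test_fewer_than_three_aps_excluded(self):
        # rates low enough that no trace reaches three spikes
        sweeps, _ = _sweeps(fmax_hz=1.0)
        shape = ap_shape(sweeps)
        assert all(math.isnan(v) for v in shape.values())


class TestExtractFeatures:
    def test_exactly_ten_named_parameters(self):
        sweeps, _ = _sweeps()
        feats = extract_features(sweeps)
        core = feats.as_dict(include_aux=False)
        assert len(core) == 10
        assert set(core) == set(FEATURE_NAMES)

    def test_full_round_trip_with_ground_truth(self):
        sweeps, spec = _sweeps()
        feats = extract_features(sweeps)
        assert feats.input_resistance_mohm == pytest.approx(spec.r_in_mohm, rel=0.02)
        assert feats.series_resistance_mohm == pytest.approx(spec.r_s_mohm, rel=0.02)
        assert feats.capacitance_pf == pytest.approx(spec.c_pf, rel=0.02)
        assert feats.attenuation_ratio == pytest.approx(spec.attenuation, rel=0.05)
        assert feats.sag_mv == pytest.approx(spec.sag_mv, abs=0.5)
        assert np.isfinite(list(feats.as_dict().values())).all()

    def test_voltage_clamp_only_input(self):
        sweeps, _ = _sweeps()
        vc_only = SweepSet(sampling_rate_hz=sweeps.sampling_rate_hz,
                           vc_step=sweeps.vc_step, cc_steps=[])
        feats = extract_features(vc_only)
        assert np.isfinite([feats.input_resistance_mohm, feats.series_resistance_mohm,
                            feats.capacitance_pf]).all()
        active = ["firing_threshold_pa", "df_di_hz_per_pa", "attenuation_ratio",
                  "sag_mv", "ap_amplitude_mv", "ap_half_width_ms", "ap_symmetry"]
        assert all(math.isnan(getattr(feats, name)) for name in active)

    def test_dc_offset_invariance(self):
        sweeps, _ = _sweeps()
        shifted = SweepSet(
            sampling_rate_hz=sweeps.sampling_rate_hz,
            vc_step=sweeps.vc_step,
            cc_steps=[type(s)(s.i_inj_pa, s.onset_ms, s.offset_ms, s.time_ms,
                              s.voltage_mv + 13.0) for s in sweeps.cc_steps])
        f0 = extract_features(sweeps).as_dict()
        f1 = extract_features(shifted).as_dict()
        for name in FEATURE_NAMES:
            if math.isnan(f0[name]):
                assert math.isnan(f1[name])
            else:
                assert f1[name] == pytest.approx(f0[name], rel=1e-6)


class TestSweepIO:
    def test_csv_json_round_trip(self, tmp_path):
        sweeps, spec = _sweeps()
        path = tmp_path / "cell.csv"
        write_sweeps(sweeps, path)
        again = read_sweeps(path)
        assert again.sampling_rate_hz == sweeps.sampling_rate_hz
        np.testing.assert_allclose(again.vc_step.current_pa, sweeps.vc_step.current_pa,
                                   rtol=1e-6)
        assert len(again.cc_steps) == len(sweeps.cc_steps)
        feats = extract_features(again)
        assert feats.input_resistance_mohm == pytest.approx(spec.r_in_mohm, rel=0.02)
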