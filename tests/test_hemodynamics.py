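"""Per-beat hemodynamics, windowed dynamics and transfer-function analysis."""

import numpy as np
import pytest

from cvreserve.hemodynamics import (
    beat_scalars,
    end_tidal_envelope,
    estimate_sv,
    interpolate_slow_channel,
    nirs_features,
    tfa_autoregulation,
    windowed_trend_variance,
)
from cvreserve.landmarks import detect_beats, parametrize_pulse, segment_beats
from cvreserve.synthetic import ChannelSignal


# ---------------------------------------------------------------------------
# beat scalars and the pulse-contour stand-in


@pytest.fixture(scope="module")
def one_beat_with_landmarks(noise_free_subject):
    rec = noise_free_subject
    onsets = detect_beats(rec.bp)
    seg = segment_beats(rec.bp, onsets)[5]
    return rec, seg, parametrize_pulse(seg), onsets[6]


def test_beat_scalar_definitions(one_beat_with_landmarks):
    rec, seg, lm, next_onset = one_beat_with_landmarks
    rec_d = beat_scalars(seg, lm, next_onset)
    assert rec_d["PP"] == pytest.approx(rec_d["SAP"] - rec_d["DAP"])
    assert rec_d["HR"] == pytest.approx(60.0 / rec_d["IBI"])
    assert rec_d["DAP"] < rec_d["MAP"] < rec_d["SAP"]


def test_lvet_is_foot_to_notch_time(one_beat_with_landmarks):
    rec, seg, lm, next_onset = one_beat_with_landmarks
    truth = min(rec.ground_truth, key=lambda b: abs(b.onset - seg.t_onset))
    lvet = beat_scalars(seg, lm, next_onset)["LVET"]
    assert lvet == pytest.approx(truth.t_notch - truth.onset, abs=1.5 / rec.bp.fs)


def test_out_of_bounds_ibi_rejected(one_beat_with_landmarks):
    _, seg, lm, _ = one_beat_with_landmarks
    with pytest.raises(ValueError, match="IBI"):
        beat_scalars(seg, lm, seg.t_onset + 3.0)


def test_sv_co_tpr_identities():
    rec = {"SAP": 120.0, "DAP": 80.0, "MAP": 93.0, "PP": 40.0, "HR": 60.0}
    out = estimate_sv(rec, calibration=400.0)
    assert out["SV"] == pytest.approx(400.0 * 40.0 / 200.0)  # 80 mL
    assert out["CO"] == pytest.approx(out["SV"] * 60.0 / 1000.0)  # 4.8 L/min
    assert out["TPR"] == pytest.approx(93.0 / out["CO"])
    # homogeneity: halving PP at constant SAP+DAP halves SV
    rec2 = {**rec, "PP": 20.0}
    assert estimate_sv(rec2, 400.0)["SV"] == pytest.approx(out["SV"] / 2.0)


# ---------------------------------------------------------------------------
# slow channels


def test_interpolation_constant_and_ramp():
    const = ChannelSignal("etco2", np.full(100, 40.0), 10.0, "mmHg")
    vals, flags = interpolate_slow_channel(const, np.array([1.0, 5.0, 9.0]))
    assert np.allclose(vals, 40.0)
    assert not flags.any()
    ramp = ChannelSignal("etco2", np.linspace(30.0, 40.0, 101), 10.0, "mmHg")
    vals, _ = interpolate_slow_channel(ramp, np.array([5.0]))  # midpoint of 10 s
    assert vals[0] == pytest.approx(35.0)


def test_interpolation_length_contract_and_edge_flag():
    ch = ChannelSignal("ti", np.linspace(30.0, 32.0, 100), 10.0, "ohm")
    beats = np.linspace(-1.0, 12.0, 375)
    vals, flags = interpolate_slow_channel(ch, beats)
    assert vals.size == 375
    assert flags[0] and flags[-1] and not flags[180]
    assert vals[0] == pytest.approx(30.0)  # edge value


def test_end_tidal_envelope_recovers_plateau_trend(default_subject):
    t, v = end_tidal_envelope(default_subject.etco2)
    assert t.size > 10
    # plateau values sit near the configured baseline early on
    early = v[t < default_subject.marks.t_lbnp_onset]
    assert abs(np.median(early) - 40.0) < 2.0


def test_nirs_feature_block():
    df = nirs_features(np.array([30.0, 20.0]), np.array([10.0, 20.0]))
    assert list(df.columns) == ["O2Hb", "HHb", "tHb", "ratio_O2Hb", "ratio_HHb"]
    assert df["tHb"].tolist() == [40.0, 40.0]
    assert df["ratio_O2Hb"].iloc[0] == pytest.approx(0.75)
    assert np.allclose(df["ratio_O2Hb"] + df["ratio_HHb"], 1.0)
    bad = nirs_features(np.array([0.0]), np.array([0.0]))
    assert np.isnan(bad["ratio_O2Hb"].iloc[0])


# ---------------------------------------------------------------------------
# windowed trend / variance


def test_constant_series_has_zero_trend_and_variance():
    t = np.arange(0.0, 200.0, 1.0)
    tr, va = windowed_trend_variance(t, np.full(t.size, 7.0))
    assert np.all(tr == 0.0)
    assert np.all(va == 0.0)


def test_linear_series_trend_and_closed_form_variance():
    t = np.arange(0.0, 200.0, 1.0)
    v = 2.0 * t + 5.0
    tr, va = windowed_trend_variance(t, v)
    assert np.allclose(tr[-1], 2.0)
    # windows are (t-w, t]: w points at unit spacing; var = 4 var(arange(w))
    for k, w in enumerate((30, 60, 90, 120)):
        expected = 4.0 * np.var(np.arange(w), ddof=1)
        assert va[-1, k] == pytest.approx(expected)


def test_short_window_carry_forward_policy():
    # < 3 beats in any window and nothing shorter to carry from → zeros
    t = np.array([0.0, 100.0, 200.0])
    tr, va = windowed_trend_variance(t, np.array([1.0, 2.0, 3.0]))
    assert np.all(tr == 0.0) and np.all(va == 0.0)


def test_trend_block_time_translation_and_affine_equivariance():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0.0, 300.0, 250))
    v = rng.normal(size=250)
    tr1, va1 = windowed_trend_variance(t, v)
    tr2, va2 = windowed_trend_variance(t + 1000.0, v)
    assert np.allclose(tr1, tr2) and np.allclose(va1, va2)
    tr3, va3 = windowed_trend_variance(t, 3.0 * v + 10.0)
    assert np.allclose(tr3, 3.0 * tr1)
    assert np.allclose(va3, 9.0 * va1)


# ---------------------------------------------------------------------------
# transfer-function autoregulation


@pytest.fixture(scope="module")
def sinusoid_grid():
    t = np.arange(0.0, 300.0, 0.5)
    return t, np.sin(2.0 * np.pi * 0.1 * t)


@pytest.mark.parametrize("gain", [0.5, 1.0, 2.0, 4.0])
def test_tfa_recovers_linear_gain_within_one_percent(sinusoid_grid, gain):
    t, x = sinusoid_grid
    res = tfa_autoregulation(t, x, gain * x)
    gains = [r.gain for r in res if r.valid]
    assert gains, "no valid TFA window"
    assert np.mean(gains) == pytest.approx(gain, rel=0.01)
    phases = [r.phase for r in res if r.valid]
    assert abs(np.mean(phases)) < 0.05


def test_tfa_delay_phase_identity(sinusoid_grid):
    t, x = sinusoid_grid
    tau = 0.5
    y = np.sin(2.0 * np.pi * 0.1 * (t - tau))
    res = tfa_autoregulation(t, x, y)
    phases = [abs(r.phase) for r in res if r.valid]
    assert np.mean(phases) == pytest.approx(2.0 * np.pi * 0.1 * tau, abs=0.05)


def test_tfa_incoherent_noise_is_flagged_missing():
    rng = np.random.default_rng(0)
    t = np.arange(0.0, 650.0, 0.5)
    res = tfa_autoregulation(t, rng.normal(size=t.size), rng.normal(size=t.size),
                             window_s=600.0, step_s=600.0, nperseg_s=30.0)
    assert res and not any(r.valid for r in res)


def test_tfa_requires_enough_data():
    t = np.arange(0.0, 100.0, 0.5)
    with pytest.raises(ValueError):
        tfa_autoregulation(t, np.sin(t), np.sin(t))


# ---------------------------------------------------------------------------
# full beat table identities


def test_beat_record_identities_hold_for_every_beat(full_beat_table):
    df, _ = full_beat_table
    assert np.allclose(df["PP"], df["SAP"] - df["DAP"])
    assert np.allclose(df["HR"], 60.0 / df["IBI"])
    assert np.allclose(df["CO"], df["SV"] * df["HR"] / 1000.0)
    assert np.allclose(df["TPR"], df["MAP"] / df["CO"])
    assert np.allclose(df["FV_PP"], df["SFV"] - df["DFV"])
    assert (df["FV_PP"] >= 0.0).all()
    assert np.allclose(df["ratio_O2Hb"] + df["ratio_HHb"], 1.0)
    assert (df["SAP"] > df["DAP"]).all()
    assert ((df["DAP"] <= df["MAP"]) & (df["MAP"] <= df["SAP"])).all()
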