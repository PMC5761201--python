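"""Per-beat hemodynamics, windowed dynamics and cerebral autoregulation.

Builds, for each detected heartbeat, the scalar hemodynamic record
(SAP, DAP, MAP, PP, IBI, HR, SV, CO, LVET, TPR and their flow-velocity
analogues), beat-interpolated slow-channel values (end-tidal CO2,
thoracic impedance, NIRS hemoglobin concentrations), moving-window
trend/variance features, and transfer-function gain/phase between mean
arterial pressure and mean cerebral flow velocity in the low-frequency
band (0.06–0.15 Hz, coherence-thresholded at 0.5, 3-min moving window).

Stroke volume uses a calibrated Liljestrand–Zander pulse-contour form,
SV ∝ PP / (SAP + DAP), with the calibration factor fixed so the
baseline-mean SV matches a supplied reference value. CO = SV × HR and
TPR = MAP / CO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import csd, find_peaks, welch

from .landmarks import (
    BeatLandmarks,
    BeatSegment,
    CURVE_FEATURE_NAMES,
    DegeneratePulseError,
    curve_feature_vector,
    detect_beats,
    parametrize_pulse,
    segment_beats,
)
from .synthetic import ChannelSignal, SubjectRecording

__all__ = [
    "beat_scalars",
    "estimate_sv",
    "interpolate_slow_channel",
    "end_tidal_envelope",
    "nirs_features",
    "windowed_trend_variance",
    "TFAResult",
    "tfa_autoregulation",
    "build_beat_table",
    "TREND_WINDOWS_S",
    "BP_TREND_PARAMS",
    "FV_TREND_PARAMS",
]

TREND_WINDOWS_S = (30.0, 60.0, 90.0, 120.0)
BP_TREND_PARAMS = ("SAP", "DAP", "HR", "PP", "SV")
FV_TREND_PARAMS = ("SFV", "DFV", "MFV", "FV_PP", "fv_area_total")


def beat_scalars(beat: BeatSegment, lm: BeatLandmarks, next_onset: float) -> dict:
    """Scalar hemodynamics of one beat.

    SAP is the value at the systolic peak C, DAP the foot value, MAP the
    time average over the beat, LVET the foot-to-notch interval.
    """
    ibi = next_onset - beat.t_onset
    if not (0.25 <= ibi <= 2.5):
        raise ValueError(f"IBI {ibi:.3f} s outside [0.25, 2.5] s")
    sap = lm.C[1]
    dap = lm.A[1]
    return {
        "t": beat.t_onset,
        "SAP": sap,
        "DAP": dap,
        "MAP": float(np.mean(beat.samples)),
        "PP": sap - dap,
        "IBI": ibi,
        "HR": 60.0 / ibi,
        "LVET": lm.D[0] - lm.A[0],
    }


def estimate_sv(rec: dict, calibration: float) -> dict:
    """Pulse-contour stroke volume (Liljestrand–Zander form) plus CO and TPR.

    SV = calibration × PP / (SAP + DAP) [mL]; CO = SV × HR / 1000 [L/min];
    TPR = MAP / CO [mmHg·min/L].
    """
    sv = calibration * rec["PP"] / (rec["SAP"] + rec["DAP"])
    co = sv * rec["HR"] / 1000.0
    if co == 0:
        raise ZeroDivisionError("cardiac output is zero")
    return {**rec, "SV": sv, "CO": co, "TPR": rec["MAP"] / co}


def interpolate_slow_channel(ch: ChannelSignal, beat_times: np.ndarray,
                             times: np.ndarray | None = None,
                             values: np.ndarray | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a slow channel at beat times.

    Returns (values_at_beats, extrapolated_mask); beats outside the
    channel support take the edge value and are flagged. ``times`` /
    ``values`` override the channel's own grid (used for breath-wise
    end-tidal envelopes).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if times is None:
        times = ch.times()
        values = ch.samples
    out = np.interp(beat_times, times, values)
    flagged = (beat_times < times[0]) | (beat_times > times[-1])
    return out, flagged


def end_tidal_envelope(ch: ChannelSignal, resp_rate_hz: float = 0.25
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Breath-wise end-tidal envelope of a capnogram-like signal.

    Detects one expiratory plateau peak per breath and returns
    (peak_times, peak_values). Falls back to the raw signal when no
    breath structure is present (already-enveloped input).
    """
    min_dist = max(int(0.6 / resp_rate_hz * ch.fs), 1)
    peaks, _ = find_peaks(ch.samples, distance=min_dist,
                          prominence=0.1 * max(np.ptp(ch.samples), 1e-9))
    if peaks.size < 2:
        return ch.times(), ch.samples
    return peaks / ch.fs, ch.samples[peaks]


def nirs_features(o2hb_bt: np.ndarray, hhb_bt: np.ndarray) -> pd.DataFrame:
    """Per-beat cortical oxygenation block: O2Hb, HHb, tHb and both ratios."""
    o2hb_bt = np.asarray(o2hb_bt, dtype=float)
    hhb_bt = np.asarray(hhb_bt, dtype=float)
    if o2hb_bt.shape != hhb_bt.shape:
        raise ValueError("O2Hb and HHb series must have equal length")
    thb = o2hb_bt + hhb_bt
    bad = thb <= 0
    safe = np.where(bad, np.nan, thb)
    return pd.DataFrame({
        "O2Hb": o2hb_bt,
        "HHb": hhb_bt,
        "tHb": thb,
        "ratio_O2Hb": o2hb_bt / safe,
        "ratio_HHb": hhb_bt / safe,
    })


def windowed_trend_variance(times: np.ndarray, values: np.ndarray,
                            windows: tuple[float, ...] = TREND_WINDOWS_S
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Right-aligned moving trend (OLS slope) and sample variance.

    For each beat time t and window length w, uses the beats in (t−w, t].
    Windows with fewer than 3 beats or covering less than half of w carry
    the value of the longest valid shorter window, else 0.

    Returns (trend, variance), each of shape (n_beats, n_windows).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = times.size
    nw = len(windows)
    trend = np.zeros((n, nw))
    var = np.zeros((n, nw))
    order = np.argsort(windows)
    for i in range(n):
        t = times[i]
        prev_valid: tuple[float, float] | None = None
        for k in order:
            w = windows[k]
            j0 = int(np.searchsorted(times, t - w, side="right"))
            tt = times[j0: i + 1]
            vv = values[j0: i + 1]
            ok = tt.size >= 3 and (t - tt[0]) >= 0.5 * w
            if ok:
                tc = tt - tt.mean()
                denom = float(np.dot(tc, tc))
                slope = float(np.dot(tc, vv - vv.mean()) / denom) if denom > 0 else 0.0
                v = float(np.var(vv, ddof=1))
                trend[i, k], var[i, k] = slope, v
                prev_valid = (slope, v)
            elif prev_valid is not None:
                trend[i, k], var[i, k] = prev_valid
            # else: leave 0 (flagged-missing policy)
    return trend, var


@dataclass
class TFAResult:
    """Transfer-function estimate for one window position."""

    window_center: float
    gain: float
    phase: float
    mean_coherence: float
    valid: bool


def tfa_autoregulation(times: np.ndarray, map_series: np.ndarray,
                       mfv_series: np.ndarray,
                       window_s: float = 180.0, step_s: float = 10.0,
                       fs_resample: float = 4.0, nperseg_s: float = 100.0,
                       band: tuple[float, float] = (0.06, 0.15),
                       coherence_min: float = 0.5) -> list[TFAResult]:
    """Cerebral-autoregulation transfer function between MAP and MFV.

    Both beat series are resampled to a uniform grid (linear
    interpolation), and within each moving window cross- and auto-spectra
    are estimated by Welch averaging (linear detrend, Hann taper, 50%
    overlap). Gain |S_xy|/S_xx and phase arg(S_xy) are averaged over the
    low-frequency band bins whose squared coherence reaches the
    threshold; a window with no qualifying bin is returned invalid.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2 or times[-1] - times[0] < window_s:
        raise ValueError(f"need at least {window_s} s of data")
    grid = np.arange(times[0], times[-1], 1.0 / fs_resample)
    x = np.interp(grid, times, np.asarray(map_series, dtype=float))
    y = np.interp(grid, times, np.asarray(mfv_series, dtype=float))

    nwin = int(round(window_s * fs_resample))
    nper = min(int(round(nperseg_s * fs_resample)), nwin)
    step = max(int(round(step_s * fs_resample)), 1)
    results: list[TFAResult] = []
    for start in range(0, grid.size - nwin + 1, step):
        xs = x[start:start + nwin]
        ys = y[start:start + nwin]
        f, pxy = csd(xs, ys, fs=fs_resample, nperseg=nper, noverlap=nper // 2,
                     window="hann", detrend="linear")
        _, pxx = welch(xs, fs=fs_resample, nperseg=nper, noverlap=nper // 2,
                       window="hann", detrend="linear")
        _, pyy = welch(ys, fs=fs_resample, nperseg=nper, noverlap=nper // 2,
                       window="hann", detrend="linear")
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.abs(pxy) ** 2 / (pxx * pyy)
            gain_bins = np.abs(pxy) / pxx
        sel = (f >= band[0]) & (f <= band[1])
        center = grid[start] + window_s / 2.0
        qual = sel & (coh >= coherence_min) & np.isfinite(gain_bins)
        if not np.any(qual):
            results.append(TFAResult(center, np.nan, np.nan,
                                     float(np.nanmean(coh[sel])) if np.any(sel) else np.nan,
                                     False))
            continue
        results.append(TFAResult(
            window_center=center,
            gain=float(np.mean(gain_bins[qual])),
            # circular mean weighted by cross-spectral magnitude, so that
            # low-power leakage bins cannot dominate the phase estimate
            phase=float(np.angle(np.sum(pxy[qual]))),
            mean_coherence=float(np.mean(coh[qual])),
            valid=True,
        ))
    return results


# ---------------------------------------------------------------------------
# beat-table assembly


def _interp_failed_rows(df: pd.DataFrame, failed: np.ndarray) -> pd.DataFrame:
    """Fill degenerate-beat rows by linear interpolation from neighbours."""
    if failed.any():
        df = df.copy()
        cols = [c for c in df.columns if c != "t"]
        df.loc[failed, cols] = np.nan
        df[cols] = df[cols].interpolate(limit_direction="both")
    return df


def build_beat_table(rec: SubjectRecording, sv_baseline_ml: float = 80.0,
                     fv: bool = True, trends: bool = True, fv_trends: bool = True,
                     tfa: bool = True, resp_rate_hz: float = 0.25) -> pd.DataFrame:
    """Full per-beat feature table for one subject.

    One row per detected beat (the final open beat is dropped), columns:
    scalar hemodynamics, 15 BP curve-dynamics entries (``bp_*``), the
    flow-velocity analogues (``fv_*``, SFV/DFV/MFV/FV_PP), slow-channel
    values (ETCO2, TI, NIRS block), trend/variance blocks for both the
    BP and FV parameter sets, and (optionally) TFA gain/phase.

    Degenerate beats are interpolated from neighbours, mirroring manual
    artifact removal in over-the-wire recordings. The SV calibration is
    fixed so that the baseline-mean SV equals ``sv_baseline_ml``.

    The ``fv``/``trends``/``fv_trends``/``tfa`` switches skip feature
    blocks a downstream model does not use (they dominate runtime).
    """
    onsets = detect_beats(rec.bp)
    if onsets.size < 3:
        raise ValueError(f"subject {rec.subject_id}: too few beats detected")
    beats = segment_beats(rec.bp, onsets)
    fv_beats = segment_beats(rec.fv, onsets)

    rows = []
    failed = np.zeros(len(beats), dtype=bool)
    for i, (beat, fvb) in enumerate(zip(beats, fv_beats)):
        next_onset = onsets[i + 1]
        row: dict = {"t": beat.t_onset}
        try:
            lm = parametrize_pulse(beat)
            row.update(beat_scalars(beat, lm, next_onset))
            for name, val in zip(CURVE_FEATURE_NAMES, curve_feature_vector(lm)):
                row[f"bp_{name}"] = val
        except (DegeneratePulseError, ValueError):
            failed[i] = True
        if fv:
            try:
                lmf = parametrize_pulse(fvb)
                fvec = curve_feature_vector(lmf)
                for name, val in zip(CURVE_FEATURE_NAMES, fvec):
                    row[f"fv_{name}"] = val
                row["SFV"] = lmf.C[1]
                row["DFV"] = lmf.A[1]
                row["MFV"] = float(np.mean(fvb.samples))
                row["FV_PP"] = lmf.C[1] - lmf.A[1]
                row["fv_area_total"] = lmf.area_total
            except (DegeneratePulseError, ValueError):
                failed[i] = True
        rows.append(row)
    df = pd.DataFrame(rows)
    df = _interp_failed_rows(df, failed | df.isna().any(axis=1).to_numpy())
    if df.isna().any().any():
        raise ValueError(f"subject {rec.subject_id}: unrecoverable degenerate beats")
    # re-derive identities on interpolated rows (interpolating HR and IBI
    # independently would break HR = 60/IBI etc.)
    df["PP"] = df["SAP"] - df["DAP"]
    df["HR"] = 60.0 / df["IBI"]
    if fv:
        df["FV_PP"] = df["SFV"] - df["DFV"]

    # pulse-contour SV calibrated to the baseline reference
    base = df["t"] < rec.marks.t_lbnp_onset
    if not base.any():
        raise ValueError(f"subject {rec.subject_id}: no baseline beats")
    raw = df["PP"] / (df["SAP"] + df["DAP"])
    calibration = sv_baseline_ml / float(raw[base].mean())
    df["SV"] = calibration * raw
    df["CO"] = df["SV"] * df["HR"] / 1000.0
    df["TPR"] = df["MAP"] / df["CO"]

    beat_times = df["t"].to_numpy()
    et_t, et_v = end_tidal_envelope(rec.etco2, resp_rate_hz)
    df["ETCO2"], _ = interpolate_slow_channel(rec.etco2, beat_times, et_t, et_v)
    df["TI"], _ = interpolate_slow_channel(rec.ti, beat_times)
    o2hb, _ = interpolate_slow_channel(rec.o2hb, beat_times)
    hhb, _ = interpolate_slow_channel(rec.hhb, beat_times)
    nirs = nirs_features(o2hb, hhb)
    for c in nirs.columns:
        df[c] = nirs[c].to_numpy()

    extra: dict[str, np.ndarray] = {}
    blocks = ([BP_TREND_PARAMS] if trends else []) + \
             ([FV_TREND_PARAMS] if fv and fv_trends else [])
    for params in blocks:
        for p in params:
            tr, va = windowed_trend_variance(beat_times, df[p].to_numpy())
            for k, w in enumerate(TREND_WINDOWS_S):
                extra[f"{p}_trend_{int(w)}"] = tr[:, k]
                extra[f"{p}_var_{int(w)}"] = va[:, k]

    if tfa and fv:
        try:
            res = tfa_autoregulation(beat_times, df["MAP"].to_numpy(),
                                     df["MFV"].to_numpy())
        except ValueError:
            res = []
        if res:
            centers = np.array([r.window_center for r in res])
            gains = np.array([r.gain for r in res])
            phases = np.array([r.phase for r in res])
            valid = np.array([r.valid for r in res])
            if valid.any():
                g = np.interp(beat_times, centers[valid], gains[valid])
                p = np.interp(beat_times, centers[valid], phases[valid])
            else:
                g = np.zeros_like(beat_times)
                p = np.zeros_like(beat_times)
        else:
            g = np.zeros_like(beat_times)
            p = np.zeros_like(beat_times)
        extra["tfa_gain"] = g
        extra["tfa_phase"] = p

    df = pd.concat([df, pd.DataFrame(extra, index=df.index)], axis=1)
    df.insert(0, "subject_id", rec.subject_id)
    return df
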