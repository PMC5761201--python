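"""Beat detection and pulse-wave parametrization.

Each pulse of the arterial-pressure (or cerebral flow-velocity) wave is
reduced to five primary points — A: wave foot, B: point of maximal
upstroke slope, C: systolic peak, D: dicrotic notch, E: end of beat
(the next foot) — plus three tangent slopes, beat areas, durations and
relative amplitudes. The fixed-order 15-entry curve-dynamics vector
built from these landmarks is the waveform feature block of the
classification models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import ChannelSignal

__all__ = [
    "BeatSegment",
    "BeatLandmarks",
    "DegeneratePulseError",
    "detect_beats",
    "segment_beats",
    "parametrize_pulse",
    "curve_feature_vector",
    "CURVE_FEATURE_NAMES",
]

IBI_MIN_S = 0.25
IBI_MAX_S = 2.5


class DegeneratePulseError(ValueError):
    """Raised when a beat segment cannot be parametrized."""


@dataclass
class BeatSegment:
    """A contiguous single-beat slice of a pulsatile waveform."""

    samples: np.ndarray
    fs: float
    t_onset: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        dur = self.samples.size / self.fs
        if not (IBI_MIN_S <= dur <= IBI_MAX_S):
            raise ValueError(f"beat duration {dur:.3f} s outside [{IBI_MIN_S}, {IBI_MAX_S}] s")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class BeatLandmarks:
    """Landmark set of one pulse; times absolute, amplitudes relative to the foot."""

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    D: tuple[float, float]
    E: tuple[float, float]
    slope_I: float
    slope_II: float
    slope_III: float
    area_sys: float
    area_dia: float
    area_total: float

    @property
    def t_AB(self) -> float:
        return self.B[0] - self.A[0]

    @property
    def t_AC(self) -> float:
        return self.C[0] - self.A[0]

    @property
    def t_AD(self) -> float:
        return self.D[0] - self.A[0]

    @property
    def t_AE(self) -> float:
        return self.E[0] - self.A[0]

    @property
    def h_B(self) -> float:
        return self.B[1] - self.A[1]

    @property
    def h_C(self) -> float:
        return self.C[1] - self.A[1]

    @property
    def h_D(self) -> float:
        return self.D[1] - self.A[1]


#: documented order of the 15-entry curve-dynamics vector
CURVE_FEATURE_NAMES = (
    "t_AB", "t_AC", "t_AD", "t_AE",
    "h_B", "h_C", "h_D",
    "slope_I", "slope_II", "slope_III",
    "area_sys", "area_dia", "area_total",
    "h_D_over_h_C", "area_sys_frac",
)


def detect_beats(signal: ChannelSignal) -> np.ndarray:
    """Detect beat onsets (wave feet) of a pulsatile signal.

    A foot is the local minimum immediately preceding a steep systolic
    upstroke. Returns onset times in seconds; empty for non-pulsatile
    input. Raises on sampling rates too low to resolve the upstroke.
    """
    if signal.fs < 50:
        raise ValueError(f"sampling rate {signal.fs} Hz too low for beat detection")
    x = signal.samples
    if x.size < int(IBI_MIN_S * signal.fs) + 2:
        return np.array([])
    dx = np.gradient(x) * signal.fs
    amp = np.ptp(x)
    if amp < 1e-9 or np.max(dx) <= 0:
        return np.array([])
    # steep-upstroke candidates; a real upstroke traverses a sizeable
    # fraction of the signal range within ~0.1 s
    thr = 0.35 * np.max(dx)
    if np.max(dx) * 0.1 < 0.1 * amp:
        return np.array([])
    peaks, _ = find_peaks(dx, height=thr, distance=int(IBI_MIN_S * signal.fs))
    onsets = []
    back = int(0.30 * signal.fs)
    for p in peaks:
        w0 = max(p - back, 0)
        seg = x[w0:p + 1]
        if seg.size == 0:
            continue
        foot = w0 + int(np.argmin(seg))
        if onsets and foot - onsets[-1] < int(IBI_MIN_S * signal.fs):
            continue
        onsets.append(foot)
    return np.asarray(onsets, dtype=float) / signal.fs


def segment_beats(signal: ChannelSignal, onsets: np.ndarray) -> list[BeatSegment]:
    """Slice a signal into per-beat segments; the final (open) beat is dropped."""
    segs = []
    for t0, t1 in zip(onsets[:-1], onsets[1:]):
        i0, i1 = int(round(t0 * signal.fs)), int(round(t1 * signal.fs))
        segs.append(BeatSegment(signal.samples[i0:i1], signal.fs, t0))
    return segs


def _lsq_slope(t: np.ndarray, v: np.ndarray) -> float:
    if t.size < 2:
        return 0.0
    t = t - t.mean()
    denom = float(np.dot(t, t))
    if denom == 0.0:
        return 0.0
    return float(np.dot(t, v - v.mean()) / denom)


def parametrize_pulse(beat: BeatSegment) -> BeatLandmarks:
    """Extract the A–E landmark set from one beat.

    The foot A is the first sample of the segment (segments are cut at
    detected feet). D is the most prominent local minimum between the
    systolic peak and the beat end, falling back to the point of maximal
    curvature of the decay when the notch leaves no minimum. slope_I is
    the derivative at B; slope_II and slope_III are least-squares slopes
    over C→D and D→E. Areas are trapezoidal, measured above the foot
    value.
    """
    x = beat.samples
    fs = beat.fs
    n = x.size
    if n < 5:
        raise DegeneratePulseError("beat too short")
    a_val = float(x[0])

    c_idx = int(np.argmax(x))
    if c_idx == 0 or x[c_idx] <= a_val:
        raise DegeneratePulseError("no systolic peak above the foot")

    dx = np.gradient(x) * fs
    b_idx = int(np.argmax(dx[: c_idx + 1]))

    # dicrotic notch: most prominent local minimum in (C, end)
    tail = x[c_idx:]
    mins, props = find_peaks(-tail, prominence=1e-6)
    interior = mins[(mins > 0) & (mins < tail.size - 1)]
    if interior.size:
        proms = props["prominences"][(mins > 0) & (mins < tail.size - 1)]
        d_idx = c_idx + int(interior[np.argmax(proms)])
    else:
        # curvature fallback: maximum of the second derivative on the decay
        lo = c_idx + max(int(0.05 * n), 2)
        hi = max(int(0.85 * n), lo + 3)
        if hi > n - 1:
            hi = n - 1
        if hi - lo < 3:
            raise DegeneratePulseError("notch search failed")
        d2 = np.gradient(np.gradient(x))
        d_idx = lo + int(np.argmax(d2[lo:hi]))

    t0 = beat.t_onset
    times = t0 + np.arange(n) / fs
    e_time = t0 + n / fs  # the next beat's foot
    e_val = float(x[-1])

    above = x - a_val
    area_sys = float(np.trapezoid(above[: d_idx + 1], dx=1.0 / fs))
    area_dia = float(np.trapezoid(above[d_idx:], dx=1.0 / fs))
    area_total = area_sys + area_dia

    lm = BeatLandmarks(
        A=(t0, a_val),
        B=(float(times[b_idx]), float(x[b_idx])),
        C=(float(times[c_idx]), float(x[c_idx])),
        D=(float(times[d_idx]), float(x[d_idx])),
        E=(e_time, e_val),
        slope_I=float(dx[b_idx]),
        slope_II=_lsq_slope(times[c_idx: d_idx + 1], x[c_idx: d_idx + 1]),
        slope_III=_lsq_slope(times[d_idx:], x[d_idx:]),
        area_sys=area_sys,
        area_dia=area_dia,
        area_total=area_total,
    )
    if not (lm.A[0] < lm.B[0] <= lm.C[0] < lm.D[0] < lm.E[0]):
        raise DegeneratePulseError("landmark ordering violated")
    return lm


def curve_feature_vector(lm: BeatLandmarks) -> np.ndarray:
    """The fixed-order 15-entry curve-dynamics vector (see CURVE_FEATURE_NAMES)."""
    if lm is None:
        raise ValueError("missing landmarks")
    h_c = lm.h_C if lm.h_C != 0 else np.nan
    total = lm.area_total if lm.area_total != 0 else np.nan
    vec = np.array([
        lm.t_AB, lm.t_AC, lm.t_AD, lm.t_AE,
        lm.h_B, lm.h_C, lm.h_D,
        lm.slope_I, lm.slope_II, lm.slope_III,
        lm.area_sys, lm.area_dia, lm.area_total,
        lm.h_D / h_c, lm.area_sys / total,
    ])
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite curve features")
    return vec
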