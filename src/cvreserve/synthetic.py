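"""Synthetic cohorts of progressive central-hypovolemia recordings.

Emulates a lower-body negative pressure (LBNP) protocol: a resting
baseline segment, a single-step −50 mmHg LBNP phase during which stroke
volume, pulse pressure and cerebral flow velocity decline while heart
rate rises, and a terminal collapse ending in pre-syncope (systolic
pressure falling below 80 mmHg, one of the protocol abort criteria).

Each heartbeat of the arterial-pressure and cerebral flow-velocity
channels is rendered from a parametric pulse template whose landmarks
(foot, point of maximal upstroke slope, systolic peak, dicrotic notch)
are analytically known; the ground truth is attached to every generated
recording so that downstream waveform analysis can be tested against it.

Slow channels (end-tidal CO2 capnogram, thoracic impedance, NIRS
oxy-/deoxyhemoglobin) are piecewise-linear trends with AR(1) noise at
their native sampling rates.

Two responder phenotypes are mixed within a cohort: resistance-dominant
compensators (vasoconstriction, modest heart-rate rise) and heart-rate-
dominant compensators (strong tachycardia, falling diastolic pressure),
so that classifiers cannot rely on a single stereotyped trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolMarks",
    "ChannelSignal",
    "BeatTruth",
    "SubjectRecording",
    "CohortConfig",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ProtocolMarks:
    """Protocol event times, in seconds from the start of the recording."""

    t_baseline_start: float
    t_lbnp_onset: float
    t_presyncope: float

    def __post_init__(self) -> None:
        if not (self.t_baseline_start < self.t_lbnp_onset < self.t_presyncope):
            raise ValueError(
                "protocol marks must satisfy baseline_start < lbnp_onset < presyncope, "
                f"got {self.t_baseline_start}, {self.t_lbnp_onset}, {self.t_presyncope}"
            )

    @property
    def baseline_duration(self) -> float:
        return self.t_lbnp_onset - self.t_baseline_start

    @property
    def lbnp_duration(self) -> float:
        return self.t_presyncope - self.t_lbnp_onset


@dataclass
class ChannelSignal:
    """One uniformly sampled physiological channel."""

    name: str
    samples: np.ndarray
    fs: float
    units: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"channel {self.name}: fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError(f"channel {self.name}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.name}: non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatTruth:
    """Ground-truth template parameters for one generated beat.

    Times are absolute (seconds from recording start); ``t_peak`` and
    ``t_notch`` are the analytic systolic-peak and dicrotic-notch times
    of the pressure template, ``t_peak_fv``/``t_notch_fv`` of the
    flow-velocity template.
    """

    onset: float
    ibi: float
    sap: float
    dap: float
    t_peak: float
    t_notch: float
    v_notch: float
    sfv: float
    dfv: float
    t_peak_fv: float
    t_notch_fv: float


@dataclass
class SubjectRecording:
    """Multi-channel recording plus protocol marks for one subject."""

    subject_id: str
    bp: ChannelSignal
    fv: ChannelSignal
    o2hb: ChannelSignal
    hhb: ChannelSignal
    etco2: ChannelSignal
    ti: ChannelSignal
    marks: ProtocolMarks
    ground_truth: list[BeatTruth] | None = None
    phenotype: str | None = None


@dataclass
class CohortConfig:
    """Generator parameters.

    Baseline levels and effect sizes are expressed in the physical units
    of the corresponding channel; fractional declines apply over the full
    LBNP phase (onset to pre-syncope). The terminal collapse occupies the
    final ``collapse_fraction`` of LBNP and drives systolic pressure
    linearly down to ``collapse_sap_floor_mmhg`` (below the 80 mmHg abort
    criterion).
    """

    n_subjects: int = 42
    seed: int = 0
    baseline_duration_s: float = 600.0
    lbnp_duration_range_s: tuple[float, float] = (300.0, 900.0)

    # baseline operating point
    hr_baseline_bpm: float = 62.0
    sap_baseline_mmhg: float = 120.0
    dap_baseline_mmhg: float = 70.0
    sv_baseline_ml: float = 80.0
    sfv_baseline_cms: float = 90.0
    dfv_baseline_cms: float = 45.0
    etco2_baseline_mmhg: float = 40.0
    ti_baseline_ohm: float = 30.0
    o2hb_baseline_umol: float = 30.0
    hhb_baseline_umol: float = 10.0

    # LBNP effect sizes (change over the whole LBNP phase, in expectation)
    pp_decline_frac: float = 0.45
    mcav_decline_frac: float = 0.30
    hr_rise_bpm_resistance: float = 18.0
    hr_rise_bpm_hrdom: float = 45.0
    dap_shift_mmhg_resistance: float = 8.0
    dap_shift_mmhg_hrdom: float = -5.0
    etco2_drop_mmhg: float = 8.0
    ti_rise_ohm: float = 2.0
    o2hb_drop_umol: float = 5.0
    hhb_rise_umol: float = 3.0

    # terminal collapse
    collapse_fraction: float = 0.05
    collapse_sap_floor_mmhg: float = 72.0

    # phenotype mixture: probability of the resistance-dominant responder
    resistance_fraction: float = 0.5

    # per-beat / per-sample noise amplitudes
    sap_noise_mmhg: float = 1.5
    dap_noise_mmhg: float = 1.0
    ibi_noise_s: float = 0.02
    fv_noise_cms: float = 1.5
    etco2_noise_mmhg: float = 0.4
    ti_noise_ohm: float = 0.04
    nirs_noise_umol: float = 0.25

    # sampling rates and respiration
    fs_bp: float = 200.0
    fs_fv: float = 200.0
    fs_slow: float = 10.0
    resp_rate_hz: float = 0.25

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_duration_s <= 0:
            raise ValueError("baseline_duration_s must be > 0")
        lo, hi = self.lbnp_duration_range_s
        if lo <= 0 or hi < lo:
            raise ValueError("lbnp_duration_range_s must be (min, max) with 0 < min <= max")
        if not 0.0 <= self.resistance_fraction <= 1.0:
            raise ValueError("resistance_fraction must be in [0, 1]")
        if not 0.0 <= self.collapse_fraction < 1.0:
            raise ValueError("collapse_fraction must be in [0, 1)")
        if self.hr_baseline_bpm <= 0:
            raise ValueError("hr_baseline_bpm must be > 0")
        if self.dap_baseline_mmhg <= 0 or self.sap_baseline_mmhg <= self.dap_baseline_mmhg:
            raise ValueError("need 0 < DAP < SAP at baseline")
        if self.collapse_sap_floor_mmhg <= 0:
            raise ValueError("collapse_sap_floor_mmhg must be > 0")
        pp_end = (self.sap_baseline_mmhg - self.dap_baseline_mmhg) * (1 - self.pp_decline_frac)
        if pp_end <= 0:
            raise ValueError("pp_decline_frac leaves no pulse pressure at pre-syncope")
        hr_end = self.hr_baseline_bpm + max(self.hr_rise_bpm_resistance, self.hr_rise_bpm_hrdom)
        if hr_end <= 0 or hr_end > 220:
            raise ValueError("terminal heart rate non-physiological")


# ---------------------------------------------------------------------------
# pulse template


def _pulse_template(tau: np.ndarray, sap: float, dap: float, dap_next: float,
                    ibi: float) -> tuple[np.ndarray, float, float, float]:
    """Evaluate one pulse at local times ``tau`` in [0, ibi).

    Shape: raised-cosine upstroke from the foot (value ``dap``) to the
    systolic peak ``sap``, raised-cosine decline to the dicrotic notch
    (a true local minimum), then a dicrotic bump superimposed on an
    exponential decay toward the next beat's foot value.

    Returns (values, t_peak, t_notch, v_notch) with times local to the
    beat onset.
    """
    pp = sap - dap
    t_notch = min(0.30 * np.sqrt(ibi), 0.45 * ibi)  # systolic-interval surrogate
    t_peak = 0.4 * t_notch
    v_notch = dap_next + 0.36 * (sap - dap_next)
    tau_d = (ibi - t_notch) / 3.0
    a_bump = 0.12 * pp
    w_bump = min(0.10, 0.45 * (ibi - t_notch))

    v = np.empty_like(tau)
    up = tau < t_peak
    v[up] = dap + pp * 0.5 * (1.0 - np.cos(np.pi * tau[up] / t_peak))
    sysdec = (tau >= t_peak) & (tau < t_notch)
    v[sysdec] = v_notch + (sap - v_notch) * 0.5 * (
        1.0 + np.cos(np.pi * (tau[sysdec] - t_peak) / (t_notch - t_peak))
    )
    dia = tau >= t_notch
    td = tau[dia] - t_notch
    base = dap_next + (v_notch - dap_next) * np.exp(-td / tau_d)
    bump = np.where(td < w_bump, a_bump * np.sin(np.pi * np.minimum(td, w_bump) / w_bump), 0.0)
    v[dia] = base + bump
    return v, t_peak, t_notch, v_notch


# ---------------------------------------------------------------------------
# beat-to-beat trajectories


def _phenotype_params(config: CohortConfig, phenotype: str) -> tuple[float, float]:
    if phenotype == "resistance":
        return config.hr_rise_bpm_resistance, config.dap_shift_mmhg_resistance
    if phenotype == "hr":
        return config.hr_rise_bpm_hrdom, config.dap_shift_mmhg_hrdom
    raise ValueError(f"unknown phenotype {phenotype!r}")


def _expected_state(t: float, config: CohortConfig, phenotype: str,
                    t_on: float, lbnp_dur: float) -> dict[str, float]:
    """Expected (noise-free) beat parameters at time ``t``."""
    hr_rise, dap_shift = _phenotype_params(config, phenotype)
    pp0 = config.sap_baseline_mmhg - config.dap_baseline_mmhg

    u = 0.0 if t < t_on else min((t - t_on) / lbnp_dur, 1.0)
    pp = pp0 * (1.0 - config.pp_decline_frac * u)
    dap = config.dap_baseline_mmhg + dap_shift * u
    sap = dap + pp
    hr = config.hr_baseline_bpm + hr_rise * u
    sfv = config.sfv_baseline_cms * (1.0 - 1.2 * config.mcav_decline_frac * u)
    dfv = config.dfv_baseline_cms * (1.0 - 0.8 * config.mcav_decline_frac * u)

    u_c = 1.0 - config.collapse_fraction
    if config.collapse_fraction > 0.0 and u > u_c:
        w = (u - u_c) / config.collapse_fraction
        dap_c = config.dap_baseline_mmhg + dap_shift * u_c
        sap_c = dap_c + pp0 * (1.0 - config.pp_decline_frac * u_c)
        # SAP driven linearly to the collapse floor; PP keeps its decline,
        # so DAP = SAP - PP.  HR holds its plateau (non-decreasing in
        # expectation over LBNP).
        sap = min(sap, sap_c + (config.collapse_sap_floor_mmhg - sap_c) * w)
        dap = sap - pp
        hr = config.hr_baseline_bpm + hr_rise * u_c
    if sap <= 0 or dap <= 0 or hr <= 0 or sfv <= 0 or dfv <= 0:
        raise ValueError("trajectory parameters produce non-physiological values")
    return {"sap": sap, "dap": dap, "hr": hr, "sfv": sfv, "dfv": dfv}


def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float = 0.95) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sigma``."""
    if sigma == 0.0 or n == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sigma * np.sqrt(1.0 - phi * phi), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def _piecewise_trend(t: np.ndarray, t_on: float, t_end: float,
                     v0: float, dv: float) -> np.ndarray:
    """Constant ``v0`` during baseline, then linear drift by ``dv`` over LBNP."""
    u = np.clip((t - t_on) / max(t_end - t_on, 1e-9), 0.0, 1.0)
    return v0 + dv * u


# ---------------------------------------------------------------------------
# subject and cohort simulation


def simulate_subject(config: CohortConfig,
                     subject_seed: int | np.random.SeedSequence,
                     subject_id: str = "S00") -> SubjectRecording:
    """Simulate one LBNP recording.

    Deterministic for a fixed (config, subject_seed). The recording runs
    from baseline start (t = 0) through LBNP onset to pre-syncope, which
    always terminates the recording.
    """
    config.validate()
    rng = np.random.default_rng(subject_seed)

    phenotype = "resistance" if rng.random() < config.resistance_fraction else "hr"
    lo, hi = config.lbnp_duration_range_s
    lbnp_dur = float(rng.uniform(lo, hi))
    t_on = float(config.baseline_duration_s)
    total = t_on + lbnp_dur
    marks = ProtocolMarks(0.0, t_on, total)

    fs = config.fs_bp
    n = int(round(total * fs))
    bp = np.empty(n)
    fv = np.empty(n)
    truth: list[BeatTruth] = []

    # render beats sequentially; beat parameters are the expected
    # trajectory plus white per-beat noise
    onset = 0.0
    state = _expected_state(0.0, config, phenotype, t_on, lbnp_dur)
    while True:
        hr = state["hr"]
        ibi = 60.0 / hr + rng.normal(0.0, config.ibi_noise_s)
        ibi = float(np.clip(ibi, 0.35, 2.2))
        sap = state["sap"] + rng.normal(0.0, config.sap_noise_mmhg)
        dap = state["dap"] + rng.normal(0.0, config.dap_noise_mmhg)
        dap = min(dap, sap - 5.0)
        sfv = state["sfv"] + rng.normal(0.0, config.fv_noise_cms)
        dfv = state["dfv"] + rng.normal(0.0, 0.7 * config.fv_noise_cms)
        dfv = min(dfv, sfv - 3.0)

        next_state = _expected_state(min(onset + ibi, total), config, phenotype,
                                     t_on, lbnp_dur)
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + ibi) * fs)), n)
        if i1 <= i0:
            break
        tau = np.arange(i0, i1) / fs - onset
        seg, tp, tn_, vn = _pulse_template(tau, sap, dap, next_state["dap"], ibi)
        bp[i0:i1] = seg
        segf, tpf, tnf, _ = _pulse_template(tau, sfv, dfv, next_state["dfv"], ibi)
        fv[i0:i1] = segf
        truth.append(BeatTruth(onset=onset, ibi=ibi, sap=sap, dap=dap,
                               t_peak=onset + tp, t_notch=onset + tn_, v_notch=vn,
                               sfv=sfv, dfv=dfv,
                               t_peak_fv=onset + tpf, t_notch_fv=onset + tnf))
        onset += ibi
        state = next_state
        if onset >= total:
            break
    if i1 < n:  # pad any residual samples with the last value
        bp[i1:] = bp[i1 - 1]
        fv[i1:] = fv[i1 - 1]

    # slow channels at their native rate
    t10 = np.arange(int(round(total * config.fs_slow))) / config.fs_slow
    etco2_env = _piecewise_trend(t10, t_on, total, config.etco2_baseline_mmhg,
                                 -config.etco2_drop_mmhg)
    etco2_env = etco2_env + _ar1(rng, t10.size, config.etco2_noise_mmhg)
    # capnogram-like wave: plateaus at the end-tidal envelope, sharp
    # inspiratory dips between breaths
    resp = 0.5 - 0.5 * np.cos(2.0 * np.pi * config.resp_rate_hz * t10)
    etco2_sig = 2.0 + (etco2_env - 2.0) * resp ** 0.2
    ti = _piecewise_trend(t10, t_on, total, config.ti_baseline_ohm, config.ti_rise_ohm)
    ti = ti + _ar1(rng, t10.size, config.ti_noise_ohm)
    o2hb = _piecewise_trend(t10, t_on, total, config.o2hb_baseline_umol,
                            -config.o2hb_drop_umol)
    o2hb = o2hb + _ar1(rng, t10.size, config.nirs_noise_umol)
    hhb = _piecewise_trend(t10, t_on, total, config.hhb_baseline_umol,
                           config.hhb_rise_umol)
    hhb = hhb + _ar1(rng, t10.size, config.nirs_noise_umol)

    return SubjectRecording(
        subject_id=subject_id,
        bp=ChannelSignal("bp", bp, fs, "mmHg"),
        fv=ChannelSignal("fv", fv, config.fs_fv, "cm/s"),
        o2hb=ChannelSignal("o2hb", o2hb, config.fs_slow, "umol/L"),
        hhb=ChannelSignal("hhb", hhb, config.fs_slow, "umol/L"),
        etco2=ChannelSignal("etco2", etco2_sig, config.fs_slow, "mmHg"),
        ti=ChannelSignal("ti", ti, config.fs_slow, "ohm"),
        marks=marks,
        ground_truth=truth,
        phenotype=phenotype,
    )


def simulate_cohort(config: CohortConfig) -> list[SubjectRecording]:
    """Simulate ``config.n_subjects`` independent recordings.

    Per-subject seeds are spawned deterministically from ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)
    cohort = []
    for i, child in enumerate(children):
        try:
            cohort.append(simulate_subject(config, child, subject_id=f"S{i:02d}"))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for subject index {i}") from exc
    return cohort
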