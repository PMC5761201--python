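"""Assembly of the nine classification feature matrices.

The models and their feature counts:

========  ==============================================  =======
model id  contents                                        columns
========  ==============================================  =======
1         10 basic hemodynamics + 15 BP curve dynamics
          + 40 trend/variance                             65
2         model 1 + end-tidal CO2                         66
3         model 1 + thoracic impedance                    66
4         model 1 + 5 NIRS oxygenation features           70
5         model 1 + 60 flow-velocity features
          (15 curve dynamics, SFV/DFV/MFV, 40
          trend/variance, autoregulatory gain + phase)    125
6         model 1 + mean flow velocity                    66
7         model 1 + flow-velocity pulse height            66
8         10 basic hemodynamics                           10
9         SAP, DAP, MAP, HR                               4
========  ==============================================  =======

Samples are labeled 0 (baseline), 1 (first 75% of LBNP) or 2 (last 25%
of LBNP, end-stage before pre-syncope). Features are normalized to the
within-subject baseline mean, min–max scaled to [0, 1] on the training
cohort, and decimated by a factor 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import BP_TREND_PARAMS, FV_TREND_PARAMS, TREND_WINDOWS_S
from .landmarks import CURVE_FEATURE_NAMES
from .synthetic import ProtocolMarks

__all__ = [
    "FeatureMatrix",
    "MODEL_COLUMN_COUNTS",
    "model_columns",
    "label_samples",
    "assemble_features",
    "concat_features",
    "normalize_to_baseline",
    "MinMaxScalerBounds",
    "scale_unit_interval",
    "downsample_rows",
]

BASIC10 = ("SAP", "DAP", "MAP", "PP", "IBI", "HR", "SV", "CO", "TPR", "LVET")

MODEL_COLUMN_COUNTS = {1: 65, 2: 66, 3: 66, 4: 70, 5: 125, 6: 66, 7: 66, 8: 10, 9: 4}


def _trend_block(params: tuple[str, ...]) -> list[str]:
    return [f"{p}_{stat}_{int(w)}"
            for p in params for w in TREND_WINDOWS_S for stat in ("trend", "var")]


def model_columns(model_id: int) -> list[str]:
    """Ordered feature-column names for one model."""
    m1 = list(BASIC10) + [f"bp_{n}" for n in CURVE_FEATURE_NAMES] + _trend_block(BP_TREND_PARAMS)
    table = {
        1: m1,
        2: m1 + ["ETCO2"],
        3: m1 + ["TI"],
        4: m1 + ["O2Hb", "HHb", "tHb", "ratio_O2Hb", "ratio_HHb"],
        5: (m1 + [f"fv_{n}" for n in CURVE_FEATURE_NAMES] + ["SFV", "DFV", "MFV"]
            + _trend_block(FV_TREND_PARAMS) + ["tfa_gain", "tfa_phase"]),
        6: m1 + ["MFV"],
        7: m1 + ["FV_PP"],
        8: list(BASIC10),
        9: ["SAP", "DAP", "MAP", "HR"],
    }
    if model_id not in table:
        raise ValueError(f"unknown model id {model_id}; expected 1-9")
    cols = table[model_id]
    assert len(cols) == MODEL_COLUMN_COUNTS[model_id]
    return cols


@dataclass
class FeatureMatrix:
    """Labeled sample-by-feature table for one model."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: np.ndarray
    times: np.ndarray
    model_id: int

    def __post_init__(self) -> None:
        n = len(self.X)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        self.times = np.asarray(self.times, dtype=float)
        if not (self.y.size == self.subject_ids.size == self.times.size == n):
            raise ValueError("misaligned feature matrix components")

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X.loc[mask].reset_index(drop=True),
                             self.y[mask], self.subject_ids[mask],
                             self.times[mask], self.model_id)

    @property
    def n_samples(self) -> int:
        return len(self.X)


def label_samples(times: np.ndarray, marks: ProtocolMarks) -> np.ndarray:
    """Three-class hypovolemia labels for sample times.

    0 during baseline; 1 during the first 75% of LBNP; 2 during the last
    25% (end-stage LBNP before pre-syncope). The 75% boundary itself
    belongs to class 2 (half-open convention). Times outside the
    recording are labeled −1 (rejected).
    """
    times = np.asarray(times, dtype=float)
    t0, t_on, t_end = marks.t_baseline_start, marks.t_lbnp_onset, marks.t_presyncope
    split = t_on + 0.75 * marks.lbnp_duration
    labels = np.full(times.shape, -1, dtype=int)
    labels[(times >= t0) & (times < t_on)] = 0
    labels[(times >= t_on) & (times < split)] = 1
    labels[(times >= split) & (times <= t_end)] = 2
    return labels


def assemble_features(beat_table: pd.DataFrame, model_id: int,
                      marks: ProtocolMarks) -> FeatureMatrix:
    """Select one model's columns from a per-subject beat table and label rows."""
    cols = model_columns(model_id)
    missing = [c for c in cols if c not in beat_table.columns]
    if missing:
        raise ValueError(
            f"model {model_id} requires channel-derived columns missing from "
            f"the beat table: {missing}")
    times = beat_table["t"].to_numpy(dtype=float)
    labels = label_samples(times, marks)
    keep = labels >= 0
    order = np.argsort(times[keep], kind="stable")
    idx = np.flatnonzero(keep)[order]
    return FeatureMatrix(
        X=beat_table.iloc[idx][cols].reset_index(drop=True),
        y=labels[idx],
        subject_ids=beat_table.iloc[idx]["subject_id"].to_numpy(),
        times=times[idx],
        model_id=model_id,
    )


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-subject matrices of the same model."""
    if not parts:
        raise ValueError("no feature matrices to concatenate")
    mid = parts[0].model_id
    if any(p.model_id != mid for p in parts):
        raise ValueError("mixed model ids")
    return FeatureMatrix(
        X=pd.concat([p.X for p in parts], ignore_index=True),
        y=np.concatenate([p.y for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        times=np.concatenate([p.times for p in parts]),
        model_id=mid,
    )


def normalize_to_baseline(fm: FeatureMatrix,
                          marks: ProtocolMarks | dict[str, ProtocolMarks],
                          min_baseline_rows: int = 10) -> FeatureMatrix:
    """Express each feature as relative change from its within-subject baseline mean.

    Features whose baseline mean is (numerically) zero — e.g. trends —
    are baseline-mean-subtracted instead of divided. Applied per subject;
    ``marks`` may be a single ProtocolMarks or a dict keyed by subject.
    """
    X = fm.X.copy()
    for sid in np.unique(fm.subject_ids):
        m = marks[sid] if isinstance(marks, dict) else marks
        rows = fm.subject_ids == sid
        base = rows & (fm.times >= m.t_baseline_start) & (fm.times < m.t_lbnp_onset)
        if base.sum() < min_baseline_rows:
            raise ValueError(f"subject {sid}: fewer than {min_baseline_rows} baseline rows")
        mu = X.loc[base].mean(axis=0)
        divide = mu.abs() >= 1e-9
        sub = X.loc[rows, divide.index[divide]]
        X.loc[rows, divide.index[divide]] = sub / mu[divide]
        subz = X.loc[rows, divide.index[~divide]]
        X.loc[rows, divide.index[~divide]] = subz - mu[~divide]
    return FeatureMatrix(X, fm.y.copy(), fm.subject_ids.copy(), fm.times.copy(), fm.model_id)


@dataclass
class MinMaxScalerBounds:
    """Per-feature min–max bounds fit on a training matrix."""

    lo: pd.Series
    hi: pd.Series
    zero_range: list[str] = field(default_factory=list)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        span = self.hi - self.lo
        out = (X - self.lo) / span.where(span != 0, 1.0)
        out[self.zero_range] = 0.5
        return out.clip(0.0, 1.0)


def scale_unit_interval(train: FeatureMatrix,
                        apply_to: FeatureMatrix | None = None
                        ) -> tuple[FeatureMatrix, FeatureMatrix | None, MinMaxScalerBounds]:
    """Min–max scale features to [0, 1] using training bounds only.

    Test values are transformed with the training bounds and clipped to
    [0, 1]; zero-range features map to 0.5.
    """
    if train.n_samples == 0:
        raise ValueError("empty training matrix")
    lo = train.X.min(axis=0)
    hi = train.X.max(axis=0)
    scaler = MinMaxScalerBounds(lo, hi, list(train.X.columns[(hi - lo) == 0]))
    train_s = FeatureMatrix(scaler.transform(train.X), train.y, train.subject_ids,
                            train.times, train.model_id)
    applied = None
    if apply_to is not None:
        applied = FeatureMatrix(scaler.transform(apply_to.X), apply_to.y,
                                apply_to.subject_ids, apply_to.times, apply_to.model_id)
    return train_s, applied, scaler


def downsample_rows(fm: FeatureMatrix, factor: int = 10) -> FeatureMatrix:
    """Keep every ``factor``-th row per subject (stride decimation, offset 0)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return fm
    keep = np.zeros(fm.n_samples, dtype=bool)
    for sid in pd.unique(fm.subject_ids):
        idx = np.flatnonzero(fm.subject_ids == sid)
        keep[idx[::factor]] = True
    return fm.subset(keep)
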