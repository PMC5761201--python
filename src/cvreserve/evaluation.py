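"""Model-performance quantification.

Three complementary methods:

1. **One-vs-all sensitivity and specificity** per class, from 3×3
   confusion counts, summarized across subjects as median [25%; 75%].
2. **Model error**: per-class mean squared error between the true class
   labels and the centered moving average of the predicted labels.
3. **Log-odds-ratio cutoff analysis**: LOR = ln(P(class 2)/P(class 0))
   per sample; a lower and upper cutoff turn the LOR into a three-class
   rule (≤ low → 0, (low, high] → 1, > high → 2), optimized by stepwise
   incremental thresholds to maximize the summed per-class sensitivity
   and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "confusion_matrix",
    "sens_spec_one_vs_all",
    "moving_average_prediction",
    "ModelError",
    "model_error",
    "log_odds_ratio",
    "CutoffPair",
    "classify_by_cutoffs",
    "optimize_cutoffs",
    "summarize_cohort",
]

N_CLASSES = 3
LOR_EPS = 1e-6


def confusion_matrix(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """3×3 counts; entry (i, j) = samples of true class i predicted as j."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.size and (pred.min() < 0 or pred.max() >= N_CLASSES
                      or truth.min() < 0 or truth.max() >= N_CLASSES):
        raise ValueError("labels must lie in {0, 1, 2}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (truth, pred), 1)
    return cm


def sens_spec_one_vs_all(cm: np.ndarray, c: int) -> tuple[float, float]:
    """One-vs-all sensitivity and specificity of class ``c``.

    sensitivity = cm[c, c] / Σ_j cm[c, j]; specificity counts every
    non-class-c sample predicted as any class other than c. Empty
    denominators yield NaN (undefined, excluded from cohort medians).
    """
    cm = np.asarray(cm)
    pos = cm[c].sum()
    sens = cm[c, c] / pos if pos > 0 else np.nan
    neg_rows = [i for i in range(N_CLASSES) if i != c]
    neg = cm[neg_rows].sum()
    tn = cm[np.ix_(neg_rows, neg_rows)].sum()
    spec = tn / neg if neg > 0 else np.nan
    return float(sens), float(spec)


def moving_average_prediction(pred: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean of integer class predictions, edges truncated."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    pred = np.asarray(pred, dtype=float)
    half = window // 2
    n = pred.size
    csum = np.concatenate([[0.0], np.cumsum(pred)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class ModelError:
    """Per-class and total mean squared error of the smoothed prediction."""

    per_class: dict[int, float]
    total: float
    window: int


def model_error(pred: np.ndarray, truth: np.ndarray, window: int = 31) -> ModelError:
    """MSE between true labels and the moving-averaged prediction, per class.

    The total is the sum over the three per-class errors; classes absent
    from ``truth`` are NaN and excluded from the total.
    """
    truth = np.asarray(truth, dtype=float)
    smoothed = moving_average_prediction(pred, window)
    if smoothed.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    per = {}
    for c in range(N_CLASSES):
        m = truth == c
        per[c] = float(np.mean((truth[m] - smoothed[m]) ** 2)) if m.any() else float("nan")
    total = float(np.nansum(list(per.values())))
    return ModelError(per_class=per, total=total, window=window)


def log_odds_ratio(probs: np.ndarray) -> np.ndarray:
    """LOR = ln(max(p2, ε) / max(p0, ε)) per probability triplet."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    return np.log(np.maximum(probs[:, 2], LOR_EPS) / np.maximum(probs[:, 0], LOR_EPS))


@dataclass(frozen=True)
class CutoffPair:
    """Lower and upper LOR thresholds (low < high)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("need low < high")


def classify_by_cutoffs(lor: np.ndarray, cutoffs: CutoffPair) -> np.ndarray:
    """LOR ≤ low → 0; low < LOR ≤ high → 1; LOR > high → 2."""
    lor = np.asarray(lor, dtype=float)
    out = np.ones(lor.shape, dtype=int)
    out[lor <= cutoffs.low] = 0
    out[lor > cutoffs.high] = 2
    return out


def _objective_grid(lor: np.ndarray, truth: np.ndarray,
                    grid: np.ndarray) -> tuple[CutoffPair, float]:
    """Exhaustive (low, high) search via per-class cumulative counts."""
    order = np.argsort(lor, kind="stable")
    lor_s = lor[order]
    truth_s = truth[order]
    n_c = np.array([(truth == c).sum() for c in range(N_CLASSES)], dtype=float)
    n = truth.size
    # cum[c][k] = number of class-c samples with LOR <= grid[k]
    pos = np.searchsorted(lor_s, grid, side="right")
    cum = np.stack([np.searchsorted(lor_s[truth_s == c], grid, side="right")
                    for c in range(N_CLASSES)]).astype(float)

    best_obj = -np.inf
    best = None
    for i in range(grid.size - 1):
        a = cum[:, i]                        # per-class counts predicted 0
        b = cum[:, i + 1:] - a[:, None]      # predicted 1, for each high > low
        c2 = n_c[:, None] - cum[:, i + 1:]   # predicted 2
        with np.errstate(invalid="ignore", divide="ignore"):
            sens0 = a[0] / n_c[0]
            sens1 = b[1] / n_c[1]
            sens2 = c2[2] / n_c[2]
            pred0 = a.sum()
            pred1 = b.sum(axis=0)
            pred2 = c2.sum(axis=0)
            spec0 = 1.0 - (pred0 - a[0]) / (n - n_c[0])
            spec1 = 1.0 - (pred1 - b[1]) / (n - n_c[1])
            spec2 = 1.0 - (pred2 - c2[2]) / (n - n_c[2])
            obj = (sens0 + spec0) + (sens1 + spec1) + (sens2 + spec2)
        j = int(np.argmax(obj))
        if obj[j] > best_obj + 1e-12:
            best_obj = float(obj[j])
            best = CutoffPair(float(grid[i]), float(grid[i + 1 + j]))
    return best, best_obj


def optimize_cutoffs(lor: np.ndarray, truth: np.ndarray,
                     step: float = 0.01) -> tuple[CutoffPair, dict]:
    """Stepwise-incremental threshold search maximizing Σ (sens + spec).

    Candidate thresholds form a grid of the given step spanning
    [min(LOR) − step, max(LOR) + step]; all pairs with low < high are
    scored and ties break toward the smallest low, then smallest high.
    """
    lor = np.asarray(lor, dtype=float)
    truth = np.asarray(truth, dtype=int)
    present = set(np.unique(truth))
    if present != {0, 1, 2}:
        raise ValueError(f"all three classes required, found {sorted(present)}")
    g0 = np.floor((lor.min() - step) / step) * step
    g1 = np.ceil((lor.max() + step) / step) * step
    grid = np.arange(g0, g1 + step / 2, step)
    best, best_obj = _objective_grid(lor, truth, grid)
    pred = classify_by_cutoffs(lor, best)
    cm = confusion_matrix(pred, truth)
    metrics = {"objective": best_obj,
               "per_class": {c: sens_spec_one_vs_all(cm, c) for c in range(N_CLASSES)}}
    return best, metrics


def summarize_cohort(values: np.ndarray | list) -> dict:
    """Median and [25%; 75%] quartiles across subjects, NaNs excluded."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return {"median": float("nan"), "q25": float("nan"), "q75": float("nan"), "n": 0}
    return {
        "median": float(np.median(arr)),
        "q25": float(np.percentile(arr, 25)),  # linear-interpolation convention
        "q75": float(np.percentile(arr, 75)),
        "n": int(arr.size),
    }
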