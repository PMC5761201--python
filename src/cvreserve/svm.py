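"""RBF-kernel SVM training, grid search and leave-one-subject-out evaluation.

Three-class soft-margin support-vector classification with a Gaussian
kernel k(u, v) = exp(−gamma·‖u−v‖²). Multiclass is one-vs-one with
pairwise-coupled sigmoid probability calibration (the libsvm scheme, via
scikit-learn's SVC with probability estimates). The hyperparameter
search spans 64 combinations: 8 log-spaced C values in [1e−2, 1e2] by
8 log-spaced gamma values in [1e−3, 1].

Evaluation follows a random-subset leave-one-subject-out protocol: for
each test subject, a fresh random draw of training subjects (default 30)
is taken from the remaining cohort, the scaler and classifier are fit on
the pooled training rows only, and every row of the held-out subject is
classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FeatureMatrix, concat_features, scale_unit_interval

__all__ = [
    "ModelConfig",
    "TrainedClassifier",
    "SubjectResult",
    "LosoRun",
    "hyperparameter_grids",
    "train_svm",
    "predict",
    "loso_evaluate",
    "grid_search",
]

N_CLASSES = 3


@dataclass(frozen=True)
class ModelConfig:
    """Feature-set id plus RBF-SVM hyperparameters."""

    model_id: int
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


def hyperparameter_grids() -> tuple[np.ndarray, np.ndarray]:
    """The 8-value C and gamma grids (64 combinations in total).

    C spans 1e−2…1e2 and gamma 1e−3…1, both log-spaced and ascending.
    """
    return np.logspace(-2, 2, 8), np.logspace(-3, 0, 8)


@dataclass
class TrainedClassifier:
    """A fitted one-vs-one RBF SVM with its scaler and provenance."""

    svc: SVC
    scaler: object
    config: ModelConfig
    training_subjects: list[str]
    seed: int
    n_features: int

    def predict_proba3(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """(n, 3) class-membership probabilities, zero for absent classes."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        raw = self.svc.predict_proba(X)
        out = np.zeros((X.shape[0], N_CLASSES))
        for k, cls in enumerate(self.svc.classes_):
            out[:, int(cls)] = raw[:, k]
        return out


def train_svm(X: pd.DataFrame, y: np.ndarray, config: ModelConfig,
              seed: int = 0, scaler: object = None,
              training_subjects: list[str] | None = None) -> TrainedClassifier:
    """Fit the soft-margin RBF SVM with probability calibration."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    svc = SVC(kernel="rbf", C=config.C, gamma=config.gamma, probability=True,
              random_state=int(seed) % (2**31), cache_size=200)
    with warnings.catch_warnings():
        # scikit-learn deprecates probability=True, but it is the libsvm
        # pairwise-coupling estimator this pipeline specifies
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(np.asarray(X, dtype=float), y)
    return TrainedClassifier(svc=svc, scaler=scaler, config=config,
                             training_subjects=list(training_subjects or []),
                             seed=int(seed), n_features=X.shape[1])


def predict(model: TrainedClassifier, X: pd.DataFrame | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Classify rows: argmax of the probability triplet, ties to the lower class.

    Returns (labels, probability triplets).
    """
    probs = model.predict_proba3(X)
    return np.argmax(probs, axis=1), probs  # argmax takes the first max → lower class


@dataclass
class SubjectResult:
    """LOSO outcome for one held-out subject."""

    subject_id: str
    truth: np.ndarray
    pred: np.ndarray
    probs: np.ndarray
    times: np.ndarray
    training_subjects: list[str]


@dataclass
class LosoRun:
    """All per-subject results of one leave-one-subject-out pass."""

    config: ModelConfig
    n_train: int
    seed: int
    results: list[SubjectResult] = field(default_factory=list)


def _training_draws(subjects: list[str], n_train: int, seed: int) -> dict[str, list[str]]:
    """One fresh uniform draw of training subjects per test subject."""
    rng = np.random.default_rng(seed)
    draws = {}
    for s in subjects:
        pool = [t for t in subjects if t != s]
        idx = rng.choice(len(pool), size=n_train, replace=False)
        draws[s] = [pool[i] for i in sorted(idx)]
    return draws


def resolve_n_train(n_subjects: int, n_train: int | None) -> int:
    """Default 30 training subjects, scaled to ⌊0.7·(N−1)⌋ for smaller cohorts."""
    if n_train is None:
        n_train = 30
    if n_subjects <= n_train:
        n_train = int(0.7 * (n_subjects - 1))
    if n_train < 1:
        raise ValueError(f"cohort of {n_subjects} subjects too small for LOSO")
    return n_train


def loso_evaluate(features_by_subject: dict[str, FeatureMatrix],
                  config: ModelConfig, n_train: int | None = None,
                  seed: int = 0,
                  draws: dict[str, list[str]] | None = None) -> LosoRun:
    """Random-subset leave-one-subject-out evaluation.

    For each subject: fit min–max scaler and SVM on the pooled rows of
    ``n_train`` randomly drawn other subjects, then classify every row of
    the held-out subject. Deterministic for fixed inputs and seed.
    """
    subjects = sorted(features_by_subject)
    n_train = resolve_n_train(len(subjects), n_train)
    if draws is None:
        draws = _training_draws(subjects, n_train, seed)
    run = LosoRun(config=config, n_train=n_train, seed=seed)
    for s in subjects:
        train_subj = draws[s]
        if s in train_subj:
            raise ValueError(f"test subject {s} leaked into its training set")
        train_fm = concat_features([features_by_subject[t] for t in train_subj])
        test_fm = features_by_subject[s]
        train_s, test_s, scaler = scale_unit_interval(train_fm, test_fm)
        model = train_svm(train_s.X, train_s.y, config, seed=seed, scaler=scaler,
                          training_subjects=train_subj)
        pred, probs = predict(model, test_s.X)
        run.results.append(SubjectResult(
            subject_id=s, truth=test_fm.y.copy(), pred=pred, probs=probs,
            times=test_fm.times.copy(), training_subjects=train_subj))
    return run


def _sens_spec_sum(truth: np.ndarray, pred: np.ndarray) -> float:
    """Σ over classes of (sensitivity + specificity); undefined terms skipped."""
    from .evaluation import confusion_matrix, sens_spec_one_vs_all

    cm = confusion_matrix(pred, truth)
    total = 0.0
    for c in range(N_CLASSES):
        sens, spec = sens_spec_one_vs_all(cm, c)
        if np.isfinite(sens):
            total += sens
        if np.isfinite(spec):
            total += spec
    return total


def loso_objective(run: LosoRun) -> float:
    """Mean over tested subjects of the summed per-class sensitivity+specificity."""
    return float(np.mean([_sens_spec_sum(r.truth, r.pred) for r in run.results]))


def grid_search(features_by_subject: dict[str, FeatureMatrix], model_id: int,
                seed: int = 0, n_train: int | None = None
                ) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive 8×8 (C, gamma) search maximizing the LOSO objective.

    The random training subsets are shared across all 64 configurations
    (variance reduction). Ties break toward smaller C, then smaller
    gamma. Returns the winning configuration and the 64-row objective
    log.
    """
    c_grid, g_grid = hyperparameter_grids()
    subjects = sorted(features_by_subject)
    n_train = resolve_n_train(len(subjects), n_train)
    draws = _training_draws(subjects, n_train, seed)
    records = []
    best: tuple[float, float, float] | None = None
    for c in c_grid:
        for g in g_grid:
            cfg = ModelConfig(model_id=model_id, C=float(c), gamma=float(g))
            run = loso_evaluate(features_by_subject, cfg, n_train=n_train,
                                seed=seed, draws=draws)
            obj = loso_objective(run)
            records.append({"C": float(c), "gamma": float(g), "objective": obj})
            if best is None or obj > best[0] + 1e-12:
                best = (obj, float(c), float(g))
    log = pd.DataFrame(records)
    assert len(log) == 64
    return ModelConfig(model_id=model_id, C=best[1], gamma=best[2]), log
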