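"""Feature-based coding/noncoding classifiers and their evaluation harness.

The primary model is a feed-forward network (two hidden ReLU layers, sigmoid
output, adaptive-moment optimizer with early stopping); SVM and Gaussian
naive-Bayes baselines share the same interface for comparison. The noncoding
class is the positive class throughout: predicted probabilities near 1 mean
noncoding.

Also here: stratified splitting and k-fold cross-validation, the
confusion-matrix metric set (precision/recall/specificity/F1/AUROC),
Monte-Carlo permutation-sampled Shapley feature attributions, and recursive
feature elimination ranked by mean |Shapley| on a held-out slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .seqio import TranscriptRecord

NONCODING = 1  # positive class
CODING = 0

ARCHIVE_SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    pass


class StratificationError(ValueError):
    pass


class AurocUndefinedError(ValueError):
    """Single-class y_true: AUROC is undefined. Carries the other metrics."""

    def __init__(self, metrics: "EvalMetrics"):
        super().__init__("AUROC undefined for single-class labels")
        self.metrics = metrics


@dataclass(frozen=True)
class ModelConfig:
    mode: str = "human_specific"  # or "species_agnostic"
    tier: str = "standard"  # or "basic"
    hidden_layers: tuple[int, ...] = (64, 32)
    seed: int = 0
    epochs: int = 300
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("human_specific", "species_agnostic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tier not in ("basic", "standard"):
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def n_features(self) -> int:
        if self.tier == "basic":
            return 10
        return 35 if self.mode == "human_specific" else 33


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    specificity: float
    f1: float
    auroc: Optional[float]
    accuracy: float


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it."""

    config: ModelConfig
    feature_names: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    estimator: object
    kind: str = "ann"
    baseline: Optional[np.ndarray] = None  # training-set feature means (raw scale)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_std


def _as_matrix(X, feature_names: Sequence[str]) -> np.ndarray:
    """Validate and coerce input features against the model's roster."""
    if hasattr(X, "columns"):  # pandas DataFrame
        cols = list(X.columns)
        missing = [n for n in feature_names if n not in cols]
        extra = [c for c in cols if c not in feature_names]
        if missing or extra:
            raise ConfigurationError(
                f"feature mismatch: missing {missing}, unexpected {extra}"
            )
        return X[list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ConfigurationError(
            f"expected {len(feature_names)} feature columns, got {X.shape}"
        )
    return X


def labels_to_y(records: Sequence[TranscriptRecord]) -> np.ndarray:
    """Map labels to ints: noncoding -> 1 (positive), coding -> 0."""
    out = []
    for r in records:
        if r.label not in ("coding", "noncoding"):
            raise ValueError(f"record {r.id!r} is unlabeled")
        out.append(NONCODING if r.label == "noncoding" else CODING)
    return np.array(out, dtype=int)


def split_train_test(
    records: Sequence[TranscriptRecord], fraction: float = 0.8, seed: int = 0
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Stratified train/test split; ``fraction`` goes to training."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    y = labels_to_y(records)
    if len(np.unique(y)) < 2:
        raise StratificationError("both classes required for a stratified split")
    train, test = train_test_split(
        list(records), train_size=fraction, stratify=y, random_state=seed
    )
    return list(train), list(test)


def train_ann(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    feature_names: Sequence[str],
    check_feature_count: bool = True,
) -> TrainedModel:
    """Standardize and fit the feed-forward network.

    Binary cross-entropy objective, ReLU activations, adam optimizer with
    L2 regularization, up to ``config.epochs`` epochs; fully deterministic
    under ``config.seed``. ``check_feature_count=False`` skips the
    tier/roster cardinality check for ad-hoc feature sets outside the four
    standard configurations.
    """
    X = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    if len(np.unique(y)) < 2:
        raise StratificationError("training requires both classes")
    if check_feature_count and len(feature_names) != config.n_features:
        raise ConfigurationError(
            f"{config.mode}/{config.tier} expects {config.n_features} features, "
            f"got {len(feature_names)}"
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    # fixed epoch budget with L2 regularization rather than early stopping:
    # a 10% validation slice is too noisy to stop on at desk-scale corpus
    # sizes and routinely halts training before the loss has moved
    est = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation="relu",
        solver="adam",
        alpha=1.0,
        max_iter=config.epochs,
        tol=1e-6,
        n_iter_no_change=30,
        random_state=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xs, y)
    return TrainedModel(
        config=config,
        feature_names=tuple(feature_names),
        scaler_mean=mean,
        scaler_std=std,
        estimator=est,
        kind="ann",
        baseline=mean.copy(),
    )


def baseline_models(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    seed: int = 0,
    config: Optional[ModelConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Fit an SVM or Gaussian naive-Bayes baseline with standard defaults."""
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    X = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise StratificationError("training requires both classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    if kind == "svm":
        est = SVC(probability=True, random_state=seed)
    elif kind == "naive_bayes":
        est = GaussianNB()
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(Xs, y)
    cfg = config or ModelConfig(seed=seed)
    return TrainedModel(
        config=cfg,
        feature_names=tuple(feature_names),
        scaler_mean=mean,
        scaler_std=std,
        estimator=est,
        kind=kind,
        baseline=mean.copy(),
    )


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    """Per-record probability of the noncoding class, in [0,1]."""
    Xm = _as_matrix(X, model.feature_names)
    Xs = model._standardize(Xm)
    proba = model.estimator.predict_proba(Xs)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(NONCODING)]


def predict_labels(model: TrainedModel, X) -> np.ndarray:
    """1 (noncoding) where p >= threshold, else 0 (coding)."""
    p = predict_proba(model, X)
    return (p >= model.config.threshold).astype(int)


def compute_metrics(
    y_true: np.ndarray, p: np.ndarray, threshold: float = 0.5
) -> EvalMetrics:
    """Confusion-matrix metrics plus rank-based AUROC (ties averaged).

    Noncoding (1) is the positive class. Raises
    :class:`AurocUndefinedError` — carrying the threshold metrics — when
    y_true contains a single class.
    """
    y_true = np.asarray(y_true)
    p = np.asarray(p, dtype=float)
    if len(y_true) != len(p):
        raise ValueError("length mismatch")
    y_pred = (p >= threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    accuracy = (tp + tn) / len(y_true)
    if len(np.unique(y_true)) < 2:
        raise AurocUndefinedError(
            EvalMetrics(precision, recall, specificity, f1, None, accuracy)
        )
    auroc = _auroc_rank(y_true, p)
    return EvalMetrics(precision, recall, specificity, f1, auroc, accuracy)


def _auroc_rank(y_true: np.ndarray, p: np.ndarray) -> float:
    """Mann–Whitney AUROC with average ranks for ties (trapezoidal ROC)."""
    from scipy.stats import rankdata

    ranks = rankdata(p)
    n_pos = int(np.sum(y_true == 1))
    n_neg = len(y_true) - n_pos
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CvResult:
    accuracies: tuple[float, ...]
    mean: float
    sd: float


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    trainer: Callable[[np.ndarray, np.ndarray], TrainedModel],
    seed: int = 0,
    threshold: float = 0.5,
) -> CvResult:
    """Stratified k-fold cross-validation; each record tested exactly once."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise StratificationError(f"k={k} exceeds the size of a class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = np.asarray(X, dtype=float)
    accs = []
    for tr_idx, te_idx in skf.split(X, y):
        model = trainer(X[tr_idx], y[tr_idx])
        p = predict_proba(model, X[te_idx])
        accs.append(float(np.mean((p >= threshold).astype(int) == y[te_idx])))
    return CvResult(tuple(accs), float(np.mean(accs)), float(np.std(accs)))


def shap_importance(
    model: TrainedModel,
    X: np.ndarray,
    n_samples: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Per-feature mean |Shapley value|, Monte-Carlo permutation sampled.

    For each row, ``n_samples`` random feature permutations are walked from
    the baseline (training-set mean) to the row, recording each feature's
    marginal change in predicted noncoding probability; the Shapley estimate
    is the average marginal contribution, and the importance is the mean of
    its absolute value over rows.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    Xm = _as_matrix(X, model.feature_names)
    if len(Xm) == 0:
        raise ValueError("X must be non-empty")
    rng = np.random.default_rng(seed)
    d = Xm.shape[1]
    baseline = model.baseline if model.baseline is not None else Xm.mean(axis=0)

    def f(mat: np.ndarray) -> np.ndarray:
        Xs = model._standardize(mat)
        proba = model.estimator.predict_proba(Xs)
        classes = list(model.estimator.classes_)
        return proba[:, classes.index(NONCODING)]

    abs_phi = np.zeros((len(Xm), d))
    for r, x in enumerate(Xm):
        phi = np.zeros(d)
        for _ in range(n_samples):
            perm = rng.permutation(d)
            # d+1 points along the path baseline -> x, evaluated in one batch
            path = np.tile(baseline, (d + 1, 1))
            for step, j in enumerate(perm, start=1):
                path[step:, j] = x[j]
            preds = f(path)
            phi[perm] += np.diff(preds)
        abs_phi[r] = np.abs(phi / n_samples)
    importances = abs_phi.mean(axis=0)
    return {name: float(v) for name, v in zip(model.feature_names, importances)}


def rfe(
    X: np.ndarray,
    y: np.ndarray,
    n_keep: int,
    config: ModelConfig,
    feature_names: Sequence[str],
    n_shap_rows: int = 50,
    n_shap_samples: int = 10,
) -> list[str]:
    """Recursive feature elimination ranked by held-out mean |Shapley|.

    Trains, attributes on a held-out slice, drops the lowest-ranked feature,
    and repeats until ``n_keep`` remain; survivors are returned in
    final-rank order (most important first). The intermediate models ignore
    ``config.n_features`` (feature count shrinks every round).
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    names = list(feature_names)
    if n_keep > len(names):
        raise ValueError("n_keep exceeds feature count")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)

    def fit_and_rank(current: list[str]) -> list[str]:
        idx = [names.index(n) for n in current]
        Xc = X[:, idx]
        tr, ho = train_test_split(
            np.arange(len(y)), train_size=0.8, stratify=y, random_state=config.seed
        )
        mean = Xc[tr].mean(axis=0)
        std = Xc[tr].std(axis=0)
        std[std == 0] = 1.0
        est = MLPClassifier(
            hidden_layer_sizes=tuple(config.hidden_layers),
            alpha=1.0,
            max_iter=config.epochs,
            tol=1e-6,
            n_iter_no_change=30,
            random_state=config.seed,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit((Xc[tr] - mean) / std, y[tr])
        model = TrainedModel(
            config=config,
            feature_names=tuple(current),
            scaler_mean=mean,
            scaler_std=std,
            estimator=est,
            baseline=mean.copy(),
        )
        rows = rng.choice(ho, size=min(n_shap_rows, len(ho)), replace=False)
        imp = shap_importance(model, Xc[rows], n_samples=n_shap_samples, seed=config.seed)
        return sorted(current, key=lambda n: -imp[n])

    current = list(names)
    while len(current) > n_keep:
        ranked = fit_and_rank(current)
        current.remove(ranked[-1])
    return fit_and_rank(current)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model archive (versioned schema) to disk."""
    joblib.dump(
        {
            "schema_version": ARCHIVE_SCHEMA_VERSION,
            "kind": model.kind,
            "config": model.config,
            "feature_names": model.feature_names,
            "scaler_mean": model.scaler_mean,
            "scaler_std": model.scaler_std,
            "estimator": model.estimator,
            "baseline": model.baseline,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(f"unsupported model archive version {blob.get('schema_version')}")
    return TrainedModel(
        config=blob["config"],
        feature_names=blob["feature_names"],
        scaler_mean=blob["scaler_mean"],
        scaler_std=blob["scaler_std"],
        estimator=blob["estimator"],
        kind=blob["kind"],
        baseline=blob["baseline"],
    )


def write_metrics_tsv(metrics: dict[str, EvalMetrics], path: str | Path) -> None:
    """One row per model: precision, recall, specificity, F1, AUROC."""
    with open(path, "w") as fh:
        fh.write("model\tprecision\trecall\tspecificity\tf1\tauroc\n")
        for name, m in metrics.items():
            auroc = f"{m.auroc:.4f}" if m.auroc is not None else "NA"
            fh.write(
                f"{name}\t{m.precision:.4f}\t{m.recall:.4f}\t{m.specificity:.4f}\t"
                f"{m.f1:.4f}\t{auroc}\n"
            )


def roc_points(y_true: np.ndarray, p: np.ndarray) -> np.ndarray:
    """(fpr, tpr) pairs for plotting, via sklearn's ROC computation."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y_true, p)
    return np.column_stack([fpr, tpr])


def write_roc_tsv(y_true: np.ndarray, p: np.ndarray, path: str | Path) -> None:
    pts = roc_points(y_true, p)
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in pts:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
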