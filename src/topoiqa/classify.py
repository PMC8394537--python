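"""Regularized logistic-regression quality classifier and evaluation metrics.

The classifier is an L2-penalized logistic regression fitted on the
30-element topological feature vectors after per-feature standardization
(zero mean, unit variance, statistics estimated on the training fold only
— mandatory at the very weak default regularization ``C = 150000`` since
descriptor magnitudes span several orders).  Labels are encoded good = 0,
bad = 1 internally (the legacy value 2 is accepted as "bad").

Metric formulas (accuracy, precision, recall, F1, MCC) are evaluated with
exact rational arithmetic from confusion counts at the 0.5 probability
threshold; ROC points sweep all score thresholds and AUC is the
trapezoidal area, which equals the tie-averaged rank probability
P(score_pos > score_neg).
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from itertools import product
from math import sqrt

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cubical import ValidationError

__all__ = [
    "LogitConfig",
    "DEFAULT_CONFIG",
    "DEFAULT_GRID",
    "ConfusionCounts",
    "ClassificationReport",
    "FittedModel",
    "encode_labels",
    "train_logit",
    "tune_logit",
    "evaluate",
    "metrics_from_counts",
    "auc_from_scores",
]

logger = logging.getLogger(__name__)

LABEL_NAMES = {0: "good", 1: "bad"}


@dataclass(frozen=True)
class LogitConfig:
    """Hyperparameters of the L2 logistic regression."""

    tolerance: float = 1e-8
    C: float = 150_000.0
    max_iterations: int = 10_000
    solver: str = "liblinear"
    penalty: str = "l2"

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.C <= 0 or self.max_iterations < 1:
            raise ValidationError(f"invalid logistic-regression config: {self}")


#: The selected configuration (grid-search optimum on the full study).
DEFAULT_CONFIG = LogitConfig()

#: Hyperparameter grid explored during tuning.
DEFAULT_GRID: dict[str, tuple] = {
    "tolerance": (1e-4, 1e-6, 1e-8),
    "C": (50_000.0, 100_000.0, 150_000.0),
    "solver": ("lbfgs", "saga", "liblinear"),
    "max_iterations": (10_000, 50_000, 100_000),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts for one positive label."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(TP=self.TN, TN=self.TP, FP=self.FN, FN=self.FP)


@dataclass
class ClassificationReport:
    """Confusion counts plus the standard binary-classification metrics."""

    counts: ConfusionCounts
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    mcc: float
    supports: dict[str, int]
    auc: float | None = None
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {
            "counts": asdict(self.counts),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "supports": self.supports,
            "auc": self.auc,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def pretty(self) -> str:
        lines = [
            f"{'label':>8} {'precision':>9} {'recall':>7} {'f1':>6} {'support':>8}"
        ]
        for lab in ("good", "bad"):
            lines.append(
                f"{lab:>8} {self.precision[lab]:>9.3f} {self.recall[lab]:>7.3f} "
                f"{self.f1[lab]:>6.3f} {self.supports[lab]:>8d}"
            )
        lines.append(f"accuracy: {self.accuracy:.3f}  MCC: {self.mcc:.3f}")
        if self.auc is not None:
            lines.append(f"AUC: {self.auc:.3f}")
        return "\n".join(lines)

    def roc_to_csv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame({"fpr": self.roc_fpr, "tpr": self.roc_tpr}).to_csv(
            path, index=False
        )


def encode_labels(labels) -> np.ndarray:
    """Encode labels to the internal {good: 0, bad: 1} convention.

    Accepts 0/1 integers, the strings "good"/"bad", and the legacy
    numeric value 2 for "bad".
    """
    out = []
    for lab in np.asarray(labels).ravel():
        if isinstance(lab, (str, np.str_)):
            name = lab.strip().lower()
            if name not in ("good", "bad"):
                raise ValidationError(f"unknown label {lab!r}")
            out.append(0 if name == "good" else 1)
        else:
            val = int(lab)
            if val == 0:
                out.append(0)
            elif val in (1, 2):
                out.append(1)
            else:
                raise ValidationError(f"unknown label value {val}")
    return np.asarray(out, dtype=np.int64)


@dataclass
class FittedModel:
    """A fitted standardize-then-logit pipeline plus its provenance."""

    pipeline: Pipeline
    config: LogitConfig
    seed: int
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Probability of the positive ("bad") class."""
        classes = list(self.pipeline.named_steps["logit"].classes_)
        return self.pipeline.predict_proba(np.asarray(X, dtype=float))[
            :, classes.index(1)
        ]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int64)

    # -- JSON persistence -------------------------------------------------
    def to_json(self, path: str | os.PathLike) -> None:
        scaler: StandardScaler = self.pipeline.named_steps["scale"]
        logit: LogisticRegression = self.pipeline.named_steps["logit"]
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "metadata": self.metadata,
            "scaler_mean": scaler.mean_.tolist(),
            "scaler_scale": scaler.scale_.tolist(),
            "coefficients": logit.coef_.tolist(),
            "intercept": logit.intercept_.tolist(),
            "classes": logit.classes_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = LogitConfig(**payload["config"])
        n = len(payload["scaler_mean"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler_mean"])
        scaler.scale_ = np.asarray(payload["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = n
        scaler.n_samples_seen_ = 1
        logit = _make_logit(cfg, payload["seed"])
        logit.coef_ = np.asarray(payload["coefficients"])
        logit.intercept_ = np.asarray(payload["intercept"])
        logit.classes_ = np.asarray(payload["classes"])
        logit.n_features_in_ = n
        pipe = Pipeline([("scale", scaler), ("logit", logit)])
        return cls(pipe, cfg, payload["seed"], payload.get("metadata", {}))


def _make_logit(cfg: LogitConfig, seed: int) -> LogisticRegression:
    if cfg.penalty.lower() != "l2":
        raise ValidationError("only the L2 penalty is supported")
    return LogisticRegression(
        C=cfg.C,
        tol=cfg.tolerance,
        max_iter=cfg.max_iterations,
        solver=cfg.solver,
        random_state=seed,
    )


def _validate_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"feature/label shape mismatch: {X.shape} vs {y.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("need at least 2 samples per class")


def train_logit(
    features,
    labels,
    cfg: LogitConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> FittedModel:
    """Fit the standardize-then-logistic-regression pipeline.

    Deterministic given ``seed``.  A convergence failure is recorded in
    ``model.metadata["converged"]`` rather than raised.
    """
    X = np.asarray(features, dtype=float)
    y = encode_labels(labels)
    _validate_training_inputs(X, y)
    pipe = Pipeline([("scale", StandardScaler()), ("logit", _make_logit(cfg, seed))])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            pipe.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                pipe.fit(X, y)
            logger.warning("logistic regression did not converge: %s", cfg)
    return FittedModel(pipe, cfg, seed, {"converged": converged})


def tune_logit(
    features,
    labels,
    grid: dict[str, tuple] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[LogitConfig, FittedModel]:
    """Exhaustive grid search by cross-validated accuracy.

    Ties break toward the smaller ``C``, then the larger tolerance (the
    weaker fit).  Returns the winning configuration and a model refitted
    on the full data.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    X = np.asarray(features, dtype=float)
    y = encode_labels(labels)
    _validate_training_inputs(X, y)
    if not all(len(v) > 0 for v in grid.values()):
        raise ValidationError("hyperparameter grid must be non-empty")
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValidationError(
            f"{folds} folds exceed the smallest class count {counts.min()}"
        )
    keys = sorted(grid)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    best: tuple | None = None
    best_cfg: LogitConfig | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for combo in product(*(grid[k] for k in keys)):
            cfg = LogitConfig(**dict(zip(keys, combo)))
            accs = []
            for tr, te in splits:
                pipe = Pipeline(
                    [("scale", StandardScaler()), ("logit", _make_logit(cfg, seed))]
                )
                pipe.fit(X[tr], y[tr])
                accs.append(float(np.mean(pipe.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
            key = (score, -cfg.C, cfg.tolerance)
            if best is None or key > best:
                best = key
                best_cfg = cfg
    assert best_cfg is not None
    return best_cfg, train_logit(X, y, best_cfg, seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _safe_div(num: int, den: int, what: str) -> Fraction:
    if den == 0:
        logger.info("0/0 in %s; reporting 0 by convention", what)
        return Fraction(0)
    return Fraction(num, den)


def metrics_from_counts(c: ConfusionCounts) -> ClassificationReport:
    """Exact metric suite from confusion counts (no scores, hence no ROC).

    The positive label of ``c`` is "bad"; per-label precision/recall/F1
    are obtained by swapping the positive role.  Any 0/0 is reported as 0.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics from zero counts")
    accuracy = Fraction(c.TP + c.TN, c.total)
    per: dict[str, dict[str, float]] = {"precision": {}, "recall": {}, "f1": {}}
    supports: dict[str, int] = {}
    for name, cc in (("bad", c), ("good", c.swapped())):
        prec = _safe_div(cc.TP, cc.TP + cc.FP, f"precision[{name}]")
        rec = _safe_div(cc.TP, cc.TP + cc.FN, f"recall[{name}]")
        f1 = (
            2 * prec * rec / (prec + rec)
            if prec + rec > 0
            else _safe_div(0, 0, f"f1[{name}]")
        )
        per["precision"][name] = float(prec)
        per["recall"][name] = float(rec)
        per["f1"][name] = float(f1)
        supports[name] = cc.TP + cc.FN
    num = c.TP * c.TN - c.FP * c.FN
    den = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if den == 0 else num / sqrt(den)
    if den == 0:
        logger.info("MCC denominator 0; reporting 0 by convention")
    return ClassificationReport(
        counts=c,
        accuracy=float(accuracy),
        precision=per["precision"],
        recall=per["recall"],
        f1=per["f1"],
        mcc=mcc,
        supports=supports,
    )


def auc_from_scores(y_true, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC points over all score thresholds and the trapezoidal AUC.

    The trapezoidal area equals the tie-averaged rank probability
    P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    fpr, tpr, _ = roc_curve(np.asarray(y_true), np.asarray(scores, dtype=float))
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


def evaluate(model: FittedModel, features, labels) -> ClassificationReport:
    """Confusion counts at the 0.5 threshold plus ROC/AUC from scores."""
    X = np.asarray(features, dtype=float)
    y = encode_labels(labels)
    if X.shape[0] == 0:
        raise ValidationError("cannot evaluate on empty input")
    scores = model.predict_proba(X)
    pred = (scores >= 0.5).astype(np.int64)
    counts = ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )
    report = metrics_from_counts(counts)
    if np.unique(y).size == 2:
        auc, fpr, tpr = auc_from_scores(y, scores)
        report.roc_fpr = fpr
        report.roc_tpr = tpr
        report.auc = auc
    return report
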