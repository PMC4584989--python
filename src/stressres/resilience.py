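"""Baseline-biomarker modelling of resilience trends.

Maps each labeled experimental subject's two pre-stressor biomarkers —
salivary cortisol (ug/dl) and state-anxiety total — to their resilience-trend
class with a linear hinge-loss model trained by stochastic gradient descent
(L2 penalty weight alpha = 1e-4, the "optimal" learning-rate schedule,
one-vs-rest).  Subjects flagged as biomarker outliers by a robust z-score
(median / scaled-MAD) screen are excluded from training but retained in
reports.

The modelling surface follows the Model/Results convention:
``ResilienceTrendModel.from_dataframe(df).fit()`` returns a
:class:`ResilienceTrendResults` with coefficients, a resubstitution
confusion summary and a ``summary()`` table.  Evaluation is resubstitution
(training-set) accuracy by default, matching the small-sample protocol of
fitting on every non-discarded point; a cross-validation helper is provided
as an extension.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Perceptron, SGDClassifier
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ClassifierConfig

logger = logging.getLogger(__name__)

FEATURE_COLS = ("cortisol_baseline", "stai_baseline")

ALTERNATIVE_METHODS = (
    "logistic", "perceptron", "linear_svm", "1nn", "gnb", "gmm",
)


# ---------------------------------------------------------------------------
# outlier screen


def flag_outliers(profiles: pd.DataFrame, z_cut: float = 2.2) -> pd.DataFrame:
    """Robust z-score outlier screen on the two baseline biomarkers.

    A subject is flagged when ``|x - median| / (1.4826 * MAD) > z_cut`` on
    either feature.  A zero MAD on a feature falls back to the mean/SD rule
    (logged).  Returns a copy of ``profiles`` with ``outlier_flag`` and
    ``outlier_reason`` columns.
    """
    if len(profiles) < 5:
        raise ValueError("outlier screen needs at least 5 subjects")
    out = profiles.copy()
    out["outlier_flag"] = False
    out["outlier_reason"] = ""
    for col in FEATURE_COLS:
        x = out[col].to_numpy(dtype=float)
        center = np.median(x)
        scale = 1.4826 * np.median(np.abs(x - center))
        if scale == 0:
            logger.warning("flag_outliers: zero MAD on %s; using mean/SD",
                           col)
            center, scale = float(np.mean(x)), float(np.std(x))
            if scale == 0:
                continue
        z = np.abs(x - center) / scale
        hit = z > z_cut
        out.loc[hit, "outlier_flag"] = True
        for idx in out.index[hit]:
            reason = f"{col} robust z = {z[out.index.get_loc(idx)]:.1f}"
            prev = out.at[idx, "outlier_reason"]
            out.at[idx, "outlier_reason"] = (
                f"{prev}; {reason}" if prev else reason
            )
    return out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ConfusionSummary:
    """Per-class confusion counts with overall accuracy."""

    classes: tuple[str, ...]
    matrix: pd.DataFrame        # rows: true class, columns: predicted
    accuracy: float

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str]
                    ) -> "ConfusionSummary":
        y_true = list(y_true)
        y_pred = list(y_pred)
        if len(y_true) != len(y_pred) or not y_true:
            raise ValueError("need equal, non-empty label sequences")
        classes = tuple(sorted(set(y_true) | set(y_pred)))
        mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        correct = 0
        for t, p in zip(y_true, y_pred):
            mat.loc[t, p] += 1
            correct += t == p
        return cls(classes=classes, matrix=mat,
                   accuracy=correct / len(y_true))

    @property
    def n(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def per_class_correct(self) -> dict[str, int]:
        return {c: int(self.matrix.loc[c, c]) for c in self.classes}

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.matrix.rename_axis("true").to_csv(buf, sep="\t")
        buf.write(f"# accuracy\t{self.accuracy:.6f}\n")
        return buf.getvalue()


def evaluate(model, features: pd.DataFrame) -> ConfusionSummary:
    """Confusion summary of a fitted model on labeled feature rows."""
    X = features.loc[:, list(FEATURE_COLS)].to_numpy(dtype=float)
    return ConfusionSummary.from_labels(
        features["label"].tolist(), list(model.predict(X))
    )


# ---------------------------------------------------------------------------
# the SGD trend classifier, Model/Results style


class ResilienceTrendModel:
    """Linear hinge-loss model of trend class from baseline biomarkers.

    Parameters
    ----------
    X : (n, 2) array of (cortisol ug/dl, state-anxiety total) per subject.
    y : length-n class labels.
    config : hyperparameters; defaults pin hinge loss, alpha = 1e-4 and the
        "optimal" learning-rate schedule.
    """

    def __init__(self, X: np.ndarray, y: Sequence[str],
                 config: ClassifierConfig | None = None,
                 feature_names: Sequence[str] = FEATURE_COLS):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(list(y), dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_subjects, n_features)")
        self.config = config or ClassifierConfig()
        self.feature_names = tuple(feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: ClassifierConfig | None = None,
                       exclude_outliers: bool = True
                       ) -> "ResilienceTrendModel":
        """Build from a table with cortisol, anxiety and label columns.

        When ``exclude_outliers`` is set, the robust z screen runs first and
        flagged subjects are dropped from the training set (they stay in the
        returned model's ``excluded`` attribute for reporting).
        """
        config = config or ClassifierConfig()
        df = df.dropna(subset=[*FEATURE_COLS, "label"])
        if exclude_outliers:
            flagged = flag_outliers(df, z_cut=config.outlier_z_cut)
            kept = flagged[~flagged["outlier_flag"]]
            excluded = flagged[flagged["outlier_flag"]]
        else:
            kept, excluded = df, df.iloc[0:0]
        # canonical subject order: fits do not depend on input row order
        kept = kept.sort_values("subject_id")
        model = cls(kept.loc[:, list(FEATURE_COLS)].to_numpy(dtype=float),
                    kept["label"].tolist(), config)
        model.train_frame = kept.reset_index(drop=True)
        model.excluded = excluded.reset_index(drop=True)
        return model

    def _estimator(self, seed: int):
        cfg = self.config
        sgd = SGDClassifier(
            loss=cfg.loss, penalty="l2", alpha=cfg.alpha,
            learning_rate=cfg.learning_rate, max_iter=cfg.max_iter,
            tol=cfg.tol, shuffle=True, random_state=seed,
        )
        if cfg.standardize:
            return make_pipeline(StandardScaler(), sgd)
        return make_pipeline(sgd)

    def fit(self, seed: int | None = None) -> "ResilienceTrendResults":
        """Fit on the full (non-discarded) training set."""
        if np.unique(self.y).size < 2:
            raise ValueError("degenerate training set: a single class")
        if np.all(np.std(self.X, axis=0) == 0):
            logger.warning("all subjects share identical features; "
                           "fit will be chance-level")
        seed = self.config.seed if seed is None else seed
        est = self._estimator(seed)
        est.fit(self.X, self.y)
        return ResilienceTrendResults(self, est, seed)

    def cross_validate(self, n_splits: int = 4,
                       seed: int | None = None) -> float:
        """Stratified k-fold accuracy — an extension beyond the
        resubstitution protocol, for honest generalization estimates."""
        seed = self.config.seed if seed is None else seed
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=seed)
        scores = cross_val_score(self._estimator(seed), self.X, self.y,
                                 cv=cv)
        return float(np.mean(scores))


class ResilienceTrendResults:
    """Fitted trend classifier: weights, diagnostics, prediction."""

    def __init__(self, model: ResilienceTrendModel, estimator, seed: int):
        self.model = model
        self.estimator = estimator
        self.seed = seed
        sgd = estimator.steps[-1][1]
        self.classes_ = tuple(sgd.classes_)
        self.coef_ = np.atleast_2d(sgd.coef_)
        self.intercept_ = np.atleast_1d(sgd.intercept_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    @property
    def confusion(self) -> ConfusionSummary:
        return ConfusionSummary.from_labels(
            list(self.model.y), list(self.predict(self.model.X))
        )

    @property
    def accuracy(self) -> float:
        """Resubstitution accuracy on the training set."""
        return self.confusion.accuracy

    def decision_grid(self, n: int = 200,
                      pad: float = 0.15) -> pd.DataFrame:
        """Predicted class over a rectangular grid of the feature plane
        (for decision-boundary plots and convexity checks)."""
        lo = self.model.X.min(axis=0)
        hi = self.model.X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        g0 = np.linspace(lo[0] - pad * span[0], hi[0] + pad * span[0], n)
        g1 = np.linspace(lo[1] - pad * span[1], hi[1] + pad * span[1], n)
        xx, yy = np.meshgrid(g0, g1)
        pred = self.predict(np.column_stack([xx.ravel(), yy.ravel()]))
        return pd.DataFrame({
            self.model.feature_names[0]: xx.ravel(),
            self.model.feature_names[1]: yy.ravel(),
            "predicted": pred,
        })

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Resilience trend classifier (SGD, hinge loss, one-vs-rest)",
            "=" * 60,
            f"n subjects (training)   {self.model.y.size}",
            f"features                {', '.join(self.model.feature_names)}",
            f"alpha (L2)              {cfg.alpha:g}",
            f"learning rate           {cfg.learning_rate}",
            f"standardized features   {cfg.standardize}",
            f"shuffle seed            {self.seed}",
            "",
            "per-class weights (standardized feature space)",
        ]
        for i, cls in enumerate(self.classes_):
            w = ", ".join(f"{v:+.4f}" for v in self.coef_[i])
            lines.append(
                f"  {cls:<14} [{w}]  intercept {self.intercept_[i]:+.4f}"
            )
        conf = self.confusion
        lines += ["", f"resubstitution accuracy  {conf.accuracy:.4f} "
                      f"({int(round(conf.accuracy * conf.n))}/{conf.n})",
                  "", "confusion (rows true, columns predicted)",
                  conf.matrix.to_string()]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize as a flat text record (classes, weights, intercepts,
        hyperparameters, seed)."""
        cfg = self.model.config
        lines = [f"classes\t{','.join(self.classes_)}",
                 f"features\t{','.join(self.model.feature_names)}"]
        for i, cls in enumerate(self.classes_):
            w = ",".join(repr(v) for v in self.coef_[i])
            lines.append(f"weights.{cls}\t{w}")
            lines.append(f"intercept.{cls}\t{self.intercept_[i]!r}")
        for key in ("loss", "alpha", "learning_rate", "max_iter", "tol",
                    "standardize"):
            lines.append(f"hyper.{key}\t{getattr(cfg, key)}")
        lines.append(f"seed\t{self.seed}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# comparison classifiers


class _GMMClassifier:
    """Per-class Gaussian mixture density with a Bayes decision rule."""

    def __init__(self, n_components: int = 1, seed: int = 0):
        self.n_components = n_components
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        self._mixtures = {}
        self._log_priors = {}
        for cls in self.classes_:
            sub = X[y == cls]
            gm = GaussianMixture(
                n_components=min(self.n_components, len(sub)),
                covariance_type="full", reg_covar=1e-4,
                random_state=self.seed,
            )
            gm.fit(sub)
            self._mixtures[cls] = gm
            self._log_priors[cls] = np.log(len(sub) / len(y))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.column_stack([
            self._mixtures[c].score_samples(X) + self._log_priors[c]
            for c in self.classes_
        ])
        return self.classes_[np.argmax(scores, axis=1)]


def alternative_classifier(method: str, seed: int = 0,
                           standardize: bool = True):
    """Construct one of the comparison classifiers by name.

    Methods: logistic regression, perceptron, linear-kernel SVM, 1 nearest
    neighbor, Gaussian naive Bayes, Gaussian mixture models.
    """
    if method == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif method == "perceptron":
        est = Perceptron(max_iter=1000, random_state=seed)
    elif method == "linear_svm":
        est = SVC(kernel="linear", random_state=seed)
    elif method == "1nn":
        est = KNeighborsClassifier(n_neighbors=1)
    elif method == "gnb":
        est = GaussianNB()
    elif method == "gmm":
        est = _GMMClassifier(seed=seed)
    else:
        raise ValueError(
            f"unknown method {method!r}; choose from {ALTERNATIVE_METHODS}"
        )
    if standardize and method != "gmm":
        return make_pipeline(StandardScaler(), est)
    return est


def fit_alternative(features: pd.DataFrame, method: str, seed: int = 0
                    ) -> tuple[object, ConfusionSummary]:
    """Fit a named comparison classifier and return it with its
    resubstitution confusion summary (same evaluation contract as the SGD
    model)."""
    est = alternative_classifier(method, seed=seed)
    X = features.loc[:, list(FEATURE_COLS)].to_numpy(dtype=float)
    y = features["label"].tolist()
    est.fit(X, y)
    return est, evaluate(est, features)
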