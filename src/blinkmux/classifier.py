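"""Multinomial logistic regression on blinking statistics.

The decision stage of blink-based multiplexing: each molecule's 10
blinking statistics are z-score normalised and fed to a softmax
(multinomial logistic) model,

    P_j = exp(w_j . x + b_j) / sum_k exp(w_k . x + b_k),

parameterised against a pivot class whose coefficients are fixed at zero
(for K classes there are K-1 coefficient sets).  The model is fit by
penalised maximum likelihood with a deterministic quasi-Newton search
started at zero coefficients; a small ridge keeps separable problems
finite.  Evaluation uses stratified 10-fold cross-validation with the
normalisation and fit strictly fold-internal, pooled confusion matrices,
and probability thresholding: a molecule is retained only when its largest
class probability reaches the threshold, trading data retention for
accuracy over the retained set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ZScoreRecord",
    "zscore_fit_apply",
    "BlinkClassifier",
    "MLRModel",
    "fit_mlr",
    "predict_proba",
    "cross_validate",
    "threshold_curve",
    "find_threshold",
    "ThresholdResult",
    "ClassificationReport",
]


# ---------------------------------------------------------------------------
# z-score normalisation


@dataclass
class ZScoreRecord:
    """Training-set means/sds and the zero-variance columns dropped."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # column indices retained
    dropped: tuple[str, ...] = ()


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def zscore_fit_apply(train, test=None):
    """Fit z-score normalisation on ``train`` and apply to both sets.

    Zero-variance statistics carry no information and break the scaling;
    they are dropped and recorded.  Returns ``(train_z, test_z, record)``
    (``test_z`` is None when no test set is given).
    """
    Xtr, names = _as_matrix(train)
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    dropped = tuple(names[i] for i in np.flatnonzero(sd == 0))
    rec = ZScoreRecord(mean=mean[kept], sd=sd[kept], kept=kept, dropped=dropped)
    train_z = (Xtr[:, kept] - rec.mean) / rec.sd
    test_z = None
    if test is not None:
        Xte, _ = _as_matrix(test)
        test_z = (Xte[:, kept] - rec.mean) / rec.sd
    return train_z, test_z, rec


# ---------------------------------------------------------------------------
# Softmax model


class BlinkClassifier(BaseEstimator, ClassifierMixin):
    """Pivot-parameterised multinomial logistic regression.

    Parameters
    ----------
    ridge : float
        L2 penalty on the coefficients (not the intercepts); the small
        default keeps perfectly separable fits numerically finite.
    normalize : bool
        Fit z-score normalisation on the training data and apply it at
        prediction time (the standard pipeline behaviour).

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; the last one is the pivot with zero
        coefficients.
    coef_ : ndarray of shape (K-1, d)
    intercept_ : ndarray of shape (K-1,)
    norm_ : ZScoreRecord or None
    feature_names_ : list of str
    """

    def __init__(self, ridge: float = 1e-6, normalize: bool = True):
        self.ridge = ridge
        self.normalize = normalize

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        K = self.classes_.size
        if K < 2:
            raise ValueError("need at least 2 classes")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if np.any(counts < 2):
            raise ValueError("each class needs at least 2 members")
        if self.normalize:
            Xz, _, rec = zscore_fit_apply(Xm)
            self.norm_ = rec
            self.feature_names_ = [names[i] for i in rec.kept]
        else:
            Xz, self.norm_ = Xm, None
            self.feature_names_ = names
        n, d = Xz.shape
        yi = np.searchsorted(self.classes_, y)
        Y = np.zeros((n, K))
        Y[np.arange(n), yi] = 1.0

        def objective(theta):
            W = theta[: (K - 1) * d].reshape(K - 1, d)
            b = theta[(K - 1) * d :]
            S = np.hstack([Xz @ W.T + b, np.zeros((n, 1))])
            ll = (S[np.arange(n), yi] - logsumexp(S, axis=1)).sum()
            P = softmax(S, axis=1)
            G = P - Y
            gW = G[:, : K - 1].T @ Xz + self.ridge * W
            gb = G[:, : K - 1].sum(axis=0)
            nll = -ll + 0.5 * self.ridge * (W ** 2).sum()
            return nll, np.concatenate([gW.ravel(), gb])

        x0 = np.zeros((K - 1) * (d + 1))
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"MLR optimisation failed: {res.message}")
        theta = res.x
        self.coef_ = theta[: (K - 1) * d].reshape(K - 1, d)
        self.intercept_ = theta[(K - 1) * d :]
        self.n_features_in_ = Xm.shape[1]
        return self

    @classmethod
    def from_coefficients(cls, classes, coef, intercept, normalize: bool = False):
        """Build a model directly from known coefficients (pivot = last class)."""
        model = cls(normalize=normalize)
        model.classes_ = np.asarray(classes)
        model.coef_ = np.atleast_2d(np.asarray(coef, dtype=float))
        model.intercept_ = np.atleast_1d(np.asarray(intercept, dtype=float))
        model.norm_ = None
        model.n_features_in_ = model.coef_.shape[1]
        model.feature_names_ = [f"x{i}" for i in range(model.coef_.shape[1])]
        return model

    def decision_scores(self, X) -> np.ndarray:
        """Linear scores per class, pivot column fixed at zero."""
        Xm, _ = _as_matrix(X)
        if self.norm_ is not None:
            Xm = (Xm[:, self.norm_.kept] - self.norm_.mean) / self.norm_.sd
        if Xm.shape[1] != self.coef_.shape[1]:
            raise ValueError(
                f"expected {self.coef_.shape[1]} features, got {Xm.shape[1]}"
            )
        S = Xm @ self.coef_.T + self.intercept_
        return np.hstack([S, np.zeros((Xm.shape[0], 1))])

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_scores(X), axis=1)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]  # ties -> earlier class


#: alias matching the domain name of the fitted model record
MLRModel = BlinkClassifier


def fit_mlr(features, labels, regularization: float = 1e-6,
            normalize: bool = True) -> BlinkClassifier:
    """Fit the softmax model; thin wrapper over `BlinkClassifier`."""
    return BlinkClassifier(ridge=regularization, normalize=normalize).fit(features, labels)


def predict_proba(model: BlinkClassifier, features) -> np.ndarray:
    """Per-class probabilities from a fitted model (columns in class order)."""
    return model.predict_proba(features)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class ThresholdResult:
    threshold: float
    accuracy: float
    retention: float
    per_class_retention: dict
    imbalance_warning: bool


@dataclass
class ClassificationReport:
    """Cross-validated BBM evaluation of one classification problem."""

    classes: np.ndarray
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    accuracy: float
    per_class_recall: pd.Series
    min_class_accuracy: float
    tpr: float | None
    fpr: float | None
    threshold_curve: pd.DataFrame
    probabilities: np.ndarray
    labels: np.ndarray
    predictions: np.ndarray
    small_sample: bool
    full_data_model: BlinkClassifier | None = None


def threshold_curve(probabilities, labels, thresholds, classes=None) -> pd.DataFrame:
    """Accuracy/retention trade-off of probability thresholding.

    A molecule is retained iff its maximum class probability reaches the
    threshold; accuracy is computed over the retained set only, and the
    retained fraction is reported overall and within each true class.
    """
    P = np.asarray(probabilities, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    pred = np.asarray(classes)[np.argmax(P, axis=1)]
    pmax = P.max(axis=1)
    rows = []
    for th in np.atleast_1d(thresholds):
        keep = pmax >= th
        n_keep = int(keep.sum())
        row = {
            "threshold": float(th),
            "retention": n_keep / labels.size,
            "n_retained": n_keep,
            "accuracy": np.nan,
            "accuracy_defined": n_keep > 0,
        }
        if n_keep:
            row["accuracy"] = float((pred[keep] == labels[keep]).mean())
        for c in classes:
            in_c = labels == c
            row[f"retention_{c}"] = float(keep[in_c].mean()) if in_c.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def find_threshold(curve: pd.DataFrame, target_accuracy: float) -> ThresholdResult | None:
    """Smallest threshold whose retained-set accuracy meets the target.

    Returns None when no threshold reaches the target.  Flags the result
    when any class's retention falls below half the overall retention —
    disproportionate discarding can silently reduce a ternary problem to a
    binary one.
    """
    if len(curve) == 0:
        raise ValueError("empty threshold curve")
    ok = curve[(curve["accuracy"] >= target_accuracy) & curve["accuracy_defined"]]
    if len(ok) == 0:
        return None
    row = ok.sort_values("threshold").iloc[0]
    per_class = {
        c.removeprefix("retention_"): float(row[c])
        for c in curve.columns
        if c.startswith("retention_")
    }
    warn = any(v < 0.5 * row["retention"] for v in per_class.values())
    if warn:
        warnings.warn(
            "thresholding discards one class disproportionately "
            "(per-class retention below half the overall retention)",
            stacklevel=2,
        )
    return ThresholdResult(
        threshold=float(row["threshold"]),
        accuracy=float(row["accuracy"]),
        retention=float(row["retention"]),
        per_class_retention=per_class,
        imbalance_warning=warn,
    )


def cross_validate(
    features,
    labels,
    folds: int = 10,
    rng_seed: int = 0,
    thresholds=None,
    ridge: float = 1e-6,
    fit_full_model: bool = False,
) -> ClassificationReport:
    """Stratified k-fold evaluation of BBM classification.

    Normalisation and the MLR fit happen inside each training fold only;
    test-fold molecules never influence them.  The pooled out-of-fold
    probabilities feed the confusion matrix (argmax rule; for a binary
    problem this is P > 0.5) and the threshold/retention curve.

    ``fit_full_model`` additionally fits an interpretation model on the
    full dataset (the coefficient set one would publish); it plays no part
    in the reported accuracies.
    """
    Xm, _ = _as_matrix(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    K = classes.size
    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts < folds):
        raise ValueError(
            f"every class needs at least {folds} members for {folds}-fold CV"
        )
    small = bool(np.any(counts <= 10))
    if small:
        warnings.warn(
            "class with n <= 10 molecules: classification accuracy is "
            "unstable at this sample size",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    P = np.zeros((labels.size, K))
    for tr, te in skf.split(Xm, labels):
        model = BlinkClassifier(ridge=ridge, normalize=True).fit(Xm[tr], labels[tr])
        # fold-internal classes match the global set (stratification)
        P[te] = model.predict_proba(Xm[te])
    pred = classes[np.argmax(P, axis=1)]
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(labels, pred):
        conf.loc[t, p] += 1
    accuracy = float((pred == labels).mean())
    recall = pd.Series(
        {c: conf.loc[c, c] / conf.loc[c].sum() for c in classes}, dtype=float
    )
    tpr = fpr = None
    if K == 2:
        pos, neg = classes[0], classes[1]
        tpr = float(recall[pos])
        fpr = float(conf.loc[neg, pos] / conf.loc[neg].sum())
    if thresholds is None:
        lo = np.ceil(100.0 / K) / 100.0
        thresholds = np.round(np.arange(lo, 1.0, 0.01), 2)
    curve = threshold_curve(P, labels, thresholds, classes)
    full_model = None
    if fit_full_model:
        full_model = BlinkClassifier(ridge=ridge, normalize=True).fit(Xm, labels)
    return ClassificationReport(
        classes=classes,
        confusion=conf,
        accuracy=accuracy,
        per_class_recall=recall,
        min_class_accuracy=float(recall.min()),
        tpr=tpr,
        fpr=fpr,
        threshold_curve=curve,
        probabilities=P,
        labels=labels,
        predictions=pred,
        small_sample=small,
        full_data_model=full_model,
    )
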