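"""PD-vs-control discrimination from marker vectors.

Binary logistic regression evaluated by leave-one-subject-out (LOSO)
cross-validation: every subject is scored by a model fitted on all other
subjects, features z-scored with the training fold's statistics so no
information leaks from the held-out subject.  A weak fixed L2 (ridge)
penalty keeps the fit defined under perfect separation; plain logistic
regression is its penalty-to-zero limit.

On top of the pooled LOSO scores the module provides rank-based ROC/AUC
metrics, an exhaustive marker-subset grid search maximising LOSO accuracy,
and a prevalence estimate at an operating point whose control
false-positive rate stays strictly under a configured bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassificationReport",
    "loso_scores",
    "roc_metrics",
    "subset_grid_search",
    "prevalence_at_fpr",
    "roc_curve_points",
    "LosoLogisticScreen",
    "MarkerSubsetSelector",
]

#: fixed ridge strength on standardised features (see module docstring)
DEFAULT_RIDGE = 1e-4


@dataclass
class ClassificationReport:
    """Pooled LOSO outcome for one marker subset."""

    subset: tuple[str, ...]
    scores: np.ndarray           # per-subject held-out P(PD)
    y: np.ndarray                # 1 = PD, 0 = HC
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    operating_threshold: float = float("nan")
    prevalence_estimate: float = float("nan")
    fpr_at_threshold: float = float("nan")

    def metrics_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "operating_threshold": self.operating_threshold,
            "prevalence_estimate": self.prevalence_estimate,
            "fpr_at_threshold": self.fpr_at_threshold,
        }


def _as_binary(y) -> np.ndarray:
    """Map labels to 1 = PD (positive class), 0 = HC."""
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        out = np.where(y == "PD", 1, 0)
        bad = set(np.unique(y)) - {"PD", "HC"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        return out
    return y.astype(int)


def _fit_fold(X_train: np.ndarray, y_train: np.ndarray, ridge: float):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X_train - mu) / sd
    # sklearn's C is the inverse of the total penalty weight; our ridge is
    # per-sample on standardised features
    model = LogisticRegression(C=1.0 / (ridge * len(y_train)), solver="lbfgs",
                               max_iter=2000, tol=1e-8)
    model.fit(Z, y_train)
    return mu, sd, model


def loso_scores(X, y, subset: list[str] | None = None,
                ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Held-out P(PD) for every subject by leave-one-subject-out CV.

    X may be a DataFrame (subset selects columns) or an array.  Requires
    complete cases on the chosen subset, at least 10 subjects, and both
    classes in every training fold.  Deterministic.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(subset) if subset else list(X.columns)
        if not cols:
            raise ValueError("subset must be nonempty")
        Xv = X[cols].to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if subset:
            raise ValueError("named subsets require a DataFrame input")
    yv = _as_binary(y)
    n = Xv.shape[0]
    if n < 10:
        raise ValueError(f"LOSO needs at least 10 subjects, got {n}")
    if np.isnan(Xv).any():
        raise ValueError("LOSO requires complete cases on the chosen markers")

    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        y_tr = yv[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a training fold contains a single class")
        mu, sd, model = _fit_fold(Xv[train], y_tr, ridge)
        z = (Xv[i] - mu) / sd
        scores[i] = model.predict_proba(z[None, :])[0, model.classes_ == 1][0]
    return scores


def roc_metrics(scores, y, threshold: float = 0.5) -> dict[str, float]:
    """AUC plus confusion metrics at a fixed probability threshold.

    AUC uses the rank (Mann-Whitney) formulation with midrank tie
    correction; accuracy, sensitivity and specificity are computed at
    ``threshold`` with PD as the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    yv = _as_binary(y)
    n_pos = int(yv.sum())
    n_neg = int((1 - yv).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[yv == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = scores > threshold
    tp = int((pred & (yv == 1)).sum())
    tn = int((~pred & (yv == 0)).sum())
    return {
        "auc": float(auc),
        "accuracy": (tp + tn) / len(yv),
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
    }


def roc_curve_points(scores, y) -> pd.DataFrame:
    """(FPR, TPR) pairs across all score thresholds, for export/plotting."""
    scores = np.asarray(scores, dtype=float)
    yv = _as_binary(y)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        rows.append({
            "threshold": thr,
            "fpr": float((pred & (yv == 0)).sum() / max(1, (yv == 0).sum())),
            "tpr": float((pred & (yv == 1)).sum() / max(1, (yv == 1).sum())),
        })
    return pd.DataFrame(rows)


def prevalence_at_fpr(scores, y, fpr_bound: float = 0.05):
    """Operating point with control false-positive rate strictly under
    ``fpr_bound``; prevalence is the patient fraction above the threshold.

    The threshold is the smallest score value achieving the bound, scanned
    over the pooled observed scores; the achieved FPR is returned.  If even
    the maximum score cannot satisfy the bound (all controls tied at the
    maximum), the threshold is placed just above it and a warning issued.
    """
    import warnings

    scores = np.asarray(scores, dtype=float)
    yv = _as_binary(y)
    controls = scores[yv == 0]
    patients = scores[yv == 1]
    if controls.size == 0 or patients.size == 0:
        raise ValueError("both classes must be present")

    threshold = None
    for cand in np.unique(scores):
        fpr = float((controls > cand).mean())
        if fpr < fpr_bound:
            threshold = float(cand)
            break
    if threshold is None:  # unreachable via the max score, but keep the contract
        threshold = float(scores.max()) + 1e-12
        warnings.warn("FPR bound unattainable; threshold placed above all scores")
    achieved_fpr = float((controls > threshold).mean())
    prevalence = float((patients > threshold).mean())
    return threshold, prevalence, achieved_fpr


def _tie_break_key(names: tuple[str, ...], accuracy: float, auc: float):
    # maximise accuracy, then AUC, then prefer smaller subsets, then
    # lexicographic name order — fully deterministic
    return (-accuracy, -auc, len(names), names)


def subset_grid_search(X: pd.DataFrame, y, candidates: list[str],
                       ridge: float = DEFAULT_RIDGE,
                       fpr_bound: float = 0.05) -> ClassificationReport:
    """Exhaustive LOSO grid search over all nonempty marker subsets.

    Evaluates every one of the 2^k - 1 subsets of ``candidates`` by pooled
    LOSO accuracy (ties broken by higher AUC, then smaller subset, then
    name order) and returns the winner's full report including the
    bounded-FPR operating point.
    """
    if not candidates:
        raise ValueError("candidate marker list must be nonempty")
    if len(candidates) > 20:
        raise ValueError("exhaustive search is limited to 20 candidates")

    yv = _as_binary(y)
    best_key = None
    best: tuple[tuple[str, ...], np.ndarray, dict] | None = None
    for k in range(1, len(candidates) + 1):
        for names in combinations(sorted(candidates), k):
            scores = loso_scores(X, yv, subset=list(names), ridge=ridge)
            m = roc_metrics(scores, yv)
            key = _tie_break_key(names, m["accuracy"], m["auc"])
            if best_key is None or key < best_key:
                best_key = key
                best = (names, scores, m)

    names, scores, m = best
    thr, prev, fpr = prevalence_at_fpr(scores, yv, fpr_bound)
    return ClassificationReport(
        subset=names, scores=scores, y=yv,
        auc=m["auc"], accuracy=m["accuracy"],
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        operating_threshold=thr, prevalence_estimate=prev, fpr_at_threshold=fpr,
    )


class LosoLogisticScreen(BaseEstimator, ClassifierMixin):
    """Logistic PD-vs-HC screen with LOSO-pooled performance estimates.

    ``fit`` computes the held-out LOSO score for every training subject
    (stored in ``loso_scores_`` with metrics ``auc_``, ``accuracy_``,
    ``sensitivity_``, ``specificity_`` and the bounded-FPR operating
    point), then refits on the full sample for out-of-sample ``predict``.

    Parameters
    ----------
    subset : list of str, optional
        Marker columns to use (DataFrame input only); default all.
    ridge : float
        L2 strength on standardised features.
    fpr_bound : float
        Control false-positive bound for the prevalence operating point.
    """

    def __init__(self, subset: list[str] | None = None,
                 ridge: float = DEFAULT_RIDGE, fpr_bound: float = 0.05):
        self.subset = subset
        self.ridge = ridge
        self.fpr_bound = fpr_bound

    def fit(self, X, y) -> "LosoLogisticScreen":
        yv = _as_binary(y)
        self.y_ = yv
        self.loso_scores_ = loso_scores(X, yv, subset=self.subset, ridge=self.ridge)
        m = roc_metrics(self.loso_scores_, yv)
        self.auc_ = m["auc"]
        self.accuracy_ = m["accuracy"]
        self.sensitivity_ = m["sensitivity"]
        self.specificity_ = m["specificity"]
        thr, prev, fpr = prevalence_at_fpr(self.loso_scores_, yv, self.fpr_bound)
        self.operating_threshold_ = thr
        self.prevalence_estimate_ = prev
        self.fpr_at_threshold_ = fpr

        if isinstance(X, pd.DataFrame):
            cols = list(self.subset) if self.subset else list(X.columns)
            Xv = X[cols].to_numpy(dtype=float)
            self.feature_names_in_ = np.asarray(cols, dtype=object)
        else:
            Xv = np.asarray(X, dtype=float)
        self.classes_ = np.array([0, 1])
        self._mu, self._sd, self._model = _fit_fold(Xv, yv, self.ridge)
        return self

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[list(self.feature_names_in_)]
        return (np.asarray(X, dtype=float) - self._mu) / self._sd

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "loso_scores_")
        return self._model.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def report(self) -> ClassificationReport:
        check_is_fitted(self, "loso_scores_")
        subset = tuple(getattr(self, "feature_names_in_", ()))
        return ClassificationReport(
            subset=subset, scores=self.loso_scores_, y=self.y_,
            auc=self.auc_, accuracy=self.accuracy_,
            sensitivity=self.sensitivity_, specificity=self.specificity_,
            operating_threshold=self.operating_threshold_,
            prevalence_estimate=self.prevalence_estimate_,
            fpr_at_threshold=self.fpr_at_threshold_,
        )


class MarkerSubsetSelector(BaseEstimator):
    """Exhaustive marker-subset selection by LOSO accuracy.

    ``fit`` enumerates every nonempty subset of ``candidates`` and keeps
    the one with the best pooled LOSO accuracy (ties: higher AUC, smaller
    subset, name order).  By the emulated procedure the selection is
    non-nested — the reported metrics reuse the same LOSO scores that
    drove the selection, which is optimistic for generalisation; set
    ``nested=True`` to re-score the winning subset with an outer LOSO in
    which the subset search is repeated per fold.

    Attributes
    ----------
    best_subset_ : tuple of str
    report_ : ClassificationReport
    """

    def __init__(self, candidates: list[str] | None = None,
                 ridge: float = DEFAULT_RIDGE, fpr_bound: float = 0.05,
                 nested: bool = False):
        self.candidates = candidates
        self.ridge = ridge
        self.fpr_bound = fpr_bound
        self.nested = nested

    def fit(self, X: pd.DataFrame, y) -> "MarkerSubsetSelector":
        candidates = list(self.candidates) if self.candidates else list(X.columns)
        self.report_ = subset_grid_search(X, y, candidates, ridge=self.ridge,
                                          fpr_bound=self.fpr_bound)
        self.best_subset_ = self.report_.subset
        if self.nested:
            self.nested_scores_ = self._nested_scores(X, _as_binary(y), candidates)
            self.nested_metrics_ = roc_metrics(self.nested_scores_, _as_binary(y))
        return self

    def _nested_scores(self, X: pd.DataFrame, yv: np.ndarray,
                       candidates: list[str]) -> np.ndarray:
        n = len(X)
        scores = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[:] = True
            mask[i] = False
            inner = subset_grid_search(X.iloc[mask], yv[mask], candidates,
                                       ridge=self.ridge, fpr_bound=self.fpr_bound)
            mu, sd, model = _fit_fold(
                X.iloc[mask][list(inner.subset)].to_numpy(dtype=float),
                yv[mask], self.ridge)
            z = (X.iloc[i][list(inner.subset)].to_numpy(dtype=float) - mu) / sd
            scores[i] = model.predict_proba(z[None, :])[0, model.classes_ == 1][0]
        return scores
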