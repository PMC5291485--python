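"""Unpenalized binary logistic regression, leave-one-out cross-validation
and backward-elimination wrapper feature selection.

The grading model is plain maximum-likelihood logistic regression (GBM = 1,
LGG = 0) fit by iteratively reweighted least squares on per-fit
standardized features.  Generalization is measured by leave-one-out
cross-validation (LOOCV): n fits, each excluding one case, with the
standardization recomputed inside each fold so no information leaks from
the held-out case.  Backward elimination greedily removes the feature
whose removal gives the lowest LOOCV misclassification rate at the 0.5
criterion, stopping when no single removal strictly lowers the error; the
selected set is the error-minimizing step of the trace (earliest on ties).

Both the low-level functions (`fit_logistic`, `loocv`,
`backward_eliminate`) and sklearn-style estimators
(`StandardizedLogisticRegression`, `BackwardEliminationGrader`) are
exposed; the estimators are thin wrappers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

DEFAULT_THRESHOLD = 0.5
_MAX_ITER = 100
_TOL = 1e-8
_ETA_CLIP = 30.0  # |linear predictor| cap; expit saturates well before this


class SingularDesignError(ValueError):
    """Raised when the (standardized) design matrix is rank-deficient."""


@dataclass
class FeatureTable:
    """Ordered cases: feature matrix, binary labels, case ids.

    Labels encode GBM (malignant, positive) as 1 and LGG as 0.
    """

    features: pd.DataFrame
    labels: np.ndarray
    case_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if self.case_ids is None:
            self.case_ids = [str(i) for i in range(len(self.labels))]
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValueError("duplicate case_ids")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (LGG) or 1 (GBM)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       label_col: str = "label",
                       case_col: str = "case_id") -> "FeatureTable":
        meta = {label_col, case_col, "degenerate_flags"}
        feat_cols = [c for c in df.columns if c not in meta]
        ids = (df[case_col].astype(str).tolist()
               if case_col in df.columns else None)
        return cls(features=df[feat_cols].reset_index(drop=True),
                   labels=df[label_col].to_numpy(),
                   case_ids=ids)

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        ids = [self.case_ids[i] for i in np.nonzero(rows)[0]] \
            if rows.dtype == bool else [self.case_ids[i] for i in rows]
        return FeatureTable(self.features.iloc[rows].reset_index(drop=True),
                            self.labels[rows], ids)


@dataclass
class LogisticModel:
    """A fitted standardized logistic model.

    Coefficients apply to z-scored features; `means`/`sds` record the
    standardization of the training data.
    """

    intercept: float
    coefficients: Dict[str, float]
    means: Dict[str, float]
    sds: Dict[str, float]
    converged: bool
    n_iter: int
    p_values: Dict[str, float] = field(default_factory=dict)
    dropped_constant: Tuple[str, ...] = ()

    @property
    def feature_names(self) -> List[str]:
        return list(self.coefficients)


def _irls(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool, int]:
    """Newton/IRLS maximum likelihood; returns (beta, converged, n_iter).

    Under perfect separation the likelihood has no finite maximum; the
    loop then exhausts its iterations (or hits a singular weighted
    Hessian) and returns the current iterate flagged non-converged —
    its predicted probabilities are still usable.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False, it
        beta = beta + step
        if np.max(np.abs(step)) < _TOL:
            return beta, True, it
    return beta, False, _MAX_ITER


def _wald_pvalues(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(len(beta), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    return 2.0 * norm.sf(np.abs(z))


def fit_logistic(table: FeatureTable,
                 features: Optional[Sequence[str]] = None) -> LogisticModel:
    """Maximum-likelihood logistic fit on standardized features.

    Constant features are dropped with a warning; an exactly collinear
    design raises :class:`SingularDesignError` naming the dependent
    columns.  Requires at least two cases per class.
    """
    names = list(features) if features is not None else table.feature_names
    if len(names) == 0:
        raise ValueError("no features to fit")
    y = table.labels.astype(float)
    for cls in (0, 1):
        if (table.labels == cls).sum() < 2:
            raise ValueError(f"need >= 2 cases of class {cls}")
    Xraw = table.features[names].to_numpy(dtype=float)
    means = Xraw.mean(axis=0)
    sds = Xraw.std(axis=0)
    keep = sds > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    names = [n for n, k in zip(names, keep) if k]
    if not names:
        raise ValueError("all candidate features are constant")
    Z = (Xraw[:, keep] - means[keep]) / sds[keep]
    X = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify dependent columns via incremental rank
        bad = []
        r = 1
        for j in range(1, X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j - 1])
            r = rj
        raise SingularDesignError(f"collinear features: {bad}")
    beta, converged, n_iter = _irls(X, y)
    pvals = _wald_pvalues(X, beta)
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        means={n: float(m) for n, m in zip(names, means[keep])},
        sds={n: float(s) for n, s in zip(names, sds[keep])},
        converged=converged,
        n_iter=n_iter,
        p_values={n: float(p) for n, p in zip(names, pvals[1:])},
        dropped_constant=dropped,
    )


def predict_prob(model: LogisticModel, x) -> float:
    """Malignancy probability of one case (mapping or Series of features)."""
    eta = model.intercept
    for name, coef in model.coefficients.items():
        try:
            v = float(x[name])
        except (KeyError, IndexError) as exc:
            raise KeyError(f"missing feature {name!r}") from exc
        eta += coef * (v - model.means[name]) / model.sds[name]
    return float(expit(eta))


def _predict_matrix(model: LogisticModel, df: pd.DataFrame) -> np.ndarray:
    names = model.feature_names
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"missing features {missing}")
    Z = (df[names].to_numpy(dtype=float)
         - np.array([model.means[n] for n in names])) \
        / np.array([model.sds[n] for n in names])
    return expit(model.intercept + Z @ np.array(
        [model.coefficients[n] for n in names]))


@dataclass
class CvResult:
    """Per-case out-of-fold probabilities from LOOCV."""

    case_ids: List[str]
    probabilities: np.ndarray
    labels: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    fold_flags: List[str] = field(default_factory=list)

    @property
    def predictions(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(int)

    @property
    def error_rate(self) -> float:
        return float(np.mean(self.predictions != self.labels))

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_rate


def loocv(table: FeatureTable,
          features: Optional[Sequence[str]] = None,
          threshold: float = DEFAULT_THRESHOLD) -> CvResult:
    """Leave-one-out cross-validation of the logistic model.

    Each fold refits (including standardization) on the n-1 remaining
    cases and records the held-out case's probability.  A fold whose
    training set lost one class entirely falls back to the training
    majority probability and is flagged.
    """
    n = len(table.labels)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    probs = np.empty(n)
    flags = []
    for i in range(n):
        rows = np.ones(n, dtype=bool)
        rows[i] = False
        train = table.subset(rows)
        if len(np.unique(train.labels)) < 2:
            probs[i] = float(train.labels.mean())
            flags.append(f"fold {i}: single-class training set")
            continue
        model = fit_logistic(train, features)
        probs[i] = predict_prob(model, table.features.iloc[i])
    return CvResult(case_ids=list(table.case_ids), probabilities=probs,
                    labels=table.labels.copy(), threshold=threshold,
                    fold_flags=flags)


@dataclass
class EliminationStep:
    feature_set: Tuple[str, ...]
    error_rate: float
    removed: Optional[str]


@dataclass
class EliminationTrace:
    steps: List[EliminationStep]
    selected_set: Tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "steps": [
                {"features": list(s.feature_set), "loocv_error": s.error_rate,
                 "removed": s.removed}
                for s in self.steps
            ],
            "selected": list(self.selected_set),
        }


def _loocv_error(table: FeatureTable, features: Sequence[str],
                 threshold: float) -> float:
    """LOOCV error of a candidate set; +inf if the design is singular."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return loocv(table, features, threshold=threshold).error_rate
    except SingularDesignError:
        return math.inf


def backward_eliminate(
    table: FeatureTable,
    start_features: Optional[Sequence[str]] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> EliminationTrace:
    """Greedy backward elimination on LOOCV misclassification rate.

    The full nested descent is traced: at each step every single-feature
    removal is scored by LOOCV error and the best-scoring removal is
    applied — even when the error ties or rises — until one feature
    remains (exactly collinear candidate sets score +inf, so duplicated
    columns fall first).  Ties between equally scoring removals are
    broken by the largest Wald p-value in the current full-data fit.
    The selected set is the trace step with the globally smallest error;
    on ties the smallest such set wins, so redundant features whose
    removal leaves the error unchanged are excluded.
    """
    current = list(start_features) if start_features is not None \
        else table.feature_names
    if len(current) == 0:
        raise ValueError("start_features must be non-empty")
    cur_err = _loocv_error(table, current, threshold)
    steps = [EliminationStep(tuple(current), cur_err, None)]
    while len(current) > 1:
        errs = {f: _loocv_error(table, [g for g in current if g != f],
                                threshold) for f in current}
        best = min(errs.values())
        tied = [f for f, e in errs.items() if e == best]
        if len(tied) > 1:
            tied = _break_tie(table, current, tied)
        removed = tied[0]
        current = [g for g in current if g != removed]
        cur_err = best
        steps.append(EliminationStep(tuple(current), cur_err, removed))
    best_step = min(steps, key=lambda s: (s.error_rate, len(s.feature_set)))
    return EliminationTrace(steps=steps, selected_set=best_step.feature_set)


def _break_tie(table: FeatureTable, current: List[str],
               tied: List[str]) -> List[str]:
    """Order tied removals by descending Wald p-value of the current fit."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_logistic(table, current)
        pv = model.p_values
        return sorted(tied, key=lambda f: (-pv.get(f, np.inf),
                                           current.index(f)))
    except (SingularDesignError, ValueError):
        return sorted(tied, key=current.index)


class StandardizedLogisticRegression(ClassifierMixin, BaseEstimator):
    """Unpenalized logistic regression with built-in z-scoring.

    sklearn-compatible front end to :func:`fit_logistic` /
    :func:`predict_prob`.

    Attributes (after fit)
    ----------------------
    model_ : LogisticModel
    coef_ : ndarray, shape (1, n_features) — standardized-scale coefficients
    intercept_ : ndarray, shape (1,)
    converged_ : bool
    n_iter_ : int
    classes_ : ndarray [0, 1]
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.reset_index(drop=True)
        X = np.asarray(X, dtype=float)
        cols = getattr(self, "feature_names_in_", None)
        if cols is None:
            cols = [f"x{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(cols))

    def fit(self, X, y):
        df = self._to_frame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        table = FeatureTable(df, np.asarray(y))
        self.model_ = fit_logistic(table)
        names = self.model_.feature_names
        self.coef_ = np.array([[self.model_.coefficients[n] for n in names]])
        self.intercept_ = np.array([self.model_.intercept])
        self.converged_ = self.model_.converged
        self.n_iter_ = self.model_.n_iter
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        p1 = _predict_matrix(self.model_, self._to_frame(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


class BackwardEliminationGrader(ClassifierMixin, BaseEstimator):
    """Backward-elimination logistic grading model.

    `fit` runs LOOCV-scored backward elimination over the input features,
    refits the final model on the selected set, and stores the selected
    set's LOOCV result (the honest generalization estimate the selection
    itself optimized — see docs/methods.md for the optimism caveat).

    Attributes (after fit)
    ----------------------
    selected_features_ : tuple of str
    trace_ : EliminationTrace
    model_ : LogisticModel — final fit on all cases, selected features
    cv_result_ : CvResult — LOOCV of the selected set
    """

    def __init__(self, select: bool = True,
                 threshold: float = DEFAULT_THRESHOLD):
        self.select = select
        self.threshold = threshold

    def fit(self, X, y):
        df = StandardizedLogisticRegression._to_frame(self, X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        table = FeatureTable(df, np.asarray(y))
        if self.select:
            self.trace_ = backward_eliminate(table, threshold=self.threshold)
            self.selected_features_ = self.trace_.selected_set
        else:
            self.trace_ = None
            self.selected_features_ = tuple(table.feature_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_ = fit_logistic(table, self.selected_features_)
            self.cv_result_ = loocv(table, self.selected_features_,
                                    threshold=self.threshold)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        df = StandardizedLogisticRegression._to_frame(self, X)
        p1 = _predict_matrix(self.model_, df)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)
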