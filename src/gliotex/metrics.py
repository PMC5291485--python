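"""Performance indices, empirical ROC/Az, DeLong paired AUC comparison,
contingency tests and misdiagnosis summaries.

Conventions: GBM (malignant) is the positive class.  Az is the empirical
(Mann-Whitney) area under the ROC curve with ties counted 1/2; paired
reader comparisons use DeLong's covariance-based test for correlated
AUCs.  Indices with a zero denominator are reported as None (undefined),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


def _frac(k: int, n: int) -> Optional[float]:
    return k / n if n > 0 else None


@dataclass
class MetricsReport:
    """Confusion counts and the five performance indices (+ optional Az)."""

    tp: int
    fp: int
    tn: int
    fn: int
    az: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> Optional[float]:
        return _frac(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> Optional[float]:
        return _frac(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _frac(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return _frac(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _frac(self.tn, self.tn + self.fn)

    def counts_as_strings(self) -> Dict[str, str]:
        """Report-parity 'x/y' count strings for each index."""
        return {
            "accuracy": f"{self.tp + self.tn}/{self.n}",
            "sensitivity": f"{self.tp}/{self.tp + self.fn}",
            "specificity": f"{self.tn}/{self.tn + self.fp}",
            "ppv": f"{self.tp}/{self.tp + self.fp}",
            "npv": f"{self.tn}/{self.tn + self.fn}",
        }

    def as_dict(self, percent_digits: int = 0) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = v
            out[f"{name}_pct"] = (
                None if v is None else round(100.0 * v, percent_digits)
            )
        out["counts"] = self.counts_as_strings()
        if self.az is not None:
            out["az"] = self.az
        return out


def confusion_metrics(predictions, truth) -> MetricsReport:
    """Exact confusion counts and indices of binary predictions vs truth."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {y.shape} truth"
        )
    return MetricsReport(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        az: Optional[float] = None) -> MetricsReport:
    """Build a report directly from published outcome counts."""
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, az=az)


@dataclass
class RocCurve:
    """Empirical ROC operating points and Mann-Whitney AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    tie_note: str = "ties counted 1/2 (Mann-Whitney)"


def empirical_auc(scores, truth) -> RocCurve:
    """Empirical ROC curve and AUC of continuous malignancy scores.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("truth must contain both classes")
    fpr, tpr, thr = roc_curve(y, s)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=float(roc_auc_score(y, s)))


def _midrank_placements(scores_pos: np.ndarray,
                        scores_neg: np.ndarray) -> Tuple[np.ndarray,
                                                         np.ndarray, float]:
    """DeLong structural components V10 (per positive), V01 (per negative)."""
    m, n = len(scores_pos), len(scores_neg)
    allv = np.concatenate([scores_pos, scores_neg])
    rank_all = stats.rankdata(allv)  # midranks
    rank_pos = stats.rankdata(scores_pos)
    rank_neg = stats.rankdata(scores_neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01, float(auc)


def delong_paired_test(scores_a, scores_b, truth) -> Tuple[float, float]:
    """DeLong two-sided test of the AUC difference of paired score sets.

    Returns ``(delta_auc, p_value)`` with ``delta = AUC_a - AUC_b``.  If
    the DeLong variance of the difference is zero (e.g., identical score
    sets) the statistic is undefined: delta 0 maps to p = 1.0, otherwise
    p is NaN with a warning-style diagnostic embedded in the exception.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(truth, dtype=int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and truth must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("truth must contain both classes")
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((a, b)):
        v10[k], v01[k], aucs[k] = _midrank_placements(s[pos], s[neg])
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        return delta, (1.0 if delta == 0.0 else float("nan"))
    z = delta / np.sqrt(var)
    return delta, float(2.0 * stats.norm.sf(abs(z)))


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    method: str = "chi2") -> float:
    """Two-sided p for H0: the two proportions k1/n1 and k2/n2 are equal.

    ``method='chi2'`` is the 2x2 chi-square without continuity
    correction; ``'fisher'`` is Fisher's exact test.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        if k1 == k2 == 0 or (n1 - k1) == (n2 - k2) == 0:
            return 1.0  # degenerate margin: no evidence of a difference
        return float(stats.chi2_contingency(table, correction=False)[1])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class MisdiagnosisSummary:
    """Per-reader and pooled per-class misdiagnosis counts and rates."""

    per_reader_missed_pos: List[int]
    per_reader_missed_neg: List[int]
    n_pos: int
    n_neg: int
    overlap_missed: Dict[int, List[int]] = field(default_factory=dict)

    @property
    def n_readers(self) -> int:
        return len(self.per_reader_missed_pos)

    @property
    def pooled_missed_pos(self) -> int:
        return sum(self.per_reader_missed_pos)

    @property
    def pooled_missed_neg(self) -> int:
        return sum(self.per_reader_missed_neg)

    @property
    def pooled_pos_rate(self) -> float:
        return self.pooled_missed_pos / (self.n_readers * self.n_pos)

    @property
    def pooled_neg_rate(self) -> float:
        return self.pooled_missed_neg / (self.n_readers * self.n_neg)

    def as_dict(self) -> dict:
        return {
            "per_reader_missed_gbm": self.per_reader_missed_pos,
            "per_reader_missed_lgg": self.per_reader_missed_neg,
            "pooled_missed_gbm": f"{self.pooled_missed_pos}/"
                                 f"{self.n_readers * self.n_pos}",
            "pooled_missed_lgg": f"{self.pooled_missed_neg}/"
                                 f"{self.n_readers * self.n_neg}",
            "pooled_gbm_miss_rate_pct": round(100 * self.pooled_pos_rate, 1),
            "pooled_lgg_miss_rate_pct": round(100 * self.pooled_neg_rate, 1),
        }


def misdiagnosis_summary(per_reader_predictions: Sequence[Sequence[int]],
                         truth) -> MisdiagnosisSummary:
    """Pool per-class misdiagnoses over readers (rates as k / (R * n_class)).

    Also records, per case index, which readers missed it, enabling
    overlap analyses between readers.
    """
    y = np.asarray(truth, dtype=int)
    preds = [np.asarray(p, dtype=int) for p in per_reader_predictions]
    if not preds:
        raise ValueError("need at least one reader")
    for p in preds:
        if p.shape != y.shape:
            raise ValueError("prediction sets must align with truth")
    missed_pos, missed_neg = [], []
    overlap: Dict[int, List[int]] = {}
    for r, p in enumerate(preds):
        wrong = p != y
        missed_pos.append(int(np.sum(wrong & (y == 1))))
        missed_neg.append(int(np.sum(wrong & (y == 0))))
        for idx in np.nonzero(wrong)[0]:
            overlap.setdefault(int(idx), []).append(r)
    return MisdiagnosisSummary(
        per_reader_missed_pos=missed_pos,
        per_reader_missed_neg=missed_neg,
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
        overlap_missed=overlap,
    )


def misdiagnosis_from_counts(correct_pos: Sequence[int], n_pos: int,
                             correct_neg: Sequence[int],
                             n_neg: int) -> MisdiagnosisSummary:
    """Pool misdiagnosis rates from published per-reader correct counts.

    ``correct_pos[r]`` is reader r's correctly graded positives out of
    ``n_pos`` (likewise for negatives); misses are the complements.
    """
    if len(correct_pos) != len(correct_neg):
        raise ValueError("reader count mismatch")
    return MisdiagnosisSummary(
        per_reader_missed_pos=[n_pos - c for c in correct_pos],
        per_reader_missed_neg=[n_neg - c for c in correct_neg],
        n_pos=n_pos,
        n_neg=n_neg,
    )
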