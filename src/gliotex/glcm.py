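"""Gray-level co-occurrence matrices and the 14 local texture features.

A GLCM ``p(i, j | d, theta)`` is the normalized joint frequency of gray
levels i and j at pixel offset (distance ``d``, direction ``theta``); only
pairs with *both* pixels inside the ROI mask are counted.  Accumulation is
symmetric (each pair counted in both orders), so ``p`` is symmetric and
the marginals px and py coincide.  Levels are 0-based indices in
``[0, G-1]``.

The feature suite is the classic Haralick-style set: autocorrelation,
contrast, correlation, cluster prominence/shade, dissimilarity, energy,
entropy, homogeneity, difference variance, difference entropy, the first
information measure of correlation (IMC1), inverse difference normalized
and inverse difference moment.  Entropies use log base 2 by default
(bits), with ``0 * log 0 == 0``.

Two formula dialects exist for a handful of features whose printed
definitions in the source literature are internally inconsistent (see
docs/methods.md): ``"canonical"`` (default) uses the standard forms;
``"printed"`` reproduces the literal printed formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

from .io import QuantizedRoi

#: (row, col) pixel offsets for the four standard directions.
DIRECTION_OFFSETS: Dict[int, tuple] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

DEFAULT_DIRECTIONS = (0, 45, 90, 135)

GLCM_FEATURE_NAMES = (
    "glcm_autocorrelation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_info_measure_correlation",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment",
)


class NoPairsError(ValueError):
    """Raised when an offset finds no in-mask pixel pair."""


@dataclass
class GlcmMatrix:
    """Normalized G x G co-occurrence probability matrix for one (d, theta)."""

    p: np.ndarray
    d: int
    theta: int
    pair_count: int


@dataclass
class GlcmMarginals:
    """Marginal, sum and difference distributions of a normalized GLCM.

    ``p_sum[k]`` is P(i + j = k) for k in [0, 2G-2]; ``p_diff[k]`` is
    P(|i - j| = k) for k in [0, G-1].  HX, HY, HXY are the marginal and
    joint entropies; HXY1 = -sum p(i,j) log(px(i) py(j)).
    """

    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray
    p_diff: np.ndarray
    hx: float
    hy: float
    hxy: float
    hxy1: float


def compute_glcm(
    qroi: QuantizedRoi,
    d: int = 1,
    theta: int = 0,
    symmetric: bool = True,
    normalize: bool = True,
) -> GlcmMatrix:
    """Count level co-occurrences at offset ``d`` in direction ``theta``.

    Both pixels of a pair must lie inside the mask.  With ``symmetric``
    each pair contributes in both orders; with ``normalize`` counts are
    divided by the total pair count so entries sum to one.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if theta not in DIRECTION_OFFSETS:
        raise ValueError(f"theta must be one of {sorted(DIRECTION_OFFSETS)}")
    dr, dc = (o * d for o in DIRECTION_OFFSETS[theta])
    lv, mask = qroi.levels, qroi.mask
    h, w = lv.shape
    rows, cols = np.nonzero(mask)
    r2, c2 = rows + dr, cols + dc
    ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
    rows, cols, r2, c2 = rows[ok], cols[ok], r2[ok], c2[ok]
    ok = mask[r2, c2]
    a = lv[rows[ok], cols[ok]]
    b = lv[r2[ok], c2[ok]]
    if a.size == 0:
        raise NoPairsError(
            f"no in-mask pixel pairs at d={d}, theta={theta} "
            f"(case {qroi.case_id!r})"
        )
    G = qroi.n_levels
    counts = np.zeros((G, G), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    p = counts / pair_count if normalize else counts
    return GlcmMatrix(p=p, d=d, theta=theta, pair_count=pair_count)


def _xlogx(v: np.ndarray, base: float) -> np.ndarray:
    """v * log(v) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(v, dtype=float)
    nz = v > 0
    out[nz] = v[nz] * np.log(v[nz]) / np.log(base)
    return out


def _entropy_of(dist: np.ndarray, base: float) -> float:
    return float(-_xlogx(dist, base).sum())


def glcm_marginals(m: GlcmMatrix, log_base: float = 2.0) -> GlcmMarginals:
    """Marginals, sum/difference distributions and entropies of ``m``."""
    p = np.asarray(m.p, dtype=float)
    G = p.shape[0]
    i = np.arange(G, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sigma_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(),
                        minlength=2 * G - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(),
                         minlength=G)
    # HXY1 only sums over cells where p > 0, so px*py > 0 there too.
    nz = p > 0
    outer = np.outer(px, py)
    hxy1 = float(-(p[nz] * np.log(outer[nz]) / np.log(log_base)).sum())
    return GlcmMarginals(
        px=px, py=py, mu_x=mu_x, mu_y=mu_y,
        sigma_x=sigma_x, sigma_y=sigma_y,
        p_sum=p_sum, p_diff=p_diff,
        hx=_entropy_of(px, log_base),
        hy=_entropy_of(py, log_base),
        hxy=_entropy_of(p.ravel(), log_base),
        hxy1=hxy1,
    )


@dataclass
class GlcmFeatures:
    values: Dict[str, float]
    degenerate: bool = False

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)


def glcm_features(
    m: GlcmMatrix,
    log_base: float = 2.0,
    formula_dialect: str = "canonical",
    difference_variance: str = "canonical",
) -> GlcmFeatures:
    """Compute the 14 texture features of a normalized GLCM.

    Parameters
    ----------
    m : GlcmMatrix
        Normalized co-occurrence matrix.
    log_base : float
        Base for every entropy term (2 = bits).
    formula_dialect : {'canonical', 'printed'}
        'printed' reproduces the literal printed formulas for
        autocorrelation (duplicates correlation), homogeneity (signed,
        negated) and difference entropy (computed on the sum
        distribution); 'canonical' uses the standard Haralick forms.
    difference_variance : {'canonical', 'printed'}
        'canonical' (default) is the variance of the difference
        distribution; 'printed' is ``sum_k k^2 p_diff(k)``, which is
        algebraically identical to contrast and therefore makes the
        joint feature set exactly collinear.

    Notes
    -----
    If either marginal SD is zero (e.g., a constant ROI whose GLCM is a
    single spike) correlation and the information measure are set to 0
    and the result is flagged degenerate.
    """
    if formula_dialect not in ("canonical", "printed"):
        raise ValueError(f"unknown formula_dialect {formula_dialect!r}")
    if difference_variance not in ("canonical", "printed"):
        raise ValueError(f"unknown difference_variance {difference_variance!r}")
    p = np.asarray(m.p, dtype=float)
    G = p.shape[0]
    mg = glcm_marginals(m, log_base=log_base)
    ii, jj = np.meshgrid(np.arange(G, dtype=float),
                         np.arange(G, dtype=float), indexing="ij")
    absdiff = np.abs(ii - jj)
    clus = ii + jj - mg.mu_x - mg.mu_y
    k_diff = np.arange(G, dtype=float)
    k_sum = np.arange(2 * G - 1, dtype=float)

    degenerate = mg.sigma_x * mg.sigma_y == 0.0
    if degenerate:
        correlation = 0.0
    else:
        correlation = float(
            (((ii - mg.mu_x) * (jj - mg.mu_y) * p).sum())
            / (mg.sigma_x * mg.sigma_y)
        )

    if formula_dialect == "printed":
        autocorrelation = correlation
        # literal signed form 1/(1+i-j) is undefined at j = i+1; those
        # cells contribute 0 rather than +/-inf
        den = 1.0 + ii - jj
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den != 0, p / np.where(den == 0, 1.0, den), 0.0)
        homogeneity = float(-ratio.sum())
        diff_entropy = _entropy_of(mg.p_sum, log_base)
    else:
        autocorrelation = float((ii * jj * p).sum())
        homogeneity = float((p / (1.0 + absdiff)).sum())
        diff_entropy = _entropy_of(mg.p_diff, log_base)

    if difference_variance == "printed":
        diff_var = float((k_diff**2 * mg.p_diff).sum())
    else:
        mu_d = float(k_diff @ mg.p_diff)
        diff_var = float(((k_diff - mu_d) ** 2) @ mg.p_diff)

    denom = max(mg.hx, mg.hy)
    imc1 = 0.0 if (degenerate or denom == 0) else float(
        (mg.hxy - mg.hxy1) / denom
    )

    values = {
        "glcm_autocorrelation": autocorrelation,
        "glcm_contrast": float((absdiff**2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_cluster_prominence": float((clus**4 * p).sum()),
        "glcm_cluster_shade": float((clus**3 * p).sum()),
        "glcm_dissimilarity": float((absdiff * p).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": _entropy_of(p.ravel(), log_base),
        "glcm_homogeneity": homogeneity,
        "glcm_difference_variance": diff_var,
        "glcm_difference_entropy": diff_entropy,
        "glcm_info_measure_correlation": imc1,
        "glcm_inverse_difference_normalized": float(
            (p / (1.0 + absdiff / G)).sum()
        ),
        "glcm_inverse_difference_moment": float(
            (p / (1.0 + (ii - jj) ** 2)).sum()
        ),
    }
    return GlcmFeatures(values=values, degenerate=bool(degenerate))


def aggregate_directions(per_direction: Sequence[GlcmFeatures]) -> GlcmFeatures:
    """Arithmetic mean of each feature over 1-4 direction results."""
    if len(per_direction) == 0:
        raise ValueError("no direction results to aggregate")
    names = list(per_direction[0].values)
    for f in per_direction[1:]:
        if list(f.values) != names:
            raise ValueError("inconsistent feature naming across directions")
    mean = {
        k: float(np.mean([f.values[k] for f in per_direction])) for k in names
    }
    return GlcmFeatures(
        values=mean, degenerate=any(f.degenerate for f in per_direction)
    )
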