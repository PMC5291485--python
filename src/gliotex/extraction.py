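"""Per-case feature extraction: 4 histogram moments + 14 direction-averaged
GLCM features, and a scikit-learn transformer wrapping it.

Histogram moments are computed on the raw in-ROI intensities; GLCM
features on the gray-level-quantized ROI (default 64 levels), averaged
over the four standard directions at distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .glcm import (
    DEFAULT_DIRECTIONS,
    GLCM_FEATURE_NAMES,
    aggregate_directions,
    compute_glcm,
    glcm_features,
)
from .histogram import HISTOGRAM_FEATURE_NAMES, histogram_moments
from .io import RoiImage, quantize, roi_pixels

ALL_FEATURE_NAMES: Tuple[str, ...] = HISTOGRAM_FEATURE_NAMES + GLCM_FEATURE_NAMES


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings shared by every case of a study.

    Attributes
    ----------
    n_levels : int
        Gray levels G for GLCM quantization.
    distance : int
        Co-occurrence offset d in pixels.
    directions : tuple of int
        Offset directions in degrees, subset of (0, 45, 90, 135).
    log_base : float
        Entropy log base (2 = bits).
    formula_dialect : {'canonical', 'printed'}
        Texture-formula dialect, see :func:`gliotex.glcm.glcm_features`.
    difference_variance : {'printed', 'canonical'}
        Difference-variance variant.
    """

    n_levels: int = 64
    distance: int = 1
    directions: Tuple[int, ...] = DEFAULT_DIRECTIONS
    log_base: float = 2.0
    formula_dialect: str = "canonical"
    difference_variance: str = "canonical"

    def as_dict(self) -> dict:
        d = asdict(self)
        d["directions"] = list(self.directions)
        return d


@dataclass
class FeatureVector:
    case_id: str
    values: Dict[str, float]
    degenerate_flags: Tuple[str, ...] = ()
    per_direction: Optional[Dict[int, Dict[str, float]]] = None


def extract_all(
    image: RoiImage,
    config: ExtractionConfig = ExtractionConfig(),
    verbose: bool = False,
) -> FeatureVector:
    """Extract the 18 named features of one masked case.

    Raises any underlying error with the case_id prepended for context.
    """
    try:
        hist = histogram_moments(roi_pixels(image))
        qroi = quantize(image, n_levels=config.n_levels)
        per_dir = {}
        feats = []
        for theta in config.directions:
            m = compute_glcm(qroi, d=config.distance, theta=theta)
            f = glcm_features(
                m,
                log_base=config.log_base,
                formula_dialect=config.formula_dialect,
                difference_variance=config.difference_variance,
            )
            feats.append(f)
            if verbose:
                per_dir[theta] = f.as_dict()
        agg = aggregate_directions(feats)
    except Exception as exc:
        raise type(exc)(f"case {image.case_id!r}: {exc}") from exc
    flags = []
    if hist.degenerate:
        flags.append("constant_roi")
    if qroi.degenerate:
        flags.append("degenerate_quantization")
    if agg.degenerate:
        flags.append("degenerate_glcm")
    values = {**hist.as_dict(), **agg.as_dict()}
    return FeatureVector(
        case_id=image.case_id,
        values=values,
        degenerate_flags=tuple(flags),
        per_direction=per_dir if verbose else None,
    )


def extract_table(
    images: Sequence[RoiImage],
    labels: Optional[Sequence[int]] = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Feature table: one row per case, columns case_id, features, label."""
    rows = []
    for k, img in enumerate(images):
        fv = extract_all(img, config=config)
        row = {"case_id": fv.case_id, **fv.values}
        if labels is not None:
            row["label"] = int(labels[k])
        row["degenerate_flags"] = ";".join(fv.degenerate_flags)
        rows.append(row)
    return pd.DataFrame(rows)


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: list of RoiImage -> (n_cases, 18) features.

    Stateless (fit is a no-op); exists so extraction composes with sklearn
    pipelines and model selection.

    Parameters mirror :class:`ExtractionConfig`.

    Examples
    --------
    >>> from gliotex.phantoms import generate_cohort
    >>> images, labels = generate_cohort(5, 5, separability=1.0, seed=0)
    >>> X = TextureFeatureExtractor().transform(images)
    >>> X.shape
    (10, 18)
    """

    def __init__(
        self,
        n_levels: int = 64,
        distance: int = 1,
        directions: Tuple[int, ...] = DEFAULT_DIRECTIONS,
        log_base: float = 2.0,
        formula_dialect: str = "canonical",
        difference_variance: str = "canonical",
    ):
        self.n_levels = n_levels
        self.distance = distance
        self.directions = directions
        self.log_base = log_base
        self.formula_dialect = formula_dialect
        self.difference_variance = difference_variance

    def _config(self) -> ExtractionConfig:
        return ExtractionConfig(
            n_levels=self.n_levels,
            distance=self.distance,
            directions=tuple(self.directions),
            log_base=self.log_base,
            formula_dialect=self.formula_dialect,
            difference_variance=self.difference_variance,
        )

    def fit(self, X, y=None):
        self.feature_names_in_ = None
        self.n_features_out_ = len(ALL_FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self._config()
        df = extract_table(list(X), config=cfg)
        return df[list(ALL_FEATURE_NAMES)]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ALL_FEATURE_NAMES, dtype=object)
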