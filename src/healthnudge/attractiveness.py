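"""Visual-attractiveness modelling and interrater agreement.

A linear model maps the five low-level image features to a human-rated
attractiveness score.  The bundled default coefficients come from a
robust regression of standardized 7-point attractiveness ratings of
recipe photographs on their features: brightness, colorfulness, entropy
and sharpness raise predicted attractiveness; saturation lowers it.

The module also implements the weighted interrater-agreement statistic
used to check the reliability of ordinal 7-point ratings: a pair of
raters scores 1 − |Δ|/6 per item (1 for an exact match, 0.83 for a
one-step difference, … 0 for the maximal six-step difference), averaged
over items and expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .exceptions import DegenerateInputError, EstimationError, InvalidInputError
from .image_features import ImageFeatures

__all__ = [
    "FEATURE_NAMES",
    "AttractivenessModel",
    "RatingMatrix",
    "predict_attractiveness",
    "zscore_ratings",
    "fit_attractiveness_model",
    "pairwise_agreement",
    "agreement_summary",
]

#: Canonical feature order used by the model coefficient vector.
FEATURE_NAMES = ("brightness", "colorfulness", "entropy", "sharpness", "saturation")

#: Width of the 7-point rating scale; a |Δ| of 6 is maximal disagreement.
_SCALE_SPAN = 6.0


@dataclass(frozen=True)
class AttractivenessModel:
    """Linear attractiveness model: intercept + coefficients over the five features.

    The default instance is the pre-trained model (robust regression on
    standardized human ratings of 475 recipe photographs):
    brightness 3.22, colorfulness 8.35, entropy 0.80, sharpness 1.42,
    saturation −4.08, intercept −6.53.
    """

    beta_brightness: float = 3.22
    beta_colorfulness: float = 8.35
    beta_entropy: float = 0.80
    beta_sharpness: float = 1.42
    beta_saturation: float = -4.08
    intercept: float = -6.53

    def __post_init__(self):
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise InvalidInputError("model parameters must all be finite")

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector in canonical feature order."""
        return np.array(
            [
                self.beta_brightness,
                self.beta_colorfulness,
                self.beta_entropy,
                self.beta_sharpness,
                self.beta_saturation,
            ]
        )

    def predict(self, features) -> float:
        """Predicted attractiveness score for one feature vector.

        ``features`` may be an :class:`ImageFeatures` or a length-5
        array in canonical order.
        """
        if isinstance(features, ImageFeatures):
            x = features.as_array()
        else:
            x = np.asarray(features, dtype=float)
            if x.shape != (5,):
                raise InvalidInputError(f"expected 5 features, got shape {x.shape}")
        return float(self.intercept + self.coefficients @ x)

    def predict_many(self, feature_matrix: np.ndarray) -> np.ndarray:
        """Predicted scores for an item × 5 feature matrix."""
        X = np.asarray(feature_matrix, dtype=float)
        if X.ndim != 2 or X.shape[1] != 5:
            raise InvalidInputError(f"expected an item x 5 matrix, got shape {X.shape}")
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict[str, float]:
        return {
            **{f"beta_{n}": float(b) for n, b in zip(FEATURE_NAMES, self.coefficients)},
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttractivenessModel":
        return cls(**{k: float(v) for k, v in d.items()})


def predict_attractiveness(features, model: AttractivenessModel | None = None) -> float:
    """Functional form of :meth:`AttractivenessModel.predict` (default model if none given)."""
    return (model or AttractivenessModel()).predict(features)


@dataclass
class RatingMatrix:
    """Integer ratings on the 7-point scale, one row per rater, one column per item."""

    ratings: np.ndarray
    rater_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        r = np.asarray(self.ratings)
        if r.ndim != 2:
            raise InvalidInputError(f"ratings must be a 2-D raters x items grid, got shape {r.shape}")
        if not np.issubdtype(r.dtype, np.integer):
            if not np.allclose(r, np.rint(r)):
                raise InvalidInputError("ratings must be integers on the 1..7 scale")
            r = np.rint(r).astype(int)
        if r.size and (r.min() < 1 or r.max() > 7):
            raise InvalidInputError("ratings must lie in 1..7")
        self.ratings = r
        if not self.rater_ids:
            self.rater_ids = [f"rater{i + 1}" for i in range(r.shape[0])]
        if not self.item_ids:
            self.item_ids = [f"item{i + 1}" for i in range(r.shape[1])]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_items(self) -> int:
        return self.ratings.shape[1]


def zscore_ratings(matrix: RatingMatrix, ddof: int = 1) -> np.ndarray:
    """Per-item mean ratings standardized across items (mean 0, SD 1).

    The per-item mean over raters is computed first; those means are
    then z-scored across items using the sample SD (``ddof=1``) by
    default.

    Raises
    ------
    DegenerateInputError
        If fewer than 2 items are given or all item means coincide.
    """
    if matrix.n_items < 2:
        raise DegenerateInputError("z-scoring needs at least 2 items")
    means = matrix.ratings.mean(axis=0)
    sd = means.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("all item mean ratings are identical; z-scores undefined")
    return (means - means.mean()) / sd


def fit_attractiveness_model(
    features: np.ndarray,
    targets: np.ndarray,
    method: str = "huber",
) -> tuple[AttractivenessModel, float]:
    """Fit the attractiveness model by robust (Huber) or ordinary regression.

    Parameters
    ----------
    features
        item × 5 matrix in canonical feature order.
    targets
        standardized attractiveness scores, one per item.
    method
        ``"huber"`` (M-estimation, tuning constant 1.345) or ``"ols"``.

    Returns
    -------
    (model, R²)
        R² is computed on the fitted values, 1 − SS_res/SS_tot.

    Raises
    ------
    EstimationError
        With fewer than 7 items (the 6 parameters would not be
        identified) or a rank-deficient design.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 5:
        raise InvalidInputError(f"features must be an item x 5 matrix, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise InvalidInputError("targets must align with feature rows")
    n = X.shape[0]
    if n <= 6:
        raise EstimationError(f"need at least 7 items to fit 6 parameters, got {n}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise EstimationError("rank-deficient design: features are collinear")

    if method == "huber":
        fit = sm.RLM(y, design, M=sm.robust.norms.HuberT(t=1.345)).fit()
    elif method == "ols":
        fit = sm.OLS(y, design).fit()
    else:
        raise InvalidInputError(f"unknown method {method!r}; use 'huber' or 'ols'")

    params = np.asarray(fit.params)
    model = AttractivenessModel(
        beta_brightness=params[1],
        beta_colorfulness=params[2],
        beta_entropy=params[3],
        beta_sharpness=params[4],
        beta_saturation=params[5],
        intercept=params[0],
    )
    resid = y - np.asarray(fit.fittedvalues)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return model, r2


def pairwise_agreement(a, b) -> float:
    """Weighted agreement between two raters' 7-point ratings, as a percentage.

    Per item the agreement weight is 1 − |a_i − b_i| / 6: exact matches
    score 1, one-step differences 0.83, two-step differences 0.67, and
    so on down to 0 at the maximal difference of 6.  The result is
    100 × the mean weight over items.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise InvalidInputError("rating vectors must be 1-D, non-empty and of equal length")
    if a.min() < 1 or a.max() > 7 or b.min() < 1 or b.max() > 7:
        raise InvalidInputError("ratings must lie in 1..7")
    return float(100.0 * (1.0 - np.abs(a - b) / _SCALE_SPAN).mean())


def agreement_summary(matrix: RatingMatrix) -> tuple[np.ndarray, float, float]:
    """Pairwise agreement over all unordered rater pairs, with mean and population SD.

    Returns
    -------
    (pairwise matrix, mean percent, SD percent)
        The matrix is symmetric with 100 on the diagonal.  The mean and
        SD summarise the strictly-lower-triangle pairs; the SD uses the
        population (divide-by-n) convention.
    """
    if matrix.n_raters < 2:
        raise InvalidInputError("agreement needs at least 2 raters")
    n = matrix.n_raters
    pm = np.full((n, n), 100.0)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_agreement(matrix.ratings[i], matrix.ratings[j])
            pm[i, j] = pm[j, i] = s
            vals.append(s)
    vals = np.array(vals)
    return pm, float(vals.mean()), float(vals.std(ddof=0))
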