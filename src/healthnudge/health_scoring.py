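"""FSA traffic-light scoring of recipes and healthy/unhealthy classification.

Each of four nutrients (fat, saturated fat, sugar, salt, all grams per
100 g) is banded green/amber/red against the UK Food Standards Agency
front-of-pack criteria and scored 1/2/3; the FSA score is the sum of
the four bands, ranging from 4 (all green, healthiest) to 12 (all red).

Classification into healthy/unhealthy follows query-type-specific
cutoffs: a recipe is healthy with a score of 6 or lower (7 or lower for
burgers, which are unhealthier as a class), unhealthy with a score of
9 or higher, and excluded in between.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "NUTRIENTS",
    "QUERY_TYPES",
    "NutrientProfile",
    "BandThresholds",
    "Recipe",
    "band",
    "fsa_score",
    "classify_recipe",
    "score_table",
    "annotate_recipes",
]

logger = logging.getLogger(__name__)

#: Nutrient names in canonical order.
NUTRIENTS = ("fat", "saturated_fat", "sugar", "salt")

#: Query types used by the study design.
QUERY_TYPES = ("burger", "salad", "pasta", "curry")

#: Healthy cutoff (score <= cutoff) per query type; unhealthy is score >= 9.
_HEALTHY_CUTOFF = {"burger": 7, "salad": 6, "pasta": 6, "curry": 6}
_UNHEALTHY_CUTOFF = 9


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient content of one recipe, grams per 100 g."""

    fat: float
    saturated_fat: float
    sugar: float
    salt: float

    def __post_init__(self):
        for name in NUTRIENTS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")
        if self.saturated_fat > self.fat:
            logger.warning(
                "saturated fat (%.2f g) exceeds total fat (%.2f g); check the source data",
                self.saturated_fat,
                self.fat,
            )

    def get(self, nutrient: str) -> float:
        if nutrient not in NUTRIENTS:
            raise InvalidParameterError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)


@dataclass(frozen=True)
class BandThresholds:
    """(low, high) green/amber/red cutoffs per nutrient, grams per 100 g.

    Defaults are the UK FSA front-of-pack per-100 g criteria.  The
    optional per-portion red cutoffs force a red band when the amount
    per portion exceeds them; they only apply when a portion size is
    supplied, which the bundled data does not provide, so the override
    is off by default.
    """

    fat: tuple[float, float] = (3.0, 17.5)
    saturated_fat: tuple[float, float] = (1.5, 5.0)
    sugar: tuple[float, float] = (5.0, 22.5)
    salt: tuple[float, float] = (0.3, 1.5)
    portion_red: dict = field(
        default_factory=lambda: {"fat": 21.0, "saturated_fat": 6.0, "sugar": 27.0, "salt": 1.8}
    )

    def __post_init__(self):
        for name in NUTRIENTS:
            low, high = getattr(self, name)
            if not (0 < low < high):
                raise InvalidParameterError(
                    f"{name} thresholds must satisfy 0 < low < high, got ({low}, {high})"
                )

    def cutoffs(self, nutrient: str) -> tuple[float, float]:
        if nutrient not in NUTRIENTS:
            raise InvalidParameterError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)


@dataclass(frozen=True)
class Recipe:
    """One food item: identity, nutrients, popularity and image attractiveness."""

    id: str
    name: str
    query_type: str
    nutrients: NutrientProfile
    mean_rating: float
    image_ref: str | None = None
    image_z: float | None = None
    fsa_printed: int | None = None
    # annotations filled in by annotate_recipes / score_table
    fsa: int | None = None
    health_class: str | None = None

    def __post_init__(self):
        if not (0 <= self.mean_rating <= 5):
            raise InvalidInputError(
                f"mean_rating must lie in [0, 5], got {self.mean_rating!r} ({self.id})"
            )
        if self.fsa_printed is not None and not (4 <= self.fsa_printed <= 12):
            raise InvalidInputError(
                f"fsa_printed must lie in 4..12, got {self.fsa_printed!r} ({self.id})"
            )

    @property
    def study_fsa(self) -> int | None:
        """The score the study design operates on.

        Curated tables may print an FSA score that includes per-portion
        adjustments not derivable from per-100 g values; when present it
        takes precedence over the computed score for classification and
        ranking.
        """
        return self.fsa_printed if self.fsa_printed is not None else self.fsa


def band(
    value: float,
    nutrient: str,
    thresholds: BandThresholds | None = None,
    portion_g: float | None = None,
) -> int:
    """Traffic-light band of one nutrient value: 1 (green), 2 (amber) or 3 (red).

    Boundaries are inclusive on the green and amber sides: a value
    exactly at the low cutoff is green, exactly at the high cutoff
    amber.  When ``portion_g`` is given, an amount per portion above
    the per-portion red cutoff forces band 3.
    """
    t = thresholds or BandThresholds()
    low, high = t.cutoffs(nutrient)
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"nutrient value must be finite and >= 0, got {value!r}")
    if portion_g is not None:
        per_portion = value * portion_g / 100.0
        if per_portion > t.portion_red[nutrient]:
            return 3
    if value <= low:
        return 1
    if value <= high:
        return 2
    return 3


def fsa_score(
    profile: NutrientProfile,
    thresholds: BandThresholds | None = None,
    portion_g: float | None = None,
) -> int:
    """FSA traffic-light score: sum of the four nutrient bands, in 4..12."""
    t = thresholds or BandThresholds()
    return sum(band(profile.get(n), n, t, portion_g=portion_g) for n in NUTRIENTS)


def classify_recipe(recipe: Recipe, score: int) -> str:
    """Classify a recipe as ``healthy``, ``unhealthy`` or ``excluded`` from its FSA score.

    Healthy means a score of 6 or lower (7 or lower for burgers);
    unhealthy means 9 or higher; everything in between is excluded
    from the study design.
    """
    if recipe.query_type not in _HEALTHY_CUTOFF:
        raise InvalidParameterError(
            f"unknown query_type {recipe.query_type!r}; expected one of {QUERY_TYPES}"
        )
    if not (4 <= score <= 12):
        raise InvalidInputError(f"FSA score must lie in 4..12, got {score!r}")
    if score <= _HEALTHY_CUTOFF[recipe.query_type]:
        return "healthy"
    if score >= _UNHEALTHY_CUTOFF:
        return "unhealthy"
    return "excluded"


def annotate_recipes(
    recipes: list[Recipe],
    thresholds: BandThresholds | None = None,
    portion_g: float | None = None,
) -> list[Recipe]:
    """Return recipes with ``fsa`` and ``health_class`` annotations filled in.

    ``fsa`` is always the per-100 g computed score; ``health_class``
    is derived from :attr:`Recipe.study_fsa`, i.e. the printed score
    when the table carries one (it may embody per-portion adjustments),
    else the computed score.
    """
    out = []
    for r in recipes:
        s = fsa_score(r.nutrients, thresholds, portion_g=portion_g)
        study = r.fsa_printed if r.fsa_printed is not None else s
        out.append(dataclasses.replace(r, fsa=s, health_class=classify_recipe(r, study)))
    return out


def score_table(
    recipes: list[Recipe],
    thresholds: BandThresholds | None = None,
    portion_g: float | None = None,
) -> tuple[list[Recipe], pd.DataFrame]:
    """Annotate a recipe table and report disagreements with printed FSA values.

    Returns the annotated recipes and a mismatch report with one row
    per recipe whose computed per-100 g score differs from its printed
    ``fsa_printed`` (columns: id, printed, computed).  Recipes without
    a printed score never appear in the report.
    """
    if not recipes:
        raise InvalidInputError("recipe list is empty")
    annotated = annotate_recipes(recipes, thresholds, portion_g=portion_g)
    rows = [
        {"id": r.id, "printed": r.fsa_printed, "computed": r.fsa}
        for r in annotated
        if r.fsa_printed is not None and r.fsa != r.fsa_printed
    ]
    report = pd.DataFrame(rows, columns=["id", "printed", "computed"])
    return annotated, report
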