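"""Construction of 8-item search-result lists under the 2×2 study design.

The design crosses two factors within subjects: ranking (popularity
vs. health) and visual presentation (baseline vs. manipulated images).
Health-ranked lists order recipes by ascending FSA score; in the
manipulated-visual conditions, unattractive images of healthy recipes
(attractiveness z-score below a threshold, default 0.99) are upgraded
and all images of unhealthy recipes are downgraded, so healthiness and
visual appeal are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError
from .health_scoring import Recipe

__all__ = [
    "SearchCondition",
    "CONDITIONS",
    "DEFAULT_Z_THRESHOLD",
    "SearchResultEntry",
    "SearchResultList",
    "filter_by_query",
    "rank_recipes",
    "assign_image_variant",
    "build_condition_list",
    "make_design_sequences",
]

#: Replacement threshold on the image-attractiveness z-score.
DEFAULT_Z_THRESHOLD = 0.99

LIST_LENGTH = 8


@dataclass(frozen=True)
class SearchCondition:
    """One cell of the 2×2 design: ranking × visual presentation."""

    ranking: str  # "popularity" | "health"
    visual: str  # "baseline" | "manipulated"

    def __post_init__(self):
        if self.ranking not in ("popularity", "health"):
            raise InvalidParameterError(f"ranking must be 'popularity' or 'health', got {self.ranking!r}")
        if self.visual not in ("baseline", "manipulated"):
            raise InvalidParameterError(f"visual must be 'baseline' or 'manipulated', got {self.visual!r}")

    @property
    def label(self) -> str:
        return f"{self.ranking}-{self.visual}"


#: The four cells in canonical order (ranking varying slowest).
CONDITIONS = (
    SearchCondition("popularity", "baseline"),
    SearchCondition("popularity", "manipulated"),
    SearchCondition("health", "baseline"),
    SearchCondition("health", "manipulated"),
)


@dataclass(frozen=True)
class SearchResultEntry:
    recipe: Recipe
    position: int  # 1..8, 1 = top
    image_variant: str  # "original" | "upgraded" | "downgraded"


@dataclass(frozen=True)
class SearchResultList:
    """An ordered 8-item result list under one condition."""

    condition: SearchCondition
    query: str
    entries: tuple[SearchResultEntry, ...]

    def __post_init__(self):
        if len(self.entries) != LIST_LENGTH:
            raise InvalidInputError(f"a result list holds exactly {LIST_LENGTH} entries")
        positions = [e.position for e in self.entries]
        if positions != list(range(1, LIST_LENGTH + 1)):
            raise InvalidInputError("entry positions must be 1..8 in order")
        ids = [e.recipe.id for e in self.entries]
        if len(set(ids)) != LIST_LENGTH:
            raise InvalidInputError("each recipe may appear only once per list")


def filter_by_query(recipes: list[Recipe], keyword: str) -> list[Recipe]:
    """Recipes whose query type or name contains the keyword (case-insensitive substring)."""
    kw = keyword.lower()
    return [r for r in recipes if kw in r.query_type.lower() or kw in r.name.lower()]


def _require_annotations(recipes: list[Recipe]) -> None:
    missing = [r.id for r in recipes if r.fsa is None or r.health_class is None]
    if missing:
        raise InvalidInputError(
            f"recipes must be FSA-annotated before ranking (missing: {missing[:3]}...)"
        )


def rank_recipes(recipes: list[Recipe], mode: str) -> list[Recipe]:
    """Order recipes for presentation.

    ``popularity`` ranks by descending mean rating (ties broken by
    ascending FSA, then name); ``health`` ranks by ascending FSA score
    (ties broken by descending rating, then name).  The FSA score used
    is :attr:`Recipe.study_fsa` — the printed score when the table
    carries one, else the computed per-100 g score.
    """
    _require_annotations(recipes)
    if mode == "popularity":
        key = lambda r: (-r.mean_rating, r.study_fsa, r.name)
    elif mode == "health":
        key = lambda r: (r.study_fsa, -r.mean_rating, r.name)
    else:
        raise InvalidParameterError(f"mode must be 'popularity' or 'health', got {mode!r}")
    return sorted(recipes, key=key)


def assign_image_variant(
    recipe: Recipe, visual: str, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> str:
    """Image variant shown for one recipe under one visual condition.

    Baseline lists always show the original image.  Under the visual
    manipulation, healthy recipes with an unattractive image (z-score
    strictly below ``z_threshold``) get an upgraded image, healthy
    recipes already attractive keep the original, and every unhealthy
    recipe gets a downgraded image.
    """
    if visual not in ("baseline", "manipulated"):
        raise InvalidParameterError(f"visual must be 'baseline' or 'manipulated', got {visual!r}")
    if visual == "baseline":
        return "original"
    if recipe.health_class == "unhealthy":
        return "downgraded"
    if recipe.health_class == "healthy":
        if recipe.image_z is None:
            raise InvalidInputError(f"recipe {recipe.id} lacks an image_z score")
        return "upgraded" if recipe.image_z < z_threshold else "original"
    raise InvalidInputError(
        f"recipe {recipe.id} is classified {recipe.health_class!r}; "
        "only healthy/unhealthy recipes enter lists"
    )


def build_condition_list(
    recipes: list[Recipe],
    condition: SearchCondition,
    query: str = "",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> SearchResultList:
    """Build one result list: rank 8 recipes, then assign image variants.

    The input must hold exactly 4 healthy and 4 unhealthy recipes.  In
    the health-ranked conditions the four healthy recipes therefore
    occupy positions 1–4; combined with the visual manipulation, the
    top half of the list shows healthy recipes with non-downgraded
    images.
    """
    if len(recipes) != LIST_LENGTH:
        raise InvalidInputError(f"need exactly {LIST_LENGTH} recipes, got {len(recipes)}")
    _require_annotations(recipes)
    classes = [r.health_class for r in recipes]
    if classes.count("healthy") != 4 or classes.count("unhealthy") != 4:
        raise InvalidInputError(
            f"need 4 healthy + 4 unhealthy recipes, got "
            f"{classes.count('healthy')} healthy / {classes.count('unhealthy')} unhealthy"
        )
    ranked = rank_recipes(recipes, condition.ranking)
    entries = tuple(
        SearchResultEntry(
            recipe=r,
            position=i + 1,
            image_variant=assign_image_variant(r, condition.visual, z_threshold),
        )
        for i, r in enumerate(ranked)
    )
    return SearchResultList(condition=condition, query=query, entries=entries)


def make_design_sequences(
    queries: list[str],
    conditions: tuple[SearchCondition, ...] = CONDITIONS,
    n_users: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[list[tuple[str, SearchCondition]]]:
    """Per-user (query, condition) trial sequences via a seeded 4×4 Latin square.

    Each user draws one of the four rows of the cyclic Latin square
    uniformly at random: trial j pairs query j with condition
    (row + j) mod 4.  Every user thus sees each query and each
    condition exactly once, and over users every (query, condition)
    pair occurs with frequency 1/4.
    """
    if len(queries) != 4 or len(set(queries)) != 4:
        raise InvalidParameterError("exactly 4 distinct queries are required")
    if len(conditions) != 4 or len(set(conditions)) != 4:
        raise InvalidParameterError("exactly 4 distinct conditions are required")
    if n_users < 1:
        raise InvalidParameterError("n_users must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = rng.integers(0, 4, size=n_users)
    return [
        [(queries[j], conditions[(row + j) % 4]) for j in range(4)]
        for row in rows
    ]
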