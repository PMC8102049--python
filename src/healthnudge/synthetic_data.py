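"""Synthetic inputs for every pipeline stage.

The generators emulate the structure of the study's materials: a
recipe table with per-100 g nutrients, popularity ratings and image
attributes (4 query types × 4 healthy + 4 unhealthy recipes each),
procedural food-photo stand-ins with controllable feature values,
7-point attractiveness rating matrices produced by the linear
attractiveness model plus rater noise, and complete within-subject
choice studies (4 queries × 4 conditions, 8-item lists) whose choices
follow a conditional-logit rule.

Calibration anchors: popularity ratings are truncated-normal on [1, 5]
with distribution mean 4.4 stars; entropy of generated image features
is centred on 7.39 bits (SD 0.53); the image variants shown under the
visual manipulation shift predicted attractiveness by −0.95
(downgraded) and +1.06 (upgraded) on average, mirroring the magnitudes
of the study's manual image edits.

A single root seed derives fixed per-component substreams (recipes,
images, raters, choices), so each generator is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .attractiveness import AttractivenessModel, RatingMatrix
from .choice_analysis import ChoiceObservation, UtilityCoefficients, get_preset, simulate_choices
from .exceptions import GenerationError, InvalidParameterError
from .health_scoring import (
    BandThresholds,
    NutrientProfile,
    QUERY_TYPES,
    Recipe,
    annotate_recipes,
    classify_recipe,
    fsa_score,
)
from .image_features import extract_features, validate_image
from .list_builder import CONDITIONS, SearchResultList, build_condition_list, make_design_sequences

__all__ = [
    "SynthConfig",
    "gen_recipes",
    "gen_image",
    "gen_attractiveness_ratings",
    "gen_study",
    "recipes_from_frame",
    "study_covariates",
    "VARIANT_PREDICTION_SHIFT",
]

#: Fixed substream indices hung off the root seed.
_STREAMS = {"recipes": 0, "images": 1, "raters": 2, "choices": 3}

#: Mean predicted-attractiveness change of each image variant, in model
#: score units (anchored to the magnitudes of the study's image edits).
VARIANT_PREDICTION_SHIFT = {"original": 0.0, "downgraded": -0.95, "upgraded": 1.06}

#: Brightness delta applied by a variant; the colorfulness delta is then
#: solved so the model-predicted shift matches VARIANT_PREDICTION_SHIFT.
_VARIANT_BRIGHTNESS_DELTA = {"original": 0.0, "downgraded": -0.10, "upgraded": 0.10}

_MAX_DRAWS = 10_000


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SynthConfig:
    """Declared distributions for every generator.

    Nutrient amounts are log-normal (location/scale on the log scale)
    clipped to ranges resembling real per-100 g recipe values.
    Popularity ratings are truncated normal on [1, 5] with the stated
    *distribution* mean and SD.  Rater noise is Gaussian on the 7-point
    scale before rounding.
    """

    seed: int = 0
    n_recipes: int = 32
    n_users: int = 239
    n_raters: int = 5
    nutrient_lognormal: dict = field(
        default_factory=lambda: {
            "fat": (2.0, 0.9),
            "saturated_fat": (0.4, 0.9),
            "sugar": (0.8, 0.9),
            "salt": (-0.8, 0.7),
        }
    )
    nutrient_clip: dict = field(
        default_factory=lambda: {
            "fat": (0.05, 45.0),
            "saturated_fat": (0.05, 8.0),
            "sugar": (0.05, 12.0),
            "salt": (0.01, 2.0),
        }
    )
    rating_mean: float = 4.4
    rating_sd: float = 0.5
    rater_noise_sd: float = 0.5
    preset: str = "simplified"

    def __post_init__(self):
        for name, v in (("n_recipes", self.n_recipes), ("n_users", self.n_users), ("n_raters", self.n_raters)):
            if v < 1:
                raise InvalidParameterError(f"{name} must be >= 1, got {v}")
        for nutrient, (_, scale) in self.nutrient_lognormal.items():
            if scale <= 0:
                raise InvalidParameterError(f"log-normal scale for {nutrient} must be > 0")
        if self.rating_sd <= 0 or self.rater_noise_sd < 0:
            raise InvalidParameterError("rating_sd must be > 0 and rater_noise_sd >= 0")


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a truncated normal whose *truncated* mean equals the target."""

    def truncated_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    return float(optimize.brentq(lambda m: truncated_mean(m) - target_mean, lo, hi + 3 * sd))


def _draw_rating(rng: np.random.Generator, loc: float, sd: float, size: int) -> np.ndarray:
    a, b = (1.0 - loc) / sd, (5.0 - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def gen_recipes(cfg: SynthConfig | None = None, model: AttractivenessModel | None = None) -> pd.DataFrame:
    """Generate a recipe table supporting the 4 healthy + 4 unhealthy per-query design.

    Query types cycle over burger/salad/pasta/curry with
    ``n_recipes // 4`` recipes each, half required healthy and half
    unhealthy under the default FSA thresholds (rejection sampling,
    capped at 10,000 draws per query).  Columns follow the package's
    CSV contract plus five image-feature columns; ``image_z`` is the
    standardized predicted attractiveness across the table.

    Raises
    ------
    GenerationError
        If the configured nutrient distributions cannot produce the
        required class composition within the draw budget.
    """
    cfg = cfg or SynthConfig()
    model = model or AttractivenessModel()
    rng = _rng(cfg.seed, "recipes")
    thresholds = BandThresholds()
    per_query = max(2, cfg.n_recipes // len(QUERY_TYPES))
    n_healthy = per_query // 2
    n_unhealthy = per_query - n_healthy
    rating_loc = _truncnorm_loc(cfg.rating_mean, cfg.rating_sd, 1.0, 5.0)

    rows = []
    for query in QUERY_TYPES:
        healthy: list[NutrientProfile] = []
        unhealthy: list[NutrientProfile] = []
        for _ in range(_MAX_DRAWS):
            vals = {}
            for nutrient, (mu, sigma) in cfg.nutrient_lognormal.items():
                lo, hi = cfg.nutrient_clip[nutrient]
                # round to the 2-decimal output precision *before* scoring, so
                # the emitted table reproduces the class composition exactly
                vals[nutrient] = round(float(np.clip(rng.lognormal(mu, sigma), lo, hi)), 2)
            if vals["saturated_fat"] > vals["fat"]:
                vals["saturated_fat"] = vals["fat"]
            profile = NutrientProfile(**vals)
            score = fsa_score(profile, thresholds)
            probe = Recipe(
                id="probe", name="probe", query_type=query, nutrients=profile, mean_rating=3.0
            )
            cls = classify_recipe(probe, score)
            if cls == "healthy" and len(healthy) < n_healthy:
                healthy.append(profile)
            elif cls == "unhealthy" and len(unhealthy) < n_unhealthy:
                unhealthy.append(profile)
            if len(healthy) == n_healthy and len(unhealthy) == n_unhealthy:
                break
        else:
            raise GenerationError(
                f"could not draw {n_healthy} healthy + {n_unhealthy} unhealthy "
                f"{query} recipes within {_MAX_DRAWS} draws; widen the nutrient distributions"
            )
        for k, profile in enumerate(healthy + unhealthy):
            rid = f"{query}-{k + 1:02d}"
            rows.append(
                {
                    "id": rid,
                    "name": f"Synthetic {query} {k + 1}",
                    "query_type": query,
                    "fat": profile.fat,
                    "sat_fat": profile.saturated_fat,
                    "sugar": profile.sugar,
                    "salt": profile.salt,
                }
            )

    df = pd.DataFrame(rows)
    n = len(df)
    df["mean_rating"] = np.round(_draw_rating(rng, rating_loc, cfg.rating_sd, n), 2)
    df["image_ref"] = ""
    df["brightness"] = np.round(rng.uniform(0.3, 0.8, n), 4)
    df["colorfulness"] = np.round(rng.uniform(0.1, 0.5, n), 4)
    df["entropy"] = np.round(np.clip(rng.normal(7.39, 0.53, n), 2.84, 7.94), 4)
    df["sharpness"] = np.round(rng.uniform(0.02, 0.3, n), 4)
    df["saturation"] = np.round(rng.uniform(0.2, 0.7, n), 4)
    pred = model.predict_many(
        df[["brightness", "colorfulness", "entropy", "sharpness", "saturation"]].to_numpy()
    )
    df["image_z"] = np.round((pred - pred.mean()) / pred.std(ddof=1), 4)
    df["fsa_printed"] = pd.array([None] * n, dtype="Int64")
    return df


def gen_image(
    target: dict | None = None, size: tuple[int, int] = (64, 64), seed: int = 0
) -> np.ndarray:
    """Procedural RGB image whose brightness and saturation hit requested targets.

    A smooth hue field with seeded noise is generated in HSV; the
    saturation channel is pinned to the target and the value channel is
    iteratively rescaled until the extracted mean luma is within ±0.05
    of the brightness target.  Other features are whatever the
    construction yields.

    ``target`` may hold ``brightness`` and/or ``saturation`` (defaults
    0.5 and 0.4).  A brightness of 0 forces an all-black image and is
    only feasible with saturation 0.

    Raises
    ------
    GenerationError
        For infeasible combinations (e.g. brightness 0 with positive
        saturation, or saturated colors too dark/bright to reach the
        requested luma).
    """
    target = dict(target or {})
    b_target = float(target.get("brightness", 0.5))
    s_target = float(target.get("saturation", 0.4))
    if not (0 <= b_target <= 1 and 0 <= s_target <= 1):
        raise GenerationError("feature targets must lie in [0, 1]")
    h, w = size
    if h < 8 or w < 8:
        raise GenerationError("image size must be at least 8x8")
    if b_target == 0:
        if s_target > 0:
            raise GenerationError("brightness 0 forces a black image, which has saturation 0")
        return np.zeros((h, w, 3), dtype=np.uint8)

    rng = _rng(seed, "images")
    yy, xx = np.mgrid[0:h, 0:w]
    phase = rng.uniform(0, 2 * np.pi, 4)
    hue = 0.5 + 0.25 * np.sin(2 * np.pi * xx / w + phase[0]) * np.cos(
        2 * np.pi * yy / h + phase[1]
    )
    hue = (hue + 0.05 * rng.standard_normal((h, w))) % 1.0
    val = np.clip(
        b_target
        + 0.15 * np.sin(4 * np.pi * xx / w + phase[2]) * np.sin(4 * np.pi * yy / h + phase[3])
        + 0.05 * rng.standard_normal((h, w)),
        0.02,
        1.0,
    )

    from skimage import color as _skcolor

    sat = np.full((h, w), s_target)
    scale = 1.0
    img = None
    for _ in range(40):
        hsv = np.stack([hue, sat, np.clip(val * scale, 0.0, 1.0)], axis=-1)
        img = np.clip(np.rint(_skcolor.hsv2rgb(hsv) * 255), 0, 255).astype(np.uint8)
        got = extract_features(img, resize=False).brightness
        if abs(got - b_target) <= 0.04:
            break
        if got <= 0 or scale > 50 or scale < 1e-3:
            raise GenerationError(
                f"cannot reach brightness {b_target} with saturation {s_target}"
            )
        scale *= b_target / max(got, 1e-6)
    else:
        raise GenerationError(
            f"brightness target {b_target} unreachable with saturation {s_target}"
        )
    return validate_image(img)


def gen_attractiveness_ratings(
    features: np.ndarray,
    model: AttractivenessModel | None = None,
    cfg: SynthConfig | None = None,
) -> RatingMatrix:
    """Simulate a panel of raters judging images on the 7-point scale.

    Latent scores are the model predictions for the item × 5 feature
    matrix, affinely mapped so the batch spans [1, 7]; each rater adds
    independent Gaussian noise (``cfg.rater_noise_sd``), and ratings
    are rounded half-up and clamped to {1..7}.

    Raises
    ------
    GenerationError
        With a single item (the affine span map is undefined).
    """
    cfg = cfg or SynthConfig()
    model = model or AttractivenessModel()
    if cfg.n_raters < 2:
        raise InvalidParameterError("need at least 2 raters")
    X = np.asarray(features, dtype=float)
    latent = model.predict_many(X)
    if latent.size < 2 or np.ptp(latent) == 0:
        raise GenerationError("need >= 2 items with distinct predictions to span the 1..7 scale")
    latent = 1.0 + 6.0 * (latent - latent.min()) / np.ptp(latent)

    rng = _rng(cfg.seed, "raters")
    noisy = latent[None, :] + rng.normal(0.0, cfg.rater_noise_sd, (cfg.n_raters, latent.size))
    # round half-up (np.floor(x + .5)), then clamp to the scale
    ratings = np.clip(np.floor(noisy + 0.5), 1, 7).astype(int)
    return RatingMatrix(ratings=ratings)


def recipes_from_frame(df: pd.DataFrame) -> list[Recipe]:
    """Convert a recipe table (the CSV contract) into annotated Recipe records."""
    recipes = []
    for _, row in df.iterrows():
        fsa_printed = row.get("fsa_printed")
        if pd.isna(fsa_printed):
            fsa_printed = None
        image_z = row.get("image_z")
        recipes.append(
            Recipe(
                id=str(row["id"]),
                name=str(row["name"]),
                query_type=str(row["query_type"]),
                nutrients=NutrientProfile(
                    fat=float(row["fat"]),
                    saturated_fat=float(row["sat_fat"]),
                    sugar=float(row["sugar"]),
                    salt=float(row["salt"]),
                ),
                mean_rating=float(row["mean_rating"]),
                image_ref=str(row.get("image_ref") or "") or None,
                image_z=None if pd.isna(image_z) else float(image_z),
                fsa_printed=None if fsa_printed is None else int(fsa_printed),
            )
        )
    return annotate_recipes(recipes)


_FEATURE_COLS = ["brightness", "colorfulness", "entropy", "sharpness", "saturation"]


def ensure_image_features(
    df: pd.DataFrame, seed: int = 0, model: AttractivenessModel | None = None
) -> pd.DataFrame:
    """Return a copy of a recipe table with image-feature columns present.

    Tables without per-recipe image features (e.g. the bundled study
    table, whose original photographs are not distributed) get
    plausible features drawn from the generator's distributions,
    seeded for reproducibility.  Existing feature columns are kept.
    """
    if all(c in df.columns for c in _FEATURE_COLS):
        return df
    model = model or AttractivenessModel()
    rng = _rng(seed, "images")
    out = df.copy()
    n = len(out)
    out["brightness"] = np.round(rng.uniform(0.3, 0.8, n), 4)
    out["colorfulness"] = np.round(rng.uniform(0.1, 0.5, n), 4)
    out["entropy"] = np.round(np.clip(rng.normal(7.39, 0.53, n), 2.84, 7.94), 4)
    out["sharpness"] = np.round(rng.uniform(0.02, 0.3, n), 4)
    out["saturation"] = np.round(rng.uniform(0.2, 0.7, n), 4)
    return out


def _variant_features(row: pd.Series, variant: str, model: AttractivenessModel) -> pd.Series:
    """Image features of the shown variant, shifted so the predicted
    attractiveness moves by the calibrated variant amount."""
    feats = row[_FEATURE_COLS].astype(float).copy()
    shift = VARIANT_PREDICTION_SHIFT[variant]
    if shift == 0.0:
        return feats
    db = _VARIANT_BRIGHTNESS_DELTA[variant]
    dc = (shift - model.beta_brightness * db) / model.beta_colorfulness
    feats["brightness"] = float(np.clip(feats["brightness"] + db, 0, 1))
    feats["colorfulness"] = float(np.clip(feats["colorfulness"] + dc, 0, 1))
    return feats


def study_covariates(
    slist: SearchResultList,
    recipe_frame: pd.DataFrame,
    model: AttractivenessModel | None = None,
) -> pd.DataFrame:
    """Per-position covariate table for one built result list.

    Columns cover both utility presets — position, popularity, fsa,
    attractiveness, the four nutrients and the five image features of
    the *shown* image variant.  ``attractiveness`` is the model
    prediction on the variant's features.
    """
    model = model or AttractivenessModel()
    frame = recipe_frame.set_index("id")
    rows = []
    for entry in slist.entries:
        r = entry.recipe
        src = frame.loc[r.id]
        feats = _variant_features(src, entry.image_variant, model)
        rows.append(
            {
                "position": float(entry.position),
                "popularity": r.mean_rating,
                "fsa": float(r.study_fsa),
                "fat": r.nutrients.fat,
                "sat_fat": r.nutrients.saturated_fat,
                "salt": r.nutrients.salt,
                "sugar": r.nutrients.sugar,
                **{k: float(v) for k, v in feats.items()},
                "attractiveness": model.predict(feats.to_numpy()),
                "recipe_id": r.id,
                "variant": entry.image_variant,
            }
        )
    return pd.DataFrame(rows)


def gen_study(
    recipes: pd.DataFrame,
    preset: str | UtilityCoefficients = "simplified",
    n_users: int = 239,
    seed: int = 0,
    model: AttractivenessModel | None = None,
) -> list[ChoiceObservation]:
    """Simulate a complete within-subject choice study.

    Each user receives a Latin-square sequence of 4 (query, condition)
    trials; per trial the 8-item list for that cell is built, its
    covariates assembled (with variant-shifted image features under the
    visual manipulation) and one choice drawn from the
    conditional-logit rule under ``preset``.
    """
    coeffs = get_preset(preset) if isinstance(preset, str) else preset
    model = model or AttractivenessModel()
    recipes = ensure_image_features(recipes, seed=seed, model=model)
    recipe_objs = recipes_from_frame(recipes)

    # the 16 distinct (query, condition) lists are fixed by the design
    covariate_cache: dict[tuple[str, str], pd.DataFrame] = {}
    for query in QUERY_TYPES:
        subset = [r for r in recipe_objs if r.query_type == query]
        for condition in CONDITIONS:
            slist = build_condition_list(subset, condition, query=query)
            covariate_cache[(query, condition.label)] = study_covariates(
                slist, recipes, model
            )

    rng = _rng(seed, "choices")
    sequences = make_design_sequences(list(QUERY_TYPES), CONDITIONS, n_users, rng)
    trials = [
        ChoiceObservation(
            user_id=uid,
            trial=t + 1,
            condition=condition,
            query=query,
            covariates=covariate_cache[(query, condition.label)],
        )
        for uid, seq in enumerate(sequences)
        for t, (query, condition) in enumerate(seq)
    ]
    return simulate_choices(trials, coeffs, rng)
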