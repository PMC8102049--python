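# Methods

This note documents the models implemented by `healthnudge`, the
design decisions taken where the underlying study leaves details open,
the synthetic-data distributions, and known limitations.

## Image features

The five descriptors are deliberately simple, parameter-free and
resolution-stable:

| feature      | definition                                                          | range  |
|--------------|---------------------------------------------------------------------|--------|
| brightness   | mean BT.601 luma (0.299 R + 0.587 G + 0.114 B) / 255                | [0, 1] |
| colorfulness | Hasler–Süsstrunk: √(σ²_rg+σ²_yb) + 0.3·√(μ²_rg+μ²_yb), / 255, clamped | [0, 1] |
| entropy      | Shannon entropy (base 2) of the 256-bin grayscale histogram          | [0, 8] |
| sharpness    | mean \|4-neighbour Laplacian\| of luma over interior pixels, / (4·255) | [0, 1] |
| saturation   | mean HSV S channel                                                   | [0, 1] |

Choices worth noting:

- **Grayscale conversion** uses ITU-R BT.601 weights everywhere, for
  internal consistency between brightness, entropy and sharpness.
- **Entropy binning** rounds luma half-up in exact integer arithmetic
  (per-mille weights 299/587/114). Floating-point luma frequently
  lands exactly on .5 boundaries (e.g. gray pixels), where the binning
  would otherwise depend on summation order; integer arithmetic makes
  the histogram bit-reproducible and lets an independent per-pixel
  oracle match it exactly.
- **Resolution stability**: images are downscaled to a maximum side of
  512 px with area (box) interpolation before extraction, so features
  do not drift with source resolution. Switchable via `resize=False`.
- Alpha channels are dropped with a logged warning; images below
  8×8 px are rejected.

### Parametric transform and the attractiveness-delta search

`apply_feature_shift` scales the HSV value channel, the HSV saturation
channel and the opponent chroma amplitude (RGB minus luma) by three
gains; (1, 1, 1) is the identity on pixels, verified exactly in tests.
`tune_attractiveness_delta` searches gain triples on a 15-point grid
per axis over [0.4, 1.8] — bounds chosen so transformed photographs
stay plausibly food-like — visiting candidates in order of increasing
L2 distance from the identity (lexicographic on ties), so the least
invasive transform meeting the requested predicted-attractiveness
change is returned, deterministically. If no triple reaches the
target, the error carries the best achieved delta and its gains.

## Attractiveness model and interrater agreement

The model is affine in the five features; the bundled default
coefficients are (brightness 3.22, colorfulness 8.35, entropy 0.80,
sharpness 1.42, saturation −4.08, intercept −6.53), a robust fit on
standardized human 7-point ratings of 475 recipe photographs.
"Robust regression" is implemented as Huber M-estimation with tuning
constant 1.345 (the standard choice); plain OLS is available via
`method="ols"`. Refitting requires ≥ 7 items (6 parameters) and a
full-rank design.

Rating standardization z-scores per-item mean ratings across items
with the sample SD (n−1); the SD convention is switchable. Interrater
agreement weights a pair's per-item difference as 1 − |Δ|/6 (1 for an
exact match down to 0 at the maximal 6-step difference) and averages
over items, reported as a percentage. The panel summary reports the
mean and the **population** (divide-by-n) SD over the ten rater pairs;
the population convention is what reproduces the published panel
summary (mean ≈ 83.0%, SD 1.46) from its pairwise values.

The model predicts on the standardized-rating scale. Published
per-image attractiveness means on a 1–7 scale are related to this
scale by an affine map that the source material does not pin down; the
module therefore returns model-scale scores and leaves any 1–7
rescaling to the caller (the synthetic rating generator performs its
own explicit span mapping, see below).

## FSA scoring and classification

Banding uses the UK FSA front-of-pack per-100 g criteria (fat
3.0/17.5, saturates 1.5/5.0, sugars 5.0/22.5, salt 0.3/1.5 g).
Boundaries are inclusive on the green and amber sides (≤ low → green,
≤ high → amber), matching the FSA "up to and including" convention —
and required to reproduce curated rows sitting exactly at cutoffs.
A per-portion red override (amount per portion above 21/6/27/1.8 g
forces red) is implemented but inactive unless a portion size is
passed, because portion sizes are not available in the bundled data.

Classification: healthy at score ≤ 6 (≤ 7 for burgers), unhealthy at
≥ 9, excluded in between. When a curated table prints an FSA score,
that printed score drives classification and health ranking
(`Recipe.study_fsa`): 13 of the bundled table's 16 unhealthy rows
print 1–3 points above the per-100 g computation, consistent with
per-portion adjustments that cannot be derived from the shipped
columns. The computed score is always reported alongside, and
`score_table` surfaces every disagreement in a mismatch report rather
than silently preferring either number.

## List construction

Ranking is deterministic: popularity mode sorts by descending mean
rating, ties by ascending FSA then name; health mode by ascending FSA,
ties by descending rating then name. The tie-break chains are a design
choice for reproducibility — the original platform's internal ordering
is unknowable. Under the visual manipulation, healthy recipes with an
image-attractiveness z-score below 0.99 (configurable) get an upgraded
image, already-attractive healthy recipes keep their original, and
every unhealthy recipe is downgraded. Lists must contain exactly
4 healthy + 4 unhealthy recipes; in health-ranked lists the healthy
half therefore occupies positions 1–4.

Per-user trial sequences come from a seeded cyclic 4×4 Latin square:
each user draws one of four rows uniformly, pairing query j with
condition (row + j) mod 4 — every user sees each query and each
condition exactly once, and over users each (query, condition) pair
occurs with frequency 1/4.

## Choice model and estimation

The conditional logit is maximized by Newton iterations with the
analytic gradient and Hessian, with step-halving, from a zero start;
convergence requires gradient ∞-norm < 1e-8 (softmax utilities are
computed with max-subtraction). Degenerate inputs are diagnosed
explicitly: covariates constant within every list (not identified,
they cancel from the likelihood), divergence of ‖β‖, and complete
separation, detected as the log-likelihood numerically reaching its
supremum of zero (every choice predicted perfectly).

Standard errors: classical inverse observed information, or the
cluster-robust sandwich with per-user score sums and the G/(G−1)
small-sample factor. Pseudo R² is McFadden's, 1 − ℓ/ℓ₀ against the
uniform 1/8 null. The implementation is cross-checked in the test
suite against `statsmodels`' `ConditionalLogit` on simulated data;
statsmodels is never on the computation path.

The chosen-FSA linear models use least squares with two fixed term
lists: the *general* spec (position, popularity, five image features)
and the *condition-specific* spec adding the two condition mains, a
position × ranking interaction and one feature × visual interaction
per image feature. Partial η² per term is SS_term/(SS_term + SS_res)
with type-III (drop-one) sums of squares, the convention of the major
commercial statistics packages. Rank-deficient designs raise an error
naming the collinear terms.

The 2×2 repeated-measures ANOVA decomposes within-subject variation;
each effect is tested against its own effect × subject interaction
mean square, with partial η² = SS_effect/(SS_effect + SS_error(effect)).
Effect or error sums of squares that are zero up to float cancellation
(≤ 1e-12 relative to the total SS) are treated as exact zeros so flat
grids yield F = 0 rather than a 0/0 artifact. The decomposition is
verified to 1e-9 against an independent brute-force oracle and against
`pingouin.rm_anova`.

TOST equivalence runs two one-sided t-tests of the paired mean
difference against ±margin, declaring equivalence when both p < .05.
No margin is inherent to the design; the pipeline defaults to 0.3 ×
the SD of the paired differences, a conventional
smallest-effect-of-interest, and the margin is configurable.

## Synthetic data

The generators emulate the structure of the study's materials; a
single root seed derives fixed substreams (recipes / images / raters /
choices) so each component is independently reproducible.

- **Recipes**: nutrients are log-normal per nutrient — location/scale
  (2.0, 0.9) for fat, (0.4, 0.9) saturated fat, (0.8, 0.9) sugar,
  (−0.8, 0.7) salt, clipped to realistic per-100 g ranges — calibrated
  by eye to the bundled table's ranges; values are rounded to the
  2-decimal output precision *before* scoring so the emitted table
  reproduces its class composition exactly. Each query type is
  rejection-sampled to 4 healthy + 4 unhealthy recipes (10,000-draw
  budget). Popularity ratings are truncated-normal on [1, 5] with
  *distribution* mean 4.4 stars (the location parameter is solved
  numerically so the truncated mean, not the latent location, hits the
  anchor) and SD 0.5. Image features are drawn uniformly from
  plausible ranges, except entropy ~ N(7.39, 0.53) clipped to
  [2.84, 7.94]; the attractiveness z-score is the standardized model
  prediction across the table.
- **Images**: a smooth seeded hue field in HSV with the saturation
  channel pinned to the target and the value channel iteratively
  rescaled until extracted brightness is within ±0.05 of target.
  Infeasible targets (brightness 0 with positive saturation) raise.
- **Ratings**: latent scores are model predictions affinely mapped to
  span [1, 7]; each rater adds Gaussian noise (default SD 0.5),
  rounded half-up and clamped to {1..7}.
- **Studies**: per user a Latin-square (query, condition) sequence;
  the 16 distinct lists are built once and cached. Under the visual
  manipulation, shown-image features are shifted so the predicted
  attractiveness moves by −0.95 (downgraded) / +1.06 (upgraded) —
  anchored to the published mean shifts of the manual image edits —
  implemented as a brightness delta of ∓0.10 with the colorfulness
  delta solved from the model coefficients. Tables lacking image
  features (such as the bundled one, whose photographs are not
  distributed) get seeded plausible features imputed.

What the generators do *not* emulate: real covariate correlations
(e.g. popularity–healthiness confounding beyond what the bundled
table induces), heterogeneous user preferences (one coefficient
vector for all users), order/fatigue effects across trials, and any
relation between a recipe's name and its nutrients. Passing tests
therefore demonstrate that the estimators recover known generating
processes and that the design machinery is internally consistent —
not that the bundled coefficient presets would be recovered from new
human data.

## Problem sizes used in the checks

Parameter recovery runs at 500 simulated users (2,000 choice sets);
the directional replication of both nudging effects at 2,000 users;
null-model coverage at 100 replicates of 100 users; ANOVA power checks
at 200 replicates of 239 users; Monte-Carlo softmax consistency at
80,000 draws. These sizes give the statistical checks comfortable
resolution while keeping the default suite fast.

## Known limitations

- The five feature definitions are standard but self-consistent
  choices; they are not bit-compatible with the unavailable extraction
  code behind the original dataset (whose entropy floor of 2.84 we can
  anchor to but not verify).
- The printed-vs-computed FSA disagreement on unhealthy curated rows
  is surfaced, not resolved; the per-portion sizes that would resolve
  it are not published.
- The conditional logit assumes IIA and homogeneous preferences; no
  mixed-logit or Bayesian variants are provided.
- The TOST margin and the attractiveness 1–7 rescaling are caller
  choices, as discussed above.
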