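# healthnudge

Health-aware presentation of recipe search results: can re-ranking a
result list on healthiness, and matching the visual attractiveness of
food photographs to it, nudge people toward healthier choices without
making them less satisfied?

`healthnudge` implements the full computational machinery of such a
food-search nudging experiment as a tested Python library: low-level
image-feature extraction feeding a linear visual-attractiveness model,
UK FSA traffic-light health scoring of recipes, construction of 8-item
search-result lists under a 2×2 within-subject design
(popularity/health ranking × baseline/manipulated images), and
simulation plus estimation of user choice behaviour. A synthetic-data
module generates every input the pipeline needs — recipe tables,
images with controllable features, rater matrices, and complete
within-subject choice studies — so all stages run and are testable
without any downloads. It is aimed at researchers in food information
retrieval, recommender systems and health-behaviour informatics who
want a reproducible reference implementation of these analyses.

## The models

**FSA traffic-light score.** Each of four nutrients (fat, saturated
fat, sugar, salt; grams per 100 g) is banded against the UK Food
Standards Agency front-of-pack criteria — fat 3.0/17.5, saturates
1.5/5.0, sugars 5.0/22.5, salt 0.3/1.5 g — scoring 1 (green, ≤ low),
2 (amber) or 3 (red, > high). The FSA score is the sum of the four
bands: 4 (healthiest) to 12. Curry, salad and pasta recipes count as
*healthy* at a score ≤ 6 and *unhealthy* at ≥ 9; burgers, unhealthier
as a class, are healthy at ≤ 7.

**Visual attractiveness.** A linear model over five image features,

    score = −6.53 + 3.22·brightness + 8.35·colorfulness + 0.80·entropy
            + 1.42·sharpness − 4.08·saturation

with brightness (mean BT.601 luma), colorfulness (Hasler–Süsstrunk
opponent-channel statistic), sharpness (mean |4-neighbour Laplacian|)
and saturation (mean HSV S) in [0, 1] and entropy (grayscale histogram
Shannon entropy) in [0, 8] bits. The default coefficients are the
pre-trained fit on standardized human 7-point ratings of 475 recipe
photographs; the model can be refit from rating matrices by robust
(Huber) regression. Weighted interrater agreement of such panels is
scored 1 − |Δ|/6 per item.

**Choice behaviour.** Choices from an 8-item list follow a conditional
logit: P(choose i) = exp(βᵀxᵢ) / Σⱼ exp(βᵀxⱼ) over item covariates
(list position, popularity rating, FSA score, attractiveness — or the
underlying nutrients and image features). The same model serves as the
generative rule for simulated users and as the estimator (Newton
maximum likelihood, user-clustered sandwich standard errors, McFadden
pseudo R²). Aggregate analyses: linear regressions of the chosen
recipe's FSA score with type-III partial η², a 2×2 repeated-measures
ANOVA on per-condition means, and TOST equivalence tests.

## Worked example

```python
from healthnudge.cli_io import load_table3
from healthnudge.health_scoring import NutrientProfile, fsa_score
from healthnudge.synthetic_data import gen_study
from healthnudge.choice_analysis import (
    SIMPLIFIED_PRESET, fit_conditional_logit, condition_cell_means, rm_anova_2x2,
)

# score one recipe ("Backyard black bean burgers"): three greens + amber salt
profile = NutrientProfile(fat=1.29, saturated_fat=0.22, sugar=2.05, salt=1.27)
print("FSA score:", fsa_score(profile))

# simulate a 500-user within-subject study on the bundled 32-recipe table,
# then recover the generating utility coefficients
table = load_table3()
obs = gen_study(table, preset="simplified", n_users=500, seed=1)
fit = fit_conditional_logit(obs, SIMPLIFIED_PRESET.names, cluster="user")
print(fit.summary().round(3))

# 2x2 repeated-measures ANOVA on the chosen recipes' FSA scores
anova = rm_anova_2x2(condition_cell_means(obs))
print(anova.summary().round(3))
```

prints

```
FSA score: 5
                 beta     se       z    p
position       -0.110  0.015  -7.203  0.0
popularity     -0.118  0.028  -4.245  0.0
fsa             0.164  0.015  10.709  0.0
attractiveness  0.234  0.021  11.360  0.0
                 SS   df      MS       F      p  partial_eta2
ranking      63.368  1.0  63.368  17.970  0.000         0.035
visual       72.962  1.0  72.962  19.428  0.000         0.037
interaction   1.058  1.0   1.058   0.279  0.598         0.001
```

The fitted utilities sit within two clustered standard errors of the
generating preset (position −0.083, popularity −0.072, FSA 0.17,
attractiveness 0.22): users favour top-of-list positions and
attractive images, so health ranking and the visual manipulation both
lower the mean chosen FSA score — the ANOVA shows both main effects
clearly with no interaction, i.e. the two nudges act additively.

A command-line interface mirrors the library
(`healthnudge features|attractiveness|fsa|build-list|synth|simulate|fit-model|anova|tost|run`);
`healthnudge run --seed 0 --out run/` executes the whole pipeline and
writes a JSON report.

## Documentation

`docs/methods.md` describes the models, the synthetic-data
distributions and their calibration anchors, numerical choices and
known limitations.
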