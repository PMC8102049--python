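"""Discrete-choice simulation and the study's three analysis layers.

Choices from an 8-item result list are modelled with a conditional
logit: the probability of picking item i is the softmax of linear
utilities U_i = beta . x_i over the item covariates, so covariates
constant across a list cancel out.  The same model serves as the
generative rule for simulated users and as the estimator (Newton
maximum likelihood with optional user-clustered sandwich standard
errors and McFadden pseudo R²).

On top of the choice model sit the aggregate analyses of the 2×2
within-subject design: linear regressions of the chosen recipe's FSA
score on list/image features (with type-III partial η² effect sizes),
a 2×2 repeated-measures ANOVA on per-condition means, and TOST
equivalence tests for null main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    EstimationError,
    InvalidInputError,
    InvalidParameterError,
)
from .list_builder import CONDITIONS, SearchCondition

__all__ = [
    "UtilityCoefficients",
    "SIMPLIFIED_PRESET",
    "FULL_PRESET",
    "get_preset",
    "ChoiceObservation",
    "choice_probabilities",
    "simulate_choices",
    "ClogitResult",
    "fit_conditional_logit",
    "ChosenFsaResult",
    "fit_chosen_fsa_model",
    "AnovaResult",
    "rm_anova_2x2",
    "TostResult",
    "tost_equivalence",
]

N_ALTERNATIVES = 8


@dataclass(frozen=True)
class UtilityCoefficients:
    """Named linear-utility coefficients over item covariates."""

    values: dict

    def __post_init__(self):
        vals = {str(k): float(v) for k, v in self.values.items()}
        if not vals:
            raise InvalidInputError("at least one coefficient is required")
        if not all(np.isfinite(v) for v in vals.values()):
            raise InvalidInputError("coefficients must be finite")
        object.__setattr__(self, "values", MappingProxyType(vals))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values.keys())

    def as_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([self.values[n] for n in names])

    def __getitem__(self, name: str) -> float:
        return self.values[name]


#: Parsimonious utility preset: position in list (1 = top), popularity rating,
#: the FSA score and the predicted visual attractiveness of the shown image.
SIMPLIFIED_PRESET = UtilityCoefficients(
    {"position": -0.083, "popularity": -0.072, "fsa": 0.17, "attractiveness": 0.22}
)

#: Full utility preset: health and visual appeal broken into their underlying
#: nutrient and image-feature components.
FULL_PRESET = UtilityCoefficients(
    {
        "position": -0.098,
        "popularity": -0.12,
        "fat": -0.069,
        "sat_fat": 0.34,
        "salt": 0.22,
        "sugar": 0.049,
        "brightness": 2.11,
        "colorfulness": -0.65,
        "entropy": 0.57,
        "sharpness": -0.79,
        "saturation": 0.094,
    }
)

_PRESETS = {"simplified": SIMPLIFIED_PRESET, "full": FULL_PRESET}


def get_preset(name: str) -> UtilityCoefficients:
    """Look up a bundled coefficient preset ('simplified' or 'full')."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass
class ChoiceObservation:
    """One user-trial record: the 8 alternatives' covariates and the chosen index."""

    user_id: int
    trial: int
    condition: SearchCondition
    query: str
    covariates: pd.DataFrame  # 8 rows, one per list position (top first)
    chosen: int | None = None  # 1-based list position

    def __post_init__(self):
        if len(self.covariates) != N_ALTERNATIVES:
            raise InvalidInputError(
                f"covariates must have {N_ALTERNATIVES} rows, got {len(self.covariates)}"
            )
        if self.chosen is not None and not (1 <= self.chosen <= N_ALTERNATIVES):
            raise InvalidInputError(f"chosen must lie in 1..{N_ALTERNATIVES}")


def _covariate_matrix(covariates, names: tuple[str, ...]) -> np.ndarray:
    """Extract the 8 × k matrix for the named covariates."""
    if isinstance(covariates, pd.DataFrame):
        missing = [n for n in names if n not in covariates.columns]
        if missing:
            raise InvalidInputError(f"covariates lack columns for coefficients: {missing}")
        X = covariates[list(names)].to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(names):
            raise InvalidInputError(
                f"expected an {N_ALTERNATIVES} x {len(names)} array, got shape {X.shape}"
            )
    if X.shape[0] != N_ALTERNATIVES:
        raise InvalidInputError(f"expected {N_ALTERNATIVES} alternatives, got {X.shape[0]}")
    return X


def choice_probabilities(covariates, coefficients: UtilityCoefficients) -> np.ndarray:
    """Softmax choice probabilities over the 8 list positions.

    Utilities are U_i = beta . x_i; the softmax is computed with
    max-subtraction for overflow safety and sums to 1.  ``covariates``
    may be a DataFrame holding (at least) one column per coefficient
    name, or an 8 × k array in coefficient order.
    """
    X = _covariate_matrix(covariates, coefficients.names)
    u = X @ coefficients.as_array()
    u -= u.max()
    e = np.exp(u)
    return e / e.sum()


def simulate_choices(
    trials: list[ChoiceObservation],
    coefficients: UtilityCoefficients,
    seed: int | np.random.Generator = 0,
) -> list[ChoiceObservation]:
    """Draw one categorical choice per trial from the conditional-logit rule.

    Returns new observations with ``chosen`` filled in (1-based);
    the inputs are not mutated.  Reproducible under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # trials frequently share covariate tables (the design has 16 distinct
    # lists), so probability vectors are cached per table object
    cache: dict[int, np.ndarray] = {}
    probs = np.empty((len(trials), N_ALTERNATIVES))
    for i, tr in enumerate(trials):
        key = id(tr.covariates)
        if key not in cache:
            cache[key] = choice_probabilities(tr.covariates, coefficients)
        probs[i] = cache[key]
    # inverse-CDF draws, one uniform per trial
    u = rng.random(len(trials))
    chosen_all = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = []
    for tr, ch in zip(trials, chosen_all):
        chosen = int(ch) + 1
        out.append(
            ChoiceObservation(
                user_id=tr.user_id,
                trial=tr.trial,
                condition=tr.condition,
                query=tr.query,
                covariates=tr.covariates,
                chosen=chosen,
            )
        )
    return out


@dataclass
class ClogitResult:
    """Conditional-logit fit: estimates, standard errors, fit statistics."""

    coefficients: UtilityCoefficients
    se: dict
    vcov: np.ndarray
    loglik: float
    loglik_null: float
    pseudo_r2: float
    n_obs: int
    n_clusters: int | None
    converged: bool
    n_iter: int

    def summary(self) -> pd.DataFrame:
        names = self.coefficients.names
        beta = self.coefficients.as_array()
        se = np.array([self.se[n] for n in names])
        z = beta / se
        return pd.DataFrame(
            {"beta": beta, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))},
            index=list(names),
        )


def _clogit_arrays(
    observations: list[ChoiceObservation], names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([_covariate_matrix(o.covariates, names) for o in observations])
    y = np.array([o.chosen - 1 for o in observations])
    users = np.array([o.user_id for o in observations])
    return X, y, users


def _clogit_ll_grad_hess(beta, X, y):
    u = X @ beta  # n x 8
    u = u - u.max(axis=1, keepdims=True)
    e = np.exp(u)
    denom = e.sum(axis=1)
    p = e / denom[:, None]
    n = X.shape[0]
    x_chosen = X[np.arange(n), y]  # n x k
    xbar = np.einsum("ni,nik->nk", p, X)  # n x k
    ll = float((u[np.arange(n), y] - np.log(denom)).sum())
    scores = x_chosen - xbar  # per-observation score contributions
    grad = scores.sum(axis=0)
    # Hessian of the log-likelihood (negative definite)
    wxx = np.einsum("ni,nik,nil->kl", p, X, X)
    hess = -(wxx - xbar.T @ xbar)
    return ll, grad, hess, scores


def fit_conditional_logit(
    observations: list[ChoiceObservation],
    covariate_names: tuple[str, ...] | list[str],
    cluster: str = "user",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> ClogitResult:
    """Maximum-likelihood conditional logit over 8-alternative choice sets.

    Newton iterations with the analytic gradient and Hessian; converged
    when the gradient infinity-norm falls below ``tol``.  With
    ``cluster='user'`` the covariance is the sandwich estimator with
    per-user score sums and the small-sample factor G/(G−1);
    ``cluster='none'`` reports classical inverse-information standard
    errors.  McFadden pseudo R² is computed against the uniform
    (all-zero-coefficient) null.

    Raises
    ------
    EstimationError
        If fewer than 30 observations are given, a covariate is
        constant within every list (not identified), or the iteration
        diverges / fails to converge (complete separation shows up as
        divergence).
    """
    if cluster not in ("none", "user"):
        raise InvalidParameterError(f"cluster must be 'none' or 'user', got {cluster!r}")
    names = tuple(covariate_names)
    if len(observations) < 30:
        raise EstimationError(
            f"need at least 30 observations, got {len(observations)}",
            diagnostics={"n_obs": len(observations)},
        )
    if any(o.chosen is None for o in observations):
        raise InvalidInputError("all observations must carry a chosen index")
    X, y, users = _clogit_arrays(observations, names)

    # identification: a covariate constant within every list drops out of the model
    within = X - X.mean(axis=1, keepdims=True)
    dead = [names[k] for k in range(len(names)) if np.abs(within[..., k]).max() < 1e-12]
    if dead:
        raise EstimationError(
            f"covariates constant within every list are not identified: {dead}",
            diagnostics={"constant_covariates": dead},
        )

    beta = np.zeros(len(names))
    ll, grad, hess, scores = _clogit_ll_grad_hess(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise EstimationError(
                "singular Hessian during Newton iteration",
                diagnostics={"iteration": it, "beta": beta.tolist()},
            ) from None
        # step halving: Newton direction is -H^{-1} g
        t = 1.0
        for _ in range(50):
            cand = beta - t * step
            ll_new, g_new, h_new, s_new = _clogit_ll_grad_hess(cand, X, y)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll, grad, hess, scores = cand, ll_new, g_new, h_new, s_new
        if np.linalg.norm(beta) > 1e4:
            raise EstimationError(
                "estimates diverging; likely complete or quasi-complete separation",
                diagnostics={"beta": beta.tolist(), "loglik": ll},
            )
    else:
        it = max_iter
    if not converged and np.abs(grad).max() >= tol:
        raise EstimationError(
            f"Newton iteration did not converge in {max_iter} steps "
            f"(gradient inf-norm {np.abs(grad).max():.2e})",
            diagnostics={"grad_norm": float(np.abs(grad).max()), "beta": beta.tolist()},
        )
    # complete separation: the likelihood attains (numerically) its supremum of
    # 0 only when every chosen alternative is predicted with probability ~1
    if ll > -1e-6 * X.shape[0]:
        raise EstimationError(
            "complete separation: the fitted model predicts every choice "
            "perfectly; coefficients are not identified",
            diagnostics={"loglik": ll, "beta": beta.tolist()},
        )

    info = -hess  # observed information
    bread = np.linalg.inv(info)
    if cluster == "user":
        groups = pd.Series(range(len(users))).groupby(users).groups
        G = len(groups)
        meat = np.zeros_like(info)
        for idx in groups.values():
            s = scores[np.asarray(idx)].sum(axis=0)
            meat += np.outer(s, s)
        vcov = bread @ meat @ bread * (G / (G - 1))
        n_clusters = G
    else:
        vcov = bread
        n_clusters = None

    n = X.shape[0]
    ll0 = -n * np.log(N_ALTERNATIVES)
    se = dict(zip(names, np.sqrt(np.diag(vcov))))
    return ClogitResult(
        coefficients=UtilityCoefficients(dict(zip(names, beta))),
        se=se,
        vcov=vcov,
        loglik=ll,
        loglik_null=ll0,
        pseudo_r2=1.0 - ll / ll0,
        n_obs=n,
        n_clusters=n_clusters,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# chosen-FSA linear models

#: Image-feature covariates of the chosen recipe used by both model specs.
_IMAGE_TERMS = ("brightness", "colorfulness", "entropy", "sharpness", "saturation")
_BASE_TERMS = ("position", "popularity") + _IMAGE_TERMS


@dataclass
class ChosenFsaResult:
    coefficients: dict
    se: dict
    r2: float
    partial_eta2: dict
    n_obs: int

    def summary(self) -> pd.DataFrame:
        idx = list(self.coefficients)
        return pd.DataFrame(
            {
                "beta": [self.coefficients[t] for t in idx],
                "se": [self.se[t] for t in idx],
                "partial_eta2": [self.partial_eta2.get(t, np.nan) for t in idx],
            },
            index=idx,
        )


def observations_frame(observations: list[ChoiceObservation]) -> pd.DataFrame:
    """One row per observation with the chosen alternative's covariates.

    Adds ``ranking`` and ``visual`` indicators (1 = health ranking,
    1 = manipulated visuals) and the chosen position.
    """
    rows = []
    for o in observations:
        if o.chosen is None:
            raise InvalidInputError("observation lacks a chosen index")
        row = o.covariates.iloc[o.chosen - 1].to_dict()
        row["position"] = float(o.chosen)
        row["ranking"] = 1.0 if o.condition.ranking == "health" else 0.0
        row["visual"] = 1.0 if o.condition.visual == "manipulated" else 0.0
        row["user_id"] = o.user_id
        rows.append(row)
    return pd.DataFrame(rows)


def fit_chosen_fsa_model(
    observations: list[ChoiceObservation], spec: str = "general"
) -> ChosenFsaResult:
    """Linear regression of the chosen recipe's FSA score on list and image features.

    The ``general`` spec pools all conditions: position, popularity and
    the five image features.  The ``condition_specific`` spec adds the
    two condition main effects (health re-ranking, visual
    manipulation), a position × ranking interaction and one
    feature × visual interaction per image feature.

    Partial η² per term is SS_term / (SS_term + SS_residual) with
    type-III (drop-one) sums of squares.

    Raises
    ------
    EstimationError
        On a rank-deficient design, naming the collinear terms.
    """
    if spec not in ("general", "condition_specific"):
        raise InvalidParameterError(f"spec must be 'general' or 'condition_specific', got {spec!r}")
    df = observations_frame(observations)
    if "fsa" not in df.columns:
        raise InvalidInputError("covariates must include the chosen recipe's 'fsa' score")

    terms: dict[str, np.ndarray] = {t: df[t].to_numpy(float) for t in _BASE_TERMS}
    if spec == "condition_specific":
        terms["ranking"] = df["ranking"].to_numpy(float)
        terms["visual"] = df["visual"].to_numpy(float)
        terms["position:ranking"] = terms["position"] * terms["ranking"]
        for f in _IMAGE_TERMS:
            terms[f"{f}:visual"] = terms[f] * terms["visual"]

    y = df["fsa"].to_numpy(float)
    n = len(y)
    names = list(terms)
    Xfull = np.column_stack([np.ones(n)] + [terms[t] for t in names])

    rank = np.linalg.matrix_rank(Xfull)
    if rank < Xfull.shape[1]:
        # identify offending terms by incremental rank growth
        collinear = []
        cols = [np.ones(n)]
        for t in names:
            cand = np.column_stack(cols + [terms[t]])
            if np.linalg.matrix_rank(cand) == len(cols):
                collinear.append(t)
            else:
                cols.append(terms[t])
        raise EstimationError(
            f"rank-deficient design; collinear terms: {collinear}",
            diagnostics={"collinear_terms": collinear},
        )

    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    dof = n - Xfull.shape[1]
    sigma2 = ss_res / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(Xfull.T @ Xfull)
    se_all = np.sqrt(sigma2 * np.diag(XtX_inv))

    partial_eta2 = {}
    for j, t in enumerate(names):
        keep = [0] + [1 + i for i in range(len(names)) if i != j]
        Xr = Xfull[:, keep]
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        ss_res_r = float(((y - Xr @ br) ** 2).sum())
        ss_term = max(ss_res_r - ss_res, 0.0)
        partial_eta2[t] = ss_term / (ss_term + ss_res) if (ss_term + ss_res) > 0 else 0.0

    coef = {"intercept": float(beta[0]), **{t: float(b) for t, b in zip(names, beta[1:])}}
    se = {"intercept": float(se_all[0]), **{t: float(s) for t, s in zip(names, se_all[1:])}}
    return ChosenFsaResult(coefficients=coef, se=se, r2=r2, partial_eta2=partial_eta2, n_obs=n)


# ---------------------------------------------------------------------------
# 2 x 2 repeated-measures ANOVA


@dataclass
class AnovaEffect:
    ss: float
    df: int
    ms: float
    error_ss: float
    error_df: int
    error_ms: float
    f: float
    p: float
    partial_eta2: float


@dataclass
class AnovaResult:
    """Within-subject 2×2 decomposition: one entry per effect."""

    effects: dict  # keys: "ranking", "visual", "interaction"
    n_subjects: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                k: {
                    "SS": e.ss,
                    "df": e.df,
                    "MS": e.ms,
                    "F": e.f,
                    "p": e.p,
                    "partial_eta2": e.partial_eta2,
                }
                for k, e in self.effects.items()
            }
        ).T


def rm_anova_2x2(cell_means: np.ndarray) -> AnovaResult:
    """2×2 repeated-measures ANOVA on a complete user × condition grid.

    ``cell_means`` is an n × 4 array with one value per user per
    condition, columns ordered as the canonical condition order
    (ranking varying slowest): (popularity, baseline),
    (popularity, manipulated), (health, baseline),
    (health, manipulated).

    Each within-subject effect is tested against its own
    effect × subject interaction mean square; partial η² is
    SS_effect / (SS_effect + SS_error(effect)).

    Raises
    ------
    InvalidInputError
        On missing cells (NaNs) or a grid that is not n × 4 with n >= 2.
    """
    x = np.asarray(cell_means, dtype=float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise InvalidInputError(f"expected an n x 4 grid, got shape {x.shape}")
    if np.isnan(x).any():
        raise InvalidInputError("missing cells are not allowed (no imputation)")
    n = x.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 subjects")

    g = x.reshape(n, 2, 2)  # [subject, ranking, visual]
    gm = g.mean()
    m_subj = g.mean(axis=(1, 2))
    m_a = g.mean(axis=(0, 2))  # ranking marginals
    m_b = g.mean(axis=(0, 1))  # visual marginals
    m_ab = g.mean(axis=0)
    m_ia = g.mean(axis=2)  # subject x ranking
    m_ib = g.mean(axis=1)  # subject x visual

    ss_a = 2 * n * ((m_a - gm) ** 2).sum()
    ss_b = 2 * n * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_axs = 2 * ((m_ia - m_subj[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bxs = 2 * ((m_ib - m_subj[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_subj = 4 * ((m_subj - gm) ** 2).sum()
    ss_total = ((g - gm) ** 2).sum()
    ss_abxs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_axs - ss_bxs

    # effect and error SS that are zero up to float cancellation noise
    tiny = 1e-12 * max(1.0, float(ss_total))

    def effect(ss, err_ss):
        df, err_df = 1, n - 1
        ms, err_ms = ss / df, err_ss / err_df
        if ss <= tiny:
            f, p = 0.0, 1.0
        elif err_ss <= tiny:
            f, p = float("inf"), 0.0
        else:
            f = ms / err_ms
            p = float(stats.f.sf(f, df, err_df))
        pe = ss / (ss + err_ss) if (ss + err_ss) > tiny else 0.0
        return AnovaEffect(
            ss=float(ss), df=df, ms=float(ms), error_ss=float(err_ss), error_df=err_df,
            error_ms=float(err_ms), f=float(f), p=p, partial_eta2=float(pe),
        )

    return AnovaResult(
        effects={
            "ranking": effect(ss_a, ss_axs),
            "visual": effect(ss_b, ss_bxs),
            "interaction": effect(ss_ab, ss_abxs),
        },
        n_subjects=n,
    )


def condition_cell_means(observations: list[ChoiceObservation], value: str = "fsa") -> np.ndarray:
    """Per-user per-condition grid of a chosen-recipe quantity, in canonical condition order.

    With one trial per condition per user (the study design) the cell
    holds that trial's value directly.
    """
    df = observations_frame(observations)
    labels = [c.label for c in CONDITIONS]
    df["condition"] = [
        CONDITIONS[2 * int(r) + int(v)].label
        for r, v in zip(df["ranking"], df["visual"])
    ]
    pivot = df.pivot_table(index="user_id", columns="condition", values=value, aggfunc="mean")
    missing = [c for c in labels if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        raise InvalidInputError(f"incomplete design: missing condition cells {missing}")
    return pivot[labels].to_numpy()


# ---------------------------------------------------------------------------
# TOST equivalence


@dataclass
class TostResult:
    p_lower: float
    p_upper: float
    equivalent: bool
    mean: float
    se: float
    df: int
    margin: float


def tost_equivalence(
    differences: np.ndarray, margin: float, alpha: float = 0.05
) -> TostResult:
    """Two one-sided t-tests of a paired mean difference against ±margin.

    Declares equivalence when the mean difference is significantly
    above −margin *and* significantly below +margin (both one-sided
    p < alpha).

    Raises
    ------
    InvalidInputError / DegenerateInputError
        With fewer than 3 differences, a non-positive margin, or zero
        variance.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise InvalidInputError("need a 1-D vector of at least 3 paired differences")
    if not np.isfinite(margin) or margin <= 0:
        raise InvalidParameterError(f"margin must be > 0, got {margin!r}")
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("differences have zero variance")
    se = sd / np.sqrt(n)
    df = n - 1
    mean = float(d.mean())
    t_lower = (mean + margin) / se  # H0: mean <= -margin
    t_upper = (mean - margin) / se  # H0: mean >= +margin
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    return TostResult(
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=bool(p_lower < alpha and p_upper < alpha),
        mean=mean,
        se=float(se),
        df=df,
        margin=float(margin),
    )
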