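"""Conditional logit, chosen-FSA regressions, RM-ANOVA and TOST."""

import numpy as np
import pandas as pd
import pytest

from healthnudge.choice_analysis import (
    ChoiceObservation,
    SIMPLIFIED_PRESET,
    UtilityCoefficients,
    choice_probabilities,
    condition_cell_means,
    fit_chosen_fsa_model,
    fit_conditional_logit,
    get_preset,
    rm_anova_2x2,
    simulate_choices,
    tost_equivalence,
)
from healthnudge.exceptions import (
    DegenerateInputError,
    EstimationError,
    InvalidInputError,
    InvalidParameterError,
)
from healthnudge.list_builder import CONDITIONS


def make_obs(cov, chosen=None, user=0, trial=1, cond=CONDITIONS[0]):
    return ChoiceObservation(
        user_id=user, trial=trial, condition=cond, query="q", covariates=cov, chosen=chosen
    )


class TestChoiceProbabilities:
    def test_identical_alternatives_uniform(self):
        cov = pd.DataFrame({"position": [3.0] * 8})
        p = choice_probabilities(cov, UtilityCoefficients({"position": 1.0}))
        assert np.allclose(p, 0.125)

    def test_negative_position_coefficient_prefers_top(self):
        cov = pd.DataFrame({"position": np.arange(1.0, 9.0)})
        p = choice_probabilities(cov, UtilityCoefficients({"position": -0.083}))
        assert np.all(np.diff(p) < 0)

    def test_matches_direct_softmax(self, rng):
        coeffs = SIMPLIFIED_PRESET
        X = rng.normal(size=(8, 4))
        p = choice_probabilities(X, coeffs)
        # independent direct evaluation
        u = X @ np.array([coeffs[n] for n in coeffs.names])
        direct = np.exp(u) / np.exp(u).sum()
        assert np.allclose(p, direct, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_constant_utility_shift(self, rng):
        X = rng.normal(size=(8, 1))
        c = UtilityCoefficients({"x": 0.7})
        assert np.allclose(
            choice_probabilities(X, c), choice_probabilities(X + 10.0, c), atol=1e-12
        )

    def test_missing_covariate_column_rejected(self):
        cov = pd.DataFrame({"position": np.arange(1.0, 9.0)})
        with pytest.raises(InvalidInputError):
            choice_probabilities(cov, UtilityCoefficients({"fsa": 1.0}))

    def test_overflow_safe(self):
        X = np.array([[1e4]] * 7 + [[1e4 + 1]])
        p = choice_probabilities(X, UtilityCoefficients({"x": 100.0}))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestSimulateChoices:
    def test_zero_coefficients_give_uniform_frequencies(self):
        cov = pd.DataFrame({"position": np.arange(1.0, 9.0)})
        trials = [make_obs(cov, user=i) for i in range(80_000)]
        out = simulate_choices(trials, UtilityCoefficients({"position": 0.0}), seed=4)
        freq = np.bincount([o.chosen - 1 for o in out], minlength=8) / len(out)
        assert np.abs(freq - 0.125).max() <= 0.005

    def test_deterministic_under_seed(self):
        cov = pd.DataFrame({"position": np.arange(1.0, 9.0)})
        trials = [make_obs(cov, user=i) for i in range(100)]
        a = simulate_choices(trials, SIMPLIFIED_PRESET_POSITION_ONLY, seed=9)
        b = simulate_choices(trials, SIMPLIFIED_PRESET_POSITION_ONLY, seed=9)
        assert [o.chosen for o in a] == [o.chosen for o in b]

    def test_extreme_coefficient_degenerate(self):
        cov = pd.DataFrame({"flag": [0.0, 0, 0, 1, 0, 0, 0, 0]})
        trials = [make_obs(cov, user=i) for i in range(200)]
        out = simulate_choices(trials, UtilityCoefficients({"flag": 100.0}), seed=0)
        assert all(o.chosen == 4 for o in out)


SIMPLIFIED_PRESET_POSITION_ONLY = UtilityCoefficients({"position": -0.083})


def _simulate_dataset(coeffs, n_users, seed, n_trials=4):
    """Choice sets with freshly drawn covariates per list."""
    rng = np.random.default_rng(seed)
    trials = []
    for u in range(n_users):
        for t in range(n_trials):
            cov = pd.DataFrame(
                {
                    name: rng.normal(0, 1, 8) if name != "position" else np.arange(1.0, 9.0)
                    for name in coeffs.names
                }
            )
            trials.append(make_obs(cov, user=u, trial=t + 1))
    return simulate_choices(trials, coeffs, rng)


class TestConditionalLogit:
    def test_recovery_against_statsmodels_oracle(self):
        """Estimates agree with statsmodels' ConditionalLogit on the same data."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        coeffs = UtilityCoefficients({"position": -0.1, "x": 0.5})
        obs = _simulate_dataset(coeffs, n_users=150, seed=21)
        res = fit_conditional_logit(obs, coeffs.names, cluster="none")

        rows, y, groups = [], [], []
        for i, o in enumerate(obs):
            rows.append(o.covariates[list(coeffs.names)].to_numpy())
            flags = np.zeros(8)
            flags[o.chosen - 1] = 1
            y.append(flags)
            groups += [i] * 8
        sm_fit = ConditionalLogit(
            np.concatenate(y), np.vstack(rows), groups=np.array(groups)
        ).fit(disp=0)
        # statsmodels stops at a looser gradient tolerance than our Newton
        assert np.allclose(
            res.coefficients.as_array(), np.asarray(sm_fit.params), atol=1e-3
        )
        assert res.loglik == pytest.approx(float(sm_fit.llf), abs=1e-4)

    def test_zero_coefficient_coverage(self):
        """Under a null model, each estimate stays within 2 SE in >= 90% of replicates."""
        coeffs = UtilityCoefficients({"a": 0.0, "b": 0.0})
        hits = np.zeros(2)
        n_rep = 100
        for rep in range(n_rep):
            obs = _simulate_dataset(coeffs, n_users=100, seed=1000 + rep)
            res = fit_conditional_logit(obs, coeffs.names, cluster="user")
            beta = res.coefficients.as_array()
            se = np.array([res.se[n] for n in coeffs.names])
            hits += (np.abs(beta) < 2 * se).astype(int)
        assert np.all(hits >= 0.9 * n_rep)

    def test_likelihood_invariant_to_list_level_shifts(self):
        """Adding a per-list constant to a covariate leaves the fit unchanged."""
        coeffs = UtilityCoefficients({"position": -0.1, "x": 0.4})
        obs = _simulate_dataset(coeffs, n_users=80, seed=5)
        shifted = []
        rng = np.random.default_rng(0)
        for o in obs:
            cov = o.covariates.copy()
            cov["x"] = cov["x"] + rng.normal(0, 5)  # same shift for all 8 rows
            shifted.append(make_obs(cov, chosen=o.chosen, user=o.user_id, trial=o.trial))
        a = fit_conditional_logit(obs, coeffs.names, cluster="none")
        b = fit_conditional_logit(shifted, coeffs.names, cluster="none")
        assert np.allclose(a.coefficients.as_array(), b.coefficients.as_array(), atol=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)

    def test_constant_within_list_covariate_rejected(self):
        cov = pd.DataFrame({"c": np.ones(8), "position": np.arange(1.0, 9.0)})
        obs = [make_obs(cov, chosen=1, user=i) for i in range(50)]
        with pytest.raises(EstimationError, match="not identified"):
            fit_conditional_logit(obs, ("c", "position"))

    def test_too_few_observations_rejected(self):
        cov = pd.DataFrame({"position": np.arange(1.0, 9.0)})
        obs = [make_obs(cov, chosen=1, user=i) for i in range(10)]
        with pytest.raises(EstimationError):
            fit_conditional_logit(obs, ("position",))

    def test_complete_separation_detected(self):
        rng = np.random.default_rng(2)
        obs = []
        for i in range(60):
            cov = pd.DataFrame({"x": rng.normal(size=8)})
            chosen = int(np.argmax(cov["x"].to_numpy())) + 1  # deterministic choice
            obs.append(make_obs(cov, chosen=chosen, user=i))
        with pytest.raises(EstimationError):
            fit_conditional_logit(obs, ("x",))

    def test_preset_lookup(self):
        assert get_preset("simplified")["fsa"] == 0.17
        assert get_preset("full")["brightness"] == 2.11
        with pytest.raises(InvalidParameterError):
            get_preset("bogus")


class TestChosenFsaModel:
    def _study_obs(self, n_users, seed):
        from healthnudge.cli_io import load_table3
        from healthnudge.synthetic_data import gen_study

        return gen_study(load_table3(), "simplified", n_users=n_users, seed=seed)

    def test_general_spec_term_list(self):
        res = fit_chosen_fsa_model(self._study_obs(60, 0), spec="general")
        expected = {
            "intercept", "position", "popularity",
            "brightness", "colorfulness", "entropy", "sharpness", "saturation",
        }
        assert set(res.coefficients) == expected

    def test_condition_specific_interaction_set(self):
        res = fit_chosen_fsa_model(self._study_obs(60, 0), spec="condition_specific")
        interactions = {t for t in res.coefficients if ":" in t}
        assert interactions == {
            "position:ranking", "brightness:visual", "colorfulness:visual",
            "entropy:visual", "sharpness:visual", "saturation:visual",
        }
        assert {"ranking", "visual"} <= set(res.coefficients)

    def test_known_linear_effects_recovered(self):
        """Coefficients recovered within 3 SE on data with a known linear rule."""
        rng = np.random.default_rng(7)
        n = 600
        truth = {"position": 0.3, "popularity": -0.5}
        rows = []
        for u in range(n):
            pos = float(rng.integers(1, 9))
            pop = rng.uniform(3, 5)
            feats = rng.uniform(0, 1, 5)
            fsa = 7 + truth["position"] * pos + truth["popularity"] * pop + rng.normal(0, 1)
            cov = pd.DataFrame(
                {
                    "position": [pos] * 8,
                    "popularity": [pop] * 8,
                    "fsa": [fsa] * 8,
                    "brightness": [feats[0]] * 8,
                    "colorfulness": [feats[1]] * 8,
                    "entropy": [feats[2]] * 8,
                    "sharpness": [feats[3]] * 8,
                    "saturation": [feats[4]] * 8,
                }
            )
            rows.append(make_obs(cov, chosen=int(pos), user=u))
        res = fit_chosen_fsa_model(rows, spec="general")
        for term, b in truth.items():
            assert abs(res.coefficients[term] - b) < 3 * res.se[term]

    def test_constant_outcome_gives_zero_slopes(self):
        rng = np.random.default_rng(3)
        obs = []
        for u in range(50):
            cov = pd.DataFrame(
                {
                    "position": np.arange(1.0, 9.0),
                    "popularity": rng.uniform(3, 5, 8),
                    "fsa": [6.0] * 8,
                    "brightness": rng.uniform(0, 1, 8),
                    "colorfulness": rng.uniform(0, 1, 8),
                    "entropy": rng.uniform(3, 8, 8),
                    "sharpness": rng.uniform(0, 1, 8),
                    "saturation": rng.uniform(0, 1, 8),
                }
            )
            obs.append(make_obs(cov, chosen=int(rng.integers(1, 9)), user=u))
        res = fit_chosen_fsa_model(obs, spec="general")
        assert res.r2 == 0.0
        slopes = [v for k, v in res.coefficients.items() if k != "intercept"]
        assert np.allclose(slopes, 0.0, atol=1e-8)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(4)
        obs = []
        for u in range(40):
            bright = rng.uniform(0, 1, 8)
            cov = pd.DataFrame(
                {
                    "position": np.arange(1.0, 9.0),
                    "popularity": rng.uniform(3, 5, 8),
                    "fsa": rng.uniform(4, 12, 8),
                    "brightness": bright,
                    "colorfulness": 2 * bright,  # exact collinearity
                    "entropy": rng.uniform(3, 8, 8),
                    "sharpness": rng.uniform(0, 1, 8),
                    "saturation": rng.uniform(0, 1, 8),
                }
            )
            obs.append(make_obs(cov, chosen=int(rng.integers(1, 9)), user=u))
        with pytest.raises(EstimationError, match="colorfulness"):
            fit_chosen_fsa_model(obs, spec="general")


def brute_force_rm_anova(x):
    """Independent SS computation from first principles (explicit loops)."""
    n = x.shape[0]
    cells = [(r, v) for r in range(2) for v in range(2)]
    val = {(i, r, v): x[i, 2 * r + v] for i in range(n) for r, v in cells}
    gm = sum(val.values()) / (4 * n)
    m_i = {i: sum(val[(i, r, v)] for r, v in cells) / 4 for i in range(n)}
    m_r = {r: sum(val[(i, r, v)] for i in range(n) for v in range(2)) / (2 * n) for r in range(2)}
    m_v = {v: sum(val[(i, r, v)] for i in range(n) for r in range(2)) / (2 * n) for v in range(2)}
    m_rv = {(r, v): sum(val[(i, r, v)] for i in range(n)) / n for r, v in cells}
    m_ir = {(i, r): (val[(i, r, 0)] + val[(i, r, 1)]) / 2 for i in range(n) for r in range(2)}
    m_iv = {(i, v): (val[(i, 0, v)] + val[(i, 1, v)]) / 2 for i in range(n) for v in range(2)}

    ss_r = 2 * n * sum((m_r[r] - gm) ** 2 for r in range(2))
    ss_v = 2 * n * sum((m_v[v] - gm) ** 2 for v in range(2))
    ss_rv = n * sum((m_rv[(r, v)] - m_r[r] - m_v[v] + gm) ** 2 for r, v in cells)
    ss_rxs = 2 * sum(
        (m_ir[(i, r)] - m_i[i] - m_r[r] + gm) ** 2 for i in range(n) for r in range(2)
    )
    ss_vxs = 2 * sum(
        (m_iv[(i, v)] - m_i[i] - m_v[v] + gm) ** 2 for i in range(n) for v in range(2)
    )
    ss_rvxs = sum(
        (
            val[(i, r, v)]
            - m_ir[(i, r)]
            - m_iv[(i, v)]
            - m_rv[(r, v)]
            + m_i[i]
            + m_r[r]
            + m_v[v]
            - gm
        )
        ** 2
        for i in range(n)
        for r, v in cells
    )
    f_r = (ss_r / 1) / (ss_rxs / (n - 1))
    f_v = (ss_v / 1) / (ss_vxs / (n - 1))
    f_rv = (ss_rv / 1) / (ss_rvxs / (n - 1))
    return (ss_r, ss_v, ss_rv), (f_r, f_v, f_rv)


class TestRmAnova:
    def test_flat_grid_gives_zero_f(self, rng):
        subj = rng.normal(0, 1, 20)
        grid = np.tile(subj[:, None], (1, 4))  # condition-independent
        res = rm_anova_2x2(grid)
        for e in res.effects.values():
            assert e.f == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            grid = rng.normal(0, 1, (12, 4))
            res = rm_anova_2x2(grid)
            (ss_r, ss_v, ss_rv), (f_r, f_v, f_rv) = brute_force_rm_anova(grid)
            assert res.effects["ranking"].ss == pytest.approx(ss_r, abs=1e-9)
            assert res.effects["visual"].ss == pytest.approx(ss_v, abs=1e-9)
            assert res.effects["interaction"].ss == pytest.approx(ss_rv, abs=1e-9)
            assert res.effects["ranking"].f == pytest.approx(f_r, abs=1e-9)
            assert res.effects["visual"].f == pytest.approx(f_v, abs=1e-9)
            assert res.effects["interaction"].f == pytest.approx(f_rv, abs=1e-9)

    def test_matches_pingouin(self, rng):
        """Cross-check F statistics against pingouin's two-way RM-ANOVA."""
        import pingouin as pg

        grid = rng.normal(0, 1, (15, 4))
        res = rm_anova_2x2(grid)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 4),
                "ranking": np.tile([0, 0, 1, 1], 15),
                "visual": np.tile([0, 1, 0, 1], 15),
                "y": grid.ravel(),
            }
        )
        table = pg.rm_anova(
            data=long, dv="y", within=["ranking", "visual"], subject="subject", detailed=True
        )
        by_src = {row["Source"]: row["F"] for _, row in table.iterrows()}
        assert res.effects["ranking"].f == pytest.approx(by_src["ranking"], rel=1e-6)
        assert res.effects["visual"].f == pytest.approx(by_src["visual"], rel=1e-6)
        assert res.effects["interaction"].f == pytest.approx(
            by_src["ranking * visual"], rel=1e-6
        )

    def test_main_effect_power(self):
        """A -0.4 shift on one factor is detected in >= 80% of replicates at n=239."""
        rng = np.random.default_rng(77)
        n, sigma, shift = 239, 1.5, -0.4
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            subj = rng.normal(0, 1, (n, 1))
            grid = subj + rng.normal(0, sigma, (n, 4))
            grid[:, 2:] += shift  # ranking main effect
            res = rm_anova_2x2(grid)
            hits += int(res.effects["ranking"].p < 0.05)
        assert hits >= 0.8 * n_rep

    def test_missing_cells_rejected(self):
        grid = np.ones((5, 4))
        grid[0, 1] = np.nan
        with pytest.raises(InvalidInputError):
            rm_anova_2x2(grid)

    def test_cell_means_require_complete_design(self):
        cov = pd.DataFrame(
            {"fsa": np.arange(4.0, 12.0), "position": np.arange(1.0, 9.0)}
        )
        obs = [make_obs(cov, chosen=1, user=0, cond=CONDITIONS[0])]
        with pytest.raises(InvalidInputError):
            condition_cell_means(obs)


class TestTost:
    def test_tight_null_is_equivalent(self, rng):
        d = rng.normal(0, 1.0, 239)
        d = d - d.mean()  # exact zero mean
        res = tost_equivalence(d, margin=0.3 * d.std(ddof=1))
        assert res.p_lower < 0.001 and res.p_upper < 0.001
        assert res.equivalent

    def test_negation_swaps_pvalues(self, rng):
        d = rng.normal(0.05, 1.0, 100)
        a = tost_equivalence(d, margin=0.5)
        b = tost_equivalence(-d, margin=0.5)
        assert a.p_lower == pytest.approx(b.p_upper)
        assert a.p_upper == pytest.approx(b.p_lower)
        assert a.equivalent == b.equivalent

    def test_vanishing_margin_never_equivalent(self, rng):
        d = rng.normal(0, 1.0, 100)
        assert not tost_equivalence(d, margin=1e-9).equivalent

    def test_large_true_effect_not_equivalent(self, rng):
        d = rng.normal(2.0, 0.5, 50)
        assert not tost_equivalence(d, margin=0.5).equivalent

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            tost_equivalence(np.zeros(10), margin=0.5)
        with pytest.raises(InvalidInputError):
            tost_equivalence(np.array([1.0, 2.0]), margin=0.5)
        with pytest.raises(InvalidParameterError):
            tost_equivalence(np.array([1.0, 2.0, 3.0]), margin=0.0)
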