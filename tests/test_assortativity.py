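import itertools
import math

import numpy as np
import pandas as pd
import pytest

from assocpat.assortativity import (
    FULL_MODEL,
    TERM_AGE,
    TERM_INFANT,
    TERM_KINSHIP,
    TERM_RANK,
    TERM_SEX,
    TERM_SEX_AGE,
    TERM_SEX_RANK,
    aicc,
    akaike_weights,
    build_dyad_rows,
    confidence_set,
    daily_standardized_ranks,
    dyad_flip_inference,
    elo_ratings,
    enumerate_submodels,
    fit_model,
    influence_check,
    multimodel_inference,
    predictor_weights,
    r2_mixed,
    standardized_ordinal_rank,
    vif,
    yearly_rank,
)
from assocpat.scan_data import Individual, SeasonRoster
from assocpat.synthetic import simulate_dyad_rows


class TestElo:
    def test_equal_ratings_split_k(self):
        sup = pd.DataFrame({"date": ["2014-10-01"], "winner": ["A"], "loser": ["B"]})
        state = elo_ratings(sup, k_factor=16.0, initial=1000.0)
        assert state.ratings["A"] == pytest.approx(1008.0)
        assert state.ratings["B"] == pytest.approx(992.0)

    def test_certain_winner_gains_nothing_in_the_limit(self):
        sup = pd.DataFrame(
            {"date": ["2014-10-01"] * 30, "winner": ["A"] * 30, "loser": ["B"] * 30}
        )
        state = elo_ratings(sup, k_factor=16.0)
        gains = np.diff(state.history["winner_rating"].to_numpy(), prepend=1000.0)
        # updates shrink monotonically toward zero as the outcome becomes certain
        assert (np.diff(gains) < 0).all()
        assert gains[-1] < gains[0] * 0.5

    def test_total_rating_conserved(self):
        rng = np.random.default_rng(0)
        ids = list("ABCDE")
        rows = []
        for d in range(40):
            w, l = rng.choice(ids, 2, replace=False)
            rows.append((f"2014-10-{d % 28 + 1:02d}", w, l))
        sup = pd.DataFrame(rows, columns=["date", "winner", "loser"])
        state = elo_ratings(sup)
        assert sum(state.ratings.values()) == pytest.approx(1000.0 * len(state.ratings))

    def test_unknown_individual_errors(self):
        sup = pd.DataFrame({"date": ["2014-10-01"], "winner": ["A"], "loser": ["Z"]})
        with pytest.raises(KeyError):
            elo_ratings(sup, individuals=["A", "B"])


class TestStandardizedRanks:
    def test_three_individuals(self):
        ranks = standardized_ordinal_rank({"a": 1100.0, "b": 1000.0, "c": 900.0})
        assert ranks == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_ties_share_mean_position(self):
        ranks = standardized_ordinal_rank({"a": 1000.0, "b": 1000.0, "c": 900.0})
        assert ranks["a"] == ranks["b"] == pytest.approx(0.75)

    def test_single_individual_convention(self):
        assert standardized_ordinal_rank({"a": 1234.0}) == {"a": 1.0}

    def test_yearly_rank_mean_and_order_invariance(self):
        daily = pd.DataFrame(
            {"date": ["d1", "d2"], "id": ["a", "a"], "rank": [1.0, 0.5]}
        )
        assert yearly_rank(daily)["a"] == pytest.approx(0.75)
        flipped = daily.iloc[::-1].reset_index(drop=True)
        assert yearly_rank(flipped)["a"] == pytest.approx(0.75)
        with pytest.raises(ValueError):
            yearly_rank(daily.iloc[:0])

    def test_daily_ranks_pipeline(self):
        sup = pd.DataFrame(
            {
                "date": ["2014-10-01", "2014-10-01", "2014-10-02"],
                "winner": ["A", "A", "B"],
                "loser": ["B", "C", "C"],
            }
        )
        daily = daily_standardized_ranks(sup)
        day1 = daily[daily["date"] == "2014-10-01"].set_index("id")["rank"]
        # A won twice; B lost to an equal, C lost to an already-higher A,
        # so B ends the day lowest
        assert day1["A"] == 1.0 and day1["B"] == 0.0
        day2 = daily[daily["date"] == "2014-10-02"].set_index("id")["rank"]
        assert day2["A"] == 1.0 and day2["C"] == 0.0


class TestDyadRows:
    @pytest.fixture
    def small_setup(self):
        members = (
            Individual("F1", "female", 2005, mother_id=None),
            Individual("F2", "female", 2006, mother_id="F1"),
            Individual("M1", "male", 2004, mother_id="F1"),
            Individual("M2", "male", 2010, mother_id=None, infant_years=frozenset()),
        )
        roster = SeasonRoster("2014/5", members, start_year=2014)
        table = pd.DataFrame(
            {
                "id_a": ["F1", "F1", "F1", "F2", "F2", "M1"],
                "id_b": ["F2", "M1", "M2", "M1", "M2", "M2"],
                "season": "2014/5",
                "pav": [0.1, 0.0, -0.05, 0.02, 0.0, 0.01],
                "significant": [True, False, False, False, False, False],
            }
        )
        ranks = {"2014/5": {"F1": 0.9, "F2": 0.4, "M1": 0.6, "M2": 0.1}}
        return table, roster, ranks

    def test_covariate_construction(self, small_setup):
        table, roster, ranks = small_setup
        rows = build_dyad_rows({"2014/5": table}, {"2014/5": roster}, ranks)
        assert len(rows) == 6
        r = rows.set_index("dyad")
        # mother-offspring and maternal siblings are kin
        assert r.loc["F1|F2", "kinship"] == 1
        assert r.loc["F1|M1", "kinship"] == 1
        assert r.loc["F2|M1", "kinship"] == 1  # same mother
        assert r.loc["F1|M2", "kinship"] == 0
        assert r.loc["F1|F2", "sex_combo"] == "female_female"
        assert r.loc["F1|F2", "rank_diff"] == pytest.approx(0.5)
        assert r.loc["F1|M2", "sex_combo"] == "female_male"
        assert r.loc["M1|M2", "age_combo"] == "adult_subadult"  # M2 is 4
        assert r.loc["F1|F2", "infant_combo"] == "no_no"

    def test_multiple_seasons_multiply_rows(self, small_setup):
        table, roster, ranks = small_setup
        t2 = table.assign(season="2015/6")
        roster2 = SeasonRoster("2015/6", roster.members, start_year=2015)
        rows = build_dyad_rows(
            {"2014/5": table, "2015/6": t2},
            {"2014/5": roster, "2015/6": roster2},
            {"2014/5": ranks["2014/5"], "2015/6": ranks["2014/5"]},
        )
        assert len(rows) == 12
        assert rows["rank_diff_z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_rank_errors(self, small_setup):
        table, roster, _ = small_setup
        with pytest.raises(ValueError, match="M2"):
            build_dyad_rows({"2014/5": table}, {"2014/5": roster}, {"2014/5": {"F1": 1, "F2": 0.5, "M1": 0.2}})


class TestEnumeration:
    def test_full_model_yields_52_submodels(self):
        assert len(enumerate_submodels(FULL_MODEL)) == 52

    def test_matches_brute_force_oracle(self):
        # independent construction: filter the raw powerset by marginality
        terms = sorted(FULL_MODEL)
        valid = set()
        for r in range(len(terms) + 1):
            for combo in itertools.combinations(terms, r):
                s = frozenset(combo)
                ok = all(set(t.split(":")) <= s for t in s if ":" in t)
                if ok:
                    valid.add(s)
        assert set(enumerate_submodels(FULL_MODEL)) == valid

    def test_contains_null_and_full(self):
        subs = enumerate_submodels(FULL_MODEL)
        assert frozenset() in subs and frozenset(FULL_MODEL) in subs

    def test_main_effects_only_gives_powerset(self):
        full = frozenset({TERM_KINSHIP, TERM_RANK, TERM_INFANT})
        assert len(enumerate_submodels(full)) == 8

    def test_no_orphan_interactions(self):
        for s in enumerate_submodels(FULL_MODEL):
            for t in s:
                if ":" in t:
                    assert set(t.split(":")) <= s


class TestInformationCriteria:
    def test_aicc_worked_value(self):
        # AIC 100 with k=2, n=10 -> 100 + 12/7
        loglik = -(100 - 2 * 2) / 2.0
        assert aicc(loglik, 2, 10) == pytest.approx(101.714, abs=1e-3)

    def test_aicc_limits_and_errors(self):
        loglik = -50.0
        aic = -2 * loglik + 2 * 3
        assert aicc(loglik, 3, 10**9) == pytest.approx(aic, abs=1e-6)
        assert aicc(loglik, 4, 100) > aicc(loglik, 3, 100)
        with pytest.raises(ValueError):
            aicc(loglik, 9, 10)

    def test_akaike_weights_worked_value(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.731, 0.269], abs=1e-3)
        assert akaike_weights([5.0]) == pytest.approx([1.0])

    def test_weights_sum_to_one_and_shift_invariant(self, rng):
        a = rng.normal(500, 20, 30)
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, akaike_weights(a + 123.4))

    def test_confidence_set_prefix(self):
        idx = confidence_set([0.6, 0.3, 0.08, 0.02])
        assert list(idx) == [0, 1, 2]
        assert list(confidence_set([1.0])) == [0]
        assert len(confidence_set(np.full(20, 0.05))) == 19

    def test_predictor_weights(self):
        specs = [frozenset(), frozenset({"a"}), frozenset({"b"}), frozenset({"a", "b"})]
        pw = predictor_weights(specs, [0.25] * 4).set_index("term")
        assert pw.loc["a", "summed_weight"] == pytest.approx(0.5)
        assert pw.loc["a", "expected_weight"] == pytest.approx(0.5)
        pw2 = predictor_weights(specs, [0.0, 0.5, 0.0, 0.5]).set_index("term")
        assert pw2.loc["a", "summed_weight"] == pytest.approx(1.0)


class TestFitting:
    def test_kin_logodds_recovery(self):
        rows = simulate_dyad_rows(1500, seed=1, kin_logodds=1.0, rank_coef=-0.5)
        fit = fit_model(rows, FULL_MODEL, family="binomial")
        assert fit.converged
        assert fit.params["kinship"] == pytest.approx(1.0, abs=0.5)

    def test_null_spec_intercept_only(self):
        rows = simulate_dyad_rows(200, seed=2)
        fit = fit_model(rows, frozenset(), family="binomial")
        assert len(fit.params) == 1 and np.isfinite(fit.loglik)

    def test_gaussian_pure_noise_estimates_near_zero(self):
        rows = simulate_dyad_rows(2000, seed=3, pav_sd=0.05)
        fit = fit_model(rows, FULL_MODEL, family="gaussian")
        slopes = fit.params.drop("Intercept")
        assert (slopes.abs() <= 3 * fit.bse.drop("Intercept") + 1e-9).all()

    def test_mixed_engine_gaussian_runs(self):
        rows = simulate_dyad_rows(300, seed=4, kin_pav=0.1)
        fit = fit_model(rows, frozenset({TERM_KINSHIP}), family="gaussian", engine="mixed")
        assert np.isfinite(fit.loglik)
        assert set(fit.vc) == {"id1", "id2", "dyad", "year"}
        with pytest.raises(NotImplementedError):
            fit_model(rows, frozenset(), family="binomial", engine="mixed")


class TestMultimodel:
    def test_strong_effect_gets_full_summed_weight(self):
        rows = simulate_dyad_rows(1500, seed=5, kin_logodds=1.2)
        mm = multimodel_inference(rows, family="binomial")
        pw = mm.predictor_weights.set_index("term")
        assert pw.loc[TERM_KINSHIP, "summed_weight"] > 0.95
        assert not mm.null_in_confidence_set
        assert mm.weights.sum() == pytest.approx(1.0)

    def test_null_data_keeps_null_model_in_confidence_set(self):
        rows = simulate_dyad_rows(600, seed=6)
        mm = multimodel_inference(rows, family="binomial")
        assert mm.null_in_confidence_set


class TestDyadFlip:
    def test_seeded_flip_is_reproducible(self):
        rows = simulate_dyad_rows(400, seed=7, kin_logodds=1.0)
        a = dyad_flip_inference(rows, family="binomial", n_selections=3, seed=11, refit_subsets=False)
        b = dyad_flip_inference(rows, family="binomial", n_selections=3, seed=11, refit_subsets=False)
        pd.testing.assert_series_equal(a.mean_estimates, b.mean_estimates)

    def test_flip_is_noop_for_fixed_effects(self):
        """Symmetric dyadic covariates make orientation irrelevant for the GLM."""
        rows = simulate_dyad_rows(400, seed=8, kin_logodds=0.8)
        flip = dyad_flip_inference(rows, family="binomial", n_selections=4, seed=1, refit_subsets=False)
        single = fit_model(rows, FULL_MODEL, family="binomial")
        pd.testing.assert_series_equal(flip.mean_estimates, single.params, atol=1e-10, rtol=0)

    def test_recovery_with_subset_refits(self):
        rows = simulate_dyad_rows(1500, seed=9, kin_logodds=1.0)
        flip = dyad_flip_inference(rows, family="binomial", n_selections=2, seed=3, refit_subsets=True)
        assert flip.n_converged == 2
        assert flip.mean_estimates["kinship"] == pytest.approx(1.0, abs=0.5)
        assert flip.mean_summed_weights is not None


class TestDiagnostics:
    def test_vif_orthogonal_predictors_near_one(self):
        rows = simulate_dyad_rows(3000, seed=10)
        v = vif(rows)
        assert (v["gvif"] < 1.2).all()

    def test_vif_closed_form_r2_half(self, rng):
        n = 20000
        x = rng.normal(size=n)
        # engineered collinearity: corr^2 = 0.5 -> VIF = 2
        y = x * np.sqrt(0.5) + rng.normal(scale=np.sqrt(0.5), size=n)
        rows = simulate_dyad_rows(n, seed=11)
        rows["rank_diff_z"] = x
        rows["kinship"] = y
        v = vif(rows, predictors=(TERM_KINSHIP, TERM_RANK)).set_index("term")
        assert v.loc[TERM_KINSHIP, "gvif"] == pytest.approx(2.0, rel=0.05)

    def test_vif_perfect_collinearity_infinite(self):
        rows = simulate_dyad_rows(500, seed=12)
        rows["rank_diff_z"] = rows["kinship"] * 2.0
        v = vif(rows, predictors=(TERM_KINSHIP, TERM_RANK)).set_index("term")
        assert not np.isfinite(v.loc[TERM_KINSHIP, "gvif"]) or v.loc[TERM_KINSHIP, "gvif"] > 1e6

    def test_r2_components_closed_form(self):
        marg, cond = r2_mixed({"fixed": 1.0, "random": 1.0, "residual": 2.0})
        assert (marg, cond) == pytest.approx((0.25, 0.5))

    def test_r2_fixed_engine_marginal_equals_conditional(self):
        rows = simulate_dyad_rows(800, seed=13, kin_logodds=1.0)
        fit = fit_model(rows, FULL_MODEL, family="binomial")
        marg, cond = r2_mixed(fit)
        assert marg == pytest.approx(cond)
        assert 0.0 <= marg <= 1.0

    def test_influence_check_shifts_finite(self):
        rows = simulate_dyad_rows(600, seed=14, kin_logodds=1.0)
        shifts = influence_check(rows, frozenset({TERM_KINSHIP, TERM_RANK}), factor="year")
        assert np.isfinite(shifts.to_numpy()).all()
        assert set(shifts.index) == set(rows["season"].unique())

    def test_influence_check_single_season_errors(self):
        rows = simulate_dyad_rows(100, seed=15, n_seasons=1)
        with pytest.raises(ValueError, match="level"):
            influence_check(rows, frozenset({TERM_KINSHIP}), factor="year")

    def test_influence_check_duplicated_level_zero_shift(self):
        rows = simulate_dyad_rows(300, seed=16, kin_logodds=0.5, n_seasons=2)
        # duplicate season S2 as S3: removing either duplicate leaves the
        # same information, so their refits agree with each other
        dup = rows[rows["season"] == "S2"].assign(season="S3")
        both = pd.concat([rows, dup], ignore_index=True)
        shifts = influence_check(both, frozenset({TERM_KINSHIP}), factor="year")
        assert np.allclose(shifts.loc["S2"], shifts.loc["S3"], atol=1e-8)
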