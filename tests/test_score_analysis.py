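"""Unweighted allele scores and covariate-adjusted GLM associations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ivmr.score_analysis import (
    EstimationError,
    GenotypeMatrix,
    build_unweighted_score,
    glm_association,
    quartile_summary,
    read_dosage_matrix,
    stratified_association,
    write_dosage_matrix,
)
from ivmr.summary_data import ConfigurationError

from conftest import SEED, make_pair, make_set


def _matrix(rng, n=100, m=24, maf=0.3, missing_rate=0.0):
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    if missing_rate:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan
    rsids = tuple(f"rs{j + 1}" for j in range(m))
    return GenotypeMatrix(
        dosages=dosages,
        rsids=rsids,
        effect_alleles=("A",) * m,
        other_alleles=("G",) * m,
    )


def _iset(m=24, raising="A", other="G"):
    pairs = [
        make_pair(rsid=f"rs{j + 1}", effect_allele=raising, other_allele=other)
        for j in range(m)
    ]
    return make_set(pairs)


class TestBuildUnweightedScore:
    def test_bounds_at_homozygous_extremes(self):
        n, m = 3, 24
        dosages = np.vstack(
            [np.full(m, 2.0), np.zeros(m), np.full(m, 1.0)]
        )
        gm = GenotypeMatrix(
            dosages=dosages,
            rsids=tuple(f"rs{j + 1}" for j in range(m)),
            effect_alleles=("A",) * m,
        )
        score = build_unweighted_score(gm, _iset(m))
        assert score.values.tolist() == [48.0, 0.0, 24.0]
        assert score.n_contributing.tolist() == [24, 24, 24]

    def test_matches_brute_force_row_sums(self, rng):
        gm = _matrix(rng, n=100, m=24)
        score = build_unweighted_score(gm, _iset(24))
        np.testing.assert_allclose(score.values, gm.dosages.sum(axis=1))

    def test_opposite_allele_columns_are_reflected(self, rng):
        gm = _matrix(rng, n=50, m=5)
        # instrument set declares G as the raising allele: dosages count A
        score = build_unweighted_score(gm, _iset(5, raising="G", other="A"))
        np.testing.assert_allclose(score.values, (2.0 - gm.dosages).sum(axis=1))

    def test_missing_dosages_reduce_contributing_count(self, rng):
        gm = _matrix(rng, n=200, m=10, missing_rate=0.2)
        score = build_unweighted_score(gm, _iset(10))
        np.testing.assert_allclose(score.values, np.nansum(gm.dosages, axis=1))
        np.testing.assert_array_equal(
            score.n_contributing, np.isfinite(gm.dosages).sum(axis=1)
        )
        assert np.all(score.values <= 2 * score.n_contributing)

    def test_score_linearity_over_a_partition(self, rng):
        gm = _matrix(rng, n=80, m=10)
        full = build_unweighted_score(gm, _iset(10))
        first = build_unweighted_score(gm, make_set(_iset(10).pairs[:4]))
        second = build_unweighted_score(gm, make_set(_iset(10).pairs[4:]))
        np.testing.assert_allclose(full.values, first.values + second.values)

    def test_unknown_rsid_is_configuration_error(self, rng):
        gm = _matrix(rng, n=10, m=3)
        with pytest.raises(ConfigurationError):
            build_unweighted_score(gm, _iset(5))

    def test_dosage_matrix_round_trip(self, rng, tmp_path):
        gm = _matrix(rng, n=20, m=4)
        path = tmp_path / "dosages.tsv"
        write_dosage_matrix(gm, path)
        back = read_dosage_matrix(path)
        np.testing.assert_allclose(back.dosages, gm.dosages)
        assert back.rsids == gm.rsids
        assert back.effect_alleles == gm.effect_alleles


class TestGlmAssociation:
    def test_noiseless_linear_fit_is_exact(self, rng):
        score = rng.binomial(2, 0.3, size=200).astype(float).cumsum() % 48
        outcome = 0.5 * score
        result = glm_association(score, outcome, family="linear")
        assert result.estimate == pytest.approx(0.5, abs=1e-12)
        assert result.family == "linear"

    def test_logistic_matches_two_by_two_odds_ratio(self):
        # binary score, binary outcome: the MLE slope is the log
        # cross-product ratio of the 2x2 table
        score = np.array([0] * 50 + [1] * 50, dtype=float)
        outcome = np.array([1] * 10 + [0] * 40 + [1] * 30 + [0] * 20, dtype=float)
        result = glm_association(score, outcome, family="logistic")
        expected = np.log((30 * 40) / (20 * 10))
        assert result.estimate == pytest.approx(expected, abs=1e-6)

    def test_logistic_matches_independent_newton_oracle(self):
        """Two-parameter toy problem: compare with a hand-rolled Newton
        maximizer of the exact log-likelihood."""
        rng = np.random.default_rng(SEED)
        g = rng.binomial(2, 0.4, size=500).astype(float)
        y = (rng.random(500) < 1 / (1 + np.exp(-(-0.5 + 0.3 * g))))
        result = glm_association(g, y.astype(float), family="logistic")

        beta = np.zeros(2)
        X = np.column_stack([np.ones_like(g), g])
        for _ in range(50):
            p = 1 / (1 + np.exp(-X @ beta))
            grad = X.T @ (y - p)
            hess = X.T @ (X * (p * (1 - p))[:, None])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        assert result.estimate == pytest.approx(beta[1], abs=1e-6)

    def test_standardized_estimate_is_unstandardized_over_sd(self, rng):
        score = rng.binomial(2, 0.3, size=500).astype(float)
        outcome = 0.3 * score + rng.normal(0, 2.0, size=500)
        raw = glm_association(score, outcome, family="linear")
        std = glm_association(score, outcome, family="linear", standardize_outcome=True)
        assert std.estimate == pytest.approx(raw.estimate / outcome.std(ddof=1), rel=1e-10)

    def test_covariate_adjustment_matches_statsmodels(self, rng):
        n = 300
        score = rng.binomial(48, 0.4, size=n).astype(float)
        age = rng.uniform(40, 70, size=n)
        sex = rng.integers(0, 2, size=n)
        outcome = 0.1 * score + 0.05 * age + 0.3 * sex + rng.normal(size=n)
        cov = pd.DataFrame({"age": age, "sex": sex})
        result = glm_association(score, outcome, covariates=cov, family="linear")
        X = sm.add_constant(pd.DataFrame({"score": score, "age": age, "sex": sex}))
        expected = sm.OLS(outcome, X).fit().params["score"]
        assert result.estimate == pytest.approx(expected, rel=1e-10)
        assert result.covariate_names == ("age", "sex")

    def test_per_allele_log_odds_recovery(self):
        """Simulated binary outcome with true per-allele log-odds 0.05:
        the mean logistic estimate over 100 cohorts of n = 20,000 lands
        within 3 Monte-Carlo SEs of the truth."""
        rng = np.random.default_rng(SEED)
        truth, n, reps = 0.05, 20_000, 100
        estimates = []
        for _ in range(reps):
            score = rng.binomial(48, 0.3, size=n).astype(float)
            logits = -1.0 + truth * (score - score.mean())
            y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
            estimates.append(glm_association(score, y, family="logistic").estimate)
        estimates = np.asarray(estimates)
        mcse = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - truth) < 3 * mcse

    def test_rank_deficient_design_rejected(self, rng):
        score = rng.binomial(2, 0.3, size=50).astype(float)
        cov = pd.DataFrame({"a": np.ones(50)})  # collinear with intercept
        with pytest.raises(ConfigurationError, match="rank"):
            glm_association(score, rng.normal(size=50), covariates=cov)

    @pytest.mark.filterwarnings("ignore::Warning")
    def test_separated_logistic_fit_raises_estimation_error(self):
        score = np.array([0.0] * 20 + [2.0] * 20)
        outcome = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(EstimationError):
            glm_association(score, outcome, family="logistic")


class TestStratifiedAssociation:
    def test_two_identical_strata_give_identical_results(self, rng):
        score = rng.binomial(48, 0.4, size=100).astype(float)
        outcome = 0.2 * score + rng.normal(size=100)
        score2 = np.concatenate([score, score])
        outcome2 = np.concatenate([outcome, outcome])
        strata = np.array(["a"] * 100 + ["b"] * 100)
        results = stratified_association(score2, outcome2, None, strata)
        assert len(results) == 2
        assert results[0].result.estimate == pytest.approx(results[1].result.estimate)

    def test_single_stratum_equals_unstratified(self, rng):
        score = rng.binomial(48, 0.4, size=100).astype(float)
        outcome = 0.2 * score + rng.normal(size=100)
        whole = glm_association(score, outcome)
        [only] = stratified_association(score, outcome, None, np.zeros(100, int))
        assert only.result.estimate == pytest.approx(whole.estimate)
        assert only.result.se == pytest.approx(whole.se)

    def test_failed_stratum_does_not_poison_others(self, rng):
        score = rng.binomial(48, 0.4, size=101).astype(float)
        outcome = 0.2 * score + rng.normal(size=101)
        strata = np.array(["ok"] * 100 + ["tiny"])
        results = {r.stratum: r for r in stratified_association(score, outcome, None, strata)}
        assert results["ok"].result is not None
        assert results["tiny"].result is None
        assert results["tiny"].error

    def test_no_spurious_trend_under_constant_effect(self):
        """Age-constant genetic effect: the meta-regression of stratum
        estimates on stratum index shows no trend in ~95% of replicates
        (3-sigma lower bound on the binomial count)."""
        rng = np.random.default_rng(SEED)
        n_reps, n_per, n_strata = 200, 500, 4
        n = n_per * n_strata
        strata = np.repeat(np.arange(n_strata), n_per)
        quiet = 0
        for _ in range(n_reps):
            score = rng.binomial(48, 0.4, size=n).astype(float)
            outcome = 0.15 * score + 0.5 * strata + rng.normal(0, 2, size=n)
            fits = stratified_association(score, outcome, None, strata)
            est = np.array([f.result.estimate for f in fits])
            se = np.array([f.result.se for f in fits])
            wls = sm.WLS(est, sm.add_constant(np.arange(n_strata, dtype=float)),
                         weights=se**-2).fit()
            if wls.pvalues[1] > 0.05:
                quiet += 1
        # nominal rate 0.95; 3 sigma at 200 reps is ~0.046
        assert quiet / n_reps >= 0.90


class TestQuartileSummary:
    def test_constant_outcome(self, rng):
        score = rng.normal(size=100)
        table = quartile_summary(score, np.ones(100))
        assert table["proportion"].tolist() == [1.0] * 4

    def test_step_outcome_over_scores_one_to_eight(self):
        score = np.arange(1, 9, dtype=float)
        outcome = (score > 4).astype(float)
        table = quartile_summary(score, outcome)
        assert table["proportion"].tolist() == [0.0, 0.0, 1.0, 1.0]
        assert table["n"].tolist() == [2, 2, 2, 2]

    def test_boundary_ties_go_to_the_lower_bin(self):
        score = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        table = quartile_summary(score, np.zeros(8))
        # the tied 25% quantile value (2.0) lands in quartile 1
        assert table["n"].iloc[0] == 3

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            quartile_summary(np.array([1.0, 1.0, 2.0, 2.0]), np.zeros(4))

    def test_rising_risk_shows_in_quartile_gradient(self):
        """Outcome probability rising with the score: the top quartile
        proportion exceeds the bottom in essentially all replicates."""
        rng = np.random.default_rng(SEED)
        wins = 0
        n_reps = 200
        for _ in range(n_reps):
            score = rng.binomial(48, 0.4, size=1_000).astype(float)
            p = 1 / (1 + np.exp(-(-0.5 + 0.08 * (score - score.mean()))))
            outcome = (rng.random(1_000) < p).astype(float)
            table = quartile_summary(score, outcome)
            if table["proportion"].iloc[3] > table["proportion"].iloc[0]:
                wins += 1
        assert wins / n_reps >= 0.95
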