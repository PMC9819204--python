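"""Subset weight estimation, signal averaging, index building, validation GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import mixbiome as mb
from mixbiome.wqs_core import SubsetFit, estimate_subset_weights, signal_average


def _profile_grid_loglik(Q, y, Z, family, step=0.01, orthant=None):
    """Independent oracle: exhaustive simplex grid, GLM profiled at each w.

    Returns the best log-likelihood over the grid (optionally restricted to
    one sign orthant of beta1, i.e. the better of the two is the
    unconstrained optimum).
    """
    m = Q.shape[1]
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    best = -np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for combo in itertools.product(ticks, repeat=m - 1):
        last = 1.0 - sum(combo)
        if last < -1e-12:
            continue
        w = np.array(list(combo) + [max(last, 0.0)])
        u = Q @ w
        X = np.column_stack([np.ones(len(u)), u] + ([Z] if Z is not None else []))
        try:
            fit = sm.GLM(y, X, family=fam).fit()
        except Exception:
            continue
        if orthant is not None and np.sign(fit.params[1]) not in (0, orthant):
            continue
        best = max(best, fit.llf)
    return best


class TestDrawRandomSubsets:
    def test_exhaustive_when_m_equals_p(self):
        subsets = mb.draw_random_subsets(5, 5, 3, seed=0)
        for s in subsets:
            assert sorted(s) == [0, 1, 2, 3, 4]

    def test_hmp_scale_subsets_are_valid(self):
        subsets = mb.draw_random_subsets(868, 30, 1000, seed=1)
        assert len(subsets) == 1000
        for s in subsets:
            assert len(set(s)) == 30 and s.min() >= 0 and s.max() < 868

    def test_seed_determinism(self):
        a = mb.draw_random_subsets(50, 10, 20, seed=7)
        b = mb.draw_random_subsets(50, 10, 20, seed=7)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_m_exceeding_p_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mb.draw_random_subsets(5, 6, 1, seed=0)


class TestEstimateSubsetWeights:
    @pytest.mark.parametrize("family", ["binomial", "gaussian"])
    def test_single_taxon_equals_plain_glm(self, family):
        rng = np.random.default_rng(3)
        q = rng.integers(0, 4, size=120).astype(float)
        if family == "binomial":
            y = (rng.random(120) < expit(-1 + 0.5 * q)).astype(float)
            fam = sm.families.Binomial()
        else:
            y = 0.4 * q + rng.normal(size=120)
            fam = sm.families.Gaussian()
        fit = estimate_subset_weights(q[:, None], y, family=family)
        ref = sm.GLM(y, sm.add_constant(q), family=fam).fit()
        assert fit.weights.tolist() == [1.0]
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-5)
        assert fit.t_stat == pytest.approx(ref.tvalues[1], rel=1e-3)

    def test_informative_taxon_dominates_noise_taxon(self):
        rng = np.random.default_rng(4)
        n = 200
        qa = rng.integers(0, 4, size=n).astype(float)
        qb = rng.integers(0, 4, size=n).astype(float)
        y = 1.0 * qa  # noiseless increasing function of taxon A's score
        fit = estimate_subset_weights(
            np.column_stack([qa, qb]), y, family="gaussian", direction="positive"
        )
        assert fit.weights[0] >= 0.9

    @pytest.mark.parametrize("family", ["binomial", "gaussian"])
    @pytest.mark.parametrize("m", [2, 3])
    def test_optimum_matches_simplex_grid_oracle(self, family, m):
        rng = np.random.default_rng(10 + m)
        n = 150
        Q = rng.integers(0, 4, size=(n, m)).astype(float)
        Z = rng.integers(0, 2, size=(n, 1)).astype(float)
        lin = 0.6 * Q[:, 0] - 0.2 * Q[:, -1] + 0.3 * Z[:, 0]
        if family == "binomial":
            y = (rng.random(n) < expit(-1 + lin)).astype(float)
        else:
            y = lin + rng.normal(size=n)
        fit = estimate_subset_weights(Q, y, Z, family=family, direction="unconstrained")
        oracle = _profile_grid_loglik(Q, y, Z, family)
        assert fit.loglik >= oracle - 1e-4
        assert fit.loglik <= oracle + 0.05  # grid is 0.01-fine; no large gap allowed

    def test_constrained_direction_matches_constrained_oracle(self):
        rng = np.random.default_rng(21)
        n = 150
        Q = rng.integers(0, 4, size=(n, 2)).astype(float)
        y = (rng.random(n) < expit(0.5 - 0.4 * Q[:, 0])).astype(float)
        fit = estimate_subset_weights(Q, y, family="binomial", direction="negative")
        oracle = _profile_grid_loglik(Q, y, None, "binomial", orthant=-1)
        assert fit.beta1 <= 0
        assert fit.loglik >= oracle - 1e-4

    def test_random_outcome_still_on_simplex(self):
        rng = np.random.default_rng(5)
        Q = rng.integers(0, 4, size=(80, 6)).astype(float)
        y = rng.integers(0, 2, size=80).astype(float)
        fit = estimate_subset_weights(Q, y, family="binomial")
        assert (fit.weights >= 0).all()
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_constant_outcome_rejected(self):
        Q = np.ones((30, 3))
        with pytest.raises(ValueError, match="constant"):
            estimate_subset_weights(Q, np.ones(30))

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(6)
        Q = rng.integers(0, 4, size=(40, 2)).astype(float)
        y = rng.integers(0, 2, size=40).astype(float)
        Z = np.column_stack([np.ones(40), np.ones(40) * 2])
        with pytest.raises(ValueError, match="rank-deficient"):
            estimate_subset_weights(Q, y, Z, covariate_names=["c1", "c2"])


class TestSignalFunctions:
    @pytest.mark.parametrize(
        "t, kind, expected",
        [
            (2.0, "t2", 4.0),
            (-2.0, "exp_t", np.exp(2.0)),
            (-3.0, "abs_t", 3.0),
            (40.0, "exp_t", np.exp(30.0)),  # clipped at |t| = 30
        ],
    )
    def test_signal_value(self, t, kind, expected):
        assert mb.signal_value(t, kind) == pytest.approx(expected)

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            mb.signal_value(np.nan, "t2")

    def test_constant_signal_reduces_to_plain_mean(self):
        rng = np.random.default_rng(8)
        fits = []
        for _ in range(12):
            idx = rng.choice(10, size=4, replace=False)
            w = rng.dirichlet(np.ones(4))
            fits.append(SubsetFit(idx, w, beta1=1.0, t_stat=2.0, converged=True))
        got = signal_average(fits, 10, "t2")
        num = np.zeros(10)
        den = np.zeros(10)
        for f in fits:
            num[f.taxon_indices] += f.weights
            den[f.taxon_indices] += 1
        plain = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        plain /= plain.sum()
        assert np.allclose(got, plain, atol=1e-12)

    def test_two_subset_hand_computation(self):
        # subsets {A,B} (w 0.6/0.4, t=2) and {B,C} (0.5/0.5, t=1), t^2 signal:
        # per-taxon means A=0.6, B=(0.4*4+0.5*1)/5=0.42, C=0.5
        # normalized -> (0.395, 0.276, 0.329)
        fits = [
            SubsetFit(np.array([0, 1]), np.array([0.6, 0.4]), 1.0, 2.0, True),
            SubsetFit(np.array([1, 2]), np.array([0.5, 0.5]), 1.0, 1.0, True),
        ]
        got = signal_average(fits, 3, "t2")
        assert np.allclose(got, [0.395, 0.276, 0.329], atol=1e-3)
        assert got.sum() == pytest.approx(1.0, abs=1e-8)

    def test_uncovered_taxon_warns_and_gets_zero(self):
        fits = [SubsetFit(np.array([0, 1]), np.array([0.5, 0.5]), 1.0, 2.0, True)]
        with pytest.warns(UserWarning, match="no converged subset"):
            got = signal_average(fits, 3, "t2")
        assert got[2] == 0.0

    def test_no_converged_fits_is_error(self):
        fits = [SubsetFit(np.array([0]), np.array([1.0]), 0.0, np.nan, False)]
        with pytest.raises(ValueError, match="no converged"):
            signal_average(fits, 1, "t2")


class TestBuildIndex:
    def test_bounds_and_degenerate_weights(self):
        rng = np.random.default_rng(9)
        S = rng.integers(0, 4, size=(50, 5)).astype(float)
        w = rng.dirichlet(np.ones(5))
        idx = mb.build_index(S, w)
        assert (idx >= 0).all() and (idx <= 3).all()
        one_hot = np.eye(5)[2]
        assert np.allclose(mb.build_index(S, one_hot), S[:, 2])
        assert np.allclose(mb.build_index(np.full((4, 5), 3.0), np.full(5, 0.2)), 3.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mb.build_index(np.zeros((3, 4)), np.ones(5) / 5)


class TestValidateIndex:
    def test_gaussian_recovers_slope(self):
        rng = np.random.default_rng(12)
        u = rng.random(300) * 3
        y = 2.0 * u + rng.normal(scale=1e-4, size=300)
        est = mb.validate_index(u, y, family="gaussian")
        assert est.beta1 == pytest.approx(2.0, abs=1e-3)

    def test_index_equal_to_covariate_is_rank_deficient(self):
        u = np.arange(20.0)
        y = np.random.default_rng(0).integers(0, 2, 20).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            mb.validate_index(u, y, covariates=u[:, None], family="binomial")

    def test_null_binomial_ci_covers_zero(self):
        # permuted outcome: the Wald CI for beta1 should cover 0 in >= 90/100 seeds
        rng = np.random.default_rng(13)
        u = rng.random(120) * 3
        covered = 0
        for s in range(100):
            y = np.random.default_rng(s).permutation((np.arange(120) < 40).astype(float))
            est = mb.validate_index(u, y, family="binomial")
            lo, hi = est.beta1_ci
            covered += lo <= 0 <= hi
        assert covered >= 90

    def test_odds_ratio_reported(self):
        rng = np.random.default_rng(14)
        u = rng.random(200) * 3
        y = (rng.random(200) < expit(-1 + 0.8 * u)).astype(float)
        est = mb.validate_index(u, y, family="binomial")
        assert est.odds_ratio == pytest.approx(np.exp(est.beta1))


class TestDetermineDirection:
    def _fit(self, beta1, converged=True):
        return SubsetFit(np.array([0]), np.array([1.0]), beta1, 1.0, converged)

    def test_majority_negative_count_split(self):
        fits = [self._fit(-1.0)] * 1228 + [self._fit(1.0)] * 772
        direction, counts = mb.determine_direction(fits)
        assert direction == "negative"
        assert counts == {"positive": 772, "negative": 1228}

    def test_all_positive(self):
        direction, _ = mb.determine_direction([self._fit(0.5)] * 5)
        assert direction == "positive"

    def test_tie_defaults_negative_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            direction, _ = mb.determine_direction([self._fit(-1.0), self._fit(1.0)])
        assert direction == "negative"


class TestRunWqsRs:
    def test_single_taxon_mixture(self, small_table):
        # a 1-taxon mixture cannot be a closed relative table, so build the
        # ranked scores directly from one abundance column
        col = small_table.data.columns[0]
        scores = pd.DataFrame(
            {col: mb.zero_anchored_rank(small_table.data[col].to_numpy(), levels=4)},
            index=small_table.data.index,
        )
        ranked = mb.RankedMatrix(scores, levels=4, split="quantile")
        one = mb.AbundanceTable(
            data=small_table.data[[col]], mode="counts",
            taxonomy=small_table.taxonomy.loc[[col]], metadata=small_table.metadata,
        )
        cfg = mb.WQSConfig(m=1, B=5, direction="unconstrained")
        res = mb.run_wqs_rs(one, ranked, "grp", None, cfg, seed=3)
        assert res.final_weights.tolist() == [1.0]

    def test_seed_reproducibility_bit_identical(self, signal_study):
        table, ranked, _ = signal_study
        cfg = mb.WQSConfig(m=10, B=25, direction="auto")
        r1 = mb.run_wqs_rs(table, ranked, "test", ["sex"], cfg, seed=17)
        r2 = mb.run_wqs_rs(table, ranked, "test", ["sex"], cfg, seed=17)
        assert (r1.final_weights == r2.final_weights).all()
        assert r1.train_ids == r2.train_ids
        assert r1.glm_estimates.beta1 == r2.glm_estimates.beta1

    def test_taxon_order_invariance_with_exhaustive_subsets(self, small_table):
        # with m = p every subset is the full taxon set, so column order only
        # permutes predictors inside each GLM — results must agree per taxon
        ranked = mb.rank_table(small_table, levels=4)
        p = small_table.n_taxa
        cfg = mb.WQSConfig(m=p, B=6, direction="positive")
        res = mb.run_wqs_rs(small_table, ranked, "grp", None, cfg, seed=19)
        perm = np.random.default_rng(2).permutation(p)
        cols = [small_table.taxon_ids[j] for j in perm]
        table2 = small_table.with_data(small_table.data[cols])
        ranked2 = mb.RankedMatrix(ranked.scores[cols], ranked.levels, ranked.split)
        res2 = mb.run_wqs_rs(table2, ranked2, "grp", None, cfg, seed=19)
        assert res2.glm_estimates.beta1 == pytest.approx(
            res.glm_estimates.beta1, rel=1e-5
        )
        pd.testing.assert_series_equal(
            res.final_weights.sort_index(), res2.final_weights.sort_index(),
            rtol=1e-5, atol=1e-8,
        )
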