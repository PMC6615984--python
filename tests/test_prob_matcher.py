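"""Bivariate-normal score models, Mahalanobis p-values and the 3-step matcher."""

import math

import numpy as np
import pytest

from omicmatch import test_cis_associations as run_cis_tests  # noqa: N813
from omicmatch import (
    CROSS_ALIGNED,
    SELF_ALIGNED,
    MatchDecisionConfig,
    ScoreDistributionModel,
    SimilarityMatrix,
    SimulationConfig,
    compute_cutoffs,
    fit_score_distribution,
    inject_label_errors,
    iterate_alignment,
    match_pvalue,
    modmatcher_align,
    promodmatcher_align,
    simulate_dataset,
)
from omicmatch.prob_matcher import _pairwise_log_pvalues
from omicmatch.similarity import build_transformed_cis_blocks, pairwise_pearson, similarity_matrix


class TestCutoffs:
    def test_arithmetic(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0.8, 0.1, size=200)
        cs, cc = compute_cutoffs(scores)
        m, sd = scores.mean(), scores.std(ddof=1)
        assert cs == pytest.approx(m - 2.576 * sd)
        assert cc == pytest.approx(m - sd)
        assert cc >= cs  # 1 < 2.576 always

    def test_identical_scores_collapse_with_warning(self):
        with pytest.warns(UserWarning):
            cs, cc = compute_cutoffs([0.7] * 12)
        assert cs == cc == pytest.approx(0.7)


class TestMatchPvalue:
    def test_at_the_mean_p_equals_prior(self):
        m = ScoreDistributionModel(mu=[0.3, 0.3], sigma=np.eye(2) * 0.01, n_real=50, n_permuted=0)
        assert match_pvalue(m, 0.3, is_self=True, p0=0.01) == pytest.approx(0.01)

    def test_closed_form_identity_sigma(self):
        m = ScoreDistributionModel(mu=[0.0, 0.0], sigma=np.eye(2), n_real=50, n_permuted=0)
        # x = (1,1): r^2 = 2, p = e^-1
        assert match_pvalue(m, 1.0) == pytest.approx(math.exp(-1.0))

    def test_non_finite_score_errors(self):
        m = ScoreDistributionModel(mu=[0, 0], sigma=np.eye(2), n_real=10, n_permuted=0)
        with pytest.raises(ValueError):
            match_pvalue(m, float("nan"))

    def test_affine_invariance(self):
        # a common affine rescaling of cloud and score leaves p unchanged
        rng = np.random.default_rng(1)
        cloud = rng.multivariate_normal([0.2, 0.1], [[0.04, 0.01], [0.01, 0.09]], size=500)
        for a, b in [(3.0, -0.5), (0.2, 1.0)]:
            m1 = ScoreDistributionModel(cloud.mean(0), np.cov(cloud.T, ddof=0), 500, 0)
            t = a * cloud + b
            m2 = ScoreDistributionModel(t.mean(0), np.cov(t.T, ddof=0), 500, 0)
            s = 0.77
            assert match_pvalue(m2, a * s + b) == pytest.approx(match_pvalue(m1, s), rel=1e-9)

    def test_mahalanobis_cdf_matches_stated_form(self):
        # F(R <= r) = 1 - exp(-r^2/2) for points drawn from the fitted normal
        rng = np.random.default_rng(2)
        mu = np.array([0.1, -0.2])
        sigma = np.array([[0.05, 0.02], [0.02, 0.08]])
        pts = rng.multivariate_normal(mu, sigma, size=10_000)
        inv = np.linalg.inv(sigma)
        d = pts - mu
        r = np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))
        from scipy.stats import kstest

        stat = kstest(r, lambda x: 1.0 - np.exp(-(x**2) / 2.0)).statistic
        assert stat < 0.05


class TestFitScoreDistribution:
    def _context_fixture(self):
        """12 matched pairs whose cloud at context (0,0) is (+-1,+-1) x3."""
        n = 13
        S = np.zeros((n, n))
        xs = [1, 1, -1, -1] * 3
        ys = [1, -1, 1, -1] * 3
        for m, (x, y) in enumerate(zip(xs, ys), start=1):
            S[0, m] = x
            S[m, 0] = y
        ids = [f"s{i}" for i in range(n)]
        sm = SimilarityMatrix(S, ids, ids, n_cis=10)
        matched = [(f"s{m}", f"s{m}") for m in range(1, n)]
        empty_U = np.empty((n, 0))
        empty_V = np.empty((0, n))
        return sm, matched, (empty_U, empty_V)

    def test_hand_cloud_gives_zero_mean_identity_sigma(self):
        sm, matched, UV = self._context_fixture()
        model = fit_score_distribution(sm, matched, 0, 0, _UV=UV)
        np.testing.assert_allclose(model.mu, [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(model.sigma, np.eye(2), atol=1e-12)
        assert model.n_real == 12

    def test_seeded_fit_is_deterministic(self, sim_clean):
        matched = [(s, s) for s in sim_clean.core_samples]
        cis = run_cis_tests(sim_clean.matA, sim_clean.matB, sim_clean.candidates, matched)
        S = similarity_matrix(sim_clean.matA, sim_clean.matB, cis)
        kw = dict(n_permuted=50, matA=sim_clean.matA, matB=sim_clean.matB, cis=cis, seed=9)
        m1 = fit_score_distribution(S, matched, 3, 3, **kw)
        m2 = fit_score_distribution(S, matched, 3, 3, **kw)
        np.testing.assert_array_equal(m1.mu, m2.mu)
        np.testing.assert_array_equal(m1.sigma, m2.sigma)

    def test_permuted_pseudo_profiles_score_near_zero(self, sim_clean):
        # permutation destroys cis structure: mean permuted score ~ 0
        from omicmatch.prob_matcher import _permuted_pseudo_profiles

        matched = [(s, s) for s in sim_clean.core_samples]
        cis = run_cis_tests(sim_clean.matA, sim_clean.matB, sim_clean.candidates, matched)
        A, B = build_transformed_cis_blocks(sim_clean.matA, sim_clean.matB, cis)
        rng = np.random.default_rng(11)
        U = pairwise_pearson(A, _permuted_pseudo_profiles(B, 500, rng), min_overlap=10)
        assert abs(np.nanmean(U)) < 0.05

    def test_vectorized_models_match_naive_reference(self):
        rng = np.random.default_rng(7)
        n_a, n_b, k = 14, 12, 30
        S = rng.normal(size=(n_a, n_b))
        U = rng.normal(size=(n_a, k))
        V = rng.normal(size=(k, n_b))
        ids_a = [f"s{i}" for i in range(n_a)]
        ids_b = [f"s{j}" for j in range(n_b)]
        sm = SimilarityMatrix(S, ids_a, ids_b, n_cis=10)
        matched = [(f"s{m}", f"s{m}") for m in range(12)]
        a_idx = np.arange(12)
        b_idx = np.arange(12)
        logp = _pairwise_log_pvalues(S, a_idx, b_idx, U, V)
        for i in range(n_a):
            for j in range(n_b):
                model = fit_score_distribution(sm, matched, i, j, _UV=(U, V))
                p_ref = match_pvalue(model, S[i, j])
                assert logp[i, j] == pytest.approx(math.log(p_ref), abs=1e-8), (i, j)


class TestProbabilisticAlignment:
    def test_error_free_data_near_complete_self_alignment(self, outcome_prob_clean, sim_clean):
        # the self-score floor (mean - 2.576 sd of the self-self scores)
        # structurally excludes its own extreme lower tail, so clean data
        # yields > 99% self-alignment with zero false alignments
        res = outcome_prob_clean.result
        self_ids = set(res.self_aligned_ids())
        core = set(sim_clean.core_samples)
        assert self_ids <= core
        assert len(self_ids) >= 0.98 * len(core)
        assert res.cross_pairs() == []
        assert outcome_prob_clean.converged

    def test_planted_reciprocal_swap_is_cross_aligned(self):
        cfg = SimulationConfig(n_cis=300, m_samples=100, seed=13)
        d = inject_label_errors(simulate_dataset(cfg), 0.02, seed=13, kind="swap")
        (s1, s2), = [list(p) for p in [list(d.injected_errors.items())[0]]]
        out = iterate_alignment(d.matA, d.matB, d.candidates, matcher="probabilistic", seed=13)
        crosses = set(out.result.cross_pairs())
        assert (s1, d.injected_errors[s1]) in crosses
        assert (s2, d.injected_errors[s2]) in crosses

    def test_seeded_procedure_is_reproducible(self, sim_clean):
        kw = dict(matcher="probabilistic", seed=21)
        r1 = iterate_alignment(sim_clean.matA, sim_clean.matB, sim_clean.candidates, **kw)
        r2 = iterate_alignment(sim_clean.matA, sim_clean.matB, sim_clean.candidates, **kw)
        assert r1.result.table.equals(r2.result.table)

    def test_rank_rejected_but_probability_accepted(self, sim_clean):
        # a profile whose row of scores is uniformly high (many pairings
        # scoring at the level of the self pair) fails the top-k rank rule,
        # but the strong reciprocal (column) evidence plus the self prior
        # keep the probabilistic self-alignment
        d = sim_clean
        matched = [(s, s) for s in d.core_samples]
        cis = run_cis_tests(d.matA, d.matB, d.candidates, matched)
        S = similarity_matrix(d.matA, d.matB, cis)
        target = "P0001"
        ti, tj = S.row_ids.index(target), S.col_ids.index(target)
        rng = np.random.default_rng(99)
        others = [j for j in range(len(S.col_ids)) if j != tj]
        elevated = rng.choice(others, size=30, replace=False)
        S.scores[ti, elevated] = S.scores[ti, tj] + rng.normal(0, 0.002, size=30)
        assert np.sum(S.scores[ti, :] > S.scores[ti, tj]) > 7  # out of the top 5%

        rank_res = modmatcher_align(S)
        prob_res = promodmatcher_align(
            S, MatchDecisionConfig(seed=7), d.matA, d.matB, cis, matched=matched
        )
        assert target not in rank_res.self_aligned_ids()
        assert target in prob_res.self_aligned_ids()
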