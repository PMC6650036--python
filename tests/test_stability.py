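"""Stability estimators: worked examples, independent oracles, invariances."""

import statistics
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    cv_analysis,
    genorm,
    linearize,
    normfinder,
    pairwise_dct,
    pearson_matrix,
    sd_cq,
)

from conftest import make_matrix

# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def oracle_genorm_m(values: pd.DataFrame) -> dict[str, float]:
    """M per gene via the definition: mean over partners of the SD of
    per-sample log2 ratios of relative quantities."""
    q = {g: [2.0 ** (-c) for c in values.loc[g]] for g in values.index}
    m = {}
    for g in values.index:
        sds = []
        for h in values.index:
            if h == g:
                continue
            ratios = [np.log2(a / b) for a, b in zip(q[g], q[h])]
            sds.append(statistics.stdev(ratios))
        m[g] = sum(sds) / len(sds)
    return m


def oracle_pairwise_table(values: pd.DataFrame, gene: str) -> float:
    """Mean SD of Cq differences for one gene, built column by column the way
    the spreadsheet example lays it out (self column of zeros excluded)."""
    sds = []
    for other in values.index:
        if other == gene:
            continue
        diffs = [values.at[gene, s] - values.at[other, s] for s in values.columns]
        sds.append(statistics.stdev(diffs))
    return sum(sds) / len(sds)


def random_matrix(rng, n_genes, n_samples):
    values = rng.uniform(18.0, 28.0, size=(n_genes, n_samples))
    groups = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    return make_matrix(values, groups)


# ---------------------------------------------------------------------------
# CV analysis
# ---------------------------------------------------------------------------


class TestCV:
    def test_constant_gene_scores_zero_and_ranks_first(self):
        m = make_matrix([[20, 20, 20], [20, 21, 22]], "AAB")
        table = cv_analysis(linearize(m))
        assert table.scores["g1"] == pytest.approx(0.0)
        assert table.ranks["g1"] == 1

    def test_hand_arithmetic_quantities_1_2_3(self):
        # quantities (1, 2, 3): sample SD = 1, mean = 2 -> CV 50%
        q = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        assert cv_analysis(q).scores["g"] == pytest.approx(50.0)

    def test_groups_are_ignored(self):
        values = [[20.0, 23.0, 21.0, 22.0]]
        a = cv_analysis(linearize(make_matrix(values, "AABB")))
        b = cv_analysis(linearize(make_matrix(values, "ABAB")))
        assert a.scores["g1"] == b.scores["g1"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            cv_analysis(pd.DataFrame([[1.0]], index=["g"], columns=["s"]))


class TestSdCq:
    def test_constant_gene_unflagged(self):
        m = make_matrix([[20, 20, 20], [20, 22, 24]], "AAB")
        table = sd_cq(m)
        assert table.scores["g1"] == 0.0 and not table.flags["g1"]

    def test_two_cycle_spread_is_flagged(self):
        m = make_matrix([[20.0, 22.0]], "AB")
        table = sd_cq(m)
        assert table.scores["g1"] == pytest.approx(np.sqrt(2.0))
        assert bool(table.flags["g1"])

    def test_sub_cycle_sd_can_hide_large_linear_cv(self):
        # Cq SD just below the 1-cycle screen, yet CV of 2^-Cq far above 50%:
        # the screen's blind spot on the quantity scale
        rng = np.random.default_rng(7)
        cq = 22.0 + 0.95 * np.sign(np.arange(24) % 2 - 0.5) + rng.normal(0, 0.05, 24)
        m = make_matrix([cq, rng.uniform(20, 21, 24)], "A" * 12 + "B" * 12)
        sd_table = sd_cq(m)
        cv_table = cv_analysis(linearize(m))
        assert sd_table.scores["g1"] < 1.0
        assert cv_table.scores["g1"] > 50.0


# ---------------------------------------------------------------------------
# GeNorm
# ---------------------------------------------------------------------------


class TestGeNorm:
    def test_duplicated_gene_pair_wins_with_identical_m(self):
        rng = np.random.default_rng(1)
        g1 = rng.uniform(19, 21, 8)
        g3 = g1 + rng.normal(0, 1.0, 8)
        m = make_matrix([g1, g1.copy(), g3], "AAAABBBB")
        table, trace = genorm(m)
        assert set(trace.final_pair) == {"g1", "g2"}
        assert table.scores["g1"] == table.scores["g2"]
        assert table.scores["g1"] < table.scores["g3"]
        assert table.ranks["g1"] == table.ranks["g2"] == 1

    def test_m_matches_bruteforce_definition(self):
        rng = np.random.default_rng(2)
        for n_genes, n_samples in [(4, 6), (5, 9), (6, 12)]:
            m = random_matrix(rng, n_genes, n_samples)
            expected = oracle_genorm_m(m.values)
            from refstab.stability import _genorm_m

            got = _genorm_m(m.values.to_numpy())
            for i, g in enumerate(m.genes):
                assert got[i] == pytest.approx(expected[g], abs=1e-12)

    def test_stepwise_elimination_matches_naive_replay(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, 10)
        table, trace = genorm(m)
        # replay the elimination with the oracle M at every step
        remaining = list(m.genes)
        for excluded, m_val in zip(trace.exclusion_order, trace.m_at_step):
            expected = oracle_genorm_m(m.values.loc[remaining])
            worst = max(remaining, key=lambda g: expected[g])
            assert worst == excluded
            assert m_val == pytest.approx(expected[excluded], abs=1e-12)
            remaining.remove(excluded)
        assert set(remaining) == set(trace.final_pair)
        ratio_sd = statistics.stdev(
            m.values.loc[trace.final_pair[0]] - m.values.loc[trace.final_pair[1]]
        )
        assert trace.final_m == pytest.approx(ratio_sd, abs=1e-12)

    def test_ranks_follow_elimination_order(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 5, 8)
        table, trace = genorm(m)
        for step, gene in enumerate(trace.exclusion_order):
            assert table.ranks[gene] == len(m.genes) - 1 - step

    def test_needs_three_genes(self):
        with pytest.raises(ValueError, match="at least 3 genes"):
            genorm(make_matrix([[20, 21], [22, 23]], "AB"))


# ---------------------------------------------------------------------------
# Pairwise dCt
# ---------------------------------------------------------------------------


class TestPairwiseDCt:
    def test_constant_offset_pair_scores_zero(self):
        g = np.array([20.0, 21.0, 19.5, 22.0])
        m = make_matrix([g, g + 3.0], "AABB")
        table = pairwise_dct(m)
        assert table.scores["g1"] == pytest.approx(0.0)
        assert table.scores["g2"] == pytest.approx(0.0)

    def test_matches_spreadsheet_style_oracle(self):
        rng = np.random.default_rng(5)
        for n_genes, n_samples in [(3, 4), (5, 8), (6, 12)]:
            m = random_matrix(rng, n_genes, n_samples)
            table = pairwise_dct(m)
            for g in m.genes:
                assert table.scores[g] == pytest.approx(
                    oracle_pairwise_table(m.values, g), abs=1e-12
                )

    def test_needs_two_genes(self):
        with pytest.raises(ValueError, match="at least 2 genes"):
            pairwise_dct(make_matrix([[20, 21]], "AB"))


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------


class TestNormFinder:
    def test_identical_genes_score_zero(self):
        base = np.array([20.0, 20.4, 19.8, 21.0, 20.2, 20.6])
        m = make_matrix([base, base, base, base], "AAABBB")
        res = normfinder(m)
        np.testing.assert_allclose(res.stability.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.intergroup_d.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.intragroup_var.to_numpy(), 0.0, atol=1e-12)

    def test_variance_decomposition_recovers_model_parameters(self):
        # simulate straight from the model: gene/group deviations + noise +
        # per-sample loading; the estimators must recover sigma2 and d
        rng = np.random.default_rng(11)
        k, reps, n = 6, 400, 40
        sigma = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        delta = np.array([[0.0, 0.5], [0.0, -0.5], [0.0, 0.3],
                          [0.0, -0.3], [0.0, 0.2], [0.0, -0.2]])
        sig2_est = np.zeros((k, 2))
        d_est = np.zeros((k, 2))
        for _ in range(reps):
            loading = rng.normal(0, 0.5, size=2 * n)
            groups = np.repeat([0, 1], n)
            y = (
                delta[:, groups]
                + rng.normal(0, sigma[:, None], size=(k, 2 * n))
                + loading
            )
            m = make_matrix(y + 25.0, "A" * n + "B" * n)
            res = normfinder(m)
            sig2_est += res.intragroup_var.to_numpy() / reps
            d_est += res.intergroup_d.to_numpy() / reps
        np.testing.assert_allclose(sig2_est, np.outer(sigma**2, [1, 1]), rtol=0.08)
        # d is estimated relative to the panel-average drift, centred across groups
        centred = delta - delta.mean(axis=0, keepdims=True)
        centred = centred - centred.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(d_est, centred, atol=0.02)

    def test_quiet_flat_gene_ranks_first(self):
        rng = np.random.default_rng(12)
        stable = 21.0 + rng.normal(0, 0.1, 12)
        drift1 = 20.0 + np.repeat([0.0, 1.0], 6) + rng.normal(0, 0.4, 12)
        drift2 = 23.0 + np.repeat([0.0, -0.8], 6) + rng.normal(0, 0.4, 12)
        noisy = 22.0 + rng.normal(0, 0.8, 12)
        m = make_matrix([stable, drift1, drift2, noisy], "A" * 6 + "B" * 6)
        res = normfinder(m)
        assert res.ranks["g1"] == 1

    def test_best_pair_beats_averaging_on_cancelling_drifts(self):
        # two genes drifting in opposite directions: their average is flat,
        # so the pair criterion should select them over any single-noise pair
        rng = np.random.default_rng(13)
        up = 20.0 + np.repeat([0.0, 0.8], 8) + rng.normal(0, 0.1, 16)
        down = 22.0 + np.repeat([0.0, -0.8], 8) + rng.normal(0, 0.1, 16)
        noisy1 = 21.0 + rng.normal(0, 0.7, 16)
        noisy2 = 23.0 + rng.normal(0, 0.7, 16)
        m = make_matrix([up, down, noisy1, noisy2], "A" * 8 + "B" * 8)
        res = normfinder(m)
        assert set(res.best_pair) == {"g1", "g2"}
        assert res.grouped_stability < res.stability.min()

    def test_contaminating_panel_changes_unrelated_rankings(self, developmental_matrix):
        # adding two high-variance drifting genes perturbs the ranking of
        # genes that did not change at all
        m = developmental_matrix
        core_genes = [g for g in m.genes if g not in ("GlycoG", "GlycoH", "TbpI")]
        res_core = normfinder(m.subset(core_genes))
        res_full = normfinder(m)
        rank_core = res_core.stability.rank()
        rank_full = res_full.stability[core_genes].rank()
        assert (rank_core != rank_full).any()

    def test_group_size_and_gene_count_preconditions(self):
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            normfinder(make_matrix(np.random.default_rng(0).uniform(20, 22, (3, 3)), "AAB"))
        with pytest.raises(ValueError, match="at least 3 genes"):
            normfinder(make_matrix(np.random.default_rng(0).uniform(20, 22, (2, 4)), "AABB"))


# ---------------------------------------------------------------------------
# shared invariances
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def base_matrix():
    rng = np.random.default_rng(21)
    return make_matrix(rng.uniform(18, 26, size=(5, 12)), "AAAABBBBCCCC")


class TestInvariances:
    @settings(derandomize=True, max_examples=15)
    @given(c=st.floats(-3, 3))
    def test_single_gene_shift_leaves_all_scores_unchanged(self, base_matrix, c):
        shift = np.zeros((5, 1))
        shift[2, 0] = c
        shifted = make_matrix(base_matrix.values.to_numpy() + shift, "AAAABBBBCCCC")

        np.testing.assert_allclose(
            genorm(shifted)[0].scores.to_numpy(),
            genorm(base_matrix)[0].scores.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(
            pairwise_dct(shifted).scores.to_numpy(),
            pairwise_dct(base_matrix).scores.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(
            normfinder(shifted).stability.to_numpy(),
            normfinder(base_matrix).stability.to_numpy(), atol=1e-10)
        # CV of 2^-Cq: the shift rescales that gene's quantities globally
        np.testing.assert_allclose(
            cv_analysis(linearize(shifted)).scores.to_numpy(),
            cv_analysis(linearize(base_matrix)).scores.to_numpy(), atol=1e-10)

    @settings(derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_per_sample_loading_invariance_except_cv(self, base_matrix, seed):
        rng = np.random.default_rng(seed)
        loading = rng.normal(0, 1.0, size=(1, 12))
        shifted = make_matrix(base_matrix.values.to_numpy() + loading, "AAAABBBBCCCC")

        np.testing.assert_allclose(
            genorm(shifted)[0].scores.to_numpy(),
            genorm(base_matrix)[0].scores.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(
            pairwise_dct(shifted).scores.to_numpy(),
            pairwise_dct(base_matrix).scores.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(
            normfinder(shifted).stability.to_numpy(),
            normfinder(base_matrix).stability.to_numpy(), atol=1e-10)
        # CV is NOT loading-invariant: a technical per-sample shift changes it
        if np.ptp(loading) > 1e-3:
            assert not np.allclose(
                cv_analysis(linearize(shifted)).scores.to_numpy(),
                cv_analysis(linearize(base_matrix)).scores.to_numpy(),
            )


# ---------------------------------------------------------------------------
# correlation structure and the co-regulation bias
# ---------------------------------------------------------------------------


class TestPearson:
    def test_duplicated_gene_correlates_perfectly(self):
        g = np.array([20.0, 21.0, 19.0, 22.0])
        m = make_matrix([g, g.copy(), g[::-1].copy()], "AABB")
        corr = pearson_matrix(linearize(m))
        assert corr.at["g1", "g2"] == pytest.approx(1.0)
        assert np.isnan(corr.at["g1", "g1"])

    def test_zero_variance_gene_is_undefined_not_one(self):
        m = make_matrix([[20, 20, 20, 20], [20, 21, 19, 22]], "AABB")
        corr = pearson_matrix(linearize(m))
        assert np.isnan(corr.at["g1", "g2"])

    def test_shared_block_genes_correlate_strongly(self, coreg_matrix):
        corr = pearson_matrix(linearize(coreg_matrix))
        assert corr.at["CoregA", "CoregB"] > 0.9

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="at least 3 samples"):
            pearson_matrix(pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"]))


class TestCoRegulationBias:
    def test_genorm_tops_the_pair_cv_bottoms_it(self, coreg_matrix):
        """Pairwise variation rewards a co-regulated unstable pair that
        overall-variation analysis correctly flags as the most variable."""
        table, trace = genorm(coreg_matrix)
        cv = cv_analysis(linearize(coreg_matrix))
        assert set(trace.final_pair) == {"CoregA", "CoregB"}
        assert table.ranks["CoregA"] == table.ranks["CoregB"] == 1
        worst_two = set(cv.ordered_genes()[-2:])
        assert worst_two == {"CoregA", "CoregB"}
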