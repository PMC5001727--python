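import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from brotree import (
    ExpressionDataset,
    SampleAnnotation,
    SyntheticSpec,
    bro_by_age_group,
    bro_score,
    bro_score_all,
    combine_subjects,
    pairwise_distances,
    permutation_null,
    simulate_expression,
    triplet_score,
    triplet_score_exhaustive,
)
from brotree.bro import DistancePairs, tree_distance_vector
from tests.conftest import random_dataset


def brute_spearman(x, y):
    """Independent oracle: explicit mid-ranks + Pearson on the ranks."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum()))


class TestPairwiseDistances:
    def test_two_samples_single_pair(self, tiny_ontology):
        ds = ExpressionDataset(
            ["g0"],
            [SampleAnnotation("s0", "a1", "d0"), SampleAnnotation("s1", "b1", "d0")],
            np.array([[1.0, 2.0]]),
        )
        dp = pairwise_distances(ds, tiny_ontology, "g0")
        assert dp.n_pairs == 1
        assert dp.tree_d[0] == 4
        assert dp.expr_d[0] == pytest.approx(1.0)

    def test_path_tree_identity(self, path_ontology, path_dataset):
        dp = pairwise_distances(path_dataset, path_ontology, "g0")
        np.testing.assert_array_equal(dp.tree_d, dp.expr_d)

    def test_within_region_pairs_have_zero_tree_distance(self, tiny_ontology):
        ds = ExpressionDataset(
            ["g0"],
            [SampleAnnotation("s0", "a1", "d0"), SampleAnnotation("s1", "a1", "d1")],
            np.array([[1.0, 5.0]]),
        )
        dp = pairwise_distances(ds, tiny_ontology, "g0")
        assert dp.tree_d[0] == 0

    def test_pair_count_formula(self, tree16):
        rng = np.random.default_rng(3)
        ds = random_dataset(tree16, 40, rng)
        assert len(tree_distance_vector(ds, tree16)) == 40 * 39 // 2

    def test_fewer_than_two_samples_errors(self, tiny_ontology):
        ds = ExpressionDataset(
            ["g0"], [SampleAnnotation("s0", "a1", "d0")], np.array([[1.0]])
        )
        with pytest.raises(ValueError):
            tree_distance_vector(ds, tiny_ontology)


class TestBroScore:
    def test_perfect_monotone_agreement(self, path_ontology, path_dataset):
        dp = pairwise_distances(path_dataset, path_ontology, "g0")
        assert bro_score(dp) == pytest.approx(1.0)

    def test_perfect_anti_agreement(self, path_ontology, path_dataset):
        dp = pairwise_distances(path_dataset, path_ontology, "g0")
        flipped = DistancePairs(dp.tree_d, dp.expr_d.max() - dp.expr_d, dp.n_samples)
        assert bro_score(flipped) == pytest.approx(-1.0)

    def test_tied_toy_instance_matches_midrank_oracle(self):
        tree_d = np.array([0, 2, 2, 4, 4, 4])
        expr_d = np.array([0.1, 0.1, 0.5, 0.5, 0.9, 0.9])
        dp = DistancePairs(tree_d, expr_d, 4)
        assert bro_score(dp) == pytest.approx(brute_spearman(tree_d, expr_d), abs=1e-12)

    def test_matches_oracle_on_small_random_instances(self, tree16):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            ds = random_dataset(tree16, n, rng)
            dp = pairwise_distances(ds, tree16, "g0")
            if np.ptp(dp.tree_d) == 0:
                continue
            assert bro_score(dp) == pytest.approx(
                brute_spearman(dp.tree_d, dp.expr_d), abs=1e-12
            )

    def test_zero_variance_undefined(self, tiny_ontology):
        ds = ExpressionDataset(
            ["g0"],
            [SampleAnnotation("s0", "a1", "d0"), SampleAnnotation("s1", "b1", "d0")],
            np.array([[2.0, 2.0]]),
        )
        dp = pairwise_distances(ds, tiny_ontology, "g0")
        assert np.isnan(bro_score(dp))

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 5.0),
        st.floats(-3.0, 3.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_increasing_transforms(self, seed, scale, shift):
        """Rank statistic: strictly increasing maps of either distance leave it fixed."""
        rng = np.random.default_rng(seed)
        tree_d = rng.integers(0, 5, size=20)
        expr_d = rng.normal(size=20) ** 2
        if np.ptp(tree_d) == 0:
            return
        base = bro_score(_dp(tree_d, expr_d))
        warped = _dp(tree_d * 3 + 1, np.exp(scale * expr_d + shift))
        assert bro_score(warped) == pytest.approx(base, abs=1e-12)


def _dp(tree_d, expr_d):
    dp = DistancePairs.__new__(DistancePairs)
    dp.tree_d = np.asarray(tree_d)
    dp.expr_d = np.asarray(expr_d, dtype=float)
    dp.n_samples = 0
    return dp


class TestBroScoreAll:
    def test_duplicate_genes_identical_scores(self, small_dataset, tree16):
        ds, _ = small_dataset
        out = bro_score_all(ds, tree16, genes=["g0000", "g0000"])
        assert out.bro.iloc[0] == out.bro.iloc[1]

    def test_gene_order_equivariance(self, small_dataset, tree16):
        ds, _ = small_dataset
        fwd = bro_score_all(ds, tree16, genes=["g0000", "g0001"])
        rev = bro_score_all(ds, tree16, genes=["g0001", "g0000"])
        assert fwd.set_index("gene_id").bro.to_dict() == rev.set_index("gene_id").bro.to_dict()

    def test_null_genes_center_on_zero(self, tree16):
        spec = SyntheticSpec(
            n_genes=200, n_donors=2, samples_per_region_per_donor=2,
            tree_signal_scale=0.0, noise_scale=1.0, seed=5,
        )
        ds, _ = simulate_expression(spec, tree16)
        out = bro_score_all(ds, tree16)
        scores = out.bro.to_numpy()
        sem = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * sem


class TestTripletScore:
    def test_path_tree_perfect_agreement(self, path_ontology, path_dataset):
        assert triplet_score_exhaustive(path_dataset, path_ontology, "g0") == pytest.approx(1.0)

    def test_anti_monotone_scores_zero(self, tiny_ontology):
        # within-region pair far apart in expression, cross-region pair close:
        # every qualifying triplet is ordered oppositely in the two distances
        ds = ExpressionDataset(
            ["g0"],
            [
                SampleAnnotation("s0", "a1", "d0"),
                SampleAnnotation("s1", "a1", "d0"),
                SampleAnnotation("s2", "b1", "d0"),
            ],
            np.array([[0.0, 10.0, 0.1]]),
        )
        assert triplet_score_exhaustive(ds, tiny_ontology, "g0") == pytest.approx(0.0)

    def test_sampled_matches_exhaustive(self, tree16):
        rng = np.random.default_rng(13)
        ds = random_dataset(tree16, 15, rng)
        exact = triplet_score_exhaustive(ds, tree16, "g0")
        approx = triplet_score(ds, tree16, "g0", n_triplets=10**5, seed=99)
        assert approx == pytest.approx(exact, abs=0.02)

    def test_reproducible_by_seed(self, tree16):
        rng = np.random.default_rng(14)
        ds = random_dataset(tree16, 20, rng)
        a = triplet_score(ds, tree16, "g0", n_triplets=10**4, seed=1)
        b = triplet_score(ds, tree16, "g0", n_triplets=10**4, seed=1)
        assert a == b


class TestPermutationNull:
    def test_add_one_rule_single_permutation(self, tree16):
        rng = np.random.default_rng(17)
        ds = random_dataset(tree16, 10, rng)
        _, tab = permutation_null(ds, tree16, n_permutations=1, seed=0)
        assert tab.p_empirical.iloc[0] in (0.5, 1.0)

    def test_score_below_median_has_large_p(self, tree16):
        spec = SyntheticSpec(
            n_genes=50, n_donors=2, samples_per_region_per_donor=2,
            tree_signal_scale=0.0, noise_scale=1.0, seed=23,
        )
        ds, _ = simulate_expression(spec, tree16)
        null, tab = permutation_null(ds, tree16, n_permutations=20, seed=24)
        med = np.median(null.scores)
        below = tab[tab.bro < med]
        assert (below.p_empirical > 0.5).all()

    def test_p_floor_is_add_one_bound(self, tree16):
        spec = SyntheticSpec(
            n_genes=20, n_donors=2, samples_per_region_per_donor=2,
            tree_signal_scale=3.0, noise_scale=0.3, seed=29,
        )
        ds, _ = simulate_expression(spec, tree16)
        null, tab = permutation_null(ds, tree16, n_permutations=10, seed=30)
        assert tab.p_empirical.min() >= 1 / (len(null.scores) + 1)

    def test_zero_variance_gene_excluded_not_fatal(self, tree16):
        rng = np.random.default_rng(31)
        ds = random_dataset(tree16, 12, rng, n_genes=3)
        ds.values[1] = 7.0  # flat gene
        _, tab = permutation_null(ds, tree16, n_permutations=5, seed=0)
        assert tab.status.iloc[1] == "zero_variance"
        assert np.isnan(tab.p_empirical.iloc[1])
        assert tab.status.iloc[0] == "ok"

    def test_per_gene_mode_runs(self, tree16):
        rng = np.random.default_rng(33)
        ds = random_dataset(tree16, 12, rng, n_genes=4)
        _, tab = permutation_null(ds, tree16, n_permutations=20, seed=0, pooled=False)
        assert tab.p_empirical.notna().all()


class TestCombineSubjects:
    def test_single_donor_modes_agree(self, tree16):
        rng = np.random.default_rng(41)
        ds = random_dataset(tree16, 20, rng, n_genes=3)
        pooled, _ = combine_subjects(ds, tree16, mode="pooled")
        per_subj, _ = combine_subjects(ds, tree16, mode="per_subject_mean")
        np.testing.assert_allclose(pooled.bro, per_subj.bro, atol=1e-12)

    def test_identical_donors_mean_equals_either(self, tree16):
        rng = np.random.default_rng(43)
        ds1 = random_dataset(tree16, 15, rng, n_genes=3)
        samples = ds1.samples + [
            SampleAnnotation(s.sample_id + "_b", s.region_id, "d1") for s in ds1.samples
        ]
        ds2 = ExpressionDataset(ds1.genes, samples, np.hstack([ds1.values, ds1.values]))
        summary, per_donor = combine_subjects(ds2, tree16, mode="per_subject_mean")
        np.testing.assert_allclose(summary.bro, per_donor["d0"], atol=1e-12)
        np.testing.assert_allclose(per_donor["d0"], per_donor["d1"], atol=1e-12)

    def test_shared_signal_gives_correlated_donor_scores(self, tree16):
        spec = SyntheticSpec(
            n_genes=60, n_donors=4, samples_per_region_per_donor=2,
            tree_signal_scale=1.5, donor_scale=0.3, noise_scale=1.0, seed=47,
        )
        ds, _ = simulate_expression(spec, tree16)
        _, per_donor = combine_subjects(ds, tree16, mode="per_subject_mean")
        donors = list(per_donor.columns)
        rhos = [
            spearmanr(per_donor[a], per_donor[b]).statistic
            for i, a in enumerate(donors)
            for b in donors[i + 1 :]
        ]
        assert np.mean(rhos) > 0.5


class TestBroByAgeGroup:
    def test_identical_groups_flat_trajectory(self, small_dataset, tree16):
        ds, _ = small_dataset
        traj, _ = bro_by_age_group([("g1", ds), ("g2", ds)], tree16)
        assert traj.mean_bro.iloc[0] == pytest.approx(traj.mean_bro.iloc[1])

    def test_single_group_reduces_to_score_all(self, small_dataset, tree16):
        ds, _ = small_dataset
        traj, per_gene = bro_by_age_group([("only", ds)], tree16)
        direct = bro_score_all(ds, tree16)
        np.testing.assert_allclose(per_gene["only"], direct.bro, atol=1e-12)
        assert traj.mean_bro.iloc[0] == pytest.approx(np.nanmean(direct.bro))
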