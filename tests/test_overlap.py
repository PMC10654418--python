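"""Overlap-statistics tests: Schoener's D against direct summation,
directional overlap, permutation-null calibration, BH step-up, group
comparison, and co-occurrence summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seasdm as ss
from seasdm.overlap import _d_from_k, pair_group_labels


def schoener_direct(a, b) -> float:
    """Independent oracle: direct |p_A - p_B| summation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return 1.0 - 0.5 * np.sum(np.abs(a / a.sum() - b / b.sum()))


def kruskal_brute_force(groups_of_values) -> float:
    """H from first principles with mid-rank ties."""
    allv = np.concatenate(groups_of_values)
    ranks = stats.rankdata(allv)
    n = allv.size
    h = 0.0
    start = 0
    for g in groups_of_values:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie_corr


def nested_pair(m: int = 50):
    """A occupies m sites, all inside B's 2m sites."""
    a = np.zeros(3 * m, dtype=int)
    b = np.zeros(3 * m, dtype=int)
    a[:m] = 1
    b[: 2 * m] = 1
    return a, b


class TestSchoenerD:
    def test_nested_half_overlap_worked_example(self):
        a, b = nested_pair()
        assert ss.schoener_d(a, b) == pytest.approx(0.5)

    def test_identical_and_disjoint_extremes(self):
        v = np.array([1, 0, 1, 0, 1])
        assert ss.schoener_d(v, v) == 1.0
        assert ss.schoener_d(v, 1 - v) == 0.0

    def test_hand_computed_closed_form(self):
        # n_A=3, n_B=2, one shared site -> 1 - (|1/3-1/2| + 2/3 + 1/2)/2 = 1/3
        a = np.array([1, 1, 1, 0, 0])
        b = np.array([1, 0, 0, 1, 0])
        assert ss.schoener_d(a, b) == pytest.approx(1.0 / 3.0)
        assert _d_from_k(1, 3, 2) == pytest.approx(1.0 / 3.0)

    def test_matches_direct_summation_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            a = (rng.uniform(size=n) < 0.4).astype(int)
            b = (rng.uniform(size=n) < 0.4).astype(int)
            if a.sum() == 0 or b.sum() == 0:
                continue
            d = ss.schoener_d(a, b)
            assert d == pytest.approx(schoener_direct(a, b))
            assert d == pytest.approx(_d_from_k(int((a & b).sum()), a.sum(), b.sum()))
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(ss.schoener_d(b, a))

    def test_equal_prevalence_reduces_to_shared_over_total(self, rng):
        for _ in range(50):
            n, k = 40, 8
            a = np.zeros(n, dtype=int)
            b = np.zeros(n, dtype=int)
            a[rng.choice(n, k, replace=False)] = 1
            b[rng.choice(n, k, replace=False)] = 1
            shared = int((a & b).sum())
            assert ss.schoener_d(a, b) == pytest.approx(shared / k)

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            ss.schoener_d([0, 0, 0], [1, 0, 1])


class TestDirectionalOverlap:
    def test_nested_pair_is_fully_asymmetric(self):
        a, b = nested_pair()
        assert ss.directional_overlap(a, b) == pytest.approx(100.0)
        assert ss.directional_overlap(b, a) == pytest.approx(50.0)

    def test_self_overlap_is_total(self):
        v = np.array([1, 0, 1])
        assert ss.directional_overlap(v, v) == 100.0

    def test_one_of_three_shared(self):
        a = np.array([1, 1, 1, 0])
        b = np.array([1, 0, 0, 1])
        assert ss.directional_overlap(a, b) == pytest.approx(100.0 / 3.0)

    def test_empty_focal_rejected(self):
        with pytest.raises(ValueError):
            ss.directional_overlap([0, 0], [1, 0])


class TestPermutationTest:
    def test_constant_vector_is_permutation_invariant(self):
        a = np.ones(50, dtype=int)
        b = np.array([1, 0] * 25)
        _, p = ss.permutation_test_d(a, b, ss.PermutationPlan(n_permutations=500, seed=0))
        assert p == 1.0

    def test_identical_vectors_are_detected(self):
        rng = np.random.default_rng(3)
        v = (rng.uniform(size=500) < 0.2).astype(int)
        _, p = ss.permutation_test_d(v, v, ss.PermutationPlan(n_permutations=2000, seed=1))
        assert p < 0.05

    def test_hypergeometric_null_matches_explicit_shuffling(self, rng):
        a = (rng.uniform(size=200) < 0.3).astype(int)
        b = (rng.uniform(size=200) < 0.4).astype(int)
        n, n_a, n_b = 200, int(a.sum()), int(b.sum())
        gen = np.random.default_rng(7)
        k_fast = gen.hypergeometric(n_b, n - n_b, n_a, size=4000)
        k_slow = np.array([(gen.permutation(a) & b).sum() for _ in range(4000)])
        # same discrete null distribution (chi-square on pooled support)
        support = np.arange(min(k_fast.min(), k_slow.min()), max(k_fast.max(), k_slow.max()) + 1)
        f_fast = np.array([(k_fast == s).sum() for s in support])
        f_slow = np.array([(k_slow == s).sum() for s in support])
        keep = (f_fast + f_slow) >= 10
        chi2 = np.sum((f_fast[keep] - f_slow[keep]) ** 2 / (f_fast[keep] + f_slow[keep]))
        assert chi2 < 2 * keep.sum() + 6 * np.sqrt(2 * keep.sum())

    def test_exact_shuffle_path_agrees_in_decision(self, rng):
        v = (rng.uniform(size=300) < 0.25).astype(int)
        w = v.copy()
        plan = ss.PermutationPlan(n_permutations=500, seed=5, exact_shuffle=True)
        _, p = ss.permutation_test_d(v, w, plan)
        assert p < 0.05

    def test_type_i_error_is_calibrated(self):
        # independent Bernoulli(0.3) species: rejections at alpha=0.05
        # should land near 0.05 over replicate datasets
        master = np.random.default_rng(17)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            a = (master.uniform(size=500) < 0.3).astype(int)
            b = (master.uniform(size=500) < 0.3).astype(int)
            if a.sum() == 0 or b.sum() == 0:
                continue
            _, p = ss.permutation_test_d(
                a, b, ss.PermutationPlan(n_permutations=2000, seed=1000 + i))
            rejections += p <= 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.04

    def test_choice_of_permuted_species_does_not_matter(self, rng):
        a = (rng.uniform(size=400) < 0.3).astype(int)
        b = (rng.uniform(size=400) < 0.5).astype(int)
        plan = ss.PermutationPlan(n_permutations=5000, seed=11)
        _, p_ab = ss.permutation_test_d(a, b, plan)
        _, p_ba = ss.permutation_test_d(b, a, plan)
        assert abs(p_ab - p_ba) < 0.05


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ss.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(ss.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            ss.bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05])

    def test_never_below_raw_and_order_invariant(self, rng):
        p = rng.uniform(size=30)
        adj = ss.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        perm = rng.permutation(30)
        np.testing.assert_allclose(ss.bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.bh_adjust([0.1, 1.2])


@pytest.fixture(scope="module")
def result(matrix):
    plan = ss.PermutationPlan(n_permutations=2000, seed=6)
    return ss.pairwise_overlap(matrix, plan), matrix


class TestPairwiseOverlap:

    def test_eleven_species_yield_fifty_five_pairs(self, small_env, community):
        table, _ = ss.simulate_survey(
            small_env, community, ss.SurveySpec(n_sites=800, seed=31))
        m = ss.prepare_survey(table, min_occurrence=1, seed=0)
        assert len(m.species) == 11
        res = ss.pairwise_overlap(m, ss.PermutationPlan(n_permutations=200, seed=0))
        assert len(res.pair_table) == 55

    def test_identical_columns_give_unit_d(self):
        values = pd.DataFrame({"a": [1, 0, 1, 0, 1], "b": [1, 0, 1, 0, 1]},
                              index=[f"s{i}" for i in range(5)])
        sites = pd.DataFrame({"site_id": values.index, "x": 0.0, "y": 0.0, "year": 2020})
        m = ss.OccurrenceMatrix(values=values, sites=sites)
        res = ss.pairwise_overlap(m, ss.PermutationPlan(n_permutations=100, seed=0))
        assert res.pair_table["d"].iloc[0] == 1.0
        assert res.d_matrix.loc["a", "b"] == 1.0

    def test_matrices_are_consistent_with_pair_table(self, result):
        res, m = result
        for _, row in res.pair_table.iterrows():
            assert res.d_matrix.loc[row["species_a"], row["species_b"]] == row["d"]
        np.testing.assert_allclose(res.d_matrix.to_numpy(), res.d_matrix.to_numpy().T)
        assert np.diag(res.d_matrix.to_numpy()).tolist() == [1.0] * len(res.species)
        assert np.diag(res.directional.to_numpy()).tolist() == [100.0] * len(res.species)
        assert (res.pair_table["p_adj"] >= res.pair_table["p_raw"] - 1e-15).all()

    def test_mean_d_is_the_unweighted_mean_over_partners(self, result):
        res, _ = result
        for sp in res.species:
            assert res.mean_d[sp] == pytest.approx(np.mean(
                [res.d_matrix.loc[sp, o] for o in res.species if o != sp]))

    def test_unassociated_matrix_rejects_about_five_percent_before_bh(self, rng):
        n_sites, n_species = 400, 10
        values = pd.DataFrame(
            (rng.uniform(size=(n_sites, n_species)) < 0.3).astype(int),
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(n_species)])
        sites = pd.DataFrame({"site_id": values.index, "x": 0.0, "y": 0.0, "year": 2020})
        m = ss.OccurrenceMatrix(values=values, sites=sites)
        res = ss.pairwise_overlap(m, ss.PermutationPlan(n_permutations=2000, seed=9))
        raw_rate = (res.pair_table["p_raw"] <= 0.05).mean()
        assert raw_rate <= 0.2  # 45 pairs: a loose bound around the nominal 5%
        assert res.n_significant <= (res.pair_table["p_raw"] <= 0.05).sum()


class TestGroupComparison:
    def _result_with_d(self, d_by_pair):
        """OverlapResult stub from explicit per-pair D values."""
        species = sorted({s for pair in d_by_pair for s in pair[:2]})
        rows = [{"species_a": a, "species_b": b, "d": d, "p_raw": 0.5}
                for a, b, d in d_by_pair]
        table = pd.DataFrame(rows)
        table["p_adj"] = table["p_raw"]
        table["significant"] = False
        dm = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
        return ss.OverlapResult(species=species, d_matrix=dm, directional=dm,
                                pair_table=table, mean_d=pd.Series(dtype=float),
                                alpha=0.05)

    def _full_community(self, rng, d_values=None):
        species = [f"a{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
        groups = {s: (ss.ANGIOSPERM if s.startswith("a") else ss.CHAROPHYTE)
                  for s in species}
        pairs = list(itertools.combinations(species, 2))
        if d_values is None:
            d_values = rng.uniform(size=len(pairs))
        d_by_pair = [(a, b, d) for (a, b), d in zip(pairs, d_values)]
        return self._result_with_d(d_by_pair), groups

    def test_h_matches_brute_force_ranking(self, rng):
        res, groups = self._full_community(rng)
        h, p, means = ss.group_overlap_comparison(res, groups)
        labels = pair_group_labels(res, groups)
        samples = [res.pair_table["d"][labels == g].to_numpy()
                   for g in sorted(labels.unique())]
        assert h == pytest.approx(kruskal_brute_force(samples))
        assert set(means.index) == {"between", "within-angiosperm", "within-charophyte"}

    def test_separated_groups_reach_the_maximum_h(self, rng):
        res, groups = self._full_community(rng)
        labels = pair_group_labels(res, groups)
        d = np.empty(len(labels))
        d[(labels == "between").to_numpy()] = 0.1
        d[(labels == "within-angiosperm").to_numpy()] = 0.5
        d[(labels == "within-charophyte").to_numpy()] = 0.9
        res.pair_table["d"] = d + rng.uniform(0, 1e-3, size=len(d))  # break ties
        h, p, _ = ss.group_overlap_comparison(res, groups)
        sizes = labels.value_counts()
        samples = [res.pair_table["d"][labels == g].to_numpy()
                   for g in sorted(labels.unique())]
        assert h == pytest.approx(kruskal_brute_force(samples))
        assert p < 0.01

    def test_identical_d_values_give_zero_h(self, rng):
        res, groups = self._full_community(rng, d_values=None)
        res.pair_table["d"] = 0.3
        h, p, _ = ss.group_overlap_comparison(res, groups)
        assert h == 0.0 and p == 1.0

    def test_null_p_values_are_roughly_uniform(self, rng):
        pvals = []
        for _ in range(150):
            res, groups = self._full_community(rng)
            _, p, _ = ss.group_overlap_comparison(res, groups)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCoOccurringCounts:
    def _matrix(self, rows, columns):
        values = pd.DataFrame(rows, columns=columns,
                              index=[f"s{i}" for i in range(len(rows))])
        sites = pd.DataFrame({"site_id": values.index, "x": 0.0, "y": 0.0, "year": 2020})
        return ss.OccurrenceMatrix(values=values, sites=sites)

    def test_loner_species(self):
        m = self._matrix([[1, 0], [1, 0], [0, 1]], ["focal", "other"])
        props, mean, sd = ss.co_occurring_counts(m, "focal")
        assert props.to_dict() == {0: 1.0}
        assert mean == 0.0 and sd == 0.0

    def test_always_one_companion(self):
        m = self._matrix([[1, 1, 0], [1, 0, 1]], ["focal", "b", "c"])
        props, mean, sd = ss.co_occurring_counts(m, "focal")
        assert mean == 1.0 and sd == 0.0

    def test_toy_count_distribution(self):
        # focal present at 5 sites with 0,1,1,2,3 companions -> mean 1.4
        rows = [
            [1, 0, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 0], [1, 1, 1, 1],
        ]
        m = self._matrix(rows, ["focal", "b", "c", "d"])
        props, mean, sd = ss.co_occurring_counts(m, "focal")
        assert mean == pytest.approx(1.4)
        assert props.sum() == pytest.approx(1.0)
        assert props.to_dict() == {0: 0.2, 1: 0.4, 2: 0.2, 3: 0.2}

    def test_absent_focal_rejected(self):
        m = self._matrix([[0, 1]], ["focal", "b"])
        with pytest.raises(ValueError):
            ss.co_occurring_counts(m, "focal")


class TestRichnessProfile:
    def test_all_zero_matrix_gives_zero_profile(self):
        values = pd.DataFrame(0, index=[f"s{i}" for i in range(20)], columns=["a", "b"])
        sites = pd.DataFrame({"site_id": values.index, "x": 0.0, "y": 0.0, "year": 2020})
        m = ss.OccurrenceMatrix(values=values, sites=sites,
                                groups={"a": ss.ANGIOSPERM, "b": ss.CHAROPHYTE})
        depth = pd.Series(np.linspace(0, 9, 20), index=values.index)
        prof = ss.richness_profile(m, depth, n_bins=5)
        assert (prof["mean_richness"] == 0).all()

    def test_depth_filter_excludes_deep_sites(self, matrix, small_env):
        feats = ss.extract_env(matrix, small_env)
        depth = feats["depth"]
        prof = ss.richness_profile(matrix, depth, n_bins=8, max_depth_filter=10.0)
        assert prof["bin_center"].max() <= 10.0 + 1e-9

    def test_charophyte_richness_declines_with_depth(self, matrix, small_env):
        feats = ss.extract_env(matrix, small_env)
        prof = ss.richness_profile(matrix, feats["depth"], n_bins=6)
        charo = prof[prof["group"] == ss.CHAROPHYTE].sort_values("bin_center")
        if len(charo) >= 3:
            rho = stats.spearmanr(charo["bin_center"], charo["mean_richness"]).statistic
            assert rho < 0
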