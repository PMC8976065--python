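"""Enrichment scoring and moderated statistics against independent oracles:
direct-summation ssGSEA, long-hand pooled variance, exhaustive permutation
enumeration, and the step-up FDR recursion."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cistroscreen.enrich import (
    SsgseaConfig,
    bh_fdr,
    common_pathways,
    normalize_scores,
    ora_hypergeometric,
    permutation_p,
    samroc_analysis,
    samroc_stat,
    ssgsea_matrix,
    ssgsea_score,
)
from cistroscreen.errors import ConfigError, DataError
from cistroscreen.io import ExpressionMatrix, GeneSetCollection


def ssgsea_oracle(values: dict, members, alpha: float) -> float:
    """Plain-loop direct summation of the running-sum definition."""
    order = sorted(values, key=lambda g: (-values[g], g))
    n = len(order)
    members = set(members) & set(order)
    denom_in = sum((n - i + 1) ** alpha for i, g in enumerate(order, 1) if g in members)
    n_out = n - len(members)
    es, cum_in, cum_out = 0.0, 0.0, 0
    for i, g in enumerate(order, 1):
        if g in members:
            cum_in += (n - i + 1) ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


class TestSsgsea:
    def test_single_top_gene_alpha_zero(self):
        expr = {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}
        es = ssgsea_score(expr, ["g1"], SsgseaConfig(alpha=0))
        assert es == pytest.approx(1 + 2 / 3 + 1 / 3 + 0)

    def test_single_bottom_gene_is_mirror(self):
        expr = {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}
        assert ssgsea_score(expr, ["g4"], SsgseaConfig(alpha=0)) == pytest.approx(-2.0)

    def test_set_equal_to_universe_rejected(self):
        with pytest.raises(DataError):
            ssgsea_score({"g1": 1.0, "g2": 2.0}, ["g1", "g2"])

    def test_disjoint_set_rejected(self):
        with pytest.raises(DataError):
            ssgsea_score({"g1": 1.0, "g2": 2.0}, ["zz"])

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_random_instances_match_direct_summation(self, alpha):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(3, 51))
            genes = [f"g{i}" for i in range(n)]
            values = {g: float(rng.normal()) for g in genes}
            k = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=k, replace=False))
            got = ssgsea_score(values, members, SsgseaConfig(alpha=alpha))
            assert got == pytest.approx(ssgsea_oracle(values, members, alpha), rel=1e-12, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(30)]
        values = {g: float(rng.uniform(1, 100)) for g in genes}
        members = genes[::4]
        base = ssgsea_score(values, members)
        for transform in (np.log, np.sqrt, lambda x: 3 * x + 7):
            transformed = {g: float(transform(v)) for g, v in values.items()}
            assert ssgsea_score(transformed, members) == pytest.approx(base, rel=1e-12)


class TestNormalize:
    def test_global_minmax(self):
        df = pd.DataFrame({"s1": [2.0, 4.0], "s2": [6.0, 4.0]})
        out = normalize_scores(df)
        assert out.to_numpy().tolist() == [[0.0, 1.0], [0.5, 0.5]]

    def test_unit_range_unchanged(self):
        df = pd.DataFrame({"s1": [0.0, 0.25], "s2": [1.0, 0.5]})
        pd.testing.assert_frame_equal(normalize_scores(df), df)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DataError):
            normalize_scores(pd.DataFrame({"s1": [1.0], "s2": [1.0]}))


class TestSamrocStat:
    def test_identical_groups_give_zero(self):
        assert samroc_stat([1, 2, 3], [1, 2, 3]) == 0.0

    def test_longhand_pooled_variance_case(self):
        # A={2,4}, B={1,3}: pooled var = (2+2)/2 = 2, s = sqrt(1*2) = sqrt(2)
        assert samroc_stat([2, 4], [1, 3], s0=0.0) == pytest.approx(1 / math.sqrt(2))

    def test_fudge_factor_shrinks_magnitude_monotonically(self):
        ds = [abs(samroc_stat([2, 4], [1, 3], s0=s0)) for s0 in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_equals_pooled_t_statistic_when_s0_zero(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(23)
        for _ in range(20):
            a = rng.normal(size=4)
            b = rng.normal(loc=0.5, size=4)
            t = ttest_ind(a, b, equal_var=True).statistic
            assert samroc_stat(a, b, s0=0.0) == pytest.approx(t, rel=1e-12)

    def test_zero_scale_rejected(self):
        with pytest.raises(DataError):
            samroc_stat([1, 1], [1, 1], s0=0.0)


class TestPermutationP:
    def test_exhaustive_enumeration_example(self):
        d = samroc_stat([10, 11], [0, 1])
        p = permutation_p(d, [10, 11, 0, 1], n_a=2)
        # 6 label splits; the observed split and its mirror attain max |d*|
        assert p == pytest.approx(3 / 7)

    def test_exhaustive_matches_independent_enumeration(self):
        pooled = [5.0, 2.0, 8.0, 1.0, 7.0, 3.0]
        d_obs = samroc_stat(pooled[:3], pooled[3:])
        got = permutation_p(d_obs, pooled, n_a=3)
        arr = np.array(pooled)
        count = 0
        splits = list(combinations(range(6), 3))
        for idx in splits:
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            if abs(samroc_stat(arr[mask], arr[~mask])) >= abs(d_obs) - 1e-12:
                count += 1
        assert got == pytest.approx((1 + count) / (1 + len(splits)))

    def test_identical_groups_give_p_one(self):
        d = samroc_stat([2.0, 2.0, 3.0], [2.0, 2.0, 3.0], s0=1.0)
        p = permutation_p(d, [2.0, 2.0, 3.0] * 2, n_a=3, s0=1.0)
        assert p == 1.0

    def test_sampled_branch_is_seeded(self):
        rng = np.random.default_rng(31)
        pooled = rng.normal(size=12).tolist()  # C(12,6) = 924 > 200 -> sampled
        d = samroc_stat(pooled[:6], pooled[6:])
        p1 = permutation_p(d, pooled, n_a=6, n_permutations=300, seed=5)
        p2 = permutation_p(d, pooled, n_a=6, n_permutations=300, seed=5)
        assert p1 == p2
        assert 0 < p1 <= 1


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_stepup_longhand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.5])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(37)
        p = rng.uniform(size=25)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= 0).all()
        assert ((0 <= q) & (q <= 1)).all()

    def test_matches_longhand_stepup(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(size=30)
        n = len(p)
        order = np.argsort(p)
        q_long = np.empty(n)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = n - rank_from_end
            prev = min(prev, n * p[i] / rank)
            q_long[i] = prev
        np.testing.assert_allclose(bh_fdr(p), q_long, rtol=1e-12)


def _samroc_results():
    rng = np.random.default_rng(43)
    sets = [f"S{i}" for i in range(6)]
    scores = pd.DataFrame(
        rng.uniform(size=(6, 8)), index=sets,
        columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
    )
    scores.loc["S0", ["a0", "a1", "a2", "a3"]] += 2.0
    groups = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
    return samroc_analysis(scores, groups, "A", "B", seed=1)


class TestCommonPathways:
    def test_strict_fdr_bounds(self):
        res = _samroc_results()
        t1 = res.table.copy()
        t1["q"] = [0.07, 0.075, 0.5, 0.5, 0.5, 0.5]
        t2 = res.table.copy()
        t2["q"] = [0.0005, 0.0005, 0.0005, 0.5, 0.5, 0.5]
        r1 = type(res)(t1, res.s0, "A", "B")
        r2 = type(res)(t2, res.s0, "A", "B")
        shared = common_pathways(r1, r2, fdr_1=0.075, fdr_2=0.001)
        # S0 (0.07, 0.0005) is in; S1 (0.075, ...) is excluded by the strict bound
        assert list(shared.index) == ["S0"]

    def test_disjoint_significance_gives_empty(self):
        res = _samroc_results()
        t1 = res.table.copy()
        t1["q"] = [0.01] + [0.9] * 5
        t2 = res.table.copy()
        t2["q"] = [0.9] * 5 + [0.0001]
        shared = common_pathways(
            type(res)(t1, res.s0, "A", "B"), type(res)(t2, res.s0, "A", "B")
        )
        assert shared.empty


class TestOra:
    def test_toy_case_exact(self):
        universe = [f"u{i}" for i in range(10)]
        coll = GeneSetCollection({"S": ("d", universe[:5])})
        out = ora_hypergeometric(universe[:5], universe, coll)
        assert out.loc["S", "p"] == pytest.approx(1 / 252)

    def test_zero_overlap_p_at_most_one(self):
        universe = [f"u{i}" for i in range(10)]
        coll = GeneSetCollection({"S": ("d", universe[:5])})
        out = ora_hypergeometric(universe[9:], universe, coll)
        assert 0 < out.loc["S", "p"] <= 1.0

    def test_list_equal_to_universe_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        coll = GeneSetCollection({"S": ("d", universe[:5])})
        out = ora_hypergeometric(universe, universe, coll)
        assert out.loc["S", "p"] == 1.0

    def test_list_outside_universe_rejected(self):
        coll = GeneSetCollection({"S": ("d", ["u1"])})
        with pytest.raises(DataError):
            ora_hypergeometric(["zz"], ["u1", "u2"], coll)


class TestPlantedSetPipeline:
    def test_planted_coherent_set_attains_best_q(self):
        """A planted coordinated shift must surface as the top-ranked and
        lowest-q set through ssGSEA -> normalization -> moderated statistic."""
        from cistroscreen.synthio import (
            PLANTED_SET_NAME,
            TruthConfig,
            generate_expression,
            generate_gene_sets,
            generate_genome,
        )

        config = TruthConfig(n_genes=80, chrom_sizes={"chr1": 16_000_000}, seed=5)
        genes = generate_genome(config)
        gids = [g.gene_id for g in genes]
        planted = gids[:15]
        de = {g: ("CR", 2.0, 8.0) for g in planted}
        coll = generate_gene_sets(gids, n_sets=15, size_range=(10, 20),
                                  planted_set=planted, seed=5)

        # zero dispersion: ranking by |d| with an explicit fudge factor
        expr0, _ = generate_expression(genes, de, dispersion=0.0, n_samples=4, seed=5)
        s0 = normalize_scores(ssgsea_matrix(expr0, coll))
        r0 = samroc_analysis(s0, expr0.conditions, "CR", "AD", s0=1.0, seed=5)
        assert r0.table["d"].abs().idxmax() == PLANTED_SET_NAME

        # realistic dispersion: default s0, planted set attains the best q
        expr1, _ = generate_expression(genes, de, dispersion=0.1, n_samples=4, seed=5)
        s1 = normalize_scores(ssgsea_matrix(expr1, coll))
        r1 = samroc_analysis(s1, expr1.conditions, "CR", "AD", seed=5)
        assert r1.table.loc[PLANTED_SET_NAME, "q"] == r1.table["q"].min()
        assert r1.table["d"].abs().idxmax() == PLANTED_SET_NAME
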