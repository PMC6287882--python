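"""Fisher right-tail scoring, tiered enrichment and bubble export."""

from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from funcat import (
    ContingencyTable,
    DifferentialTable,
    SimulationConfig,
    bubble_export,
    enrich,
    fisher_right_tail,
    fisher_two_sided,
    simulate_annotation,
    simulate_de_table,
    tiered_enrichment,
)


def exact_right_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact rational hypergeometric right tail (independent oracle)."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(K, x) * comb(N - K, n - x), total)
         for x in range(k, min(n, K) + 1)),
        Fraction(0),
    )


def random_tables(rng, count, n_max=200):
    for _ in range(count):
        N = int(rng.integers(2, n_max + 1))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(1, N + 1))
        lo = max(0, n + K - N)
        k = int(rng.integers(lo, min(n, K) + 1))
        yield ContingencyTable(k=k, n=n, K=K, N=N)


class TestFisherRightTail:
    def test_zero_overlap_gives_one(self):
        assert fisher_right_tail(ContingencyTable(0, 10, 5, 100)) == 1.0

    def test_category_spanning_universe_gives_one(self):
        # K = N forces k = n; the tail is the whole support
        assert fisher_right_tail(ContingencyTable(7, 7, 20, 20)) == pytest.approx(1.0)

    def test_single_tail_term_exact_value(self):
        # k = n = 3, K = 5, N = 10: only x = 3 contributes, C(5,3)/C(10,3)
        p = fisher_right_tail(ContingencyTable(3, 3, 5, 10))
        assert p == pytest.approx(comb(5, 3) / comb(10, 3), abs=1e-15)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(0)
        for t in random_tables(rng, 200):
            expected = float(exact_right_tail(t.k, t.n, t.K, t.N))
            assert fisher_right_tail(t) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for t in random_tables(rng, 50):
            sp = stats.fisher_exact(t.as_2x2(), alternative="greater")[1]
            assert fisher_right_tail(t) == pytest.approx(sp, rel=1e-9, abs=1e-12)

    def test_tail_monotone_in_k(self):
        n, K, N = 30, 40, 120
        ps = [fisher_right_tail(ContingencyTable(k, n, K, N))
              for k in range(0, min(n, K) + 1)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_pmf_sums_to_one(self):
        # right tail at the support floor covers the whole distribution
        n, K, N = 25, 60, 90
        lo = max(0, n + K - N)
        assert fisher_right_tail(ContingencyTable(lo, n, K, N)) == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize(
        "t, msg",
        [
            (ContingencyTable(5, 3, 5, 10), "k"),
            (ContingencyTable(0, 11, 5, 10), "n"),
            (ContingencyTable(0, 3, 15, 10), "K"),
            (ContingencyTable(-1, 3, 5, 10), "k"),
        ],
    )
    def test_invalid_margins_named(self, t, msg):
        with pytest.raises(ValueError, match=msg):
            fisher_right_tail(t)

    def test_two_sided_mode(self):
        t = ContingencyTable(8, 10, 12, 50)
        assert fisher_two_sided(t) == pytest.approx(
            stats.fisher_exact(t.as_2x2())[1], rel=1e-9
        )


class TestEnrich:
    def test_fold_enrichment_arithmetic(self, small_annotation):
        # 4 of 10 universe genes are proteasomal; the query is 3 of them
        res = enrich({"g01", "g02", "g03"}, small_annotation, level=1)
        top = {r.category_key: r for r in res}["Proteolysis Proteasome"]
        assert top.counts == ContingencyTable(3, 3, 4, 10)
        assert top.fold_enrichment == pytest.approx((3 / 3) / (4 / 10))

    def test_absent_genes_dropped_from_n(self, small_annotation):
        res = enrich({"g01", "nope"}, small_annotation, level=1)
        assert res[0].counts.n == 1

    def test_alpha_is_strict(self, small_annotation):
        res = enrich({"g01", "g02"}, small_annotation, level=1)
        r = res[0]
        at_p = enrich({"g01", "g02"}, small_annotation, level=1, alpha=r.p)
        assert {x.category_key: x for x in at_p}[r.category_key].significant is False
        below = enrich({"g01", "g02"}, small_annotation, level=1,
                       alpha=np.nextafter(r.p, 1))
        assert {x.category_key: x for x in below}[r.category_key].significant is True

    def test_sorted_by_p_then_key(self, sim_annotation_1k):
        rng = np.random.default_rng(3)
        query = rng.choice(sorted(sim_annotation_1k.entries), 40, replace=False)
        res = enrich(set(query), sim_annotation_1k, level=2)
        keys = [(r.p, r.category_key) for r in res]
        assert keys == sorted(keys)

    def test_empty_query_warns(self, small_annotation, caplog):
        with caplog.at_level("WARNING"):
            assert enrich({"absent"}, small_annotation, level=1) == []
        assert "no regulated genes" in caplog.text

    def test_level_k_conservation(self, sim_annotation_1k):
        """Per level-1 category, k at level 1 equals the sum over its children."""
        rng = np.random.default_rng(4)
        query = set(rng.choice(sorted(sim_annotation_1k.entries), 100, replace=False))
        res1 = {r.category_key: r.counts.k for r in enrich(query, sim_annotation_1k, 1)}
        res2 = enrich(query, sim_annotation_1k, 2)
        child_to_parent = {
            keys[1]: keys[0] for keys in sim_annotation_1k.expanded_keys.values()
        }
        rolled = Counter()
        for r in res2:
            rolled[child_to_parent[r.category_key]] += r.counts.k
        assert dict(rolled) == res1

    def test_null_queries_are_calibrated(self, sim_annotation_1k):
        """Uniform random queries produce a (conservative) super-uniform p."""
        rng = np.random.default_rng(5)
        genes = sorted(sim_annotation_1k.entries)
        hits = total = 0
        for _ in range(100):
            query = set(rng.choice(genes, 50, replace=False))
            for r in enrich(query, sim_annotation_1k, level=1):
                hits += r.p < 0.05
                total += 1
        rate = hits / total
        se = (0.05 * 0.95 / total) ** 0.5
        assert rate <= 0.05 + 3 * se


class TestTieredEnrichment:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_run():
        cfg = SimulationConfig(
            seed=11, n_genes=2000, n_level1=20, query_size=100,
            pinned_level1=(("planted", 40),), planted=(("planted", 6.0),),
        )
        ann = simulate_annotation(cfg)
        de = simulate_de_table(ann, cfg)
        return tiered_enrichment(de, ann, "up")

    def test_super_k_never_exceeds_enriched_k(self, planted_run):
        for level in (1, 2, 3):
            k_enr = {r.category_key: r.counts.k for r in planted_run["enriched"][level]}
            for r in planted_run["super_enriched"][level]:
                assert r.counts.k <= k_enr[r.category_key]

    def test_planted_category_has_minimum_p(self, planted_run):
        for tier in ("enriched", "super_enriched"):
            assert planted_run[tier][1][0].category_key == "planted"

    def test_empty_super_tier_warns(self, small_annotation, caplog):
        de = DifferentialTable.from_records(
            [("g01", 1.5, 0.001), ("g02", 1.2, 0.001), ("g03", 0.1, 0.9)]
        )
        with caplog.at_level("WARNING"):
            res = tiered_enrichment(de, small_annotation, "up", levels=(1,))
        assert res["super_enriched"][1] == []
        assert len(res["enriched"][1]) > 0
        assert "super_enriched" in caplog.text


class TestBubbleExport:
    def test_projection_and_labels(self, small_annotation):
        res = enrich({"g01", "g02", "g05"}, small_annotation, level=1)
        df = bubble_export(res)
        assert len(df) == len(res)
        assert df["gene_count"].tolist() == [r.counts.k for r in res]
        assert set(df.loc[~df["p"].lt(0.05), "label"]) <= {"NS"}

    def test_p_of_one_maps_to_zero(self, small_annotation):
        res = enrich({"g10"}, small_annotation, level=1)
        df = bubble_export(res).set_index("category_key")
        # categories with no query member have k = 0, p = 1 -> -log10 p = 0
        assert df.loc["Metabolism", "p"] == 1.0
        assert df.loc["Metabolism", "minus_log10_p"] == 0.0

    def test_optional_bh_column_is_monotone(self, small_annotation):
        res = enrich({"g01", "g02", "g05", "g08"}, small_annotation, level=2)
        df = bubble_export(res, padj=True)
        assert (df["padj"] >= df["p"] - 1e-15).all()
        assert (df["padj"] <= 1.0).all()
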