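"""ORA exactness, ranking, enrichment-score enumeration, permutation GSEA,
z-scoring and the lollipop report table."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from txconcord import gsea, gsea_es, lollipop_table, ora, rank_genes, zscore_rows
from txconcord.diffexp import ContrastResults
from txconcord.enrichment import RankedList, gsea_from_counts
from txconcord.exceptions import ValidationError
from txconcord.io import GeneSet, GeneSetCollection


def exact_hypergeom_tail(k, N, K, n) -> float:
    """P(X >= k) by integer combinatorics (independent of scipy)."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def collection_of(*sets):
    coll = GeneSetCollection()
    for name, members in sets:
        coll.add(GeneSet(name, "d", tuple(members)))
    return coll


class TestOra:
    def test_closed_form_tail_example(self):
        universe = [f"g{i}" for i in range(20)]
        members = universe[:5]
        query = universe[:3] + universe[10:12]  # k=3, n=5
        frame = ora(query, universe, collection_of(("S", members)))
        assert frame.loc["S", "p_value"] == pytest.approx(
            exact_hypergeom_tail(3, 20, 5, 5), abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        frame = ora(universe[5:7], universe, collection_of(("S", universe[:3])),
                    min_overlap=0)
        assert frame.loc["S", "p_value"] == pytest.approx(1.0)

    def test_query_equals_universe_p_is_one(self):
        universe = [f"g{i}" for i in range(12)]
        frame = ora(universe, universe, collection_of(("S", universe[:4])))
        assert frame.loc["S", "k"] == frame.loc["S", "K"]
        assert frame.loc["S", "p_value"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            ora({"x"}, {"a", "b"}, collection_of(("S", ["a"])))

    def test_namespace_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            ora({"a"}, {"a", "b"}, collection_of(("S", ["zzz"])))

    def test_min_overlap_excludes_from_family(self):
        universe = [f"g{i}" for i in range(30)]
        coll = collection_of(("hit", universe[:5]), ("miss", universe[20:25]))
        frame = ora(universe[:5], universe, coll, min_overlap=1)
        assert np.isnan(frame.loc["miss", "p_adjust"])
        assert not np.isnan(frame.loc["hit", "p_adjust"])

    def test_exact_tail_sweep_small_N(self):
        """scipy tail equals integer combinatorics across a dense small grid."""
        from scipy.stats import hypergeom

        for N in range(2, 26):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(K, n) + 1):
                        p = float(hypergeom.sf(k - 1, N, K, n))
                        assert p == pytest.approx(
                            exact_hypergeom_tail(k, N, K, n), abs=1e-10)


class TestRankGenes:
    def _result(self, stats, lfcs=None, ps=None):
        n = len(stats)
        frame = pd.DataFrame({
            "base_mean": 1.0,
            "log2fc": lfcs if lfcs is not None else stats,
            "se": 1.0,
            "stat": stats,
            "pvalue": ps if ps is not None else [0.5] * n,
            "padj": 0.5,
        }, index=[f"g{i}" for i in range(n)])
        return ContrastResults(frame=frame, contrast=("A", "B"))

    def test_order_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        stats = rng.normal(size=20)
        rl = rank_genes(self._result(stats), metric="signed_stat")
        expected = [f"g{i}" for i in np.argsort(-stats, kind="stable")]
        assert list(rl.genes) == expected

    def test_all_equal_metrics_tie_break_lexicographic(self):
        rl = rank_genes(self._result([1.0] * 5), metric="signed_stat")
        assert list(rl.genes) == sorted(rl.genes)

    def test_negating_metric_reverses_order(self):
        rng = np.random.default_rng(5)
        stats = rng.normal(size=15)  # distinct with prob 1
        fwd = rank_genes(self._result(stats), metric="signed_stat")
        rev = rank_genes(self._result(-stats), metric="signed_stat")
        assert list(rev.genes) == list(fwd.genes)[::-1]

    def test_missing_metric_dropped(self):
        res = self._result([1.0, np.nan, -1.0])
        rl = rank_genes(res, metric="signed_stat")
        assert len(rl) == 2 and "g1" not in rl.genes


def enumerate_running(scores, hits, w=0.0):
    """Independent running-sum oracle: explicit python loop."""
    N = len(scores)
    nh = sum(hits)
    denom = sum(abs(scores[i]) ** w if w else 1.0 for i in range(N) if hits[i])
    run, out = 0.0, []
    for i in range(N):
        if hits[i]:
            run += (abs(scores[i]) ** w if w else 1.0) / denom
        else:
            run -= 1.0 / (N - nh)
        out.append(run)
    return out


def enumerate_es(scores, hits, w=0.0):
    running = enumerate_running(scores, hits, w)
    best = 0.0
    for run in running:
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaEs:
    def _ranked(self, n):
        return RankedList(genes=np.array([f"g{i}" for i in range(n)], dtype=object),
                          scores=np.linspace(2, -2, n))

    def test_single_member_at_top_is_one(self):
        es, _ = gsea_es(self._ranked(5), {"g0"}, weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_single_member_at_bottom_is_minus_one(self):
        es, running = gsea_es(self._ranked(4), {"g3"}, weight_exponent=0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)
        assert es == pytest.approx(-1.0)

    def test_six_gene_enumeration_example(self):
        rl = self._ranked(6)
        es, _ = gsea_es(rl, {"g1", "g2"}, weight_exponent=0)
        hits = [g in {"g1", "g2"} for g in rl.genes]
        assert es == pytest.approx(enumerate_es(list(rl.scores), hits, 0.0), abs=1e-12)

    def test_all_subsets_up_to_n12_match_enumeration(self):
        rng = np.random.default_rng(8)
        for N in range(2, 13):
            scores = np.sort(rng.normal(size=N))[::-1]
            genes = np.array([f"g{i:02d}" for i in range(N)], dtype=object)
            rl = RankedList(genes=genes, scores=scores)
            for bits in range(1, 2 ** N - 1):
                hits = [(bits >> i) & 1 == 1 for i in range(N)]
                members = {g for g, h in zip(genes, hits) if h}
                for w in (0.0, 1.0):
                    es, _ = gsea_es(rl, members, weight_exponent=w)
                    assert abs(es) <= 1.0 + 1e-12
                    running = enumerate_running(list(scores), hits, w)
                    pos, neg = max(running), min(running)
                    if abs(abs(pos) - abs(neg)) > 1e-9:
                        assert es == pytest.approx(
                            enumerate_es(list(scores), hits, w), abs=1e-9)
                    else:
                        # positive and negative extrema tie in magnitude:
                        # the sign of the ES is genuinely ambiguous
                        assert abs(es) == pytest.approx(abs(pos), abs=1e-9)

    def test_degenerate_sets_rejected(self):
        rl = self._ranked(4)
        with pytest.raises(ValidationError):
            gsea_es(rl, {"nope"})
        with pytest.raises(ValidationError):
            gsea_es(rl, set(rl.genes))


class TestGsea:
    def _ranked(self, n, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return RankedList(genes=np.array([f"g{i:03d}" for i in range(n)], dtype=object),
                          scores=scores)

    def test_small_B_rejected(self):
        rl = self._ranked(10)
        with pytest.raises(ValidationError):
            gsea(rl, collection_of(("S", ["g000", "g001"])), B=5)

    def test_determinism_same_seed_identical(self):
        rl = self._ranked(100)
        coll = collection_of(("S1", [f"g{i:03d}" for i in range(0, 20, 2)]),
                             ("S2", [f"g{i:03d}" for i in range(50, 70, 2)]))
        a = gsea(rl, coll, B=50, seed=11)
        b = gsea(rl, coll, B=50, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_enumerated_permutation_p_matches_exhaustive_oracle(self):
        """C(6,2)=15 <= B: the permutation null is fully enumerated."""
        rl = self._ranked(6, seed=3)
        members = ["g001", "g002"]
        frame = gsea(rl, collection_of(("S", members)), B=100, seed=0)
        es_obs = frame.loc["S", "es"]
        null = []
        for combo in itertools.combinations(range(6), 2):
            hits = [i in combo for i in range(6)]
            null.append(enumerate_es(list(rl.scores), hits, 1.0))
        if es_obs >= 0:
            side = [e for e in null if e >= 0]
            count = sum(1 for e in side if e >= es_obs)
        else:
            side = [e for e in null if e < 0]
            count = sum(1 for e in side if e <= es_obs)
        assert frame.loc["S", "n_perm"] == 15
        assert frame.loc["S", "p_value"] == pytest.approx((1 + count) / (len(side) + 1))

    def test_p_bounded_by_granularity_floor(self):
        rl = self._ranked(200, seed=5)
        coll = collection_of(("S", [f"g{i:03d}" for i in range(10)]))
        frame = gsea(rl, coll, B=50, seed=2)
        assert 1 / 51 <= frame.loc["S", "p_value"] <= 1.0

    def test_nes_sign_matches_es(self):
        rl = self._ranked(150, seed=6)
        coll = collection_of(("top", [f"g{i:03d}" for i in range(12)]),
                             ("bottom", [f"g{i:03d}" for i in range(138, 150)]))
        frame = gsea(rl, coll, B=100, seed=3)
        assert (np.sign(frame["nes"]) == np.sign(frame["es"])).all()
        assert frame.loc["top", "es"] > 0 > frame.loc["bottom", "es"]

    def test_null_sets_calibrated(self):
        """Random sets on random rankings: p < 0.05 in roughly 5% of runs."""
        rng = np.random.default_rng(0)
        genes = np.array([f"g{i:03d}" for i in range(150)], dtype=object)
        hits = 0
        n_runs = 100
        for i in range(n_runs):
            scores = np.sort(rng.normal(size=150))[::-1]
            rl = RankedList(genes=genes, scores=scores)
            members = rng.choice(genes, size=12, replace=False)
            frame = gsea(rl, collection_of(("S", members)), B=200, seed=10_000 + i)
            hits += frame.loc["S", "p_value"] < 0.05
        assert 0.02 <= hits / n_runs <= 0.09

    def test_phenotype_fallback_below_three_per_group(self, demo_study, caplog):
        import logging

        sheet = demo_study.reference_sheet
        sub = type(sheet)(sheet.data.iloc[[0, 1, 12, 13]])
        counts = demo_study.reference_counts.subset_samples(list(sub.data.index))
        coll = collection_of(("S", demo_study.reference_counts.gene_ids[:20]))
        with caplog.at_level(logging.WARNING):
            frame = gsea_from_counts(counts, sub, "CTL", "ASD", coll, B=50,
                                     permutation="phenotype", seed=1)
        assert any("falling back" in r.message for r in caplog.records)
        assert len(frame) == 1

    def test_phenotype_enumerates_small_designs(self, demo_study):
        sheet = demo_study.model_sheet
        coll = collection_of(("S", demo_study.model_counts.gene_ids[:25]))
        frame = gsea_from_counts(demo_study.model_counts, sheet, "NM", "NTr", coll,
                                 B=100, permutation="phenotype", seed=1)
        # C(7,3) = 35 distinct label splits, all enumerated
        assert frame.loc["S", "n_perm"] == 35


class TestZscoreRows:
    def test_rows_standardised(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(10, 3, size=(5, 6)))
        z = zscore_rows(df)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(5, 6)))
        z = zscore_rows(df)
        for i in range(5):
            row = df.iloc[i].to_numpy()
            np.testing.assert_allclose(
                z.iloc[i], (row - row.mean()) / row.std(ddof=1), atol=1e-12)

    def test_constant_row_zeroed_with_warning(self, caplog):
        import logging

        df = pd.DataFrame([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]])
        with caplog.at_level(logging.WARNING):
            z = zscore_rows(df)
        assert (z.iloc[0] == 0).all()
        assert any("constant" in r.message for r in caplog.records)


class TestLollipopTable:
    def _ora_frame(self, entries):
        df = pd.DataFrame(entries, columns=["set_name", "k", "K", "p_adjust"])
        df["n"] = 10
        df["N"] = 100
        df["p_value"] = df["p_adjust"] / 2
        df["retained"] = df["p_adjust"] < 0.05
        return df.set_index("set_name")

    def test_one_sided_when_only_divergent_retained(self):
        conv = self._ora_frame([("A", 3, 5, 0.5)])
        div = self._ora_frame([("B", 4, 6, 0.01)])
        table = lollipop_table(conv, div)
        assert table["side"].tolist() == ["divergent"]

    def test_pathway_on_both_sides_appears_twice(self):
        conv = self._ora_frame([("A", 3, 5, 0.01)])
        div = self._ora_frame([("A", 4, 6, 0.02)])
        table = lollipop_table(conv, div)
        assert len(table) == 2 and set(table["side"]) == {"convergent", "divergent"}

    def test_assembly_matches_brute_force_sorting(self):
        rng = np.random.default_rng(9)
        conv = self._ora_frame([(f"C{i}", 3, 5, float(rng.uniform(0, 0.1)))
                                for i in range(6)])
        div = self._ora_frame([(f"D{i}", 3, 5, float(rng.uniform(0, 0.1)))
                               for i in range(6)])
        table = lollipop_table(conv, div)
        for side, src in (("convergent", conv), ("divergent", div)):
            got = table.loc[table["side"] == side, "set_name"].tolist()
            expected = src[src["retained"]].sort_values("p_adjust").index.tolist()
            assert got == expected
        np.testing.assert_allclose(table["neg_log10_padj"],
                                   -np.log10(table["p_adjust"]), atol=1e-12)
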