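"""Ranking, enrichment score, preranked GSEA and ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rewirenet.enrichment import (
    RankedList,
    enrichment_score,
    gsea_prerank,
    ora,
    rank_genes,
    read_gmt,
    write_gmt,
)


def de_frame(genes, lfc, p):
    return pd.DataFrame({"log2FoldChange": lfc, "pvalue": p}, index=genes)


def loop_es(ranked, members, weight=1.0):
    """Literal running-sum oracle."""
    members = set(members)
    w = [abs(s) ** weight for g, s in zip(ranked.genes, ranked.scores) if g in members]
    total = sum(w)
    n, k = len(ranked.genes), len(w)
    running, best, cur = [], 0.0, 0.0
    for g, s in zip(ranked.genes, ranked.scores):
        if g in members:
            cur += abs(s) ** weight / total
        else:
            cur -= 1.0 / (n - k)
        running.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestRanking:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(-0.5, 0.01, -2.0), (1.0, 0.001, 3.0), (2.0, 1.0, 0.0), (-3.0, 1.0, 0.0)],
    )
    def test_rank_statistic(self, lfc, p, expected):
        ranked = rank_genes(de_frame(["g", "other"], [lfc, 0.1], [p, 0.5]))
        score = dict(zip(ranked.genes, ranked.scores))
        assert score["g"] == pytest.approx(expected)

    def test_sorted_descending_with_lexicographic_ties(self):
        ranked = rank_genes(de_frame(["b", "a", "c"], [1.0, 1.0, -1.0], [0.1, 0.1, 0.01]))
        assert list(ranked.genes) == ["a", "b", "c"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(genes=np.array(["a", "a"], dtype=object), scores=np.array([1.0, 0.5]))


class TestEnrichmentScore:
    def test_singleton_top_set_scores_one(self):
        ranked = RankedList(
            genes=np.array(list("abcde"), dtype=object),
            scores=np.array([5.0, 1.0, 0.5, -1.0, -2.0]),
        )
        es, _ = enrichment_score(ranked, {"a"})
        assert es == pytest.approx(1.0)

    def test_zero_statistic_members_raise(self):
        ranked = RankedList(
            genes=np.array(list("abcd"), dtype=object), scores=np.array([2.0, 1.0, 0.0, -1.0])
        )
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(ranked, {"c"})

    def test_matches_loop_oracle(self, rng):
        genes = np.array([f"g{i:02d}" for i in range(50)], dtype=object)
        scores = np.sort(rng.normal(size=50))[::-1]
        ranked = RankedList(genes=genes, scores=scores)
        for seed in range(5):
            members = set(np.random.default_rng(seed).choice(genes, 10, replace=False))
            es, running = enrichment_score(ranked, members)
            assert es == pytest.approx(loop_es(ranked, members), abs=1e-12)
            assert np.all(running <= 1.0 + 1e-12) and np.all(running >= -1.0 - 1e-12)

    def test_weight_zero_reduces_to_classical_ks(self, rng):
        genes = np.array([f"g{i:02d}" for i in range(40)], dtype=object)
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = RankedList(genes=genes, scores=scores)
        members = set(genes[[3, 7, 19, 30]])
        es, _ = enrichment_score(ranked, members, weight=0.0)
        hit = np.array([g in members for g in genes])
        k, n = hit.sum(), len(genes)
        running = np.cumsum(np.where(hit, 1.0 / k, -1.0 / (n - k)))
        expected = running[np.argmax(np.abs(running))]
        assert es == pytest.approx(expected, abs=1e-12)


class TestGseaPrerank:
    def _ranked(self, rng, n=300):
        genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
        scores = np.sort(rng.normal(size=n))[::-1]
        return RankedList(genes=genes, scores=scores)

    def test_fixed_seed_bit_identical(self, rng):
        ranked = self._ranked(rng)
        sets = {f"s{i}": list(np.random.default_rng(i).choice(ranked.genes, 15, replace=False))
                for i in range(4)}
        r1 = gsea_prerank(ranked, sets, n_perm=200, seed=5)
        r2 = gsea_prerank(ranked, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_p_invariant_under_positive_scaling(self, rng):
        ranked = self._ranked(rng)
        scaled = RankedList(genes=ranked.genes.copy(), scores=ranked.scores * 37.5)
        sets = {"s": list(np.random.default_rng(1).choice(ranked.genes, 20, replace=False))}
        r1 = gsea_prerank(ranked, sets, n_perm=300, seed=2)
        r2 = gsea_prerank(scaled, sets, n_perm=300, seed=2)
        assert r1.loc["s", "pvalue"] == r2.loc["s", "pvalue"]
        assert r1.loc["s", "nes"] == pytest.approx(r2.loc["s", "nes"])

    def test_disjoint_set_skipped(self, rng, caplog):
        ranked = self._ranked(rng)
        sets = {"ok": list(ranked.genes[:10]), "gone": ["not_a_gene"]}
        with caplog.at_level("WARNING", logger="rewirenet.enrichment"):
            res = gsea_prerank(ranked, sets, n_perm=100, seed=1)
        assert list(res.index) == ["ok"]

    def test_null_es_matches_loop_oracle_distributionally(self, rng):
        """The vectorized permutation ES and the loop ES agree exactly for
        the same membership draw."""
        ranked = self._ranked(rng, n=80)
        from rewirenet.enrichment import _es_null

        abs_w = np.abs(ranked.scores)
        child = np.random.default_rng(7)
        null = _es_null(abs_w, 8, 50, child)
        # replay the same permutations through the loop oracle
        child2 = np.random.default_rng(7)
        positions = np.argsort(child2.random((50, 80)), axis=1)[:, :8]
        positions.sort(axis=1)
        for row in range(50):
            members = set(ranked.genes[positions[row]])
            assert null[row] == pytest.approx(loop_es(ranked, members), abs=1e-12)


class TestOra:
    def test_zero_overlap_gives_p_one(self):
        res = ora(["g1"], ["g1", "g2", "g3", "g4"], {"s": ["g2", "g3"]})
        assert res.loc["s", "overlap"] == 0
        assert res.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_exact_combinatorial_sum(self):
        """Universe 100, set 10, list 10, overlap 5: upper-tail sum of the
        hypergeometric pmf."""
        universe = [f"g{i}" for i in range(100)]
        test = universe[:10]
        members = universe[5:15]  # overlap = 5
        res = ora(test, universe, {"s": members})
        from math import comb

        expected = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) / comb(100, 10)
        assert res.loc["s", "pvalue"] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_set_excluded_with_log(self, caplog):
        universe = ["a", "b", "c", "d"]
        with caplog.at_level("WARNING", logger="rewirenet.enrichment"):
            res = ora(["a"], universe, {"in": ["a", "b"], "out": ["zzz"]})
        assert list(res.index) == ["in"]
        assert any("disjoint" in m for m in caplog.messages)

    def test_non_subset_test_list_raises(self):
        with pytest.raises(ValueError, match="subset"):
            ora(["x"], ["a", "b"], {"s": ["a"]})

    def test_calibration_under_random_draws(self, rng):
        """ORA p-values are super-uniform-ish under the null; check the mean
        overlap matches expectation rather than the tail."""
        universe = [f"g{i}" for i in range(200)]
        sets = {f"s{i}": list(rng.choice(universe, 20, replace=False)) for i in range(50)}
        test = list(rng.choice(universe, 30, replace=False))
        res = ora(test, universe, sets)
        assert res["overlap"].mean() == pytest.approx(20 * 30 / 200, rel=0.35)
        assert not res["significant"].any() or res["significant"].mean() < 0.1


class TestGmtIo:
    def test_round_trip(self, tmp_path):
        sets = {"alpha": ["g1", "g2"], "beta": ["g3", "g4", "g5"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\nbroken_line\n")
        with pytest.raises(ValueError, match="2"):
            read_gmt(path)

    def test_duplicate_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s\td\tg1\ns\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)
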