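"""PCIT: closed forms, worked trios, and equivalence with a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from rewirenet.pcit import (
    build_condition_network,
    correlation_matrix,
    partial_correlation,
    pcit_significant_edges,
    trio_tolerance,
    trio_tolerance_values,
)

from test_rif import make_expr


# ---------------------------------------------------------------------------
# independent naive reference: literal triple loop over trios
# ---------------------------------------------------------------------------

def naive_pcit(R, floor=1e-12):
    n = R.shape[0]
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(y + 1, n):
                rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
                if min(abs(rxy), abs(rxz), abs(ryz)) <= floor:
                    continue
                try:
                    pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
                    pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
                    pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
                except FloatingPointError:
                    continue
                eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    keep[x, y] = keep[y, x] = False
                if abs(rxz) <= abs(eps * rxy) and abs(rxz) <= abs(eps * ryz):
                    keep[x, z] = keep[z, x] = False
                if abs(ryz) <= abs(eps * rxy) and abs(ryz) <= abs(eps * rxz):
                    keep[y, z] = keep[z, y] = False
    return keep


def random_psd_correlation(rng, n, n_factors=4):
    """Random correlation matrix from factor loadings plus noise."""
    load = rng.normal(size=(n, n_factors))
    cov = load @ load.T + np.diag(rng.uniform(0.5, 2.0, n))
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    R = np.clip(R, -0.999999, 0.999999)
    np.fill_diagonal(R, 1.0)
    return R


class TestPartialCorrelation:
    def test_uncorrelated_conditioner_leaves_r(self):
        assert partial_correlation(0.8, 0.0, 0.0) == pytest.approx(0.8)

    def test_product_rule_gives_zero(self):
        assert partial_correlation(0.25, 0.5, 0.5) == pytest.approx(0.0)

    def test_hand_value(self):
        assert partial_correlation(0.8, 0.5, 0.5) == pytest.approx(0.55 / 0.75)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError, match="denominator"):
            partial_correlation(0.5, 1.0, 0.2)


class TestTrioTolerance:
    def test_equicorrelated_hand_value(self):
        R = np.full((3, 3), 0.9)
        np.fill_diagonal(R, 1.0)
        # each partial is 0.09/0.19; each ratio (0.09/0.19)/0.9 = 0.5263 = eps
        assert partial_correlation(0.9, 0.9, 0.9) == pytest.approx(0.09 / 0.19)
        assert trio_tolerance(R, 0, 1, 2) == pytest.approx(0.5263, abs=5e-5)
        assert trio_tolerance(R, 0, 1, 2) == pytest.approx(1 / 1.9)

    @pytest.mark.parametrize("rho", [0.1, 0.3, 0.5, 0.7, 0.95])
    def test_equicorrelated_closed_form(self, rho):
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        assert trio_tolerance(R, 0, 1, 2) == pytest.approx(1 / (1 + rho), abs=1e-12)

    def test_worked_mixed_trio(self):
        assert trio_tolerance_values(0.1, 0.6, 0.6) == pytest.approx(-0.6004, abs=5e-5)

    def test_near_zero_direct_correlation_is_non_eliminating(self):
        assert np.isnan(trio_tolerance_values(0.0, 0.6, 0.6))


class TestEliminationRule:
    def test_weak_edge_in_mixed_trio_is_eliminated(self):
        R = np.array([[1.0, 0.1, 0.6], [0.1, 1.0, 0.6], [0.6, 0.6, 1.0]])
        adj = pcit_significant_edges(R)
        assert not adj[0, 1]  # |eps * 0.6| = 0.36 >= 0.1 on both arms
        assert adj[0, 2] and adj[1, 2]

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.9])
    def test_equicorrelated_matrix_keeps_all_edges(self, rho):
        R = np.full((6, 6), rho)
        np.fill_diagonal(R, 1.0)
        adj = pcit_significant_edges(R)
        assert adj.sum() == 6 * 5  # every off-diagonal pair survives

    def test_two_genes_trivially_significant(self, caplog):
        with caplog.at_level("WARNING", logger="rewirenet.pcit"):
            adj = pcit_significant_edges(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert adj[0, 1] and not adj[0, 0]
        assert any("fewer than 3" in m for m in caplog.messages)

    def test_matches_naive_oracle_on_random_psd_matrices(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            R = random_psd_correlation(rng, 20)
            assert np.array_equal(pcit_significant_edges(R), naive_pcit(R)), f"seed {seed}"

    def test_elimination_monotone_in_edge_strength(self):
        """If an edge survives, increasing |r_xy| (rest fixed) cannot kill it."""
        rng = np.random.default_rng(3)
        R = random_psd_correlation(rng, 12)
        adj = pcit_significant_edges(R)
        x, y = 0, 1
        for bump in (0.05, 0.15, 0.3):
            R2 = R.copy()
            r = min(abs(R[x, y]) + bump, 0.999) * np.sign(R[x, y] or 1.0)
            R2[x, y] = R2[y, x] = r
            adj2 = pcit_significant_edges(R2)
            if adj[x, y]:
                assert adj2[x, y]


class TestNetworkBuilder:
    def test_perfectly_covarying_pair_retained(self, rng):
        base = rng.normal(size=12)
        noise = rng.normal(size=(4, 12)) * 10
        vals = np.vstack([base, base * 2 + 1, noise])
        genes = ["a", "b", "n1", "n2", "n3", "n4"]
        expr = make_expr(vals, genes)
        net = build_condition_network(expr, "CON", keep_ids={"a"}, r_threshold=0.9)
        pairs = set(map(tuple, net.edges[["gene_x", "gene_y"]].to_numpy()))
        assert ("a", "b") in pairs

    def test_empty_keep_set_raises(self, rng):
        expr = make_expr(rng.normal(size=(4, 8)), ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="keep_ids"):
            build_condition_network(expr, "CON", keep_ids=set())

    def test_edge_list_matches_filter_after_oracle(self, rng):
        vals = rng.normal(size=(15, 10))
        genes = [f"g{i:02d}" for i in range(15)]
        expr = make_expr(vals, genes)
        keep = {"g00", "g03", "g07"}
        threshold = 0.6
        net = build_condition_network(expr, "VTM", keep_ids=keep, r_threshold=threshold)
        idx, R = correlation_matrix(expr, "VTM")
        oracle_adj = naive_pcit(R)
        expected = set()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if oracle_adj[i, j] and abs(R[i, j]) >= threshold and (
                    idx[i] in keep or idx[j] in keep
                ):
                    expected.add((idx[i], idx[j]))
        got = set(map(tuple, net.edges[["gene_x", "gene_y"]].to_numpy()))
        assert got == expected
        assert net.nodes == {g for pair in expected for g in pair}

    def test_edges_canonically_ordered(self, rng):
        vals = rng.normal(size=(10, 10))
        expr = make_expr(vals, [f"g{9 - i}" for i in range(10)])
        net = build_condition_network(expr, "CON", keep_ids=set(expr.gene_ids), r_threshold=0.3)
        assert (net.edges["gene_x"] < net.edges["gene_y"]).all()
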