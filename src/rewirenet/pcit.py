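"""Per-condition co-expression networks with PCIT edge significance.

PCIT (partial correlation and information theory) examines every gene trio
(x, y, z). For a trio it computes the three first-order partial correlations
and an information-theoretic tolerance

    eps = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3

with SIGNED ratios. The edge (x, y) is eliminated when some third gene z
dominates it on both arms: |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|.
Surviving edges are "PCIT-significant"; the network builder then applies a
|r| magnitude threshold (default 0.9, on the direct correlation) and keeps
only edges touching a gene of interest (DEGs and significant RIF TFs).

Trios containing a near-zero direct correlation cannot eliminate edges (the
tolerance ratio is undefined there), and a degenerate partial-correlation
denominator skips the trio.
"""

from __future__ import annotations

import dataclasses
import logging

import numba
import numpy as np
import pandas as pd

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)

R_FLOOR = 1e-12
CLIP = 0.999999
GENE_CAP_WARN = 5000


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z."""
    den = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if den <= R_FLOOR:
        raise ValueError("degenerate denominator in partial correlation")
    return (r_xy - r_xz * r_yz) / den


def trio_tolerance_values(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Tolerance eps of a trio from its three direct correlations.

    Returns NaN when any direct correlation is below the floor: such a trio
    is non-eliminating.
    """
    if min(abs(r_xy), abs(r_xz), abs(r_yz)) <= R_FLOOR:
        return float("nan")
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    return (p_xy / r_xy + p_xz / r_xz + p_yz / r_yz) / 3.0


def trio_tolerance(R: np.ndarray, x: int, y: int, z: int) -> float:
    """Tolerance eps for the trio of matrix rows/columns (x, y, z)."""
    return trio_tolerance_values(R[x, y], R[x, z], R[y, z])


@numba.njit(cache=True)
def _pcit_eliminated(R: np.ndarray, floor: float) -> np.ndarray:  # pragma: no cover - numba
    n = R.shape[0]
    elim = np.zeros((n, n), dtype=np.uint8)
    for x in range(n - 1):
        for y in range(x + 1, n):
            rxy = R[x, y]
            if abs(rxy) <= floor:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                rxz = R[x, z]
                ryz = R[y, z]
                if abs(rxz) <= floor or abs(ryz) <= floor:
                    continue
                d_xy = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                d_xz = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                d_yz = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                if d_xy <= floor * floor or d_xz <= floor * floor or d_yz <= floor * floor:
                    continue
                p_xy = (rxy - rxz * ryz) / np.sqrt(d_xy)
                p_xz = (rxz - rxy * ryz) / np.sqrt(d_xz)
                p_yz = (ryz - rxy * rxz) / np.sqrt(d_yz)
                eps = (p_xy / rxy + p_xz / rxz + p_yz / ryz) / 3.0
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    elim[x, y] = 1
                    elim[y, x] = 1
                    break
    return elim


@numba.njit(cache=True)
def _min_abs_partial(R: np.ndarray, floor: float) -> np.ndarray:  # pragma: no cover - numba
    """min over z of |r_xy.z| for every pair; trios with a degenerate
    denominator are skipped."""
    n = R.shape[0]
    out = np.abs(R).copy()
    for x in range(n - 1):
        for y in range(x + 1, n):
            best = abs(R[x, y])
            for z in range(n):
                if z == x or z == y:
                    continue
                d = (1.0 - R[x, z] ** 2) * (1.0 - R[y, z] ** 2)
                if d <= floor * floor:
                    continue
                p = abs((R[x, y] - R[x, z] * R[y, z]) / np.sqrt(d))
                if p < best:
                    best = p
            out[x, y] = best
            out[y, x] = best
    return out


def correlation_matrix(expr: ExpressionMatrix, condition: str) -> tuple[pd.Index, np.ndarray]:
    """Pearson correlation across the samples of one condition.

    Zero-variance genes get r = 0 everywhere (warned); off-diagonal entries
    are clipped to +-0.999999 and the diagonal set to 1.
    """
    block = expr.condition_values(condition)
    if block.shape[1] < 3:
        raise ValueError(f"condition {condition!r} has < 3 samples")
    vals = block.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d gene(s) with zero variance in %s; correlations set to 0",
            int(degenerate.sum()), condition,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(vals)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    R = np.clip(R, -CLIP, CLIP)
    np.fill_diagonal(R, 1.0)
    return block.index, R


def pcit_significant_edges(R: np.ndarray) -> np.ndarray:
    """Boolean adjacency of PCIT-surviving edges (symmetric, no self-edges)."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if n < 3:
        logger.warning("fewer than 3 genes: every edge is trivially significant")
        adj = np.ones((n, n), dtype=bool)
        np.fill_diagonal(adj, False)
        return adj
    if n > GENE_CAP_WARN:
        logger.warning("PCIT on %d genes exceeds the advisory cap of %d", n, GENE_CAP_WARN)
    elim = _pcit_eliminated(R, R_FLOOR)
    adj = elim == 0
    np.fill_diagonal(adj, False)
    return adj


@dataclasses.dataclass
class CoexpressionNetwork:
    """Edge list of one condition's filtered co-expression network."""

    condition: str
    edges: pd.DataFrame  # columns: gene_x, gene_y, r (canonical gene_x < gene_y)
    nodes: set[str]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_condition_network(
    expr: ExpressionMatrix,
    condition: str,
    keep_ids,
    r_threshold: float = 0.9,
    r_mode: str = "direct",
) -> CoexpressionNetwork:
    """Pearson -> PCIT significance -> magnitude threshold -> DEG/RIF restriction.

    ``r_mode`` selects what the magnitude threshold is applied to: the direct
    Pearson correlation of PCIT-significant edges (``"direct"``, default) or
    the minimum absolute first-order partial correlation over all conditioning
    genes (``"partial_min"``).
    """
    keep = set(keep_ids)
    if not keep:
        raise ValueError("keep_ids is empty; network restriction is undefined")
    if r_mode not in ("direct", "partial_min"):
        raise ValueError(f"unknown r_mode {r_mode!r}")
    genes, R = correlation_matrix(expr, condition)
    adj = pcit_significant_edges(R)
    if r_mode == "direct":
        magnitude = np.abs(R)
    else:
        magnitude = _min_abs_partial(R, R_FLOOR)
    in_keep = np.array([g in keep for g in genes])
    mask = adj & (magnitude >= r_threshold) & (in_keep[:, None] | in_keep[None, :])
    xs, ys = np.nonzero(np.triu(mask, k=1))
    genes_arr = genes.to_numpy(dtype=object)
    gx = genes_arr[xs]
    gy = genes_arr[ys]
    lo = np.where(gx < gy, gx, gy)
    hi = np.where(gx < gy, gy, gx)
    edges = pd.DataFrame({"gene_x": lo, "gene_y": hi, "r": R[xs, ys]})
    edges = edges.sort_values(["gene_x", "gene_y"], kind="mergesort").reset_index(drop=True)
    nodes = set(edges["gene_x"]) | set(edges["gene_y"])
    logger.info(
        "%s network: %d edges over %d nodes (|r| >= %.3g on %s)",
        condition, len(edges), len(nodes), r_threshold, r_mode,
    )
    return CoexpressionNetwork(condition=condition, edges=edges, nodes=nodes)


def to_graphml(net: CoexpressionNetwork, path) -> None:
    """Export an edge list as GraphML for external visualization tools."""
    import networkx as nx

    g = nx.Graph(condition=net.condition)
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.gene_x, row.gene_y, r=float(row.r))
    nx.write_graphml(g, path)
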