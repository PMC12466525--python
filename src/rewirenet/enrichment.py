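"""Over-representation analysis and preranked GSEA.

Genes are ranked by ``sign(log2FC) * -log10(p)`` (p clamped away from zero).
GSEA uses the weighted Kolmogorov-Smirnov running sum (weight exponent 1 by
default) with gene-label permutations of set membership: for each set the
null is drawn by resampling member positions, the NES is the observed ES
divided by the mean |ES*| of same-sign permutations, and the nominal p is the
add-one-smoothed fraction of same-sign permutations at least as extreme. A
set is flagged at p <= 0.1 and |NES| >= 1.5. ORA is a one-sided
hypergeometric upper tail over an expressed-gene universe with BH control at
FDR <= 0.05.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclasses.dataclass
class RankedList:
    """Gene ids sorted by rank statistic, descending; lexicographic tie order."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        if not np.isfinite(self.scores).all():
            raise ValueError("rank statistics must be finite")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(de_res: pd.DataFrame, p_floor: float = P_FLOOR) -> RankedList:
    """Rank statistic sign(log2FC) * -log10(p) from a DE result table."""
    p = de_res["pvalue"].to_numpy(dtype=float)
    n_clamped = int((p < p_floor).sum())
    if n_clamped:
        logger.warning("%d p-value(s) clamped to the floor %.3g", n_clamped, p_floor)
    score = np.sign(de_res["log2FoldChange"].to_numpy()) * -np.log10(np.clip(p, p_floor, None))
    order = sorted(range(len(score)), key=lambda i: (-score[i], str(de_res.index[i])))
    return RankedList(
        genes=np.asarray(de_res.index.to_numpy()[order], dtype=object),
        scores=score[order],
    )


def enrichment_score(
    ranked: RankedList, members, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running-sum profile.

    Hits step up by |score|^weight (normalized over hits), misses step down by
    1/(N - n_set); ES is the running-sum value of largest magnitude (first
    occurrence on ties).
    """
    members = set(members)
    hit = np.array([g in members for g in ranked.genes])
    k = int(hit.sum())
    n = len(ranked)
    if k == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if k == n:
        raise ValueError("gene set equals the ranked universe; miss step undefined")
    w = np.abs(ranked.scores) ** weight
    w_hit_sum = w[hit].sum()
    if w_hit_sum == 0:
        raise ValueError("all member rank statistics are zero; hit normalizer undefined")
    steps = np.where(hit, w / w_hit_sum, -1.0 / (n - k))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _es_null(
    abs_w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES values from random membership of size k over the universe.

    Vectorized: the running sum only changes at hit positions, so extremes
    are evaluated at the k hit positions of each permutation.
    """
    n = len(abs_w)
    positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    positions.sort(axis=1)
    g = abs_w[positions]
    cum = np.cumsum(g, axis=1)
    total = cum[:, -1:]
    safe_total = np.where(total > 0, total, 1.0)
    miss = (positions - np.arange(k)[None, :]) / (n - k)
    after = cum / safe_total - miss
    before = after - g / safe_total
    i_max = np.argmax(after, axis=1)
    i_min = np.argmin(before, axis=1)
    rows = np.arange(n_perm)
    es_pos = after[rows, i_max]
    es_neg = before[rows, i_min]
    # tie on magnitude -> earlier profile position wins (matches the loop rule)
    pos_at = positions[rows, i_max]
    neg_at = positions[rows, i_min] - 1
    take_pos = (np.abs(es_pos) > np.abs(es_neg)) | (
        (np.abs(es_pos) == np.abs(es_neg)) & (pos_at <= neg_at)
    )
    es = np.where(take_pos, es_pos, es_neg)
    return np.where(total[:, 0] > 0, es, 0.0)


def gsea_prerank(
    ranked: RankedList,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    p_thr: float = 0.1,
    nes_thr: float = 1.5,
) -> pd.DataFrame:
    """Preranked GSEA over a collection; bit-identical for a fixed seed."""
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    universe = set(ranked.genes)
    abs_w = np.abs(ranked.scores) ** weight
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(gene_sets))
    rows = []
    for (name, members), child in zip(sorted(gene_sets.items()), children):
        inter = sorted(set(members) & universe)
        if not inter or len(inter) == len(universe):
            logger.warning("set %r skipped (usable size %d)", name, len(inter))
            continue
        es, running = enrichment_score(ranked, inter, weight=weight)
        idx = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = [g for g in ranked.genes[: idx + 1] if g in set(inter)]
        else:
            leading = [g for g in ranked.genes[idx:] if g in set(inter)]
        null = _es_null(abs_w, len(inter), n_perm, np.random.default_rng(child))
        same_sign = null[null > 0] if es > 0 else null[null < 0] if es < 0 else null
        if es == 0:
            nes, pval = 0.0, 1.0
        elif len(same_sign) == 0:
            logger.warning("set %r: no same-sign permutations; NES undefined", name)
            nes, pval = np.nan, np.nan
        else:
            nes = es / np.mean(np.abs(same_sign))
            pval = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
        rows.append(
            {
                "set": name,
                "size": len(inter),
                "es": es,
                "nes": nes,
                "pvalue": pval,
                "leading_edge": ",".join(map(str, leading)),
            }
        )
    if not rows:
        raise ValueError("no usable gene set after intersection with the universe")
    res = pd.DataFrame(rows).set_index("set")
    ok = res["pvalue"].notna()
    fdr = np.full(len(res), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(res.loc[ok, "pvalue"], method="fdr_bh")[1]
    res["fdr"] = fdr
    res["significant"] = (res["pvalue"] <= p_thr) & (res["nes"].abs() >= nes_thr)
    return res


def ora(
    test_ids,
    universe_ids,
    gene_sets: dict[str, list[str]],
    fdr_thr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment."""
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    test = set(test_ids)
    if not test <= universe:
        raise ValueError("test gene list is not a subset of the universe")
    m = len(universe)
    n_test = len(test)
    rows = []
    for name, members in sorted(gene_sets.items()):
        in_universe = set(members) & universe
        if not in_universe:
            logger.warning("set %r is disjoint from the universe; excluded", name)
            continue
        k = len(in_universe & test)
        big_k = len(in_universe)
        pval = float(stats.hypergeom.sf(k - 1, m, big_k, n_test))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": big_k,
                "list_size": n_test,
                "universe_size": m,
                "expected": big_k * n_test / m,
                "pvalue": pval,
            }
        )
    if not rows:
        raise ValueError("no gene set intersects the universe")
    res = pd.DataFrame(rows).set_index("set")
    res["fdr"] = multipletests(res["pvalue"], method="fdr_bh")[1]
    res["significant"] = res["fdr"] <= fdr_thr
    return res


# ---------------------------------------------------------------------------
# GMT helpers
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")
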