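"""Recovery and calibration experiments on synthetic data.

Each function runs one self-contained experiment against the generator's
ground truth and returns the summary statistic a method-validation report
would quote: type-I error of the DE test on null data, AUROC of rewired-TF
recovery by the RIF metrics, Fisher enrichment of a rewired module among
differentially connected genes, and GSEA calibration/recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity, diffexpr, enrichment, pcit, preprocess, rif
from .synthetic import SimulationParams, simulate_counts, strong_signal_preset


def _auroc(score: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUROC of ``score`` for the boolean ``positive`` labels."""
    r = stats.rankdata(score)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    return float((r[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _prepare(params: SimulationParams):
    cm, truth = simulate_counts(params)
    filtered = preprocess.filter_low_expressed(cm)
    sf = preprocess.size_factors(filtered)
    expr = preprocess.vst(filtered, sf)
    return cm, truth, filtered, sf, expr


def de_null_type1(seed: int = 0, n_genes: int = 2000) -> float:
    """Fraction of p <= 0.05 on a null simulation (no DE, no coupling), 6 vs 6."""
    params = SimulationParams(
        n_genes=n_genes, n_tfs=10, n_modules=1, module_size=1,
        coupling_a=0.0, coupling_b=0.0, frac_deg=0.0, seed=seed,
    )
    _, _, filtered, sf, _ = _prepare(params)
    alpha = diffexpr.estimate_dispersion(filtered, sf)
    res = diffexpr.nb_wald_test(filtered, sf, alpha)
    return float((res["pvalue"] <= 0.05).mean())


def rif_recovery_auroc(seed: int = 0) -> float:
    """AUROC of max(|z RIF1|, |z RIF2|) for planted rewired TFs, one seed."""
    params = strong_signal_preset(seed)
    _, truth, _, _, expr = _prepare(params)
    expressed = set(expr.gene_ids)
    tfs = [t for t in truth.tf_ids if t in expressed]
    degs = [d for d in truth.deg_ids if d in expressed]
    table = rif.compute_rif(expr, tfs, degs)
    score = table[["rif1_z", "rif2_z"]].abs().max(axis=1).to_numpy()
    positive = np.array([t in set(truth.rewired_tf_ids) for t in table.index])
    return _auroc(score, positive)


def dk_params(seed: int = 0) -> SimulationParams:
    """One rewired module (0.9 -> 0.0) next to one stable module.

    Deliberately narrow (400 genes): at n = 6/group a |r| >= 0.9 cut passes
    ~1.5% of null pairs, so the rewiring signal must compete with noise
    degree proportional to the gene count. Tight dispersion and a strong
    latent amplitude keep the module's true correlations near the threshold.
    """
    return SimulationParams(
        n_genes=400, n_tfs=20, n_modules=2, module_size=40,
        coupling_a=0.9, coupling_b=(0.0, 0.9),
        frac_deg=0.25, lfc_range=(1.0, 2.0), latent_sd=1.0,
        dispersion_rate=100, seed=seed,
    )


def dk_module_enrichment_p(seed: int = 0, z_thr: float = 1.96) -> float:
    """Fisher p for over-representation of the rewired module's genes among
    |z(DK)| >= z_thr flags."""
    params = dk_params(seed)
    _, truth, _, _, expr = _prepare(params)
    rewired_tf = truth.rewired_tf_ids[0]
    module_genes = set(truth.module_map[rewired_tf]) | {rewired_tf}
    keep = [g for g in truth.deg_ids if g in set(expr.gene_ids)]
    nets = {
        lev: pcit.build_condition_network(expr, lev, keep) for lev in expr.levels
    }
    dk = connectivity.compare_networks(nets[expr.levels[0]], nets[expr.levels[1]])
    flagged = dk["class"] != "unchanged"
    in_module = pd.Series([g in module_genes for g in dk.index], index=dk.index)
    table = [
        [int((flagged & in_module).sum()), int((flagged & ~in_module).sum())],
        [int((~flagged & in_module).sum()), int((~flagged & ~in_module).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def gsea_null_calibration(seed: int = 0, n_sets: int = 200, n_perm: int = 500) -> float:
    """Fraction of nominal p <= 0.05 over uniformly random sets on a null-ish
    ranked list (uniform scores); should be close to 0.05."""
    rng = np.random.default_rng(seed)
    n = 2000
    genes = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    scores = np.sort(rng.normal(size=n))[::-1]
    ranked = enrichment.RankedList(genes=genes, scores=scores)
    sets = {
        f"random_{i:03d}": list(rng.choice(genes, size=int(rng.integers(10, 51)), replace=False))
        for i in range(n_sets)
    }
    res = enrichment.gsea_prerank(ranked, sets, n_perm=n_perm, seed=seed + 1)
    return float((res["pvalue"] <= 0.05).mean())


def gsea_recovery_params(seed: int = 0) -> SimulationParams:
    """Single strongly shifted 50-gene program over a modest DEG background.

    GSEA's permutation null is computed from the same rank distribution as
    the observed set, so a genome crowded with hundreds of extreme DEGs
    inflates the null |ES*| and caps the NES; the canonical recovery question
    is one coherent program against a mostly null background.
    """
    return SimulationParams(
        n_genes=2000, n_tfs=100, n_modules=1, module_size=50,
        coupling_a=0.9, coupling_b=0.0, frac_deg=0.03,
        lfc_range=(2.0, 2.0), seed=seed,
    )


def gsea_planted_set_recovered(seed: int = 0, n_perm: int = 500) -> bool:
    """Whether the planted program's target set is flagged (p <= 0.1,
    |NES| >= 1.5) among random decoy sets."""
    params = gsea_recovery_params(seed)
    _, truth, filtered, sf, expr = _prepare(params)
    alpha = diffexpr.estimate_dispersion(filtered, sf)
    de = diffexpr.nb_wald_test(filtered, sf, alpha)
    ranked = enrichment.rank_genes(de)
    tf = list(truth.module_map)[0]
    rng = np.random.default_rng(seed)
    universe = np.asarray(ranked.genes, dtype=object)
    sets = {"planted": [g for g in truth.module_map[tf]]}
    for i in range(20):
        sets[f"random_{i:02d}"] = list(rng.choice(universe, size=50, replace=False))
    res = enrichment.gsea_prerank(ranked, sets, n_perm=n_perm, seed=seed)
    return bool(res.loc["planted", "significant"])
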