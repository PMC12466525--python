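"""Per-gene two-condition differential expression via a negative-binomial Wald test.

A deliberately small NB GLM: log link, design = intercept + condition
indicator, offsets log(size factor), per-gene dispersion fixed at a
method-of-moments estimate, fitted by IRLS. There is no fold-change
shrinkage, no dispersion trend, and no outlier filtering; those omissions
are recorded in the result provenance. DEG calls use the raw p-value
(p <= 0.05) together with |log2FC| >= 0.5; BH-adjusted p-values are reported
but do not gate the call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix

logger = logging.getLogger(__name__)

LFC_CAP = 30.0  # |log2FC| cap for separated (all-zero group) genes
_MAX_ITER = 50
_TOL = 1e-8


def estimate_dispersion(counts: CountMatrix, sf: pd.Series) -> pd.Series:
    """Method-of-moments dispersion on normalized counts pooled within conditions.

    alpha = max((s2 - mu) / mu^2, 1e-8), where mu and s2 are the averages of
    the two condition-level means and variances of ``count / sf``.
    """
    sf = sf.loc[counts.sample_ids]
    norm = counts.counts / sf
    means, variances = [], []
    for lev in counts.levels:
        block = norm[counts.samples_of(lev)]
        means.append(block.mean(axis=1))
        variances.append(block.var(axis=1, ddof=1))
    mu = (means[0] + means[1]) / 2.0
    s2 = (variances[0] + variances[1]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = alpha.where(mu > 0, 0.0)
    return alpha.clip(lower=1e-8).rename("dispersion")


def _fit_group(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS for the per-group log-mean of an NB GLM with offsets log(sf).

    Vectorized over genes. Returns (beta, sum of IRLS weights, converged).
    """
    beta = np.log(np.clip((y / sf[None, :]).mean(axis=1), 1e-8, None))
    delta = np.full(y.shape[0], np.inf)
    sw = np.zeros(y.shape[0])
    for _ in range(_MAX_ITER):
        eta = np.clip(beta, -60.0, 40.0)[:, None]
        mu = sf[None, :] * np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta + (y - mu) / mu
        sw = w.sum(axis=1)
        new = (w * z).sum(axis=1) / sw
        delta = np.abs(new - beta)
        beta = new
        if (delta < _TOL).all():
            break
    return beta, sw, delta < _TOL


def _irls_nb(
    y: np.ndarray, sf: np.ndarray, is_b: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene NB GLM fit for a two-group design.

    The binary design is saturated, so the weighted normal equations decouple
    into two independent one-parameter fits; fitting the groups separately
    also makes the result exactly mirror-symmetric under a label swap.
    Returns (b0, b1, se(b1), converged).
    """
    a_mask = is_b == 0
    beta_a, sw_a, conv_a = _fit_group(y[:, a_mask], sf[a_mask], alpha)
    beta_b, sw_b, conv_b = _fit_group(y[:, ~a_mask], sf[~a_mask], alpha)
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / sw_a + 1.0 / sw_b)
    return beta_a, beta_b - beta_a, se, conv_a & conv_b


def nb_wald_test(
    counts: CountMatrix,
    sf: pd.Series,
    alpha: pd.Series,
    p_thr: float = 0.05,
    lfc_thr: float = 0.5,
) -> pd.DataFrame:
    """Wald test of the condition coefficient for every gene.

    Returns a DataFrame indexed by gene with baseMean, log2FoldChange
    (treatment vs reference), dispersion, stat, pvalue, padj, converged,
    lfc_capped and deg_flag columns.
    """
    sf = sf.loc[counts.sample_ids]
    alpha = alpha.loc[counts.gene_ids]
    y = counts.counts.to_numpy(dtype=float)
    is_b = (counts.conditions == counts.levels[1]).to_numpy(dtype=float)
    b0, b1, se, converged = _irls_nb(y, sf.to_numpy(), is_b, alpha.to_numpy())

    capped = np.abs(b1) > LFC_CAP * np.log(2.0)
    b1 = np.where(capped, np.sign(b1) * LFC_CAP * np.log(2.0), b1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(np.isfinite(se) & (se > 0), b1 / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("%d gene(s) did not converge in %d IRLS iterations; p set to 1", n_bad, _MAX_ITER)
        pvalue = np.where(converged, pvalue, 1.0)
        stat = np.where(converged, stat, 0.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    norm = y / sf.to_numpy()[None, :]
    res = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FoldChange": b1 / np.log(2.0),
            "dispersion": alpha.to_numpy(),
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "converged": converged,
            "lfc_capped": capped,
        },
        index=counts.gene_ids,
    )
    res.attrs["provenance"] = (
        "NB Wald, IRLS, MoM dispersion; no LFC shrinkage, no dispersion trend, "
        "no outlier filtering; DEG gate uses raw p"
    )
    return call_degs(res, p_thr=p_thr, lfc_thr=lfc_thr)


def call_degs(res: pd.DataFrame, p_thr: float = 0.05, lfc_thr: float = 0.5) -> pd.DataFrame:
    """Assign up/down/none DEG flags at the raw-p and |log2FC| thresholds."""
    res = res.copy()
    hit = (res["pvalue"] <= p_thr) & (res["log2FoldChange"].abs() >= lfc_thr)
    res["deg_flag"] = np.where(~hit, "none", np.where(res["log2FoldChange"] > 0, "up", "down"))
    return res


def deg_ids(res: pd.DataFrame) -> list[str]:
    return list(res.index[res["deg_flag"] != "none"])
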