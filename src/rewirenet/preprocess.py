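"""Low-expression filtering, size factors, and a variance-stabilizing transform.

The stabilized matrix feeds every correlation-based stage (RIF, PCIT). The
transform is a shifted log2 of size-factor-normalized counts: closed-form,
monotone, and adequate for Pearson-correlation work; it is deliberately not a
fitted-dispersion VST, and the provenance tag of the output records that.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts[g, s] / libsize[s] * 1e6``."""
    lib = counts.library_sizes()
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for sample(s): {zero}")
    return counts.counts / lib * 1e6


def filter_low_expressed(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    min_total: int = 15,
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_samples`` samples and a
    total count >= ``min_total``.

    ``min_samples`` defaults to the smallest condition-group size. Gene order
    is preserved. This is a fixed CPM rule in the spirit of edgeR's
    ``filterByExpr``, not a reimplementation of its design-aware heuristic.
    """
    if min_samples is None:
        min_samples = int(counts.conditions.value_counts().min())
    cpm = compute_cpm(counts)
    keep = ((cpm >= min_cpm).sum(axis=1) >= min_samples) & (
        counts.counts.sum(axis=1) >= min_total
    )
    if not keep.any():
        raise ValueError(
            "no gene passes the expression filter; lower min_cpm/min_samples/min_total"
        )
    logger.info("expression filter kept %d of %d genes", int(keep.sum()), len(keep))
    return CountMatrix(counts.counts.loc[keep], counts.conditions.copy(), counts.levels)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For genes whose geometric mean across samples is positive (i.e. no zero
    count), the factor of sample ``s`` is the median over those genes of
    ``counts[g, s] / geomean[g]``.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in every sample; cannot compute size factors")
    positive = mat[all_positive]
    geomean = np.exp(np.log(positive).mean(axis=1))
    sf = np.median(positive / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def vst(counts: CountMatrix, sf: pd.Series) -> ExpressionMatrix:
    """Shifted-log stabilization: ``log2(count / sf + 1)``."""
    sf = sf.loc[counts.sample_ids]
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    vals = np.log2(counts.counts / sf + 1.0)
    return ExpressionMatrix(
        values=vals,
        conditions=counts.conditions.copy(),
        levels=counts.levels,
        provenance="log2(count/sf + 1); median-of-ratios size factors",
    )
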