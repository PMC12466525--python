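"""Regulatory impact factors: RIF1 and RIF2 scoring of transcription factors.

Both metrics contrast, for every expressed TF, its co-expression with the
differentially expressed genes (DEGs) between the two conditions (A =
reference, conventionally CON; B = treatment, conventionally VTM):

* RIF1 weights the squared differential wiring of a TF-DEG pair,
  ``dw = r_A - r_B``, by the DEG's phenotypic impact factor
  ``PIF = 0.5 (e_A + e_B)(e_A - e_B)``, and averages over DEGs.
* RIF2 averages the change in the squared expression-weighted predictive
  ability of the TF, ``(e_A r_A)^2 - (e_B r_B)^2``.

Scores are z-standardized across TFs and a TF is flagged as a candidate
regulator when |z| >= 1.96 for either metric. Condition means ``e`` are
taken on the variance-stabilized scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)


def _standardized(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardized to mean 0, sd 1 (ddof=1); zero-variance rows zeroed."""
    mean = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (block - mean) / sd
    z[degenerate] = 0.0
    return z, degenerate


def condition_correlations(
    expr: ExpressionMatrix, tf_ids, deg_ids
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-condition Pearson correlation for every (TF, DEG) pair.

    Pairs where either gene has zero within-condition variance get r = 0 (with
    a warning); a TF that is also a DEG gets r = 0 against itself in both
    conditions so it never contributes to its own target sum.
    """
    tf_ids = list(tf_ids)
    deg_ids = list(deg_ids)
    missing = [g for g in tf_ids + deg_ids if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"gene ids absent from expression matrix: {missing[:5]}")
    out = []
    for level in expr.levels:
        block = expr.condition_values(level)
        if block.shape[1] < 3:
            raise ValueError(f"condition {level!r} has < 3 samples")
        n = block.shape[1]
        z_tf, bad_tf = _standardized(block.loc[tf_ids].to_numpy(dtype=float))
        z_deg, bad_deg = _standardized(block.loc[deg_ids].to_numpy(dtype=float))
        n_bad = int(bad_tf.sum() + bad_deg.sum())
        if n_bad:
            logger.warning(
                "%d gene(s) with zero within-%s variance; their correlations set to 0",
                n_bad, level,
            )
        r = np.clip(z_tf @ z_deg.T / (n - 1), -1.0, 1.0)
        out.append(pd.DataFrame(r, index=pd.Index(tf_ids, name="tf"), columns=deg_ids))
    r_a, r_b = out
    for i, tf in enumerate(tf_ids):
        if tf in r_a.columns:
            r_a.loc[tf, tf] = 0.0
            r_b.loc[tf, tf] = 0.0
    return r_a, r_b


def rif_raw_scores(
    e_a: np.ndarray,
    e_b: np.ndarray,
    r_a: np.ndarray,
    r_b: np.ndarray,
    n_de: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw RIF1/RIF2 from condition-mean DEG expression and TF-DEG correlations.

    ``e_a``/``e_b`` have shape (n_deg,), ``r_a``/``r_b`` shape (n_tf, n_deg).
    ``n_de`` is the per-TF number of DEGs entering the average (defaults to
    n_deg; callers exclude a TF's self-pair by zeroing its correlations and
    decrementing its count).
    """
    e_a = np.atleast_1d(np.asarray(e_a, dtype=float))
    e_b = np.atleast_1d(np.asarray(e_b, dtype=float))
    r_a = np.atleast_2d(np.asarray(r_a, dtype=float))
    r_b = np.atleast_2d(np.asarray(r_b, dtype=float))
    if n_de is None:
        n_de = np.full(r_a.shape[0], r_a.shape[1], dtype=float)
    pif = (e_a + e_b) / 2.0 * (e_a - e_b)
    dw = r_a - r_b
    rif1 = (pif[None, :] * dw**2).sum(axis=1) / n_de
    rif2 = ((e_a[None, :] * r_a) ** 2 - (e_b[None, :] * r_b) ** 2).sum(axis=1) / n_de
    return rif1, rif2


def compute_rif(
    expr: ExpressionMatrix, tf_ids, deg_ids, z_thr: float = 1.96
) -> pd.DataFrame:
    """Score every expressed TF by RIF1 and RIF2 against the DEG set.

    Returns a DataFrame indexed by TF with rif1_raw, rif1_z, rif2_raw,
    rif2_z, significant_rif1 and significant_rif2 columns; bookkeeping counts
    (list size, tested, unexpressed) are logged and stored in ``.attrs``.
    """
    tf_list = list(dict.fromkeys(tf_ids))
    tested = [g for g in tf_list if g in expr.gene_ids]
    n_removed = len(tf_list) - len(tested)
    logger.info(
        "TF bookkeeping: %d in list, %d tested (expressed), %d removed (unexpressed)",
        len(tf_list), len(tested), n_removed,
    )
    deg = [g for g in dict.fromkeys(deg_ids) if g in expr.gene_ids]
    if not deg:
        raise ValueError("no expressed DEGs; RIF is undefined")
    if not tested:
        raise ValueError("no expressed TFs to test")

    e_a = expr.condition_values(expr.levels[0]).loc[deg].mean(axis=1).to_numpy()
    e_b = expr.condition_values(expr.levels[1]).loc[deg].mean(axis=1).to_numpy()
    r_a_df, r_b_df = condition_correlations(expr, tested, deg)
    r_a = r_a_df.to_numpy()
    r_b = r_b_df.to_numpy()

    deg_index = {g: j for j, g in enumerate(deg)}
    n_de = np.array([len(deg) - (1 if tf in deg_index else 0) for tf in tested], dtype=float)
    if (n_de == 0).any():
        raise ValueError("a TF has no DEGs other than itself; RIF undefined")
    rif1, rif2 = rif_raw_scores(e_a, e_b, r_a, r_b, n_de)

    res = pd.DataFrame({"rif1_raw": rif1, "rif2_raw": rif2}, index=pd.Index(tested, name="tf"))
    for metric in ("rif1", "rif2"):
        raw = res[f"{metric}_raw"]
        sd = raw.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            logger.warning("%s has zero spread across TFs; all z set to 0", metric)
            res[f"{metric}_z"] = 0.0
        else:
            res[f"{metric}_z"] = (raw - raw.mean()) / sd
        res[f"significant_{metric}"] = res[f"{metric}_z"].abs() >= z_thr
    res = res[
        ["rif1_raw", "rif1_z", "rif2_raw", "rif2_z", "significant_rif1", "significant_rif2"]
    ]
    res.attrs["tf_counts"] = {
        "tf_list": len(tf_list),
        "tf_tested": len(tested),
        "tf_unexpressed": n_removed,
    }
    res.attrs["provenance"] = (
        f"A={expr.levels[0]} (reference), B={expr.levels[1]}; condition means on "
        "stabilized scale; z over tested TFs; significant at |z| >= "
        f"{z_thr}"
    )
    return res


def significant_tfs(rif_table: pd.DataFrame) -> list[str]:
    mask = rif_table["significant_rif1"] | rif_table["significant_rif2"]
    return list(rif_table.index[mask])
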