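"""Differential connectivity (DK) between the two condition networks.

Each gene's degree K is max-normalized within its network (k = K / max K),
DK = k_treatment - k_reference over the union of both node sets, and DK is
z-scored across genes. Genes at z >= +1.96 gained connectivity in the
treatment network, z <= -1.96 lost it.
"""

from __future__ import annotations

import logging

import pandas as pd

from .pcit import CoexpressionNetwork

logger = logging.getLogger(__name__)


def node_degrees(net: CoexpressionNetwork) -> pd.Series:
    """Number of retained edges incident to each network node."""
    if net.edges.empty:
        return pd.Series(dtype=int, name="K")
    deg = pd.concat([net.edges["gene_x"], net.edges["gene_y"]]).value_counts()
    return deg.sort_index().rename("K")


def differential_connectivity(
    k_ref: pd.Series,
    k_trt: pd.Series,
    z_thr: float = 1.96,
    population: list[str] | None = None,
) -> pd.DataFrame:
    """DK table over the union of both degree indexes.

    ``population`` optionally restricts the gene set over which DK is
    z-scored (default: the union of both networks' nodes); genes absent from
    one network enter with degree 0.
    """
    if population is None:
        genes = sorted(set(k_ref.index) | set(k_trt.index))
    else:
        genes = sorted(set(population))
    if not genes:
        raise ValueError("both networks are empty; DK is undefined")
    K_ref = k_ref.reindex(genes).fillna(0).astype(float)
    K_trt = k_trt.reindex(genes).fillna(0).astype(float)
    norm_ref = K_ref / K_ref.max() if K_ref.max() > 0 else K_ref * 0.0
    norm_trt = K_trt / K_trt.max() if K_trt.max() > 0 else K_trt * 0.0
    dk = norm_trt - norm_ref
    sd = dk.std(ddof=1)
    if sd == 0 or pd.isna(sd):
        logger.warning("DK has zero spread; all z set to 0")
        z = dk * 0.0
    else:
        z = (dk - dk.mean()) / sd
    cls = pd.Series("unchanged", index=dk.index)
    cls[z >= z_thr] = "gained"
    cls[z <= -z_thr] = "lost"
    out = pd.DataFrame(
        {
            "K_con": K_ref.astype(int),
            "K_vtm": K_trt.astype(int),
            "k_con": norm_ref,
            "k_vtm": norm_trt,
            "dk": dk,
            "dk_z": z,
            "class": cls,
            "in_con": [g in k_ref.index for g in genes],
            "in_vtm": [g in k_trt.index for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return out


def compare_networks(
    net_ref: CoexpressionNetwork,
    net_trt: CoexpressionNetwork,
    z_thr: float = 1.96,
    population: list[str] | None = None,
) -> pd.DataFrame:
    return differential_connectivity(
        node_degrees(net_ref), node_degrees(net_trt), z_thr=z_thr, population=population
    )
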