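#!/usr/bin/env python
"""Score regulators (RIF1/RIF2), build the per-condition PCIT networks, and
compare connectivity between conditions.

TFs with |z| >= 1.96 on either RIF metric and the DEGs form the gene set of
interest; each condition's Pearson matrix is pruned with PCIT, thresholded at
|r| >= 0.9, and restricted to edges touching those genes. Differential
connectivity (DK) is the difference of max-normalized degrees, z-scored over
the union of network nodes.
"""

import argparse
from pathlib import Path

import pandas as pd

from rewirenet import connectivity, diffexpr, pcit, rif
from rewirenet.data import ExpressionMatrix
from rewirenet.io import read_table, read_tf_list, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cond = pd.read_csv(args.datadir / "metadata.tsv", sep="\t", dtype=str).set_index("sample")["condition"]
    expr = ExpressionMatrix(read_table(args.outdir / "expression.tsv"), cond, ("CON", "VTM"))
    de = read_table(args.outdir / "de_results.tsv")
    degs = diffexpr.deg_ids(de)

    rif_table = rif.compute_rif(expr, read_tf_list(args.datadir / "tf_list.txt"), degs)
    sig_tfs = rif.significant_tfs(rif_table)
    write_table(rif_table, args.outdir / "rif.tsv")
    print(f"{len(sig_tfs)} significant TFs of {len(rif_table)} tested "
          f"(RIF1: {int(rif_table['significant_rif1'].sum())}, "
          f"RIF2: {int(rif_table['significant_rif2'].sum())})")

    keep = sorted(set(degs) | set(sig_tfs))
    nets = {}
    for level in expr.levels:
        net = pcit.build_condition_network(expr, level, keep)
        write_table(net.edges, args.outdir / f"network_{level}.tsv")
        nets[level] = net
        print(f"{level} network: {net.n_edges} edges over {len(net.nodes)} nodes")

    dk = connectivity.compare_networks(nets["CON"], nets["VTM"])
    write_table(dk, args.outdir / "dk.tsv")
    gained = int((dk["class"] == "gained").sum())
    lost = int((dk["class"] == "lost").sum())
    print(f"{gained + lost} differentially connected genes ({gained} gained, {lost} lost)")


if __name__ == "__main__":
    main()
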