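#!/usr/bin/env python
"""Filter, normalize and test every gene for differential expression.

Reads the dataset written by 01_simulate_dataset.py, applies the CPM
expression filter, median-of-ratios size factors and the shifted-log
stabilization, then the NB Wald test. DEGs are called at p <= 0.05 and
|log2FC| >= 0.5. Writes the stabilized expression and the DE table under
results/.
"""

import argparse
from pathlib import Path

from rewirenet import diffexpr, preprocess
from rewirenet.io import read_counts, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cm = read_counts(args.datadir / "counts.tsv", args.datadir / "metadata.tsv", ("CON", "VTM"))
    filtered = preprocess.filter_low_expressed(cm)
    sf = preprocess.size_factors(filtered)
    expr = preprocess.vst(filtered, sf)
    alpha = diffexpr.estimate_dispersion(filtered, sf)
    res = diffexpr.nb_wald_test(filtered, sf, alpha)

    write_table(filtered.counts, args.outdir / "filtered_counts.tsv")
    write_table(sf.to_frame(), args.outdir / "size_factors.tsv")
    write_table(expr.values, args.outdir / "expression.tsv")
    write_table(res, args.outdir / "de_results.tsv")

    n_up = int((res["deg_flag"] == "up").sum())
    n_down = int((res["deg_flag"] == "down").sum())
    print(f"kept {filtered.counts.shape[0]} of {cm.counts.shape[0]} genes")
    print(f"{n_up + n_down} DEGs ({n_up} up, {n_down} down in the treatment condition)")


if __name__ == "__main__":
    main()
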