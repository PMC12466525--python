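"""Configuration and end-to-end orchestration of the analysis stages.

Stage order: preprocess -> differential expression -> RIF -> PCIT networks
(one per condition) -> differential connectivity -> ORA + preranked GSEA.
Every stage writes a TSV under the output directory, and a JSON manifest
records versions, the seed, a hash of the configuration, per-stage counts
and the number of warnings raised, mirroring the bookkeeping a study report
would print (genes kept, DEGs by direction, TFs tested/significant, edges
and nodes per network, shared/unique nodes, DK genes gained/lost).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, connectivity, diffexpr, enrichment, pcit, preprocess, rif
from .data import CountMatrix
from .io import read_counts, read_tf_list, write_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    tf_list: str = ""
    gmt: str = ""
    outdir: str = "results"
    reference: str = "CON"
    treatment: str = "VTM"
    p_thr: float = 0.05
    lfc_thr: float = 0.5
    rif_z: float = 1.96
    dk_z: float = 1.96
    r_threshold: float = 0.9
    nes_thr: float = 1.5
    gsea_p: float = 0.1
    ora_fdr: float = 0.05
    min_cpm: float = 1.0
    min_total: int = 15
    n_perm: int = 1000
    seed: int = 0
    pcit_gene_cap: int = 5000
    r_mode: str = "direct"          # "direct" | "partial_min"
    dk_population: str = "union"    # "union" | "keep"

    def __post_init__(self) -> None:
        for name in ("p_thr", "lfc_thr", "rif_z", "dk_z", "r_threshold", "nes_thr",
                     "gsea_p", "ora_fdr", "min_cpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r_mode not in ("direct", "partial_min"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        if self.dk_population not in ("union", "keep"):
            raise ValueError(f"unknown dk_population {self.dk_population!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run_pipeline(config: PipelineConfig, counts: CountMatrix | None = None) -> dict:
    """Execute all stages and write outputs plus ``manifest.json``.

    ``counts`` may be passed directly (e.g. from the simulator); otherwise
    the configured files are read. On a stage failure the partial manifest
    is written with a ``.partial`` suffix and the error re-raised with the
    stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.hash()} seed={config.seed}"
    counter = _WarningCounter()
    logging.getLogger("rewirenet").addHandler(counter)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "setup"
    try:
        if counts is None:
            stage = "read"
            counts = read_counts(
                config.counts, config.metadata, (config.reference, config.treatment)
            )
        tf_ids = read_tf_list(config.tf_list) if config.tf_list else []
        gene_sets = enrichment.read_gmt(config.gmt) if config.gmt else {}

        stage = "preprocess"
        filtered = preprocess.filter_low_expressed(
            counts, min_cpm=config.min_cpm, min_total=config.min_total
        )
        sf = preprocess.size_factors(filtered)
        expr = preprocess.vst(filtered, sf)
        write_table(filtered.counts, outdir / "filtered_counts.tsv", tag)
        write_table(sf.to_frame(), outdir / "size_factors.tsv", tag)
        write_table(expr.values, outdir / "expression.tsv", tag)
        manifest["stages"]["preprocess"] = {
            "genes_total": int(counts.counts.shape[0]),
            "genes_kept": int(filtered.counts.shape[0]),
            "samples": int(filtered.counts.shape[1]),
        }

        stage = "diffexpr"
        alpha = diffexpr.estimate_dispersion(filtered, sf)
        de = diffexpr.nb_wald_test(
            filtered, sf, alpha, p_thr=config.p_thr, lfc_thr=config.lfc_thr
        )
        degs = diffexpr.deg_ids(de)
        write_table(de, outdir / "de_results.tsv", tag)
        manifest["stages"]["diffexpr"] = {
            "n_deg": len(degs),
            "deg_up": int((de["deg_flag"] == "up").sum()),
            "deg_down": int((de["deg_flag"] == "down").sum()),
            "non_converged": int((~de["converged"]).sum()),
        }

        stage = "rif"
        if not tf_ids:
            raise ValueError("no TF list configured; the RIF stage requires one")
        rif_table = rif.compute_rif(expr, tf_ids, degs, z_thr=config.rif_z)
        sig_tfs = rif.significant_tfs(rif_table)
        write_table(rif_table, outdir / "rif.tsv", tag)
        manifest["stages"]["rif"] = {
            **rif_table.attrs["tf_counts"],
            "tf_significant_rif1": int(rif_table["significant_rif1"].sum()),
            "tf_significant_rif2": int(rif_table["significant_rif2"].sum()),
            "tf_significant_any": len(sig_tfs),
        }

        stage = "pcit"
        keep = sorted(set(degs) | set(sig_tfs))
        if len(expr.gene_ids) > config.pcit_gene_cap:
            logger.warning(
                "%d genes exceed pcit_gene_cap=%d; networks may be slow",
                len(expr.gene_ids), config.pcit_gene_cap,
            )
        nets = {}
        for level in expr.levels:
            net = pcit.build_condition_network(
                expr, level, keep, r_threshold=config.r_threshold, r_mode=config.r_mode
            )
            write_table(net.edges, outdir / f"network_{level}.tsv", tag)
            nets[level] = net
        shared = nets[config.reference].nodes & nets[config.treatment].nodes
        manifest["stages"]["pcit"] = {
            "keep_genes": len(keep),
            f"edges_{config.reference}": nets[config.reference].n_edges,
            f"edges_{config.treatment}": nets[config.treatment].n_edges,
            f"nodes_{config.reference}": len(nets[config.reference].nodes),
            f"nodes_{config.treatment}": len(nets[config.treatment].nodes),
            "nodes_shared": len(shared),
            f"nodes_unique_{config.reference}": len(nets[config.reference].nodes - shared),
            f"nodes_unique_{config.treatment}": len(nets[config.treatment].nodes - shared),
        }

        stage = "connectivity"
        population = keep if config.dk_population == "keep" else None
        dk = connectivity.compare_networks(
            nets[config.reference], nets[config.treatment],
            z_thr=config.dk_z, population=population,
        )
        write_table(dk, outdir / "dk.tsv", tag)
        manifest["stages"]["connectivity"] = {
            "dk_genes": int((dk["class"] != "unchanged").sum()),
            "dk_gained": int((dk["class"] == "gained").sum()),
            "dk_lost": int((dk["class"] == "lost").sum()),
        }

        stage = "enrichment"
        if gene_sets:
            universe = list(expr.gene_ids)
            ora_res = enrichment.ora(degs, universe, gene_sets, fdr_thr=config.ora_fdr)
            write_table(ora_res, outdir / "ora.tsv", tag)
            ranked = enrichment.rank_genes(de)
            gsea_res = enrichment.gsea_prerank(
                ranked, gene_sets, n_perm=config.n_perm, seed=config.seed,
                p_thr=config.gsea_p, nes_thr=config.nes_thr,
            )
            write_table(gsea_res, outdir / "gsea.tsv", tag)
            manifest["stages"]["enrichment"] = {
                "sets": len(gene_sets),
                "ora_significant": int(ora_res["significant"].sum()),
                "gsea_significant": int(gsea_res["significant"].sum()),
            }
        else:
            manifest["stages"]["enrichment"] = {"sets": 0}

        manifest["warnings"] = counter.count
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return {
            "manifest": manifest,
            "filtered": filtered,
            "size_factors": sf,
            "expression": expr,
            "de": de,
            "rif": rif_table,
            "networks": nets,
            "dk": dk,
        }
    except Exception as err:
        manifest["warnings"] = counter.count
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.partial.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {err}") from err
    finally:
        logging.getLogger("rewirenet").removeHandler(counter)
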