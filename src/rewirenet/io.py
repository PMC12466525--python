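"""Readers and writers for the pipeline's plain-text formats.

Counts are genes-as-rows TSV (first column the gene id, header the sample
ids) or MatrixMarket plus two id files; metadata is a TSV with ``sample`` and
``condition`` columns. Output tables carry a ``#`` header comment with the
config hash and seed of the run that produced them, which readers skip.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CountMatrix

logger = logging.getLogger(__name__)


def read_metadata(path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample", "condition"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata must have a {col!r} column")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dup}")
    return meta.set_index("sample")["condition"]


def read_counts(
    path, metadata_path, levels: tuple[str, str] | None = None
) -> CountMatrix:
    """Read a genes-as-rows counts TSV plus a sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        first = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {first!r}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{path}: counts must be integers")
    conditions = read_metadata(metadata_path)
    return CountMatrix(df.astype(np.int64), conditions, levels)


def read_counts_mtx(
    mtx_path, genes_path, samples_path, metadata_path, levels: tuple[str, str] | None = None
) -> CountMatrix:
    """Read MatrixMarket counts with one-id-per-line gene and sample files."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = _read_id_list(genes_path, "gene")
    samples = _read_id_list(samples_path, "sample")
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(samples)} samples"
        )
    df = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    conditions = read_metadata(metadata_path)
    return CountMatrix(df.round().astype(np.int64), conditions, levels)


def _read_id_list(path, what: str) -> list[str]:
    ids: list[str] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token in seen:
                raise ValueError(f"{path}:{lineno}: duplicate {what} id {token!r}")
            seen.add(token)
            ids.append(token)
    return ids


def read_tf_list(path) -> list[str]:
    """One gene id per line; duplicates are an error naming the line."""
    return _read_id_list(path, "TF")


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    meta = pd.DataFrame({"sample": cm.sample_ids, "condition": cm.conditions.to_numpy()})
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a TSV with an optional ``#`` provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
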