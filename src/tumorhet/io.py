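"""Reading and writing expression matrices (TSV / GCT 1.2), annotations and GMT gene sets.

All formats are UTF-8, tab-delimited; LF and CRLF line endings are both
accepted. Expression matrices carry genes in rows and samples in columns.
Annotations are a three-column TSV (sample_id, case_id, histotype).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    return df


def _read_matrix_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValidationError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValidationError(f"{path}: malformed GCT size line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    # drop the Description metadata column
    df = df.drop(columns=df.columns[0])
    if df.shape != (n_genes, n_samples):
        raise ValidationError(
            f"{path}: GCT size line says {(n_genes, n_samples)}, matrix is {df.shape}"
        )
    return df


def _to_float_naming_gaps(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    na = df.isna()
    if na.to_numpy().any():
        g = na.index[na.any(axis=1)][0]
        s = na.columns[na.loc[g]][0]
        raise ValidationError(f"{path}: missing value at gene {g!r}, sample {s!r}")
    try:
        return df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})") from exc


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a (sample_id, case_id, histotype) TSV into an annotation table."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "case_id", "histotype"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    return ann.set_index("sample_id")


def read_expression(
    path: str | Path,
    annotations: str | Path | pd.DataFrame,
    format: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix (TSV or GCT 1.2) plus its annotation table.

    ``format`` may be ``'tsv'`` or ``'gct'``; when None it is inferred from
    the file suffix (``.gct``) with TSV as the fallback. Row and column
    order are preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        raw = _read_matrix_gct(path)
    elif format == "tsv":
        raw = _read_matrix_tsv(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    values = _to_float_naming_gaps(raw, path)
    if isinstance(annotations, (str, Path)):
        annotations = read_annotations(annotations)
    return ExpressionDataset(values, annotations)


def write_expression(
    dataset: ExpressionDataset, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        dataset.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            out = dataset.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def write_annotations(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.annotations.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate member ids within a line are de-duplicated with a warning;
    a duplicated set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} fields (expected >= 3)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}: line {lineno} set {name!r} has "
                    f"{len(members) - len(unique)} duplicate member id(s); de-duplicated",
                    UserWarning,
                    stacklevel=2,
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# probe collapsing and global median
# ---------------------------------------------------------------------------

def collapse_probes(
    dataset: ExpressionDataset, probe_to_gene: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probe-level rows to gene level by averaging.

    Each gene row in the result is the arithmetic mean of the rows of the
    probes that map to it. Probes absent from ``probe_to_gene`` are dropped
    (the count is logged). Gene order follows the first occurrence of each
    gene among the probe rows.
    """
    if len(probe_to_gene) == 0:
        raise ValidationError("empty probe-to-gene mapping")
    genes = dataset.gene_ids.map(lambda p: probe_to_gene.get(p))
    mapped = genes.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped == dataset.n_genes:
        raise ValidationError("no probe in the matrix maps to a gene")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probe row(s)", n_dropped)
    sub = dataset.values.loc[np.asarray(mapped)]
    gene_labels = genes[np.asarray(mapped)]
    collapsed = sub.groupby(gene_labels.to_numpy(), sort=False).mean()
    # groupby(sort=False) preserves first-occurrence order
    collapsed.index.name = dataset.values.index.name
    return ExpressionDataset(collapsed, dataset.annotations.copy())


def median_log2(dataset: ExpressionDataset) -> float:
    """Median over every entry of the matrix (genes x samples flattened).

    With an even number of entries this is the mean of the two central
    values. Used to resolve the ``'median'`` expression threshold for
    druggable-target calls.
    """
    if dataset.values.size == 0:
        raise ValidationError("empty expression matrix")
    return float(np.median(dataset.values.to_numpy()))
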