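"""Core data containers: expression matrices with sample annotations, and gene-set collections.

The universal input of every analysis stage is an :class:`ExpressionDataset`:
a log2-scale expression matrix (genes in rows, samples in columns) together
with a per-sample annotation table assigning each sample to a *case* (one
tumor mass, represented by several spatially distinct blocks) and a
*histotype* (the tumor's histological type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("case_id", "histotype")


class ValidationError(ValueError):
    """Raised when an input matrix or annotation table violates the data contract."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes x samples) plus per-sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns. All entries
        must be finite; the matrix is assumed already normalized and on the
        log2 scale.
    annotations : pandas.DataFrame
        Indexed by sample id (or carrying a ``sample_id`` column), with
        columns ``case_id`` and ``histotype``. Every sample in ``values``
        must be annotated, and every case must map to exactly one histotype.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if values.size == 0:
            raise ValidationError("empty expression matrix")
        _check_unique(values.index, "gene ids")
        _check_unique(values.columns, "sample ids")

        arr = values.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value at gene {values.index[g]!r}, "
                f"sample {values.columns[s]!r}"
            )

        ann = self.annotations
        if "sample_id" in ann.columns:
            ann = ann.set_index("sample_id")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        if missing_cols:
            raise ValidationError(f"annotation table missing columns {missing_cols}")
        _check_unique(ann.index, "annotation sample ids")
        unannotated = values.columns.difference(ann.index)
        if len(unannotated):
            raise ValidationError(
                f"samples missing from annotations: {unannotated.tolist()[:5]}"
            )
        # one histotype per case
        per_case = ann.groupby("case_id")["histotype"].nunique()
        conflicted = per_case[per_case > 1]
        if len(conflicted):
            raise ValidationError(
                f"case(s) mapped to multiple histotypes: {conflicted.index.tolist()}"
            )
        # align annotation rows to matrix column order
        self.annotations = ann.loc[values.columns, list(ANNOTATION_COLUMNS)].copy()

        # guard against linear-scale input slipping through
        frac_odd = float(np.mean((arr > 30) | (arr < 0)))
        if frac_odd > 0.01:
            warnings.warn(
                f"{frac_odd:.1%} of entries are negative or exceed 30; "
                "input may not be log2-scale",
                UserWarning,
                stacklevel=2,
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_ids(self) -> pd.Series:
        """Per-sample case id, aligned with ``sample_ids``."""
        return self.annotations["case_id"]

    @property
    def histotypes(self) -> pd.Series:
        """Per-sample histotype, aligned with ``sample_ids``."""
        return self.annotations["histotype"]

    # -- convenience -----------------------------------------------------
    def samples_by(self, level: str) -> dict[str, list[str]]:
        """Group sample ids by ``'histotype'`` or ``'case'``."""
        col = {"histotype": "histotype", "case": "case_id"}.get(level)
        if col is None:
            raise ValueError(f"unknown level {level!r}; expected 'histotype' or 'case'")
        groups: dict[str, list[str]] = {}
        for sid, label in self.annotations[col].items():
            groups.setdefault(str(label), []).append(sid)
        return groups

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.annotations.copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[:, list(sample_ids)], self.annotations.loc[list(sample_ids)]
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.annotations.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), each a de-duplicated list of gene ids."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # preserve order, drop repeats
                seen: dict[str, None] = dict.fromkeys(members)
                self.sets[name] = list(seen)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: object) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}
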