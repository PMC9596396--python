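"""Druggable-target expression calls and their heterogeneity patterns.

A target gene is called *expressed* in a sample when its log2 value reaches
a threshold (default 6.0, the global median of the study's log2 matrix;
``'median'`` resolves the threshold from the dataset itself). Within each
histotype a target is then classified as expressed in all samples, not
expressed, heterogeneous between cases (cases internally uniform but
disagreeing), or heterogeneous within a case (some case has mixed calls —
the pattern that can defeat a targeted therapy inside a single tumor mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection
from .io import median_log2

__all__ = [
    "TargetCallMatrix",
    "CLASSES",
    "expressed_call",
    "target_heterogeneity",
    "shared_pathways",
    "DruggableTargets",
    "DruggableTargetsResults",
]

CLASSES = (
    "expressed_in_all",
    "not_expressed",
    "heterogeneous_between_cases",
    "heterogeneous_within_case",
)


@dataclass
class TargetCallMatrix:
    expressed: pd.DataFrame  # boolean, targets x samples
    threshold: float
    missing: list[str] = field(default_factory=list)


def expressed_call(
    dataset: ExpressionDataset,
    targets: Sequence[str],
    threshold: float | str = 6.0,
) -> TargetCallMatrix:
    """Boolean expressed calls per (target, sample) at an inclusive threshold.

    ``threshold='median'`` uses the median over every entry of the matrix.
    Targets absent from the matrix are reported as missing; no matched
    target at all is an error.
    """
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError(f"unknown threshold {threshold!r}")
        threshold = median_log2(dataset)
    threshold = float(threshold)
    targets = list(dict.fromkeys(targets))
    present = [g for g in targets if g in dataset.gene_ids]
    missing = [g for g in targets if g not in dataset.gene_ids]
    if not present:
        raise ValueError("none of the target genes is present in the matrix")
    calls = dataset.values.loc[present] >= threshold
    return TargetCallMatrix(expressed=calls, threshold=threshold, missing=missing)


def target_heterogeneity(
    calls: TargetCallMatrix,
    annotations: pd.DataFrame,
    level: str = "histotype",
) -> pd.DataFrame:
    """Classify each target's expression pattern within each group.

    ``level='histotype'`` (default) classifies per histotype using its
    cases; ``level='case'`` treats every case as its own group (where the
    between-case class cannot occur). Classes are mutually exclusive, and
    within-case heterogeneity takes precedence over between-case.
    """
    if level not in ("histotype", "case"):
        raise ValueError(f"unknown level {level!r}")
    ann = annotations.loc[calls.expressed.columns]
    group_col = "histotype" if level == "histotype" else "case_id"
    rows = []
    for group in pd.unique(ann[group_col]):
        mask = (ann[group_col] == group).to_numpy()
        block = calls.expressed.loc[:, mask]
        cases = ann.loc[mask, "case_id"]
        for target, flags in block.iterrows():
            n_expr = int(flags.sum())
            n = len(flags)
            if n_expr == n:
                cls = "expressed_in_all"
            elif n_expr == 0:
                cls = "not_expressed"
            else:
                per_case = flags.groupby(cases.to_numpy()).agg(["sum", "size"])
                mixed = (per_case["sum"] > 0) & (per_case["sum"] < per_case["size"])
                cls = (
                    "heterogeneous_within_case"
                    if bool(mixed.any())
                    else "heterogeneous_between_cases"
                )
            rows.append((target, group, cls, n_expr, n))
    return pd.DataFrame(
        rows, columns=["target", level, "class", "n_expressed", "n_samples"]
    )


def shared_pathways(common_flags: pd.DataFrame) -> list[tuple[str, tuple[str, ...]]]:
    """Gene sets commonly enriched in two or more histotypes.

    ``common_flags`` is the boolean sets x histotypes table from
    :func:`tumorhet.scoring.commonly_enriched`. Returns (set, histotypes)
    pairs with at least two flagged histotypes, sorted by subset size
    descending then set name; histotypes within a subset are sorted by name.
    """
    if common_flags.shape[1] < 2:
        raise ValueError("shared-pathway detection needs flags for >= 2 histotypes")
    out = []
    for set_name, flags in common_flags.iterrows():
        hits = tuple(sorted(flags.index[flags.fillna(False).astype(bool)]))
        if len(hits) >= 2:
            out.append((set_name, hits))
    out.sort(key=lambda item: (-len(item[1]), item[0]))
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DruggableTargets:
    """Model: expressed/not-expressed calls and heterogeneity per target.

    ``targets`` may be a flat gene list or a GeneSetCollection mapping
    pathways to their druggable member genes (the pathway structure is kept
    for reporting).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        targets: Sequence[str] | GeneSetCollection,
        threshold: float | str = 6.0,
    ) -> None:
        self.dataset = dataset
        if isinstance(targets, GeneSetCollection):
            self.pathways = {name: list(members) for name, members in targets.items()}
            flat: list[str] = []
            for members in self.pathways.values():
                flat.extend(members)
            self.targets = list(dict.fromkeys(flat))
        else:
            self.pathways = None
            self.targets = list(targets)
        self.threshold = threshold

    def fit(self) -> "DruggableTargetsResults":
        calls = expressed_call(self.dataset, self.targets, self.threshold)
        het = target_heterogeneity(calls, self.dataset.annotations, level="histotype")
        return DruggableTargetsResults(self, calls, het)


class DruggableTargetsResults:
    def __init__(self, model, calls, heterogeneity):
        self.model = model
        self.calls: TargetCallMatrix = calls
        self.heterogeneity: pd.DataFrame = heterogeneity

    def class_counts(self) -> pd.DataFrame:
        """Targets per heterogeneity class, per histotype."""
        return (
            self.heterogeneity.groupby(["histotype", "class"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(CLASSES), fill_value=0)
        )

    def summary(self) -> str:
        lines = [
            "Druggable-target expression calls",
            "=" * 46,
            f"threshold (log2): {self.calls.threshold:g}   "
            f"targets matched: {self.calls.expressed.shape[0]}   "
            f"missing: {len(self.calls.missing)}",
            "",
            "heterogeneity classes per histotype:",
            self.class_counts().to_string(),
        ]
        return "\n".join(lines)
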