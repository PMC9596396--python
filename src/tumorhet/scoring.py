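"""Single-sample gene-set scoring: z-score method, ssGSEA, and enrichment summaries.

The z-score method standardizes each gene across samples (mean 0, sd 1,
unbiased denominator), then scores a gene set in a sample as the sum of
its members' z-values divided by the square root of the number of matched
genes:

    S[set, s] = sum_{g in set} z[g, s] / sqrt(|set matched|)

A set is called *enriched* in a sample when its score is strictly above
zero. Per-case and per-histotype summaries count enriched samples, and a
set is *commonly enriched* in a histotype when the enriched fraction
reaches ``min_fraction`` (default 0.8, i.e. at least 16 of 19-20 samples).

ssGSEA scores a set per sample from the expression ranking alone: genes
are ranked by decreasing expression, in-set positions accumulate weight
|N - rank + 1|^alpha while out-of-set positions accumulate uniformly, and
the (un-normalized) enrichment score is the sum over rank positions of the
difference between the two cumulative distributions. Ties in expression
break by gene-id lexicographic order, so scores are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedMatrix",
    "SetScoreMatrix",
    "EnrichmentSummary",
    "standardize",
    "zscore_set_score",
    "ssgsea_score",
    "ssgsea_score_collection",
    "case_enrichment_summary",
    "commonly_enriched",
    "GeneSetScoring",
    "GeneSetScoringResults",
]

SCOPES = ("all_samples", "per_histotype")


@dataclass
class StandardizedMatrix:
    """Gene-wise z-values, with the means/sds used and the scope they were
    computed in (globally, or within each histotype block)."""

    z: pd.DataFrame  # genes x samples
    scope: str
    means: pd.DataFrame  # genes x scope-groups
    sds: pd.DataFrame


@dataclass
class SetScoreMatrix:
    """Gene-set x sample single-sample scores with boolean enrichment calls."""

    scores: pd.DataFrame  # sets x samples
    method: str
    enriched: pd.DataFrame  # boolean, sets x samples
    n_genes_used: pd.Series  # per set, matched gene count
    missing_sets: list[str] = field(default_factory=list)


@dataclass
class EnrichmentSummary:
    by_case: pd.DataFrame  # set, case_id, histotype, n_enriched, n_samples, fraction
    by_histotype: pd.DataFrame  # set, histotype, n_enriched, n_samples, fraction


def _zscore_block(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe
    z[constant, :] = 0.0
    return z, mean[:, 0], sd[:, 0], int(constant.sum())


def standardize(dataset: ExpressionDataset, scope: str = "all_samples") -> StandardizedMatrix:
    """Center and scale each gene to z-scores (unbiased sd).

    ``scope='per_histotype'`` standardizes each histotype block
    independently, so that a set's enrichment is judged against that
    histotype's own distribution. Constant genes get z = 0 (logged count).
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    values = dataset.values.to_numpy(dtype=float)
    if scope == "all_samples":
        groups = {"all_samples": np.ones(dataset.n_samples, dtype=bool)}
    else:
        hist = dataset.histotypes
        groups = {h: (hist == h).to_numpy() for h in pd.unique(hist)}
    z = np.empty_like(values)
    means, sds = {}, {}
    n_constant = 0
    for name, mask in groups.items():
        if mask.sum() < 2:
            raise ValueError(f"scope group {name!r} has fewer than 2 samples")
        zb, mb, sb, nc = _zscore_block(values[:, mask])
        z[:, mask] = zb
        means[name], sds[name] = mb, sb
        n_constant += nc
    if n_constant:
        logger.info("standardize: %d constant gene block(s) set to z = 0", n_constant)
    return StandardizedMatrix(
        z=pd.DataFrame(z, index=dataset.gene_ids, columns=dataset.sample_ids),
        scope=scope,
        means=pd.DataFrame(means, index=dataset.gene_ids),
        sds=pd.DataFrame(sds, index=dataset.gene_ids),
    )


def zscore_set_score(std: StandardizedMatrix, sets: GeneSetCollection) -> SetScoreMatrix:
    """Single-sample z-score per set: sum of member z-values over sqrt(matched size).

    Set members absent from the matrix are dropped and the square root uses
    the matched count; sets with no matched gene are flagged missing and
    carry no score row.
    """
    gene_index = std.z.index
    rows, used, missing = {}, {}, []
    for name, members in sets.items():
        matched = [g for g in members if g in gene_index]
        if not matched:
            missing.append(name)
            continue
        block = std.z.loc[matched].to_numpy()
        rows[name] = block.sum(axis=0) / np.sqrt(len(matched))
        used[name] = len(matched)
    if missing:
        logger.warning("zscore_set_score: %d set(s) had no matched genes", len(missing))
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=std.z.columns)
    return SetScoreMatrix(
        scores=scores,
        method="zscore",
        enriched=scores > 0,
        n_genes_used=pd.Series(used, dtype=int),
        missing_sets=missing,
    )


def _ssgsea_one_sample(order_in_set: np.ndarray, weights: np.ndarray) -> float:
    """Un-normalized ssGSEA enrichment score for one ranked gene list.

    ``order_in_set`` flags, per rank position (best first), whether the gene
    belongs to the set; ``weights`` is the per-position rank weight
    |N - rank + 1|^alpha. The score sums, over positions, the difference
    between the weighted in-set CDF and the uniform out-of-set CDF.
    """
    in_w = np.where(order_in_set, weights, 0.0)
    total_in = in_w.sum()
    p_in = np.cumsum(in_w) / total_in
    n_out = int((~order_in_set).sum())
    if n_out == 0:
        p_out = np.zeros_like(p_in)
    else:
        p_out = np.cumsum(~order_in_set) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    dataset: ExpressionDataset, gene_set, alpha: float = 0.25
) -> pd.Series:
    """Per-sample ssGSEA score for one gene set (un-normalized ES).

    Genes are ranked by expression descending within each sample; the rank
    statistic of the gene at rank r (1 = highest) is N - r + 1 and in-set
    positions are weighted by its alpha-th power. Ties break by gene id.
    Requires at least two matched set genes.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = set(gene_set)
    gene_ids = dataset.gene_ids
    matched = np.asarray(gene_ids.isin(members))
    if matched.sum() < 2:
        raise ValueError(
            f"ssGSEA needs >= 2 matched set genes; got {int(matched.sum())}"
        )
    n = dataset.n_genes
    # stable ranking: descending value, ascending gene id on ties
    lex_rank = pd.Series(np.argsort(np.argsort(gene_ids)), index=gene_ids)
    values = dataset.values
    rank_stat = (n - np.arange(n)).astype(float)  # N, N-1, ..., 1 by position
    weights = np.abs(rank_stat) ** alpha
    scores = {}
    in_set = matched
    for sid in dataset.sample_ids:
        keys = np.lexsort((lex_rank.to_numpy(), -values[sid].to_numpy()))
        scores[sid] = _ssgsea_one_sample(in_set[keys], weights)
    return pd.Series(scores, name="ssgsea")


def ssgsea_score_collection(
    dataset: ExpressionDataset, sets: GeneSetCollection, alpha: float = 0.25
) -> SetScoreMatrix:
    """ssGSEA over a collection; sets with <2 matched genes are flagged missing."""
    rows, used, missing = {}, {}, []
    present = set(dataset.gene_ids)
    for name, members in sets.items():
        matched = [g for g in members if g in present]
        if len(matched) < 2:
            missing.append(name)
            continue
        rows[name] = ssgsea_score(dataset, matched, alpha=alpha).to_numpy()
        used[name] = len(matched)
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=dataset.sample_ids)
    return SetScoreMatrix(
        scores=scores,
        method="ssgsea",
        enriched=scores > 0,
        n_genes_used=pd.Series(used, dtype=int),
        missing_sets=missing,
    )


def case_enrichment_summary(
    scores: SetScoreMatrix, annotations: pd.DataFrame
) -> EnrichmentSummary:
    """Count enriched samples per (set, case) and per (set, histotype)."""
    enriched = scores.enriched
    ann = annotations.loc[enriched.columns]
    case_rows, hist_rows = [], []
    case_hist = ann.groupby("case_id")["histotype"].first()
    for set_name, flags in enriched.iterrows():
        by_case = flags.groupby(ann["case_id"].to_numpy())
        for case, grp in by_case:
            case_rows.append(
                (set_name, case, case_hist[case], int(grp.sum()), len(grp))
            )
        by_hist = flags.groupby(ann["histotype"].to_numpy())
        for hist, grp in by_hist:
            hist_rows.append((set_name, hist, int(grp.sum()), len(grp)))
    by_case = pd.DataFrame(
        case_rows, columns=["set", "case_id", "histotype", "n_enriched", "n_samples"]
    )
    by_hist = pd.DataFrame(
        hist_rows, columns=["set", "histotype", "n_enriched", "n_samples"]
    )
    for df in (by_case, by_hist):
        df["fraction"] = df["n_enriched"] / df["n_samples"]
    return EnrichmentSummary(by_case=by_case, by_histotype=by_hist)


def commonly_enriched(
    summary: EnrichmentSummary, min_fraction: float = 0.8
) -> pd.DataFrame:
    """Boolean sets x histotypes table: enriched fraction >= ``min_fraction``.

    The default 0.8 encodes the "at least 16 of 19-20 samples" rule.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    wide = summary.by_histotype.pivot(index="set", columns="histotype", values="fraction")
    return wide >= min_fraction


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class GeneSetScoring:
    """Model: single-sample gene-set scores with enrichment decision rules.

    Parameters
    ----------
    dataset : ExpressionDataset
    sets : GeneSetCollection
    method : 'zscore' or 'ssgsea'
    scope : standardization scope for the z-score method
        ('all_samples' keeps scores comparable across histotypes;
        'per_histotype' judges each histotype against itself).
    alpha : ssGSEA rank-weight exponent (default 0.25).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        sets: GeneSetCollection,
        method: str = "zscore",
        scope: str = "all_samples",
        alpha: float = 0.25,
    ) -> None:
        if method not in ("zscore", "ssgsea"):
            raise ValueError(f"unknown method {method!r}")
        self.dataset = dataset
        self.sets = sets
        self.method = method
        self.scope = scope
        self.alpha = alpha

    def fit(self) -> "GeneSetScoringResults":
        if self.method == "zscore":
            std = standardize(self.dataset, scope=self.scope)
            matrix = zscore_set_score(std, self.sets)
        else:
            std = None
            matrix = ssgsea_score_collection(self.dataset, self.sets, alpha=self.alpha)
        summary = case_enrichment_summary(matrix, self.dataset.annotations)
        return GeneSetScoringResults(self, matrix, std, summary)


class GeneSetScoringResults:
    def __init__(self, model, matrix, standardized, enrichment):
        self.model = model
        self.matrix: SetScoreMatrix = matrix
        self.standardized: StandardizedMatrix | None = standardized
        self.enrichment: EnrichmentSummary = enrichment

    @property
    def scores(self) -> pd.DataFrame:
        return self.matrix.scores

    @property
    def enriched(self) -> pd.DataFrame:
        return self.matrix.enriched

    def case_summary(self) -> pd.DataFrame:
        return self.enrichment.by_case

    def histotype_summary(self) -> pd.DataFrame:
        return self.enrichment.by_histotype

    def commonly_enriched(self, min_fraction: float = 0.8) -> pd.DataFrame:
        return commonly_enriched(self.enrichment, min_fraction=min_fraction)

    def summary(self) -> str:
        m = self.matrix
        lines = [
            f"Single-sample gene-set scores ({m.method})",
            "=" * 46,
            f"sets scored: {len(m.scores)}   samples: {m.scores.shape[1]}",
            f"sets with no matched genes: {len(m.missing_sets)}",
            "",
            "enriched samples per (set, histotype):",
            self.enrichment.by_histotype.to_string(index=False, float_format="%.3f"),
        ]
        return "\n".join(lines)
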