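"""Simplified consensus weighted co-expression modules.

The network is unsigned: the adjacency between two genes is
``|pearson_cor|^beta`` (soft threshold, default beta = 12). Topological
overlap (TOM) rescales adjacency by shared neighborhood:

    TOM[i,j] = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_u a_iu   (u != i, j; diagonal 1)

A consensus network across histotypes is the elementwise minimum of the
per-histotype TOMs, keeping only co-expression supported in every group.
Modules come from average-linkage hierarchical clustering of 1 - TOM with
a static cut (in place of the dynamic hybrid tree cut); each module is
summarised by its eigengene — the first principal component of the
module's standardized expression — and modules whose eigengenes correlate
strongly (dissimilarity 1 - cor below ``merge_cut_height``, default 0.25)
are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datasets import ExpressionDataset

__all__ = [
    "ModulePartition",
    "adjacency",
    "tom",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "top_variable_genes",
    "ConsensusCoexpression",
    "CoexpressionResults",
]


@dataclass
class ModulePartition:
    """Gene -> module labels (0 = unassigned) with optional eigengenes.

    Eigengene columns (one per module, named ``ME1``, ``ME2``, ...) have
    unit norm and are sign-oriented to correlate positively with the
    module's mean standardized expression profile.
    """

    labels: pd.Series  # index gene ids, int labels
    eigengenes: pd.DataFrame | None = None  # samples x modules
    variance_explained: pd.Series | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(l) for l in self.labels.unique() if l != 0)

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


def adjacency(dataset: ExpressionDataset, power: float = 12.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``|cor|^power`` (unit diagonal).

    Constant genes have undefined correlations; their off-diagonal entries
    are set to 0 with a warning.
    """
    if dataset.n_samples < 3:
        raise ValueError("adjacency needs at least 3 samples")
    if power <= 0:
        raise ValueError("power must be > 0")
    values = dataset.values.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** power
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): adjacency set to 0",
            UserWarning,
            stacklevel=2,
        )
        adj[constant, :] = 0.0
        adj[:, constant] = 0.0
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=dataset.gene_ids, columns=dataset.gene_ids)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix of an adjacency matrix."""
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # l_ij: u = i and u = j terms vanish with zero diagonal
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def consensus_tom(toms: list[pd.DataFrame]) -> pd.DataFrame:
    """Elementwise minimum across TOMs computed over identical gene sets."""
    if len(toms) < 2:
        raise ValueError("consensus needs at least 2 TOM matrices")
    first = toms[0]
    out = first.to_numpy(dtype=float).copy()
    for other in toms[1:]:
        if not (other.index.equals(first.index) and other.columns.equals(first.columns)):
            raise ValueError("TOM matrices must share the same gene set and order")
        np.minimum(out, other.to_numpy(dtype=float), out=out)
    return pd.DataFrame(out, index=first.index, columns=first.columns)


def detect_modules(
    tom_matrix: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static cut.

    ``cut_height=None`` uses 0.995 times the dendrogram's maximum merge
    height. Clusters smaller than ``min_module_size`` become label 0
    (unassigned); surviving modules are numbered by decreasing size, ties
    broken by the lexicographically smallest member gene id.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = tom_matrix.index
    diss = 1.0 - tom_matrix.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    link = linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.995 * float(link[:, 2].max())
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    keep = []
    for cluster_id, members in labels.groupby(labels).groups.items():
        if len(members) >= min_module_size:
            keep.append((len(members), min(members), cluster_id))
    keep.sort(key=lambda item: (-item[0], item[1]))
    relabel = {old: new for new, (_, _, old) in enumerate(keep, start=1)}
    final = labels.map(lambda c: relabel.get(c, 0)).astype(int)
    final.index.name = "gene_id"
    final.name = "module"
    return ModulePartition(labels=final)


def _standardized_block(dataset: ExpressionDataset, members: list[str]) -> np.ndarray:
    """Samples x genes block, each gene centered/scaled across samples."""
    block = dataset.values.loc[members].to_numpy(dtype=float).T
    mean = block.mean(axis=0, keepdims=True)
    sd = block.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (block - mean) / sd


def module_eigengene(
    dataset: ExpressionDataset, labels: pd.Series
) -> ModulePartition:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm per sample-vector and sign-oriented to
    correlate positively with the module's mean standardized profile (tie
    broken toward positive correlation with the lexicographically first
    member gene). ``variance_explained`` is the first-eigenvalue fraction.
    """
    labels = labels.astype(int)
    eigengenes = {}
    var_explained = {}
    for module_id in sorted(l for l in labels.unique() if l != 0):
        members = sorted(labels.index[labels == module_id])
        if len(members) < 2:
            raise ValueError(f"module {module_id} has fewer than 2 genes")
        z = _standardized_block(dataset, members)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        me = u[:, 0]
        mean_profile = z.mean(axis=1)
        orient = float(me @ mean_profile)
        if orient == 0.0:
            orient = float(me @ z[:, 0])
        if orient < 0:
            me = -me
        eigengenes[f"ME{module_id}"] = me
        total = float((s**2).sum())
        var_explained[f"ME{module_id}"] = float(s[0] ** 2 / total) if total else 0.0
    me_df = pd.DataFrame(eigengenes, index=dataset.sample_ids)
    return ModulePartition(
        labels=labels,
        eigengenes=me_df,
        variance_explained=pd.Series(var_explained, dtype=float),
    )


def merge_modules(
    dataset: ExpressionDataset,
    partition: ModulePartition,
    merge_cut_height: float = 0.25,
    max_iter: int = 100,
) -> ModulePartition:
    """Merge modules whose eigengenes are highly correlated.

    Modules are clustered (average linkage) on 1 - pearson_cor(ME_a, ME_b);
    clusters joined below ``merge_cut_height`` are merged, eigengenes are
    recomputed, and the procedure iterates to a fixed point (at most
    ``max_iter`` rounds). Merged modules are renumbered by decreasing size.
    """
    if partition.eigengenes is None:
        partition = module_eigengene(dataset, partition.labels)
    labels = partition.labels.copy()
    for _ in range(max_iter):
        module_ids = sorted(l for l in labels.unique() if l != 0)
        if len(module_ids) < 2:
            break
        me = module_eigengene(dataset, labels).eigengenes
        cor = np.corrcoef(me.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, 0.0)
        diss = np.clip(diss, 0.0, None)
        link = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(module_ids):
            break
        mapping: dict[int, int] = {}
        for module_id, group in zip(module_ids, groups):
            mapping[module_id] = group
        labels = labels.map(lambda l: 0 if l == 0 else mapping[l]).astype(int)
        # renumber by decreasing size, ties by smallest member gene id
        nonzero = labels[labels != 0]
        sizes = [
            (len(members), min(members), mid)
            for mid, members in nonzero.groupby(nonzero).groups.items()
        ]
        sizes.sort(key=lambda item: (-item[0], item[1]))
        renumber = {old: new for new, (_, _, old) in enumerate(sizes, start=1)}
        labels = labels.map(lambda l: renumber.get(l, 0)).astype(int)
    return module_eigengene(dataset, labels)


def top_variable_genes(dataset: ExpressionDataset, max_genes: int) -> list[str]:
    """The ``max_genes`` genes with highest across-sample variance (order kept)."""
    var = dataset.values.var(axis=1, ddof=1)
    if len(var) <= max_genes:
        return list(dataset.gene_ids)
    cutoff_genes = var.sort_values(ascending=False, kind="stable").index[:max_genes]
    keep = set(cutoff_genes)
    return [g for g in dataset.gene_ids if g in keep]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ConsensusCoexpression:
    """Model: consensus weighted co-expression modules across histotypes.

    Parameters
    ----------
    dataset : ExpressionDataset
    power : soft-threshold exponent beta (default 12).
    min_module_size : smallest cluster kept as a module (default 30).
    cut_height : static tree-cut height on 1 - TOM; None uses 0.995 of the
        maximum merge height.
    merge_cut_height : eigengene dissimilarity below which modules merge
        (default 0.25).
    consensus_by : 'histotype' builds one TOM per histotype and takes the
        elementwise minimum; None uses a single TOM over all samples.
    max_genes : cap on genes (most variable kept) so the dense TOM stays
        tractable (default 5000).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        power: float = 12.0,
        min_module_size: int = 30,
        cut_height: float | None = None,
        merge_cut_height: float = 0.25,
        consensus_by: str | None = "histotype",
        max_genes: int = 5000,
    ) -> None:
        if consensus_by not in (None, "histotype"):
            raise ValueError(f"unknown consensus_by {consensus_by!r}")
        self.dataset = dataset
        self.power = power
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_cut_height = merge_cut_height
        self.consensus_by = consensus_by
        self.max_genes = max_genes

    def fit(self) -> "CoexpressionResults":
        genes = top_variable_genes(self.dataset, self.max_genes)
        data = self.dataset.subset_genes(genes)
        if self.consensus_by == "histotype":
            groups = data.samples_by("histotype")
            if len(groups) < 2:
                toms = [tom(adjacency(data, self.power))]
            else:
                toms = []
                for label, sample_ids in groups.items():
                    if len(sample_ids) < 3:
                        raise ValueError(
                            f"histotype {label!r} has {len(sample_ids)} samples; "
                            "need >= 3 for a correlation network"
                        )
                    toms.append(tom(adjacency(data.subset_samples(sample_ids), self.power)))
            tom_matrix = toms[0] if len(toms) == 1 else consensus_tom(toms)
        else:
            tom_matrix = tom(adjacency(data, self.power))
        partition = detect_modules(tom_matrix, self.min_module_size, self.cut_height)
        if partition.module_ids:
            partition = merge_modules(data, partition, self.merge_cut_height)
        return CoexpressionResults(self, data, tom_matrix, partition)


class CoexpressionResults:
    def __init__(self, model, data, tom_matrix, partition):
        self.model = model
        self.data: ExpressionDataset = data
        self.tom: pd.DataFrame = tom_matrix
        self.partition: ModulePartition = partition

    @property
    def labels(self) -> pd.Series:
        return self.partition.labels

    @property
    def eigengenes(self) -> pd.DataFrame:
        return self.partition.eigengenes

    @property
    def n_modules(self) -> int:
        return len(self.partition.module_ids)

    def module_sizes(self) -> pd.Series:
        labels = self.partition.labels
        return labels[labels != 0].value_counts().sort_index()

    def summary(self) -> str:
        lines = [
            "Consensus co-expression modules",
            "=" * 46,
            f"genes used: {self.data.n_genes}   samples: {self.data.n_samples}",
            f"power: {self.model.power:g}   merge cut height: "
            f"{self.model.merge_cut_height:g}   min module size: "
            f"{self.model.min_module_size}",
            f"modules detected: {self.n_modules}   "
            f"unassigned genes: {int((self.partition.labels == 0).sum())}",
        ]
        if self.n_modules:
            lines += [
                "",
                "module sizes:",
                self.module_sizes().to_string(),
                "",
                "variance explained by eigengenes:",
                self.partition.variance_explained.to_string(float_format="%.3f"),
            ]
        return "\n".join(lines)

    def plot_eigengenes(self, ax=None):
        """Eigengene values per sample, grouped by histotype (one line per module)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        me = self.partition.eigengenes
        order = self.data.annotations.sort_values(["histotype", "case_id"]).index
        for col in me.columns:
            ax.plot(range(len(order)), me.loc[order, col].to_numpy(), label=col, lw=1)
        ax.set_xlabel("samples (grouped by histotype)")
        ax.set_ylabel("eigengene value")
        ax.legend(frameon=False, fontsize=8)
        return ax
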