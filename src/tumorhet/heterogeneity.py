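"""PC-space heterogeneity: embedding, centroids, and four distance summaries.

Samples are embedded by PCA on the gene-centered expression matrix; the
retained leading components define a low-dimensional space in which
euclidean distances summarise transcriptomic heterogeneity at two levels:

* intra-histotype — spread among all samples of one histological type;
* intra-case (ITH) — spread among the multi-region samples of one tumor.

For each group the four summaries are the mean and maximum pairwise
distance d(i, j) over unordered distinct sample pairs, and the mean and
maximum distance d(i, c) from each sample to the group centroid c (the
arithmetic mean position of the group's samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .datasets import ExpressionDataset

__all__ = [
    "PCEmbedding",
    "CentroidSet",
    "fit_pca",
    "select_components",
    "compute_centroids",
    "heterogeneity_metrics",
    "PCHeterogeneity",
    "PCHeterogeneityResults",
]

METRIC_COLUMNS = ["mean_pairwise", "max_pairwise", "mean_centroid", "max_centroid"]
_LEVELS = ("histotype", "case")


@dataclass
class PCEmbedding:
    """Per-sample PC coordinates with explained-variance ratios.

    ``coordinates`` is samples x components (columns PC1, PC2, ...);
    components are ordered by decreasing variance, and each component's
    sign is fixed so that its largest-|loading| gene has a positive loading,
    making coordinates reproducible across runs.
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    centering: pd.Series
    loadings: pd.DataFrame  # genes x components

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def retained(self, k: int) -> pd.DataFrame:
        if not 1 <= k <= self.n_components:
            raise ValueError(
                f"cannot retain {k} components; {self.n_components} available"
            )
        return self.coordinates.iloc[:, :k]


@dataclass
class CentroidSet:
    level: str
    coordinates: pd.DataFrame  # labels x components


def fit_pca(dataset: ExpressionDataset, scale_genes: bool = False) -> PCEmbedding:
    """PCA with samples as observations and genes as variables.

    Genes are mean-centered; by default they are not scaled to unit
    variance (the matrix is already on a common log2 scale). Raises on a
    constant matrix, which has no principal directions.
    """
    if dataset.n_samples < 2 or dataset.n_genes < 2:
        raise ValueError("PCA requires at least 2 samples and 2 genes")
    X = dataset.values.to_numpy(dtype=float).T  # samples x genes
    centering = X.mean(axis=0)
    if scale_genes:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - centering) / sd + centering  # keep centering bookkeeping simple
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant expression matrix: no variance to decompose")
    n_comp = min(dataset.n_samples - 1, dataset.n_genes)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    components = pca.components_  # n_comp x genes
    # sign convention: largest-|loading| gene positive
    flip = np.sign(components[np.arange(n_comp), np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    coords = coords * flip
    components = components * flip[:, None]
    cols = [f"PC{i}" for i in range(1, n_comp + 1)]
    return PCEmbedding(
        coordinates=pd.DataFrame(coords, index=dataset.sample_ids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        centering=pd.Series(centering, index=dataset.gene_ids),
        loadings=pd.DataFrame(components.T, index=dataset.gene_ids, columns=cols),
    )


def _elbow_index(ratios: np.ndarray) -> int:
    """1-based index of the scree point farthest (perpendicular) from the
    line joining the first and last scree points."""
    n = len(ratios)
    pts = np.column_stack([np.arange(1, n + 1, dtype=float), ratios])
    p1, p2 = pts[0], pts[-1]
    direction = p2 - p1
    norm = np.hypot(*direction)
    rel = pts - p1
    dist = np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / norm
    return int(np.argmax(dist)) + 1


def select_components(embedding: PCEmbedding, method: str | int = "elbow") -> int:
    """Choose how many leading components to retain.

    ``method`` is ``'elbow'`` (scree-plot elbow: components strictly before
    the point of maximum perpendicular distance to the first-to-last scree
    line are kept), an integer or ``'fixed:K'`` (pass-through), or
    ``'variance:t'`` (smallest K whose cumulative ratio reaches t).
    """
    ratios = np.asarray(embedding.explained_variance_ratio, dtype=float)
    n = len(ratios)
    if isinstance(method, (int, np.integer)):
        method = f"fixed:{int(method)}"
    if method == "elbow":
        if n < 3:
            raise ValueError("elbow selection needs at least 3 computable components")
        return max(1, _elbow_index(ratios) - 1)
    if method.startswith("fixed:"):
        k = int(method.split(":", 1)[1])
        if not 1 <= k <= n:
            raise ValueError(f"fixed K={k} out of range (1..{n})")
        return k
    if method.startswith("variance:"):
        tau = float(method.split(":", 1)[1])
        cum = np.cumsum(ratios)
        hit = np.nonzero(cum >= tau)[0]
        return int(hit[0]) + 1 if len(hit) else n
    raise ValueError(f"unknown component-selection method {method!r}")


def _group_labels(annotations: pd.DataFrame, level: str) -> pd.Series:
    if level == "histotype":
        return annotations["histotype"]
    if level == "case":
        return annotations["case_id"]
    raise ValueError(f"unknown level {level!r}; expected 'histotype' or 'case'")


def compute_centroids(
    embedding: PCEmbedding,
    annotations: pd.DataFrame,
    level: str,
    n_components: int | None = None,
) -> CentroidSet:
    """Group centroids (componentwise mean) on the retained components."""
    k = n_components or embedding.n_components
    coords = embedding.retained(k)
    labels = _group_labels(annotations.loc[coords.index], level)
    centroids = coords.groupby(labels.to_numpy()).mean()
    centroids.index.name = level
    return CentroidSet(level=level, coordinates=centroids)


def heterogeneity_metrics(
    embedding: PCEmbedding,
    annotations: pd.DataFrame,
    level: str,
    n_components: int | None = None,
) -> pd.DataFrame:
    """The four distance summaries per group at ``level``.

    Pairwise statistics run over unordered distinct within-group pairs;
    centroid statistics over each member's distance to its group centroid.
    Singleton groups report all four metrics as 0 with a warning.
    """
    k = n_components or embedding.n_components
    coords = embedding.retained(k)
    labels = _group_labels(annotations.loc[coords.index], level)
    rows = []
    for label in pd.unique(labels):
        pts = coords.loc[(labels == label).to_numpy()].to_numpy()
        m = len(pts)
        if m == 0:
            raise ValueError(f"empty group {label!r}")
        if m == 1:
            warnings.warn(
                f"{level} group {label!r} has a single sample; metrics set to 0",
                UserWarning,
                stacklevel=2,
            )
            rows.append((label, m, 0.0, 0.0, 0.0, 0.0))
            continue
        d = pdist(pts)
        centroid = pts.mean(axis=0)
        dc = np.linalg.norm(pts - centroid, axis=1)
        rows.append((label, m, d.mean(), d.max(), dc.mean(), dc.max()))
    out = pd.DataFrame(rows, columns=["label", "n_members", *METRIC_COLUMNS])
    out.insert(1, "level", level)
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PCHeterogeneity:
    """Model: PC-space heterogeneity of a multi-region expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
    components : 'elbow' | int | 'fixed:K' | 'variance:t'
        How many leading components to retain for all distances.
    scale_genes : bool
        Scale genes to unit variance before PCA (default off).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        components: str | int = "elbow",
        scale_genes: bool = False,
    ) -> None:
        self.dataset = dataset
        self.components = components
        self.scale_genes = scale_genes

    def fit(self) -> "PCHeterogeneityResults":
        embedding = fit_pca(self.dataset, scale_genes=self.scale_genes)
        k = select_components(embedding, self.components)
        centroids = {
            level: compute_centroids(embedding, self.dataset.annotations, level, k)
            for level in _LEVELS
        }
        reports = {
            level: heterogeneity_metrics(embedding, self.dataset.annotations, level, k)
            for level in _LEVELS
        }
        return PCHeterogeneityResults(self, embedding, k, centroids, reports)


class PCHeterogeneityResults:
    """Fitted PC embedding plus histotype- and case-level distance reports."""

    def __init__(self, model, embedding, n_retained, centroids, reports):
        self.model = model
        self.embedding: PCEmbedding = embedding
        self.n_retained: int = n_retained
        self.centroids: dict[str, CentroidSet] = centroids
        self.reports: dict[str, pd.DataFrame] = reports

    @property
    def cumulative_variance(self) -> float:
        """Fraction of variance explained by the retained components."""
        return float(self.embedding.explained_variance_ratio[: self.n_retained].sum())

    def report(self, level: str) -> pd.DataFrame:
        if level not in self.reports:
            raise ValueError(f"unknown level {level!r}")
        return self.reports[level]

    def mean_case_pairwise_by_histotype(self) -> pd.Series:
        """Average intra-case mean pairwise distance per histotype.

        The case-level mean pairwise distances are averaged over the cases
        of each histotype; this is the single-number ITH ranking of
        histotypes.
        """
        case_rep = self.reports["case"].set_index("label")
        case_hist = self.model.dataset.annotations.groupby("case_id")["histotype"].first()
        grouped = case_rep["mean_pairwise"].groupby(case_hist.loc[case_rep.index])
        return grouped.mean().sort_values(ascending=False)

    def summary(self) -> str:
        evr = self.embedding.explained_variance_ratio
        lines = [
            "PC-space heterogeneity",
            "=" * 46,
            f"samples: {self.model.dataset.n_samples}   genes: {self.model.dataset.n_genes}",
            f"retained components: {self.n_retained} "
            f"(cumulative explained variance {100 * self.cumulative_variance:.2f}%)",
            f"PC1+PC2 explained variance: {100 * evr[:2].sum():.2f}%",
            "",
            "intra-histotype metrics:",
            self.reports["histotype"].to_string(index=False, float_format="%.3f"),
            "",
            "intra-case mean pairwise distance, averaged per histotype:",
            self.mean_case_pairwise_by_histotype().to_string(float_format="%.3f"),
        ]
        return "\n".join(lines)

    def plot_embedding(self, ax=None, components=(1, 2)):
        """Scatter of two PCs colored by histotype, with case and histotype centroids."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        cx, cy = (f"PC{components[0]}", f"PC{components[1]}")
        coords = self.embedding.coordinates
        hist = self.model.dataset.histotypes
        for i, label in enumerate(pd.unique(hist)):
            pts = coords.loc[(hist == label).to_numpy()]
            ax.scatter(pts[cx], pts[cy], s=18, label=str(label), alpha=0.75)
        cen = self.centroids["histotype"].coordinates
        if cx in cen.columns and cy in cen.columns:
            ax.scatter(cen[cx], cen[cy], c="black", s=60, marker="o", label="centroid")
        evr = self.embedding.explained_variance_ratio
        ax.set_xlabel(f"{cx} ({100 * evr[components[0] - 1]:.1f}%)")
        ax.set_ylabel(f"{cy} ({100 * evr[components[1] - 1]:.1f}%)")
        ax.legend(frameon=False, fontsize=8)
        return ax
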