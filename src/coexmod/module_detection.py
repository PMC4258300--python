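"""Module detection inside one gene-set network.

Genes are clustered by average-linkage hierarchical clustering on the TOM
dissimilarity; modules come from a deterministic scan of static tree cuts
(heights from 0.99 * max merge height downward on a fixed grid) that keeps
the cut yielding the most clusters of at least ``min_module_size`` genes.
Each module is summarized by its eigengene (first principal component of the
standardized module submatrix) and per-gene module membership kME (Pearson
correlation between a gene's profile and the eigengene).  Close modules are
merged on eigengene dissimilarity; low-membership genes (kME <= 0.3) are
reassigned to the grey (unassigned) module in a single pruning pass.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data import ExpressionMatrix, impute_gene_means
from .network import SimilarityMatrix

GREY = 0

#: WGCNA-style color aliases for size-ranked module labels (1-based).
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


def label_color(label: int) -> str:
    if label == GREY:
        return "grey"
    if label <= len(COLOR_SEQUENCE):
        return COLOR_SEQUENCE[label - 1]
    return f"module{label}"


class ConstantModuleError(ValueError):
    """Module expression has no variance; eigengene undefined."""


@dataclasses.dataclass
class Module:
    label: int
    genes: list[str]
    eigengene: pd.Series  # unit-norm over samples
    variance_explained: float
    kme: pd.Series  # per member gene

    @property
    def color(self) -> str:
        return label_color(self.label)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclasses.dataclass
class ModulePartition:
    """Gene -> module labels for one term; label 0 ("grey") = unassigned."""

    term: str
    labels: pd.Series  # gene -> int
    modules: dict[int, Module]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def grey_genes(self) -> list[str]:
        return list(self.labels.index[self.labels == GREY])

    def module_list(self) -> list[Module]:
        return [self.modules[k] for k in sorted(self.modules)]


def _standardized(term_matrix: ExpressionMatrix, genes) -> np.ndarray:
    """Gene rows imputed to the gene mean, then centered and scaled to unit
    standard deviation (zero-variance rows become all-zero)."""
    X = impute_gene_means(term_matrix.values.loc[list(genes)].to_numpy(float))
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return X / sd


def module_eigengene(
    term_matrix: ExpressionMatrix, genes
) -> tuple[pd.Series, float]:
    """First principal component over samples of the standardized module
    submatrix, unit norm, sign-fixed so its correlation with the module's
    mean standardized profile is non-negative."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("eigengene needs >=2 genes")
    if term_matrix.n_samples < 3:
        raise ValueError("eigengene needs >=3 samples")
    X = _standardized(term_matrix, genes)
    if not np.any(X):
        raise ConstantModuleError("all module genes are constant")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    e = vt[0]
    mean_profile = X.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e = -e
    variance_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(e, index=term_matrix.sample_ids), variance_explained


def compute_kme(term_matrix: ExpressionMatrix, eigengene: pd.Series) -> pd.Series:
    """kME_g = Pearson correlation of each gene's expression with the
    eigengene, for every gene in the matrix (members and non-members alike).
    Zero-variance genes get NaN."""
    e = eigengene.reindex(term_matrix.sample_ids).to_numpy(float)
    X = impute_gene_means(term_matrix.values.to_numpy(float))
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(ec)
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = np.where(denom > 0, Xc @ ec / denom, np.nan)
    return pd.Series(kme, index=term_matrix.gene_ids)


def _make_module(term_matrix: ExpressionMatrix, label: int, genes) -> Module:
    e, ve = module_eigengene(term_matrix, genes)
    kme = compute_kme(term_matrix.subset_genes(genes), e)
    return Module(label, list(genes), e, ve, kme)


def _build_partition(
    term: str, term_matrix: ExpressionMatrix, clusters: list[list[str]]
) -> ModulePartition:
    """Assemble a partition from gene clusters, size-ranked (ties break on the
    smallest member gene id) with all other genes grey."""
    clusters = sorted(clusters, key=lambda g: (-len(g), min(g)))
    labels = pd.Series(GREY, index=term_matrix.gene_ids, dtype=int)
    modules = {}
    for i, genes in enumerate(clusters, start=1):
        labels.loc[genes] = i
        modules[i] = _make_module(term_matrix, i, genes)
    return ModulePartition(term, labels, modules)


def detect_modules(
    term_matrix: ExpressionMatrix,
    tom_dissimilarity: SimilarityMatrix,
    min_module_size: int = 10,
    cut_step: float = 0.01,
    term: str | None = None,
) -> ModulePartition:
    """Deterministic static-cut scan of the average-linkage TOM dendrogram.

    Candidate cut heights run from ``0.99 * max merge height`` downward on a
    fixed grid (``cut_step``); the retained cut maximizes the number of
    clusters with at least ``min_module_size`` genes (ties resolve to the
    highest such cut).  Qualifying clusters become modules; everything else is
    grey.  A term smaller than ``min_module_size`` is entirely grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    term = term or "term"
    genes = tom_dissimilarity.genes
    if list(term_matrix.gene_ids) != list(genes):
        raise ValueError("term matrix and dissimilarity gene order differ")
    n = len(genes)
    if n < min_module_size:
        return ModulePartition(
            term, pd.Series(GREY, index=term_matrix.gene_ids, dtype=int), {}
        )
    D = np.array(tom_dissimilarity.values, dtype=float, copy=True)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    h_max = float(Z[:, 2].max())
    if h_max <= 1e-12:
        # all dissimilarities (numerically) zero: everything is one module
        return _build_partition(term, term_matrix, [list(genes)])
    top = 0.99 * h_max
    heights = np.arange(cut_step, top + 1e-12, cut_step)[::-1]
    if heights.size == 0:
        heights = np.array([top])
    best_cut, best_count = None, 0
    gene_arr = np.asarray(genes)
    for h in heights:
        flat = fcluster(Z, t=h, criterion="distance")
        _, counts = np.unique(flat, return_counts=True)
        count = int((counts >= min_module_size).sum())
        if count > best_count:
            best_cut, best_count = h, count
    if best_count == 0:
        return ModulePartition(
            term, pd.Series(GREY, index=term_matrix.gene_ids, dtype=int), {}
        )
    flat = fcluster(Z, t=best_cut, criterion="distance")
    clusters = []
    for cid in np.unique(flat):
        members = gene_arr[flat == cid]
        if len(members) >= min_module_size:
            clusters.append(list(members))
    return _build_partition(term, term_matrix, clusters)


def merge_close_modules(
    partition: ModulePartition,
    term_matrix: ExpressionMatrix,
    cut_height: float = 0.25,
) -> ModulePartition:
    """Merge modules whose eigengenes cluster below ``cut_height`` on the
    dissimilarity ``1 - cor(eigengene_a, eigengene_b)`` (average linkage,
    strict threshold so ``cut_height=0`` is the identity).  Merged modules are
    recomputed from the gene union and the partition is re-ranked by size."""
    mods = partition.module_list()
    if len(mods) < 2 or cut_height <= 0:
        clusters = [list(m.genes) for m in mods]
        return _build_partition(partition.term, term_matrix, clusters)
    ME = np.vstack([m.eigengene.to_numpy(float) for m in mods])
    corr = np.corrcoef(ME)
    diss = 1.0 - corr
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    flat = fcluster(Z, t=np.nextafter(cut_height, 0.0), criterion="distance")
    clusters: dict[int, list[str]] = {}
    for m, cid in zip(mods, flat):
        clusters.setdefault(int(cid), []).extend(m.genes)
    return _build_partition(partition.term, term_matrix, list(clusters.values()))


def prune_low_kme(
    partition: ModulePartition,
    term_matrix: ExpressionMatrix,
    kme_cut: float = 0.3,
) -> ModulePartition:
    """Reassign module genes with kME <= ``kme_cut`` (inclusive) to grey.

    Eigengene and kME are recomputed once after pruning (single pass, no
    iteration), so survivors are not re-checked against the cut.  A module
    left with fewer than two genes is deleted and its genes go grey.
    """
    clusters = []
    for m in partition.module_list():
        kept = [g for g in m.genes if np.isfinite(m.kme[g]) and m.kme[g] > kme_cut]
        if len(kept) >= 2:
            clusters.append(kept)
    return _build_partition(partition.term, term_matrix, clusters)


def kmeans_baseline(
    term_matrix: ExpressionMatrix,
    k: int,
    seed: int = 0,
    min_module_size: int = 10,
) -> ModulePartition:
    """K-means comparison partition: k clusters of standardized gene profiles
    (Euclidean distance, 10 restarts, fixed seed); clusters smaller than
    ``min_module_size`` go grey."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > term_matrix.n_genes:
        raise ValueError("k exceeds the number of genes")
    X = _standardized(term_matrix, term_matrix.gene_ids)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    flat = km.fit_predict(X)
    gene_arr = np.asarray(term_matrix.gene_ids)
    clusters = []
    for cid in np.unique(flat):
        members = gene_arr[flat == cid]
        if len(members) >= min_module_size:
            clusters.append(list(members))
    return _build_partition("kmeans", term_matrix, clusters)
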