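"""Weighted co-expression network construction for one gene-set matrix.

The chain is: pairwise Pearson correlation -> unsigned soft-thresholded
adjacency ``a_ij = |r_ij|^beta`` -> topological overlap matrix (TOM) ->
dissimilarity ``1 - TOM`` used for clustering.  The power ``beta`` can be
fixed (the classical unsigned default is 6) or chosen by the scale-free
topology criterion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .data import ExpressionMatrix


@dataclasses.dataclass
class NetworkParams:
    """Parameters controlling adjacency construction.

    ``power`` is the soft-threshold exponent beta; ``candidate_powers`` and
    ``r2_cut`` drive the scale-free selection when it is used.  Networks are
    unsigned (absolute correlation)."""

    power: int = 6
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_cut: float = 0.80
    network_sign: str = "unsigned"

    def __post_init__(self):
        if self.power not in self.candidate_powers:
            raise ValueError("power must be one of candidate_powers")


@dataclasses.dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene similarity with a kind tag."""

    values: np.ndarray
    genes: list[str]
    kind: str  # correlation | adjacency | tom | dissimilarity

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.genes):
            raise ValueError("similarity matrix shape inconsistent with gene list")
        finite = np.isfinite(v)
        asym = np.nanmax(np.abs(np.where(finite & finite.T, v - v.T, 0.0))) if v.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix not symmetric (max deviation {asym:.2e})")
        if self.kind in ("adjacency", "tom"):
            vv = v[finite]
            if vv.size and (vv.min() < -1e-10 or vv.max() > 1 + 1e-10):
                raise ValueError(f"{self.kind} entries outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")


def correlation_matrix(term_matrix: ExpressionMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation between gene rows, pairwise-complete over
    non-missing samples; the diagonal is 1.  Correlations involving a
    zero-variance gene are set missing (NaN)."""
    df = term_matrix.values.T  # samples x genes; pandas corr is column-wise
    corr = df.corr(min_periods=3).to_numpy(dtype=float)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(corr, term_matrix.gene_ids, "correlation")


@dataclasses.dataclass
class PowerSelection:
    power: int
    fit_table: pd.DataFrame  # columns: power, r_squared, slope
    warning: bool  # True when no candidate reached r2_cut


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for a connectivity vector.

    log10(k) is discretized into at most ``n_bins`` equal-count bins; the
    empirical density p(k) per bin (count normalized by total and by the bin's
    log10-k width) is regressed on the bin's mean log10(k).  Returns
    ``(signed_r2, slope)`` where the R^2 is negated when the slope is positive
    (scale-free topology requires a decaying degree distribution).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < 4:
        raise ValueError("too few positive connectivities for a scale-free fit")
    if np.ptp(k) < 1e-12:
        raise ValueError("all-constant connectivity")
    logk = np.sort(np.log10(k))
    n_bins = int(min(n_bins, max(logk.size // 2, 2)))
    chunks = [c for c in np.array_split(logk, n_bins) if c.size]
    # bin edges at midpoints between adjacent chunks; outer edges at the data
    # range so every bin has a well-defined log10(k) width
    edges = [logk[0]]
    for left, right in zip(chunks[:-1], chunks[1:]):
        edges.append((left[-1] + right[0]) / 2.0)
    edges.append(logk[-1])
    xs, ys = [], []
    total = logk.size
    for chunk, lo, hi in zip(chunks, edges[:-1], edges[1:]):
        width = hi - lo
        if width <= 0:
            continue  # collapse of tied values; bin carries no density info
        density = len(chunk) / (total * width)
        xs.append(chunk.mean())
        ys.append(np.log10(density))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity distribution")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-r2 if slope > 0 else r2), float(slope)


def connectivity(adjacency_matrix: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return adjacency_matrix.sum(axis=1) - np.diag(adjacency_matrix)


def pick_soft_threshold(
    correlation: SimilarityMatrix, params: NetworkParams | None = None
) -> PowerSelection:
    """Choose the smallest candidate power whose signed scale-free fit R^2
    reaches ``r2_cut``; if none does, fall back to the R^2-maximizing power
    with a warning flag."""
    params = params or NetworkParams()
    n = len(correlation.genes)
    if n < 10:
        raise ValueError("need >=10 genes to pick a soft threshold")
    rows = []
    for beta in params.candidate_powers:
        adj = adjacency(correlation, beta)
        k = connectivity(adj.values)
        try:
            r2, slope = scale_free_fit(k)
        except ValueError:
            if np.ptp(k) < 1e-12:
                raise
            r2, slope = np.nan, np.nan
        rows.append({"power": beta, "r_squared": r2, "slope": slope})
    table = pd.DataFrame(rows)
    ok = table[table["r_squared"] >= params.r2_cut]
    if len(ok):
        return PowerSelection(int(ok.iloc[0]["power"]), table, warning=False)
    best = table["r_squared"].idxmax()
    if not np.isfinite(table.loc[best, "r_squared"]):
        raise ValueError("scale-free fit failed for every candidate power")
    warnings.warn(
        "no candidate power reached the scale-free R^2 threshold; "
        "falling back to the best-fitting power",
        stacklevel=2,
    )
    return PowerSelection(int(table.loc[best, "power"]), table, warning=True)


def adjacency(correlation: SimilarityMatrix, beta: int) -> SimilarityMatrix:
    """Unsigned soft-threshold adjacency ``a_ij = |r_ij|^beta`` with unit
    diagonal.  Missing correlations become zero adjacency (with a warning) so
    term matrices keep stable dimensions."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = correlation.values
    a = np.abs(r, dtype=float) ** beta
    if np.isnan(a).any():
        warnings.warn(
            "missing correlations set to zero adjacency", stacklevel=2
        )
        a = np.where(np.isnan(a), 0.0, a)
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(a, list(correlation.genes), "adjacency")


def tom(adjacency_matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Topological overlap matrix.

    For i != j::

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with ``l_ij = sum_{u != i,j} a_iu * a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.
    """
    A = np.array(adjacency_matrix.values, dtype=float, copy=True)
    n = A.shape[0]
    if n < 2:
        raise ValueError("TOM undefined for a single-gene network")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # l_ij for i != j since the diagonal of A is zeroed
    denom = np.minimum.outer(k, k) + 1.0 - A
    if np.any(denom <= 0):
        raise ValueError("nonpositive TOM denominator (degenerate adjacency)")
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    T = (T + T.T) / 2.0
    return SimilarityMatrix(T, list(adjacency_matrix.genes), "tom")


def tom_dissimilarity(tom_matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Clustering dissimilarity ``1 - TOM``."""
    d = 1.0 - tom_matrix.values
    np.fill_diagonal(d, 0.0)
    return SimilarityMatrix(d, list(tom_matrix.genes), "dissimilarity")


def build_network(
    term_matrix: ExpressionMatrix,
    params: NetworkParams | None = None,
    auto_power: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix, int, bool]:
    """Convenience: correlation -> (auto-)power -> adjacency -> TOM dissim.

    Returns (correlation, dissimilarity, beta, power_warning)."""
    params = params or NetworkParams()
    corr = correlation_matrix(term_matrix)
    warned = False
    beta = params.power
    if auto_power:
        sel = pick_soft_threshold(corr, params)
        beta, warned = sel.power, sel.warning
    adj = adjacency(corr, beta)
    dissim = tom_dissimilarity(tom(adj))
    return corr, dissim, beta, warned
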