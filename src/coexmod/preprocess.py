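"""Microarray-style quality control and normalization.

Pipeline order is fixed: outlier-sample removal (inter-array correlation,
within phenotype stratum) -> log2 + quantile normalization -> probe
missingness filter -> probe-to-gene collapse -> cross-cohort gene
intersection.  No step reorders samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import ExpressionMatrix


@dataclasses.dataclass
class QCReport:
    """Record of what QC removed and why."""

    mean_iac: pd.Series = dataclasses.field(default_factory=lambda: pd.Series(dtype=float))
    removed_samples: dict[str, str] = dataclasses.field(default_factory=dict)
    removed_probes: list[str] = dataclasses.field(default_factory=list)
    collapse_map: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_iac": {k: float(v) for k, v in self.mean_iac.items()},
            "removed_samples": dict(self.removed_samples),
            "removed_probes": list(self.removed_probes),
            "collapse_map": dict(self.collapse_map),
        }


def mean_iac(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample mean inter-array correlation (IAC).

    For each sample, the mean of pairwise Pearson correlations with all other
    samples of the *same phenotype stratum*, pairwise-complete over
    non-missing genes.  Requires >=3 samples per stratum.
    """
    out = {}
    for status in sorted(matrix.phenotype.unique()):
        ids = list(matrix.phenotype.index[matrix.phenotype == status])
        if len(ids) < 3:
            raise ValueError(
                f"phenotype stratum {status} has {len(ids)} samples (<3)"
            )
        corr = matrix.values[ids].corr(min_periods=2)
        arr = corr.to_numpy(dtype=float, copy=True)
        np.fill_diagonal(arr, np.nan)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(arr, axis=1)
        for sid, m in zip(ids, means):
            out[sid] = m
    return pd.Series(out).reindex(matrix.sample_ids)


def remove_outlier_samples(
    matrix: ExpressionMatrix, z_cut: float = 2.0
) -> tuple[ExpressionMatrix, QCReport]:
    """Iteratively drop samples with stratum mean-IAC z-score < -z_cut.

    IAC is recomputed after each removal round until a fixed point; a stratum
    is never reduced below 3 samples.  All-missing samples are removed first
    with reason "degenerate".
    """
    if not (z_cut > 0):
        raise ValueError("z_cut must be > 0")
    report = QCReport()
    work = matrix.copy()

    degenerate = [
        s for s in work.sample_ids if work.values[s].isna().all()
    ]
    for s in degenerate:
        report.removed_samples[s] = "degenerate"
    if degenerate:
        keep = [s for s in work.sample_ids if s not in set(degenerate)]
        work = work.subset_samples(keep)

    report.mean_iac = mean_iac(work)  # pre-removal snapshot
    while True:
        iac = mean_iac(work)
        to_drop: list[str] = []
        for status in sorted(work.phenotype.unique()):
            ids = list(work.phenotype.index[work.phenotype == status])
            vals = iac.loc[ids]
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd <= 0:
                continue
            z = (vals - vals.mean()) / sd
            flagged = z[z < -z_cut].sort_values()  # worst first
            allowed = max(len(ids) - 3, 0)
            to_drop.extend(flagged.index[:allowed])
        if not to_drop:
            break
        for s in to_drop:
            report.removed_samples[s] = "low_iac"
        keep = [s for s in work.sample_ids if s not in set(to_drop)]
        work = work.subset_samples(keep)
    return work, report


def quantile_normalize(matrix: ExpressionMatrix, log2: bool = False) -> ExpressionMatrix:
    """Quantile-normalize samples (optionally after log2 transform).

    Each sample's sorted value vector is mapped onto the across-sample mean of
    sorted vectors (the reference distribution).  Missing values stay missing
    and are excluded from the reference; tied values receive the mean of their
    quantile targets.  With equal per-sample counts this is the classical
    algorithm exactly, and a second application is the identity.
    """
    V = matrix.values.to_numpy(dtype=float, copy=True)
    if log2:
        if np.nanmin(V) <= 0:
            raise ValueError("nonpositive values cannot be log2-transformed")
        V = np.log2(V)
    n_genes, n_samples = V.shape
    obs_counts = (~np.isnan(V)).sum(axis=0)
    if (obs_counts == 0).any():
        raise ValueError("cannot quantile-normalize an all-missing sample")
    m = int(obs_counts.max())
    grid = (np.arange(m) + 0.5) / m

    # reference quantile curve: mean of per-sample quantile functions
    ref = np.zeros(m)
    for j in range(n_samples):
        col = V[:, j]
        s = np.sort(col[~np.isnan(col)])
        pos = (np.arange(len(s)) + 0.5) / len(s)
        ref += np.interp(grid, pos, s)
    ref /= n_samples

    out = np.full_like(V, np.nan)
    for j in range(n_samples):
        col = V[:, j]
        obs_idx = np.flatnonzero(~np.isnan(col))
        nj = len(obs_idx)
        pos = (np.arange(nj) + 0.5) / nj
        targets = np.interp(pos, grid, ref)
        order = np.argsort(col[obs_idx], kind="mergesort")
        assigned = np.empty(nj)
        assigned[order] = targets
        # ties: average the targets within each group of equal input values
        vals = col[obs_idx]
        uniq, inv = np.unique(vals, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        assigned = (sums / counts)[inv]
        out[obs_idx, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.phenotype.copy(),
    )


def filter_probes(
    matrix: ExpressionMatrix, max_missing_frac: float = 0.30
) -> ExpressionMatrix:
    """Drop probes missing in strictly more than ``max_missing_frac`` of
    samples (a probe missing in exactly the threshold fraction is kept)."""
    if not (0.0 <= max_missing_frac < 1.0):
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac.index[frac <= max_missing_frac]
    return matrix.subset_genes(list(keep))


def collapse_probes(
    matrix: ExpressionMatrix,
    probe2gene: dict[str, str],
    return_map: bool = False,
):
    """Collapse probes to genes, keeping per gene the probe with the highest
    mean intensity across samples (missing values excluded from the mean);
    ties break to the lexicographically smallest probe id.  Probes absent from
    the mapping are dropped."""
    if not probe2gene:
        raise ValueError("empty probe-to-gene mapping")
    means = matrix.values.mean(axis=1, skipna=True)
    best: dict[str, str] = {}
    for probe in matrix.gene_ids:
        gene = probe2gene.get(probe)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None:
            best[gene] = probe
            continue
        m_new, m_cur = means[probe], means[cur]
        if m_new > m_cur or (m_new == m_cur and probe < cur):
            best[gene] = probe
    genes = sorted(best)
    values = matrix.values.loc[[best[g] for g in genes]].copy()
    values.index = genes
    collapsed = ExpressionMatrix(values, matrix.phenotype.copy())
    if return_map:
        return collapsed, dict(best)
    return collapsed


def intersect_genes(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both cohorts to their sorted common gene set."""
    common = sorted(set(train.gene_ids) & set(test.gene_ids))
    if not common:
        raise ValueError("no genes shared between the two matrices")
    return train.subset_genes(common), test.subset_genes(common)


def run_qc(
    matrix: ExpressionMatrix,
    iac_z: float = 2.0,
    max_missing_frac: float = 0.30,
    log2: bool = False,
    probe2gene: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """The full single-cohort QC chain in the fixed order."""
    work, report = remove_outlier_samples(matrix, z_cut=iac_z)
    work = quantile_normalize(work, log2=log2)
    before = set(work.gene_ids)
    work = filter_probes(work, max_missing_frac=max_missing_frac)
    report.removed_probes = sorted(before - set(work.gene_ids))
    if probe2gene is not None:
        work, cmap = collapse_probes(work, probe2gene, return_map=True)
        report.collapse_map = cmap
    return work, report
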