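"""Shared in-memory containers for expression data.

The central object is :class:`ExpressionMatrix`: a genes x samples matrix of
log-scale intensities (``NaN`` marks a missing measurement) together with a
binary phenotype (1 = tumor/case, 0 = control) defined for every sample.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a per-sample binary phenotype.

    Parameters
    ----------
    values
        DataFrame indexed by gene id (rows) with sample ids as columns.
        Missing measurements are ``NaN``.
    phenotype
        Series mapping every sample id to 0 (control) or 1 (case).
    """

    values: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.phenotype.index]
        if missing:
            raise ValueError(f"phenotype undefined for samples: {missing[:5]}")
        # align phenotype to the sample order of the matrix
        self.phenotype = self.phenotype.reindex(self.values.columns).astype(int)
        bad = set(self.phenotype.unique()) - {0, 1}
        if bad:
            raise ValueError(f"phenotype values must be 0/1, got {sorted(bad)}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_ids(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == 1])

    def control_ids(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == 0])

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy(), self.phenotype.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(
            self.values[samples].copy(), self.phenotype.loc[samples].copy()
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.phenotype.copy())

    # -- I/O (TSV, as emitted by the synthetic generator) ---------------
    def write_tsv(self, expr_path, pheno_path=None) -> None:
        """Write expression (rows=genes, header of sample ids) and optionally
        the two-column phenotype table (sample_id, status)."""
        Path(expr_path).parent.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        if pheno_path is not None:
            pheno = self.phenotype.rename("status").rename_axis("sample_id")
            pheno.to_frame().to_csv(pheno_path, sep="\t")

    @classmethod
    def read_tsv(cls, expr_path, pheno_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)["status"]
        pheno.index = pheno.index.astype(str)
        return cls(values.astype(float), pheno)


def align_union_phenotype(a: ExpressionMatrix, b: ExpressionMatrix) -> pd.Series:
    """Phenotype over the union of the two cohorts' samples (must agree)."""
    merged = pd.concat([a.phenotype, b.phenotype])
    dup = merged.index.duplicated(keep="first")
    return merged[~dup]


def impute_gene_means(values: np.ndarray) -> np.ndarray:
    """Replace NaNs row-wise by the gene's observed mean (0 if all missing)."""
    out = np.array(values, dtype=float, copy=True)
    mask = np.isnan(out)
    if not mask.any():
        return out
    counts = (~mask).sum(axis=1)
    sums = np.where(mask, 0.0, out).sum(axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    rows, cols = np.where(mask)
    out[rows, cols] = means[rows]
    return out
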