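"""Permutation Z_summary preservation statistics.

How well does the co-expression structure of a gene set (a whole GO-like term
or a detected module), defined in a reference cohort, replicate in an
independent test cohort?  Observed statistics are computed in the TEST data on
the given genes, using the eigengene direction defined in the REFERENCE data:

density statistics
    ``meanCor``  mean off-diagonal test correlation;
    ``meanAdj``  mean off-diagonal test adjacency (|r|^beta_test);
    ``propVarExplained``  mean squared test kME against the reference-defined
    eigengene re-projected into the test samples (the variance fraction that
    component explains of the standardized test profiles);
    ``meanKME``  mean of those signed test kMEs.

connectivity statistics
    ``cor_kIM``  correlation of intramodular connectivity between cohorts;
    ``cor_cor``  correlation of the vectorized off-diagonal correlation
    matrices;
    ``cor_kME``  correlation of the reference and test kME vectors.

The null draws ``n_perm`` random gene sets of equal size from the test
matrix's gene universe and recomputes every statistic; per-statistic
``Z = (obs - null mean) / null sd``.  ``Z_density`` and ``Z_connectivity``
are the medians of their groups and ``Z_summary`` is their mean.
Interpretation bands: Z_summary < 2 no evidence, 2-10 weak to moderate,
> 10 strong; selection gates use a strict ``Z_summary > cut``.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data import ExpressionMatrix, impute_gene_means
from .genesets import GeneSetCollection

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExplained", "meanKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_cor", "cor_kME")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def derive_seed(master_seed: int, stage: str, name: str) -> int:
    """Stable per-(stage, name) seed below 2**31, independent of iteration
    order."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}:{name}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclasses.dataclass
class StatResult:
    name: str
    group: str  # density | connectivity
    observed: float
    null_mean: float
    null_sd: float
    z: float
    dropped: bool = False  # degenerate null sd


@dataclasses.dataclass
class PreservationStats:
    name: str
    stats: dict[str, StatResult]
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    seed: int
    null_draws: pd.DataFrame | None = None  # one row per permutation

    def table_row(self) -> dict:
        row: dict = {"name": self.name}
        for s in self.stats.values():
            row[f"{s.name}_obs"] = s.observed
            row[f"{s.name}_null_mean"] = s.null_mean
            row[f"{s.name}_null_sd"] = s.null_sd
            row[f"{s.name}_Z"] = s.z
        row["Z_density"] = self.z_density
        row["Z_connectivity"] = self.z_connectivity
        row["Z_summary"] = self.z_summary
        return row


@dataclasses.dataclass
class PreservationVerdict:
    band: str  # none | weak_moderate | strong
    selected: bool
    threshold: float


def classify_preservation(
    stats: PreservationStats, select_cut: float = 5.0
) -> PreservationVerdict:
    """Band per the <2 / 2-10 / >10 rule; selected iff Z_summary > select_cut
    (strict)."""
    z = stats.z_summary
    if z < 2:
        band = "none"
    elif z > 10:
        band = "strong"
    else:
        band = "weak_moderate"
    return PreservationVerdict(band, bool(z > select_cut), select_cut)


class _Cohort:
    """Pre-standardized expression rows for fast repeated subset statistics.

    ``unit`` rows have unit Euclidean norm, so ``unit[idx] @ unit[idx].T`` is
    the Pearson correlation matrix of the subset.
    """

    def __init__(self, matrix: ExpressionMatrix):
        X = impute_gene_means(matrix.values.to_numpy(float))
        X = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.unit = X / norms
        self.genes = np.asarray(matrix.gene_ids)
        self.index = {g: i for i, g in enumerate(self.genes)}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _set_statistics(
    ref: _Cohort, test: _Cohort, idx_ref: np.ndarray, idx_test: np.ndarray,
    beta_ref: int, beta_test: int,
) -> dict[str, float]:
    Ur, Ut = ref.unit[idx_ref], test.unit[idx_test]
    m = Ur.shape[0]
    Cr = Ur @ Ur.T
    Ct = Ut @ Ut.T
    iu = np.triu_indices(m, 1)
    ct_off = Ct[iu]
    out = {
        "meanCor": float(ct_off.mean()),
        "meanAdj": float((np.abs(ct_off) ** beta_test).mean()),
    }
    # reference eigengene direction (top eigenvector of the ref correlation),
    # sign-aligned with the mean reference profile, projected into the test
    # samples: the density statistics ask how much of the test data that
    # reference-defined component still explains
    def _pc1(C: np.ndarray, U: np.ndarray) -> np.ndarray:
        _, vec = eigh(C, subset_by_index=[m - 1, m - 1])
        u1 = vec[:, 0]
        if float(u1 @ U @ U.mean(axis=0)) < 0:
            u1 = -u1
        return u1

    def _profile(u1: np.ndarray, U: np.ndarray) -> np.ndarray:
        e = u1 @ U
        norm = np.linalg.norm(e)
        return e / norm if norm > 0 else e

    u1_ref = _pc1(Cr, Ur)
    kme_t_ref = Ut @ _profile(u1_ref, Ut)  # unit rows -> dot = Pearson r
    out["propVarExplained"] = float((kme_t_ref**2).mean())
    out["meanKME"] = float(kme_t_ref.mean())
    # connectivity statistics compare each cohort's own network geometry;
    # kME is taken against each cohort's own eigengene (projecting reference
    # loadings into the test data would correlate every gene with its own
    # contribution and inflate the statistic even for random sets)
    kme_r_own = Ur @ _profile(u1_ref, Ur)
    kme_t_own = Ut @ _profile(_pc1(Ct, Ut), Ut)
    k_ref = (np.abs(Cr) ** beta_ref).sum(axis=1) - 1.0
    k_test = (np.abs(Ct) ** beta_test).sum(axis=1) - 1.0
    out["cor_kIM"] = _pearson(k_ref, k_test)
    out["cor_cor"] = _pearson(Cr[iu], ct_off)
    out["cor_kME"] = _pearson(kme_r_own, kme_t_own)
    return out


def preservation_zsummary(
    genes,
    reference: ExpressionMatrix,
    test: ExpressionMatrix,
    beta_ref: int = 6,
    beta_test: int = 6,
    n_perm: int = 200,
    seed: int = 0,
    keep_null: bool = False,
    min_genes: int = 10,
    _cohorts: tuple["_Cohort", "_Cohort"] | None = None,
) -> PreservationStats:
    """Permutation Z_summary for one gene set across two cohorts.

    ``genes`` must be present in both matrices; the null samples random gene
    sets of equal size from the test matrix's gene universe (restricted to
    genes also present in the reference, so every null statistic is
    computable).  Reproducible from ``seed``; set ``keep_null`` to retain the
    per-permutation draws for audit.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    ref_c, test_c = _cohorts if _cohorts is not None else (
        _Cohort(reference), _Cohort(test)
    )
    genes = list(genes)
    if len(genes) < min_genes:
        raise ValueError(f"gene set has {len(genes)} genes (<{min_genes})")
    missing = [g for g in genes if g not in ref_c.index or g not in test_c.index]
    if missing:
        raise ValueError(f"genes absent from a cohort: {missing[:5]}")
    idx_ref = np.array([ref_c.index[g] for g in genes])
    idx_test = np.array([test_c.index[g] for g in genes])
    observed = _set_statistics(
        ref_c, test_c, idx_ref, idx_test, beta_ref, beta_test
    )

    shared = [g for g in test_c.genes if g in ref_c.index]
    shared_test_idx = np.array([test_c.index[g] for g in shared])
    shared_ref_idx = np.array([ref_c.index[g] for g in shared])
    if len(shared) < len(genes):
        raise ValueError("test gene universe smaller than the gene set")
    rng = np.random.default_rng(seed)
    draws = []
    m = len(genes)
    for _ in range(n_perm):
        pick = rng.choice(len(shared), size=m, replace=False)
        draws.append(
            _set_statistics(
                ref_c, test_c,
                shared_ref_idx[pick], shared_test_idx[pick],
                beta_ref, beta_test,
            )
        )
    null = pd.DataFrame(draws)

    stats: dict[str, StatResult] = {}
    for name in ALL_STATS:
        group = "density" if name in DENSITY_STATS else "connectivity"
        col = null[name].to_numpy(float)
        col = col[np.isfinite(col)]
        obs = observed[name]
        mean = float(col.mean()) if col.size else np.nan
        sd = float(col.std(ddof=1)) if col.size > 1 else np.nan
        dropped = (not np.isfinite(obs)) or (not np.isfinite(sd)) or sd <= 1e-12
        z = np.nan if dropped else (obs - mean) / sd
        stats[name] = StatResult(name, group, obs, mean, sd, z, dropped)

    def _median(names) -> float:
        zs = [stats[n].z for n in names if not stats[n].dropped]
        return float(np.median(zs)) if zs else np.nan

    z_density = _median(DENSITY_STATS)
    z_connectivity = _median(CONNECTIVITY_STATS)
    parts = [z for z in (z_density, z_connectivity) if np.isfinite(z)]
    # if every statistic of one group is degenerate (e.g. the two cohorts are
    # literally identical), the composite falls back to the other group
    z_summary = float(np.mean(parts)) if parts else np.nan
    return PreservationStats(
        name="",
        stats=stats,
        z_density=z_density,
        z_connectivity=z_connectivity,
        z_summary=z_summary,
        n_permutations=n_perm,
        seed=seed,
        null_draws=null if keep_null else None,
    )


@dataclasses.dataclass
class ScreenResult:
    selected: GeneSetCollection
    table: pd.DataFrame
    stats: dict[str, PreservationStats]
    failures: dict[str, str]


def screen_go_terms(
    collection: GeneSetCollection,
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    beta_ref: int = 6,
    beta_test: int = 6,
    n_perm: int = 200,
    master_seed: int = 0,
    select_cut: float = 5.0,
    keep_null: bool = False,
) -> ScreenResult:
    """Z_summary preservation screen over every term of a collection.

    Per-term seeds derive from ``master_seed`` and the term name, so results
    do not depend on term iteration order.  Terms whose statistics cannot be
    computed are recorded in ``failures`` rather than aborting the screen.
    """
    cohorts = (_Cohort(train), _Cohort(test))
    rows, stats, failures, kept = [], {}, {}, []
    for term in collection:
        seed = derive_seed(master_seed, "term_preservation", term.name)
        try:
            ps = preservation_zsummary(
                term.genes, train, test,
                beta_ref=beta_ref, beta_test=beta_test,
                n_perm=n_perm, seed=seed, keep_null=keep_null,
                _cohorts=cohorts,
            )
        except ValueError as exc:
            failures[term.name] = str(exc)
            continue
        ps.name = term.name
        verdict = classify_preservation(ps, select_cut)
        stats[term.name] = ps
        row = ps.table_row()
        row.update(
            n_genes=len(term.genes), band=verdict.band, selected=verdict.selected
        )
        rows.append(row)
        if verdict.selected:
            kept.append(term)
    table = pd.DataFrame(rows)
    return ScreenResult(
        GeneSetCollection(kept, category=collection.category),
        table,
        stats,
        failures,
    )
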