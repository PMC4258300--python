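"""Module-trait association, evidence enrichment, and candidate calling.

The two-step gate: modules must be trait-associated in the training cohort
(eigengene vs case/control status, Pearson r, BH-FDR < 0.05) and preserved in
the testing cohort (Z_summary > 5).  Surviving modules are tested for
hypergeometric enrichment against five evidence categories (cis-eQTL,
trans-eQTL, SCNA, somatic mutation, prognostic); a module is a candidate when
at least two distinct categories reach FDR < 0.05.  Overlapping candidates
(two-sided Fisher exact test, Bonferroni over pairs) are merged, and
candidate gene unions are tested against TF / miRNA target sets.
"""

from __future__ import annotations

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection


@dataclasses.dataclass
class TraitAssociation:
    term: str
    module_label: int | str
    r: float
    p: float
    n_samples: int
    fdr: float | None = None

    @property
    def module_id(self) -> str:
        return f"{self.term}|{self.module_label}"


@dataclasses.dataclass
class EnrichmentRecord:
    module_id: str
    category: str  # evidence category or regulator name
    overlap: int  # k
    module_size: int  # m (within universe)
    set_size: int  # K (within universe)
    universe_size: int  # N
    p: float
    overlap_genes: tuple[str, ...]
    fdr: float | None = None


@dataclasses.dataclass
class CandidateModule:
    module_id: str
    member_modules: tuple[str, ...]
    genes: tuple[str, ...]
    qualifying: dict[str, float]  # category -> FDR


def trait_association(
    eigengene: pd.Series,
    phenotype: pd.Series,
    term: str = "",
    module_label: int | str = "",
) -> TraitAssociation:
    """Pearson correlation of a module eigengene with case/control status and
    its two-sided p value from the t distribution with n-2 df."""
    common = eigengene.index.intersection(phenotype.index)
    if len(common) < 4:
        raise ValueError("need >=4 samples for a trait association")
    e = eigengene.loc[common].to_numpy(float)
    y = phenotype.loc[common].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class")
    r, p = sps.pearsonr(e, y)
    return TraitAssociation(term, module_label, float(r), float(p), len(common))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotonicity enforced,
    stable under input-order permutation)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_trait_fdr(associations: list[TraitAssociation]) -> list[TraitAssociation]:
    """BH-FDR across the given associations (one joint family)."""
    if not associations:
        return associations
    fdrs = bh_fdr([a.p for a in associations])
    for a, f in zip(associations, fdrs):
        a.fdr = float(f)
    return associations


def hypergeometric_enrichment(
    module_genes,
    evidence_set: GeneSet,
    universe,
    module_id: str = "",
    category: str | None = None,
) -> EnrichmentRecord:
    """Upper-tail hypergeometric enrichment P(X >= k) of a module against one
    gene set, conditioned on the measured-gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module:
        raise ValueError("empty module")
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    evid = evidence_set.gene_set() & universe
    overlap = sorted(module & evid)
    N, K, m, k = len(universe), len(evid), len(module), len(overlap)
    p = float(sps.hypergeom.sf(k - 1, N, K, m)) if k > 0 else 1.0
    return EnrichmentRecord(
        module_id=module_id,
        category=category if category is not None else evidence_set.name,
        overlap=k,
        module_size=m,
        set_size=K,
        universe_size=N,
        p=min(p, 1.0),
        overlap_genes=tuple(overlap),
    )


def enrichment_table(
    modules: dict[str, set],
    collection: GeneSetCollection,
    universe,
) -> list[EnrichmentRecord]:
    """All (module x gene set) hypergeometric tests with BH-FDR computed over
    the whole batch (one family; the family definition is recorded by the
    pipeline manifest)."""
    records = [
        hypergeometric_enrichment(genes, s, universe, module_id=mid)
        for mid, genes in modules.items()
        for s in collection
    ]
    if records:
        fdrs = bh_fdr([r.p for r in records])
        for r, f in zip(records, fdrs):
            r.fdr = float(f)
    return records


def call_candidates(
    modules: dict[str, set],
    enrichment_records: list[EnrichmentRecord],
    rule: str = "any_two",
    min_categories: int = 2,
    fdr_cut: float = 0.05,
) -> list[CandidateModule]:
    """Candidate modules from evidence enrichment.

    ``rule="any_two"``: enriched (FDR < fdr_cut) in at least
    ``min_categories`` distinct evidence categories (cis- and trans-eQTL
    count as distinct).  ``rule="eqtl_plus_other"``: enriched in at least one
    eQTL category and at least one of SCNA / mutation / prognostic.
    Callers pass only modules that already survived the trait and
    preservation gates.
    """
    by_module: dict[str, dict[str, float]] = {}
    for rec in enrichment_records:
        if rec.fdr is None:
            raise ValueError("enrichment records need batch FDR first")
        if rec.fdr < fdr_cut:
            by_module.setdefault(rec.module_id, {})[rec.category] = rec.fdr
    out = []
    for mid in sorted(modules):
        quals = by_module.get(mid, {})
        if rule == "any_two":
            ok = len(quals) >= min_categories
        elif rule == "eqtl_plus_other":
            eqtl = {"cis_eqtl", "trans_eqtl"} & set(quals)
            other = {"scna", "mutation", "prognostic"} & set(quals)
            ok = bool(eqtl) and bool(other)
        else:
            raise ValueError(f"unknown candidate rule {rule!r}")
        if ok:
            out.append(
                CandidateModule(
                    module_id=mid,
                    member_modules=(mid,),
                    genes=tuple(sorted(modules[mid])),
                    qualifying=dict(sorted(quals.items())),
                )
            )
    return out


def module_overlap_fisher(module_a, module_b, universe) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 gene-membership table of two
    modules within the universe.  Returns (odds_ratio, p)."""
    universe = set(universe)
    a, b = set(module_a) & universe, set(module_b) & universe
    if not a or not b:
        raise ValueError("empty module")
    if not (set(module_a) <= universe and set(module_b) <= universe):
        raise ValueError("modules must be subsets of the universe")
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ]
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def merge_overlapping_candidates(
    candidates: list[CandidateModule],
    evidence_collection: GeneSetCollection,
    universe,
    alpha: float = 0.01,
    fdr_cut: float = 0.05,
) -> list[CandidateModule]:
    """Merge candidates with significant pairwise gene overlap.

    Edges join candidate pairs whose two-sided Fisher p times the number of
    pairs (Bonferroni) is below ``alpha``; connected components merge, gene
    sets union, and evidence enrichment is recomputed on the unions (one
    joint FDR batch over the merged modules).  Order-independent.
    """
    if len(candidates) < 2:
        return list(candidates)
    graph = nx.Graph()
    graph.add_nodes_from(c.module_id for c in candidates)
    by_id = {c.module_id: c for c in candidates}
    pairs = list(itertools.combinations(sorted(by_id), 2))
    n_pairs = len(pairs)
    for a, b in pairs:
        _, p = module_overlap_fisher(by_id[a].genes, by_id[b].genes, universe)
        if p * n_pairs < alpha:
            graph.add_edge(a, b)
    merged = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        genes = tuple(sorted(set().union(*(by_id[m].genes for m in members))))
        merged.append(
            CandidateModule(
                module_id="+".join(members),
                member_modules=members,
                genes=genes,
                qualifying={},
            )
        )
    merged.sort(key=lambda c: c.module_id)
    records = enrichment_table(
        {c.module_id: set(c.genes) for c in merged}, evidence_collection, universe
    )
    by_mid: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.fdr is not None and rec.fdr < fdr_cut:
            by_mid.setdefault(rec.module_id, {})[rec.category] = rec.fdr
    for c in merged:
        c.qualifying = dict(sorted(by_mid.get(c.module_id, {}).items()))
    return merged


def regulator_enrichment(
    module_genes,
    regulator_sets: GeneSetCollection,
    universe,
    fdr_cut: float = 0.01,
    min_overlap: int = 2,
    top_n: int = 5,
    module_id: str = "",
) -> list[EnrichmentRecord]:
    """Ranked TF / miRNA target-set enrichment for one candidate module.

    Hypergeometric test per regulator set; sets overlapping the module in
    fewer than ``min_overlap`` genes are discarded before the BH-FDR (family:
    all surviving regulator sets for this module); records with FDR <
    ``fdr_cut`` are ranked by (FDR, p, name) and the top ``top_n`` returned.
    """
    records = [
        hypergeometric_enrichment(
            module_genes, s, universe, module_id=module_id
        )
        for s in regulator_sets
    ]
    records = [r for r in records if r.overlap >= min_overlap]
    if not records:
        return []
    fdrs = bh_fdr([r.p for r in records])
    for r, f in zip(records, fdrs):
        r.fdr = float(f)
    kept = [r for r in records if r.fdr < fdr_cut]
    kept.sort(key=lambda r: (r.fdr, r.p, r.category))
    return kept[: max(top_n, 0)]
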