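"""End-to-end orchestration: QC -> term filter -> term preservation screen ->
per-term networks and modules -> trait association -> module preservation ->
evidence enrichment -> candidate merging -> regulator enrichment.

Every stage seed derives from the master seed and a stage/term name via a
stable hash, so a rerun with the same configuration reproduces the manifest
exactly (timestamps aside) regardless of iteration order.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ExpressionMatrix
from .genesets import GeneSetCollection, filter_by_size, read_gmt, term_expression
from .module_detection import (
    Module,
    ModulePartition,
    detect_modules,
    merge_close_modules,
    prune_low_kme,
)
from .network import NetworkParams, SimilarityMatrix, build_network
from .preprocess import intersect_genes, run_qc
from .preservation import (
    classify_preservation,
    derive_seed,
    preservation_zsummary,
    screen_go_terms,
)
from .significance import (
    CandidateModule,
    attach_trait_fdr,
    call_candidates,
    enrichment_table,
    merge_overlapping_candidates,
    regulator_enrichment,
    trait_association,
)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus optional file paths."""

    # paths (optional; in-memory runs pass objects to `run` directly)
    train_expression: str | None = None
    train_phenotype: str | None = None
    test_expression: str | None = None
    test_phenotype: str | None = None
    go_gmt: str | None = None
    evidence_gmt: str | None = None
    tf_gmt: str | None = None
    mirna_gmt: str | None = None
    out_dir: str | None = None
    # QC
    iac_z: float = 2.0
    max_missing: float = 0.30
    log2: bool = False
    # term eligibility and screening
    go_min: int = 50
    go_max: int = 500
    term_select_cut: float = 5.0
    # network and modules
    power: int = 6
    auto_power: bool = False
    r2_cut: float = 0.80
    min_module_size: int = 10
    merge_height: float = 0.25
    kme_cut: float = 0.3
    # gates
    trait_fdr: float = 0.05
    module_select_cut: float = 5.0
    enrich_fdr: float = 0.05
    candidate_rule: str = "any_two"
    min_categories: int = 2
    merge_alpha: float = 0.01
    regulator_fdr: float = 0.01
    regulator_min_overlap: int = 2
    regulator_top_n: int = 5
    # permutations
    n_perm: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.go_min > self.go_max:
            raise ValueError("go_min must be <= go_max")
        for name in ("max_missing",):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("trait_fdr", "enrich_fdr", "regulator_fdr", "merge_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_perm < 50:
            raise ValueError("n_perm must be >= 50")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclasses.dataclass
class PipelineResult:
    manifest: dict
    screen_table: pd.DataFrame
    partitions: dict[str, ModulePartition]
    trait_table: pd.DataFrame
    module_preservation_table: pd.DataFrame
    enrichment_table: pd.DataFrame
    candidates: list[CandidateModule]
    regulator_tables: dict[str, pd.DataFrame]
    train: ExpressionMatrix
    test: ExpressionMatrix
    module_genes: dict[str, set]
    module_eigengenes: dict[str, pd.Series]
    correlations: dict[str, SimilarityMatrix]

    def trait_significant_ids(self) -> list[str]:
        t = self.trait_table
        return list(t.loc[t["significant"], "module_id"])

    def preserved_ids(self) -> list[str]:
        t = self.module_preservation_table
        if t.empty:
            return []
        return list(t.loc[t["selected"], "module_id"])


def _module_id(term: str, module: Module) -> str:
    return f"{term}|{module.color}"


def _screen_cache_key(train, test, collection, config: PipelineConfig) -> str:
    """Content hash of everything the screen stage depends on."""
    import hashlib

    h = hashlib.blake2b(digest_size=12)
    for m in (train, test):
        h.update(np.ascontiguousarray(m.values.to_numpy()).tobytes())
        h.update(",".join(m.sample_ids).encode())
    for s in collection:
        h.update(s.name.encode() + b"\x00" + ",".join(s.genes).encode())
    h.update(
        f"{config.power}:{config.n_perm}:{config.seed}:"
        f"{config.term_select_cut}".encode()
    )
    return h.hexdigest()


def _cached_screen(train, test, eligible, config: PipelineConfig):
    """Term screen, resumable from a cached intermediate under out_dir.

    The cache key hashes the post-QC matrices, the eligible collection, and
    every screen parameter, so a stale cache can never be reused silently.
    """
    from .preservation import ScreenResult

    cache_path = None
    if config.out_dir:
        key = _screen_cache_key(train, test, eligible, config)
        cache_path = Path(config.out_dir) / "cache" / f"term_screen_{key}.tsv"
        if cache_path.exists():
            table = pd.read_csv(cache_path, sep="\t")
            selected_names = set(table.loc[table["selected"], "name"])
            kept = [s for s in eligible if s.name in selected_names]
            return ScreenResult(
                GeneSetCollection(kept, category=eligible.category),
                table, stats={}, failures={},
            )
    screen = screen_go_terms(
        eligible, train, test,
        beta_ref=config.power, beta_test=config.power,
        n_perm=config.n_perm, master_seed=config.seed,
        select_cut=config.term_select_cut,
    )
    if cache_path is not None and not screen.table.empty:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        screen.table.to_csv(cache_path, sep="\t", index=False)
    return screen


def run(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    go_terms: GeneSetCollection,
    evidence: GeneSetCollection,
    regulators: dict[str, GeneSetCollection] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on in-memory inputs."""
    config = config or PipelineConfig()
    config.validate()
    regulators = regulators or {}
    warnings_log: list[str] = []
    t0 = datetime.datetime.now().isoformat(timespec="seconds")

    # --- stage 1: QC + gene intersection ---------------------------------
    train_qc, rep_train = run_qc(
        train, iac_z=config.iac_z, max_missing_frac=config.max_missing,
        log2=config.log2,
    )
    test_qc, rep_test = run_qc(
        test, iac_z=config.iac_z, max_missing_frac=config.max_missing,
        log2=config.log2,
    )
    train_qc, test_qc = intersect_genes(train_qc, test_qc)
    universe = set(train_qc.gene_ids)

    # --- stage 2: term eligibility ---------------------------------------
    eligible = filter_by_size(
        go_terms, universe, min_size=config.go_min, max_size=config.go_max
    )

    # --- stage 3: term preservation screen (cached when out_dir is set) ---
    screen = _cached_screen(train_qc, test_qc, eligible, config)
    for term, msg in screen.failures.items():
        warnings_log.append(f"term {term}: preservation failed: {msg}")

    # --- stage 4: per-term network + modules -----------------------------
    params = NetworkParams(
        power=config.power, r2_cut=config.r2_cut
    )
    partitions: dict[str, ModulePartition] = {}
    correlations: dict[str, SimilarityMatrix] = {}
    powers: dict[str, int] = {}
    module_genes: dict[str, set] = {}
    module_eigengenes: dict[str, pd.Series] = {}
    for term in screen.selected:
        tm = term_expression(train_qc, term)
        corr, dissim, beta, warned = build_network(
            tm, params, auto_power=config.auto_power
        )
        if warned:
            warnings_log.append(f"term {term.name}: soft-threshold fallback")
        part = detect_modules(
            tm, dissim, min_module_size=config.min_module_size, term=term.name
        )
        part = merge_close_modules(part, tm, cut_height=config.merge_height)
        part = prune_low_kme(part, tm, kme_cut=config.kme_cut)
        partitions[term.name] = part
        correlations[term.name] = corr
        powers[term.name] = beta
        for mod in part.module_list():
            mid = _module_id(term.name, mod)
            module_genes[mid] = set(mod.genes)
            module_eigengenes[mid] = mod.eigengene

    n_detected = sum(p.n_modules for p in partitions.values())

    # --- stage 5: trait association (training cohort) --------------------
    assocs = []
    for term_name, part in partitions.items():
        for mod in part.module_list():
            a = trait_association(
                mod.eigengene, train_qc.phenotype,
                term=term_name, module_label=mod.color,
            )
            assocs.append(a)
    attach_trait_fdr(assocs)
    trait_rows = [
        {
            "module_id": f"{a.term}|{a.module_label}",
            "term": a.term,
            "module": a.module_label,
            "size": len(module_genes[f"{a.term}|{a.module_label}"]),
            "r": a.r,
            "p": a.p,
            "fdr": a.fdr,
            "significant": bool(a.fdr is not None and a.fdr < config.trait_fdr),
        }
        for a in assocs
    ]
    trait_table = pd.DataFrame(
        trait_rows,
        columns=["module_id", "term", "module", "size", "r", "p", "fdr",
                 "significant"],
    )
    significant_ids = [r["module_id"] for r in trait_rows if r["significant"]]

    # --- stage 6: module preservation (testing cohort) --------------------
    pres_rows = []
    preserved_ids = []
    for mid in significant_ids:
        term_name = mid.split("|", 1)[0]
        genes = sorted(module_genes[mid])
        seed = derive_seed(config.seed, "module_preservation", mid)
        try:
            ps = preservation_zsummary(
                genes, train_qc, test_qc,
                beta_ref=powers[term_name], beta_test=powers[term_name],
                n_perm=config.n_perm, seed=seed,
            )
        except ValueError as exc:
            warnings_log.append(f"module {mid}: preservation failed: {exc}")
            continue
        ps.name = mid
        verdict = classify_preservation(ps, config.module_select_cut)
        row = ps.table_row()
        row.update(module_id=mid, band=verdict.band, selected=verdict.selected)
        pres_rows.append(row)
        if verdict.selected:
            preserved_ids.append(mid)
    pres_table = pd.DataFrame(pres_rows)

    # --- stage 7: evidence enrichment + candidates ------------------------
    gated = {mid: module_genes[mid] for mid in preserved_ids}
    records = enrichment_table(gated, evidence, universe)
    enrich_rows = [
        {
            "module_id": r.module_id,
            "category": r.category,
            "overlap": r.overlap,
            "module_size": r.module_size,
            "set_size": r.set_size,
            "universe_size": r.universe_size,
            "p": r.p,
            "fdr": r.fdr,
            "overlap_genes": ",".join(r.overlap_genes),
        }
        for r in records
    ]
    enrich_table = pd.DataFrame(
        enrich_rows,
        columns=["module_id", "category", "overlap", "module_size", "set_size",
                 "universe_size", "p", "fdr", "overlap_genes"],
    )
    candidates = call_candidates(
        gated, records,
        rule=config.candidate_rule,
        min_categories=config.min_categories,
        fdr_cut=config.enrich_fdr,
    )
    n_candidates_raw = len(candidates)

    # --- stage 8: merge overlapping candidates -----------------------------
    candidates = merge_overlapping_candidates(
        candidates, evidence, universe,
        alpha=config.merge_alpha, fdr_cut=config.enrich_fdr,
    )

    # --- stage 9: regulator enrichment -------------------------------------
    regulator_tables: dict[str, pd.DataFrame] = {}
    for kind, coll in regulators.items():
        rows = []
        for cand in candidates:
            hits = regulator_enrichment(
                cand.genes, coll, universe,
                fdr_cut=config.regulator_fdr,
                min_overlap=config.regulator_min_overlap,
                top_n=config.regulator_top_n,
                module_id=cand.module_id,
            )
            for rank, rec in enumerate(hits, start=1):
                rows.append(
                    {
                        "module_id": cand.module_id,
                        "rank": rank,
                        "regulator": rec.category,
                        "overlap": rec.overlap,
                        "p": rec.p,
                        "fdr": rec.fdr,
                        "member_genes": ",".join(rec.overlap_genes),
                    }
                )
        regulator_tables[kind] = pd.DataFrame(
            rows,
            columns=["module_id", "rank", "regulator", "overlap", "p", "fdr",
                     "member_genes"],
        )

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "started": t0,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
        "seeds": {"master": config.seed,
                  "derivation": "blake2b(master:stage:name) % 2^31"},
        "fdr_families": {
            "trait": "all detected modules, one joint batch",
            "evidence": "all (module x category) tests, one joint batch",
            "regulator": "per module, across regulator sets of one kind",
        },
        "counts": {
            "train_samples_in": train.n_samples,
            "train_samples_kept": train_qc.n_samples,
            "test_samples_in": test.n_samples,
            "test_samples_kept": test_qc.n_samples,
            "genes_shared": len(universe),
            "terms_in": len(go_terms),
            "terms_eligible": len(eligible),
            "terms_screened": len(screen.selected),
            "modules_detected": n_detected,
            "modules_trait_significant": len(significant_ids),
            "modules_preserved": len(preserved_ids),
            "candidates": n_candidates_raw,
            "candidates_merged": len(candidates),
        },
        "removed_samples": {
            "train": rep_train.removed_samples,
            "test": rep_test.removed_samples,
        },
        "term_powers": powers,
        "warnings": warnings_log,
    }
    counts = manifest["counts"]
    funnel = [
        counts["modules_detected"],
        counts["modules_trait_significant"],
        counts["modules_preserved"],
        counts["candidates"],
    ]
    assert all(a >= b for a, b in zip(funnel, funnel[1:])), "funnel must shrink"

    return PipelineResult(
        manifest=manifest,
        screen_table=screen.table,
        partitions=partitions,
        trait_table=trait_table,
        module_preservation_table=pres_table,
        enrichment_table=enrich_table,
        candidates=candidates,
        regulator_tables=regulator_tables,
        train=train_qc,
        test=test_qc,
        module_genes=module_genes,
        module_eigengenes=module_eigengenes,
        correlations=correlations,
    )


def export_module_network(
    module: Module,
    correlation: SimilarityMatrix,
    threshold: float = 0.0,
):
    """Edge list of a module's co-expression graph.

    Nodes are ranked by kME descending; edges keep gene pairs with
    ``|r| > threshold`` and weight ``|r|``.  Returns (node table, edge table,
    networkx graph ready for GraphML export).
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    frame = correlation.to_frame()
    genes = [g for g in module.genes if g in frame.index]
    ranked = sorted(genes, key=lambda g: (-module.kme.get(g, -np.inf), g))
    nodes = pd.DataFrame(
        {
            "gene": ranked,
            "rank": np.arange(1, len(ranked) + 1),
            "kme": [module.kme.get(g, np.nan) for g in ranked],
        }
    )
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        graph.add_node(row["gene"], kme=float(row["kme"]), rank=int(row["rank"]))
    edges = []
    for i, a in enumerate(ranked):
        for b in ranked[i + 1:]:
            w = abs(float(frame.loc[a, b]))
            if w > threshold:
                edges.append({"source": a, "target": b, "weight": w})
                graph.add_edge(a, b, weight=w)
    return nodes, pd.DataFrame(edges, columns=["source", "target", "weight"]), graph


def export_eigengene_profiles(
    eigengenes: dict[str, pd.Series], phenotype: pd.Series
) -> pd.DataFrame:
    """Long-format (module, sample, phenotype, eigengene value) table for
    case/control plotting."""
    rows = []
    for mid, e in eigengenes.items():
        for sample, value in e.items():
            rows.append(
                {
                    "module_id": mid,
                    "sample": sample,
                    "phenotype": int(phenotype.loc[sample]),
                    "eigengene": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["module_id", "sample", "phenotype", "eigengene"])


def _write_tables(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.screen_table.to_csv(out_dir / "term_screen.tsv", sep="\t", index=False)
    result.trait_table.to_csv(out_dir / "trait_association.tsv", sep="\t", index=False)
    result.module_preservation_table.to_csv(
        out_dir / "module_preservation.tsv", sep="\t", index=False
    )
    result.enrichment_table.to_csv(
        out_dir / "evidence_enrichment.tsv", sep="\t", index=False
    )
    module_rows = []
    for term, part in result.partitions.items():
        for mod in part.module_list():
            for g in mod.genes:
                module_rows.append(
                    {
                        "term": term,
                        "module": mod.color,
                        "gene": g,
                        "kme": float(mod.kme[g]),
                    }
                )
    pd.DataFrame(
        module_rows, columns=["term", "module", "gene", "kme"]
    ).to_csv(out_dir / "modules.tsv", sep="\t", index=False)
    cand_rows = [
        {
            "module_id": c.module_id,
            "members": ",".join(c.member_modules),
            "n_genes": len(c.genes),
            "qualifying": ";".join(f"{k}:{v:.3g}" for k, v in c.qualifying.items()),
            "genes": ",".join(c.genes),
        }
        for c in result.candidates
    ]
    pd.DataFrame(
        cand_rows, columns=["module_id", "members", "n_genes", "qualifying", "genes"]
    ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    for kind, table in result.regulator_tables.items():
        table.to_csv(out_dir / f"regulators_{kind}.tsv", sep="\t", index=False)
    profiles = export_eigengene_profiles(
        {c.module_id: _merged_eigengene(result, c) for c in result.candidates},
        result.train.phenotype,
    )
    profiles.to_csv(out_dir / "candidate_eigengenes.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)


def _merged_eigengene(result: PipelineResult, candidate: CandidateModule) -> pd.Series:
    from .module_detection import module_eigengene

    e, _ = module_eigengene(result.train.subset_genes(candidate.genes),
                            candidate.genes)
    return e


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs from the configured paths, run the
    pipeline, and write every output table plus the manifest to ``out_dir``."""
    config.validate()
    needed = ["train_expression", "train_phenotype", "test_expression",
              "test_phenotype", "go_gmt", "evidence_gmt"]
    missing = [n for n in needed if getattr(config, n) is None]
    if missing:
        raise ValueError(f"missing required paths: {missing}")
    for n in needed + ["tf_gmt", "mirna_gmt"]:
        path = getattr(config, n)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{n}: {path}")
    train = ExpressionMatrix.read_tsv(config.train_expression, config.train_phenotype)
    test = ExpressionMatrix.read_tsv(config.test_expression, config.test_phenotype)
    go_terms = read_gmt(config.go_gmt, category="go_bp")
    evidence = read_gmt(config.evidence_gmt, category="evidence")
    regulators = {}
    if config.tf_gmt:
        regulators["tf"] = read_gmt(config.tf_gmt, category="regulator")
    if config.mirna_gmt:
        regulators["mirna"] = read_gmt(config.mirna_gmt, category="regulator")
    result = run(train, test, go_terms, evidence, regulators, config)
    if config.out_dir:
        _write_tables(result, Path(config.out_dir))
    return result
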