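"""Two-cohort synthetic expression data with planted co-expression modules.

The generator emulates a training and a testing case/control cohort sharing a
gene universe, GO-like gene sets, and planted latent-factor modules whose
cross-cohort preservation, case/control eigengene shift, and evidence-set
enrichment are all controlled and recorded as ground truth.

Generative model (single latent factor per module):

    x_gs = mu_g + loading * f_ms + eps_gs        for gene g in module m
    x_gs = mu_g + eps_gs                         for background genes

with ``f_ms ~ N(case_shift * phenotype_s, 1)`` per sample, i.i.d. noise
``eps ~ N(0, noise_sd^2)`` and per-gene baseline intercepts
``mu_g ~ N(baseline_mean, baseline_sd^2)`` giving the matrix a realistic
log2-intensity scale (baselines make inter-array correlations high, so the
IAC-based QC is exercisable; they do not affect any gene-gene correlation).

A module with ``preserved=False`` keeps its structure in the training cohort
but, in the testing cohort, its gene rows are swapped with genes outside every
term, so the named genes no longer carry the factor there.  Outlier samples
receive an independent per-gene additive shift of magnitude ``4 * noise_sd``
(IAC-detectable); missing values are missing-completely-at-random.  Everything
is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection, write_gmt


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


EVIDENCE_CATEGORIES = ("cis_eqtl", "trans_eqtl", "scna", "mutation", "prognostic")


@dataclasses.dataclass(frozen=True)
class PlantedModuleSpec:
    """One planted co-expression module inside a host GO-like term."""

    host_term: str
    size: int = 25
    loading: float = 0.9
    case_shift: float = 1.2
    preserved: bool = True
    loading_min: float | None = None  # default 0.55 * loading

    def validate(self) -> None:
        if self.size < 10:
            raise ConfigurationError(
                f"planted module in {self.host_term}: size {self.size} < 10"
            )
        if not (0.0 < self.loading <= 1.0):
            raise ConfigurationError(
                f"planted module in {self.host_term}: loading must be in (0, 1]"
            )
        lo = self.effective_loading_min()
        if not (0.0 < lo <= self.loading):
            raise ConfigurationError(
                f"planted module in {self.host_term}: loading_min must be in "
                f"(0, loading]"
            )

    def effective_loading_min(self) -> float:
        """Per-gene loadings are drawn uniformly in [loading_min, loading];
        the spread gives modules a hub structure (variable kME and
        intramodular connectivity) like real co-expression modules."""
        return 0.55 * self.loading if self.loading_min is None else self.loading_min


@dataclasses.dataclass(frozen=True)
class EvidenceLink:
    """Design: the planted module of ``host_term`` contributes
    ``overlap_fraction`` of its genes to evidence set ``category``."""

    host_term: str
    category: str
    overlap_fraction: float


@dataclasses.dataclass(frozen=True)
class RegulatorLink:
    """Design: regulator target set covering ``coverage`` of a module."""

    regulator: str
    host_term: str
    coverage: float


@dataclasses.dataclass
class SimulationConfig:
    n_genes: int = 3000
    n_train_case: int = 82
    n_train_ctrl: int = 40
    n_test_case: int = 60
    n_test_ctrl: int = 19
    n_go_terms: int = 10
    go_size_range: tuple[int, int] = (60, 100)
    planted_modules: tuple[PlantedModuleSpec, ...] = ()
    noise_sd: float = 0.5
    missing_rate: float = 0.01
    n_outliers: int = 2
    seed: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    evidence_links: tuple[EvidenceLink, ...] = ()
    evidence_set_size: int = 60
    regulator_links: tuple[RegulatorLink, ...] = ()
    regulator_set_size: int = 40
    n_decoy_tf: int = 4
    n_decoy_mirna: int = 4

    def validate(self) -> None:
        lo, hi = self.go_size_range
        if not (10 <= lo <= hi <= self.n_genes):
            raise ConfigurationError(
                f"go_size_range {self.go_size_range} must lie within "
                f"[10, n_genes={self.n_genes}]"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        hosts = {}
        for spec in self.planted_modules:
            spec.validate()
            hosts.setdefault(spec.host_term, 0)
            hosts[spec.host_term] += spec.size
        for host, total in hosts.items():
            if total > hi:
                raise ConfigurationError(
                    f"planted modules in term {host!r} total {total} genes, "
                    f"larger than the maximum host term size {hi}"
                )
        for link in self.evidence_links:
            if link.category not in EVIDENCE_CATEGORIES:
                raise ConfigurationError(f"unknown evidence category {link.category!r}")
            if not (0.0 <= link.overlap_fraction <= 1.0):
                raise ConfigurationError(
                    "evidence overlap_fraction requests more genes than the "
                    "module contains (must be in [0, 1])"
                )
        for link in self.regulator_links:
            if not (0.0 <= link.coverage <= 1.0):
                raise ConfigurationError("regulator coverage must be in [0, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study design: ten GO-like terms, each hosting one planted
    module (six preserved across cohorts, four label-permuted in the testing
    cohort), all with a case/control eigengene shift; two modules are wired to
    evidence sets so they are the designed candidates, and each designed
    candidate has one designed regulator."""
    sizes = [30, 28, 25, 32, 22, 26, 24, 30, 20, 27]
    modules = tuple(
        PlantedModuleSpec(
            host_term=f"T{i + 1:02d}",
            size=sizes[i],
            loading=0.9,
            case_shift=1.2,
            preserved=(i < 6),
        )
        for i in range(10)
    )
    evidence = (
        EvidenceLink("T01", "cis_eqtl", 0.6),
        EvidenceLink("T01", "trans_eqtl", 0.5),
        EvidenceLink("T01", "mutation", 0.5),
        EvidenceLink("T02", "scna", 0.6),
        EvidenceLink("T02", "prognostic", 0.5),
    )
    regulators = (
        RegulatorLink("TF_A", "T01", 0.8),
        RegulatorLink("MIR_A", "T02", 0.8),
    )
    return SimulationConfig(
        planted_modules=modules,
        evidence_links=evidence,
        regulator_links=regulators,
        seed=seed,
    )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the simulated cohorts."""

    module_genes: dict[str, dict[str, list[str]]]  # cohort -> module key -> genes
    term_genes: dict[str, list[str]]
    factors: dict[str, pd.DataFrame]  # cohort -> (module key x sample)
    outlier_samples: dict[str, list[str]]
    host_term: dict[str, str]  # module key -> term
    preserved: dict[str, bool]
    case_shift: dict[str, float]
    evidence_links: tuple[EvidenceLink, ...]
    regulator_links: tuple[RegulatorLink, ...]

    def modules_of_term(self, term: str) -> list[str]:
        return [k for k, t in self.host_term.items() if t == term]

    def preserved_terms(self) -> list[str]:
        return sorted({self.host_term[k] for k, p in self.preserved.items() if p})

    def designed_candidates(self, min_categories: int = 2) -> list[str]:
        """Module keys designed to be enriched in >= min_categories evidence
        categories (and hosted by a preserved term, so they survive the
        screen)."""
        per_module: dict[str, set[str]] = {}
        for link in self.evidence_links:
            if link.overlap_fraction <= 0:
                continue
            for key in self.modules_of_term(link.host_term):
                per_module.setdefault(key, set()).add(link.category)
        return sorted(
            k
            for k, cats in per_module.items()
            if len(cats) >= min_categories and self.preserved[k]
        )

    def to_json(self, path) -> None:
        payload = {
            "module_genes": self.module_genes,
            "term_genes": self.term_genes,
            "factors": {c: df.to_dict(orient="index") for c, df in self.factors.items()},
            "outlier_samples": self.outlier_samples,
            "host_term": self.host_term,
            "preserved": self.preserved,
            "case_shift": self.case_shift,
            "evidence_links": [dataclasses.asdict(x) for x in self.evidence_links],
            "regulator_links": [dataclasses.asdict(x) for x in self.regulator_links],
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# rng stream names, in fixed order, so adding streams never perturbs others
_STREAMS = (
    "baseline",
    "assign",
    "loadings",
    "terms",
    "factors_train",
    "factors_test",
    "noise_train",
    "noise_test",
    "swap",
    "outliers_train",
    "outliers_test",
    "missing_train",
    "missing_test",
    "gene_sets",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _sample_frame(prefix: str, n_case: int, n_ctrl: int):
    ids = [f"{prefix}_CASE_{i + 1:03d}" for i in range(n_case)] + [
        f"{prefix}_CTRL_{i + 1:03d}" for i in range(n_ctrl)
    ]
    pheno = pd.Series([1] * n_case + [0] * n_ctrl, index=ids)
    return ids, pheno


def simulate_cohorts(config: SimulationConfig):
    """Generate (train, test, truth) for the configured design."""
    config.validate()
    rngs = _rngs(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    baseline = rngs["baseline"].normal(
        config.baseline_mean, config.baseline_sd, config.n_genes
    )

    # --- assign disjoint gene blocks to planted modules ------------------
    order = rngs["assign"].permutation(config.n_genes)
    cursor = 0
    module_idx: dict[str, np.ndarray] = {}
    host_term: dict[str, str] = {}
    preserved: dict[str, bool] = {}
    case_shift: dict[str, float] = {}
    specs: dict[str, PlantedModuleSpec] = {}
    counter: dict[str, int] = {}
    total = sum(s.size for s in config.planted_modules)
    if total > config.n_genes:
        raise ConfigurationError("planted modules exceed the gene universe")
    for spec in config.planted_modules:
        counter.setdefault(spec.host_term, 0)
        counter[spec.host_term] += 1
        key = f"{spec.host_term}::m{counter[spec.host_term]}"
        module_idx[key] = np.sort(order[cursor : cursor + spec.size])
        cursor += spec.size
        host_term[key] = spec.host_term
        preserved[key] = spec.preserved
        case_shift[key] = spec.case_shift
        specs[key] = spec
    module_gene_pool = (
        np.concatenate(list(module_idx.values())) if module_idx else np.array([], int)
    )
    non_module = np.setdiff1d(np.arange(config.n_genes), module_gene_pool)

    # --- term membership: host modules + background ----------------------
    lo, hi = config.go_size_range
    term_names = [f"T{i + 1:02d}" for i in range(config.n_go_terms)]
    term_idx: dict[str, np.ndarray] = {}
    rt = rngs["terms"]
    for term in term_names:
        hosted = [k for k in module_idx if host_term[k] == term]
        hosted_idx = (
            np.concatenate([module_idx[k] for k in hosted])
            if hosted
            else np.array([], int)
        )
        if len(hosted_idx) > hi:
            raise ConfigurationError(
                f"planted modules larger than host term {term!r}"
            )
        size = int(rt.integers(max(lo, len(hosted_idx)), hi + 1))
        n_bg = size - len(hosted_idx)
        bg = rt.choice(non_module, size=n_bg, replace=False)
        term_idx[term] = np.sort(np.concatenate([hosted_idx, bg]))
    in_any_term = (
        np.unique(np.concatenate(list(term_idx.values())))
        if term_idx
        else np.array([], int)
    )
    free_pool = np.setdiff1d(non_module, in_any_term)

    # --- per-cohort expression -------------------------------------------
    # per-gene loadings (a gene property, shared by both cohorts)
    loadings = {
        key: rngs["loadings"].uniform(
            specs[key].effective_loading_min(), specs[key].loading, len(idx)
        )
        for key, idx in module_idx.items()
    }

    cohorts = {
        "train": _sample_frame("TR", config.n_train_case, config.n_train_ctrl),
        "test": _sample_frame("TE", config.n_test_case, config.n_test_ctrl),
    }
    matrices: dict[str, ExpressionMatrix] = {}
    factors: dict[str, pd.DataFrame] = {}
    module_genes: dict[str, dict[str, list[str]]] = {}
    outliers: dict[str, list[str]] = {}

    swap_partner: dict[str, np.ndarray] = {}
    pool = free_pool.copy()
    for key in module_idx:
        if preserved[key]:
            continue
        size = len(module_idx[key])
        if len(pool) < size:
            raise ConfigurationError(
                "not enough genes outside all terms to displace a "
                "non-preserved module in the testing cohort"
            )
        pick = rngs["swap"].choice(len(pool), size=size, replace=False)
        swap_partner[key] = pool[np.sort(pick)]
        pool = np.delete(pool, pick)

    for cohort, (ids, pheno) in cohorts.items():
        n_s = len(ids)
        X = baseline[:, None] + rngs[f"noise_{cohort}"].normal(
            0.0, config.noise_sd, (config.n_genes, n_s)
        )
        f_rows = {}
        for key, idx in module_idx.items():
            shift = case_shift[key] * pheno.to_numpy()
            f = rngs[f"factors_{cohort}"].normal(shift, 1.0)
            f_rows[key] = f
            X[idx] += loadings[key][:, None] * f[None, :]
        factors[cohort] = pd.DataFrame(f_rows, index=ids).T

        cohort_map = {k: list(genes[idx]) for k, idx in module_idx.items()}
        if cohort == "test":
            for key, partner in swap_partner.items():
                idx = module_idx[key]
                tmp = X[idx].copy()
                X[idx] = X[partner]
                X[partner] = tmp
                cohort_map[key] = list(genes[partner])
        module_genes[cohort] = cohort_map

        # outlier samples: per-gene additive artifact, IAC-detectable
        out_ids: list[str] = []
        if config.n_outliers > 0:
            picks = rngs[f"outliers_{cohort}"].choice(
                n_s, size=min(config.n_outliers, n_s), replace=False
            )
            for s in np.sort(picks):
                X[:, s] += rngs[f"outliers_{cohort}"].normal(
                    0.0, 4.0 * config.noise_sd, config.n_genes
                )
                out_ids.append(ids[s])
        outliers[cohort] = out_ids

        if config.missing_rate > 0:
            mask = rngs[f"missing_{cohort}"].random((config.n_genes, n_s))
            X = np.where(mask < config.missing_rate, np.nan, X)

        matrices[cohort] = ExpressionMatrix(
            pd.DataFrame(X, index=genes, columns=ids), pheno
        )

    truth = SyntheticTruth(
        module_genes=module_genes,
        term_genes={t: list(genes[idx]) for t, idx in term_idx.items()},
        factors=factors,
        outlier_samples=outliers,
        host_term=host_term,
        preserved=preserved,
        case_shift=case_shift,
        evidence_links=config.evidence_links,
        regulator_links=config.regulator_links,
    )
    return matrices["train"], matrices["test"], truth


@dataclasses.dataclass
class SimulatedGeneSets:
    """GMT-ready collections emitted by :func:`simulate_gene_sets`."""

    go_bp: GeneSetCollection
    evidence: GeneSetCollection
    tf: GeneSetCollection
    mirna: GeneSetCollection

    def write_all(self, directory) -> None:
        directory = Path(directory)
        write_gmt(self.go_bp, directory / "go_bp.gmt")
        write_gmt(self.evidence, directory / "evidence.gmt")
        write_gmt(self.tf, directory / "tf_targets.gmt")
        write_gmt(self.mirna, directory / "mirna_targets.gmt")


def simulate_gene_sets(truth: SyntheticTruth, config: SimulationConfig) -> SimulatedGeneSets:
    """Emit GO-like terms, the five evidence categories, and regulator target
    sets matching the truth's design.  Evidence/regulator background genes are
    drawn outside every planted module so only the designed overlaps are
    enriched."""
    config.validate()
    rng = _rngs(config.seed)["gene_sets"]
    all_module_genes = {
        g for cmap in truth.module_genes.values() for gl in cmap.values() for g in gl
    }
    bg_pool = np.array(
        sorted(
            set(f"G{i:05d}" for i in range(config.n_genes)) - all_module_genes
        )
    )

    go_sets = [
        GeneSet(t, "synthetic GO_BP-like term", tuple(gl))
        for t, gl in truth.term_genes.items()
    ]

    def _designed_overlap(host: str, fraction: float) -> list[str]:
        keys = truth.modules_of_term(host)
        if not keys:
            raise ConfigurationError(f"no planted module in term {host!r}")
        chosen: list[str] = []
        for key in keys:
            mod = truth.module_genes["train"][key]
            n = int(round(fraction * len(mod)))
            if n > len(mod):
                raise ConfigurationError(
                    "requested evidence overlap exceeds module size"
                )
            pick = rng.choice(len(mod), size=n, replace=False)
            chosen.extend(mod[i] for i in np.sort(pick))
        return chosen

    evidence_sets = []
    for category in EVIDENCE_CATEGORIES:
        members: list[str] = []
        for link in truth.evidence_links:
            if link.category != category:
                continue
            members.extend(_designed_overlap(link.host_term, link.overlap_fraction))
        n_bg = max(config.evidence_set_size - len(members), 0)
        if n_bg > 0:
            bg = rng.choice(len(bg_pool), size=n_bg, replace=False)
            members.extend(bg_pool[np.sort(bg)])
        if not members:
            continue  # category unused by this design
        evidence_sets.append(
            GeneSet(category, "synthetic evidence gene set", tuple(dict.fromkeys(members)))
        )

    def _regulator_set(name: str, link: RegulatorLink | None) -> GeneSet:
        members = []
        if link is not None:
            members = _designed_overlap(link.host_term, link.coverage)
        n_bg = max(config.regulator_set_size - len(members), 0)
        if n_bg > 0:
            bg = rng.choice(len(bg_pool), size=n_bg, replace=False)
            members.extend(bg_pool[np.sort(bg)])
        return GeneSet(name, "synthetic regulator target set", tuple(dict.fromkeys(members)))

    tf_sets, mirna_sets = [], []
    for link in truth.regulator_links:
        target = tf_sets if link.regulator.startswith("TF") else mirna_sets
        target.append(_regulator_set(link.regulator, link))
    for i in range(config.n_decoy_tf):
        tf_sets.append(_regulator_set(f"TF_DECOY{i + 1}", None))
    for i in range(config.n_decoy_mirna):
        mirna_sets.append(_regulator_set(f"MIR_DECOY{i + 1}", None))

    return SimulatedGeneSets(
        go_bp=GeneSetCollection(go_sets, category="go_bp"),
        evidence=GeneSetCollection(evidence_sets, category="evidence"),
        tf=GeneSetCollection(tf_sets, category="regulator"),
        mirna=GeneSetCollection(mirna_sets, category="regulator"),
    )
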