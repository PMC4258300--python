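"""Module detection, eigengenes, kME, pruning, merging, K-means baseline."""

import numpy as np
import pandas as pd
import pytest

from coexmod import (
    build_network,
    compute_kme,
    detect_modules,
    kmeans_baseline,
    merge_close_modules,
    module_eigengene,
    prune_low_kme,
    term_expression,
)
from coexmod.genesets import GeneSet
from coexmod.module_detection import GREY, ConstantModuleError
from coexmod.network import SimilarityMatrix
from coexmod.synthetic import PlantedModuleSpec, simulate_cohorts

from conftest import make_matrix, small_config


def two_factor_matrix(sizes=(15, 15), n_bg=0, n_samples=40, noise=0.0, seed=0):
    """Two independent latent factors; optional pure-noise background genes."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(2, n_samples))
    rows, truth = [], []
    for m, size in enumerate(sizes):
        for _ in range(size):
            rows.append(f[m] + rng.normal(0, noise, n_samples))
            truth.append(m + 1)
    for _ in range(n_bg):
        rows.append(rng.normal(0, 1.0, n_samples))
        truth.append(GREY)
    pheno = [1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2)
    return make_matrix(np.array(rows), phenotype=pheno), np.array(truth)


def detect_from_matrix(matrix, **kwargs):
    _, dissim, _, _ = build_network(matrix)
    return detect_modules(matrix, dissim, **kwargs)


class TestDetectModules:
    def test_recovers_two_noise_free_modules_exactly(self):
        m, truth = two_factor_matrix(noise=0.0, n_bg=10)
        part = detect_from_matrix(m)
        assert part.n_modules == 2
        for label in (1, 2):
            detected = set(part.modules[label].genes)
            best = max(
                (set(np.array(m.gene_ids)[truth == t]) for t in (1, 2)),
                key=lambda s: len(s & detected),
            )
            assert detected == best  # Jaccard 1.0
        assert all(truth[m.gene_ids.index(g)] == GREY for g in part.grey_genes())

    def test_min_size_excludes_small_cluster(self):
        # clusters of sizes {12, 9}: one module plus grey
        m, _ = two_factor_matrix(sizes=(12, 9), noise=0.05, seed=1)
        part = detect_from_matrix(m, min_module_size=10)
        assert part.n_modules == 1
        assert part.modules[1].size == 12
        assert len(part.grey_genes()) == 9

    def test_pure_noise_term_is_mostly_grey(self):
        grey_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = make_matrix(
                rng.normal(0, 1, (40, 30)),
                phenotype=[1] * 15 + [0] * 15,
            )
            part = detect_from_matrix(m)
            grey_ok += part.n_modules == 0
        assert grey_ok >= 18

    def test_deterministic(self):
        m, _ = two_factor_matrix(noise=0.3, n_bg=20, seed=2)
        a = detect_from_matrix(m)
        b = detect_from_matrix(m)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_tiny_term_all_grey(self):
        m, _ = two_factor_matrix(sizes=(3, 3), seed=3)
        part = detect_from_matrix(m, min_module_size=10)
        assert part.n_modules == 0
        assert len(part.grey_genes()) == 6


class TestEigengene:
    def test_identical_genes_give_variance_one_and_profile(self):
        x = np.random.default_rng(4).normal(size=20)
        m = make_matrix(np.vstack([x, x, x]), phenotype=[1] * 10 + [0] * 10)
        e, ve = module_eigengene(m, m.gene_ids)
        assert ve == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(e.to_numpy(), z / np.linalg.norm(z), atol=1e-10)

    def test_sign_convention_survives_global_negation(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(6, 15)) + rng.normal(size=15)
        m = make_matrix(V, phenotype=[1] * 8 + [0] * 7)
        m_neg = make_matrix(-V, phenotype=[1] * 8 + [0] * 7)
        for mat in (m, m_neg):
            e, _ = module_eigengene(mat, mat.gene_ids)
            X = mat.values.to_numpy()
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            assert np.corrcoef(e, Xs.mean(0))[0, 1] >= 0

    def test_matches_explicit_covariance_eigendecomposition(self):
        rng = np.random.default_rng(6)
        V = rng.normal(size=(5, 12)) + 0.8 * rng.normal(size=12)
        m = make_matrix(V, phenotype=[1] * 6 + [0] * 6)
        e, ve = module_eigengene(m, m.gene_ids)
        X = (V - V.mean(1, keepdims=True)) / V.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(X.T @ X)  # sample-sample covariance
        v1 = evecs[:, -1]
        if np.corrcoef(v1, X.mean(0))[0, 1] < 0:
            v1 = -v1
        np.testing.assert_allclose(e.to_numpy(), v1, atol=1e-8)
        assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_unit_norm(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(8, 10)), phenotype=[1] * 5 + [0] * 5)
        e, _ = module_eigengene(m, m.gene_ids)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_constant_module_errors(self):
        m = make_matrix(np.ones((3, 5)), phenotype=[1, 1, 1, 0, 0])
        with pytest.raises(ConstantModuleError):
            module_eigengene(m, m.gene_ids)


class TestKME:
    def test_top_gene_of_noise_free_module_has_unit_kme(self):
        m, _ = two_factor_matrix(sizes=(10,), noise=0.0, seed=8)
        e, _ = module_eigengene(m, m.gene_ids)
        kme = compute_kme(m, e)
        np.testing.assert_allclose(kme.to_numpy(), 1.0, atol=1e-10)

    def test_eigengene_as_pseudo_gene_scores_one(self):
        m, _ = two_factor_matrix(sizes=(6,), noise=0.4, seed=9)
        e, _ = module_eigengene(m, m.gene_ids)
        pseudo = make_matrix(
            np.vstack([m.values.to_numpy(), e.to_numpy()]),
            gene_ids=m.gene_ids + ["eigengene"],
            sample_ids=m.sample_ids,
            phenotype=list(m.phenotype),
        )
        assert compute_kme(pseudo, e)["eigengene"] == pytest.approx(1.0)

    def test_background_kme_matches_permutation_null(self):
        # independent genes: |kME| should look like correlation of two random
        # vectors -> compare the empirical spread to a permutation null
        rng = np.random.default_rng(10)
        m, _ = two_factor_matrix(sizes=(12,), n_bg=80, noise=0.2, seed=10)
        part = detect_from_matrix(m)
        e = part.modules[1].eigengene
        kme = compute_kme(m, e)
        bg = kme[[g for g in part.grey_genes()]].to_numpy()
        null = []
        e_arr = e.to_numpy()
        X = m.values.loc[part.grey_genes()].to_numpy()
        for _ in range(200):
            null.append(np.corrcoef(X[0], rng.permutation(e_arr))[0, 1])
        assert np.abs(bg).mean() < 3 * np.abs(null).mean() + 0.1
        assert np.quantile(np.abs(bg), 0.9) < 0.4

    def test_zero_variance_gene_gets_nan(self):
        m = make_matrix(
            np.vstack([np.ones(8), np.random.default_rng(1).normal(size=8)]),
            phenotype=[1] * 4 + [0] * 4,
        )
        e, _ = module_eigengene(m, ["g0", "g1"])  # constant row contributes 0
        kme = compute_kme(m, e)
        assert np.isnan(kme["g0"])


class TestPrune:
    def _partition_with_kme(self, values):
        """Partition with one module whose kME values are controlled."""
        m, _ = two_factor_matrix(sizes=(12,), noise=0.3, seed=11)
        part = detect_from_matrix(m)
        mod = part.modules[1]
        values = list(values)[: mod.size]
        mod.kme = pd.Series(values, index=mod.genes[: len(values)]).reindex(
            mod.genes, fill_value=0.9
        )
        return m, part

    def test_kme_boundary_inclusive_removal(self):
        m, part = self._partition_with_kme([0.3, 0.31])
        pruned = prune_low_kme(part, m, kme_cut=0.3)
        removed = set(part.modules[1].genes) - set(pruned.modules[1].genes)
        assert part.modules[1].genes[0] in removed  # kME = 0.30 removed
        assert part.modules[1].genes[1] not in removed  # kME = 0.31 kept

    def test_emptied_module_is_deleted(self):
        m, part = self._partition_with_kme([0.1] * 12)
        pruned = prune_low_kme(part, m, kme_cut=0.3)
        assert pruned.n_modules == 0
        assert len(pruned.grey_genes()) == len(part.labels)

    def test_all_noise_module_empties_under_pruning(self):
        # a module forced onto pure-noise genes loses its membership
        emptied = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = make_matrix(
                rng.normal(0, 1, (15, 60)), phenotype=[1] * 30 + [0] * 30
            )
            from coexmod.module_detection import _build_partition

            part = _build_partition("noise", m, [list(m.gene_ids)])
            pruned = prune_low_kme(part, m, kme_cut=0.3)
            emptied += pruned.n_modules == 0 or pruned.modules[1].size < 15
        assert emptied >= 8


class TestMerge:
    def test_duplicated_factor_modules_merge(self):
        # two "modules" driven by the same factor -> eigengene dissimilarity 0
        m, _ = two_factor_matrix(sizes=(24,), noise=0.05, seed=12)
        from coexmod.module_detection import _build_partition

        half = m.gene_ids[:12], m.gene_ids[12:]
        part = _build_partition("t", m, [list(half[0]), list(half[1])])
        merged = merge_close_modules(part, m, cut_height=0.25)
        assert merged.n_modules == 1
        assert merged.modules[1].size == 24

    def test_orthogonal_factors_do_not_merge(self):
        m, _ = two_factor_matrix(sizes=(15, 15), noise=0.05, seed=13)
        part = detect_from_matrix(m)
        merged = merge_close_modules(part, m, cut_height=0.25)
        assert merged.n_modules == 2

    def test_zero_cut_height_is_identity(self):
        m, _ = two_factor_matrix(sizes=(15, 15), noise=0.05, seed=14)
        part = detect_from_matrix(m)
        merged = merge_close_modules(part, m, cut_height=0.0)
        pd.testing.assert_series_equal(merged.labels, part.labels)

    def test_merge_is_idempotent(self):
        m, _ = two_factor_matrix(sizes=(15, 12), noise=0.4, n_bg=10, seed=15)
        part = detect_from_matrix(m)
        once = merge_close_modules(part, m, cut_height=0.25)
        twice = merge_close_modules(once, m, cut_height=0.25)
        pd.testing.assert_series_equal(once.labels, twice.labels)


class TestKMeansBaseline:
    def test_k1_single_module(self):
        m, _ = two_factor_matrix(sizes=(12,), noise=0.2, seed=16)
        part = kmeans_baseline(m, k=1, seed=0)
        assert part.n_modules == 1
        assert part.modules[1].size == m.n_genes

    def test_recovers_noise_free_two_factor_truth(self):
        m, truth = two_factor_matrix(noise=0.0, seed=17)
        part = kmeans_baseline(m, k=2, seed=0)
        assert part.n_modules == 2
        genes = np.array(m.gene_ids)
        for label in (1, 2):
            detected = set(part.modules[label].genes)
            assert detected in (set(genes[truth == 1]), set(genes[truth == 2]))

    def test_same_seed_reproduces_labels(self):
        m, _ = two_factor_matrix(noise=0.5, n_bg=10, seed=18)
        a = kmeans_baseline(m, k=3, seed=7)
        b = kmeans_baseline(m, k=3, seed=7)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_k_larger_than_genes_errors(self):
        m, _ = two_factor_matrix(sizes=(10,), seed=19)
        with pytest.raises(ValueError):
            kmeans_baseline(m, k=11, seed=0)


def test_planted_module_recovery_with_generator_truth():
    """End-to-end detect -> merge -> prune on the small synthetic design."""
    cfg = small_config(seed=21)
    train, _, truth = simulate_cohorts(cfg)
    term_genes = truth.term_genes["T01"]
    tm = train.subset_genes(term_genes)
    _, dissim, _, _ = build_network(tm)
    part = detect_modules(tm, dissim, term="T01")
    part = merge_close_modules(part, tm)
    part = prune_low_kme(part, tm)
    planted = set(truth.module_genes["train"]["T01::m1"])
    best = max(
        (set(mod.genes) for mod in part.module_list()),
        key=lambda s: len(s & planted) / len(s | planted),
    )
    assert len(best & planted) / len(best | planted) >= 0.8
    # every surviving member clears the kME cut
    for mod in part.module_list():
        assert (mod.kme.loc[mod.genes] > 0.3).all()
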