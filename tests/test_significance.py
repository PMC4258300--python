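"""Trait association, BH-FDR, exact tests, candidate calling and merging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy import stats as sps

from coexmod import (
    bh_fdr,
    call_candidates,
    hypergeometric_enrichment,
    merge_overlapping_candidates,
    module_overlap_fisher,
    regulator_enrichment,
    trait_association,
)
from coexmod.genesets import GeneSet, GeneSetCollection
from coexmod.significance import CandidateModule, enrichment_table


def hypergeom_tail_enumeration(N, K, m, k):
    """P(X >= k) by exhaustive enumeration of all m-subsets of the universe."""
    hits = total = 0
    for draw in itertools.combinations(range(N), m):
        total += 1
        hits += sum(1 for x in draw if x < K) >= k
    return hits / total


class TestTraitAssociation:
    def test_eigengene_equal_to_phenotype_gives_r_one(self):
        pheno = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
        e = pheno.astype(float)
        a = trait_association(e, pheno)
        assert a.r == pytest.approx(1.0)
        assert a.p < 1e-10

    def test_orthogonal_eigengene_on_balanced_toy_gives_p_one(self):
        pheno = pd.Series([1, 1, 0, 0], index=list("abcd"))
        e = pd.Series([1.0, -1.0, 1.0, -1.0], index=list("abcd"))
        a = trait_association(e, pheno)
        assert a.r == pytest.approx(0.0, abs=1e-12)
        assert a.p == pytest.approx(1.0)

    def test_p_matches_numerically_integrated_t_tail(self):
        rng = np.random.default_rng(0)
        pheno = pd.Series([1] * 10 + [0] * 10, index=[f"s{i}" for i in range(20)])
        e = pd.Series(
            0.4 * pheno.to_numpy() + rng.normal(size=20), index=pheno.index
        )
        a = trait_association(e, pheno)
        n = 20
        t = abs(a.r) * math.sqrt((n - 2) / (1 - a.r**2))
        tail, _ = integrate.quad(
            lambda x: sps.t.pdf(x, df=n - 2), t, np.inf
        )
        assert a.p == pytest.approx(2 * tail, abs=1e-8)

    def test_single_class_phenotype_errors(self):
        pheno = pd.Series([1, 1, 1, 1], index=list("abcd"))
        with pytest.raises(ValueError, match="single class"):
            trait_association(pd.Series([1.0, 2, 3, 4], index=list("abcd")), pheno)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up_including_tie_case(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        # hand step-up: sorted p * m / rank, cummin from the right
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.04, 0.20]), [0.015, 0.06, 0.20]
        )

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_permutation_stability(self, ps, rnd):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = list(range(len(ps)))
        rnd.shuffle(order)
        adj_shuffled = bh_fdr([ps[i] for i in order])
        np.testing.assert_allclose(adj_shuffled, adj[order], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestHypergeometric:
    def setup_method(self):
        self.universe = [f"g{i}" for i in range(20)]

    def record(self, N, K, m, k):
        universe = [f"g{i}" for i in range(N)]
        evid = GeneSet("E", "", tuple(universe[:K]))
        module = universe[:k] + universe[K : K + (m - k)]
        return hypergeometric_enrichment(module, evid, universe)

    def test_module_equals_universe_gives_p_one(self):
        evid = GeneSet("E", "", tuple(self.universe))
        rec = hypergeometric_enrichment(self.universe, evid, self.universe)
        assert rec.p == pytest.approx(1.0)
        assert rec.overlap == 20

    def test_closed_form_full_overlap(self):
        # N=20, K=5, m=5, k=5 -> 1 / C(20,5)
        rec = self.record(20, 5, 5, 5)
        assert rec.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            N = int(rng.integers(4, 11))
            K = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, K + m - N), min(K, m) + 1))
            rec = self.record(N, K, m, k)
            assert rec.p == pytest.approx(
                hypergeom_tail_enumeration(N, K, m, k), rel=1e-9
            )

    def test_equals_one_sided_fisher(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            m = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + m - N), min(K, m) + 1))
            rec = self.record(N, K, m, k)
            table = [[k, m - k], [K - k, N - K - m + k]]
            _, p_fisher = sps.fisher_exact(table, alternative="greater")
            assert rec.p == pytest.approx(p_fisher, rel=1e-9)

    def test_empty_inputs_rejected(self):
        evid = GeneSet("E", "", ("g0",))
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], evid, self.universe)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["g0"], evid, [])


class TestFisherOverlap:
    def test_identical_modules_extreme(self):
        universe = [f"g{i}" for i in range(200)]
        module = universe[:20]
        _, p = module_overlap_fisher(module, module, universe)
        assert p < 1e-10

    def test_table_matches_tail_enumeration(self):
        # table (3,2; 1,4): N=10, |a|=5, |b|=4, k=3
        universe = [f"g{i}" for i in range(10)]
        a = universe[:5]
        b = universe[:3] + universe[5:6]
        odds, p = module_overlap_fisher(a, b, universe)
        # exhaustive two-sided tail: sum over k' with pmf <= pmf(k)
        pmf = sps.hypergeom(10, 5, 4).pmf
        p_ref = sum(
            pmf(kk) for kk in range(0, 5) if pmf(kk) <= pmf(3) * (1 + 1e-9)
        )
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_random_disjoint_modules_usually_not_significant(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(500)]
        sig = 0
        for _ in range(20):
            picks = rng.choice(500, size=30, replace=False)
            a = [universe[i] for i in picks[:15]]
            b = [universe[i] for i in picks[15:]]
            _, p = module_overlap_fisher(a, b, universe)
            sig += p < 0.05
        assert sig <= 2

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module_overlap_fisher([], ["g1"], ["g0", "g1"])


class TestCallCandidates:
    def records(self, fdr_map):
        recs = []
        for (mid, cat), fdr in fdr_map.items():
            from coexmod.significance import EnrichmentRecord

            recs.append(
                EnrichmentRecord(
                    module_id=mid, category=cat, overlap=5, module_size=20,
                    set_size=50, universe_size=1000, p=fdr / 2,
                    overlap_genes=(), fdr=fdr,
                )
            )
        return recs

    def test_two_categories_qualify(self):
        # mirrors a candidate enriched in cis-eQTL (8.93e-3) and SCNA (0.040)
        recs = self.records(
            {("M", "cis_eqtl"): 8.93e-3, ("M", "scna"): 0.040,
             ("M", "mutation"): 0.4}
        )
        out = call_candidates({"M": set("abc")}, recs)
        assert [c.module_id for c in out] == ["M"]
        assert set(out[0].qualifying) == {"cis_eqtl", "scna"}

    def test_single_category_does_not_qualify(self):
        recs = self.records({("M", "cis_eqtl"): 1e-5})
        assert call_candidates({"M": set("abc")}, recs) == []

    def test_min_categories_one_is_superset_of_default(self):
        recs = self.records(
            {("A", "cis_eqtl"): 0.01, ("A", "scna"): 0.02,
             ("B", "mutation"): 0.01}
        )
        modules = {"A": set("ab"), "B": set("cd")}
        default = {c.module_id for c in call_candidates(modules, recs)}
        relaxed = {
            c.module_id
            for c in call_candidates(modules, recs, min_categories=1)
        }
        assert default <= relaxed
        assert relaxed == {"A", "B"}

    def test_eqtl_plus_other_rule(self):
        recs = self.records(
            {("A", "cis_eqtl"): 0.01, ("A", "trans_eqtl"): 0.02,
             ("B", "cis_eqtl"): 0.01, ("B", "scna"): 0.02}
        )
        modules = {"A": set("ab"), "B": set("cd")}
        strict = {
            c.module_id
            for c in call_candidates(modules, recs, rule="eqtl_plus_other")
        }
        assert strict == {"B"}


class TestMergeCandidates:
    def _cand(self, mid, genes):
        return CandidateModule(mid, (mid,), tuple(genes), {})

    def _evidence(self, universe):
        return GeneSetCollection(
            [GeneSet("cis_eqtl", "", tuple(universe[:30]))], category="evidence"
        )

    def test_disjoint_candidates_unchanged(self):
        universe = [f"g{i}" for i in range(300)]
        cands = [
            self._cand("A", universe[:20]),
            self._cand("B", universe[100:120]),
        ]
        out = merge_overlapping_candidates(cands, self._evidence(universe), universe)
        assert sorted(c.module_id for c in out) == ["A", "B"]

    def test_near_duplicates_merge_into_one(self):
        universe = [f"g{i}" for i in range(300)]
        cands = [
            self._cand("A", universe[:20]),
            self._cand("B", universe[2:22]),
        ]
        out = merge_overlapping_candidates(cands, self._evidence(universe), universe)
        assert len(out) == 1
        assert out[0].module_id == "A+B"
        assert set(out[0].genes) == set(universe[:22])

    def test_merge_is_order_independent(self):
        universe = [f"g{i}" for i in range(300)]
        cands = [
            self._cand("A", universe[:20]),
            self._cand("B", universe[2:22]),
            self._cand("C", universe[200:220]),
        ]
        a = merge_overlapping_candidates(cands, self._evidence(universe), universe)
        b = merge_overlapping_candidates(cands[::-1], self._evidence(universe), universe)
        assert [(c.module_id, c.genes) for c in a] == [
            (c.module_id, c.genes) for c in b
        ]


class TestRegulatorEnrichment:
    def setup_method(self):
        self.universe = [f"g{i}" for i in range(500)]
        self.module = self.universe[:25]

    def test_single_gene_overlap_excluded_regardless_of_p(self):
        sets = GeneSetCollection(
            [GeneSet("R1", "", (self.universe[0],))], category="regulator"
        )
        assert regulator_enrichment(self.module, sets, self.universe) == []

    def test_designed_regulator_ranks_first(self):
        designed = GeneSet("HIT", "", tuple(self.module[:20] + self.universe[400:420]))
        rng = np.random.default_rng(4)
        decoys = [
            GeneSet(
                f"D{i}", "",
                tuple(np.array(self.universe)[rng.choice(range(100, 500), 40, replace=False)]),
            )
            for i in range(5)
        ]
        sets = GeneSetCollection([designed, *decoys], category="regulator")
        hits = regulator_enrichment(self.module, sets, self.universe)
        assert hits and hits[0].category == "HIT"

    def test_top_n_zero_gives_empty_report(self):
        designed = GeneSet("HIT", "", tuple(self.module[:20]))
        sets = GeneSetCollection([designed], category="regulator")
        assert regulator_enrichment(self.module, sets, self.universe, top_n=0) == []


def test_enrichment_table_fdr_is_joint_across_modules_and_sets():
    universe = [f"g{i}" for i in range(100)]
    coll = GeneSetCollection(
        [
            GeneSet("E1", "", tuple(universe[:30])),
            GeneSet("E2", "", tuple(universe[30:60])),
        ],
        category="evidence",
    )
    modules = {"A": set(universe[:10]), "B": set(universe[90:])}
    records = enrichment_table(modules, coll, universe)
    assert len(records) == 4
    np.testing.assert_allclose(
        [r.fdr for r in records], bh_fdr([r.p for r in records])
    )
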