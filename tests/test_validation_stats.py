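"""Disease overlap, co-mention Fisher tests, Resnik similarity, patient support."""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from phenco.cohort_io import (
    Cohort,
    DiseaseAnnotations,
    LiteratureCorpus,
    Ontology,
    Patient,
)
from phenco.sor_mapping import PhenotypeGeneMap
from phenco.validation_stats import (
    build_ic_table,
    cluster_membership_summary,
    cluster_semantic_score,
    comention_test,
    gene_comention_count,
    pair_disease_overlap,
    patient_cluster_support,
    resnik_similarity,
)


class TestPairDiseaseOverlap:
    ann = DiseaseAnnotations(annotations={
        "D1": frozenset({"p1", "p2"}),
        "D2": frozenset({"p1", "p2", "p3"}),
        "D3": frozenset({"p1"}),
    })

    def test_hand_count(self):
        pairs = [("p1", "p2")]
        assert pair_disease_overlap(pairs, self.ann, 1) == 1
        assert pair_disease_overlap(pairs, self.ann, 2) == 1
        assert pair_disease_overlap(pairs, self.ann, 3) == 0

    def test_empty_annotations(self):
        empty = DiseaseAnnotations(annotations={})
        assert pair_disease_overlap([("p1", "p2")], empty, 1) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        terms = [f"p{i}" for i in range(10)]
        ann = DiseaseAnnotations(annotations={
            f"D{i}": frozenset(terms[j] for j in rng.choice(10, 4, replace=False))
            for i in range(20)
        })
        pairs = [(terms[i], terms[j]) for i in range(10) for j in range(i + 1, 10)]
        counts = [pair_disease_overlap(pairs, ann, t) for t in (1, 2, 3)]
        assert counts[0] >= counts[1] >= counts[2]


def fisher_oracle(n11, sa, sb, U) -> float:
    """Exact one-sided enumeration over tables with fixed margins."""
    num = sum(
        comb(sa, i) * comb(U - sa, sb - i)
        for i in range(n11, min(sa, sb) + 1)
        if sb - i <= U - sa
    )
    return float(Fraction(num, comb(U, sb)))


class TestComention:
    def test_saturated_margin(self, small_corpus):
        res = comention_test(small_corpus, "HP:all", "HP:B")
        assert res.fisher_p == pytest.approx(1.0)

    def test_disjoint_sets(self, small_corpus):
        res = comention_test(small_corpus, "HP:C", "HP:disj")
        assert res.n11 == 0 and res.fisher_p == pytest.approx(1.0)

    def test_missing_term_flagged(self, small_corpus):
        res = comention_test(small_corpus, "HP:A", "HP:nope")
        assert res.fisher_p is None and res.missing_terms == ("HP:nope",)

    def test_table_cells_sum_to_universe(self, small_corpus):
        res = comention_test(small_corpus, "HP:A", "HP:B")
        assert res.n11 + res.n10 + res.n01 + res.n00 == small_corpus.U

    def test_oracle_example(self, small_corpus):
        # |A|=8, |B|=6, n11=5, U=20
        res = comention_test(small_corpus, "HP:A", "HP:B")
        assert (res.n11, res.n10, res.n01) == (5, 3, 1)
        assert res.fisher_p == pytest.approx(fisher_oracle(5, 8, 6, 20), rel=1e-12)

    def test_matches_scipy_fisher_greater(self, small_corpus):
        from scipy.stats import fisher_exact
        res = comention_test(small_corpus, "HP:A", "HP:B")
        table = [[res.n11, res.n10], [res.n01, res.n00]]
        assert res.fisher_p == pytest.approx(
            fisher_exact(table, alternative="greater")[1], rel=1e-10
        )


class TestGeneComention:
    def test_empty_gene_abstracts_observed_zero(self):
        corpus = LiteratureCorpus(term_abstracts={"HP:A": frozenset({"x"})})
        pg = PhenotypeGeneMap(genes={"HP:A": frozenset({"g1", "g2"})})
        obs, mu, sd, z = gene_comention_count(corpus, pg, 10, seed=1)
        assert obs == 0

    def test_single_gene_null_degenerate(self):
        corpus = LiteratureCorpus(term_abstracts={
            "HP:A": frozenset({"x"}), "g1": frozenset({"x"}),
        })
        pg = PhenotypeGeneMap(genes={"HP:A": frozenset({"g1"})})
        obs, mu, sd, z = gene_comention_count(corpus, pg, 10, seed=1)
        # only one gene: every permutation is the identity
        assert obs == 1 and mu == 1.0 and sd == 0.0 and z is None

    def test_planted_signal_positive_z(self):
        rng = np.random.default_rng(8)
        abstracts = [f"a{i}" for i in range(300)]
        terms = {}
        genes = {}
        for i in range(10):
            block = frozenset(abstracts[i * 20:(i + 1) * 20])
            terms[f"HP:{i}"] = block
            terms[f"g{i}"] = block  # gene shares its phenotype's abstracts
            genes[f"HP:{i}"] = frozenset({f"g{i}"})
        terms["pad"] = frozenset(abstracts)
        corpus = LiteratureCorpus(term_abstracts=terms)
        pg = PhenotypeGeneMap(genes=genes)
        obs, mu, sd, z = gene_comention_count(corpus, pg, 200, seed=2)
        assert obs == 10
        assert z is not None and z > 3


@pytest.fixture
def ic_fixture(diamond_ontology):
    # annotate 4 objects; counts propagate through the DAG
    annotations = {
        "O1": ["HP:leaf"],
        "O2": ["HP:leaf"],
        "O3": ["HP:sib"],
        "O4": ["HP:mid2"],
    }
    return build_ic_table(diamond_ontology, annotations)


class TestResnik:
    def test_hand_computed_ic(self, ic_fixture):
        # p(root)=1, p(mid1)=3/4, p(mid2)=3/4, p(leaf)=1/2, p(sib)=1/4
        assert ic_fixture["HP:root"] == pytest.approx(0.0)
        assert ic_fixture["HP:mid1"] == pytest.approx(-math.log(0.75))
        assert ic_fixture["HP:leaf"] == pytest.approx(-math.log(0.5))
        assert ic_fixture["HP:sib"] == pytest.approx(-math.log(0.25))

    def test_root_only_ancestor_gives_zero(self, diamond_ontology):
        # two terms whose only common ancestor is the (uninformative) root
        onto = Ontology(parents={
            "r": frozenset(), "x": frozenset({"r"}), "y": frozenset({"r"}),
        })
        ic = build_ic_table(onto, {"O1": ["x"], "O2": ["y"]})
        assert resnik_similarity("x", "y", ic, onto) == 0.0

    def test_self_similarity(self, diamond_ontology, ic_fixture):
        ic_max = max(ic_fixture.values())
        expected = ic_fixture["HP:leaf"] / ic_max
        assert resnik_similarity("HP:leaf", "HP:leaf", ic_fixture,
                                 diamond_ontology) == pytest.approx(expected)

    def test_mica_across_diamond(self, diamond_ontology, ic_fixture):
        # leaf vs sib: common ancestors {mid1, root}; MICA is mid1
        ic_max = max(ic_fixture.values())
        expected = ic_fixture["HP:mid1"] / ic_max
        got = resnik_similarity("HP:leaf", "HP:sib", ic_fixture, diamond_ontology)
        assert got == pytest.approx(expected)

    def test_unannotated_term_is_error(self, diamond_ontology):
        ic = build_ic_table(diamond_ontology, {"O1": ["HP:sib"]})
        with pytest.raises(ValueError, match="HP:leaf"):
            resnik_similarity("HP:leaf", "HP:sib", ic, diamond_ontology)

    def test_range_zero_one(self, diamond_ontology, ic_fixture):
        terms = ["HP:leaf", "HP:sib", "HP:mid1", "HP:mid2"]
        for a in terms:
            for b in terms:
                v = resnik_similarity(a, b, ic_fixture, diamond_ontology)
                assert 0.0 <= v <= 1.0


def _tight_ontology(n_branches=4, leaves_per_branch=4):
    parents = {"root": frozenset()}
    branches = {}
    for b in range(n_branches):
        parents[f"br{b}"] = frozenset({"root"})
        branches[f"br{b}"] = []
        for l in range(leaves_per_branch):
            parents[f"t{b}_{l}"] = frozenset({f"br{b}"})
            branches[f"br{b}"].append(f"t{b}_{l}")
    return Ontology(parents=parents), branches


class TestClusterSemanticScore:
    def test_planted_tight_clusters_high_z(self):
        onto, branches = _tight_ontology()
        annotations = {f"O{i}_{t}": [t] for i in range(2)
                       for leaves in branches.values() for t in leaves}
        ic = build_ic_table(onto, annotations)
        clusters = list(branches.values())  # semantically tight by construction
        cmp = cluster_semantic_score(clusters, ic, onto, n_randomizations=300, seed=5)
        assert cmp.z is not None and cmp.z > 3

    def test_identical_phenotype_clusters_z_degenerate(self):
        onto, branches = _tight_ontology(1, 2)
        ic = build_ic_table(onto, {"O1": ["t0_0"], "O2": ["t0_1"]})
        clusters = [["t0_0", "t0_1"], ["t0_0", "t0_1"]]
        cmp = cluster_semantic_score(clusters, ic, onto, n_randomizations=50, seed=1)
        # only two distinct terms pooled: every reassignment yields the same
        # multiset of cluster compositions on average; observed within noise
        assert cmp.observed == pytest.approx(cmp.observed)
        assert cmp.n_randomizations == 50

    def test_cluster_size_validation(self, diamond_ontology):
        ic = build_ic_table(diamond_ontology, {"O1": ["HP:leaf"]})
        with pytest.raises(ValueError):
            cluster_semantic_score([["HP:leaf"]], ic, diamond_ontology, 10, 0)


class TestPatientClusterSupport:
    def _cohort(self):
        return Cohort([
            Patient("P1", frozenset({"a", "b", "c"})),      # full 3-term cluster
            Patient("P2", frozenset({"a", "x"})),            # 1 per cluster
            Patient("P3", frozenset({"x", "y", "q"})),       # 2 in cluster 2
            Patient("P4", frozenset({"q", "r"})),            # no cluster terms
        ])

    clusters = [["a", "b", "c"], ["x", "y", "z"]]

    def test_counts(self):
        sup = patient_cluster_support(self._cohort(), self.clusters,
                                      n_randomizations=20, seed=0)
        assert sup.per_patient_max == {"P1": 3, "P2": 1, "P3": 2}
        assert sup.n_ge2 == 2 and sup.n_ge3 == 1
        assert sup.per_patient_max["P1"] <= 3  # bounded by phenotype count

    def test_planted_support_beats_random(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(40)]
        clusters = [terms[i * 4:(i + 1) * 4] for i in range(10)]
        patients = []
        for i in range(60):
            cl = clusters[rng.integers(10)]
            extra = terms[rng.integers(40)]
            patients.append(Patient(f"P{i}", frozenset(cl[:3]) | {extra}))
        sup = patient_cluster_support(Cohort(patients), clusters,
                                      n_randomizations=50, seed=1)
        assert sup.n_ge2 > sup.random_mean_ge2
        assert sup.n_ge3 > sup.random_mean_ge3

    def test_membership_summary_marginals(self):
        rows = cluster_membership_summary(self._cohort(), self.clusters)
        assert sum(n for *_, n in rows) == 3  # P4 excluded

    def test_membership_rows(self):
        rows = set(cluster_membership_summary(self._cohort(), self.clusters))
        # P1 and P3: 3 phenotypes touching 1 cluster; P2: 2 phenotypes, 2 clusters
        assert rows == {(3, 1, 2), (2, 2, 1)}
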