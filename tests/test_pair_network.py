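"""Pair construction, the hypergeometric index and the network null models."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenco.cohort_io import Cohort, Patient
from phenco.pair_network import (
    PairAssociation,
    build_pair_table,
    hypergeometric_index,
    hypergeometric_index_arr,
    index_from_pvalue,
    randomize_links,
    randomize_nodes,
    sample_pairs,
    split_pairs,
    unconnected_universe,
)


def exact_index(k: int, n_a: int, n_b: int, N: int) -> float:
    """Independent oracle: exact rational upper-tail sum, then -log10."""
    num = sum(
        comb(n_a, i) * comb(N - n_a, n_b - i)
        for i in range(k, min(n_a, n_b) + 1)
        if n_b - i <= N - n_a
    )
    tail = Fraction(num, comb(N, n_b))
    return -math.log10(float(tail))


class TestHypergeometricIndex:
    def test_zero_overlap_gives_zero(self):
        assert hypergeometric_index(0, 5, 5, 20) == 0.0

    def test_tail_probability_001_maps_to_2(self):
        # one marked patient, one draw, cohort of 100: tail is exactly 1/100
        assert hypergeometric_index(1, 1, 1, 100) == pytest.approx(2.0, abs=1e-12)
        assert index_from_pvalue(0.01) == pytest.approx(2.0, abs=1e-12)

    def test_derived_example(self):
        # k=4, n_a=5, n_b=4, N=10: tail = C(5,4)/C(10,4) = 5/210
        expected = -math.log10(5 / 210)
        assert hypergeometric_index(4, 5, 4, 10) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("k,n_a,n_b,N", [
        (1, 3, 4, 12), (2, 6, 6, 12), (5, 5, 5, 5), (1, 1, 1, 60),
        (3, 10, 7, 30), (7, 20, 15, 40), (2, 30, 30, 31),
    ])
    def test_matches_exact_rational_oracle(self, k, n_a, n_b, N):
        assert hypergeometric_index(k, n_a, n_b, N) == pytest.approx(
            exact_index(k, n_a, n_b, N), abs=1e-9
        )

    def test_monotone_in_k(self):
        vals = [hypergeometric_index(k, 12, 9, 40) for k in range(0, 10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("args", [
        (5, 4, 4, 10),   # k > min(n_a, n_b)
        (1, 11, 4, 10),  # n_a > N
        (1, 0, 4, 10),   # empty margin
        (-1, 4, 4, 10),
    ])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            hypergeometric_index(*args)

    def test_forced_overlap_has_index_zero(self):
        # n_a + n_b > N forces k >= 1, so P(X >= 1) = 1
        assert hypergeometric_index(1, 6, 6, 10) == 0.0

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        N = 50
        n_a = rng.integers(1, N + 1, 200)
        n_b = rng.integers(1, N + 1, 200)
        k = np.array([rng.integers(0, min(a, b) + 1) for a, b in zip(n_a, n_b)])
        vec = hypergeometric_index_arr(k, n_a, n_b, N)
        for i in range(200):
            assert vec[i] == pytest.approx(
                hypergeometric_index(int(k[i]), int(n_a[i]), int(n_b[i]), N),
                abs=1e-10,
            )


def brute_force_pairs(cohort: Cohort) -> dict[tuple[str, str], int]:
    """O(|terms|^2) overlap counting straight from patient sets."""
    terms = sorted(cohort.phenotype_universe)
    tp = cohort.patients_by_phenotype()
    out = {}
    for a, b in combinations(terms, 2):
        k = len(tp[a] & tp[b])
        if k >= 1:
            out[(a, b)] = k
    return out


class TestPairTable:
    def test_minimal_example(self):
        cohort = Cohort([
            Patient("P1", frozenset({"HP:A", "HP:B"})),
            Patient("P2", frozenset({"HP:B"})),
        ])
        (pair,) = build_pair_table(cohort)
        assert pair.pair == ("HP:A", "HP:B")
        assert (pair.k, pair.n_a, pair.n_b, pair.N) == (1, 1, 2, 2)

    def test_saturated_overlap_index_zero(self):
        cohort = Cohort([
            Patient("P1", frozenset({"HP:A", "HP:B"})),
            Patient("P2", frozenset({"HP:A", "HP:B"})),
        ])
        (pair,) = build_pair_table(cohort)
        assert pair.k == 2 and pair.index == 0.0

    def test_matches_brute_force_on_random_cohort(self):
        rng = np.random.default_rng(7)
        terms = [f"HP:{i:02d}" for i in range(15)]
        patients = []
        for i in range(20):
            size = rng.integers(1, 6)
            chosen = rng.choice(len(terms), size=size, replace=False)
            patients.append(Patient(f"P{i}", frozenset(terms[j] for j in chosen)))
        cohort = Cohort(patients)
        table = {p.pair: p.k for p in build_pair_table(cohort)}
        assert table == brute_force_pairs(cohort)

    def test_unconnected_complement(self):
        rng = np.random.default_rng(11)
        terms = [f"HP:{i:02d}" for i in range(15)]
        patients = [
            Patient(f"P{i}", frozenset(
                terms[j] for j in rng.choice(15, size=rng.integers(1, 5), replace=False)
            ))
            for i in range(12)
        ]
        cohort = Cohort(patients)
        connected = build_pair_table(cohort)
        unconnected = unconnected_universe(cohort)
        n_terms = len(cohort.phenotype_universe)
        assert len(connected) + len(unconnected) == n_terms * (n_terms - 1) // 2
        assert set(unconnected) == {
            pq for pq in combinations(sorted(cohort.phenotype_universe), 2)
            if pq not in {p.pair for p in connected}
        }


class TestSplit:
    def _mk(self, index):
        return PairAssociation("HP:A", "HP:B", 1, 1, 1, 10, index)

    def test_threshold_tie_goes_more_specific(self):
        more, less = split_pairs([self._mk(2.0)], 2.0)
        assert len(more) == 1 and not less

    def test_just_below_threshold_less_specific(self):
        more, less = split_pairs([self._mk(1.999)], 2.0)
        assert len(less) == 1 and not more

    @given(st.lists(st.floats(0, 10, allow_nan=False), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_partition_exhaustive_and_disjoint(self, indices):
        pairs = [self._mk(float(i)) for i in indices]
        more, less = split_pairs(pairs, 2.0)
        assert len(more) + len(less) == len(pairs)
        assert all(p.index >= 2.0 for p in more)
        assert all(p.index < 2.0 for p in less)


class TestSampling:
    universe = [(f"a{i}", f"b{i}") for i in range(10)]

    def test_full_size_sample_is_universe(self):
        reps = sample_pairs(self.universe, 10, 3, seed=1)
        for r in reps:
            assert sorted(r.pairs) == sorted(self.universe)

    def test_determinism_per_seed_and_replicate(self):
        a = sample_pairs(self.universe, 4, 5, seed=9)
        b = sample_pairs(self.universe, 4, 5, seed=9)
        assert [r.pairs for r in a] == [r.pairs for r in b]
        assert a[0].pairs != a[1].pairs or a[0].pairs != a[2].pairs

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            sample_pairs(self.universe, 11, 1, seed=0)

    def test_inclusion_frequency_binomial(self):
        # each pair appears with probability size/|universe| = 0.4
        reps = sample_pairs(self.universe, 4, 2000, seed=3)
        hits = sum(self.universe[0] in r.pairs for r in reps)
        p = 0.4
        sigma = math.sqrt(2000 * p * (1 - p))
        assert abs(hits - 2000 * p) < 3 * sigma


def _degrees(edges):
    d = {}
    for a, b in edges:
        d[a] = d.get(a, 0) + 1
        d[b] = d.get(b, 0) + 1
    return d


class TestRandomization:
    edges = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"),
             ("e", "f"), ("f", "a"), ("b", "e")]

    def test_links_preserves_every_degree(self):
        for seed in range(20):
            out = randomize_links(self.edges, seed)
            assert _degrees(out) == _degrees(self.edges)
            assert len(out) == len(self.edges)
            assert all(a != b for a, b in out)
            assert len(set(out)) == len(out)

    def test_links_actually_rewires(self):
        changed = sum(
            set(randomize_links(self.edges, s)) != {tuple(sorted(e)) for e in self.edges}
            for s in range(100)
        )
        assert changed >= 95

    def test_links_tiny_graph_returned_unchanged(self):
        with pytest.warns(UserWarning):
            out = randomize_links([("a", "b")], seed=0)
        assert out == [("a", "b")]

    def test_nodes_preserves_edge_count_and_degree_multiset(self):
        for seed in range(20):
            out = randomize_nodes(self.edges, seed)
            assert len(out) == len(self.edges)
            assert sorted(_degrees(out).values()) == sorted(_degrees(self.edges).values())

    def test_nodes_is_a_relabeling(self):
        out = randomize_nodes(self.edges, seed=5)
        # the permuted graph is isomorphic: same sorted degree sequence and
        # the same number of triangles
        import networkx as nx
        g1, g2 = nx.Graph(self.edges), nx.Graph(out)
        assert sorted(nx.triangles(g1).values()) == sorted(nx.triangles(g2).values())
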