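"""Phenotype-phenotype comorbidity pairs and their null models.

Patients form a phenotype-patient bipartite network; each co-occurring
phenotype pair is scored with the hypergeometric index, the -log10 of the
upper-tail hypergeometric probability of the observed patient overlap.  An
index >= 2 (tail probability <= 0.01) defines the *more-specific* (comorbid)
pairs; the rest are *less-specific*.  Null datasets come from uniform
sampling, degree-preserving edge rewiring (links model) and node-label
permutation (nodes model).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from .cohort_io import Cohort

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


def index_from_pvalue(p: float) -> float:
    """Hypergeometric index of a tail probability: -log10(p)."""
    if not (0 < p <= 1):
        raise ValueError("tail probability must be in (0, 1]")
    return -math.log10(p)


def hypergeometric_index(k: int, n_a: int, n_b: int, N: int) -> float:
    """-log10 of P(X >= k) for X ~ Hypergeometric(N, n_a, n_b).

    X is the overlap of two patient sets of sizes ``n_a`` and ``n_b`` drawn
    from a cohort of ``N`` patients.  Computed in log space via scipy's
    ``logsf`` so large cohorts do not underflow; k = 0 gives index 0.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    if n_a > N or n_b > N:
        raise ValueError("marginal counts cannot exceed the cohort size N")
    if k < 0 or k > min(n_a, n_b):
        raise ValueError(f"k={k} outside [0, min(n_a, n_b)={min(n_a, n_b)}]")
    if k == 0:
        return 0.0
    return float(hypergeometric_index_arr([k], [n_a], [n_b], N)[0])


def _log_tail(k, n_a, n_b, N) -> np.ndarray:
    """log P(X >= k), X ~ Hypergeometric(N, n_a, n_b), elementwise.

    Log-gamma evaluation of the pmf at k followed by a log-sum-exp
    accumulation of the pmf ratio recurrence up the tail; numerically stable
    for cohort-scale N where naive factorials overflow.
    """
    from scipy.special import gammaln

    k = np.asarray(k, dtype=np.int64)
    n_a = np.asarray(n_a, dtype=np.int64)
    n_b = np.asarray(n_b, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    lower = np.maximum(0, n_a + n_b - N)  # smallest possible overlap
    hi = np.minimum(n_a, n_b)
    full = k <= lower  # tail covers the whole support
    kk = np.maximum(k, lower)

    def logpmf(i):
        return (
            gammaln(n_a + 1) - gammaln(i + 1) - gammaln(n_a - i + 1)
            + gammaln(N - n_a + 1) - gammaln(n_b - i + 1)
            - gammaln(N - n_a - n_b + i + 1)
            - (gammaln(N + 1) - gammaln(n_b + 1) - gammaln(N - n_b + 1))
        )

    log_s = logpmf(kk)
    log_term = log_s.copy()
    steps = int(np.max(hi - kk)) if kk.size else 0
    i = kk.astype(float)
    for _ in range(steps):
        active = i < hi
        with np.errstate(divide="ignore", invalid="ignore"):
            log_r = (
                np.log(n_a - i) + np.log(n_b - i)
                - np.log(i + 1) - np.log(N - n_a - n_b + i + 1)
            )
        log_term = np.where(active, log_term + log_r, -np.inf)
        log_s = np.logaddexp(log_s, log_term)
        i += 1
    log_s = np.where(full, 0.0, np.minimum(log_s, 0.0))
    return log_s


def hypergeometric_index_arr(k, n_a, n_b, N) -> np.ndarray:
    """Vectorized :func:`hypergeometric_index` (no domain checking)."""
    k = np.asarray(k)
    logp = _log_tail(k, n_a, n_b, N)
    out = np.where(k <= 0, 0.0, -logp / LN10)
    return np.maximum(out, 0.0)


@dataclass(frozen=True)
class PairAssociation:
    """One unordered phenotype pair with its patient-overlap statistics."""

    term_a: str
    term_b: str
    k: int
    n_a: int
    n_b: int
    N: int
    index: float

    def __post_init__(self) -> None:
        if self.term_a >= self.term_b:
            raise ValueError("pair terms must be in canonical order term_a < term_b")
        if not (1 <= self.k <= min(self.n_a, self.n_b)):
            raise ValueError("k must satisfy 1 <= k <= min(n_a, n_b)")
        if not (self.index >= 0 and math.isfinite(self.index)):
            raise ValueError("index must be finite and non-negative")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.term_a, self.term_b)


@dataclass
class PairDataset:
    """A labelled pair list: real split, sampled replicate or randomization."""

    label: str  # more_specific | less_specific | unconnected | links_random | nodes_random
    pairs: list
    replicate: int = 0
    provenance: dict = field(default_factory=dict)


def build_pair_table(cohort: Cohort) -> list[PairAssociation]:
    """Score every phenotype pair that co-occurs in at least one patient.

    Pairs never co-occurring (k = 0) are excluded; they form the unconnected
    universe (see :func:`unconnected_universe`).
    """
    if cohort.N < 2:
        raise ValueError("cohort must contain at least 2 patients")
    term_patients = cohort.patients_by_phenotype()
    counts: dict[tuple[str, str], int] = {}
    for p in cohort.patients:
        for a, b in combinations(sorted(p.phenotypes), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    if not counts:
        return []
    pairs = sorted(counts)
    k = np.array([counts[p] for p in pairs])
    n_a = np.array([len(term_patients[a]) for a, _ in pairs])
    n_b = np.array([len(term_patients[b]) for _, b in pairs])
    idx = hypergeometric_index_arr(k, n_a, n_b, cohort.N)
    out = [
        PairAssociation(a, b, int(ki), int(na), int(nb), cohort.N, float(ix))
        for (a, b), ki, na, nb, ix in zip(pairs, k, n_a, n_b, idx)
    ]
    logger.info("pair table: %d co-occurring pairs from %d patients", len(out), cohort.N)
    return out


def split_pairs(
    pairs: Sequence[PairAssociation], t: float
) -> tuple[list[PairAssociation], list[PairAssociation]]:
    """Partition pairs at the index threshold; index >= t is more-specific."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    more = [p for p in pairs if p.index >= t]
    less = [p for p in pairs if p.index < t]
    return more, less


def _child_rng(seed: int, replicate: int) -> np.random.Generator:
    # replicate-specific stream, reproducible independently of the others
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


def sample_pairs(
    universe: Sequence, size: int, R: int, seed: int, label: str = "sampled"
) -> list[PairDataset]:
    """R uniform without-replacement samples of ``size`` pairs from ``universe``."""
    if size > len(universe):
        raise ValueError(f"sample size {size} exceeds universe size {len(universe)}")
    universe = sorted(universe, key=_pair_key)
    out = []
    for r in range(1, R + 1):
        rng = _child_rng(seed, r)
        idx = rng.choice(len(universe), size=size, replace=False)
        sampled = sorted((universe[i] for i in idx), key=_pair_key)
        out.append(
            PairDataset(label=label, pairs=sampled, replicate=r,
                        provenance={"seed": seed, "size": size})
        )
    return out


def _pair_key(p):
    return p.pair if isinstance(p, PairAssociation) else tuple(p)


def unconnected_universe(cohort: Cohort) -> list[tuple[str, str]]:
    """All unordered phenotype pairs sharing no patient (k = 0)."""
    connected = {
        (a, b)
        for p in cohort.patients
        for a, b in combinations(sorted(p.phenotypes), 2)
    }
    terms = sorted(cohort.phenotype_universe)
    return [pq for pq in combinations(terms, 2) if pq not in connected]


def _as_edge_list(pairs: Iterable) -> list[tuple[str, str]]:
    return [_pair_key(p) for p in pairs]


def randomize_links(pairs: Sequence, seed: int) -> list[tuple[str, str]]:
    """Degree-preserving rewiring (links-based random model).

    Repeated double-edge swaps that reject self-loops and parallel edges;
    every node keeps its exact degree.  Swap budget is 10x the edge count.
    """
    edges = _as_edge_list(pairs)
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges: links randomization returns the input")
        return sorted(tuple(sorted(e)) for e in edges)
    g = nx.Graph(edges)
    nswap = 10 * g.number_of_edges()
    nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap + 100,
                        seed=int(np.random.default_rng((seed, 0xE)).integers(2**31)))
    return sorted(tuple(sorted(e)) for e in g.edges())


def randomize_nodes(pairs: Sequence, seed: int) -> list[tuple[str, str]]:
    """Node-label permutation (nodes-based random model).

    A uniform random permutation of the phenotype labels is applied to both
    endpoints of every edge: edge count and the degree multiset are kept, but
    each individual phenotype generally changes degree.
    """
    edges = _as_edge_list(pairs)
    labels = sorted({n for e in edges for n in e})
    rng = np.random.default_rng((seed, 0xA))
    perm = dict(zip(labels, (labels[i] for i in rng.permutation(len(labels)))))
    return sorted(tuple(sorted((perm[a], perm[b]))) for a, b in edges)


def write_pair_table(
    datasets: Sequence[PairDataset], path: str | Path, header_note: str = ""
) -> None:
    """Write pair datasets as one TSV (bare pairs get empty statistic columns)."""
    with Path(path).open("w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("term_a\tterm_b\tk\tn_a\tn_b\tN\tindex\tdataset_label\treplicate\n")
        for ds in datasets:
            for p in ds.pairs:
                if isinstance(p, PairAssociation):
                    fh.write(
                        f"{p.term_a}\t{p.term_b}\t{p.k}\t{p.n_a}\t{p.n_b}\t{p.N}"
                        f"\t{p.index:.6g}\t{ds.label}\t{ds.replicate}\n"
                    )
                else:
                    a, b = p
                    fh.write(f"{a}\t{b}\t\t\t\t\t\t{ds.label}\t{ds.replicate}\n")


def prevalence(cohort: Cohort) -> dict[str, float]:
    """Per-phenotype prevalence: fraction of patients presenting the term."""
    tp = cohort.patients_by_phenotype()
    return {t: len(s) / cohort.N for t, s in tp.items()}


def pair_mean_prevalence(
    pairs: Sequence[PairAssociation], cohort: Cohort
) -> list[float]:
    """Mean prevalence of the two terms of each pair (specificity summaries)."""
    prev = prevalence(cohort)
    return [(prev[p.term_a] + prev[p.term_b]) / 2 for p in pairs]
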