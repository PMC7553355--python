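"""External-evidence validation statistics.

Covers disease-database overlap of pairs, literature co-mention (one-sided
Fisher exact tests over a precomputed term -> abstract-id corpus), Resnik
semantic similarity of cluster phenotypes with a size-preserving
randomization z-score, and patient-cluster support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .cohort_io import Cohort, DiseaseAnnotations, LiteratureCorpus, Ontology
from .pair_network import PairAssociation
from .sor_mapping import PhenotypeGeneMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComentionResult:
    term_a: str
    term_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    U: int
    fisher_p: float | None  # None when a term is absent from the corpus
    missing_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class SemanticComparison:
    observed: float
    mu_random: float
    sd_random: float
    z: float | None
    n_randomizations: int


@dataclass
class PatientClusterSupport:
    per_patient_max: dict[str, int]  # patient -> max phenotypes in one cluster
    n_ge2: int
    n_ge3: int
    random_mean_ge2: float
    random_mean_ge3: float
    n_randomizations: int


def _pair_terms(pairs: Iterable) -> list[tuple[str, str]]:
    out = []
    for p in pairs:
        out.append(p.pair if isinstance(p, PairAssociation) else tuple(p))
    return out


def pair_disease_overlap(
    pairs: Iterable,
    disease_annotations: DiseaseAnnotations,
    min_diseases: int = 1,
) -> int:
    """Count pairs whose two terms co-occur in >= ``min_diseases`` diseases."""
    term_diseases: dict[str, set[str]] = {}
    for d, terms in disease_annotations.items():
        for t in terms:
            term_diseases.setdefault(t, set()).add(d)
    count = 0
    for a, b in _pair_terms(pairs):
        da = term_diseases.get(a)
        db = term_diseases.get(b)
        if da and db and len(da & db) >= min_diseases:
            count += 1
    return count


def comention_test(
    corpus: LiteratureCorpus, term_a: str, term_b: str
) -> ComentionResult:
    """One-sided Fisher exact test for joint mention of two terms.

    The 2x2 table is built over the corpus universe (all distinct abstract
    ids); the p-value is the upper hypergeometric tail, i.e. enrichment of
    joint mention.  A term absent from the corpus yields an explicit
    missing-term result rather than p = 1.
    """
    missing = tuple(t for t in (term_a, term_b) if t not in corpus)
    if missing:
        return ComentionResult(term_a, term_b, 0, 0, 0, 0, corpus.U, None, missing)
    A = corpus.term_abstracts[term_a]
    B = corpus.term_abstracts[term_b]
    U = corpus.U
    n11 = len(A & B)
    n10 = len(A) - n11
    n01 = len(B) - n11
    n00 = U - n11 - n10 - n01
    p = float(hypergeom.sf(n11 - 1, U, len(A), len(B))) if n11 > 0 else 1.0
    return ComentionResult(term_a, term_b, n11, n10, n01, n00, U, min(p, 1.0))


def gene_comention_count(
    corpus: LiteratureCorpus,
    pg_map: PhenotypeGeneMap,
    n_randomizations: int = 100,
    seed: int = 0,
) -> tuple[int, float, float, float | None]:
    """Phenotype-gene co-mention count against a gene-permutation null.

    Observed = number of (phenotype, gene) assignments sharing >= 1 abstract.
    The null permutes the gene -> abstract-set assignment uniformly across the
    genes of the map, preserving the multiset of abstract-set sizes.  Returns
    (observed, mu_random, sd_random, z).
    """
    pairs = [
        (t, g) for t in sorted(pg_map.genes) for g in sorted(pg_map.genes[t])
    ]
    genes = sorted({g for _, g in pairs})
    gene_abs = {g: corpus.term_abstracts.get(g, frozenset()) for g in genes}
    pheno_abs = {
        t: corpus.term_abstracts.get(t, frozenset()) for t in sorted(pg_map.genes)
    }

    def count(assign: Mapping[str, frozenset[str]]) -> int:
        return sum(1 for t, g in pairs if pheno_abs[t] & assign[g])

    observed = count(gene_abs)
    rng = np.random.default_rng((seed, 0xC0))
    sets = [gene_abs[g] for g in genes]
    null = np.empty(n_randomizations)
    for r in range(n_randomizations):
        perm = rng.permutation(len(genes))
        null[r] = count({g: sets[perm[i]] for i, g in enumerate(genes)})
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if n_randomizations > 1 else 0.0
    z = (observed - mu) / sd if sd > 0 else None
    return observed, mu, sd, z


# ---------------------------------------------------------------------------
# Resnik semantic similarity
# ---------------------------------------------------------------------------


def build_ic_table(
    ontology: Ontology, annotations: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Information content per term from an annotation corpus.

    Each annotated object's terms are propagated to all ancestors; p(t) =
    annotated objects reaching t / total annotated objects; IC(t) = -ln p(t).
    Terms never reached have no defined IC and are absent from the table.
    """
    total = 0
    counts: dict[str, int] = {}
    for _, terms in sorted(annotations.items()):
        reached: set[str] = set()
        for t in terms:
            r = ontology.resolve(t)
            if r is not None:
                reached |= ontology.ancestors(r)
        if not reached:
            continue
        total += 1
        for t in reached:
            counts[t] = counts.get(t, 0) + 1
    if total == 0:
        raise ValueError("no annotated objects: cannot build an IC table")
    return {t: -math.log(c / total) for t, c in counts.items()}


def ic_max(ic_table: Mapping[str, float]) -> float:
    return max(ic_table.values())


def resnik_similarity(
    a: str,
    b: str,
    ic_table: Mapping[str, float],
    ontology: Ontology,
    normalize: bool = True,
) -> float:
    """Normalized Resnik similarity: IC of the most informative common ancestor.

    Normalization divides by the maximum IC in the table, giving values in
    [0, 1].  A term with no defined IC (never annotated) is an error.
    """
    for t in (a, b):
        if t not in ic_table:
            raise ValueError(f"term {t!r} has no defined information content")
    common = ontology.ancestors(a) & ontology.ancestors(b)
    mica_ic = max((ic_table[t] for t in common if t in ic_table), default=0.0)
    if not normalize:
        return mica_ic
    m = ic_max(ic_table)
    return mica_ic / m if m > 0 else 0.0


def _mean_within_cluster_similarity(
    clusters: Sequence[Sequence[str]],
    sim,
) -> float:
    vals: list[float] = []
    for cl in clusters:
        for a, b in combinations(sorted(cl), 2):
            vals.append(sim(a, b))
    if not vals:
        raise ValueError("no within-cluster phenotype pairs to score")
    return float(np.mean(vals))


def cluster_semantic_score(
    clusters: Sequence[Iterable[str]],
    ic_table: Mapping[str, float],
    ontology: Ontology,
    n_randomizations: int = 100,
    seed: int = 0,
) -> SemanticComparison:
    """Mean within-cluster Resnik similarity vs size-preserving random clusters.

    The null reassigns the pooled phenotype multiset to clusters of identical
    sizes uniformly at random; z = (observed - mu) / sd over the replicates.
    """
    clusters = [sorted(c) for c in clusters]
    if any(len(c) < 2 for c in clusters):
        raise ValueError("every cluster must contain >= 2 phenotypes")
    if n_randomizations < 2:
        raise ValueError("n_randomizations must be >= 2")
    cache: dict[tuple[str, str], float] = {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        v = cache.get(key)
        if v is None:
            v = resnik_similarity(a, b, ic_table, ontology)
            cache[key] = v
        return v

    observed = _mean_within_cluster_similarity(clusters, sim)
    pool = [t for c in clusters for t in c]
    sizes = [len(c) for c in clusters]
    rng = np.random.default_rng((seed, 0x5E))
    null = np.empty(n_randomizations)
    for r in range(n_randomizations):
        perm = rng.permutation(len(pool))
        shuffled = [pool[i] for i in perm]
        rand_clusters, pos = [], 0
        for s in sizes:
            rand_clusters.append(shuffled[pos:pos + s])
            pos += s
        null[r] = _mean_within_cluster_similarity(rand_clusters, sim)
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mu) / sd if sd > 0 else None
    return SemanticComparison(observed, mu, sd, z, n_randomizations)


# ---------------------------------------------------------------------------
# patient-cluster support
# ---------------------------------------------------------------------------


def _max_in_cluster_counts(
    patients: Sequence[tuple[str, frozenset[str]]],
    clusters: Sequence[frozenset[str]],
) -> dict[str, int]:
    out: dict[str, int] = {}
    for pid, phenos in patients:
        best = 0
        touched = False
        for cl in clusters:
            inter = len(phenos & cl)
            if inter >= 1:
                touched = True
                best = max(best, inter)
        if touched:
            out[pid] = best
    return out


def patient_cluster_support(
    cohort: Cohort,
    clusters: Sequence[Iterable[str]],
    n_randomizations: int = 100,
    seed: int = 0,
) -> PatientClusterSupport:
    """How often a patient's phenotypes co-locate within a single cluster.

    For each patient with >= 1 phenotype in >= 1 cluster, the maximum number
    of their phenotypes falling into one cluster; cohort counts at >= 2 and
    >= 3 are compared to cluster-membership randomizations preserving cluster
    sizes and the pooled phenotype multiset.
    """
    cl_sets = [frozenset(c) for c in clusters]
    patients = [(p.id, p.phenotypes) for p in cohort.patients]
    real = _max_in_cluster_counts(patients, cl_sets)
    n_ge2 = sum(1 for v in real.values() if v >= 2)
    n_ge3 = sum(1 for v in real.values() if v >= 3)
    pool = [t for c in cl_sets for t in sorted(c)]
    sizes = [len(c) for c in cl_sets]
    rng = np.random.default_rng((seed, 0x9A))
    r2 = np.empty(n_randomizations)
    r3 = np.empty(n_randomizations)
    for r in range(n_randomizations):
        perm = rng.permutation(len(pool))
        shuffled = [pool[i] for i in perm]
        rand_clusters, pos = [], 0
        for s in sizes:
            rand_clusters.append(frozenset(shuffled[pos:pos + s]))
            pos += s
        rand = _max_in_cluster_counts(patients, rand_clusters)
        r2[r] = sum(1 for v in rand.values() if v >= 2)
        r3[r] = sum(1 for v in rand.values() if v >= 3)
    return PatientClusterSupport(
        per_patient_max=real,
        n_ge2=n_ge2,
        n_ge3=n_ge3,
        random_mean_ge2=float(r2.mean()),
        random_mean_ge3=float(r3.mean()),
        n_randomizations=n_randomizations,
    )


def cluster_membership_summary(
    cohort: Cohort, clusters: Sequence[Iterable[str]]
) -> list[tuple[int, int, int]]:
    """Contingency rows (phenotype count, distinct clusters touched, n patients).

    Patients with no phenotype in any cluster are excluded.
    """
    cl_sets = [frozenset(c) for c in clusters]
    table: dict[tuple[int, int], int] = {}
    for p in cohort.patients:
        touched = sum(1 for cl in cl_sets if p.phenotypes & cl)
        if touched == 0:
            continue
        key = (len(p.phenotypes), touched)
        table[key] = table.get(key, 0) + 1
    return [(k, c, n) for (k, c), n in sorted(table.items())]
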