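"""Over-representation analysis of phenotype gene sets against functional systems.

For one subject (a phenotype, or a phenotype pair's gene union) and one
functional-system collection, each gene set S is scored with the upper-tail
hypergeometric probability of the observed overlap, Benjamini-Hochberg
adjusted within the subject's family of tested sets.  A pair is *consistent*
for a FunSys when both phenotypes and their union are significant, and
*emergent* when only the union is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cohort_io import FunSysCollection
from .sor_mapping import PhenotypeGeneMap

logger = logging.getLogger(__name__)

CONSISTENT = "consistent"
EMERGENT = "emergent"


@dataclass(frozen=True)
class EnrichmentRecord:
    subject: str
    funsys: str
    overlap: int
    query_size: int
    set_size: int
    universe: int
    p_raw: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class PairFunSysLabel:
    pair: tuple[str, str]
    funsys: str
    status: str  # consistent | emergent


def overrepresentation(
    query_genes: Iterable[str],
    collection: FunSysCollection,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    subject: str = "query",
) -> list[EnrichmentRecord]:
    """Hypergeometric ORA of ``query_genes`` against every set in ``collection``.

    The gene universe defaults to the union of the collection's sets; query
    genes outside the universe are dropped (count logged).  Only sets with
    overlap >= 1 are tested and reported; BH adjustment runs across that
    family.  Empty queries yield an empty result.
    """
    uni = frozenset(universe) if universe is not None else collection.gene_universe
    query = frozenset(query_genes)
    outside = len(query - uni)
    if outside:
        logger.debug("subject %s: dropped %d query genes outside the universe", subject, outside)
    query &= uni
    if not query:
        logger.debug("subject %s: empty query after universe filtering", subject)
        return []
    U, n = len(uni), len(query)
    tested: list[tuple[str, int, int]] = []
    for name in sorted(collection.sets):
        S = collection.sets[name] & uni
        ov = len(query & S)
        if ov >= 1:
            tested.append((name, ov, len(S)))
    if not tested:
        return []
    ov = np.array([t[1] for t in tested])
    K = np.array([t[2] for t in tested])
    p_raw = hypergeom.sf(ov - 1, U, K, n)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return [
        EnrichmentRecord(
            subject=subject, funsys=name, overlap=int(o), query_size=n,
            set_size=int(k), universe=U, p_raw=float(pr), p_adj=float(pa),
            significant=bool(pa < alpha),
        )
        for (name, o, k), pr, pa in zip(tested, p_raw, p_adj)
    ]


def significant_funsys(records: Sequence[EnrichmentRecord]) -> frozenset[str]:
    return frozenset(r.funsys for r in records if r.significant)


def pair_gene_union(
    pg_map: PhenotypeGeneMap, term_a: str, term_b: str
) -> frozenset[str]:
    """Union of the two phenotypes' gene sets (missing phenotype -> empty set)."""
    return pg_map.gene_set(term_a) | pg_map.gene_set(term_b)


def classify_pair_terms(
    enr_a: Sequence[EnrichmentRecord],
    enr_b: Sequence[EnrichmentRecord],
    enr_union: Sequence[EnrichmentRecord],
    pair: tuple[str, str] = ("a", "b"),
) -> list[PairFunSysLabel]:
    """Label each FunSys significant for the pair union.

    both singles + union significant -> consistent; neither single but union
    significant -> emergent; any other combination -> no label.
    """
    sig_a = significant_funsys(enr_a)
    sig_b = significant_funsys(enr_b)
    sig_u = significant_funsys(enr_union)
    labels: list[PairFunSysLabel] = []
    for f in sorted(sig_u):
        if f in sig_a and f in sig_b:
            labels.append(PairFunSysLabel(pair=pair, funsys=f, status=CONSISTENT))
        elif f not in sig_a and f not in sig_b:
            labels.append(PairFunSysLabel(pair=pair, funsys=f, status=EMERGENT))
    return labels


def enrich_phenotypes(
    pg_map: PhenotypeGeneMap,
    collection: FunSysCollection,
    alpha: float = 0.05,
    universe: Iterable[str] | None = None,
) -> dict[str, list[EnrichmentRecord]]:
    """ORA for every phenotype in the gene map."""
    return {
        term: overrepresentation(
            pg_map.gene_set(term), collection, universe=universe,
            alpha=alpha, subject=term,
        )
        for term in sorted(pg_map.genes)
    }


def label_pairs(
    pairs: Iterable[tuple[str, str]],
    pg_map: PhenotypeGeneMap,
    collection: FunSysCollection,
    alpha: float = 0.05,
    universe: Iterable[str] | None = None,
    phenotype_enrichment: Mapping[str, Sequence[EnrichmentRecord]] | None = None,
) -> dict[tuple[str, str], list[PairFunSysLabel]]:
    """Consistent/emergent labels for every pair with a non-empty gene union.

    Per-phenotype enrichment may be precomputed (one ORA per phenotype is
    reused across all its pairs).
    """
    enr = (
        dict(phenotype_enrichment)
        if phenotype_enrichment is not None
        else enrich_phenotypes(pg_map, collection, alpha=alpha, universe=universe)
    )
    out: dict[tuple[str, str], list[PairFunSysLabel]] = {}
    for a, b in pairs:
        union = pair_gene_union(pg_map, a, b)
        if not union:
            continue
        enr_u = overrepresentation(
            union, collection, universe=universe, alpha=alpha, subject=f"{a}|{b}"
        )
        labels = classify_pair_terms(
            enr.get(a, ()), enr.get(b, ()), enr_u, pair=(a, b)
        )
        if labels:
            out[(a, b)] = labels
    return out


def count_significant_associations(
    enrichment: Mapping[str, Sequence[EnrichmentRecord]],
) -> tuple[int, int]:
    """(number of significant subject-FunSys associations, distinct subjects)."""
    n_assoc = 0
    subjects: set[str] = set()
    for subj, records in enrichment.items():
        sig = [r for r in records if r.significant]
        n_assoc += len(sig)
        if sig:
            subjects.add(subj)
    return n_assoc, len(subjects)


def write_enrichment(
    enrichment: Mapping[str, Sequence[EnrichmentRecord]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "subject\tfunsys\toverlap\tquery_size\tset_size\tuniverse\t"
            "p_raw\tp_adj\tsignificant\n"
        )
        for subj in sorted(enrichment):
            for r in enrichment[subj]:
                fh.write(
                    f"{r.subject}\t{r.funsys}\t{r.overlap}\t{r.query_size}\t"
                    f"{r.set_size}\t{r.universe}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t"
                    f"{int(r.significant)}\n"
                )


def write_pair_labels(
    labels: Mapping[tuple[str, str], Sequence[PairFunSysLabel]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_a\tterm_b\tfunsys\tstatus\n")
        for pair in sorted(labels):
            for lab in labels[pair]:
                fh.write(f"{pair[0]}\t{pair[1]}\t{lab.funsys}\t{lab.status}\n")
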