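"""CNV decomposition into small overlapping regions (SORs) and gene mapping.

All patient CNVs on a chromosome are broken at every breakpoint into atomic
segments; each segment covered by at least two distinct patients is a SOR.
Phenotypes are associated with SORs through the patients that carry both
(hypergeometric index, same threshold as the pair network), and retained
associations are converted to phenotype->gene assignments through the genes
the SOR overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .cohort_io import Cohort, GeneModel
from .pair_network import hypergeometric_index_arr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SORRecord:
    """An atomic genomic segment shared by >= 2 patients."""

    id: str
    chrom: str
    start: int
    end: int
    patients: frozenset[str]
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("SOR start must be < end")
        if len(self.patients) < 2:
            raise ValueError("a SOR requires at least two covering patients")


@dataclass(frozen=True)
class PhenotypeSORAssociation:
    phenotype: str
    sor_id: str
    k: int
    n_pheno: int
    n_sor: int
    N: int
    index: float


@dataclass
class PhenotypeGeneMap:
    """phenotype id -> gene set, with the SORs supporting each assignment."""

    genes: dict[str, frozenset[str]]
    supporting_sors: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: str = "real"

    def gene_set(self, term: str) -> frozenset[str]:
        return self.genes.get(term, frozenset())

    def __len__(self) -> int:
        return len(self.genes)


def decompose_to_sors(cohort: Cohort) -> list[SORRecord]:
    """Sweep-line decomposition of all patient CNVs into SORs.

    Per chromosome, the sorted union of CNV breakpoints defines atomic
    segments; a segment becomes a SOR when covered by >= 2 distinct patients
    (a patient with several CNVs over one segment counts once).  Adjacent
    segments are kept atomic even when their patient sets coincide.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for p in cohort.patients:
        for c in p.cnvs:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end, p.id))
    sors: list[SORRecord] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        cuts = sorted({x for s, e, _ in ivs for x in (s, e)})
        events: dict[int, list[tuple[str, int]]] = {}
        for s, e, pid in ivs:
            events.setdefault(s, []).append((pid, +1))
            events.setdefault(e, []).append((pid, -1))
        depth: dict[str, int] = {}
        for left, right in zip(cuts, cuts[1:]):
            for pid, delta in events.get(left, ()):
                depth[pid] = depth.get(pid, 0) + delta
            covering = frozenset(pid for pid, d in depth.items() if d > 0)
            if len(covering) >= 2:
                sors.append(
                    SORRecord(
                        id=f"sor:{chrom}:{left}-{right}",
                        chrom=chrom,
                        start=left,
                        end=right,
                        patients=covering,
                    )
                )
    logger.info("decomposed CNVs into %d SORs", len(sors))
    return sors


def assign_genes_to_sors(
    sors: Sequence[SORRecord], gene_models: Sequence[GeneModel]
) -> list[SORRecord]:
    """Attach to each SOR the genes it overlaps by >= 1 bp (strand ignored)."""
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene)
    out = []
    for sor in sors:
        tree = trees.get(sor.chrom)
        hits = frozenset(iv.data for iv in tree.overlap(sor.start, sor.end)) if tree else frozenset()
        out.append(replace(sor, genes=hits))
    return out


def associate_phenotypes_to_sors(
    cohort: Cohort, sors: Sequence[SORRecord], t: float = 2.0
) -> list[PhenotypeSORAssociation]:
    """Hypergeometric association of each phenotype with each SOR.

    The tripartite SOR-patient-phenotype network is projected through the
    patient layer: k counts patients both presenting the phenotype and
    covered by the SOR.  Records with index >= t are retained.
    """
    term_patients = cohort.patients_by_phenotype()
    patient_terms = {p.id: p.phenotypes for p in cohort.patients}
    N = cohort.N
    rows: list[tuple[str, str, int, int, int]] = []
    for sor in sors:
        n_sor = len(sor.patients)
        counts: dict[str, int] = {}
        for pid in sor.patients:
            for term in patient_terms[pid]:
                counts[term] = counts.get(term, 0) + 1
        for term in sorted(counts):
            rows.append((term, sor.id, counts[term], len(term_patients[term]), n_sor))
    if not rows:
        return []
    k = np.array([r[2] for r in rows])
    n_p = np.array([r[3] for r in rows])
    n_s = np.array([r[4] for r in rows])
    idx = hypergeometric_index_arr(k, n_p, n_s, N)
    out = [
        PhenotypeSORAssociation(term, sid, int(ki), int(np_), int(ns), N, float(ix))
        for (term, sid, *_), ki, np_, ns, ix in zip(rows, k, n_p, n_s, idx)
        if ix >= t
    ]
    logger.info("retained %d phenotype-SOR associations (index >= %g)", len(out), t)
    return out


def map_sors_to_genes(
    associations: Sequence[PhenotypeSORAssociation],
    sors: Sequence[SORRecord],
    provenance: str = "real",
) -> PhenotypeGeneMap:
    """Replace each retained phenotype-SOR link with phenotype-gene links.

    SOR gene content must already be attached (see
    :func:`assign_genes_to_sors`); SORs overlapping no gene contribute
    nothing.
    """
    sor_genes = {s.id: s.genes for s in sors}
    genes: dict[str, set[str]] = {}
    support: dict[str, set[str]] = {}
    for a in associations:
        g = sor_genes.get(a.sor_id, frozenset())
        if not g:
            continue
        genes.setdefault(a.phenotype, set()).update(g)
        support.setdefault(a.phenotype, set()).add(a.sor_id)
    return PhenotypeGeneMap(
        genes={t: frozenset(s) for t, s in genes.items()},
        supporting_sors={t: frozenset(s) for t, s in support.items()},
        provenance=provenance,
    )


def randomize_sor_genes(
    sors: Sequence[SORRecord], seed: int
) -> list[SORRecord]:
    """One gene-content randomization replicate.

    Each SOR keeps its coordinates, patients (hence its phenotype links) and
    its gene count, but its genes are redrawn from the pooled multiset of all
    SOR genes, without replacement within a SOR.
    """
    pool = [g for s in sors for g in sorted(s.genes)]
    rng = np.random.default_rng((seed, 0x50))
    out: list[SORRecord] = []
    for sor in sorted(sors, key=lambda s: s.id):
        want = len(sor.genes)
        if want == 0:
            out.append(sor)
            continue
        # draw from the multiset until `want` distinct genes are collected
        order = rng.permutation(len(pool))
        picked: set[str] = set()
        for i in order:
            picked.add(pool[i])
            if len(picked) == want:
                break
        out.append(replace(sor, genes=frozenset(picked)))
    return out


def check_sor_invariants(sors: Sequence[SORRecord]) -> None:
    """Assert pairwise disjointness per chromosome and >=2-patient coverage."""
    by_chrom: dict[str, list[SORRecord]] = {}
    for s in sors:
        if len(s.patients) < 2:
            raise AssertionError(f"SOR {s.id} covered by < 2 patients")
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, lst in by_chrom.items():
        lst = sorted(lst, key=lambda s: s.start)
        for a, b in zip(lst, lst[1:]):
            if a.end > b.start:
                raise AssertionError(f"overlapping SORs {a.id} / {b.id}")


def write_sor_table(sors: Sequence[SORRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sor_id\tchrom\tstart\tend\tn_patients\tpatient_ids\tgenes\n")
        for s in sorted(sors, key=lambda s: (s.chrom, s.start)):
            fh.write(
                f"{s.id}\t{s.chrom}\t{s.start}\t{s.end}\t{len(s.patients)}\t"
                f"{','.join(sorted(s.patients))}\t{','.join(sorted(s.genes))}\n"
            )


def write_phenotype_gene_map(pg_map: PhenotypeGeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("phenotype\tgene\tsupporting_sors\n")
        for term in sorted(pg_map.genes):
            sors = ",".join(sorted(pg_map.supporting_sors.get(term, ())))
            for gene in sorted(pg_map.genes[term]):
                fh.write(f"{term}\t{gene}\t{sors}\n")
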