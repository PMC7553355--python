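"""Domain types and readers/writers for every external format the workflow touches.

The cohort file is a TSV with a header line naming the columns
``patient_id``, ``hpo_terms`` (comma-separated ontology term ids) and
``cnvs`` (semicolon-separated ``chrom:start-end:kind`` intervals, 0-based
half-open, kind one of ``deletion``/``duplication``).  All genomic
coordinates in the package are 0-based half-open, matching BED, so CNVs,
SORs and gene models never need converting between conventions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet
import yaml

logger = logging.getLogger(__name__)

VALID_CNV_KINDS = ("deletion", "duplication")


class CohortParseError(ValueError):
    """Raised for malformed cohort/annotation input, naming the offending line."""


@dataclass(frozen=True)
class CNVInterval:
    """A copy-number variant call: a deleted or duplicated genomic segment."""

    chrom: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("CNV interval requires a chromosome name")
        if self.start >= self.end:
            raise ValueError(
                f"CNV interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.kind not in VALID_CNV_KINDS:
            raise ValueError(f"unknown CNV kind {self.kind!r}")


@dataclass(frozen=True)
class Patient:
    id: str
    phenotypes: frozenset[str]
    cnvs: tuple[CNVInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValueError(f"patient {self.id!r} has no phenotypes")


@dataclass
class Cohort:
    """A patient cohort: each patient carries a phenotype set and CNV calls.

    ``N`` is the cohort size used as the population size of every
    hypergeometric index computed downstream.
    """

    patients: list[Patient]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        self.patients = sorted(self.patients, key=lambda p: p.id)

    @property
    def N(self) -> int:
        return len(self.patients)

    @property
    def phenotype_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.patients:
            out |= p.phenotypes
        return out

    def patients_with_cnvs(self) -> list[Patient]:
        return [p for p in self.patients if p.cnvs]

    def patients_by_phenotype(self) -> dict[str, frozenset[str]]:
        """Map each phenotype term to the set of patient ids presenting it."""
        idx: dict[str, set[str]] = {}
        for p in self.patients:
            for t in p.phenotypes:
                idx.setdefault(t, set()).add(p.id)
        return {t: frozenset(s) for t, s in idx.items()}


class Ontology:
    """A term DAG (is_a edges only) with ancestor closure and alt-id mapping."""

    def __init__(
        self,
        parents: Mapping[str, frozenset[str]],
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.parents = {t: frozenset(ps) for t, ps in parents.items()}
        undeclared = {
            p for ps in self.parents.values() for p in ps if p not in self.parents
        }
        if undeclared:
            raise CohortParseError(
                f"is_a reference to undeclared term(s): {sorted(undeclared)}"
            )
        self.names = dict(names or {})
        self.alt_ids = dict(alt_ids or {})
        self._check_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            g.add_edges_from((t, p) for p in ps)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CohortParseError(f"ontology contains a cycle: {cycle}")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def resolve(self, term: str) -> str | None:
        """Map ``term`` to its primary id via alt_id, or None if unknown."""
        if term in self.parents:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive is_a closure of ``term``."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown ontology term {term!r}")
        out = {term}
        for p in self.parents[term]:
            out |= self.ancestors(p)
        res = frozenset(out)
        self._anc_cache[term] = res
        return res

    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}


@dataclass
class DiseaseAnnotations:
    """disease id -> set of phenotype term ids, plus a source label."""

    annotations: dict[str, frozenset[str]]
    source: str = "diseases"

    def __len__(self) -> int:
        return len(self.annotations)

    def items(self):
        return self.annotations.items()


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start >= end")


@dataclass
class FunSysCollection:
    """Named functional gene sets (pathway / GO-style), e.g. read from a GMT."""

    sets: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty functional gene set(s): {empty}")

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class LiteratureCorpus:
    """term id (phenotype or gene) -> set of abstract ids; U is the universe size."""

    term_abstracts: dict[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.term_abstracts.values():
            out |= s
        return frozenset(out)

    @property
    def U(self) -> int:
        return len(self.universe)

    def __contains__(self, term: str) -> bool:
        return term in self.term_abstracts


@dataclass
class PipelineConfig:
    """Workflow-wide tunables, with the study's defaults.

    index_threshold: hypergeometric-index cut separating more- from
        less-specific pairs (2.0 corresponds to a tail probability of 0.01).
    enrichment_alpha: BH-adjusted significance level for over-representation.
    coherence_theta: minimum fraction of a cluster's phenotypes that must
        share evidence for one FunSys for the cluster to be coherent.
    replicates: sampling / network-randomization replicate count.
    sor_randomization_reps: SOR gene-content randomization replicate count.
    """

    index_threshold: float = 2.0
    enrichment_alpha: float = 0.05
    coherence_theta: float = 0.70
    replicates: int = 50
    sor_randomization_reps: int = 100
    pair_disease_thresholds: tuple[int, ...] = (1, 2, 3)
    cluster_allowed_missing: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.coherence_theta <= 1):
            raise ValueError("coherence_theta must be in (0, 1]")
        if self.index_threshold < 0:
            raise ValueError("index_threshold must be >= 0")
        for name in ("replicates", "sor_randomization_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_allowed_missing < 0:
            raise ValueError("cluster_allowed_missing must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "pair_disease_thresholds" in data:
            data["pair_disease_thresholds"] = tuple(data["pair_disease_thresholds"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_cnv(token: str, lineno: int) -> CNVInterval:
    try:
        chrom, span, kind = token.split(":")
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise CohortParseError(
            f"line {lineno}: malformed CNV field {token!r} "
            "(expected chrom:start-end:kind)"
        ) from exc
    try:
        return CNVInterval(chrom=chrom, start=start, end=end, kind=kind)
    except ValueError as exc:
        raise CohortParseError(f"line {lineno}: {exc}") from exc


def read_cohort(path: str | Path) -> Cohort:
    """Read the cohort TSV (columns patient_id, hpo_terms, cnvs)."""
    path = Path(path)
    patients: list[Patient] = []
    seen: set[str] = set()
    with path.open() as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("patient_id", "hpo_terms", "cnvs"):
                    if col not in header:
                        raise CohortParseError(
                            f"line {lineno}: missing required column {col!r}"
                        )
                idx = {c: header.index(c) for c in ("patient_id", "hpo_terms", "cnvs")}
                continue
            pid = fields[idx["patient_id"]].strip()
            if not pid:
                raise CohortParseError(f"line {lineno}: empty patient id")
            if pid in seen:
                raise CohortParseError(f"line {lineno}: duplicate patient id {pid!r}")
            seen.add(pid)
            terms = frozenset(
                t.strip() for t in fields[idx["hpo_terms"]].split(",") if t.strip()
            )
            if not terms:
                raise CohortParseError(f"line {lineno}: patient {pid!r} has no phenotypes")
            cnv_field = fields[idx["cnvs"]].strip() if len(fields) > idx["cnvs"] else ""
            cnvs = tuple(
                _parse_cnv(tok.strip(), lineno)
                for tok in cnv_field.split(";")
                if tok.strip()
            )
            patients.append(Patient(id=pid, phenotypes=terms, cnvs=cnvs))
    cohort = Cohort(patients)
    logger.info(
        "read cohort %s: %d patients, %d distinct phenotype terms",
        path, cohort.N, len(cohort.phenotype_universe),
    )
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("patient_id\thpo_terms\tcnvs\n")
        for p in cohort.patients:
            terms = ",".join(sorted(p.phenotypes))
            cnvs = ";".join(
                f"{c.chrom}:{c.start}-{c.end}:{c.kind}"
                for c in sorted(p.cnvs, key=lambda c: (c.chrom, c.start, c.end, c.kind))
            )
            fh.write(f"{p.id}\t{terms}\t{cnvs}\n")


def read_ontology(path: str | Path) -> Ontology:
    """Read an OBO file into an :class:`Ontology` (is_a edges only)."""
    graph = obonet.read_obo(str(path))
    parents: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    # obonet materializes is_a targets that have no stanza of their own as
    # bare nodes with empty data; exclude them so the constructor flags the
    # dangling reference
    declared = {n for n, d in graph.nodes(data=True) if d}
    for node in declared:
        data = graph.nodes[node]
        parents[node] = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        if "name" in data:
            names[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return Ontology(parents=parents, names=names, alt_ids=alt_ids)


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write an ontology back out as a minimal OBO file (is_a edges only)."""
    by_primary: dict[str, list[str]] = {}
    for alt, primary in ontology.alt_ids.items():
        by_primary.setdefault(primary, []).append(alt)
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(ontology.parents):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {ontology.names.get(term, term)}\n")
            for alt in sorted(by_primary.get(term, ())):
                fh.write(f"alt_id: {alt}\n")
            for parent in sorted(ontology.parents[term]):
                fh.write(f"is_a: {parent}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED file (chrom, start, end, name[, score, strand])."""
    genes: list[GeneModel] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CohortParseError(
                    f"line {lineno}: BED line needs >= 4 columns (chrom start end name)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CohortParseError(f"line {lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                genes.append(GeneModel(fields[3], fields[0], start, end, strand))
            except ValueError as exc:
                raise CohortParseError(f"line {lineno}: {exc}") from exc
    return genes


def read_gmt(path: str | Path) -> FunSysCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise CohortParseError(f"line {lineno}: GMT line with empty gene set")
            name = fields[0]
            sets[name] = frozenset(g for g in fields[2:] if g.strip())
            labels[name] = fields[1]
    return FunSysCollection(sets=sets, labels=labels)


def write_gmt(collection: FunSysCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.sets):
            label = collection.labels.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{label}\t{genes}\n")


def read_disease_annotations(
    path: str | Path,
    ontology: Ontology | None = None,
    source: str = "diseases",
) -> DiseaseAnnotations:
    """Read a disease->phenotype TSV (columns disease_id, phenotype_id).

    When an ontology is supplied, phenotype ids are resolved through alt_id to
    primary ids; unresolvable ids are dropped and the drop count logged.
    """
    ann: dict[str, set[str]] = {}
    dropped = 0
    with Path(path).open() as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "disease_id":
                header = fields
                continue
            if len(fields) < 2:
                raise CohortParseError(f"line {lineno}: expected disease_id<TAB>phenotype_id")
            disease, term = fields[0].strip(), fields[1].strip()
            if ontology is not None:
                resolved = ontology.resolve(term)
                if resolved is None:
                    dropped += 1
                    continue
                term = resolved
            ann.setdefault(disease, set()).add(term)
    if dropped:
        logger.warning("dropped %d disease annotations with unresolvable phenotype ids", dropped)
    return DiseaseAnnotations(
        annotations={d: frozenset(s) for d, s in ann.items()}, source=source
    )


def read_corpus(path: str | Path) -> LiteratureCorpus:
    """Read a term->abstract-id TSV (columns term_id, abstract_id)."""
    terms: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "term_id":
                header = fields
                continue
            if len(fields) < 2:
                raise CohortParseError(f"line {lineno}: expected term_id<TAB>abstract_id")
            terms.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return LiteratureCorpus(term_abstracts={t: frozenset(s) for t, s in terms.items()})


def validate_cohort_terms(cohort: Cohort, ontology: Ontology) -> tuple[Cohort, int]:
    """Resolve every patient phenotype through the ontology.

    Returns a new cohort with alt ids mapped to primary ids, plus the count of
    dropped (unknown) terms.  Patients left with no valid term are removed.
    """
    dropped = 0
    patients: list[Patient] = []
    for p in cohort.patients:
        resolved: set[str] = set()
        for t in p.phenotypes:
            r = ontology.resolve(t)
            if r is None:
                dropped += 1
            else:
                resolved.add(r)
        if resolved:
            patients.append(replace(p, phenotypes=frozenset(resolved)))
    if dropped:
        logger.warning("dropped %d phenotype annotations not found in the ontology", dropped)
    return Cohort(patients), dropped
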