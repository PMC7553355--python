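"""Synthetic cohorts with planted comorbidity and genotype structure.

The generator emulates the structure the workflow is built to detect: groups
of phenotypes that co-occur in patients because of shared CNV gene modules.
Each planted module consists of

* ``m`` module phenotypes, each with its own carrier group whose patients
  carry two CNVs: one over a *shared* locus (common noise genes) and one
  over a phenotype-*private* locus holding a disjoint slice of the module's
  FunSys genes;
* a *bridge* group of patients expressing every module phenotype but
  carrying none of the module CNVs.  The bridge drives pairwise phenotype
  co-occurrence, so comorbidity is decoupled from the genotype layer — the
  union of two phenotypes' gene slices is enriched for the module FunSys
  while neither slice is on its own, which is exactly the emergent pattern.

Around the planted signal: background phenotypes at a per-term rate, a few
high-prevalence "general" phenotypes (the low-specificity regime), and noise
CNVs at recurrent hotspot loci carrying genes that belong to no FunSys (they
feed the SOR gene-content randomization pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import (
    CNVInterval,
    Cohort,
    DiseaseAnnotations,
    FunSysCollection,
    GeneModel,
    LiteratureCorpus,
    Ontology,
    Patient,
)
from .link_clustering import CoherentCluster
from .pair_network import PairAssociation
from .sor_mapping import PhenotypeGeneMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedModule:
    """One planted comorbidity module (see module docstring)."""

    name: str
    phenotypes: tuple[str, ...]
    funsys_id: str
    chrom: str
    carriers_per_phenotype: int = 20
    n_bridge: int = 10
    penetrance: float = 0.9
    n_shared_noise_genes: int = 50
    n_private_funsys_genes: int = 3
    n_private_noise_genes: int = 7
    n_funsys_filler_genes: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.penetrance <= 1):
            raise ValueError("penetrance must be in (0, 1]")
        if len(self.phenotypes) < 2:
            raise ValueError("a module needs >= 2 phenotypes")


@dataclass
class SimConfig:
    """Default scenario: 500 patients, 200 phenotype terms, 5 planted modules."""

    n_patients: int = 500
    n_background_terms: int = 120
    background_rate: float = 0.02
    n_general_terms: int = 3
    general_prevalence: float = 0.30
    modules: tuple[PlantedModule, ...] = ()
    n_hotspots: int = 30
    noise_cnv_prob: float = 0.30
    hotspot_genes: int = 8
    n_decoy_funsys: int = 50
    decoy_pool_size: int = 600
    decoy_set_size: tuple[int, int] = (8, 20)
    chrom_length: int = 3_000_000
    jitter: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modules:
            self.modules = default_modules()
        total = sum(
            len(m.phenotypes) * m.carriers_per_phenotype + m.n_bridge
            for m in self.modules
        )
        if total > self.n_patients:
            raise ValueError(
                f"planted carriers ({total}) exceed n_patients ({self.n_patients})"
            )


def default_modules() -> tuple[PlantedModule, ...]:
    sizes = (3, 4, 5, 4, 3)
    modules = []
    t = 0
    for i, m in enumerate(sizes, start=1):
        phenos = tuple(f"HP:M{t + j:03d}" for j in range(m))
        t += m
        modules.append(
            PlantedModule(
                name=f"module{i}",
                phenotypes=phenos,
                funsys_id=f"FS:MOD{i}",
                chrom=f"chr{i}",
                # keep |FunSys| = 18 for every module so a single phenotype's
                # 3-gene slice is never significant on its own while the
                # pair union's 6 genes always are
                n_funsys_filler_genes=18 - 3 * m,
            )
        )
    return tuple(modules)


@dataclass
class GroundTruth:
    planted_pairs: frozenset[tuple[str, str]]
    planted_genes: dict[str, frozenset[str]]  # phenotype -> causal gene set
    planted_clusters: tuple[tuple[frozenset[str], str], ...]  # (phenotypes, funsys)
    module_of_phenotype: dict[str, str] = field(default_factory=dict)


@dataclass
class _Layout:
    """Genomic layout of one module: locus coordinates and gene placement."""

    shared_span: tuple[int, int]
    private_spans: dict[str, tuple[int, int]]
    shared_genes: list[GeneModel]
    private_genes: dict[str, list[GeneModel]]  # phenotype -> genes in its locus
    funsys_genes: dict[str, list[str]]  # phenotype -> its module-FunSys slice


GENE_MARGIN = 6_000  # genes stay this far from locus edges, > jitter


def _place_genes(
    chrom: str, span: tuple[int, int], n: int, prefix: str
) -> list[GeneModel]:
    lo, hi = span[0] + GENE_MARGIN, span[1] - GENE_MARGIN
    if hi - lo < n * 1200:
        raise ValueError(f"locus {chrom}:{span} too small for {n} genes")
    step = (hi - lo) // n
    return [
        GeneModel(f"{prefix}{i:02d}", chrom, lo + i * step, lo + i * step + 1000)
        for i in range(n)
    ]


def _module_layout(mod: PlantedModule) -> _Layout:
    shared_span = (100_000, 300_000)
    shared = _place_genes(mod.chrom, shared_span, mod.n_shared_noise_genes,
                          f"{mod.name}.SH")
    private_spans: dict[str, tuple[int, int]] = {}
    private_genes: dict[str, list[GeneModel]] = {}
    funsys_genes: dict[str, list[str]] = {}
    for i, ph in enumerate(mod.phenotypes):
        start = 400_000 + i * 150_000
        span = (start, start + 100_000)
        n = mod.n_private_funsys_genes + mod.n_private_noise_genes
        genes = _place_genes(mod.chrom, span, n, f"{mod.name}.P{i}G")
        private_spans[ph] = span
        private_genes[ph] = genes
        funsys_genes[ph] = [g.gene for g in genes[: mod.n_private_funsys_genes]]
    return _Layout(shared_span, private_spans, shared, private_genes, funsys_genes)


def _jittered(span: tuple[int, int], rng: np.random.Generator, jitter: int,
              chrom_length: int) -> tuple[int, int]:
    s = int(span[0] + rng.integers(-jitter, jitter + 1))
    e = int(span[1] + rng.integers(-jitter, jitter + 1))
    return max(0, s), min(chrom_length, max(e, s + 1))


def generate_cohort(
    config: SimConfig,
) -> tuple[Cohort, list[GeneModel], FunSysCollection, GroundTruth]:
    """Generate the cohort, gene models, FunSys collection and ground truth."""
    rng = np.random.default_rng(config.seed)
    layouts = {m.name: _module_layout(m) for m in config.modules}
    for m in config.modules:
        lay = layouts[m.name]
        last = max(sp[1] for sp in lay.private_spans.values())
        if last + GENE_MARGIN > config.chrom_length:
            raise ValueError(f"module {m.name}: loci exceed chromosome length")

    # --- gene models -------------------------------------------------------
    gene_models: list[GeneModel] = []
    for m in config.modules:
        lay = layouts[m.name]
        gene_models.extend(lay.shared_genes)
        for ph in m.phenotypes:
            gene_models.extend(lay.private_genes[ph])
    hotspot_chroms = [f"chrN{i + 1}" for i in range(3)]
    hotspots: list[tuple[str, int, int]] = []
    for h in range(config.n_hotspots):
        chrom = hotspot_chroms[h % len(hotspot_chroms)]
        start = 100_000 + (h // len(hotspot_chroms)) * 250_000
        span = (start, start + 120_000)
        genes = _place_genes(chrom, span, config.hotspot_genes, f"NG{h:02d}.")
        gene_models.extend(genes)
        hotspots.append((chrom, *span))

    # --- FunSys collection -------------------------------------------------
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    for m in config.modules:
        lay = layouts[m.name]
        planted = [g for ph in m.phenotypes for g in lay.funsys_genes[ph]]
        filler = [f"{m.name}.FF{i:02d}" for i in range(m.n_funsys_filler_genes)]
        sets[m.funsys_id] = frozenset(planted + filler)
        labels[m.funsys_id] = f"planted module FunSys ({m.name})"
        for i, ph in enumerate(m.phenotypes):
            pid = f"FS:PRIV.{m.name}.{i}"
            sets[pid] = frozenset(g.gene for g in lay.private_genes[ph])
            labels[pid] = f"private-locus gene set ({ph})"
    # housekeeping-style sets crossing module boundaries: slice j of every
    # module's shared-locus genes.  Real maps pack a full slice of each,
    # randomized gene content scatters them, so these sets separate the real
    # association counts from the SOR gene-content null.
    n_slices = 5
    for j in range(n_slices):
        members: list[str] = []
        for m in config.modules:
            shared = [g.gene for g in layouts[m.name].shared_genes]
            per = len(shared) // n_slices
            members.extend(shared[j * per:(j + 1) * per])
        sets[f"FS:HK{j}"] = frozenset(members)
        labels[f"FS:HK{j}"] = "cross-module housekeeping gene set"
    decoy_pool = [f"UG{i:04d}" for i in range(config.decoy_pool_size)]
    lo, hi = config.decoy_set_size
    for d in range(config.n_decoy_funsys):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(decoy_pool), size=size, replace=False)
        sets[f"FS:DEC{d:03d}"] = frozenset(decoy_pool[i] for i in members)
        labels[f"FS:DEC{d:03d}"] = "decoy gene set"
    collection = FunSysCollection(sets=sets, labels=labels)

    # --- patients ----------------------------------------------------------
    pids = [f"pt{i:04d}" for i in range(config.n_patients)]
    order = rng.permutation(config.n_patients)
    cursor = 0
    phenotypes: dict[str, set[str]] = {pid: set() for pid in pids}
    cnvs: dict[str, list[CNVInterval]] = {pid: [] for pid in pids}

    def take(n: int) -> list[str]:
        nonlocal cursor
        ids = [pids[i] for i in order[cursor:cursor + n]]
        cursor += n
        return ids

    for m in config.modules:
        lay = layouts[m.name]
        for ph in m.phenotypes:
            for pid in take(m.carriers_per_phenotype):
                s, e = _jittered(lay.shared_span, rng, config.jitter, config.chrom_length)
                cnvs[pid].append(CNVInterval(m.chrom, s, e, "deletion"))
                s, e = _jittered(lay.private_spans[ph], rng, config.jitter,
                                 config.chrom_length)
                cnvs[pid].append(CNVInterval(m.chrom, s, e, "deletion"))
                if rng.random() < m.penetrance:
                    phenotypes[pid].add(ph)
        for pid in take(m.n_bridge):
            for ph in m.phenotypes:
                if rng.random() < m.penetrance:
                    phenotypes[pid].add(ph)

    background_terms = [f"HP:B{i:03d}" for i in range(config.n_background_terms)]
    general_terms = [f"HP:G{i:02d}" for i in range(config.n_general_terms)]
    for pid in pids:
        hits = rng.random(config.n_background_terms) < config.background_rate
        phenotypes[pid].update(t for t, h in zip(background_terms, hits) if h)
        for t in general_terms:
            if rng.random() < config.general_prevalence:
                phenotypes[pid].add(t)
        if rng.random() < config.noise_cnv_prob:
            chrom, s0, e0 = hotspots[int(rng.integers(len(hotspots)))]
            s, e = _jittered((s0, e0), rng, config.jitter, config.chrom_length)
            kind = "deletion" if rng.random() < 0.5 else "duplication"
            cnvs[pid].append(CNVInterval(chrom, s, e, kind))

    patients = []
    for pid in pids:
        if not phenotypes[pid]:
            # guarantee the Cohort invariant: give phenotype-less patients one
            # background term drawn at random
            phenotypes[pid].add(background_terms[int(rng.integers(len(background_terms)))])
        patients.append(
            Patient(id=pid, phenotypes=frozenset(phenotypes[pid]),
                    cnvs=tuple(cnvs[pid]))
        )
    cohort = Cohort(patients)

    # --- ground truth ------------------------------------------------------
    planted_pairs = frozenset(
        tuple(sorted(pq))
        for m in config.modules
        for pq in combinations(m.phenotypes, 2)
    )
    planted_genes: dict[str, frozenset[str]] = {}
    module_of: dict[str, str] = {}
    for m in config.modules:
        lay = layouts[m.name]
        shared = frozenset(g.gene for g in lay.shared_genes)
        for ph in m.phenotypes:
            planted_genes[ph] = shared | frozenset(
                g.gene for g in lay.private_genes[ph]
            )
            module_of[ph] = m.name
    planted_clusters = tuple(
        (frozenset(m.phenotypes), m.funsys_id) for m in config.modules
    )
    truth = GroundTruth(
        planted_pairs=planted_pairs,
        planted_genes=planted_genes,
        planted_clusters=planted_clusters,
        module_of_phenotype=module_of,
    )
    logger.info(
        "generated cohort: %d patients, %d terms, %d gene models, %d FunSys",
        cohort.N, len(cohort.phenotype_universe), len(gene_models), len(collection),
    )
    return cohort, gene_models, collection, truth


# ---------------------------------------------------------------------------
# companion fixtures: ontology, diseases, literature corpus
# ---------------------------------------------------------------------------


def generate_ontology(config: SimConfig) -> Ontology:
    """A small DAG mirroring the cohort's term structure.

    One branch per planted module (module phenotypes share a dedicated
    parent, so planted clusters are semantically tight), one branch for
    background terms and one for the general terms.
    """
    root = "HP:0000001"
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    for m in config.modules:
        branch = f"HP:{m.name}"
        parents[branch] = frozenset({root})
        for ph in m.phenotypes:
            parents[ph] = frozenset({branch})
    for group, terms in (
        ("HP:background", [f"HP:B{i:03d}" for i in range(config.n_background_terms)]),
        ("HP:general", [f"HP:G{i:02d}" for i in range(config.n_general_terms)]),
    ):
        parents[group] = frozenset({root})
        for t in terms:
            parents[t] = frozenset({group})
    return Ontology(parents=parents)


def generate_disease_annotations(
    config: SimConfig, n_decoy_diseases: int = 30
) -> DiseaseAnnotations:
    """Diseases matching each planted module plus random decoy diseases."""
    rng = np.random.default_rng((config.seed, 0xD1))
    ann: dict[str, frozenset[str]] = {}
    background = [f"HP:B{i:03d}" for i in range(config.n_background_terms)]
    for i, m in enumerate(config.modules, start=1):
        extra = background[int(rng.integers(len(background)))]
        ann[f"DIS:M{i:03d}"] = frozenset(m.phenotypes) | {extra}
    for d in range(n_decoy_diseases):
        size = int(rng.integers(3, 7))
        members = rng.choice(len(background), size=size, replace=False)
        ann[f"DIS:D{d:03d}"] = frozenset(background[j] for j in members)
    return DiseaseAnnotations(annotations=ann, source="synthetic")


def generate_corpus(
    config: SimConfig,
    truth: GroundTruth,
    n_abstracts: int = 5_000,
    per_term: int = 40,
    shared_per_module: int = 15,
) -> LiteratureCorpus:
    """A term/gene -> abstract-id corpus with planted co-mention structure.

    Terms of one module (and that module's causal genes) share a block of
    abstracts; every term additionally gets random abstracts, so unrelated
    terms co-mention only by chance.
    """
    rng = np.random.default_rng((config.seed, 0xAB))
    universe = [f"PMID:{i:06d}" for i in range(n_abstracts)]
    terms: dict[str, set[str]] = {}

    def random_abstracts(n: int) -> set[str]:
        return {universe[i] for i in rng.choice(n_abstracts, size=n, replace=False)}

    for m in config.modules:
        block = random_abstracts(shared_per_module)
        for ph in m.phenotypes:
            terms.setdefault(ph, set()).update(block)
            terms[ph].update(random_abstracts(per_term - shared_per_module))
            for g in truth.planted_genes[ph]:
                terms.setdefault(g, set()).update(block)
    for i in range(config.n_background_terms):
        terms.setdefault(f"HP:B{i:03d}", set()).update(random_abstracts(per_term))
    for i in range(config.n_general_terms):
        terms.setdefault(f"HP:G{i:02d}", set()).update(random_abstracts(3 * per_term))
    return LiteratureCorpus(term_abstracts={t: frozenset(s) for t, s in terms.items()})


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    pair_precision: float
    pair_recall: float
    gene_precision: float
    gene_recall: float
    cluster_precision: float
    cluster_recall: float
    empty_output: bool = False


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def evaluate_recovery(
    more_specific_pairs: Sequence,
    pg_map: PhenotypeGeneMap,
    clusters: Sequence[CoherentCluster],
    truth: GroundTruth,
    cluster_match_fraction: float = 0.75,
) -> RecoveryReport:
    """Set-overlap precision/recall of planted pairs, genes and clusters.

    A planted cluster counts as recovered when some returned *coherent*
    cluster contains >= ``cluster_match_fraction`` of its phenotypes; the
    same rule, reversed, scores precision.
    """
    found_pairs = {
        (p.pair if isinstance(p, PairAssociation) else tuple(p))
        for p in more_specific_pairs
    }
    tp_pairs = found_pairs & truth.planted_pairs
    found_genes = {
        (t, g) for t in pg_map.genes for g in pg_map.genes[t]
    }
    true_genes = {
        (t, g) for t in truth.planted_genes for g in truth.planted_genes[t]
    }
    tp_genes = found_genes & true_genes

    coherent = [c for c in clusters if c.is_coherent]
    recovered = 0
    for planted, _ in truth.planted_clusters:
        if any(
            len(c.phenotypes & planted) / len(planted) >= cluster_match_fraction
            for c in coherent
        ):
            recovered += 1
    matched_found = 0
    for c in coherent:
        if any(
            len(c.phenotypes & planted) / len(planted) >= cluster_match_fraction
            for planted, _ in truth.planted_clusters
        ):
            matched_found += 1
    empty = not found_pairs and not coherent
    return RecoveryReport(
        pair_precision=_safe_ratio(len(tp_pairs), len(found_pairs)),
        pair_recall=_safe_ratio(len(tp_pairs), len(truth.planted_pairs)),
        gene_precision=_safe_ratio(len(tp_genes), len(found_genes)),
        gene_recall=_safe_ratio(len(tp_genes), len(true_genes)),
        cluster_precision=_safe_ratio(matched_found, len(coherent)),
        cluster_recall=_safe_ratio(recovered, len(truth.planted_clusters)),
        empty_output=empty,
    )
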