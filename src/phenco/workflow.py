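"""End-to-end orchestration of the workflow stages.

``run_pipeline`` executes pairs -> SOR -> enrichment -> clustering on
in-memory objects and returns a :class:`PipelineResult`; the CLI and the
report writer are thin layers over it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .cohort_io import (
    Cohort,
    DiseaseAnnotations,
    FunSysCollection,
    GeneModel,
    PipelineConfig,
)
from .funsys_enrichment import (
    EnrichmentRecord,
    PairFunSysLabel,
    count_significant_associations,
    enrich_phenotypes,
    label_pairs,
)
from .link_clustering import (
    CoherentCluster,
    LinkCommunitySolution,
    attach_disease_overlap,
    coherent_clusters,
    link_communities,
)
from .pair_network import PairAssociation, build_pair_table, split_pairs
from .sor_mapping import (
    PhenotypeGeneMap,
    PhenotypeSORAssociation,
    SORRecord,
    assign_genes_to_sors,
    associate_phenotypes_to_sors,
    check_sor_invariants,
    decompose_to_sors,
    map_sors_to_genes,
    randomize_sor_genes,
)

logger = logging.getLogger(__name__)


@dataclass
class StageRecord:
    name: str
    wall_time_s: float
    sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    cohort: Cohort
    config: PipelineConfig
    pair_table: list[PairAssociation]
    more_specific: list[PairAssociation]
    less_specific: list[PairAssociation]
    sors: list[SORRecord]
    associations: list[PhenotypeSORAssociation]
    pg_map: PhenotypeGeneMap
    phenotype_enrichment: dict[str, list[EnrichmentRecord]]
    pair_labels: dict[tuple[str, str], list[PairFunSysLabel]]
    solution: LinkCommunitySolution | None
    clusters: list[CoherentCluster]
    manifest: RunManifest


def labeled_pair_graph(
    pair_labels: Mapping[tuple[str, str], Sequence[PairFunSysLabel]],
) -> nx.Graph:
    """The phenotype network whose edges carry >= 1 consistent/emergent label."""
    g = nx.Graph()
    g.add_edges_from(pair_labels.keys())
    return g


def run_pipeline(
    cohort: Cohort,
    gene_models: Sequence[GeneModel],
    collection: FunSysCollection,
    config: PipelineConfig | None = None,
    disease_annotations: DiseaseAnnotations | None = None,
) -> PipelineResult:
    """Run pairs -> SOR -> enrichment -> clustering and collect all outputs."""
    config = config or PipelineConfig()
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)

    def stage(name: str, start: float, **sizes: int) -> None:
        rec = StageRecord(name, time.perf_counter() - start, dict(sizes))
        manifest.stages.append(rec)
        logger.info("stage %s: %.2fs %s", name, rec.wall_time_s, sizes)

    t0 = time.perf_counter()
    pair_table = build_pair_table(cohort)
    more, less = split_pairs(pair_table, config.index_threshold)
    stage("pairs", t0, pairs=len(pair_table), more_specific=len(more),
          less_specific=len(less))

    t0 = time.perf_counter()
    sors = decompose_to_sors(cohort)
    sors = assign_genes_to_sors(sors, gene_models)
    check_sor_invariants(sors)
    associations = associate_phenotypes_to_sors(cohort, sors, config.index_threshold)
    pg_map = map_sors_to_genes(associations, sors)
    stage("sor", t0, sors=len(sors), associations=len(associations),
          mapped_phenotypes=len(pg_map))

    t0 = time.perf_counter()
    phenotype_enrichment = enrich_phenotypes(
        pg_map, collection, alpha=config.enrichment_alpha
    )
    pair_labels = label_pairs(
        [p.pair for p in more], pg_map, collection,
        alpha=config.enrichment_alpha,
        phenotype_enrichment=phenotype_enrichment,
    )
    stage("enrich", t0, labeled_pairs=len(pair_labels))

    t0 = time.perf_counter()
    graph = labeled_pair_graph(pair_labels)
    if graph.number_of_edges() >= 2:
        solution = link_communities(graph)
        clusters = coherent_clusters(
            solution, phenotype_enrichment, pair_labels,
            theta=config.coherence_theta,
        )
    else:
        solution = None
        clusters = []
    if disease_annotations is not None and clusters:
        attach_disease_overlap(
            clusters, disease_annotations, config.cluster_allowed_missing
        )
    stage("cluster", t0, communities=len(clusters),
          coherent=sum(1 for c in clusters if c.is_coherent))
    return PipelineResult(
        cohort=cohort, config=config, pair_table=pair_table,
        more_specific=more, less_specific=less, sors=sors,
        associations=associations, pg_map=pg_map,
        phenotype_enrichment=phenotype_enrichment, pair_labels=pair_labels,
        solution=solution, clusters=clusters, manifest=manifest,
    )


def sor_randomization_analysis(
    result: PipelineResult,
    collection: FunSysCollection,
    n_reps: int | None = None,
) -> tuple[int, np.ndarray]:
    """Real vs SOR-gene-randomized counts of significant phenotype-FunSys links.

    Each replicate shuffles the gene content of the SORs (coordinates,
    patients, gene counts and phenotype links untouched), rebuilds the
    phenotype->gene map and recounts significant ORA associations.  Returns
    (real count, array of replicate counts).
    """
    config = result.config
    n_reps = n_reps or config.sor_randomization_reps
    real_count, _ = count_significant_associations(result.phenotype_enrichment)
    counts = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        rand_sors = randomize_sor_genes(result.sors, seed=config.seed * 100003 + r)
        rand_map = map_sors_to_genes(
            result.associations, rand_sors, provenance=f"sor_randomized:{r}"
        )
        enr = enrich_phenotypes(rand_map, collection, alpha=config.enrichment_alpha)
        counts[r], _ = count_significant_associations(enr)
    return real_count, counts
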