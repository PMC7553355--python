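"""Shared fixtures: tiny handmade cohorts and a small ontology DAG."""

from __future__ import annotations

import pytest

from phenco.cohort_io import (
    CNVInterval,
    Cohort,
    DiseaseAnnotations,
    FunSysCollection,
    GeneModel,
    LiteratureCorpus,
    Ontology,
    Patient,
)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Five patients, three CNVs on chr1, phenotype overlap on HP:B."""
    return Cohort([
        Patient("P1", frozenset({"HP:A", "HP:B"}),
                (CNVInterval("chr1", 100, 200, "deletion"),)),
        Patient("P2", frozenset({"HP:B"}),
                (CNVInterval("chr1", 150, 250, "deletion"),)),
        Patient("P3", frozenset({"HP:C", "HP:B"}),
                (CNVInterval("chr1", 0, 300, "duplication"),)),
        Patient("P4", frozenset({"HP:D"})),
        Patient("P5", frozenset({"HP:A", "HP:D"})),
    ])


@pytest.fixture
def diamond_ontology() -> Ontology:
    """root <- {mid1, mid2} <- leaf (two lineages), plus a sibling leaf."""
    return Ontology(
        parents={
            "HP:root": frozenset(),
            "HP:mid1": frozenset({"HP:root"}),
            "HP:mid2": frozenset({"HP:root"}),
            "HP:leaf": frozenset({"HP:mid1", "HP:mid2"}),
            "HP:sib": frozenset({"HP:mid1"}),
        },
        alt_ids={"HP:old_leaf": "HP:leaf"},
    )


@pytest.fixture
def small_collection() -> FunSysCollection:
    return FunSysCollection(
        sets={
            "F1": frozenset({"g1", "g2", "g3", "g4", "g5"}),
            "F2": frozenset({"g6", "g7"}),
            "F3": frozenset(f"g{i}" for i in range(1, 21)),
        }
    )


@pytest.fixture
def small_corpus() -> LiteratureCorpus:
    abstracts = [f"PM{i}" for i in range(20)]
    return LiteratureCorpus(
        term_abstracts={
            "HP:A": frozenset(abstracts[:8]),
            "HP:B": frozenset(abstracts[3:9]),
            "HP:C": frozenset(abstracts[10:12]),
            "HP:all": frozenset(abstracts),
            "HP:disj": frozenset(abstracts[15:]),
            "pad": frozenset(abstracts),  # fixes the universe at 20
        }
    )
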