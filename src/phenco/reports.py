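"""Tabular and graphical report surfaces.

Every figure is written as SVG with a TSV twin holding exactly the numbers
drawn, so reports are pure functions of the stage outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cohort_io import DiseaseAnnotations, LiteratureCorpus
from .link_clustering import sort_clusters_for_report
from .pair_network import pair_mean_prevalence, prevalence
from .validation_stats import (
    cluster_membership_summary,
    comention_test,
    pair_disease_overlap,
)
from .workflow import PipelineResult

logger = logging.getLogger(__name__)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _hist_figure(path: Path, values: Sequence[float], xlabel: str, title: str,
                 bins: int = 40, vline: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(values, bins=bins, color="#4878b0")
    if vline is not None:
        ax.axvline(vline, color="crimson", ls="--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _bar_figure(path: Path, labels: Sequence[str], values: Sequence[float],
                ylabel: str, title: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(range(len(labels)), values, color="#4878b0")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_pairs_report(
    result: PipelineResult,
    outdir: Path,
    disease_annotations: DiseaseAnnotations | None = None,
    corpus: LiteratureCorpus | None = None,
) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    cfg = result.config

    summary_rows = [
        ("patients", result.cohort.N),
        ("phenotype_terms", len(result.cohort.phenotype_universe)),
        ("pairs_total", len(result.pair_table)),
        ("pairs_more_specific", len(result.more_specific)),
        ("pairs_less_specific", len(result.less_specific)),
        ("index_threshold", cfg.index_threshold),
    ]
    p = outdir / "pairs_report.tsv"
    _write_tsv(p, ("statistic", "value"), summary_rows)
    written.append(str(p))

    idx = [pa.index for pa in result.pair_table]
    p = outdir / "index_distribution.tsv"
    _write_tsv(p, ("term_a", "term_b", "index"),
               [(pa.term_a, pa.term_b, f"{pa.index:.6g}") for pa in result.pair_table])
    _hist_figure(outdir / "index_distribution.svg", idx,
                 "hypergeometric index", "Pair index distribution",
                 vline=cfg.index_threshold)
    written += [str(p), str(outdir / "index_distribution.svg")]

    prev = prevalence(result.cohort)
    p = outdir / "phenotype_prevalence.tsv"
    _write_tsv(p, ("term", "prevalence"),
               [(t, f"{v:.6g}") for t, v in sorted(prev.items())])
    _hist_figure(outdir / "phenotype_prevalence.svg",
                 [100 * v for v in prev.values()],
                 "prevalence (% of patients)", "Phenotype prevalence")
    written += [str(p), str(outdir / "phenotype_prevalence.svg")]

    rows = []
    for label, pairs in (("more_specific", result.more_specific),
                         ("less_specific", result.less_specific)):
        for v in pair_mean_prevalence(pairs, result.cohort):
            rows.append((label, f"{100 * v:.6g}"))
    p = outdir / "pair_prevalence.tsv"
    _write_tsv(p, ("dataset", "mean_prevalence_pct"), rows)
    written.append(str(p))

    if disease_annotations is not None:
        rows = []
        for label, pairs in (("more_specific", result.more_specific),
                             ("less_specific", result.less_specific)):
            for thr in cfg.pair_disease_thresholds:
                rows.append((label, thr,
                             pair_disease_overlap(pairs, disease_annotations, thr)))
        p = outdir / "pair_disease_overlap.tsv"
        _write_tsv(p, ("dataset", "min_diseases", "n_pairs"), rows)
        _bar_figure(outdir / "pair_disease_overlap.svg",
                    [f"{lab}/{thr}" for lab, thr, _ in rows],
                    [n for *_, n in rows], "pairs overlapping disease",
                    "Disease overlap of pair lists")
        written += [str(p), str(outdir / "pair_disease_overlap.svg")]

    if corpus is not None:
        rows = []
        for label, pairs in (("more_specific", result.more_specific),
                             ("less_specific", result.less_specific)):
            for pa in pairs:
                res = comention_test(corpus, pa.term_a, pa.term_b)
                if res.fisher_p is not None:
                    rows.append((label, pa.term_a, pa.term_b, f"{res.fisher_p:.6g}"))
        p = outdir / "pair_comention.tsv"
        _write_tsv(p, ("dataset", "term_a", "term_b", "fisher_p"), rows)
        pvals = [float(r[3]) for r in rows]
        if pvals:
            _hist_figure(outdir / "pair_comention.svg", pvals,
                         "one-sided Fisher p", "Pair co-mention p-values", bins=20)
            written.append(str(outdir / "pair_comention.svg"))
        written.append(str(p))
    return written


def write_clustering_report(result: PipelineResult, outdir: Path) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    clusters = result.clusters
    n_coherent = sum(1 for c in clusters if c.is_coherent)
    n_disease = sum(1 for c in clusters if c.overlaps_disease)
    n_both = sum(1 for c in clusters if c.is_coherent and c.overlaps_disease)
    rows = [
        ("clusters_total", len(clusters)),
        ("clusters_coherent", n_coherent),
        ("clusters_disease_overlap", n_disease),
        ("clusters_coherent_and_disease", n_both),
        ("partition_density", f"{result.solution.D:.6g}" if result.solution else ""),
        ("cut_height", f"{result.solution.cut_height:.6g}" if result.solution else ""),
    ]
    p = outdir / "clustering_report.tsv"
    _write_tsv(p, ("statistic", "value"), rows)
    _bar_figure(outdir / "clustering_report.svg",
                ["total", "coherent", "disease", "both"],
                [len(clusters), n_coherent, n_disease, n_both],
                "clusters", "Cluster counts")
    written += [str(p), str(outdir / "clustering_report.svg")]

    detail_rows = []
    for c in sort_clusters_for_report(clusters):
        funsys = ";".join(f"{f}:{cov:.3f}" for f, cov in sorted(c.coherent_funsys.items()))
        diseases = ";".join(f"{d}(missing={m})" for d, m in sorted(c.diseases.items()))
        detail_rows.append(
            (c.cluster_id, ",".join(sorted(c.phenotypes)), c.m_c,
             len(c.phenotypes), funsys, diseases)
        )
    p = outdir / "cluster_details.tsv"
    _write_tsv(p, ("cluster_id", "phenotypes", "m_c", "n_c",
                   "coherent_funsys", "overlapping_diseases"), detail_rows)
    written.append(str(p))
    return written


def write_patient_report(result: PipelineResult, outdir: Path) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    clusters = [c.phenotypes for c in result.clusters if c.is_coherent]
    rows = cluster_membership_summary(result.cohort, clusters)
    p = outdir / "patient_report.tsv"
    _write_tsv(p, ("n_phenotypes", "clusters_touched", "n_patients"), rows)
    return [str(p)]


def write_reports(
    result: PipelineResult,
    outdir: str | Path,
    disease_annotations: DiseaseAnnotations | None = None,
    corpus: LiteratureCorpus | None = None,
) -> list[str]:
    """Write all report surfaces; returns the list of files written."""
    outdir = Path(outdir)
    written = write_pairs_report(result, outdir, disease_annotations, corpus)
    written += write_clustering_report(result, outdir)
    written += write_patient_report(result, outdir)
    result.manifest.outputs.extend(written)
    return written
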