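# Methods

## The model

`phenco` treats a patient cohort as a phenotype–patient bipartite network
plus, for patients with CNVs, a genotype layer. All association scoring uses
one statistic, the hypergeometric index: for two entities connected through a
shared patient layer with overlap `k`, marginal patient counts `n_a`, `n_b`
and cohort size `N`,

    index = -log10 P(X >= k),   X ~ Hypergeometric(N, n_a, n_b).

The upper tail is inclusive, so `index(k=0) = 0` and an index of 2
corresponds exactly to a tail probability of 0.01. The tail is evaluated in
log space (log-gamma pmf at `k`, then a log-sum-exp accumulation of the pmf
ratio recurrence up the tail), which is stable for cohort-scale `N`; an exact
rational-arithmetic enumeration serves as the test oracle for `N <= 60`.

The same index with the same threshold (2.0) is used in two places: to split
phenotype pairs into more-/less-specific lists, and to retain phenotype–SOR
associations. Ties at the threshold go to the more-specific side
(“greater than or equal to”).

## Stages and their assumptions

**Pairs.** One record per unordered phenotype pair with `k >= 1`; pairs never
co-occurring form the unconnected universe. Patients with identical phenotype
profiles are not deduplicated. Null datasets: uniform sampling without
replacement (replicate `r` uses an RNG stream derived from `(seed, r)`, so
replicates are individually reproducible), degree-preserving double-edge
swaps (10×|E| swaps, rejecting self-loops and parallel edges; every node's
degree is preserved exactly), and uniform node-label permutation (edge count
and degree multiset preserved, individual degrees not).

**SORs.** Per chromosome, the sorted union of CNV breakpoints defines atomic
segments; segments covered by ≥ 2 distinct patients become SORs. A patient
with several CNVs over one segment counts once; deletions and duplications
are pooled (the kind is retained for reporting only); adjacent segments are
never merged, even with identical patient sets — the gene map is unaffected
because the union of segments is identical. Gene overlap is ≥ 1 bp on the
same chromosome, strand ignored. The SOR union equals exactly the regions of
CNV pileup depth ≥ 2 (asserted against a per-base oracle in the tests). The
gene-content null redraws each SOR's genes from the pooled multiset of all
SOR genes, without replacement within a SOR, keeping coordinates, patient
sets (hence phenotype links) and per-SOR gene counts fixed.

**Enrichment.** Hypergeometric upper-tail ORA. The gene universe defaults to
the union of the collection's sets, mirroring the common default of ORA
tools; it is configurable (e.g. to all SOR-mappable genes). Query genes
outside the universe are dropped with a logged count. Only sets with overlap
≥ 1 are tested and reported, and the Benjamini–Hochberg family is exactly
that per-subject set of reported records — adjustment is never pooled across
subjects. Significance is `p_adj < 0.05`. Pair labels: a FunSys significant
for both phenotypes and for their gene union is *consistent*; significant
for the union but neither phenotype is *emergent*; mixed combinations carry
no label. One FunSys collection per run.

**Link communities.** Edges of the labelled-pair network are clustered
hierarchically (average linkage by default, single linkage behind a flag) on
distance 1 − S, where S is the inclusive-neighborhood Jaccard similarity of
adjacent edges and 0 for non-adjacent edges. The dendrogram is cut at the
height maximizing partition density

    D = (2/M) * sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)),

with a community's term defined as 0 when `n_c = 2`. Ties between cut
heights go to the lower (finer) cut; candidate heights are the merge heights
plus 0 (all-singletons). Single-edge communities are reported, flagged
trivial by their size, rather than dropped. On all graphs with ≤ 7 edges the
returned cut matches an exhaustive-cut oracle. Edge communities partition the
edge set; node memberships may overlap.

**Coherence and disease overlap.** A phenotype carries evidence for FunSys F
when it is individually significant for F or is an endpoint of an in-cluster
pair labelled consistent/emergent for F. A cluster is coherent when the best
per-FunSys coverage is ≥ θ = 0.70. A disease overlaps a cluster when at most
`allowed_missing = 1` of the cluster's phenotypes are absent from the
disease's annotations. Cluster reports are ordered: coherent + disease
overlap, coherent only, disease only, neither.

**Validation.** Pair–disease overlap counts pairs whose two terms co-occur
in ≥ {1,2,3} diseases. Literature co-mention uses a one-sided (enrichment)
Fisher exact test over a 2×2 table whose universe U is the number of
distinct abstract ids anywhere in the corpus file; a term absent from the
corpus yields an explicit missing-term result, not p = 1. Phenotype–gene
co-mention is a count of assignments sharing ≥ 1 abstract, compared to a
null permuting the gene → abstract-set assignment (100 replicates by
default). Resnik similarity uses information content from the
disease-annotation corpus (annotations propagated to ancestors, natural log),
normalized by the maximum IC so scores lie in [0, 1]; the cluster score is
the mean over all within-cluster phenotype pairs pooled across clusters,
compared to random clusters of identical sizes drawn from the pooled
phenotype multiset. Patient–cluster support reports, per patient, the
maximum number of their phenotypes co-located in one cluster, with cohort
counts at ≥ 2 and ≥ 3 against the same size-preserving membership null.
z-scores are the standard `(observed − mean) / sd`; when the null sd is 0
the z is reported as undefined rather than a number.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `index_threshold` | 2.0 | index cut (tail p = 0.01) for pairs and phenotype–SOR links |
| `enrichment_alpha` | 0.05 | BH-adjusted ORA significance level |
| `coherence_theta` | 0.70 | minimum per-FunSys phenotype coverage of a coherent cluster |
| `replicates` | 50 | sampling / network-null / validation-randomization replicates |
| `sor_randomization_reps` | 100 | SOR gene-content randomization replicates |
| `pair_disease_thresholds` | 1, 2, 3 | disease-count thresholds for pair overlap |
| `cluster_allowed_missing` | 1 | phenotypes a disease may miss and still overlap a cluster |

All randomness flows from a single seed; derived streams are namespaced per
component so stages are reproducible independently.

## The synthetic generator

The generator emulates the structure the workflow exists to detect. Each of
the 5 default modules has 3–5 phenotypes. Per phenotype, a carrier group of
20 patients carries two deletions — one over a module-shared locus (50
"housekeeping" noise genes) and one over a phenotype-private locus (3 genes
of the module's FunSys + 7 private noise genes) — and expresses that
phenotype with penetrance 0.9. A separate bridge group of 10 patients
expresses *all* module phenotypes but carries none of the module CNVs. The
bridge drives pairwise co-occurrence, so comorbidity is decoupled from the
genotype layer: each phenotype maps only to its own 3-gene slice (plus
shared noise), the pair union holds 6 of the 18 FunSys genes, and with the
default gene universe (~870 genes) the single-slice overlap is
non-significant while the union survives BH — the emergent pattern, by
construction. This decoupling is deliberate: if the comorbidity-driving
patients carried a single shared causal locus, every phenotype would inherit
the full gene set and all planted FunSys would be consistent instead.
FunSys sets that slice the shared-locus genes *across* modules
(housekeeping-style) make the real association counts separate cleanly from
the SOR gene-content null, because random reassignment scatters their genes.
Around the signal: 120 background terms at rate 0.02/patient, 3 general
terms at prevalence 0.30 (the high-prevalence/low-index regime exercising
the specificity split), and noise CNVs (probability 0.30/patient) at 30
recurrent hotspot loci holding 8 FunSys-free genes each, which diversify the
randomization gene pool. Breakpoints are jittered ±2 kb (genes stay ≥ 6 kb
from locus edges, so all carriers always cover all locus genes).

What the generator does **not** emulate: human genome scale and gene
density, dosage direction (deletions and duplications are interchangeable),
inheritance, phenotype-term correlations from ontology structure, and
clinical ascertainment biases. Passing recovery tests therefore shows the
pipeline recovers the planted generative structure at realistic desk-scale
sizes, not that it reproduces any particular clinical cohort's numbers.

## Numerical choices and degenerate inputs

Index and ORA tails are clamped to [0, 1] before logs; `index(k=0) = 0` and
forced overlaps (`n_a + n_b > N`) give index 0. Graphs with < 2 edges are
rejected by link clustering (and returned unchanged, with a warning, by edge
rewiring). Empty ORA queries yield empty results. Cohort loading rejects
patients with no phenotypes; patients without CNVs participate in
phenotype-only stages. Obsolete/alternate ontology ids are mapped to primary
ids when the ontology provides them, otherwise dropped with a warning count.
Inheritance filtering (e.g. to de novo CNVs) is assumed done upstream of the
cohort file.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use the default scenario (500
patients, ~140 terms, 5 modules), 50 pipeline replicates for recovery
properties, 100 SOR randomizations, exhaustive oracle grids to N = 40
(index) and U = 40 (Fisher) with seeded sampling to N = 60, and 200 random
graphs for the partition-density oracle. These sizes were chosen so the
whole suite completes in a few minutes on one CPU while every check still
exercises the full code path.

## Known limitations

* The ORA universe and minimum-set-size conventions differ between published
  ORA tools; ours (collection union, overlap ≥ 1) is documented rather than
  claimed identical to any specific tool/version.
* Association is dosage-blind: a deletion and a duplication over the same
  segment are pooled.
* Link-community behaviour on weighted or directed networks is out of scope;
  so are alternative association indices (Jaccard, correlation) and
  GSEA-style ranked enrichment.
* Live database/literature queries are out of scope; disease annotations and
  the co-mention corpus are input files.
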