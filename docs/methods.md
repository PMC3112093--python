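# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations of the procedures.

## Study data

The `gsis69` fixture holds the 69 human–mouse orthologue pairs of the core
GSIS network, each with Swiss-Prot accession, ordered sub-pathway codes
(G glycolysis, T TCA cycle, P pyruvate cycle, N NADH shuttle, R respiratory
chain, M metabolite transport, S glutathione pathway), phylogenetic class
(U/E/M/V), human–mouse percent similarity (printed to 0.1 %), plus
positive-selection episodes (taxon, age in Mya) and OMIM disease
associations. Five mouse membrane transporters whose human orthologues could
not be unambiguously identified are excluded and listed in the fixture
metadata. Per-gene duplication counts are stored as missing: the underlying
duplication matrix was published only as a figure, so the duplication-history
stages run on user-supplied NHX trees or on synthetic data.

Because the fixture similarities are rounded to 0.1 %, statistics recomputed
from them (mean, SD, F) can differ from values computed on unrounded inputs
by roughly the rounding scale; the acceptance script reports what the fixture
yields: mean 93.8 %, SD 4.84 %.

Two fixture-derived statistics deserve a note. The one-way six-group pathway
ANOVA on the fixture gives F = 8.40 (df = 5, 63; p ≈ 4 × 10⁻⁶). A
multi-factor sequential (type-I) decomposition entering pathway first and
age class second gives an adjusted class-effect p ≈ 0.47, i.e. class adds
nothing once pathway is in the model; when per-gene duplication counts are
available they can be added to the same sequential model, which will further
adjust the pathway F. Second, the positive-selection × disease 2×2 table
from the fixture margins (1/24 disease genes selected vs 8/45 others) gives
χ² = 2.56, p = 0.11 (1 df, no continuity correction); with Yates correction
p = 0.22.

## Alignment and percent similarity

Global alignment uses the Gotoh three-state dynamic program (match state and
one gap state per sequence) with affine penalties: a gap run of length L
costs `gap_open + (L−1)·gap_extend`. Defaults are BLOSUM62, open 10,
extend 0.5, end gaps penalized — the classic EMBOSS/EBI "needle" settings
for protein pairs; a flag switches to end-gap-free semi-global alignment.
Traceback ties break deterministically: diagonal over gap-in-second-sequence
over gap-in-first-sequence, so identical inputs always give identical
alignments. Scores are validated in the test suite against an independently
written recursive three-state oracle and against Biopython's
`PairwiseAligner` at the same penalties.

Percent similarity is 100 × (columns whose residue pair has a strictly
positive BLOSUM62 score) / (all alignment columns, gap columns included in
the denominator only). Percent identity uses the same denominator, so
identity ≤ similarity always holds (BLOSUM62 diagonals are positive).

## Age classification

The rule is applied in fixed order to distinct-genome hit counts:
Universal if more than five prokaryote genomes are hit (threshold ≥ 6,
configurable); else Eukaryote-specific if ≥ 1 non-metazoan eukaryote hit;
else Metazoan-specific if ≥ 1 non-mammalian metazoan hit; else
Vertebrate-specific. Hits labelled "mammal" in input tables collapse into
the vertebrate category, which is the terminal class. Hit tables are
filtered at E ≤ 10 (configurable) and reduced to the best hit per
query/genome pair; homologue sets for the sharing analysis keep all
post-cutoff subject genomes. Shared-homologue clusters are single-linkage
connected components over edges weighted by homologue-set intersection size;
single linkage is the weakest assumption that preserves mutually disjoint
reported groups.

The composition test is a Pearson goodness of fit of the U/E/M/V counts
against reference proportions (default: the genome-wide metabolic complement,
0.56/0.20/0.05/0.19), df = k − 1.

## Duplication vectors and group tests

The default bin schedule is the eight vertebrate taxa named in the study
data, oldest first: Euteleostomi 420, Tetrapoda 359, Clupeocephala 320,
Percomorpha 190, Theria 166, Eutheria 102, Murinae 37, Catarrhini 31 (Mya).
A vector counts duplication-flagged nodes (NHX `D=Y`) on the root-to-focal
path whose taxon matches a bin. Pre-vertebrate duplications fall outside the
schedule window and contribute nothing; in strict mode an unmapped
duplication taxon raises, in lenient mode it is dropped with a warning.
"New family founded here" is a curator judgement, so truncation is explicit:
an `F=Y` tag excludes that node and everything rootward of it.

Distances are plain Euclidean; the dendrogram uses complete linkage by
default (configurable), and the zero-height cut recovers exactly the groups
with identical vectors under any linkage — this partition, not the
dendrogram shape, is the interpreted output.

The group test rank-sums within-group pairwise distances against all
remaining pairs (Mann–Whitney, two-sided; exact enumeration when both pair
sets have ≤ 8 elements and no cross-sample ties, otherwise the normal
approximation with tie correction). Direction is "clustered" when the
within-group median distance is significantly smaller than background,
"anticlustered" when larger. A caveat inherent to the method: pairwise
distances sharing a gene are dependent, so the raw Mann–Whitney p is
anticonservative under the null (the test suite measures this directly).
Results should therefore be read after Bonferroni correction across the
family of groups tested (7 for pathways, 4 for classes), at which point the
simulated type-I error is at or below nominal; very small p-values
("clustered respiratory chain"-style results) are robust to this caveat.
The leave-one-out variant (`exclude_gene_and_retest`) removes a member's
row/column and re-tests, to check whether a signal is driven by a single
gene; excluding a gene outside the tested group leaves the result unchanged
by definition.

## Statistical battery

* Pathway grouping: multi-pathway proteins take their first-listed code (the
  only ordering the source table provides). The `six_group` scheme
  {G, T, P∪N, M, R, S} gives the df = 5 one-way ANOVA; `five_group_figure3`
  merges T, P, N into TPN for the boxplot/outlier view.
* ANOVA is one-way fixed-effects on percent similarity; the degenerate
  zero-variance case raises rather than returning 0/0. For two groups F
  equals the squared pooled t (tested as an identity).
* Tukey HSD uses the studentized-range distribution via statsmodels; its
  adjusted p is never below the unadjusted pairwise p from the same
  pooled-error model.
* Spearman correlation uses midranks for ties; for n ≤ 9 the permutation
  null is enumerated exactly, otherwise the t approximation is used.
* Disease comparisons: the similarity t-test defaults to Welch (the default
  of R's `t.test`, the environment this style of analysis is normally run
  in; pooled-variance available by flag). On the fixture it gives
  p = 0.079. The Universal-proportion comparison is a goodness of fit of
  the disease-gene class split against the whole-network proportion;
  χ² contrasts with a degenerate margin (e.g. every record Universal)
  return NaN rather than a spurious p. 2×2 tables use no continuity
  correction by default; a Yates flag exists.
* Quintile bins: five rank-based bins sized as equally as possible; tied
  values all take the lowest bin any of them would occupy. Tukey fences use
  linearly interpolated quartiles; groups with < 4 members yield no
  outliers, with a warning (fences from 2–3 points are noise).

## Synthetic generators

The generators emulate the *statistical shape* of the inputs, nothing more —
no substitution-rate matrices over trees, no real taxon sampling:

* `synth_protein_pair` mutates a random sequence with substitutions biased
  (85 %) toward non-positive BLOSUM62 partners plus rare 1-residue indels
  (rate 0.01/site), and rejection-samples (≤ 50 draws) until the measured
  similarity is within ±2 points of target; supported targets 50–100 %.
  Closed-form inversion is impractical because the realized similarity
  depends on the optimal alignment, hence the bounded rejection loop.
* `synth_hit_profile` draws counts under hard constraints so the classifier
  recovers the requested class with probability 1; `synth_hit_table` expands
  profiles into the TSV dialect of the reader.
* `synth_gene_tree` builds a ladder backbone whose focal lineage receives
  Poisson(rate) duplication nodes per schedule bin (default rate 0.5/bin,
  a history of a few duplications per gene), each emitting a paralog leaf,
  and returns the ground-truth vector.
* `synth_cohort` draws group-specific Gaussian similarities (defaults match
  the observed per-pathway means/SDs/sizes of the 69-protein network,
  rounded to 0.1 as in the fixture) and couples duplication counts to the
  cohort-wide similarity ranks through a Gaussian copula
  (r = 2·sin(π·ρ_s/6)) discretized through a Poisson(2) quantile map. The
  discretization attenuates the realized rank correlation slightly (planted
  0.4 recovers ≈ 0.38–0.39 on average), which the recovery tests account
  for within their stated ±0.05 band.

All generators take a single integer seed through `numpy.random.Generator`;
identical seeds give identical outputs. Because the generators are Gaussian/
Poisson idealizations, passing recovery tests demonstrates correctness of
the estimators and bookkeeping, not robustness to real-data features such as
alignment ambiguity, annotation errors in gene trees, or non-Gaussian
divergence distributions.

## Problem sizes

The test suite and acceptance script run the simulation-based checks at
moderate sizes chosen to keep the whole suite interactive on one CPU while
leaving Monte-Carlo standard errors well inside the asserted tolerances:
400–1000 membership shuffles for null calibration, 200–500 simulated trees
for vector round trips, 150–300 cohort replicates for effect-size and
correlation recovery, and exhaustive grids where the space is small (the
11³ classifier truth table, all sequence-length combinations ≤ 12 for the
alignment oracle).

## Known limitations

* The duplication-history results for the real network (cluster memberships,
  the divergence–duplication correlation) are demonstrated on synthetic
  data; the fixture cannot carry the per-gene duplication matrix.
* The group clustering test inherits the pairwise-dependence caveat above;
  a full Mantel-style permutation test would be the conservative
  alternative and is easy to build from `group_clustering_test` plus a
  label-shuffling loop.
* Percent similarity is a protein-level proxy; it conflates mutation rate
  and selection and is not a substitute for dN/dS.
* The age classifier is detection-based: rapidly evolving ancient genes can
  be misclassified young because homology search loses them first.
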