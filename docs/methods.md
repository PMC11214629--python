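# Methods

## The analysis model

The package operates on the *annotated peptide table*: one row per identified
peptide carrying (i) a ranked taxonomic lineage from lowest-common-ancestor
(LCA) assignment, possibly truncated above genus where the sequence is
conserved across taxa; (ii) zero or more KEGG Orthology (KO) identifiers; and
(iii) one MS1-intensity abundance per subject.  All quantities downstream are
*relative* abundances: after removing peptides not assigned to Bacteria or
Archaea, each subject's abundances are rescaled to total 100.  The abundance
of any feature — a taxon, a KO, a pathway, or a (taxon, function) pair — is
the sum of the abundances of all peptides carrying that feature among their
annotations.  Two consequences are deliberate and documented rather than
"fixed":

* a peptide with k KO annotations contributes its full abundance to each of
  the k KOs, so KO columns may sum to more than 100 per subject (feature
  abundance is a sum over annotations, not a partition of the signal);
  at the pathway level a peptide is counted once per pathway even when
  several of its KOs share that pathway;
* taxon tables carry an explicit "unassigned" residual for signal whose
  lineage stops above the requested rank, so they partition each subject's
  total exactly, and taxon-function tables marginalize exactly onto the
  plain function tables (asserted in the conservation tests).

## Cross-cohort statistics

Datasets are never pooled at the abundance level.  Per dataset we compute the
mean relative abundance over subjects and the coefficient of variation
CV = 100·SD/mean (sample SD, n−1 denominator; undefined when the dataset mean
is zero, and then excluded for that dataset); cross-dataset values are
unweighted arithmetic means over the datasets where defined.  Ranks are
computed within each subject (rank 1 = most abundant; ties, including the
block of undetected features, receive average ranks) and summarized over the
pooled subject axis by median and IQR with linear interpolation between order
statistics.  Undetected features are kept with worst-tied ranks rather than
dropped, so every subject ranks the same harmonized feature universe — a
requirement for pooled medians; a switch (`drop_undetected`) exposes the
alternative.  "Detected" means abundance > 0; no abundance floor is imposed.

Core catalogs use two definitions: *all-subjects* (abundance > 0 in every
subject of every dataset) and *all-datasets* (abundance > 0 in at least one
subject of every dataset); the first is a subset of the second by
construction.

## Correlation meta-analysis

For each unordered feature pair, Spearman's ρ is computed separately per
dataset over all subjects (zeros are data, not missing; a constant feature
makes ρ undefined for that dataset and the dataset is skipped).  Each defined
ρ_d with n_d subjects is Fisher-transformed, z_d = atanh(ρ_d), with sampling
variance v_d = 1/(n_d−3) (the standard ZCOR convention; the Fieller-type
1.06/(n−3) variant is available via `variance_model="fieller"`).  The z_d are
pooled with a random-effects model whose between-dataset variance τ² is the
REML maximizer of the profiled restricted likelihood; the optimizer is a
bounded one-dimensional search on τ² ∈ [0, 100] with argument tolerance
1e−12 and an explicit boundary check at τ² = 0.  The combined estimate is
μ̂ = Σw_i z_i / Σw_i with w_i = 1/(v_i+τ̂²), SE = (Σw_i)^(−1/2), back-transformed
as tanh(μ̂).  P-values are the two-sided Wald normal tail by default (this
matches the very small FDR values such analyses report); the
Hartung–Knapp–Sidik–Jonkman t adjustment is available behind a flag.
Pairs with fewer than two datasets contributing a defined ρ are reported
unpooled and excluded from the FDR family.  Benjamini–Hochberg adjustment is
applied jointly across all pooled pairs of one run (one family per
correlation matrix), with significance at q < 0.05.

Selection rules for the two standard families follow the figure-legend
conventions: the top-n (default 50) KO functions by mean abundance among
those detected in all datasets and in at least 75% of subjects on average,
with ribosomal KOs excluded via an explicit list
(`src/mpmeta/data/ribosomal_kos.tsv`) rather than name matching; and the
pathways detected in all subjects with mean abundance strictly above 1%.
Matrix ordering uses average-linkage hierarchical clustering on the distance
1 − ρ̂ (missing cells imputed as 0 for ordering only); when every off-diagonal
distance is equal the input order is returned, making the ordering
deterministic.

## Phylum contrast, genus specificity, attribution

The phylum contrast compares, per function, the per-subject abundances
assigned to two phyla (default Bacillota vs Bacteroidota) after log
transformation, pooling subjects across datasets into one two-sided paired t
test per function, BH-corrected across functions.  Zeros are handled with a
data-scaled pseudocount, half the smallest nonzero abundance in the two
phyla's rows across all datasets, so the choice is unit-independent.
Zero-variance difference vectors get p = 1 when the mean difference is zero
and p = 0 flagged `degenerate` otherwise.  The log base (natural by default)
and a dataset-stratified variant (one-sample t on per-dataset mean
differences) are configurable.

Genus specificity classifies each function from the genus-KO tables
*including* the unassigned rows: per dataset, the missing fraction is the
genus-unassigned share of the function's subject-summed abundance, and genus
shares are computed over the genus-annotated portion only (otherwise the
≥ 90% rule could never fire once missingness exceeds 10%); both are averaged
unweighted across datasets.  A function is *not-evaluable* when mean
missingness ≥ 50%, *genus-specific* when the top genus's mean share ≥ 90%,
*shared* when that share is < 75%, and *intermediate* otherwise.  Exact
threshold hits are resolved with a 1e−12 tolerance on the side the rules
state.  A per-subject missing-fraction variant is exposed via `per_subject`.

Attribution matrices label every peptide by the deepest resolvable of
(phylum, order, genus, species) — residual signal goes to
"Bacteria/unassigned" — and report cross-dataset mean abundances per
(taxon, KO) cell for KOs detected in strictly more than 6 datasets with mean
abundance strictly above 0.001%.  Column totals equal the plain KO means by
construction and the code asserts it.

## The synthetic cohort generator

The generator emulates the *inputs* of a ten-cohort reanalysis, not raw
spectra: its defaults are ten datasets with (6, 16, 20, 17, 19, 20, 8, 12,
10, 6) subjects (134 total), four phyla with base weights (0.60, 0.35, 0.03,
0.02) and five genera each (geometric within-phylum decay), 80 KOs of which
15% are community-wide "housekeeping" functions, a genus-level annotation
ambiguity target of 70% of abundance (with ~19% resolving to species), batch
effect SD 0.30 and subject noise SD 0.60 on the log scale.  The two noise
SDs are calibrated only to the qualitative regime the design describes —
clear dataset-to-dataset batch structure and high inter-individual
variability — since no variance decomposition is published for such data.

Subject compositions are logistic-normal draws around the log base weights
plus a per-dataset genus offset (the batch effect); each genus's proteome is
normalized to the same total so a genus's share of the community signal
tracks its ecological share (the softmax still flattens extreme weights
slightly under noise, which is why realized phylum means sit a few points
below the base weights).  A (genus, KO) signal per subject is composition ×
expression × log-normal noise, split across 1–5 peptides with Dirichlet
weights — the many-peptides-per-function structure aggregation must invert.
Lineage truncation is applied per peptide with a probability boosted for
housekeeping KOs (conserved sequences drive LCA ambiguity) and solved
per dataset so the abundance-weighted expectation equals the target.

Features named in `planted_pairs` become community-wide functions expressed
uniformly (at a deliberately small weight, so compositional closure does not
couple them) and driven by per-subject Gaussian latents; a pair's latents are
correlated with Pearson r = 2·sin(πρ/6), the copula mapping for which the
population Spearman correlation equals the requested ρ.  Pairs must be
disjoint, so ρ = 0 pairs yield mutually independent features — the negative
controls used for false-discovery checks.  Ordinary genus-coupled KOs are
*not* null pairs: they genuinely co-vary through the shared composition,
exactly as real functions expressed by the same taxon do.

All randomness derives from one integer seed through named
`numpy.random.SeedSequence` streams; identical configs give byte-identical
output files.

What the generator does not emulate — identification error, shared peptides
between genera, protein-level correlation structure, fungal/viral fractions,
and real taxon names below phylum — bounds what passing tests show: they
validate the statistical machinery and the aggregation algebra under known
truth, not the biological conclusions one would draw from real cohorts.

## Problem sizes and numerical choices

The recovery experiments use 10 datasets × 15 subjects with planted
ρ ∈ {−0.8, −0.4, 0, 0.4, 0.8} over 20 replicate simulations; the
false-discovery experiment uses 46 independent features (1035 null pairs)
over 50 replicates with a reduced community (12 genera, 60 KOs), sizes chosen
to give stable Monte-Carlo estimates at desk scale.  At n = 15 subjects the
Spearman estimator itself is biased toward zero (its exact finite-sample
expectation at ρ = 0.8 is ≈ 0.76), so recovered estimates sit slightly
inside the planted values; the recovery criterion (mean absolute bias < 0.05)
accounts for this.  The REML oracle used in tests is a two-stage exhaustive
grid (coarse 1e−4 over [0, 2], then 1e−6 within ±2e−4 of the coarse optimum),
equivalent in resolution to a flat 1e−6 grid.  Known limitations: Spearman on
relative abundances ignores compositional coupling (no log-ratio correction,
matching the method being reproduced), and the REML p-values are Wald-normal
by default, which is anti-conservative for very small numbers of datasets —
the HKSJ flag exists for that case.
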