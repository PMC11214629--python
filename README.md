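# mpmeta — cross-cohort meta-analysis of gut metaproteomes

`mpmeta` is a tested re-implementation of the analysis chain used to
characterize the healthy human gut metaproteome across independent cohorts:
from taxonomically and functionally annotated peptide abundance tables to

* **core / variable feature catalogs** — per-dataset mean relative abundance
  and coefficient of variation (CV), pooled rank summaries (median, IQR), and
  two core definitions (detected in *all subjects* vs in *all datasets*);
* **random-effects meta-analysis of Spearman correlations** — per-dataset
  Spearman ρ between feature pairs (or a feature and a subject covariate such
  as age), Fisher Z transform z = atanh(ρ) with variance 1/(n−3), REML
  estimation of the between-dataset variance τ², back-transform with tanh,
  and Benjamini–Hochberg FDR across all pairs;
* **taxon-specific function attribution** — paired-t contrasts of
  log-abundances between the two dominant phyla (Bacillota vs Bacteroidota),
  genus-specificity classification of functions, and mixed-rank
  taxon × enzyme attribution matrices with conserved column totals.

Because the original inputs are ten external raw mass-spectrometry datasets,
the package ships a first-class **synthetic cohort generator** that emulates
the post-annotation stage of such a study — compositional subject profiles
dominated by two phyla, per-dataset batch effects, lowest-common-ancestor
ambiguity (~70% of peptide abundance unassignable at genus rank), and
*planted* feature–feature correlations — so every downstream stage is tested
against known ground truth.

The REML criterion, profiled over μ(τ²) = Σwᵢzᵢ/Σwᵢ with wᵢ = 1/(vᵢ+τ²), is

    ℓ_R(τ²) = −½ [ Σ ln(vᵢ+τ²) + ln Σ wᵢ + Σ wᵢ (zᵢ−μ)² ]

maximized over τ² ≥ 0; it is implemented from scratch and cross-checked in the
tests against an exhaustive grid search and against `metafor::rma` in R.

## Worked example

The `analysis/` scripts run the whole study on a simulated ten-cohort
collection (134 subjects, matching the cohort sizes the design emulates):

```
python analysis/01_simulate_cohorts.py
python analysis/02_aggregate_features.py
python analysis/03_core_and_variability.py
python analysis/04_correlation_meta.py
python analysis/05_taxon_attribution.py
```

Output (abridged):

```
simulated 10 datasets, 134 subjects, 17907 peptides -> results/sim
mean genus-unassigned abundance fraction: 0.686
phylum: 4 features; core all-subjects 4, core all-datasets 4
  top phyla (mean %): {'Bacillota': 53.9, 'Bacteroidota': 33.2, ...}
top-50 KO functions: 1225 pairs, 50 significant at q < 0.05
  planted (K00070, K00071, rho=+0.8): recovered +0.783, q=3.60e-16
  planted (K00072, K00073, rho=-0.8): recovered -0.739, q=1.56e-16
  planted (K00074, K00075, rho=+0.4): recovered +0.515, q=6.15e-08
  planted (K00078, K00079, rho=+0.0): recovered +0.023, q=9.82e-01
age vs genus abundance: 0 significant of 20
genus specificity over 77 functions: {'shared': 41, 'not-evaluable': 20,
                                      'genus-specific': 9, 'intermediate': 7}
attribution matrix: 77 enzymes x 65 taxa (column totals conserved)
```

Reading the numbers: the simulated community is dominated by the two phyla
(≈54% and ≈33% mean relative abundance); about 69% of peptide abundance is
unassignable at genus rank, as configured; the meta-analysis recovers the
planted correlations at their signs and magnitudes while the null pair stays
non-significant; ages, generated independently of composition, yield no
significant correlations; and the attribution matrix's per-enzyme totals
equal the plain KO means exactly.

The same pipeline runs on real annotated peptide TSVs via the `mpmeta` CLI
(`mpmeta run --config <yaml>`, or the per-stage subcommands `simulate`,
`aggregate`, `summarize`, `corr-meta`, `phylum-contrast`, `specificity`,
`attribution`).

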