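# Methods

## Design

The package separates two confounded clinical factors — alcoholic
dependence and liver cirrhosis — using a three-cohort design in which the
cirrhotic cohort carries both factors and the dependence-only cohort
carries one. All statistics operate on relative abundances in percent;
no compositional (log-ratio) transformation is applied, matching the
practice of testing raw relative abundances with rank statistics.

## Normalization and aggregation

Gene-level relative abundance divides each gene's mapped-read count by its
length and renormalizes per sample, so columns sum to 100 %. Aggregation
to species/genus/KO is an exact sum of member features with no
renormalization: a full partition preserves column sums bitwise-close
(the implementation clips at 100 to absorb float round-off), and features
without a label are dropped from the output while remaining in the
normalization totals — so sums after subsetting are interpretable as
"share of everything mapped". A gene present in the counts but missing
from the annotation is a fatal error, because the normalization needs
every gene's length.

Prevalence filters use strict inequalities (`> 1 %` genus, `> 0.1 %`
species, in at least one sample), and the multifactor filter keeps taxa
`> 0.01 %` in at least 10 samples.

## Hypothesis tests

* **Mann-Whitney.** Exact when the pooled sample is ≤ 12: by enumeration
  of the rank-sum null for tie-free data, and by exhaustive permutation
  with average ranks when ties are present (ties are routine here — the
  rank matrix assigns every undetected species the same sentinel). Larger
  samples use the normal approximation with tie correction. The
  permutation route at small n makes the one-sided oral-rank p equal to
  the exhaustive-permutation p even when sentinels tie.
* **Benjamini-Hochberg** step-up with monotonicity enforcement, applied
  within each feature level (species and genus tables separately), and at
  q < 0.01 for taxa vs q < 0.05 for functional features and the
  multifactor model — thresholds follow the study design the package
  implements.
* **Welch's t** for alpha-diversity comparisons; identical constant groups
  return (t = 0, p = 1), distinct constants are rejected as degenerate.
* **Pathway calls** use the explicit "at least half of the detected KO
  terms differential" criterion, with membership counted over KOs present
  in the KO abundance matrix (not all KOs annotated to the pathway —
  undetected KOs cannot testify either way). Gene-set enrichment smoothing
  (reporter-feature style) is intentionally not reproduced.

## PERMANOVA and the multifactor model

One-factor PERMANOVA computes the pseudo-F from among/within sums of
squared Bray-Curtis dissimilarities; the permutation p uses the +1
correction (p ≥ 1/(n_perm+1)) and R² = SS_among/SS_total. The screen runs
each factor marginally and BH-adjusts across the factor set; age enters
dichotomized at the cohort median. On small fixtures the Monte-Carlo p
converges to the exhaustive-permutation value (tested at n = 8).

Per-taxon association uses ordinary least squares on
arcsine-square-root-transformed abundance fractions against the three
binary covariates jointly (yes = 1, M = 1), with BH across all
(taxon, factor) pairs. This is the classical variance-stabilized linear
model underlying boosted-GLM multifactor tools; the boosting/feature-
selection layer is deliberately omitted and the output is labelled an
approximation. The joint fit is what attributes shared patient-cohort
shifts to the dependence term while the cirrhosis term absorbs the
cirrhosis-specific extra.

## Outlier rule

Samples are hierarchically clustered (Ward by default, complete linkage
offered) on Bray-Curtis dissimilarity; the tree is cut at the top level
and the smaller branch is the outlier set. An exact tie leaves "smaller"
undefined and returns no outliers with a warning. Bray-Curtis is not a
metric (no triangle inequality), which Ward tolerates in practice; the
choice mirrors dissimilarity-based quality control of metagenome
collections. The dominance report flags samples whose top genus exceeds a
configurable threshold (default 50 %; the threshold is a free parameter
because "dominated" is not sharply defined).

## Synthetic cohort generator

The generator emulates the study conditions: cohorts of 72 ADS / 27 ALC /
60 controls, ~300 species in a curated gut taxonomy, 20 000 catalogue
genes, 100 000 reads per sample (scaled down from tens of millions in a
real survey to keep desk-scale runtimes; configurable upward).

* **Baseline.** Species means are log-normal around genus-level locations
  (heavy-tailed, Bacteroides/Prevotella-weighted), with per-sample
  log-normal noise (σ = 0.5) and a detection limit of 0.001 %. Each
  species' baseline mean share is capped at 4 % — real species-level
  means top out at a few percent, and an uncapped log-normal occasionally
  mints a mega-species whose natural fluctuations masquerade as dominance
  outliers. The per-sample noise is deliberately moderate so that
  single-genus dominance occurs only where planted, matching a cohort in
  which abnormal communities are rare (a handful per hundred samples);
  the cost is that inter-individual variance is lower than the most
  variable real cohorts.
* **Planted effects** multiply species fractions before renormalization
  (default: dependence depletes butyrate-producing Clostridiales 4-fold
  and enriches Enterobacteriaceae and a Bifidobacterium/Lactobacillus set
  4-fold; cirrhosis depletes Bacteroidales and enriches a different
  Bifidobacterium/Lactobacillus set). Signature species draw their
  baseline from a narrowed band floored at a moderate level: they must be
  detectable study taxa (above the 0.01 %-in-10-samples model filter), and
  keeping them minor keeps each factor's community-level R² at a few
  percent, the regime the multifactor analysis is designed for.
  Compositional spillover onto unplanted taxa is accepted and visible
  (enriching one set deflates everything else slightly).
* **Oral spike-ins.** Five buccal species (Streptococcus and Veillonella
  spp.), near-absent from the gut baseline, are planted into cirrhosis-
  cohort samples with probability 0.6 at 0.5–4 % — percent-scale
  detections concentrated in the cirrhotic cohort, with only sporadic
  baseline detections elsewhere.
* **Dominance outliers.** Planted samples have a single dominant genus
  (one genus by default) scaled to 70 % of the community, the dominant
  mass concentrated in a leading congener, and the remainder community
  collapsed to a random ~30 % species subset — reproducing the low
  richness (Shannon ≈ 2) of real dominated samples. All planted outliers
  sharing one dominant taxon is what makes "the smaller branch at the
  top-level cut" a well-posed recovery target; outliers dominated by
  pairwise-different genera are mutually as distant as they are from the
  bulk, and no two-branch cut can group them.
* **Gene layer.** Genes are assigned to species (every species gets at
  least one), with lengths uniform in [300, 3000] bp and log-normal
  per-gene weights; reads are drawn multinomially with probability ∝
  species fraction × gene weight × length, so length-normalized abundances
  recover species fractions. KO effects multiply member-gene sampling
  weights (default: 6 alcohol-metabolism KOs up under dependence, 9 under
  cirrhosis, a few down). VF hits link Enterobacteriaceae-tagged genes to
  50 VF reference ids with passing similarity scores plus decoy rows that
  fail each criterion in turn; VF enrichment therefore follows the planted
  Enterobacteriaceae expansion.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  configs give bitwise-identical outputs.

What the generator does **not** emulate: enterotype-like bimodality,
taxon-taxon correlation structure, batch/sequencing-center effects,
overdispersion beyond log-normal × multinomial, strain-level variation,
and viruses. Passing recovery tests therefore show that the statistics
detect the planted signal classes at study-like sizes and noise — not that
they are robust to every pathology of real surveys.

## Numerical choices

* Shannon uses natural log (values ≈ 3–4 nats for hundreds of species).
* Rank ties share their average rank rounded half-up; rows are kept in
  lexicographic order for determinism.
* MDS is classical (metric) scaling; negative-eigenvalue axes (inevitable
  for Bray-Curtis) are dropped, and requesting more axes than positive
  eigenvalues truncates with a warning.
* The VF coverage denominator is read as the reference gene's length; a
  catalogue gene similar to several VF genes contributes its full
  abundance to each (abundances are summed, never split).
* Direction of differential features is the sign of the median difference,
  falling back to the mean difference when medians tie (common with
  zero-inflated features).
* "Enriched" in the oral-rank test means numerically smaller rank
  (rank 1 = most abundant).

## Known limitations

* The OLS multifactor model is an approximation to boosted GLMs; with
  strongly collinear factors the attribution can differ.
* PERMANOVA is marginal per factor (no partialling); confounded metadata
  (e.g. age differing between cohorts by design) can surface as an
  apparent age signal even though the generator plants none.
* The Mann-Whitney normal approximation is used above 12 pooled samples;
  at moderate sizes with extreme tie mass (features detected in only a
  couple of samples) its p values are approximate and conservative.
* Bray-Curtis + Ward is a pragmatic, not theoretically clean, pairing;
  complete linkage on Euclidean distances is offered as an alternative.
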