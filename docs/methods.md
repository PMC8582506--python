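# Methods

`ffpe16s` analyses paired fresh-frozen (FF) and formalin-fixed
paraffin-embedded (FFPE) tissue microbiomes profiled by 16S rRNA amplicon
sequencing. The scientific question it operationalises: when only FFPE
material is available, how far does its microbial profile recapitulate the
matched frozen tissue, and can that comparability be scored from the FFPE
sample itself? This note documents the models, conventions and numerical
choices; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing cascade

Raw ASV (amplicon sequence variant) count tables pass through a fixed-order
cascade, each step logged in a provenance report:

1. **Eukaryote filtering.** ASVs with kingdom `Eukaryota` (host and other
   non-microbial reads) are dropped. Kingdom-unassigned ASVs are kept.
2. **Negative-control subtraction.** Every ASV with a non-zero count in the
   no-template control (NTC) is removed *as an identity* from all samples
   — counts are not decremented — and the NTC column is dropped. Presence
   (count > 0), not an abundance threshold, defines the NTC set.
3. **Singleton removal.** ASVs with a cohort-wide total of exactly one read
   are dropped. "Singleton" is defined at the table level, not per sample;
   an ASV with one read in each of two samples (total 2) survives.

Rarefaction (where used: alpha diversity and the comparability index) is
subsampling without replacement — one multivariate-hypergeometric draw per
sample — to a common depth, by default the minimum library size. Column
sums equal the requested depth exactly and a fixed seed reproduces the
draw bit-for-bit. Relative abundances are percentages, `100 * x / sum(x)`.

BLAST tabular hits (standard 12 columns, optional `qcovs`) are filtered at
identity ≥ 98% and query coverage ≥ 90%; survivors are sorted by ascending
e-value (bitscore descending as tie-break) and the best hit per query is
kept. When `qcovs` is absent, coverage is the aligned query span over a
caller-supplied query length; without either, the filter refuses rather
than guessing.

## Diversity and ordination

* **Shannon index** H = −Σ pᵢ ln pᵢ over non-zero proportions. Natural log
  (the common ecology convention).
* **Bray–Curtis** 1 − 2·Σ min(xᵢ, yᵢ) / (Σx + Σy), computed on relative
  abundances.
* **Jaccard** on presence/absence (the classical set form): membership
  dissimilarity, deliberately contrasted with the abundance-weighted
  Bray–Curtis.
* **Jensen–Shannon divergence** ½KL(p‖m) + ½KL(q‖m), m = ½(p+q), natural
  log, bounded by ln 2. The divergence itself is reported, not its square
  root; square-root it to match software that returns the metric form.
* **PCoA** Gower-centres −½D², eigendecomposes, and keeps axes with
  eigenvalues above 1e−9 × the largest. Negative eigenvalues (possible for
  semi-metrics such as Bray–Curtis) are dropped without Lingoes/Cailliez
  correction; each axis's proportion of variance is its eigenvalue over
  the sum of *positive* eigenvalues, so proportions sum to ≤ 1.
* **Ward clustering** applies Ward's minimum-variance linkage to a chosen
  community dissimilarity; sample columns are sorted lexicographically
  first so ties break deterministically.

## Hypothesis testing

* **PERMANOVA** (single factor). SS_total = (1/N)Σ_{i<j} d²ᵢⱼ, SS_within =
  Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ, pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)).
  The permutation p-value includes the observed labelling,
  (1 + exceedances)/(1 + n_perm), with n_perm = 999 by default — the
  standard convention that avoids p = 0. An exhaustive mode enumerates all
  label orderings for small n (used by the oracle tests). Multi-factor
  sequential partitioning is out of scope; factors such as preservation
  and patient are tested in separate single-factor runs.
* **Paired Wilcoxon signed-rank.** Zero differences are dropped (Wilcoxon's
  original treatment — implementations differ, so this is stated
  explicitly). Up to 25 non-zero pairs, the p-value comes from the exact
  sign-flip distribution of the positive-rank sum, computed by convolution
  with tied mid-ranks doubled to integers; the two-sided p doubles the
  smaller tail. Beyond 25 pairs, the tie-corrected normal approximation.
* **Benjamini–Hochberg** step-up, capped at 1, original order restored.
* **Spearman.** rho is the Pearson correlation of mid-ranks. For n ≤ 9 the
  p-value is exact (all n! rank permutations enumerated); for larger n the
  t approximation on n − 2 degrees of freedom.
* **LEfSe (two-class).** Stage 1 gates each taxon by a two-class
  Kruskal–Wallis test (equivalent to Wilcoxon rank-sum for two classes) at
  α = 0.05. Stage 2 rescales samples to a fixed total of 10⁶, then over 30
  bootstrap rounds resamples ⌈2n/3⌉ samples per class without replacement
  and fits a one-axis regularised linear discriminant (lsqr solver,
  automatic shrinkage — compositional data make the sample covariance
  singular). A taxon's per-round effect is the mean of (a) the class-mean
  gap along the discriminant axis scaled by the taxon's unit-norm
  coefficient and (b) its raw class-mean gap; the LDA score is
  log10(1 + mean effect) and taxa with score > 3 are reported for the
  class with the larger mean. The subclass (one-against-all) stage is
  omitted: the paired FF/FFPE design has no subclasses, and with two
  classes the gate test coincides with the pairwise rank test. All
  internals (rescale constant, rounds, resample fraction, thresholds) are
  exposed as arguments.

## The comparability index

For each pair, **dominance** is the summed relative abundance, within the
FFPE sample, of the two most abundant bacterial orders of its matched FF
sample. The unassigned-order bucket and archaeal orders are excluded from
top-2 candidacy (an "NA" bucket is not an order, and trace archaea never
dominate FF tissue); ties break lexicographically. **Contaminant
prevalence** is the FFPE mass assigned to a configurable list of typical
sequencing contaminants (default genera: Rhizobium, Acinetobacter,
Lysinibacillus, Delftia, Paracoccus, Sphingomonas, Pseudomonas,
Aquipuribacter; fallback orders Rhodobacterales and Sphingomonadales for
ASVs whose genus is unlisted or unassigned — each ASV counts once).

A pair is classified **high** comparability iff dominance > 50% (the
published convention) *and* contaminant prevalence ≤ 25%. The 25% default
is a package choice, not a published value — no prevalence threshold
exists in the literature this models — and both cutoffs are arguments.

Pair dissimilarities for the dominance correlation are computed at ASV
level on relative abundances of counts rarefied to the minimum depth,
after the full preprocessing cascade. Spearman correlations of dominance
against the three metrics are BH-adjusted as a family of three (the trio
reported together); both raw and adjusted p-values are emitted because
conventions differ on which is quoted.

## RNA-ISH concordance

ISH signal counts (per sample × probe × region) model RNAscope-style
quantification; image analysis itself is out of scope. Samples with fewer
than 100 whole-section total-bacteria counts fail QC and are excluded
before any summary. Presence calls: ≥ 100 counts for ISH (tumor-region
count, matching the tumor-ROI semantics of the assay), ≥ 10 reads for 16S.
The 16S threshold is applied to post-cascade, pre-rarefaction counts
(rarefaction would make presence depend on the subsampling draw). Missing
platform readouts are explicit NA, never imputed as absent, and NA rows
drop out of the (k of n) concordance summaries. The packaged
`reference_presence_7pairs.tsv` fixture carries the published
presence/absence pattern for seven evaluable pairs × three genera and is
the exact regression target for those summaries.

## Synthetic cohort generator

The generator produces the study design the pipeline assumes: `n_pairs`
(default 10) FF/FFPE pairs plus one NTC; ~16,000 microbial reads per
tissue sample and ~25,000 for the NTC; eukaryote (host) reads layered on
top at 15.6% (FF) and 18% (FFPE) of total reads; Poisson-distributed
singleton ASVs (mean 3/sample) injected at one read each.

* **FF communities.** A base profile of 18 gut genera — Bacteroidales
  (47%) and Clostridiales (38%) dominant, minor Fusobacteriales /
  Enterobacteriales / Coriobacteriales / Propionibacteriales /
  Lactobacillales components, and a 0.2% trace of Methanobacteriales
  archaea. Patient effect: one Dirichlet draw per patient around the base
  (concentration 200), the simplest exchangeable model consistent with
  patient identity explaining more variance than preservation.
* **FFPE derivation.** The patient's FF profile is scaled by per-role
  dropout multipliers (archaea → 0, the *Fusobacterium* marker → 0.25),
  renormalised, then mixed with the contaminant pool as
  (1−c)·ff + c·pool, so the expected contaminant relative abundance equals
  the planted fraction c exactly. Degradation beyond role dropout is
  deliberately uniform across taxa: fragmentation-length effects are not
  identifiable from count data and are not modelled. The default
  contamination gradient is linspace(0.05, 0.8) across pairs; the pool
  composition is identical across samples (a shared reagent/environment
  source), only its fraction varies.
* **Contaminant pool and NTC.** Pool proportions follow NTC-like genus
  frequencies (Rhizobium 56%, Acinetobacter 11%, Lysinibacillus 7%,
  Delftia 5%, remainder split among Paracoccus, Sphingomonas, Pseudomonas,
  Aquipuribacter). Each genus is split into reagent-type ASVs — the
  per-genus abundance prefix closest to half the genus mass — which the
  NTC can draw, and environment-type ASVs that occur only in FFPE tissue.
  NTC subtraction therefore removes roughly half the planted contaminant
  mass and the rest survives into the analysed table, which is what makes
  a post-decontamination comparability index worth having at all.
* **ASV-level structure.** Each genus spans 16 ASVs with a geometric
  (ratio 0.78) within-genus split: one dominant variant plus a long rare
  tail. The tail places many ASVs near the detection limit so that
  community *membership* — hence the binary Jaccard distance — responds to
  dilution of the FF fraction, as it must for a membership metric to track
  contamination. The tail stops at 16 variants (smallest weight ≈ 0.55%)
  so every real ASV's expected cohort-wide total stays well above one
  read, keeping injected singletons identifiable as exactly the
  total-count-1 ASVs; trace archaeal lineages get 2 variants for the same
  reason. The split is fixed, not random, so ASV identities are stable
  across seeds.
* **Ground truth.** The cohort records planted contamination fractions,
  per-patient FF profiles, injected eukaryote read counts and singleton
  ids, contaminant/NTC-shared ASV sets, the planted discriminant genera,
  and a true comparability label per pair — high iff c ≤ 0.4, the midpoint
  of the default gradient; a generator convention, since no published
  numeric rule exists.
* **ISH counts.** Negative-binomial (dispersion 10) tumor/normal counts
  per probe around configurable means; tumor-associated probes
  (total-bacteria 600/40, Fusobacterium 300/5, Bacteroides 250/5) have
  tumor ≫ mucosa means, the contaminant-mode Propionibacterium is
  region-independent (150/150). Designated low-biomass samples are drawn
  with suppressed signal capped below the 100-count QC threshold.

**What the generator does not emulate** — and hence what green tests do
not show about real data: read-level error and chimeras (it starts from
counts), PCR and extraction bias, taxon-specific formalin degradation,
block-age effects, inter-sample cross-contamination, and real phylogenetic
correlation between taxa. Recovery results on the synthetic gradient
demonstrate that the index responds to the planted mechanism, not that
real FFPE discordance is caused solely by that mechanism.

## Problem sizes and numerical conventions

Simulation-backed checks use the cohort's native scale (10 pairs at
16,000 reads; ~50 seeds for recovery rates), 1000 null datasets at 199
permutations for PERMANOVA calibration, and exhaustive enumeration up to
n = 6 samples (PERMANOVA), n = 10 pairs (Wilcoxon) and n = 8 (Spearman).
Fixed seeds make every stochastic test reproducible. Degenerate inputs
fail loudly: all-zero samples, constant vectors in correlations,
single-group PERMANOVA, rarefaction depths exceeding a library, and
missing taxonomy entries all raise validation errors naming the offender.
Tables are re-ordered lexicographically on I/O, and all results are
invariant to sample/ASV order.
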