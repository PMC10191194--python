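# Methods

## Two-pool isotope mixing model

The mixing model treats the ERM of a symbiosis plate as a mixture of two
carbon pools with distinct ¹³C signatures: fungal carbon fixed before/
without the host (FLM baseline, natural abundance ≈ 1.08 atom%) and
host-fixed carbon (leaf signature after ¹³CO₂ labelling). The fraction of
host-derived fungal carbon is the lever-rule position of the ERM atom%
between those end members. Multiplying by the colony's carbon content and
dry biomass (both isolate-level averages from fungus-only plates) gives
absolute mg of host-derived C retained in hyphal tissue. Respired and
exuded carbon are invisible to both quantities by construction, so the
estimate is a retention floor, not total transfer.

Assumptions: the FLM mean is a valid unlabelled baseline for symbiotic
hyphae; the leaf atom% is the signature of currently transferred carbon;
isotopic fractionation during transfer is negligible relative to the
labelling signal.

Numerical choices:

- **Outlier filter.** Per tissue role within an isolate, values outside
  the closed interval [Q1 − k·IQR, Q3 + k·IQR] are removed once (no
  re-iteration), k = 1.5, quartiles by linear interpolation (R type 7).
  Fewer than 4 values: nothing is removed and a warning is raised.
  Constant vectors are never touched (closed fences).
- **Leaf pairing.** Each ERM replicate is paired with the leaf sample
  from the same plate (plates are the experimental unit); an isolate-mean
  leaf is available via `leaf_pairing="isolate_mean"`. If a plate's leaf
  value is itself removed as an outlier, that plate has no usable source
  end member and its ERM replicate is dropped with a report entry; a leaf
  sample absent from the input is an error.
- **Units.** Both percentages in the absolute-carbon product are treated
  as fractions (÷100 each) so C_symbiosis carries the biomass unit (mg).
- **Degenerate denominator.** |leaf − FLM| ≤ 1e−9 atom% raises an error:
  unlabelled leaves cannot anchor the mixture.
- Mixing fractions below 0% or above 100% (possible under measurement
  noise) are passed through unclamped and flagged `out_of_range`;
  truncation would bias isolate means.

## Growth traits and statistics

Derived traits: colonization % = colonized lateral root tips / tips in
contact with mycelium × 100; hyphal density = colony dry biomass / colony
area at harvest (mg/cm²); radial growth rate = percent area increase from
week 2 ("plant contact") to week 4 ("harvest") per day, with the week-2
colony area as denominator (the colony state when the host was
introduced; the original agar-block area is available as an alternative
reference). The day count defaults to 14 and is configurable.

ANOVA is one-way fixed-effects; post-hoc all-pairs comparisons use the
Tukey HSD studentized-range test with the Tukey–Kramer harmonic-size
correction for unbalanced designs (4–5 replicates per isolate are
routine). Letters come from the insert-and-absorb compact-letter-display
algorithm: start from one column containing all groups, split every
significant pair out of any shared column, absorb columns that become
subsets, and assign letters in order of descending group mean (so "a"
marks the largest mean). Groups share a letter iff no significant
difference separates them. Zero within-group variance is special-cased
(identical data → F = 0, p = 1, one letter; distinct constant groups →
all pairs significant).

PCA is a singular-value decomposition of the centered (and by default
scaled, since traits mix mg, µm and %/day) natural-log data; log uses
ln(x + ε) with ε = smallest positive matrix value × 10⁻³ so occasional
zero measurements stay finite while typical values move negligibly. Signs
are fixed by making the largest-magnitude loading of each component
positive. Variables with missing values are dropped rather than imputed.

Trait–carbon correlations are Pearson with a two-tailed t-test. Traits
measured on the same plates as the carbon data (colonization) are
correlated at replicate level ("paired"); traits measured on fungus-only
plates are correlated through isolate means ("averaged").

## Expression screen

- **Filter.** A transcript is "expressed" if its within-condition mean
  raw count reaches the organism threshold (plant 10, fungus 5) in at
  least one condition.
- **Normalization.** Median-of-ratios size factors: per-transcript
  geometric means over samples (transcripts with all-positive counts),
  per-sample factor = median count/geomean ratio. Note the estimator is
  identified only up to a common constant: the median of skewed count
  ratios carries a shared offset (≈3% at dispersion 0.1), and scaling one
  library by c changes all geometric means, so exact scale-equivariance
  holds for factor *ratios*, not individual factors. Normalized counts
  divide by the factors.
- **Screen.** Pearson r between each transcript's normalized counts and
  the per-isolate carbon means. Default pairing is replicate-level
  (every sample carries its isolate's mean C; n = isolates × replicates
  = 27), which uses all count data; condition-mean pairing (n = 9) is
  selectable. The uninoculated control has no carbon value and is always
  excluded. Zero-variance transcripts get r = 0, an `r_undefined` flag,
  and are never selected.
- **Selection.** Top/bottom tails of m = ⌈0.01 n⌉ transcripts
  (24 615 → 247, 12 959 → 130), ties broken by transcript ID order; the
  reported q₀.₉₉/q₀.₀₁ are the smallest selected top and largest selected
  bottom correlation. n < 100 is an error (a percentile smaller than one
  transcript).
- **Significance.** Critical |r| from inverting the t statistic,
  r_crit = t / √(t² + n − 2) at the effective n of the pairing mode
  (e.g. 0.666 at n = 9, α = 0.05), matching published critical-value
  tables.
- **Fold changes and clustering.** Condition means of normalized counts
  divided by the mean over isolate conditions (control excluded from the
  baseline but displayed against it), log₂; a pseudocount of 1 normalized
  count enters numerator and denominator only for genes with a zero
  condition mean. Hierarchical clustering is agglomerative on Euclidean
  distances, average linkage by default (complete linkage by flag),
  deterministic tie-breaks by input order. The "genes of interest" rule is
  generic: flag genes whose focal condition attains the row max or min.
- **Categories.** Case-insensitive keyword lexicon over free-text
  annotations, eight categories (C metabolism, defence/disease
  resistance, growth/cell cycle, host–fungus interaction, signal
  transduction, stress response, transcription regulation, transport); a
  transcript may match several. The default keyword lists are package
  choices and fully configurable.

## Synthetic data generator

The generator emulates the study design: 9 isolates + uninoculated plant
control; 3 transcriptome replicates per condition; 5 isotope/growth
replicates; 3 FLM plates; 24 615 plant and 12 959 fungal transcripts.
Per-isolate true carbon is drawn uniform 0.01–0.15 mg C — the scale
implied by ≈0.4–1.4 mg colonies at 37–42 %C with mixing fractions below
~80%. Isotope samples are generated by *inverting* the mixing model
(ERM placed at the fraction corresponding to the true mg C, per-plate
leaf drawn in 2.0–4.0 atom%, FLM at 1.08) plus Gaussian measurement
noise (SD 0.02 atom% by default); with zero noise the pipeline recovers
the truth to machine precision. Optional outlier injection appends one
ERM value above the upper IQR fence per isolate.

Counts are gamma–Poisson (negative binomial, dispersion 0.1 by default;
Poisson at 0) with log-normal base means (median ≈ 30, wide, so a
realistic fraction falls below the expression filter), per-sample size
factors drawn from 0.7–1.4 and normalized to geometric mean 1, and — in
each organism — 100 planted positive and 100 negative transcripts whose
natural-log mean shifts by ±2.0 per SD of the standardized carbon vector.
Planted transcripts are drawn from base means ≥ 30 so the planted signal
is a property of the response, not of the filter. Fungal transcripts are
zero in control samples (no fungus on those plates).

Growth data are built from configured per-isolate trait means (ranges
matching the observed spread of the study system: biomass 0.1–1.4 mg,
%C 37–42, Hartig depth 4–17 µm, mantle 20–63 µm, growth rate 4–21 %/day,
colonization on a 5% grid between 50 and 95%), with week-2 areas
back-computed from the growth rate so that zero-noise derivation returns
the configured means exactly; root-tip totals are fixed at 20 with
binomial colonization counts under noise.

Three RNG streams (isotope / growth / counts) are spawned from the master
seed, so each family is reproducible independently; identical seeds give
bit-identical tables.

What the generator does *not* emulate: transcript-length or GC effects,
correlated gene modules, batch structure beyond library depth, isotopic
fractionation, or biological covariance between growth traits and the
carbon vector. Passing tests therefore demonstrate that the algorithms
recover the structure they assume, not that real data satisfy those
assumptions.

## Problem sizes in the test suite

Unit tests run on reduced matrices (hundreds of transcripts) with the
same design structure; the screen-recovery and selected-correlation
checks run at the full transcript-set sizes (25 000 / 24 615 + 12 959),
the recovery check over 20 seeds. These sizes were chosen so the whole
suite completes in well under a minute of compute per heavy test while
exercising the full-scale selection arithmetic exactly.

## Known limitations

- The mixing model ignores respired/exuded carbon and isotopic
  fractionation; results are retained-carbon floors.
- The category lexicon is keyword-based; annotation phrasing outside the
  lexicon is counted as uncategorized.
- The compact letter display is a summary of pairwise tests; with
  borderline adjusted p-values near α, letters can change under tiny data
  perturbations, as with any CLD.
- Size factors are reported unrescaled (no geometric-mean renormalization
  of the estimates), matching the standard median-of-ratios definition;
  comparisons to known truth should use factor ratios.
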