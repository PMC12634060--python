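# Methods

This note documents the models and procedures implemented in `firegraze`,
the assumptions behind them, the defaults and why they were chosen, and the
design decisions taken where the underlying methods leave room.

## Data model and conventions

The pipeline consumes three tables: integer palynomorph counts (taxon ×
sample), per-taxon metadata (ecological group, habitat, combustibility
class), and a per-sample chronology (depth in cm, age in calendar years BP
with larger = older, deposition time in yr/cm from a pre-computed age–depth
model). Age–depth modelling itself is out of scope: deposition times are
taken from the chronology as given, never recomputed from adjacent ages.

Taxa fall into four groups: terrestrial pollen, (semi)aquatic pollen,
coprophilous fungal spores, and other palynomorphs. The *terrestrial pollen
sum* excludes aquatics and spores and is the denominator for terrestrial
percentages; non-terrestrial groups are expressed against (terrestrial sum
+ own group sum), the standard convention for taxa excluded from the pollen
sum. Taxa present in the counts but absent from the metadata fail
validation rather than being dropped silently — the habitat assignment is
scientifically load-bearing and must be explicit.

The habitat → combustibility mapping is fixed: beech forest and white oak
coppice 1 (very low), green oak coppice 2, pine forest 3, garrigue/heathland
4, dry grassland 5 (very high). Taxa that cannot be placed in one of the six
habitats (typically riparian/floodplain trees) go to an "other" category
with no class.

## Combustibility index

The per-sample index is the influx-weighted mean of the habitat classes.
The "other" category is excluded from numerator *and* denominator by
default (`include_other_in_denominator=False`): including an unclassed mass
in the denominator would pull the index below the 1–5 scale on which the
classes are defined. The switch exists for sensitivity analysis.

Period boundaries (default 6500, 4000, 1000 cal BP) are half-open,
inclusive on the older side: a sample dated exactly at a boundary belongs
to the *younger* period. This is a documented convention, not a claim
about any particular dataset; the boundary samples are few and the choice
is config-exposed. Period means weight samples equally (not by time span).

Pairwise period comparisons use the two-sided Mann–Whitney U test: exact
enumeration when n₁+n₂ ≤ 12 with no ties, the tie-corrected normal
approximation otherwise (via scipy). Raw p-values at α = 0.05 feed an
insert-and-absorb compact letter display; no multiplicity correction is
applied, mirroring common practice of reporting raw pairwise p-values.

## Diversity metrics

*Rarefied richness* uses the exact hypergeometric expectation
Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated with log-gamma terms so large counts
do not overflow. Samples with fewer than n grains are flagged undefined
(NaN) — richness is never extrapolated. The default base count n is the
minimum terrestrial pollen sum across samples. Richness and evenness are
computed on terrestrial taxa only, matching the base count's definition;
a config switch admits all pollen taxa.

*PIE* is Hurlbert's probability of interspecific encounter with the
without-replacement correction N/(N−1). *DPRI* is the raw OLS residual of
PRI on PIE (mean zero); when PIE is constant the regression is degenerate
and DPRI falls back to centered PRI with a warning. Undefined values
propagate as NaN flags, never as zeros.

Coprophilous-spore richness is the count of spore types present (no
rarefaction — spore tallies are far too low), and spore influx sums the
chosen subset: all types, or only those well documented as herbivory
indicators (`reliable_only`).

## Rate-of-change analysis

The sequence is analysed on moving-window time bins: `bin_size_yr` (default
200) with `n_shifts` (default 5) binnings offset by bin_size/n_shifts. Each
non-empty bin is a working unit whose age is the **bin midpoint**; adjacent
units are therefore one bin apart and the age gap in the RoC denominator
never collapses below the bin size (using raw sample ages instead inflates
RoC wherever two selected samples happen to lie close together across a
bin edge).

Per randomization (default 100) and shift: one sample is drawn per
multi-sample bin; its terrestrial counts are subsampled without replacement
(multivariate hypergeometric) to the global minimum terrestrial count,
removing sampling-intensity bias; unit count vectors are smoothed by
age-weighted averaging with weights 1/(1+|Δage|) inside a ±window/2
neighbourhood (window defaults to the bin size); the chi-squared
dissimilarity between temporally adjacent units, divided by their age gap
and multiplied by `time_standardisation_yr` (default 200), gives
dissimilarity per 200 years. All values are pooled across shifts and
randomizations, then summarized per (unshifted) output bin as the median
with 5%/95% quantiles. The whole procedure is deterministic under the
config seed.

Peak detection fits a LOESS trend (span 0.5) to the median series and flags
units exceeding trend + 1.96 residual standard deviations. The local
regression runs **without robustifying iterations**: on series where most
values are identical the robust weights degenerate (residual MAD = 0) and
the trend interpolates the very peaks it should expose. A small absolute
epsilon guards against flagging float fuzz on flat series.

The kernel, window, per-bin selection rule, pooling, and peak criterion are
one concrete interpretation of the moving-window RoC family of methods;
each is config-exposed and none is claimed to reproduce any reference
implementation bit-for-bit.

## Zonation

CONISS agglomerates depth-adjacent blocks, at each step merging the pair
with the smallest Ward increment (n_a·n_b/(n_a+n_b)·‖mean_a − mean_b‖²),
which equals the increase in total within-block sum of squares. Proportions
are square-root transformed by default (the usual variance-stabilizing
choice for this clustering family; switchable to raw). Significance of the
zone count follows the broken-stick rule: splits, taken in reverse merge
order, are significant while their share of total dispersion exceeds
b_k = (1/n)Σ_{i=k..n} 1/i, counting from the first split to the first
failure. Identical samples (zero total dispersion) give one zone. Zone
boundaries are reported as midpoints between the adjacent sample ages at
each significant split.

## Association statistics

Spearman's rho uses average ranks; the p-value is exact (full permutation
enumeration) for n ≤ 9 without ties and the t-approximation otherwise.
Constant inputs yield an undefined (NaN) flag. Linear fits are reported
only when Shapiro–Wilk accepts residual normality at α = 0.05 (the
`r_squared` field is null exactly when the gate fails); the rank
correlation is always reported. The default battery pairs pollen influx,
richness, spore influx and spore richness. Richness enters as DPRI by
default, switchable to raw PRI; note that when evenness and richness share
a common driver, detrending removes part of that shared signal, so the raw
PRI battery is the right tool for questions about total richness.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Period structure.** Four periods (boundaries 6500/4000/1000 cal BP)
  with per-period habitat profiles: expected influx shares over the six
  classed habitats plus "other". The defaults alternate open–closed–
  closed–open with closed-form mean combustibility 3.10/2.68/2.69/3.33 and
  open-habitat share (grassland + garrigue) 0.40/0.14/0.16/0.40 — an
  open early phase, two forested middle phases nearly indistinguishable
  from each other, and a recent reopening.
- **Counting noise.** Per-sample terrestrial totals are Poisson around 450
  grains (floored at 92, the realistic minimum for a countable sample);
  counts are multinomial over the taxon expansion of the period profile.
  Ages are equally spaced over (8000, 0) cal BP; deposition time is a
  constant 20 yr/cm by default.
- **Rank-abundance structure.** Forest habitats carry 4 taxa under a steep
  geometric rank-abundance curve (one dominant tree); open habitats carry
  10 herb taxa under a shallow curve. Rarefied richness and evenness
  therefore genuinely rise in open phases, as observed in Mediterranean
  sequences.
- **Spike and productivity.** A fixed number of pollen grains is counted
  per sample, so higher pollen productivity appears as fewer marker grains
  encountered: spike counts are Poisson with expectation
  `expected_spike_counted / (1 + influx_openness_gain · openness)`
  (gain default 3), making total pollen influx higher in open phases.
- **Herbivory proxy.** Expected spore influx is
  `spore_base_influx + spore_coupling · openness` (defaults 3 + 25·openness
  grains cm⁻² yr⁻¹) with gamma-Poisson overdispersion (CV 0.6) — low,
  overdispersed tallies whose intensity tracks landscape openness. Setting
  the coupling to zero leaves background spore rain uncorrelated with
  openness. Expected tallies follow from the realized marker ratio, so the
  influx estimator is unbiased for the generative influx.

The ground-truth object records each sample's period, openness, exact
expected combustibility (a closed-form function of the profile) and
expected spore influx, enabling parameter-recovery tests.

What the generator does **not** emulate: taphonomic loss and differential
pollen preservation, pollen-productivity differences among taxa (no
correction factors), age–depth uncertainty, autocorrelated within-period
vegetation drift, and real between-sample variance in habitat composition
(profiles are constant within a period, so per-sample index variance is
pure counting noise — smaller than in real sequences, which makes the
period tests conservative about means but anticonservative about
significance). Passing tests therefore validate the *estimators and
pipeline plumbing*, not the ecological interpretation of any real record.

## Problem sizes and numerical tolerances

Default runs use 80 samples, ~45 taxa, 100 randomizations and 5 shifts for
RoC — a full pipeline run takes a few seconds on one core. Test-suite
oracles use exhaustive enumeration up to n = 8 (rank tests, PIE), 100k-draw
Monte Carlo for rarefaction (3 MC-SE tolerance), brute-force dispersion
recomputation for CONISS up to 6 samples, and 2-standard-error bands for
ground-truth recovery at n = 80. Profile rows must sum to 1 within 1e-9;
proportion vectors entering the chi-squared dissimilarity likewise.

## Known limitations

- The shipped habitat table covers the exemplar taxa of the six habitats;
  real applications must extend the taxon metadata (unmapped taxa fail
  validation by design).
- RoC output bins at the sequence ends pool fewer shifted values and are
  noisier than interior bins.
- Correlation p-values ignore temporal autocorrelation of the series, as
  is standard for these descriptive batteries; they should be read as
  association strength, not formal inference on independent samples.
- The compact letter display uses raw pairwise p-values; with many periods
  a multiplicity-aware display would be preferable.
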