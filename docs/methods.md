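# Methods

This note documents the models implemented in `herbauth`, the
assumptions they rest on, the tunable parameters that matter, and what
the synthetic-data generators do and do not emulate.

## Droplet digital PCR quantification

### Partitioning model

A ddPCR reaction distributes template molecules over ~20,000
nanolitre-scale droplets. Under random partitioning the number of
copies in a droplet is Poisson(λ), so the probability of an empty
(negative) droplet is e^(−λ). Everything rests on the negative
fraction:

    λ̂ = −ln(n_negative / n_total)        [copies per droplet]
    copies per reaction = λ̂ · n_total
    copies per µL      = λ̂ / v,  v = droplet volume

Copies **per reaction** is the primary downstream quantity because it
does not involve the droplet-volume constant `v`, which is an
instrument property the assay cannot verify. `v` defaults to 0.85 nL
(typical of the emulated instrument class) and is configurable; it only
affects copies/µL.

Confidence intervals: a binomial interval on the negative fraction
p̂ = n_neg/n_total, mapped through −ln (upper fraction bound → lower λ
bound and vice versa). The Wilson score interval is the default —
better behaviour than Wald at extreme counts — and the method is
configurable via `statsmodels`. Saturated wells (no negatives) raise an
"above dynamic range" error by default, or are carried as
infinite-λ flagged estimates so that replicate-well pooling still
works. Wells with no positives return λ̂ = 0 with a one-sided interval
and a `not_detected` flag.

Replicate wells are pooled by summing negative and total droplet
counts before re-estimating — i.e. replicates are treated as one large
partition set, which is exact under the Poisson model and gives
strictly narrower intervals than any component well.

### Droplet calling

The caller assigns each droplet a class from its one-dimensional
end-point amplitude. No reference description of the externally
published algorithm used in routine practice is available at parameter
level, so the module fixes a concrete, testable method in the same
behaviour class (density-based 1-D calling):

1. **Density estimate** — a 512-bin histogram smoothed with a Gaussian
   kernel (a binned KDE, O(n + bins)); bandwidth is Silverman's rule on
   the robust scale min(sd, IQR/1.349), multiplied by `bw_adjust = 0.5`
   so that well-separated modes are not merged.
2. **Valley thresholding** — candidate thresholds are the density
   minima between adjacent detected peaks (peak prominence ≥ 2% of the
   tallest mode). A candidate is accepted only if the valley density is
   ≤ 50% of the smaller flanking side's maximum (sampling noise on a
   single population produces shallow wiggles; genuine two-population
   valleys are nearly empty). Among accepted valleys the one minimising
   pooled within-class variance wins — with sparse minority clusters,
   several near-empty valleys can exist and the variance criterion
   picks the one that actually separates the populations.
3. **Minority-cluster rescue** — the routine ddPCR regime has a
   positive cluster far too small (≪ 2% of droplets) to raise a density
   mode. If no valley is accepted, droplets beyond median ±
   `outlier_k`·MAD (default 7 MADs ≈ 4.7 σ) of the dominant population
   are examined: at least `min_minority = 3` such droplets constitute
   the opposite class (above the population → positives; below → the
   dominant population itself is positive). The 3-droplet floor keeps
   the blank false-positive rate at zero — for a pure Gaussian
   population of 20,000 droplets the chance of three simultaneous
   4.7 σ outliers is negligible — while three droplets is also the
   quantification floor downstream.
4. **Rain handling** — droplets between the robust class centres
   (median + 5·MAD of the negatives, median − 5·MAD of the positives)
   are reassigned to the nearer centre in robust z-distance. Ties and
   droplets exactly at the threshold go to the negative class: the
   conservative direction when a positive call supports a
   contamination claim.

Unimodal wells are flagged and called single-population (all-negative
if the mode lies in the configured `negative_band`, default
0–5000 amplitude units); constant-amplitude wells additionally get a
`constant_amplitude` flag. Calling refuses to run below
`min_droplets = 100` (density estimation on fewer droplets is
meaningless).

Measured performance (seeded simulations, also recomputed by
`scripts/acceptance.py`): misclassification < 0.1% at 10-σ population
separation and < 0.25% at 6 σ (the theoretical overlap of two
Gaussians at 6 σ is already ≈ 0.135%); zero false-positive wells at
zero template; exact agreement with an exhaustive
variance-minimising threshold oracle on wells of ≤ 200 droplets whose
realised cluster separation exceeds 6 σ.

The test oracle (`threshold_oracle`) scans all midpoints between
consecutive sorted unique amplitudes and returns the split minimising
the pooled sum of squared deviations. It is brute force, independent of
the caller's code path, and used only in tests.

## DNA accounting (purity screen)

If all of a sample's DNA belongs to the declared species, the number of
assay-target copies in the reaction is predictable from the DNA mass:

    expected copies = mass_ng · 1000 / genome_size_1C_pg
                      × target_copies_per_haploid

The fluorometric mass estimate comes from four replicate readings (two
independent dilutions measured twice), averaged; their standard
deviation propagates linearly into an expected-copy interval evaluated
at mass mean ± k·sd, k = 2 by default (exposed in config; the lower
bound is clipped at zero). The published description of this screen
defers the exact range construction to its own reference; the linear
mean ± k·sd propagation implemented here is the simplest defensible
choice and is documented as this package's own.

A ddPCR measurement below the interval flags foreign DNA (or heavy
degradation — the screen cannot distinguish the two); the
measured/expected ratio estimates the declared species' share of the
DNA mass. On synthetic cohorts with a foreign-DNA fraction f and equal
genome sizes, the mean ratio converges to 1 − f; with fluorometry at
5% CV and k = 2, ≥ 93% of genuinely pure samples are flagged `within`
(measured ≈ 97% in the seeded studies).

## Adulterant copy percentage

ddPCR counts *target sequences*. Species differ in targets per genome,
so copies are corrected to genome equivalents before comparison:

    GE    = copies_per_reaction / target_copies_per_haploid
    copy% = 100 · GE_adulterant / (GE_adulterant + GE_ingredient)

Ploidy deliberately does **not** enter the per-haploid convention: a
diploid cell carries two haploid genomes, but per-haploid GE already
counts genome copies, which is the mass-relevant unit. The published
phrase describing this correction bundles ploidy and target count into
one step; this module separates them and exposes a `units="per_cell"`
switch that additionally divides by ploidy, for workflows that express
copies per cell. The convention only changes copy% when the two
species' ploidies differ.

Mass percentage multiplies GE by the 1C genome mass (pg) per species
and renormalises — directly comparable to gravimetric (m/m) mixture
design **when DNA content per unit tissue mass is similar between the
species**, which is an assumption, not a fact, for real leaf material.

Results supported by fewer than 3 positive adulterant droplets are
reported as trace / not quantifiable rather than as a percentage; zero
positive droplets with a detected ingredient report copy% = 0 with an
explicit flag, and zero on both assays is a distinct not-detected
outcome.

## Read-table classification

Input: one row per (taxon, kingdom, read count) per sample, the output
shape of a read-attribution pipeline. Processing:

1. **Kingdom filter** — restrict to Plantae (idempotent; an empty
   result is allowed and logged).
2. **Read percentages** — default denominator is the *retained*
   (post-filter) total, so the percentages sum to 100 and are
   reproducible from the table itself. A mode using a caller-supplied
   pre-filter total exists because published percentage columns are
   often computed against a larger, unlisted denominator that cannot be
   reconstructed from the printed rows; the packaged fixture's listed
   rows sum to 13,270 reads and percentages here are computed against
   that sum.
3. **Classes** — a shipped taxon → class map (ingredient / adulterant /
   contaminant / noise) reflecting the published oregano scheme:
   adulterants are bulking species reported in the fraud literature,
   contaminants are field weeds and co-processed foodstuffs, noise is
   rare or geographically implausible attributions. Lookup is
   case/whitespace-normalised; entries ending in "spp." act as genus
   wildcards, and unmapped taxa default to noise with a logged flag.
   The map also carries alias rows for reported-name variants
   (abbreviations like "O. majorana", slash-composites like
   "Salvia/perilla spp.") as attribution pipelines emit them.
4. **Actions** — an adulterant with ≥ 1 read always goes to ddPCR
   confirmation (sensitivity is the point); a contaminant only when its
   read share is **strictly** above the threshold (default 5%); 
   ingredients and noise trigger nothing.

## Concordance

For each species, the paired (copy%, read%) observations across
samples are summarised by the Pearson correlation and the OLS
regression **of read% on copy%** — copy% is the reference measurement,
read% the proxy under evaluation. For simple linear regression the
slope's t-test p-value and the correlation p-value coincide; one
two-sided p-value is reported. Degenerate inputs are explicit: constant
read% yields slope 0 with r undefined (NaN, flagged); constant copy%
leaves the slope undefined.

Reporting-bias direction uses a sign test on read% − copy% (ties
dropped, default α = 0.05): `over` when reads significantly exceed
copies, `under` for the reverse.

Statistics are computed on the linear scale. The scatter export draws
log–log axes for readability only; zeros are drawn at half the
smallest positive value on that axis (annotated in the title), while
the accompanying tidy CSV always carries the raw values.

The per-sample survey table behind the published per-species summary
statistics is not distributable with this package, so the
`study_table5` recomputation study reports an explicit skipped status
unless a user supplies that table as CSV
(sample, species, read_pct, copy_pct), optionally with a reference
summary (species, n, pearson_r, slope) to compare against at printed
precision. Concordance correctness is instead validated on synthetic
cohorts with injected bias (below).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical mechanisms the analysis
relies on, under a fixed integer seed (bit-reproducible):

* **Droplet wells** — Poisson occupancy; Gaussian amplitude
  populations (defaults: negative 2000 ± 200, positive 8000 ± 200,
  20,000 droplets — free knobs, since no amplitude distributions are
  published for the emulated assays); an optional `rain_fraction` of
  droplets drawn uniformly between the population means while keeping
  their occupancy-derived ground-truth label (rain originates from
  partly amplified positives; a label-preserving model suffices for
  caller testing).
* **Fluorometry** — four lognormal replicates parameterised so the
  replicate expectation equals the true concentration at the stated
  CV (concentrations are positive and fluorometric error is
  multiplicative); a zero-truncated normal is available as an option.
* **Mixtures** — mass fractions × total template mass, converted to
  per-species target copies through 1C genome mass; deterministic, the
  ground truth for recovery studies. 18 ng per reaction is the default
  template input, matching the emulated PCR workflow.
* **Read tables** — expected shares ∝ abundance × per-species bias;
  stochastic per-species dropout; multinomial read sampling; then a
  row-stochastic misattribution matrix re-labels reads (defaults:
  identity plus a small leak from the declared ingredient to close
  relatives in the mint tribe, emulating cross-talk between
  phylogenetically adjacent taxa). The default cohort regime
  over-reports bindweed 25×, under-reports the woody-leaved
  adulterants (olive 0.3×, myrtle 0.1×, cistus 0.5×) and drops sumac
  entirely — the qualitative pattern seen in real quality-control
  material.

Not emulated: raw sequencing reads, chimera formation, alignment or
attribution itself (noise is modelled at the count level); DNA
degradation; extraction-efficiency differences between species
(acknowledged confounders of mass interpretation); droplet-volume
dispersion; two-channel joint (2-D) droplet clustering — duplex assays
are processed channel by channel. Passing tests therefore demonstrate
correctness of the *statistical machinery* under its stated
assumptions, not robustness to every artefact of real herb extracts.

The packaged assay metadata table (`data/assays_synthetic.tsv`) carries
**synthetic, representative** 1C genome masses of plausible magnitude —
the per-species constants used in the original laboratory work are not
published — and real analyses should substitute curated C-values for
their actual assays.

## Validation studies and problem sizes

`herbauth.studies` packages the seeded Monte-Carlo experiments, with
all pass/fail tolerances declared once in `studies.TOLERANCES`:

* **λ recovery** — full simulate → call → estimate chain across
  λ ∈ {0.05 … 1.5} at 20,000 droplets; relative bias < 1% and 95% CI
  coverage in (93.5%, 96.5%). A finite-replicate coverage estimate
  carries binomial noise of √(0.95·0.05/reps), so the study's gate
  allows 3 σ of it on top of the band; the acceptance test instead
  verifies true coverage exactly by summing binomial probabilities
  over all negative-count outcomes, which removes Monte-Carlo noise
  altogether. λ = 0 rows check a zero false-positive rate.
* **Mixture recovery** — 1/2/5% (m/m) adulterant spikes, equal genome
  sizes, 100 replicates: mean copy% within (0.7–1.3), (1.4–2.6),
  (3.5–6.5) respectively, mean mass% of the 5% spike within (4–6);
  a parallel biased read simulator (0.25× recovery) must leave read%
  below copy% in every replicate — the central contrast between the
  two measurement principles.
* **Concordance recovery** — 50-sample cohorts with an injected
  read-bias multiplier b: fitted slope ≈ b, r > 0.9, sign test
  recovers the direction for both the under-reporting (b = 0.3) and
  over-reporting (b = 20) regimes.

The default test suite runs these at reduced replicate counts chosen to
keep the full suite under a minute while leaving comfortable
statistical margins; `scripts/acceptance.py` re-runs them at the sizes
quoted above (500 Monte-Carlo wells per λ, 100 mixture replicates,
400,000 droplets of caller evaluation) in a few seconds.

## Known limitations

* The caller is a fixed, documented algorithm in the density-based
  family; equivalence with any specific published caller is not
  claimed — only the Poisson layer above the calls is
  instrument-agnostic.
* Cohort-level survey statistics (market failure rates, per-species
  detection frequencies) depend on physical samples and are out of
  scope by design; nothing in this package estimates them.
* copy% → mass% conversion inherits all uncertainty in C-values and in
  the equal-DNA-yield assumption; treat mass% as indicative, not
  metrological.
* The accounting screen cannot separate adulteration from severe DNA
  degradation; both depress measured copies.
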