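# Methods

`hetsilence` reimplements, as a tested pipeline on synthetic data, the
statistical analyses used to establish that polyphosphate (polyP) directs
the nucleoid-associated protein Hfq to AT-rich mobile genetic elements
(MGEs) in *E. coli*: a Bayesian Poisson model for dilution-plating
survival assays, a robust-z / control-subtraction procedure for ChIP
occupancy, condition-dependent peak classification with permutation-based
enrichment, expression-shift statistics, per-cell nucleoid statistics and
FRAP recovery fitting.  This note records the models, the defaults and
why, and what the synthetic data does and does not emulate.

## Survival model

Colony counts from a 10-fold dilution series are Poisson:

    untreated_i ~ Poisson(10^(υ_i + φ_i))
    treated_i   ~ Poisson(10^(υ_i + δ + φ_i))

with υ_i the unknown log10 CFU/ml of replicate *i*, δ a shared log10
survival effect per genotype-stress combination, and φ_i the known log10
dilution (φ = −6 means a 10^6-fold dilution — the sign convention used in
all I/O).  Priors are Uniform(0, 15) on υ and Uniform(−10, 10) on δ; the
likelihood is evaluated exactly, including Poisson mass at zero counts,
with no continuity corrections.  One model is fit per genotype-stress
combination; mixing genotypes in one fit is an error.

Sampling uses the emcee ensemble sampler with differential-evolution
moves (80% `DEMove`, 20% `DESnookerMove`); on this narrow, correlated
(υ, δ) posterior the DE moves cut the autocorrelation time from ~30 to
~9 steps relative to the default stretch move.  Defaults: 48 walkers,
1000 warm-up steps, 2000 retained steps (96,000 draws).  Convergence is
assessed with the rank-normalized split-Rhat (arviz), treating walkers as
chains; the threshold is 1.01.  Walkers in an ensemble sampler are not
independent chains, so this Rhat is a diagnostic, not a guarantee; fits
that exceed the threshold are flagged (`converged=False`) and warn rather
than fail.

Credible intervals are equal-tailed quantile intervals (not HPD): they
are order-statistic testable and match common practice.  Two significance
conventions are provided, as both appear in this kind of reporting:
non-overlapping 95% credible intervals, and the posterior probability of
a difference in the observed direction (`prob_direction`, tiers * > 0.95,
*** > 0.999).  The log-additive double-mutant prediction is computed
samplewise as δ_a + δ_b − δ_wt over paired random draws.  Mutation rate
is the ratio of selective-plate CFU/ml to total CFU/ml.

The test suite checks the sampler against an independent 2-D
grid-integration oracle (brute-force numerical posterior on a fine
(υ, δ) grid) on 1- and 2-replicate designs, with agreement required to
0.05 log10 units, and checks 95% CI coverage over 100 simulated
3-replicate datasets.

## ChIP occupancy

ChIP-vs-input log2 ratio tracks (their estimation is out of scope; tracks
are inputs) are converted to robust z-scores

    z = (x − median(x)) / (1.4826 · MAD(x)),

with the Gaussian-consistency constant 1.4826 made explicit and
configurable in the module constant.  The untagged-strain negative
control is subtracted per bin as `max(tagged − max(untagged, 0), 0)`:
the control is clamped at zero first so its noise can never add apparent
occupancy, and the result is clamped at zero so only positive occupancy
remains.

Bins are partitioned three ways — background (no EPOD), EPODs without
MGEs, EPODs covering MGEs — by the bin midpoint, and per-class occupancy
is compared between conditions with a two-sided Wilcoxon rank-sum test on
bin-level values, Benjamini-Hochberg corrected across the three classes
(the smallest defensible family; configurable by calling the test per
family of choice).  Bin-level observations match a per-position average
occupancy but ignore spatial autocorrelation between neighbouring bins,
so the P values are anti-conservative on real, correlated data; on the
synthetic data the planted effects are so large that this does not affect
the qualitative conclusions.

## Peaks and enrichment

No published peak-calling rule exists for this analysis, so a simple
threshold rule is used: maximal runs of bins with z ≥ 2, gaps ≤ 100 bp
merged, merged runs < 200 bp discarded (all configurable).  The pipeline
applies the rule to a 100-bp rolling-mean-smoothed occupancy track: at
1-bp bins with unit noise, ~1.4% of raw background bins cross z = 2 and
the merge rule would chain those crossings into meaningless genome-wide
runs; smoothing restores the intended semantics of "a sustained region
above threshold".

Peaks from the two conditions are merged into union intervals; presence
in a condition means reciprocal overlap ≥ 0.5 with a peak called in that
condition.  Classes partition the result: ppk-dependent (wild type only),
ppk-independent (both), secondary (ppk deletion only).

Class-level enrichment of a non-negative smoothed metric (500-bp rolling
means of AT content and H-NS binding; motif occurrence) is
log2(class mean / genome mean), with −inf when the class mean is zero and
NaN for an empty class.  Permutation P values re-place the class's
intervals (widths preserved, spacing not) uniformly at random on the
genome, with the two-sided add-one convention
P = (1 + #{|null − genome mean| ≥ |obs − genome mean|}) / (n_perm + 1),
n_perm ≥ 999.  Two-sided because both enrichment and depletion are
reported.  The permutation P is validated against exhaustive enumeration
on a 10-bin toy genome.

Motif enrichment compares each class's fraction of hit-bearing peaks
against the pooled fraction of the *other* classes (the ±inf cases imply
class-vs-class rates); a genome-background denominator is available via
`denominator="genome"`.  Motif hits are either supplied externally or
produced by the bundled exact IUPAC consensus scanner (de novo motif
discovery is out of scope).

## Expression statistics

The MGE-vs-other shift test is a two-sided Mann-Whitney U on per-gene
log2 fold changes (exact null for small samples without ties, normal
approximation with tie correction otherwise).  Genotype-genotype
concordance is a pairwise Spearman matrix per gene category; constant
columns yield NaN rather than an error.  Differential-expression
estimation itself is out of scope; tables are inputs.

## Imaging statistics

Chromosome occupancy per cell is DAPI area / cell area, in [0, 1] by
validation.  Genotype means get percentile bootstrap CIs of the mean
(10,000 resamples by default, seeded; percentile rather than BCa because
nothing stated requires more) and two-sided Wilcoxon rank-sum P values
against wild type.

FRAP traces are normalized by dividing the bleached-droplet ROI by an
unbleached reference droplet (correcting full-field photobleaching), then
rescaled so the pre-bleach mean is 1; division (not detrending) was
chosen as the simplest reading of reference normalization, and the
normalization is invariant to rescaling either channel.  The post-bleach
points are fit by least squares to the one-phase association curve
Y(t) = Y0 + (Plateau − Y0)(1 − e^(−kt)) with t from the bleach step, and
t1/2 = ln 2 / k exactly.  Initialization: Y0 from the first post-bleach
point, Plateau from the last, k from a log-linear regression of the
remaining fraction.  A flat post-bleach trace makes k unidentifiable and
raises `FrapFitError`.  Half-bleach geometry is not modelled; the fit
operates on the 1-D intensity series.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the analyses assume, so every
downstream estimate is a parameter-recovery experiment:

- **Genome**: 200 kb (a scale chosen so 1-bp tracks stay cheap), 16 EPODs
  of 1–2.5 kb placed by rejection sampling ≥ 1 kb apart, so EPODs cover
  ~14% of the genome — matching the reported 10–15% EPOD coverage of the
  *E. coli* chromosome.  40% of EPODs are flagged MGE and drawn with
  per-base P(A or T) = 0.65 against a 0.50 background, mirroring the
  AT-richness of horizontally acquired DNA.  Six GC-rich (AT 0.35)
  800-bp "secondary" sites sit outside EPODs.  The circular chromosome is
  treated as linear for interval placement.
- **Affinity**: true Hfq enrichment is +6 robust-z-like units at MGE
  EPODs in wild type only (the polyP-dependent binding), +6 at non-MGE
  EPODs in both conditions, and +4 at secondary sites in the ppk deletion
  only.  No effect sizes are published for the occupancy loss; these
  free parameters were fixed once so that all three peak classes clear
  the z ≥ 2 calling threshold after smoothing while keeping the secondary
  elevation the smallest.  The H-NS track is 0.5 baseline + 1.0 inside
  MGE EPODs.
- **Tracks**: tagged = affinity + Gaussian noise (sd 1); untagged = noise
  only.  Real ChIP noise is heteroscedastic and autocorrelated; this
  generator is homoscedastic and independent per bin, which is exactly
  why bin-level Wilcoxon tests behave well here and must be read
  cautiously on real data.
- **Counts, tables, cells, traces**: Poisson counts share the survival
  model's exponent structure exactly; expression tables have a per-gene
  latent effect (sd 1) shared across contrasts — the source of high
  genotype-genotype rank correlations — plus contrast noise (sd 0.5) and
  a +1 log2 MGE shift in the ppk/hfq deletion contrasts; cell occupancy
  ratios are clipped Gaussians; FRAP traces are the one-phase association
  curve times multiplicative Gaussian noise (CV 2%) with a constant
  reference channel.

All generators are bit-reproducible for a fixed seed, and the pipeline is
byte-deterministic under a fixed configuration (config hash recorded in
the run manifest).

Passing tests on these data demonstrate the *statistical machinery* —
estimators recover planted parameters, conventions match their
definitions, null configurations stay null.  They do not demonstrate
anything about read processing, peak calling on realistic noise spectra,
or the biological effect sizes themselves.

## Numerical choices and degenerate inputs

- Robust z requires ≥ 2 distinct values and errors on MAD = 0.
- Rolling means use truncated windows at the edges (no padding); even
  windows are centred with the extra element on the left.
- Wilcoxon/Mann-Whitney use scipy's automatic exact/asymptotic switch;
  all-tied comparisons report P = 1.
- Expected plating counts above 10^9 raise, with advice to dilute
  further, rather than risking Poisson overflow.
- Sampler seeds, permutation seeds and bootstrap seeds are all explicit;
  `PipelineConfig.reseed(base)` derives every stage seed from one
  integer.

## Problem sizes

Default sizes (200-kb genome at 1-bp bins, 96,000 posterior draws per
survival fit, 999 permutations, 100-dataset coverage simulations at a
reduced 24-walker sampler setting) were chosen so the full test suite and
the end-to-end study each complete in minutes on a single core while
leaving every assertion comfortably powered.

## Known limitations

- Walker-based Rhat (see above) and bin-level autocorrelation (see
  above) are the two places where the statistics are knowingly
  optimistic about their own assumptions.
- The permutation null places intervals independently, so permuted
  intervals may overlap each other; with few, narrow intervals on a long
  genome the effect is negligible.
- `prob_direction` defines the observed direction from posterior means;
  for posteriors centred exactly on each other the reported probability
  is ~0.5 by symmetry, not a meaningful direction call.
- The consensus motif scanner is exact-match IUPAC only; no PWM scoring.
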