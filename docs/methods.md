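# Methods

## The copying model

Painting treats each recipient haploid as an imperfect mosaic of donor
haplotypes (Li & Stephens).  Hidden states are donor haploids; between
adjacent sites at genetic distance `d` Morgans a recombination event
occurs with probability `1 − exp(−Ne·d)`, after which the new donor is
drawn from the prior copying probabilities π (so a "switch" may return
to the same donor; chunk boundaries are only counted where the donor
identity actually changes).  Emissions allow miscopying: the donor
allele is observed with probability `1 − θ`, flipped with probability
`θ`.  Missing genotypes are not accepted at painting time — synthetic
data are complete and real data must be pre-filtered — which avoids an
emission-model ambiguity.

Forward–backward is computed with per-site rescaling (contract:
posterior accuracy to 1e−9 against exhaustive path enumeration on toys,
which the test suite checks on 20-site/2-donor and 8-site/5-donor
problems; 5²⁰ paths makes a literal 20-site/5-donor enumeration
impossible).  Expected chunk counts use the transition-level identity
E[chunk starts of donor j at site t] = (1−a)·π_j·(1−α_{t−1}(j))·e_t(j)·β_t(j)/c_t;
expected copied lengths weight posteriors by half-interval cM site
weights and therefore sum exactly to the chromosome's site span.
Sampled mosaics come from stochastic traceback of the scaled forward
values.

`Ne` and `θ` are estimated by EM (default 10 steps) on a subset of
recipients painted against all other individuals' haploids: the E step
accumulates expected recombination events and miscopies, the M step
maximises the expected complete-data log-likelihood — closed form for
θ, a bounded 1-D numeric solve for Ne (so the likelihood is
nondecreasing by construction).  Per-chromosome estimates are combined
by a cM-weighted average.  Defaults Ne = 190.82, θ = 0.00045 are
data-scale values retained only as plausible starting points; every
analysis here re-estimates them.

Diploid individuals contribute two independently painted haploids.  A
recipient is rejected if it is physically a row of the donor panel
(self-painting); an identical *copy* of a donor is legal, and is
painted almost entirely from its twin.

## Synthetic data

Source panels follow the Balding–Nichols model: ancestral frequencies
Uniform(0.05, 0.95), population frequencies Beta-distributed with drift
F.  The default F = 0.15 yields pairwise Hudson FST ≈ 0.157, the scale
of Eurasian–African differentiation, so painting contrasts and
weighted-LD weights are realistic.  LD within a panel comes from
building each haplotype as a mosaic of a small founder set (default 10
founders, mean segment 0.5 cM), rather than from coalescent simulation:
adequate for painting and curve behaviour, with no external simulator
dependency.  Per-site founder allele counts are constrained to
`round(n_founders · p)` so the founder pool adds no drift beyond the
Balding–Nichols layer (otherwise panel FST would be inflated by
~1/n_founders).

Admixed haploids are ancestry mosaics: switch points fall as a Poisson
process at rate n per Morgan (n = generations since the pulse), each
segment's ancestry is drawn from the pulse proportions, and the
segment's sequence is copied from one random haplotype of that source
panel.  Adjacent same-ancestry segments are kept separate — they copy
from different donors, like recombination among same-ancestry lineages
— so the switch-point count per haploid is exactly Poisson(n × Morgans)
and interior inter-switch distances are exactly Exp(n).  A second, more
recent pulse overlays the older mosaic: its Poisson segments replace
the underlying ancestry with probability equal to the pulse's total
proportion, which produces the two-exponential ancestry-LD decay that
two-date fits target.  Truth tracts (haploid, chromosome, start, end,
source) tile each chromosome exactly and are recorded for every
haploid.  Coordinates are 0-based, half-open.

Reference/donor panels in the study scenarios are *held-out halves* of
the source populations, disjoint from the haplotypes the admixed
genomes copy from.  Real reference panels are contemporaries of an
admixed population, not its literal ancestors; reusing the ancestor
haplotypes as references overstates shared haplotype structure and
measurably biases weighted-LD dates.

What the generator does **not** emulate: mutation after admixture,
selection, phasing error, genotyping error, background (coalescent)
LD beyond the founder-mosaic scale, and continuous or multi-wave
migration.  Passing tests therefore demonstrate correct recovery of the
generative model's signal at realistic differentiation and sample
sizes, not robustness to every artefact of real array data.

## Study scenarios and problem sizes

Frozen in `haplomix.scenarios` and shared by the examples, the test
suite and `scripts/acceptance.py`:

- **single pulse**: 3 sources (A, B, C), 5,000 SNPs on four 25 cM
  chromosomes (a 100 cM genome), 60 haploids per source (30 ancestor /
  30 reference), target 20 diploids mixed 30% A into B ten generations
  ago, C an unadmixed outgroup donor.
- **weighted LD**: two sources, reference panels of 50 haploids,
  5,000 SNPs, 100 cM, 50 diploid targets.
- **two pulse**: six 50 cM chromosomes (realistic human chromosome
  lengths — resolving a ~5-generation decay, scale 20 cM, needs
  chromosomes spanning several decay lengths), 9,000 SNPs, an old pulse
  (A into B, 40 generations) and a recent pulse (C, 30%, 5 generations),
  40 diploid targets.
- **no admixture**: the target is a fresh, unadmixed 20-diploid sample
  of source B.

These sizes keep a full pipeline replicate in the tens of seconds while
leaving every inference well-posed.

## Coancestry curves and date fitting

For every pair of surrogate groups, chunk pairs at binned
midpoint-to-midpoint distance g (bins 0.1 cM) are tabulated within and
between the painting samples (default 10) of each recipient haploid,
and divided by the independence expectation `tot(g)·f_a·f_b` built from
the pooled genome-wide chunk shares.  Composition heterogeneity between
recipients appears as a flat offset that the per-curve intercept
absorbs; normalising per individual instead would subtract the signal
itself at desk scale, because a 100 cM genome holds only ~10 tracts of
a 10-generation event.

Pairing is per haploid by default (`phasing_mode="haploid"`); pooling
across an individual's two haploids (`"pooled"`) makes curves robust to
phasing switch errors at the cost of adding pure composition noise, and
is the right choice for statistically phased real data.

Dates are the shared rate(s) λ of one or two exponentials fitted to all
curves jointly (grid search over [1, 400] generations plus local
refinement, per-curve weighted linear coefficients).  Two numerical
safeguards matter at desk scale:

- per-curve intercepts are constrained to [0.7, 1.3] — these are ratio
  curves with asymptote near 1, and an unconstrained fit can explain a
  noisy near-linear curve equally well by a very slow exponential on a
  large negative intercept, making λ unidentifiable;
- after an initial equal-weight fit, curves are reweighted by inverse
  residual variance and λ refit (two-pass GLS), so flat uninformative
  curves do not dilute the rate estimate.

Fits use bins from min_g = 1 cM (painting resolution is ~0.5 cM chunks)
to ~55% of the chromosome length: beyond that every chunk pair has its
ends near opposite chromosome ends, where painting posteriors are
diffuse, and the curve tail decays anomalously fast.

The **null procedure** rebuilds curves from chunk pairs of *different*
individuals (each individual paired with its neighbour), which keeps
the marginal chunk distribution but destroys within-genome admixture
LD; observed curves are divided bin-wise by the null before the final
date fit.  This is an approximation to the original software's
permutation-based background.

The per-date coefficient matrix over surrogate pairs is symmetrised and
eigendecomposed; under a single two-source event it is approximately
rank one with structure α(1−α)(β₁−β₂)(β₁−β₂)ᵀ.  FQ1 and FQ2 are the
variance fractions of the one and two leading components (λ₁²/Σλᵢ²
form).  The admixture proportion is estimated by a 1-D grid search over
α ∈ (0, 0.5]: given α, the implied sources are β ± scaled leading
eigenvector; they are clipped to the simplex and the α minimising the
copying-vector reconstruction error (plus clipped mass) wins.  The
minor source is reported first; α ≤ 0.5 by convention.  The mixture
coefficients are re-estimated as α·source1 + (1−α)·source2 and the
fit/decomposition loop runs for five iterations.

**Uncertainty.**  Dates are bootstrapped 100 times.  The empirical
p-value uses genome-block-only resampling (is there a dated signal
anywhere) and equals the fraction of bootstrap dates at the rate-search
bounds (≤1 or ≥400 generations); the 95% CI uses joint resampling of
genome blocks and recipient haploids (how well located the date is).
With only 4–6 toy chromosomes, whole-chromosome resampling is too
coarse — a resample can silently drop half the genome — so chromosomes
are subdivided into at least 8 equal-cM blocks, the desk-scale analogue
of the 22-chromosome bootstrap.

**Classification** (in order): p ≥ 0.05 → *no admixture*; more than 25%
of bootstrap dates at the search bounds, or a 95% interval more than
five times the point date → *uncertain*; M > 0.35 (the largest
additional per-curve R² gained by a second date) → *multiple dates*;
FQ2 − FQ1 ≥ 0.35 → *one date, multiway*; otherwise *one date*.  All
thresholds are configuration, not code.

Restricted-surrogate reruns zero masked groups out of the mixture model
and the decomposition (their composition weight is exactly 0); region
post-rules are data-driven configuration — collapse two dates to the
older one (the West African convention) or flag the event as
standardised by the null individual (the Southern African / Afroasiatic
convention).

## Weighted-LD dating

The two-reference statistic for a SNP pair is the sample covariance of
target alleles times `w(s₁)·w(s₂)` with `w(s)` the reference
allele-frequency difference; one-reference mode substitutes the target
for the second reference and removes the self-correlation bias by
sample splitting (one half of the target supplies the weight
frequencies, the other the covariances), since the original software's
internal correction is unpublished.  Curves are binned at 0.05 cM from
min_d to max_d (default 0.5–30 cM, truncated to ~55% of the chromosome
length in the desk scenarios); min_d is either the data-driven shared
short-range-LD threshold — the end of the initial contiguous run of
distance bins where the target×reference LD product is more than two
jackknife SEs from zero — or the conventional 0.5 cM override.

Exponential fits (`Σ C_k exp(−n_k d) + c`, rates bounded to [0.5, 400]
generations) use weighted least squares with multi-start rates.
Jackknife uncertainty comes from delete-one units (whole chromosomes,
subdivided to at least 8 blocks when there are few); model order grows
while every amplitude stays more than two jackknife SEs from zero —
the published multi-wave acceptance rule is not printed, so this
significance rule stands in for it.  Dates are reported in generations;
calendar conversion is `D = 1950 − (n+1)·g` with g = 29 years, and
intervals quoted as 1 SE are scaled by 1.96.

## Other estimators

- Hudson FST: per-site numerator `(p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
  p₂(1−p₂)/(n₂−1)`, denominator `p₁(1−p₂) + p₂(1−p₁)`, ratio of
  site averages, block-jackknife SE; `n = inf` gives the
  infinite-sample limit.
- f3 is computed without a frequency-bias correction on the target (the
  reference implementation's corrections are not printed); the
  admixture call in downstream use is jackknife Z < −5, reading the
  published "f3 < −5" rule as a Z-score since the raw statistic is
  scale-dependent.
- LD pruning is greedy left-to-right within a bp-anchored sliding
  window; monomorphic SNPs (undefined r²) never trigger removals.
- PI_HAT uses method-of-moments IBD from IBS counts and allele
  frequencies (no small-sample corrections); one member of each pair
  above threshold is removed at random, seeded.  The estimate assumes a
  homogeneous outbred cohort — admixture or a small founder pool
  legitimately inflate it.

## Determinism

Every simulation, painting, bootstrap and removal decision flows from
explicit integer seeds; identical configuration and seed give
bit-identical panels, events and output files.  Output directories get
a manifest (package version, seed, configuration echo) sufficient to
re-run them.

## Known limitations

- Coancestry dates at desk scale carry a modest bias (point estimates
  for a 10-generation event typically land between 7 and 16) from
  painting resolution and chromosome-end effects; bootstrap CIs are
  calibrated to cover the truth, and real-genome scale (thousands of
  cM) shrinks the bias.
- Two-date fits are weakly identified in the young rate at a ~300 cM
  genome: the profile residual over the young rate is nearly flat, so
  point estimates of a 5-generation pulse scatter widely (roughly
  2.5–10) even though the event is reliably *detected* (M far above
  0.35) and the old rate is recovered within ~±30%.  This is an
  information limit of the painting/curve stage, not of the tract
  process (truth tracts would date the pulse to within a few percent);
  genome size is the remedy.
- The null procedure and the one-reference bias handling are documented
  approximations to unpublished internals of the original software.
- Pair tabulation is quadratic per haploid (vectorised, no FFT);
  adequate below ~10⁴ chunks per haploid, not for biobank scale.
- The mixture model and decomposition describe sources as combinations
  of *sampled* surrogates; an unsampled true source is expressed as its
  closest sampled relatives, never detected as missing.
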