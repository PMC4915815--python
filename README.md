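# haplomix

Haplotype-painting admixture analysis for phased genotype panels: a
reusable, tested re-implementation of the chromosome-painting /
coancestry-curve approach to characterising historical admixture, of the
kind used to map gene-flow between human population groups.

## Who it is for

Population geneticists who have phased biallelic haplotypes, a
recombination map, and population labels, and who want to ask: *is this
group admixed, when did the mixing happen, what proportion arrived, and
which sampled groups best describe the sources?* — plus everyone who
wants a fully synthetic, truth-known testbed for those methods.

## What it implements

- **Chromosome painting** under the Li & Stephens copying model: each
  recipient haploid is an imperfect mosaic of donor haplotypes, a hidden
  Markov chain with switch probability `1 − exp(−Ne·d)` between sites at
  genetic distance `d` Morgans and miscopy probability `θ`.
  Forward–backward gives expected chunk counts/lengths per donor;
  stochastic traceback gives sampled chunk mosaics; `Ne` and `θ` are
  estimated by EM.
- **Copying-vector statistics**: per-group copying vectors, total
  variation distance `TVD = ½ Σᵢ |aᵢ − bᵢ|`, and a non-negative
  least-squares mixture model `fᵏ = Σₗ βₗ fˡ` (β ≥ 0, Σβ = 1,
  coefficients < 0.001 dropped and rescaled).
- **Allele-frequency statistics**: Hudson's FST (ratio of averages,
  block-jackknife SE), the three-population test
  `f3(X; A, B) = E[(x−a)(x−b)]` with a 500-SNP block jackknife, LD
  pruning (r² > 0.2 in 50 kb windows) and PI_HAT relatedness filtering
  (`PI_HAT = P(IBD=2) + ½P(IBD=1)`, threshold 0.2).
- **Weighted-LD dating** (ALDER/MALDER-style): admixture LD weighted by
  reference allele-frequency differences decays as `exp(−n·d)`; single
  and multi-exponential fits date the event(s), amplitude Z-scores
  compare reference pairs and assign ancestry regions, and a shared
  short-range-LD diagnostic sets the minimum fitting distance (with the
  conventional 0.5 cM override).
- **Coancestry-curve event characterisation** (GLOBETROTTER-style):
  curves of relative joint-copying probability per surrogate pair,
  null-normalised, fitted with one or two shared-rate exponentials; an
  eigendecomposition of the per-curve coefficient matrix recovers the
  admixture proportion α and source compositions; bootstrap dates give
  95% CIs and an empirical p-value; events are classified five ways
  (no admixture / uncertain / one date / multiple dates / one date,
  multiway), with restricted-surrogate reruns and region-specific
  post-rules.
- **Downstream summaries**: calendar conversion `D = 1950 − (n+1)·g`
  (g = 29 years), 1.96×SE interval scaling, composition-weighted date
  densities, and country-level gene-flow edges.
- **Synthetic data**: Balding–Nichols source panels with founder-mosaic
  LD, genetic maps, and admixed genomes as Poisson recombination mosaics
  with recorded truth tracts — one- and two-pulse events.

## Worked example

```python
from haplomix.pipeline import characterise_admixture
from haplomix.scenarios import single_pulse_study

study = single_pulse_study(seed=31)   # 30% A into B, 10 generations ago
event, _ = characterise_admixture(
    study["target"], study["donors"], n_samples=10,
    seed=study["pipeline_seed"], min_g=study["min_g"],
    max_g=study["max_g"], n_boot=100,
)
```

prints (via `examples/globetrotter_event.py`):

```
classification: one date
date: 7.9 generations (95% CI 4.0-19.5; truth: 10)
admixture proportion alpha: 0.31 (truth: 0.30)
empirical p-value: 0.00 (fraction of bootstrap dates at the 1/400-generation bounds)
minor-source composition over surrogates (should load on the true minor source A):
  A: 0.90
  B: 0.00
  C: 0.10
fit metrics: {'max_r1': 0.986, 'fq1': 0.998, 'fq2': 0.999, 'm': 0.062}
```

The event is called as a single admixture pulse whose 95% bootstrap CI
covers the true date, with the admixture proportion recovered to within
one percentage point and the minor source correctly attributed to
population A.  The `examples/` directory has one short script per
capability (simulation, painting, allele-frequency statistics,
weighted-LD dating, event characterisation, date densities and flow
maps), and the `haplomix` command exposes the same steps from the shell
(`haplomix simulate`, `paint`, `vectors`, `fst`, `f3`, `alder`,
`malder`, `globetrotter`, `density`, `flows`, `report`).

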