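"""Simulate source panels and an admixed cohort with known truth.

Builds two Balding-Nichols source populations over a 4 x 25 cM genome,
mixes them 30/70 ten generations ago, and summarises the recorded truth
tracts.
"""

import numpy as np

import haplomix as hm

maps = hm.make_genome_maps(n_chrom=4, cm_per_chrom=25.0, bp_per_chrom=25_000_000)
sources = hm.simulate_source_panels(
    2, F=0.15, n_snps=5000, n_haps=60, maps=maps, names=["A", "B"], seed=1
)
target, truth = hm.simulate_admixed_population(
    sources, mix={"A": 0.3, "B": 0.7}, n_gen=10, n_ind=20, seed=2
)

fst = hm.hudson_fst(
    sources.panels["A"].allele_freq(), 60,
    sources.panels["B"].allele_freq(), 60,
)
# tracts per haploid = within-chromosome switch points + one tract
# opening each of the 4 chromosomes
switches = truth.tracts.groupby("haploid").size() - len(maps)

print(f"source differentiation: Hudson FST = {fst.estimate:.3f}")
print(f"admixed cohort: {target.n_hap} haploids x {target.n_sites} SNPs")
print(f"genome-wide minor-source fraction: {truth.source_fractions()['A']:.3f}"
      " (truth alpha = 0.3)")
print(f"mean ancestry switch points per haploid: {switches.mean():.1f}"
      " (expected ~ n_gen x genome Morgans = 10)")
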