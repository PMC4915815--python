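"""Allele-frequency admixture statistics: Hudson FST, f3, QC filters.

A 50/50 mixture of two differentiated populations has frequencies
intermediate between its sources, so f3(target; A, B) is significantly
negative (the admixture call threshold in downstream use is Z < -5).
"""

import numpy as np

import haplomix as hm
from haplomix.panel import diploid_genotypes

maps = hm.make_genome_maps(2, 20.0, 20_000_000)
src = hm.simulate_source_panels(
    2, F=0.15, n_snps=10_000, n_haps=60, maps=maps, names=["A", "B"], seed=5
)
target, _ = hm.simulate_admixed_population(
    src, mix={"A": 0.5, "B": 0.5}, n_gen=10, n_ind=30, seed=6
)

fst = hm.hudson_fst(
    src.panels["A"].allele_freq(), 60, src.panels["B"].allele_freq(), 60
)
print(f"Hudson FST(A, B) = {fst.estimate:.3f} +/- {fst.se:.3f}"
      " (the Eurasian-African scale of differentiation)")

f3 = hm.f3_test(
    target.allele_freq(), src.panels["A"].allele_freq(),
    src.panels["B"].allele_freq(),
)
print(f"f3(target; A, B) = {f3.estimate:.5f}, Z = {f3.z:.1f}"
      " -> strongly negative: unambiguous admixture signal")

geno = diploid_genotypes(target)
kept = hm.ld_prune(geno, target.positions, r2_max=0.2, window_bp=50_000)
print(f"LD pruning at r^2 > 0.2 in 50 kb windows keeps "
      f"{kept.size}/{geno.shape[1]} SNPs")

# relatedness is assessed within a homogeneous, outbred cohort (a large
# founder pool), as in real QC; admixture or small founder pools would
# legitimately inflate PI_HAT
outbred = hm.simulate_source_panels(
    1, F=0.0, n_snps=6000, n_haps=60, maps=maps, names=["Q"],
    n_founders=80, ld_blockiness=0.2, seed=8,
)
gq = diploid_genotypes(outbred.panels["Q"])
kq = hm.ld_prune(gq, outbred.panels["Q"].positions)
est, removed = hm.pihat_filter(gq[:, kq], threshold=0.2, seed=7)
print(f"relatedness filter on an outbred cohort: max PI_HAT = "
      f"{est.pi_hat.max():.3f}, {len(removed)} removed (none expected)")
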