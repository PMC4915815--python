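"""Reference synthetic study scenarios.

Frozen end-to-end study conditions used by the examples, the test suite
and the acceptance script, so every consumer exercises the same
simulated world.  Sources are Balding–Nichols panels at F = 0.15,
giving pairwise Hudson FST near 0.157, the Eurasian–African scale of
differentiation; reference/donor panels are held-out halves of the
source populations, disjoint from the haplotypes the admixed genomes
copy from (reference samples are contemporaries, not literal
ancestors).

Genome layouts are desk-scale: a 100 cM genome of four 25 cM
chromosomes for single-pulse studies, and six 50 cM chromosomes
(realistic human chromosome lengths) where a slow ~5-generation decay
must be resolved.  Curve fits stop at ~55% of the chromosome length:
beyond that, every chunk pair has both ends near opposite chromosome
ends, where painting posteriors are diffuse, and the curve tail is
unreliable.
"""

from __future__ import annotations

import numpy as np

from .panel import HaplotypePanel
from .simulate import (
    make_genome_maps,
    simulate_admixed_population,
    simulate_source_panels,
    split_panelset,
)

__all__ = [
    "DRIFT_F",
    "single_pulse_study",
    "weighted_ld_study",
    "two_pulse_study",
    "no_admixture_study",
]

DRIFT_F = 0.15  # Balding-Nichols drift; realized Hudson FST ~ 0.157


def _seeds(seed, n):
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def single_pulse_study(
    seed: int,
    n_gen: float = 10.0,
    alpha: float = 0.3,
    n_ind: int = 20,
):
    """Single-pulse admixture study on a 4 x 25 cM genome.

    Three source populations (A, B, C); the target mixes A (minor,
    proportion ``alpha``) into B ``n_gen`` generations ago; C is an
    unadmixed outgroup available as donor/surrogate.  Returns a dict
    with the target panel, tract truth, donor (reference) panel set and
    the recommended coancestry fit range.
    """
    s = _seeds(seed, 3)
    maps = make_genome_maps(4, 25.0, 25_000_000)
    src = simulate_source_panels(
        3, DRIFT_F, 5000, 60, maps, names=["A", "B", "C"], seed=s[0]
    )
    ancestors, refs = split_panelset(src, 30)
    target, truth = simulate_admixed_population(
        ancestors, mix={"A": alpha, "B": 1 - alpha}, n_gen=n_gen,
        n_ind=n_ind, seed=s[1],
    )
    return {
        "maps": maps,
        "target": target,
        "truth": truth,
        "refs": refs,
        "donors": refs.combined(),
        "min_g": 1.0,
        "max_g": 14.0,
        "pipeline_seed": s[2],
    }


def weighted_ld_study(seed: int, n_gen: float = 10.0, alpha: float = 0.3):
    """Two 50-haploid reference panels, 5,000 SNPs, 100 cM; a 50-diploid
    target admixed ``n_gen`` generations ago.  Study for ALDER-style
    weighted-LD dating."""
    s = _seeds(seed, 2)
    maps = make_genome_maps(4, 25.0, 25_000_000)
    src = simulate_source_panels(
        2, DRIFT_F, 5000, 100, maps, names=["A", "B"], seed=s[0]
    )
    ancestors, refs = split_panelset(src, 50)
    target, truth = simulate_admixed_population(
        ancestors, mix={"A": alpha, "B": 1 - alpha}, n_gen=n_gen,
        n_ind=50, seed=s[1],
    )
    return {
        "maps": maps,
        "target": target,
        "truth": truth,
        "ref_a": refs.panels["A"],
        "ref_b": refs.panels["B"],
        "min_d": 0.5,
        "max_d": 14.0,
        "bin_cm": 0.05,
    }


def two_pulse_study(
    seed: int,
    n_old: float = 40.0,
    n_recent: float = 5.0,
    alpha_recent: float = 0.3,
    n_ind: int = 40,
):
    """Two-pulse study on six 50 cM chromosomes: an old A-into-B pulse
    and a recent pulse from C replacing ``alpha_recent`` of the genome."""
    s = _seeds(seed, 3)
    maps = make_genome_maps(6, 50.0, 50_000_000)
    src = simulate_source_panels(
        3, DRIFT_F, 9000, 60, maps, names=["A", "B", "C"], seed=s[0]
    )
    ancestors, refs = split_panelset(src, 30)
    target, truth = simulate_admixed_population(
        ancestors,
        pulses=[(n_old, {"A": 0.3, "B": 0.7}), (n_recent, {"C": alpha_recent})],
        n_ind=n_ind,
        seed=s[1],
    )
    return {
        "maps": maps,
        "target": target,
        "truth": truth,
        "refs": refs,
        "donors": refs.combined(),
        "min_g": 1.0,
        "max_g": 28.0,
        "pipeline_seed": s[2],
    }


def no_admixture_study(seed: int, n_ind: int = 20):
    """Null study: the target is a fresh, unadmixed sample of source B."""
    s = _seeds(seed, 2)
    maps = make_genome_maps(4, 25.0, 25_000_000)
    src = simulate_source_panels(
        3, DRIFT_F, 5000, 30 + 2 * n_ind, maps, names=["A", "B", "C"],
        seed=s[0],
    )
    refs, rest = split_panelset(src, 30)
    held_out = rest.panels["B"]
    target = HaplotypePanel(
        haps=held_out.haps,
        positions=held_out.positions,
        chrom=held_out.chrom,
        cm=held_out.cm,
        sample_ids=[f"t{i}" for i in range(n_ind)],
        groups=np.full(2 * n_ind, "target"),
    )
    return {
        "maps": maps,
        "target": target,
        "refs": refs,
        "donors": refs.combined(),
        "min_g": 1.0,
        "max_g": 14.0,
        "pipeline_seed": s[1],
    }
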