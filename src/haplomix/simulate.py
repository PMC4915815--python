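"""Synthetic haplotype data with known admixture truth.

Source populations are simulated under the Balding–Nichols model: each
population's allele frequency at a site is a Beta draw around a shared
ancestral frequency, with drift parameter ``F`` controlling differentiation
(pairwise Hudson FST between two populations with drift F is on the
2F/(1+F) scale).  Linkage disequilibrium within a panel comes from building
each haplotype as a mosaic of a small founder set, so allelic correlation
decays with genetic distance on a tunable scale.

Admixed genomes are recombination mosaics: ancestry switch points fall as a
Poisson process with rate n per Morgan (n = generations since the pulse),
each tract's ancestry is drawn from the pulse proportions, and the tract's
sequence is copied from a random haplotype of that source panel.  A more
recent second pulse overlays the older mosaic, which yields the
two-exponential ancestry-LD decay that two-date fits target.  True tracts
are recorded per haploid so every inference stage can be checked against
known truth.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap, make_genetic_map
from .panel import HaplotypePanel, concat_panels

__all__ = [
    "SourcePanelSet",
    "TractTruth",
    "make_genome_maps",
    "simulate_source_panels",
    "simulate_admixed_population",
    "split_panelset",
]


@dataclass
class SourcePanelSet:
    """A set of source (donor) panels sharing sites and maps."""

    panels: dict[str, HaplotypePanel]
    maps: list[GeneticMap]
    ancestral_freq: np.ndarray
    F: dict[str, float]

    @property
    def names(self) -> list[str]:
        return list(self.panels)

    def combined(self) -> HaplotypePanel:
        return concat_panels([self.panels[n] for n in self.names])

    @property
    def sites(self) -> HaplotypePanel:
        return next(iter(self.panels.values()))


@dataclass
class TractTruth:
    """True ancestry tracts of simulated admixed haploids.

    ``tracts`` has columns haploid, chrom, start_bp, end_bp, source.
    Tracts tile each chromosome without gaps or overlaps.
    """

    tracts: pd.DataFrame
    times: tuple[float, ...]
    proportions: tuple[dict[str, float], ...]

    def source_fractions(self, maps: Sequence[GeneticMap] | None = None) -> pd.Series:
        """Genome-wide bp fraction of each source across all haploids."""
        t = self.tracts
        w = (t.end_bp - t.start_bp).astype(float)
        frac = w.groupby(t.source).sum()
        return frac / frac.sum()

    def to_tsv(self, path) -> None:
        self.tracts.to_csv(path, sep="\t", index=False)


def make_genome_maps(
    n_chrom: int = 5,
    cm_per_chrom: float = 20.0,
    bp_per_chrom: int = 20_000_000,
) -> list[GeneticMap]:
    """Uniform-rate maps for a toy genome of ``n_chrom`` chromosomes."""
    rate = cm_per_chrom / (bp_per_chrom / 1e6)
    return [
        make_genetic_map(bp_per_chrom, ((0.0, rate),), n_sites=2, chrom=str(c + 1))
        for c in range(n_chrom)
    ]


def _site_grid(maps: Sequence[GeneticMap], n_snps: int, rng) -> tuple[np.ndarray, ...]:
    """Distribute n_snps across chromosomes proportional to bp length."""
    lens = np.array([m.length_bp for m in maps], dtype=float)
    counts = np.maximum(2, np.round(n_snps * lens / lens.sum()).astype(int))
    pos_all, chrom_all, cm_all = [], [], []
    for m, k in zip(maps, counts):
        pos = np.sort(rng.choice(m.length_bp, size=k, replace=False))
        pos_all.append(pos)
        chrom_all.append(np.full(k, m.chrom))
        cm_all.append(m.interp_cm(pos))
    return (
        np.concatenate(pos_all),
        np.concatenate(chrom_all),
        np.concatenate(cm_all),
    )


def _mosaic_indices(cm: np.ndarray, scale_cm: float, n_choices: int, rng) -> np.ndarray:
    """Founder index per site: segments of mean length scale_cm in cM."""
    n = cm.size
    out = np.empty(n, dtype=np.int64)
    cur = rng.integers(n_choices)
    next_switch = cm[0] + rng.exponential(scale_cm)
    for i in range(n):
        if cm[i] >= next_switch:
            cur = rng.integers(n_choices)
            next_switch = cm[i] + rng.exponential(scale_cm)
        out[i] = cur
    return out


def simulate_source_panels(
    n_pops: int,
    F,
    n_snps: int,
    n_haps: int,
    maps: Sequence[GeneticMap] | GeneticMap | None = None,
    ld_blockiness: float = 0.5,
    n_founders: int = 10,
    names: Sequence[str] | None = None,
    seed: int | None = None,
) -> SourcePanelSet:
    """Simulate differentiated source panels with decaying LD.

    Parameters
    ----------
    F
        Balding–Nichols drift per population, scalar or per-pop sequence,
        each in [0, 1).
    ld_blockiness
        Mean founder-mosaic segment length in cM; smaller values mean
        faster LD decay.
    n_founders
        Founder haplotypes per population; LD strength scales with
        1/n_founders.
    """
    if n_haps < 4:
        raise ValueError("n_haps must be at least 4 for downstream estimators")
    if n_snps < 10:
        raise ValueError("n_snps must be at least 10")
    rng = np.random.default_rng(seed)
    if maps is None:
        maps = make_genome_maps()
    if isinstance(maps, GeneticMap):
        maps = [maps]
    Fs = np.broadcast_to(np.asarray(F, dtype=float), (n_pops,))
    if np.any((Fs < 0) | (Fs >= 1)):
        raise ValueError("each F must lie in [0, 1)")
    if names is None:
        names = [f"pop{i}" for i in range(n_pops)]

    positions, chrom, cm = _site_grid(maps, n_snps, rng)
    n_sites = positions.size
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    panels: dict[str, HaplotypePanel] = {}
    for name, f in zip(names, Fs):
        if f == 0:
            p = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p = rng.beta(a, b)
        # constrain per-site founder allele counts to round(n_founders * p)
        # so the founder pool adds no extra drift on top of the
        # Balding-Nichols frequencies; the mosaic still gives LD
        count = np.round(n_founders * p).astype(int)
        founders = np.zeros((n_founders, n_sites), dtype=np.uint8)
        order = np.argsort(rng.random((n_founders, n_sites)), axis=0)
        founders[order < count[None, :]] = 1
        haps = np.empty((n_haps, n_sites), dtype=np.uint8)
        for h in range(n_haps):
            row = np.empty(n_sites, dtype=np.uint8)
            for mobj in maps:
                sel = np.flatnonzero(chrom == mobj.chrom)
                idx = _mosaic_indices(cm[sel], ld_blockiness, n_founders, rng)
                row[sel] = founders[idx, sel]
            haps[h] = row
        panels[name] = HaplotypePanel(
            haps=haps,
            positions=positions,
            chrom=chrom,
            cm=cm,
            sample_ids=[f"{name}_{i}" for i in range(n_haps // 2 + n_haps % 2)],
            groups=np.full(n_haps, name),
        )
    return SourcePanelSet(
        panels=panels, maps=list(maps), ancestral_freq=p_anc,
        F={n: float(f) for n, f in zip(names, Fs)},
    )


def split_panelset(
    sources: SourcePanelSet, n_first: int
) -> tuple[SourcePanelSet, SourcePanelSet]:
    """Split every panel into two disjoint haploid sets.

    The first split is typically used as the ancestral pool that admixed
    genomes copy from, the second as the reference/donor sample — mirroring
    real studies, where reference panels are contemporaries of the admixed
    population rather than its literal ancestors (using the same haploids
    for both overstates shared haplotype structure).
    """
    first, second = {}, {}
    for name, p in sources.panels.items():
        if p.n_hap <= n_first:
            raise ValueError("n_first must be smaller than the panel size")
        first[name] = p.take_haploids(np.arange(n_first))
        second[name] = p.take_haploids(np.arange(n_first, p.n_hap))
    return (
        SourcePanelSet(first, sources.maps, sources.ancestral_freq, dict(sources.F)),
        SourcePanelSet(second, sources.maps, sources.ancestral_freq, dict(sources.F)),
    )


def _pulse_tracts(cm_lo, cm_hi, n_gen, labels, probs, rng):
    """Poisson ancestry mosaic over [cm_lo, cm_hi) in cM; returns
    (breaks_cm, label_idx per segment)."""
    morgans = (cm_hi - cm_lo) / 100.0
    k = rng.poisson(n_gen * morgans)
    breaks = np.sort(rng.uniform(cm_lo, cm_hi, size=k))
    edges = np.concatenate([[cm_lo], breaks, [cm_hi]])
    lab = rng.choice(len(labels), size=edges.size - 1, p=probs)
    return edges, lab


def simulate_admixed_population(
    sources: SourcePanelSet,
    mix: dict[str, float] | None = None,
    n_gen: float | None = None,
    pulses: Sequence[tuple[float, dict[str, float]]] | None = None,
    n_ind: int = 20,
    group: str = "admixed",
    seed: int | None = None,
) -> tuple[HaplotypePanel, TractTruth]:
    """Simulate an admixed cohort as ancestry mosaics of the source panels.

    Either give ``mix`` (per-source proportions summing to 1) with ``n_gen``
    for a single pulse, or an explicit ``pulses`` list ordered oldest first:
    the first pulse's proportions sum to 1 (the base mosaic); each later
    pulse's proportions sum to the fraction of the genome it replaces.
    """
    rng = np.random.default_rng(seed)
    if pulses is None:
        if mix is None or n_gen is None:
            raise ValueError("give either mix+n_gen or pulses")
        pulses = [(float(n_gen), dict(mix))]
    for n, props in pulses:
        if n <= 0:
            raise ValueError("admixture time must be positive (generations)")
        unknown = set(props) - set(sources.names)
        if unknown:
            raise ValueError(f"unknown source(s): {sorted(unknown)}")
    base_total = sum(pulses[0][1].values())
    if abs(base_total - 1.0) > 1e-6:
        raise ValueError("first pulse proportions must sum to 1")
    for n, props in pulses[1:]:
        tot = sum(props.values())
        if not (0 < tot <= 1 + 1e-6):
            raise ValueError("later pulse proportions must sum into (0, 1]")

    template = sources.sites
    positions, chrom, cm = template.positions, template.chrom, template.cm
    n_sites = positions.size
    n_hap = 2 * n_ind
    haps = np.zeros((n_hap, n_sites), dtype=np.uint8)
    records: list[tuple] = []

    src_names = sources.names
    for h in range(n_hap):
        for mobj in sources.maps:
            sel = np.flatnonzero(chrom == mobj.chrom)
            site_cm = cm[sel]
            cm_lo, cm_hi = float(mobj.cm[0]), float(mobj.cm[-1])
            # base (oldest) pulse mosaic
            n0, props0 = pulses[0]
            labels0 = list(props0)
            p0 = np.array([props0[k] for k in labels0]) / base_total
            edges, lab = _pulse_tracts(cm_lo, cm_hi, n0, labels0, p0, rng)
            seg_labels = [labels0[j] for j in lab]
            # overlay each more recent pulse
            for n_k, props_k in pulses[1:]:
                alpha_k = sum(props_k.values())
                labels_k = list(props_k)
                p_k = np.array([props_k[j] for j in labels_k]) / alpha_k
                edges_k, _ = _pulse_tracts(cm_lo, cm_hi, n_k, labels_k, p_k, rng)
                new_edges = np.unique(np.concatenate([edges, edges_k]))
                # which overlay segment each new interval falls in
                mid = 0.5 * (new_edges[:-1] + new_edges[1:])
                old_idx = np.searchsorted(edges, mid) - 1
                ov_idx = np.searchsorted(edges_k, mid) - 1
                replace = rng.random(edges_k.size - 1) < alpha_k
                repl_lab = rng.choice(len(labels_k), size=edges_k.size - 1, p=p_k)
                seg_labels = [
                    labels_k[repl_lab[ov_idx[i]]]
                    if replace[ov_idx[i]]
                    else seg_labels[old_idx[i]]
                    for i in range(mid.size)
                ]
                edges = new_edges
            # one tract per Poisson segment (adjacent same-source segments
            # stay separate: they copy from different donor haplotypes,
            # like recombination among same-ancestry lineages)
            bp_edges = mobj.interp_bp(edges)
            bp_edges[0] = mobj.positions[0]
            bp_edges[-1] = mobj.positions[-1]
            for k, src in enumerate(seg_labels):
                lo_bp, hi_bp = bp_edges[k], bp_edges[k + 1]
                in_tract = sel[(positions[sel] >= lo_bp) & (positions[sel] < hi_bp)]
                if in_tract.size:
                    donor_panel = sources.panels[src]
                    donor = rng.integers(donor_panel.n_hap)
                    haps[h, in_tract] = donor_panel.haps[donor, in_tract]
                records.append(
                    (h, mobj.chrom, int(lo_bp), int(hi_bp), src)
                )

    tracts = pd.DataFrame(
        records, columns=["haploid", "chrom", "start_bp", "end_bp", "source"]
    )
    panel = HaplotypePanel(
        haps=haps,
        positions=positions,
        chrom=chrom,
        cm=cm,
        sample_ids=[f"{group}_{i}" for i in range(n_ind)],
        groups=np.full(n_hap, group),
    )
    truth = TractTruth(
        tracts=tracts,
        times=tuple(n for n, _ in pulses),
        proportions=tuple(dict(p) for _, p in pulses),
    )
    return panel, truth
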