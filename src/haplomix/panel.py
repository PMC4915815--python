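"""Phased haplotype panels.

The central in-memory container: a matrix of phased 0/1 haplotypes over
biallelic sites, with physical and genetic coordinates per site and
sample/group labels per haploid.  Diploid individuals contribute two
consecutive haploid rows (2i, 2i+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with coordinates and labels.

    Attributes
    ----------
    haps
        ``(n_haploids, n_sites)`` array of 0/1 alleles (uint8).
    positions
        Site positions in bp (0-based), per site.
    chrom
        Chromosome label per site.
    cm
        Cumulative genetic position (cM) per site, within its chromosome.
    sample_ids
        One id per diploid sample; haploids ``2i`` and ``2i+1`` belong to
        sample ``i``.  For odd haploid counts (pure haploid panels) ids may
        instead be per haploid.
    groups
        Group (population) label per haploid.
    """

    haps: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    cm: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.haps = np.ascontiguousarray(np.asarray(self.haps, dtype=np.uint8))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.groups = np.asarray(self.groups)
        n_hap, n_sites = self.haps.shape
        if not (
            self.positions.size == n_sites
            and self.chrom.size == n_sites
            and self.cm.size == n_sites
        ):
            raise ValueError("per-site arrays must match the number of sites")
        if self.groups.size != n_hap:
            raise ValueError("groups must have one label per haploid")
        for c in self.chromosomes:
            sel = self.chrom == c
            if np.any(np.diff(self.positions[sel]) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return list(self.chrom[np.sort(idx)])

    def sites_on(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def allele_freq(self, haploid_idx=None) -> np.ndarray:
        """Per-site frequency of the '1' allele over the given haploids."""
        h = self.haps if haploid_idx is None else self.haps[haploid_idx]
        return h.mean(axis=0)

    def take_haploids(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        diploid = len(self.sample_ids) * 2 == self.n_hap
        whole_pairs = (
            diploid
            and idx.size % 2 == 0
            and np.all(idx[0::2] % 2 == 0)
            and np.all(idx[1::2] == idx[0::2] + 1)
        )
        if whole_pairs:
            sample_ids = [self.sample_ids[i // 2] for i in idx[0::2]]
        elif diploid:
            sample_ids = [self.sample_ids[i // 2] + f"_{i % 2}" for i in idx]
        else:
            sample_ids = [self.sample_ids[i] for i in idx]
        return HaplotypePanel(
            haps=self.haps[idx],
            positions=self.positions,
            chrom=self.chrom,
            cm=self.cm,
            sample_ids=sample_ids,
            groups=self.groups[idx],
        )

    def take_sites(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            haps=self.haps[:, idx],
            positions=self.positions[idx],
            chrom=self.chrom[idx],
            cm=self.cm[idx],
            sample_ids=list(self.sample_ids),
            groups=self.groups,
        )

    def haploids_of_group(self, group) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def group_list(self) -> list:
        _, idx = np.unique(self.groups, return_index=True)
        return list(self.groups[np.sort(idx)])


def concat_panels(panels: Sequence[HaplotypePanel]) -> HaplotypePanel:
    """Stack panels sharing identical sites along the haploid axis."""
    first = panels[0]
    for p in panels[1:]:
        if not (
            np.array_equal(p.positions, first.positions)
            and np.array_equal(p.chrom, first.chrom)
        ):
            raise ValueError("panels must share the same sites to concatenate")
    return HaplotypePanel(
        haps=np.vstack([p.haps for p in panels]),
        positions=first.positions,
        chrom=first.chrom,
        cm=first.cm,
        sample_ids=[s for p in panels for s in p.sample_ids],
        groups=np.concatenate([p.groups for p in panels]),
    )


def diploid_genotypes(panel: HaplotypePanel) -> np.ndarray:
    """Collapse phased haploids into diploid dosages (n_samples, n_sites)."""
    if panel.n_hap % 2:
        raise ValueError("panel has an odd number of haploids")
    h = panel.haps.astype(np.int16)
    return h[0::2] + h[1::2]
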