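"""Genetic maps: physical position to genetic distance.

A :class:`GeneticMap` stores a piecewise-linear mapping from base-pair
position to cumulative genetic distance in centimorgans (cM) for one
chromosome, the convention used by HapMap-style recombination map files
(columns: position, rate in cM/Mb, cumulative cM).  Interpolation between
anchor points is linear in bp; queries outside the anchored range are
extrapolated at the boundary rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative genetic map for a single chromosome.

    Parameters
    ----------
    positions
        Anchor positions in bp, strictly increasing, 0-based.
    cm
        Cumulative genetic position in cM at each anchor, nondecreasing.
    chrom
        Chromosome label (free-form).
    """

    positions: np.ndarray
    cm: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if pos.ndim != 1 or pos.shape != cm.shape:
            raise ValueError("positions and cm must be 1-D arrays of equal length")
        if pos.size < 2:
            raise ValueError("a genetic map needs at least two anchor points")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("cumulative cM must be nondecreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cm", cm)

    @property
    def length_bp(self) -> int:
        return int(self.positions[-1] - self.positions[0])

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def interp_cm(self, positions_bp) -> np.ndarray:
        """Cumulative cM at arbitrary bp positions (linear, boundary-rate
        extrapolation outside the anchored range)."""
        q = np.asarray(positions_bp, dtype=np.float64)
        pos = self.positions.astype(np.float64)
        out = np.interp(q, pos, self.cm)
        # extrapolate with the first/last segment rate
        lo = q < pos[0]
        if np.any(lo):
            r0 = (self.cm[1] - self.cm[0]) / (pos[1] - pos[0])
            out = np.where(lo, self.cm[0] + (q - pos[0]) * r0, out)
        hi = q > pos[-1]
        if np.any(hi):
            r1 = (self.cm[-1] - self.cm[-2]) / (pos[-1] - pos[-2])
            out = np.where(hi, self.cm[-1] + (q - pos[-1]) * r1, out)
        return out

    def interp_bp(self, cm_values) -> np.ndarray:
        """Inverse lookup: bp position at a cumulative cM value.

        Flat (zero-rate) segments are resolved to their left endpoint.
        """
        q = np.atleast_1d(np.asarray(cm_values, dtype=np.float64))
        return np.interp(q, self.cm, self.positions.astype(np.float64))


def make_genetic_map(
    length_bp: int,
    rate_profile=((0.0, 1.0),),
    n_sites: int = 2,
    chrom: str = "1",
) -> GeneticMap:
    """Build a map over ``[0, length_bp)`` from a piecewise rate profile.

    ``rate_profile`` is a sequence of ``(start_bp, rate_cm_per_mb)`` pairs,
    sorted by start, each rate applying from its start to the next segment's
    start (the last runs to ``length_bp``).  ``n_sites`` anchor points are
    placed evenly over the chromosome (segment breakpoints are always
    included as anchors so the map is exact).
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if n_sites < 2:
        raise ValueError("n_sites must be at least 2")
    starts = np.array([s for s, _ in rate_profile], dtype=np.float64)
    rates = np.array([r for _, r in rate_profile], dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("recombination rates must be nonnegative")
    if starts[0] != 0 or np.any(np.diff(starts) <= 0):
        raise ValueError("rate_profile must start at 0 with increasing starts")

    anchors = np.unique(
        np.concatenate(
            [np.linspace(0, length_bp, n_sites), starts, [length_bp]]
        )
    ).astype(np.int64)
    anchors = np.unique(anchors)
    # integrate the step-function rate (cM/Mb) over bp
    seg_ends = np.append(starts[1:], length_bp)
    cum_at_start = np.concatenate(
        [[0.0], np.cumsum((seg_ends - starts) * rates / 1e6)[:-1]]
    )

    idx = np.searchsorted(starts, anchors, side="right") - 1
    cm = cum_at_start[idx] + (anchors - starts[idx]) * rates[idx] / 1e6
    return GeneticMap(positions=anchors, cm=cm, chrom=chrom)
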