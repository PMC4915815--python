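"""Allele-frequency and copying-vector statistics.

Hudson's FST estimator (ratio of averages, block-jackknife SE), total
variation distance between copying vectors, the three-population f3 test
with a 500-SNP block jackknife, greedy LD pruning, and PI_HAT
relatedness filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StatResult",
    "block_jackknife",
    "hudson_fst",
    "tvd",
    "f3_test",
    "ld_prune",
    "pihat_filter",
]


@dataclass
class StatResult:
    """Point estimate with block-jackknife uncertainty."""

    estimate: float
    se: float
    block_size: int
    n_blocks: int

    @property
    def z(self) -> float:
        if self.se <= 0:
            raise ValueError("Z is undefined when the jackknife SE is zero")
        return self.estimate / self.se


def block_jackknife(num: np.ndarray, den: np.ndarray | None, block: int):
    """Delete-one-block jackknife for a ratio (or mean) of per-site terms.

    ``num`` (and optionally ``den``) are per-site contributions; the
    statistic is sum(num)/sum(den), or mean(num) when ``den`` is None.
    """
    n = num.size
    if den is None:
        den = np.ones(n)
    starts = np.arange(0, n, block)
    B = starts.size
    tot_num, tot_den = num.sum(), den.sum()
    full = tot_num / tot_den
    if B < 2:
        return full, np.nan, B
    loo = np.empty(B)
    for b, s in enumerate(starts):
        e = min(s + block, n)
        loo[b] = (tot_num - num[s:e].sum()) / (tot_den - den[s:e].sum())
    se = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    return full, se, B


def hudson_fst(p1, n1, p2, n2, block: int = 500) -> StatResult:
    """Hudson's FST between two populations, ratio-of-averages form.

    Per-site numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1); the estimate is the ratio of the
    site-averaged numerator and denominator, with a block-jackknife SE.
    Sample sizes may be ``np.inf`` for the infinite-sample limit.  Sites
    where either sample size is below 2 are dropped with a warning.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape).copy()
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape).copy()
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} site(s) with sample size < 2"
        )
    if not ok.any():
        raise ValueError("no usable sites for FST (all sample sizes < 2)")
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    with np.errstate(invalid="ignore"):
        corr1 = np.where(np.isinf(n1), 0.0, p1 * (1 - p1) / (n1 - 1))
        corr2 = np.where(np.isinf(n2), 0.0, p2 * (1 - p2) / (n2 - 1))
    num = (p1 - p2) ** 2 - corr1 - corr2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    est, se, B = block_jackknife(num, den, block)
    return StatResult(float(est), float(se), block, B)


def tvd(a, b, labels_a=None, labels_b=None) -> float:
    """Total variation distance between two copying vectors:
    0.5 * sum_i |a_i - b_i|.  Both must be distributions over the same
    donor support."""
    if labels_a is not None or labels_b is not None:
        if list(labels_a) != list(labels_b):
            raise ValueError("copying vectors are over different donor sets")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("copying vectors are over different donor sets")
    for v, nm in ((a, "a"), (b, "b")):
        if np.any(v < -1e-12) or not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"vector {nm} is not a normalised distribution")
    return float(0.5 * np.abs(a - b).sum())


def f3_test(x, a, b, block: int = 500) -> StatResult:
    """f3(X; A, B): mean over SNPs of (x - a)(x - b).

    ``x``, ``a``, ``b`` are per-site sample allele frequencies.
    Significantly negative Z (the admixture call in downstream use is
    Z < -5) indicates X arose as a mixture of relatives of A and B.
    No frequency-bias correction is applied to X (``StatResult`` carries
    the raw moment); see the methods note.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    poly = (x * (1 - x) + a * (1 - a) + b * (1 - b)) > 0
    if not poly.any():
        raise ValueError("all sites monomorphic in all three populations")
    term = ((x - a) * (x - b))[poly]
    est, se, B = block_jackknife(term, None, block)
    return StatResult(float(est), float(se), block, B)


def _r2(g1: np.ndarray, g2: np.ndarray) -> float:
    s1, s2 = g1.std(), g2.std()
    if s1 == 0 or s2 == 0:
        return np.nan
    return float(np.corrcoef(g1, g2)[0, 1] ** 2)


def ld_prune(
    genotypes: np.ndarray,
    positions: np.ndarray,
    r2_max: float = 0.2,
    window_bp: int = 50_000,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a bp sliding window.

    Returns indices of retained SNPs; no retained pair closer than
    ``window_bp`` has r^2 > ``r2_max``.  Monomorphic SNPs (r^2 undefined)
    never trigger removals.
    """
    g = np.asarray(genotypes, dtype=float)
    positions = np.asarray(positions)
    kept: list[int] = []
    for j in range(g.shape[1]):
        drop = False
        for k in reversed(kept):
            if positions[j] - positions[k] > window_bp:
                break
            r2 = _r2(g[:, k], g[:, j])
            if not np.isnan(r2) and r2 > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=np.int64)


def _ibs_expectations(p: np.ndarray) -> tuple[float, ...]:
    q = 1 - p
    e0_ibd0 = np.sum(2 * p**2 * q**2)
    e1_ibd0 = np.sum(4 * p**3 * q + 4 * p * q**3)
    e1_ibd1 = np.sum(2 * p * q)
    e2_ibd0 = np.sum(p**4 + q**4 + 4 * p**2 * q**2)
    e2_ibd1 = np.sum(p**2 + q**2)
    return e0_ibd0, e1_ibd0, e1_ibd1, e2_ibd0, e2_ibd1


def pihat_filter(
    genotypes: np.ndarray,
    threshold: float = 0.2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Method-of-moments IBD estimation and relatedness filtering.

    ``genotypes`` is (n_individuals, n_snps) diploid dosage (0/1/2),
    ideally on an LD-pruned SNP set.  PI_HAT = P(IBD=2) + 0.5 P(IBD=1);
    for each pair exceeding ``threshold`` one member is removed at random
    (seeded) until no retained pair exceeds it.  Returns the pairwise
    estimates and the removed individual indices.
    """
    g = np.asarray(genotypes, dtype=float)
    n_ind, n_snp = g.shape
    if n_ind < 2:
        raise ValueError("relatedness filtering needs at least 2 individuals")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    g, p = g[:, poly], p[poly]
    e00, e10, e11, e20, e21 = _ibs_expectations(p)
    n_used = p.size

    rows = []
    pihat = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            diff = np.abs(g[i] - g[j])
            ibs0 = float(np.sum(diff == 2))
            ibs1 = float(np.sum(diff == 1))
            ibs2 = n_used - ibs0 - ibs1
            p0 = ibs0 / e00 if e00 > 0 else 0.0
            p1 = (ibs1 - p0 * e10) / e11 if e11 > 0 else 0.0
            p2 = (ibs2 - p0 * e20 - p1 * e21) / n_used
            probs = np.clip([p0, p1, p2], 0, 1)
            if probs.sum() > 0:
                probs = probs / probs.sum()
            ph = float(probs[2] + 0.5 * probs[1])
            pihat[i, j] = pihat[j, i] = ph
            rows.append((i, j, *probs, ph))
    est = pd.DataFrame(
        rows, columns=["id1", "id2", "ibd0", "ibd1", "ibd2", "pi_hat"]
    )
    rng = np.random.default_rng(seed)
    removed: list[int] = []
    active = np.ones(n_ind, dtype=bool)
    while True:
        masked = np.where(
            np.outer(active, active), pihat, 0.0
        )
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        drop = int(rng.choice([i, j]))
        active[drop] = False
        removed.append(drop)
    return est, removed
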