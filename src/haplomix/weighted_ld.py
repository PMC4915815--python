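"""Admixture-LD dating from weighted LD curves.

Admixture between differentiated populations creates linkage
disequilibrium whose expectation decays as exp(-n * d) in genetic distance
d (Morgans) over n generations.  The weighted LD statistic for a SNP pair
(s1, s2) is the sample covariance of target alleles at the two sites
multiplied by w(s1) * w(s2), where w(s) is the allele-frequency difference
between two reference populations; binned by distance it yields a decay
curve whose rate estimates the admixture date and whose amplitude (the
y-axis intercept of the exponential term) grows as the references approach
the true mixing sources.

One-reference mode substitutes the target itself for one reference; to
avoid the self-correlation bias this induces, the target sample is split:
one half supplies the weight frequencies, the other the covariances.

Uncertainty comes from a delete-one jackknife over chromosomes (or over
contiguous site blocks when only one chromosome is available), which also
drives the model-order rule for multiple-event fits: an added exponential
is kept only when its amplitude is more than two jackknife SEs from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .panel import HaplotypePanel

__all__ = [
    "WeightedLDCurve",
    "ExponentialFit",
    "SourceAssignment",
    "weighted_ld_curve",
    "min_shared_ld_distance",
    "fit_admixture_exponentials",
    "curve_amplitude_zscore",
    "assign_event_sources",
]


@dataclass
class WeightedLDCurve:
    """Binned weighted-LD curve with per-jackknife-unit partial sums."""

    bin_edges: np.ndarray  # (B+1,) cM
    sums: np.ndarray  # (U, B) per-unit sums of pair values
    counts: np.ndarray  # (U, B) per-unit pair counts
    unit_labels: list
    mode: str = "two-ref"
    zero_weights: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def min_d(self) -> float:
        return float(self.bin_edges[0])

    @property
    def max_d(self) -> float:
        return float(self.bin_edges[-1])

    def values(self, exclude_unit: int | None = None) -> np.ndarray:
        s, c = self.sums, self.counts
        if exclude_unit is not None:
            keep = np.ones(s.shape[0], dtype=bool)
            keep[exclude_unit] = False
            s, c = s[keep], c[keep]
        with np.errstate(invalid="ignore"):
            return np.where(c.sum(0) > 0, s.sum(0) / np.maximum(c.sum(0), 1), np.nan)

    @property
    def pair_counts(self) -> np.ndarray:
        return self.counts.sum(0)

    def bin_se(self) -> np.ndarray:
        """Per-bin jackknife SE over units."""
        U = self.sums.shape[0]
        if U < 2:
            return np.full(self.sums.shape[1], np.nan)
        loo = np.stack([self.values(exclude_unit=u) for u in range(U)])
        return np.sqrt((U - 1) / U * np.nansum((loo - np.nanmean(loo, 0)) ** 2, 0))

    @property
    def n_units(self) -> int:
        return self.sums.shape[0]


def _jackknife_units(panel: HaplotypePanel, min_units: int = 8):
    """Assign each site a jackknife unit: whole chromosomes when there
    are enough, otherwise contiguous within-chromosome blocks so at
    least ``min_units`` delete-one units exist."""
    chroms = panel.chromosomes
    unit = np.empty(panel.n_sites, dtype=np.int64)
    per_chrom = max(1, int(np.ceil(min_units / len(chroms))))
    labels = []
    u = 0
    for c in chroms:
        sel = panel.sites_on(c)
        splits = np.array_split(sel, per_chrom)
        for k, block in enumerate(splits):
            if block.size == 0:
                continue
            unit[block] = u
            labels.append(f"{c}.{k}" if per_chrom > 1 else str(c))
            u += 1
    return unit, labels


def _pair_accumulate(dmat, wprod, dist, unit, edges, sums, counts, ok_extra=None):
    """Accumulate pair values into per-(unit, bin) sums.  ``dist``/``unit``
    refer to the pair's left site; upper-triangle pairs only."""
    B = edges.size - 1
    iu, ju = np.triu_indices(dmat.shape[0], k=1)
    d = dist[ju] - dist[iu]
    binidx = np.searchsorted(edges, d, side="right") - 1
    ok = (binidx >= 0) & (binidx < B) & (d > 0)
    if ok_extra is not None:
        ok &= ok_extra[iu] | ok_extra[ju]
    iu, ju, binidx = iu[ok], ju[ok], binidx[ok]
    vals = dmat[iu, ju] * wprod[iu, ju]
    key = unit[iu] * B + binidx
    nb = sums.shape[0] * B
    sums.ravel()[:] += np.bincount(key, weights=vals, minlength=nb)[:nb]
    counts.ravel()[:] += np.bincount(key, minlength=nb)[:nb]


def weighted_ld_curve(
    target: HaplotypePanel,
    ref_a: HaplotypePanel,
    ref_b: HaplotypePanel | None = None,
    min_d: float = 0.5,
    max_d: float = 30.0,
    bin_cm: float = 0.05,
) -> WeightedLDCurve:
    """Weighted admixture-LD curve for a target against two references.

    ``ref_b=None`` selects one-reference mode (the target stands in for
    the second reference, with sample splitting; see module docstring).
    Passing the same panel as both references is legal but yields a
    flagged all-zero curve (the weights vanish).
    """
    if min_d >= max_d:
        raise ValueError("min_d must be smaller than max_d")
    edges = np.arange(min_d, max_d + bin_cm / 2, bin_cm)
    unit, unit_labels = _jackknife_units(target)
    U, B = len(unit_labels), edges.size - 1
    sums = np.zeros((U, B))
    counts = np.zeros((U, B))

    one_ref = ref_b is None
    if one_ref:
        half = target.n_hap // 2
        perm = np.arange(target.n_hap)
        w_half, cov_half = perm[:half], perm[half:]
        pa = ref_a.allele_freq()
        pb = target.allele_freq(w_half)
        cov_haps = target.haps[cov_half].astype(np.float64)
    else:
        pa = ref_a.allele_freq()
        pb = ref_b.allele_freq()
        cov_haps = target.haps.astype(np.float64)
    w = pa - pb
    zero_weights = bool(np.allclose(w, 0.0))

    n = cov_haps.shape[0]
    for c in target.chromosomes:
        sel = target.sites_on(c)
        X = cov_haps[:, sel]
        Xc = X - X.mean(0)
        dmat = (Xc.T @ Xc) / max(n - 1, 1)
        wprod = np.outer(w[sel], w[sel])
        _pair_accumulate(
            dmat, wprod, target.cm[sel], unit[sel], edges, sums, counts
        )
    return WeightedLDCurve(
        bin_edges=edges,
        sums=sums,
        counts=counts,
        unit_labels=unit_labels,
        mode="one-ref" if one_ref else "two-ref",
        zero_weights=zero_weights,
    )


def min_shared_ld_distance(
    target: HaplotypePanel,
    reference: HaplotypePanel,
    bin_cm: float = 0.25,
    max_d: float = 5.0,
    z_threshold: float = 2.0,
    override_cm: float | None = None,
) -> float:
    """Distance (cM) beyond which target and reference share no LD.

    Computes the per-bin mean product of target-pair and reference-pair LD
    (covariance) and finds the smallest distance beyond which this
    correlation is indistinguishable from zero (jackknife |Z| below
    ``z_threshold`` in every further bin).  Shared short-range LD at
    larger distances indicates shared demography (e.g. a common
    bottleneck), which would confound admixture-curve fitting; curve fits
    should start beyond the returned value.  ``override_cm`` short-circuits
    the calculation with a prescribed minimum distance (the conventional
    0.5 cM choice).
    """
    if override_cm is not None:
        return float(override_cm)
    if target is reference:
        raise ValueError("target and reference must be distinct panels")
    edges = np.arange(0.0, max_d + bin_cm / 2, bin_cm)
    unit, unit_labels = _jackknife_units(target)
    U, B = len(unit_labels), edges.size - 1
    sums = np.zeros((U, B))
    counts = np.zeros((U, B))
    nt, nr = target.n_hap, reference.n_hap
    for c in target.chromosomes:
        sel = target.sites_on(c)
        Xt = target.haps[:, sel].astype(np.float64)
        Xr = reference.haps[:, sel].astype(np.float64)
        Dt = ((Xt - Xt.mean(0)).T @ (Xt - Xt.mean(0))) / max(nt - 1, 1)
        Dr = ((Xr - Xr.mean(0)).T @ (Xr - Xr.mean(0))) / max(nr - 1, 1)
        _pair_accumulate(
            Dt, Dr, target.cm[sel], unit[sel], edges, sums, counts
        )
    curve = WeightedLDCurve(edges, sums, counts, unit_labels, mode="ld-share")
    vals, ses = curve.values(), curve.bin_se()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(vals) / ses
    # shared LD is contiguous from zero distance: take the initial run of
    # significant bins (an isolated far excursion is bin noise)
    sig = np.nan_to_num(z) >= z_threshold
    run_end = 0
    while run_end < sig.size and sig[run_end]:
        run_end += 1
    return float(edges[max(run_end, 1)])


@dataclass
class ExponentialFit:
    """Multi-exponential fit y(d) = sum_k C_k exp(-n_k d) + c (d in
    Morgans, bins in cM)."""

    amplitudes: np.ndarray
    rates: np.ndarray  # generations
    intercept: float
    se_amplitudes: np.ndarray
    se_rates: np.ndarray
    significant: np.ndarray  # bool per event
    n_units: int

    @property
    def n_events(self) -> int:
        return int(self.significant.sum())

    def sorted_events(self):
        """(rate, amplitude, se_rate, se_amplitude) of significant events,
        youngest first."""
        idx = np.argsort(self.rates)
        idx = [i for i in idx if self.significant[i]]
        return [
            (self.rates[i], self.amplitudes[i],
             self.se_rates[i], self.se_amplitudes[i])
            for i in idx
        ]


def _fit_exp_sum(d_cm, y, wgt, k, rate_bounds=(0.5, 400.0)):
    """Weighted LS fit of k exponentials + affine intercept; multistart on
    rates.  Returns (amplitudes, rates, intercept, cost)."""
    d = d_cm / 100.0
    wroot = np.sqrt(wgt / wgt.mean()) if wgt is not None else np.ones_like(y)
    span = y[: max(3, y.size // 20)].mean() - y[-max(3, y.size // 20):].mean()

    def model(p):
        amps, rates, c0 = p[:k], p[k: 2 * k], p[-1]
        return (amps[None, :] * np.exp(-np.outer(d, rates))).sum(1) + c0

    def resid(p):
        return (model(p) - y) * wroot

    starts: list[np.ndarray] = []
    grid = [2.0, 8.0, 25.0, 60.0, 150.0]
    if k == 1:
        for r in grid:
            starts.append(np.array([span, r, y[-1]]))
    else:
        for i, r1 in enumerate(grid):
            for r2 in grid[i + 1:]:
                starts.append(
                    np.array([span / 2, span / 2, r1, r2, y[-1]])
                )
    best = None
    lo = np.concatenate([np.full(k, -np.inf), np.full(k, rate_bounds[0]), [-np.inf]])
    hi = np.concatenate([np.full(k, np.inf), np.full(k, rate_bounds[1]), [np.inf]])
    for p0 in starts:
        p0c = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(resid, p0c, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    p = best.x
    order = np.argsort(p[k: 2 * k])
    return p[:k][order], p[k: 2 * k][order], float(p[-1]), float(best.cost)


def fit_admixture_exponentials(
    curve: WeightedLDCurve,
    max_events: int = 2,
    z_accept: float = 2.0,
    min_count: int = 1,
) -> ExponentialFit:
    """Fit one or more exponentials to a weighted-LD curve.

    Model order grows while each added exponential's amplitude passes a
    jackknife Z > ``z_accept`` test (all amplitudes must remain
    significant).  SEs come from delete-one-unit refits.
    """
    d = curve.centers
    cnt = curve.pair_counts
    ok = np.isfinite(curve.values()) & (cnt >= min_count)
    if ok.sum() < 2 * max_events + 2:
        raise ValueError("not enough usable bins to fit the requested model")

    chosen = None
    for k in range(1, max_events + 1):
        y = curve.values()[ok]
        amps, rates, c0, _ = _fit_exp_sum(d[ok], y, cnt[ok], k)
        # jackknife over units
        U = curve.n_units
        jack = np.empty((U, 2 * k))
        for u in range(U):
            yu = curve.values(exclude_unit=u)
            oku = ok & np.isfinite(yu)
            a_u, r_u, _, _ = _fit_exp_sum(d[oku], yu[oku], cnt[oku], k)
            jack[u] = np.concatenate([a_u, r_u])
        se = np.sqrt((U - 1) / U * np.sum((jack - jack.mean(0)) ** 2, 0))
        se_a, se_r = se[:k], se[k:]
        with np.errstate(divide="ignore"):
            zs = np.abs(amps) / np.where(se_a > 0, se_a, np.inf)
        sig = zs > z_accept
        fit = ExponentialFit(
            amplitudes=amps, rates=rates, intercept=c0,
            se_amplitudes=se_a, se_rates=se_r,
            significant=sig, n_units=U,
        )
        if k == 1:
            chosen = fit
            if not sig.all():
                break
        else:
            if sig.all():
                chosen = fit
            else:
                break
    return chosen


def curve_amplitude_zscore(c1: float, se1: float, c2: float, se2: float) -> float:
    """Z = (C1 - C2) / sqrt(se1^2 + se2^2) for comparing curve amplitudes."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("amplitude SEs must be positive for a Z comparison")
    return float((c1 - c2) / np.hypot(se1, se2))


@dataclass
class SourceAssignment:
    """Ancestry-region attribution of a dated admixture signal."""

    best_pair: tuple
    best_region_pair: tuple
    source1_regions: list
    source2_regions: list
    major_regions: list
    zscores: dict


def assign_event_sources(
    amplitudes: dict,
    region_of_pop: dict,
    z_threshold: float = 2.0,
) -> SourceAssignment:
    """Attribute an admixture signal to ancestry regions.

    ``amplitudes`` maps reference population pairs (popA, popB) to
    ``(amplitude, se, significant)`` from per-pair curve fits.  The best
    pair is the significant curve with the largest amplitude.  For each
    side of the best pair, competing regions whose best substituted curve
    is within Z < ``z_threshold`` of the maximum join that side's source
    set.  The major ancestry is any region r of the best pair for which
    the best curve containing r beats the best curve excluding r at
    Z > ``z_threshold`` (possibly neither).
    """
    sig = {
        pair: (c, se) for pair, (c, se, s) in amplitudes.items() if s
    }
    if not sig:
        raise ValueError("no significant curves to assign sources from")
    best_pair = max(sig, key=lambda p: sig[p][0])
    r1, r2 = (region_of_pop[best_pair[0]], region_of_pop[best_pair[1]])
    c_best, se_best = sig[best_pair]

    def region_pair(pair):
        return frozenset(
            (region_of_pop[pair[0]], region_of_pop[pair[1]])
        ) if region_of_pop[pair[0]] != region_of_pop[pair[1]] else frozenset(
            {region_of_pop[pair[0]]}
        )

    def best_of(pred):
        cands = [(c, se) for pair, (c, se) in sig.items() if pred(pair)]
        if not cands:
            return None
        return max(cands, key=lambda t: t[0])

    zscores: dict = {}
    source_sets = []
    all_regions = sorted(set(region_of_pop.values()))
    for keep, other in ((r1, r2), (r2, r1)):
        members = [keep]
        for m in all_regions:
            if m in (keep, other):
                continue
            sub = best_of(
                lambda pair, m=m, other=other: region_pair(pair)
                == (frozenset({m, other}) if m != other else frozenset({m}))
            )
            if sub is None:
                continue
            z = curve_amplitude_zscore(c_best, se_best, sub[0], sub[1])
            zscores[(keep, other, m)] = z
            if z < z_threshold:
                members.append(m)
        source_sets.append(members)

    major = []
    for r in {r1, r2}:
        with_r = best_of(lambda pair, r=r: r in region_pair(pair))
        without_r = best_of(lambda pair, r=r: r not in region_pair(pair))
        if with_r is None or without_r is None:
            continue
        z = curve_amplitude_zscore(with_r[0], with_r[1], without_r[0], without_r[1])
        zscores[("major", r)] = z
        if z > z_threshold:
            major.append(r)

    return SourceAssignment(
        best_pair=best_pair,
        best_region_pair=(r1, r2),
        source1_regions=source_sets[0],
        source2_regions=source_sets[1],
        major_regions=sorted(major),
        zscores=zscores,
    )
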