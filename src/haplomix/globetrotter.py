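"""Haplotype-based admixture inference from painted chromosomes.

The pipeline characterises admixture in a recipient group from its painted
chunk mosaics:

1. the recipient group's copying vector is modelled as a non-negative
   mixture of surrogate groups' copying vectors (NNLS, coefficients >= 0
   summing to 1; coefficients below 0.001 dropped and the rest rescaled);
2. coancestry curves tabulate, for every pair of surrogate groups, the
   relative probability that two chunks at genetic distance g cM are
   copied from that pair, within and between painting samples of the same
   haploid (optionally pooled across an individual's two haploids to
   absorb phasing switch errors); after admixture these curves relax
   exponentially toward independence (ratio 1) at rate lambda =
   generations since admixture;
3. one or two shared-rate exponentials are fitted to all curves jointly;
   the per-curve exponential coefficients form a matrix which, for a
   single two-source event, is approximately rank one with structure
   alpha(1-alpha) (beta1 - beta2)(beta1 - beta2)^T;
4. an eigendecomposition of that matrix plus a grid search over the
   admixture proportion alpha in (0, 0.5] recovers the two source
   compositions as simplex vectors over surrogates;
5. the mixture coefficients are re-estimated from the decomposition and
   steps 2-4 iterate;
6. a "null" renormalisation (curves rebuilt from chunk pairs of
   *different* individuals, capturing the background chunk distribution)
   removes LD not attributable to admixture; dates are re-fitted on the
   normalised curves and bootstrapped across chromosomes for confidence
   intervals and an empirical p-value (the fraction of bootstrap dates at
   the search bounds, <=1 or >=400 generations);
7. the event is classified as one of: no admixture, uncertain, one date,
   multiple dates, or one date multiway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize, minimize_scalar, nnls

from .painting import PaintingResult

__all__ = [
    "MixtureFit",
    "CoancestryCurveSet",
    "AdmixtureEvent",
    "fit_mixture_model",
    "build_coancestry_curves",
    "build_null_curves",
    "fit_coancestry_dates",
    "decompose_admixture_sources",
    "run_globetrotter",
    "classify_event",
    "run_restricted_surrogates",
    "apply_region_rules",
]

LAMBDA_MIN = 1.0
LAMBDA_MAX = 400.0


# ---------------------------------------------------------------- mixture

@dataclass
class MixtureFit:
    """NNLS description of a copying vector as a mixture of surrogates."""

    surrogates: list
    beta: np.ndarray
    residual: float
    dropped: list


def fit_mixture_model(
    recipient_vector: np.ndarray,
    surrogate_vectors: np.ndarray,
    surrogates: list,
    beta_min: float = 0.001,
) -> MixtureFit:
    """Fit f^k = sum_l beta_l f^l with beta >= 0, sum beta = 1.

    ``surrogate_vectors`` is (n_surrogates, n_donor_groups); the recipient
    and all surrogate vectors must already have self-copy entries zeroed
    and be renormalised.  Coefficients below ``beta_min`` are excluded and
    the remainder rescaled to sum to 1.
    """
    F = np.asarray(surrogate_vectors, dtype=float)
    f = np.asarray(recipient_vector, dtype=float)
    if F.shape[0] < 2:
        raise ValueError("mixture model needs at least 2 surrogates")
    if F.shape[1] != f.size:
        raise ValueError("surrogate vectors do not match the recipient vector")
    # sum-to-one via a heavily weighted augmented row
    lam = 1000.0
    A = np.vstack([F.T, lam * np.ones(F.shape[0])])
    b = np.concatenate([f, [lam]])
    beta, rnorm = nnls(A, b)
    dropped = [s for s, v in zip(surrogates, beta) if v < beta_min]
    beta = np.where(beta < beta_min, 0.0, beta)
    if beta.sum() == 0:
        raise ValueError("all mixture coefficients fell below the threshold")
    beta = beta / beta.sum()
    resid = float(np.linalg.norm(F.T @ beta - f))
    return MixtureFit(
        surrogates=list(surrogates), beta=beta, residual=resid, dropped=dropped
    )


# ------------------------------------------------------------- coancestry

@dataclass
class CoancestryCurveSet:
    """Binned chunk-pair counts per surrogate-group pair.

    ``counts[u, k, b, a, a2]`` counts ordered chunk pairs (both orders of
    each unordered pair are recorded) for recipient unit u (a haploid or
    individual, depending on the pairing mode) in genome block k in
    distance bin b with the two chunks copied from groups a and a2.
    ``expected`` is the matching independence expectation tot(u, k, b) *
    f_a * f_a2 from the pooled genome-wide chunk shares f; composition
    heterogeneity between recipients then appears as a flat offset in the
    ratio, which the date fit's per-curve intercept absorbs.  The
    observed curve is counts / expected and relaxes to a constant at
    large g.  Keeping both the unit and chromosome axes lets the
    bootstrap resample recipients and genome blocks jointly.
    """

    edges: np.ndarray
    groups: list
    counts: np.ndarray  # (n_units, n_blocks, B, G, G)
    expected: np.ndarray  # (n_units, n_blocks, B, G, G)
    f: np.ndarray  # pooled genome-wide chunk share per group

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def ratio(self, block_weights=None, unit_weights=None):
        """(ratio (B, G, G), total pair count per bin (B,)), optionally
        with genome-block / recipient-unit resampling weights."""
        cw = (
            np.ones(self.counts.shape[1])
            if block_weights is None
            else np.asarray(block_weights, dtype=float)
        )
        uw = (
            np.ones(self.counts.shape[0])
            if unit_weights is None
            else np.asarray(unit_weights, dtype=float)
        )
        cnt = np.einsum("u,c,ucbij->bij", uw, cw, self.counts)
        exp_ = np.einsum("u,c,ucbij->bij", uw, cw, self.expected)
        tot = cnt.sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(exp_ > 0, cnt / np.maximum(exp_, 1e-300), np.nan)
        return r, tot

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[1]

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]


MIN_BOOT_BLOCKS = 8


def _block_assigner(chrom_mid_pairs, n_chrom):
    """Partition the genome into >= MIN_BOOT_BLOCKS equal-cM blocks
    (whole chromosomes, subdivided when there are few) for block
    bootstrapping.  Returns (assign(chrom, mid) -> block, n_blocks)."""
    bpc = max(1, int(np.ceil(MIN_BOOT_BLOCKS / max(n_chrom, 1))))
    lo = np.full(n_chrom, np.inf)
    hi = np.full(n_chrom, -np.inf)
    for chrom, mid in chrom_mid_pairs:
        for c in range(n_chrom):
            sel = chrom == c
            if sel.any():
                lo[c] = min(lo[c], mid[sel].min())
                hi[c] = max(hi[c], mid[sel].max())
    span = np.where(hi > lo, hi - lo, 1.0)

    def assign(chrom, mid):
        frac = (mid - lo[chrom]) / span[chrom]
        sub = np.clip((frac * bpc).astype(np.int64), 0, bpc - 1)
        return chrom * bpc + sub

    return assign, n_chrom * bpc


def _chunk_arrays(res: PaintingResult, site_cm: np.ndarray):
    """Per painting sample: (chrom_idx, mid_cm, donor) arrays."""
    out = []
    for chunks in res.mosaics:
        mid = 0.5 * (site_cm[chunks[:, 1]] + site_cm[chunks[:, 2] - 1])
        out.append((chunks[:, 0], mid, chunks[:, 3]))
    return out


@njit(cache=True)
def _pair_kernel(counts, pair_tot, bin_cm, B, mid1, grp1, blk1,
                 mid2, grp2, blk2, cross):
    """Sorted two-pointer pair accumulation for one chromosome.

    ``mid1``/``mid2`` must be ascending.  Within mode (cross=False)
    counts unordered pairs of one set once; cross mode counts all pairs
    between the two sets.  Both orders are recorded; a pair is filed
    under its first chunk's genome block."""
    max_d = B * bin_cm
    n1, n2 = mid1.size, mid2.size
    j_lo = 0
    for i in range(n1):
        j = i + 1 if not cross else j_lo
        if cross:
            while j < n2 and mid2[j] < mid1[i] - max_d:
                j += 1
            j_lo = j
        while j < n2 and mid2[j] - mid1[i] < max_d:
            d = mid2[j] - mid1[i]
            if d < 0:
                d = -d
            b = int(d / bin_cm)
            if b < B:
                counts[blk1[i], b, grp1[i], grp2[j]] += 1
                counts[blk1[i], b, grp2[j], grp1[i]] += 1
                pair_tot[blk1[i], b] += 2
            j += 1


def _accumulate_pairs(counts, pair_tot, edges, G, chrom1, mid1, grp1,
                      chrom2=None, mid2=None, grp2=None,
                      block1=None, block2=None):
    """Add chunk-pair counts.  With one chunk set, all unordered pairs
    within it; with two, all cross pairs.  Same-chromosome pairs only.
    Both orders of each pair are recorded; ``pair_tot`` (n_blocks, B)
    accumulates the per-bin totals of this call.  ``block*`` give the
    genome-block index each chunk's pairs are filed under (defaults to
    the chromosome index); a pair belongs to its first chunk's block."""
    B = edges.size - 1
    bin_cm = float(edges[1] - edges[0])
    cross = chrom2 is not None
    if not cross:
        chrom2, mid2, grp2 = chrom1, mid1, grp1
        block2 = block1
    if block1 is None:
        block1 = chrom1
    if block2 is None:
        block2 = chrom2
    for c in np.unique(chrom1):
        s1 = np.flatnonzero(chrom1 == c)
        s2 = np.flatnonzero(chrom2 == c)
        if s1.size == 0 or s2.size == 0:
            continue
        o1 = s1[np.argsort(mid1[s1], kind="stable")]
        m1 = np.ascontiguousarray(mid1[o1], dtype=np.float64)
        g1 = np.ascontiguousarray(grp1[o1], dtype=np.int64)
        b1 = np.ascontiguousarray(np.asarray(block1)[o1], dtype=np.int64)
        if cross:
            o2 = s2[np.argsort(mid2[s2], kind="stable")]
            m2 = np.ascontiguousarray(mid2[o2], dtype=np.float64)
            g2 = np.ascontiguousarray(grp2[o2], dtype=np.int64)
            b2 = np.ascontiguousarray(np.asarray(block2)[o2], dtype=np.int64)
        else:
            m2, g2, b2 = m1, g1, b1
        _pair_kernel(counts, pair_tot, bin_cm, B, m1, g1, b1, m2, g2, b2,
                     cross)


def build_coancestry_curves(
    paintings: list[PaintingResult],
    donor_group_idx: np.ndarray,
    site_cm: np.ndarray,
    groups: list,
    bin_cm: float = 0.1,
    max_g: float = 50.0,
    n_chrom: int | None = None,
    phasing_mode: str = "haploid",
) -> CoancestryCurveSet:
    """Observed coancestry curves for a recipient group.

    ``paintings`` holds one PaintingResult per recipient haploid in
    haploid order (two consecutive entries per individual); each must
    carry >= 2 sampled mosaics.  ``donor_group_idx`` maps each donor
    haploid to its surrogate-group index in ``groups``.

    ``phasing_mode`` controls chunk pairing: ``"haploid"`` pairs chunks
    within and between painting samples of the same haploid only (best
    for reliably phased data — pairs across a diploid's two haploids
    carry no coancestry signal, only composition noise); ``"pooled"``
    additionally pairs across the individual's two haploids, which makes
    the curves robust to phasing switch errors at some cost in noise.
    """
    if any(len(p.mosaics) < 2 for p in paintings):
        raise ValueError(
            "coancestry curves need at least 2 painting samples per haploid"
        )
    if phasing_mode not in ("haploid", "pooled"):
        raise ValueError("phasing_mode must be 'haploid' or 'pooled'")
    donor_group_idx = np.asarray(donor_group_idx)
    G = len(groups)
    edges = np.arange(0.0, max_g + bin_cm / 2, bin_cm)
    B = edges.size - 1
    if n_chrom is None:
        n_chrom = len(paintings[0].chrom_labels)
    if phasing_mode == "pooled":
        units = [
            (2 * i, 2 * i + 1) for i in range(len(paintings) // 2)
        ]
    else:
        units = [(h,) for h in range(len(paintings))]
    U = len(units)
    per_unit = []
    for unit in units:
        chs, mids, grps = [], [], []
        for h in unit:
            for ch, mid, donor in _chunk_arrays(paintings[h], site_cm):
                chs.append(ch)
                mids.append(mid)
                grps.append(donor_group_idx[donor])
        per_unit.append(
            (np.concatenate(chs), np.concatenate(mids), np.concatenate(grps))
        )
    assign, n_blocks = _block_assigner(
        [(c, m) for c, m, _ in per_unit], n_chrom
    )
    counts = np.zeros((U, n_blocks, B, G, G))
    pair_tot = np.zeros((U, n_blocks, B))
    f_acc = np.zeros(G)
    for u, (chrom, mid, grp) in enumerate(per_unit):
        f_acc += np.bincount(grp, minlength=G)
        _accumulate_pairs(
            counts[u], pair_tot[u], edges, G, chrom, mid, grp,
            block1=assign(chrom, mid),
        )
    f = f_acc / f_acc.sum()
    # pooled-share expectation; individual-level composition heterogeneity
    # shows up as a flat offset that the date fit's intercept absorbs
    expected = pair_tot[:, :, :, None, None] * np.outer(f, f)[None, None, None]
    return CoancestryCurveSet(
        edges=edges, groups=list(groups), counts=counts, expected=expected, f=f
    )


def build_null_curves(
    paintings: list[PaintingResult],
    donor_group_idx: np.ndarray,
    site_cm: np.ndarray,
    groups: list,
    bin_cm: float = 0.1,
    max_g: float = 50.0,
    n_chrom: int | None = None,
) -> CoancestryCurveSet:
    """Background ("null") curves from cross-individual chunk pairs.

    Pairing chunks drawn from different individuals' paintings destroys
    within-genome admixture LD while keeping the marginal chunk
    distribution, so dividing observed curves by these removes signal not
    attributable to admixture.
    """
    n_ind = len(paintings) // 2
    if n_ind < 2:
        raise ValueError("the null procedure needs at least 2 individuals")
    donor_group_idx = np.asarray(donor_group_idx)
    G = len(groups)
    edges = np.arange(0.0, max_g + bin_cm / 2, bin_cm)
    B = edges.size - 1
    if n_chrom is None:
        n_chrom = len(paintings[0].chrom_labels)
    f_acc = np.zeros(G)
    per_ind = []
    for i in range(n_ind):
        samples = []
        for h in (2 * i, 2 * i + 1):
            for ch, mid, donor in _chunk_arrays(paintings[h], site_cm):
                g = donor_group_idx[donor]
                samples.append((ch, mid, g))
                f_acc += np.bincount(g, minlength=G)
        per_ind.append(samples)
    assign, n_blocks = _block_assigner(
        [(ch, m) for samples in per_ind for ch, m, _ in samples], n_chrom
    )
    counts = np.zeros((n_ind, n_blocks, B, G, G))
    pair_tot = np.zeros((n_ind, n_blocks, B))
    for i in range(n_ind):
        j = (i + 1) % n_ind
        for (ch1, m1, g1), (ch2, m2, g2) in zip(per_ind[i], per_ind[j]):
            _accumulate_pairs(
                counts[i], pair_tot[i], edges, G, ch1, m1, g1, ch2, m2, g2,
                block1=assign(ch1, m1), block2=assign(ch2, m2),
            )
    f = f_acc / f_acc.sum()
    expected = pair_tot[:, :, :, None, None] * np.outer(f, f)[None, None, None]
    return CoancestryCurveSet(
        edges=edges, groups=list(groups), counts=counts, expected=expected, f=f
    )


# ------------------------------------------------------------- date fits

def _curve_stack(ratio: np.ndarray, tot: np.ndarray, centers, min_g, max_g):
    """Flatten the symmetric (B, G, G) ratio into per-curve responses for
    pairs a <= b, restricted to usable bins."""
    B, G, _ = ratio.shape
    ok = (centers >= min_g) & (centers <= max_g) & (tot > 0)
    pairs = [(a, b) for a in range(G) for b in range(a, G)]
    Y = np.stack([ratio[:, a, b] for a, b in pairs], axis=1)[ok]
    finite = np.all(np.isfinite(Y), axis=1)
    return Y[finite], centers[ok][finite], tot[ok][finite], pairs


INTERCEPT_BOUNDS = (0.7, 1.3)


def _shared_rate_ssr(Y, g_cm, w, lambdas, curve_w=None):
    """Weighted per-curve linear fits with shared exponential rate(s).

    ``w`` weights bins (pair counts); ``curve_w`` optionally weights
    curves (inverse residual variance).  The responses are coancestry
    *ratio* curves, whose asymptote is near 1 by construction, so the
    per-curve intercept is constrained to INTERCEPT_BOUNDS: without the
    constraint a near-linear noisy curve can be fit equally well by a
    very slow exponential riding on a large negative intercept, which
    makes the rate unidentifiable.  Returns (ssr_total, coef
    (n_curves, 1+k), r2 per curve)."""
    d = g_cm / 100.0
    X = np.column_stack(
        [np.ones_like(d)] + [np.exp(-lam * d) for lam in lambdas]
    )
    sw = np.sqrt(w / w.mean())
    Xw = X * sw[:, None]
    Yw = Y * sw[:, None]
    coef, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    lo, hi = INTERCEPT_BOUNDS
    off = np.where(coef[0] < lo, lo, np.where(coef[0] > hi, hi, np.nan))
    bad = np.flatnonzero(np.isfinite(off))
    if bad.size:
        # clamp the intercept and refit the exponential coefficients
        Xe = Xw[:, 1:]
        sol, _, _, _ = np.linalg.lstsq(
            Xe, Yw[:, bad] - np.outer(Xw[:, 0], off[bad]), rcond=None
        )
        coef[0, bad] = off[bad]
        coef[1:, bad] = sol
    resid = Yw - Xw @ coef
    ssr = np.sum(resid**2, axis=0)
    ybar = np.sum(Yw * sw[:, None], axis=0) / np.sum(sw)
    sst = np.sum((Yw - ybar[None, :] * sw[:, None]) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1 - ssr / sst, 0.0)
    if curve_w is None:
        total = float(ssr.sum())
    else:
        total = float(np.dot(ssr, curve_w))
    return total, coef.T, r2


def _optimise_lambdas(Y, g_cm, w, n_dates, curve_w=None):
    """Grid search plus local refinement of the shared rate(s)."""
    grid = np.exp(np.linspace(np.log(LAMBDA_MIN), np.log(LAMBDA_MAX), 40))
    if n_dates == 1:
        ssrs = [_shared_rate_ssr(Y, g_cm, w, [lam], curve_w)[0] for lam in grid]
        lam0 = grid[int(np.argmin(ssrs))]
        res = minimize_scalar(
            lambda L: _shared_rate_ssr(Y, g_cm, w, [L], curve_w)[0],
            bounds=(max(LAMBDA_MIN, lam0 / 3), min(LAMBDA_MAX, lam0 * 3)),
            method="bounded",
        )
        return [float(res.x)]
    best = None
    sub = grid[::2]
    for i, l1 in enumerate(sub):
        for l2 in sub[i + 1:]:
            s = _shared_rate_ssr(Y, g_cm, w, [l1, l2], curve_w)[0]
            if best is None or s < best[0]:
                best = (s, l1, l2)
    res = minimize(
        lambda p: _shared_rate_ssr(Y, g_cm, w, list(np.exp(p)), curve_w)[0],
        np.log([best[1], best[2]]),
        method="Nelder-Mead",
    )
    return sorted(
        float(np.clip(np.exp(v), LAMBDA_MIN, LAMBDA_MAX)) for v in res.x
    )


def _fit_lambdas_gls(Y, g_cm, w, n_dates):
    """Two-pass fit: initial equal-curve-weight rates, then rates refit
    with curves weighted by inverse residual variance, so flat
    uninformative curves do not dilute the shared-rate estimate."""
    lam0 = _optimise_lambdas(Y, g_cm, w, n_dates)
    ssr_tot, coef, _ = _shared_rate_ssr(Y, g_cm, w, lam0)
    d = g_cm / 100.0
    X = np.column_stack([np.ones_like(d)] + [np.exp(-l * d) for l in lam0])
    sw = np.sqrt(w / w.mean())
    resid = (Y - X @ coef.T) * sw[:, None]
    var = np.maximum(np.mean(resid**2, axis=0), 1e-12)
    curve_w = (1.0 / var) / np.mean(1.0 / var)
    return _optimise_lambdas(Y, g_cm, w, n_dates, curve_w)


def fit_coancestry_dates(
    curves: CoancestryCurveSet,
    n_dates: int = 1,
    min_g: float = 1.0,
    max_g: float = 50.0,
    block_weights=None,
) -> dict:
    """MLE of shared exponential rate(s) across all coancestry curves.

    Returns a dict with ``lambdas`` (generations, ascending), per-date
    coefficient matrices (G, G), per-curve R^2 under the fitted model,
    ``max_r1`` (best single-date R^2), and a bound flag when the rate
    search hits 1 or 400 generations.
    """
    ratio, tot = curves.ratio(block_weights)
    Y, g_cm, w, pairs = _curve_stack(ratio, tot, curves.centers, min_g, max_g)
    if Y.shape[0] < 4 + n_dates:
        raise ValueError("not enough usable coancestry bins to fit dates")
    lambdas = _fit_lambdas_gls(Y, g_cm, w, n_dates)
    _, coef, r2 = _shared_rate_ssr(Y, g_cm, w, lambdas)
    # single-date R^2 for max(R1) regardless of requested order
    _, _, r2_one = _shared_rate_ssr(Y, g_cm, w, lambdas[:1])

    G = len(curves.groups)
    mats = []
    for k in range(len(lambdas)):
        m = np.zeros((G, G))
        for (a, b), row in zip(pairs, coef):
            m[a, b] = m[b, a] = row[1 + k]
        mats.append(m)
    at_bound = any(
        lam <= LAMBDA_MIN * 1.001 or lam >= LAMBDA_MAX * 0.999 for lam in lambdas
    )
    return {
        "lambdas": lambdas,
        "coef_matrices": mats,
        "r2": r2,
        "r2_one": r2_one,
        "max_r1": float(np.max(r2_one)),
        "pairs": pairs,
        "at_bound": at_bound,
    }


# ---------------------------------------------------------- decomposition

def decompose_admixture_sources(
    coef_matrix: np.ndarray,
    mixture_beta: np.ndarray,
    alpha_grid: np.ndarray | None = None,
) -> dict:
    """Recover (alpha, source compositions) from a date's coefficient
    matrix.

    For a single two-source event the matrix has structure
    alpha(1-alpha) * delta delta^T with delta = beta_source1 -
    beta_source2; the leading eigenvector gives the source contrast and a
    grid search over alpha in (0, 0.5] picks the proportion whose implied
    sources are closest to valid simplex vectors reproducing the mixture
    coefficients.  Returns alpha, source1/source2 (minor first), FQ1, FQ2
    (variance fractions of one/two leading components) and a degeneracy
    flag.
    """
    A = np.asarray(coef_matrix, dtype=float)
    A = 0.5 * (A + A.T)
    if not np.any(A):
        raise ValueError("all-zero coefficient matrix")
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(np.abs(evals))[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tot = float(np.sum(evals**2))
    fq1 = float(evals[0] ** 2 / tot)
    fq2 = float((evals[0] ** 2 + evals[1] ** 2) / tot) if evals.size > 1 else 1.0
    lead = abs(float(evals[0]))
    u = evecs[:, 0]
    beta = np.asarray(mixture_beta, dtype=float)

    degenerate = lead < 1e-12
    if alpha_grid is None:
        alpha_grid = np.linspace(0.01, 0.5, 50)
    best = None
    for sign in (1.0, -1.0):
        for alpha in alpha_grid:
            t = np.sqrt(lead / (alpha * (1 - alpha)))
            s1 = beta + (1 - alpha) * t * sign * u
            s2 = beta - alpha * t * sign * u
            clip_pen = float(np.sum(np.clip(-s1, 0, None)) + np.sum(np.clip(-s2, 0, None)))
            s1c = np.clip(s1, 0, None)
            s2c = np.clip(s2, 0, None)
            if s1c.sum() == 0 or s2c.sum() == 0:
                continue
            s1c = s1c / s1c.sum()
            s2c = s2c / s2c.sum()
            err = float(
                np.abs(beta - (alpha * s1c + (1 - alpha) * s2c)).sum()
            ) + clip_pen
            if best is None or err < best[0]:
                best = (err, alpha, s1c, s2c)
    _, alpha, s1, s2 = best
    return {
        "alpha": float(alpha),
        "source1": s1,  # minor source (weight alpha)
        "source2": s2,
        "fq1": fq1,
        "fq2": fq2,
        "degenerate": bool(degenerate),
        "recon_error": best[0],
    }


# ---------------------------------------------------------------- events

@dataclass
class AdmixtureEvent:
    """A characterised admixture event for one recipient group."""

    classification: str
    dates: list  # generations, one per inferred date
    date_ci: list  # (lo, hi) 95% bootstrap percentile per date
    alpha: float
    sources: list  # per date: dict(source1=..., source2=..., alpha=...)
    metrics: dict  # max_r1, fq1, fq2, m
    p_value: float
    bootstrap_dates: list
    surrogates: list
    standardised: bool = False
    notes: list = field(default_factory=list)


def classify_event(
    metrics: dict,
    p_value: float,
    bootstrap_dates,
    p_threshold: float = 0.05,
    m_threshold: float = 0.35,
    multiway_threshold: float = 0.35,
    uncertain_width: float = 5.0,
    uncertain_bound_frac: float = 0.25,
    point_date: float | None = None,
) -> str:
    """Five-way event classification.

    no admixture (p above threshold) / uncertain (unstable bootstrap
    dates: a substantial fraction at the rate-search bounds, or an
    extremely dispersed interval) / multiple dates (two-date fit explains
    M > 0.35 more) / one date multiway (rank-2 structure in a single
    date: FQ2 - FQ1 large) / one date.
    """
    for k in ("max_r1", "fq1", "fq2", "m"):
        if k not in metrics:
            raise ValueError(f"missing metric {k!r}")
    if p_value >= p_threshold:
        return "no admixture"
    boot = np.asarray(list(bootstrap_dates), dtype=float)
    if boot.size:
        at_bound = np.mean(
            (boot <= LAMBDA_MIN * 1.001) | (boot >= LAMBDA_MAX * 0.999)
        )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        ref = point_date if point_date is not None else np.median(boot)
        if at_bound > uncertain_bound_frac or (
            ref > 0 and (hi - lo) / max(ref, 1.0) > uncertain_width
        ):
            return "uncertain"
    if metrics["m"] > m_threshold:
        return "multiple dates"
    if metrics["fq2"] - metrics["fq1"] >= multiway_threshold:
        return "one date, multiway"
    return "one date"


def _bootstrap_dates(curves, null_curves, n_dates, min_g, max_g, n_boot, rng,
                     resample_units=True):
    """Bootstrap dates by resampling genome blocks (and, by default,
    recipient units) with replacement."""
    C, U = curves.n_blocks, curves.n_units
    out = []
    for _ in range(n_boot):
        cw = np.bincount(rng.integers(0, C, size=C), minlength=C).astype(float)
        if resample_units:
            uw = np.bincount(
                rng.integers(0, U, size=U), minlength=U
            ).astype(float)
        else:
            uw = None
        try:
            fit = _fit_normalised(
                curves, null_curves, n_dates, min_g, max_g, cw, uw
            )
            out.append(fit["lambdas"])
        except (ValueError, np.linalg.LinAlgError):
            out.append([np.nan] * n_dates)
    return out


def _fit_normalised(curves, null_curves, n_dates, min_g, max_g,
                    block_weights=None, unit_weights=None):
    """Date fit on null-normalised curves (observed ratio / null ratio)."""
    robs, tot = curves.ratio(block_weights, unit_weights)
    rnull, _ = null_curves.ratio(block_weights)
    with np.errstate(invalid="ignore", divide="ignore"):
        rnorm = np.where(
            np.isfinite(rnull) & (rnull > 0), robs / rnull, np.nan
        )
    Y, g_cm, w, pairs = _curve_stack(
        rnorm, tot, curves.centers, min_g, max_g
    )
    if Y.shape[0] < 4 + n_dates:
        raise ValueError("not enough usable normalised bins")
    lambdas = _fit_lambdas_gls(Y, g_cm, w, n_dates)
    _, coef, r2 = _shared_rate_ssr(Y, g_cm, w, lambdas)
    _, _, r2_one = _shared_rate_ssr(Y, g_cm, w, lambdas[:1])
    G = len(curves.groups)
    mats = []
    for k in range(len(lambdas)):
        m = np.zeros((G, G))
        for (a, b), row in zip(pairs, coef):
            m[a, b] = m[b, a] = row[1 + k]
        mats.append(m)
    return {
        "lambdas": lambdas,
        "coef_matrices": mats,
        "r2": r2,
        "r2_one": r2_one,
        "max_r1": float(np.max(r2_one)),
        "m": float(np.max(r2 - r2_one)) if len(lambdas) > 1 else 0.0,
        "pairs": pairs,
    }


def run_globetrotter(
    paintings: list[PaintingResult],
    donor_group_idx: np.ndarray,
    site_cm: np.ndarray,
    groups: list,
    recipient_vector: np.ndarray,
    surrogate_vectors: np.ndarray,
    n_iter: int = 5,
    n_boot: int = 100,
    bin_cm: float = 0.1,
    min_g: float = 1.0,
    max_g: float = 50.0,
    p_threshold: float = 0.05,
    m_threshold: float = 0.35,
    multiway_threshold: float = 0.35,
    allowed_surrogates: list | None = None,
    seed: int | None = None,
) -> AdmixtureEvent:
    """Full admixture characterisation for one recipient group.

    ``groups`` are the surrogate/donor groups; ``recipient_vector`` and
    the rows of ``surrogate_vectors`` are copying vectors over those
    groups (self-copy already zeroed and renormalised).
    ``allowed_surrogates`` restricts the surrogate set used for mixture
    and source description (masked groups receive exactly zero weight in
    compositions); painting donors are unaffected.
    """
    rng = np.random.default_rng(seed)
    if len(paintings) < 4:
        raise ValueError("need at least 2 recipient diploids")
    groups = list(groups)
    allow = (
        np.ones(len(groups), dtype=bool)
        if allowed_surrogates is None
        else np.array([g in set(allowed_surrogates) for g in groups])
    )
    if allow.sum() < 2:
        raise ValueError("surrogate mask leaves fewer than 2 surrogates")

    curves = build_coancestry_curves(
        paintings, donor_group_idx, site_cm, groups, bin_cm=bin_cm, max_g=max_g
    )
    if curves.n_blocks < 2:
        raise ValueError("bootstrap needs at least 2 genome blocks")
    null_curves = build_null_curves(
        paintings, donor_group_idx, site_cm, groups, bin_cm=bin_cm, max_g=max_g
    )

    sur_idx = np.flatnonzero(allow)
    mix = fit_mixture_model(
        recipient_vector,
        surrogate_vectors[sur_idx],
        [groups[i] for i in sur_idx],
    )
    beta_full = np.zeros(len(groups))
    beta_full[sur_idx] = mix.beta

    def restrict(vec):
        v = np.where(allow, vec, 0.0)
        return v / v.sum() if v.sum() > 0 else v

    # iterate date fit + decomposition, re-estimating mixing coefficients
    fit1 = None
    decomp = None
    for _ in range(n_iter):
        fit1 = fit_coancestry_dates(curves, 1, min_g, max_g)
        decomp = decompose_admixture_sources(
            _mask_matrix(fit1["coef_matrices"][0], allow), beta_full
        )
        beta_full = restrict(
            decomp["alpha"] * decomp["source1"]
            + (1 - decomp["alpha"]) * decomp["source2"]
        )

    # null-normalised final fits (one and two dates) and metrics
    final1 = _fit_normalised(curves, null_curves, 1, min_g, max_g)
    try:
        final2 = _fit_normalised(curves, null_curves, 2, min_g, max_g)
        m_metric = final2["m"]
    except ValueError:
        final2 = None
        m_metric = 0.0

    decomp1 = decompose_admixture_sources(
        _mask_matrix(final1["coef_matrices"][0], allow), beta_full
    )
    metrics = {
        "max_r1": final1["max_r1"],
        "fq1": decomp1["fq1"],
        "fq2": decomp1["fq2"],
        "m": m_metric,
    }

    # chromosome-only bootstrap drives the empirical p-value (is there a
    # dated signal anywhere in the genome); the joint chromosome + unit
    # bootstrap drives the date confidence interval (how well located)
    boots_p = _bootstrap_dates(
        curves, null_curves, 1, min_g, max_g, n_boot, rng, resample_units=False
    )
    p_dates = np.array([b[0] for b in boots_p], dtype=float)
    pv = p_dates[np.isfinite(p_dates)]
    extreme = np.sum((pv <= LAMBDA_MIN * 1.001) | (pv >= LAMBDA_MAX * 0.999))
    p_value = float(
        (extreme + np.sum(~np.isfinite(p_dates))) / max(len(boots_p), 1)
    )
    boots = _bootstrap_dates(
        curves, null_curves, 1, min_g, max_g, n_boot, rng
    )
    boot_dates = np.array([b[0] for b in boots], dtype=float)
    valid = boot_dates[np.isfinite(boot_dates)]

    classification = classify_event(
        metrics, p_value, valid,
        p_threshold=p_threshold, m_threshold=m_threshold,
        multiway_threshold=multiway_threshold,
        point_date=final1["lambdas"][0],
    )

    if classification == "multiple dates" and final2 is not None:
        dates = final2["lambdas"]
        boots2 = _bootstrap_dates(
            curves, null_curves, 2, min_g, max_g, n_boot, rng
        )
        cis = []
        for k in range(2):
            bk = np.array([b[k] for b in boots2], dtype=float)
            bk = bk[np.isfinite(bk)]
            cis.append(tuple(np.percentile(bk, [2.5, 97.5])) if bk.size else (np.nan, np.nan))
        sources = []
        for k in range(2):
            dk = decompose_admixture_sources(
                _mask_matrix(final2["coef_matrices"][k], allow), beta_full
            )
            sources.append(
                {"alpha": dk["alpha"], "source1": dk["source1"],
                 "source2": dk["source2"]}
            )
        alpha = sources[0]["alpha"]
    else:
        dates = final1["lambdas"]
        cis = (
            [tuple(np.percentile(valid, [2.5, 97.5]))] if valid.size else [(np.nan, np.nan)]
        )
        sources = [
            {"alpha": decomp1["alpha"], "source1": decomp1["source1"],
             "source2": decomp1["source2"]}
        ]
        alpha = decomp1["alpha"]

    return AdmixtureEvent(
        classification=classification,
        dates=list(dates),
        date_ci=cis,
        alpha=float(alpha),
        sources=sources,
        metrics=metrics,
        p_value=p_value,
        bootstrap_dates=list(boot_dates),
        surrogates=groups,
        notes=(["rate search hit bounds"] if fit1 and fit1.get("at_bound") else []),
    )


def _mask_matrix(mat: np.ndarray, allow: np.ndarray) -> np.ndarray:
    out = np.array(mat, dtype=float)
    out[~allow, :] = 0.0
    out[:, ~allow] = 0.0
    return out


def run_restricted_surrogates(
    mask_spec: str,
    recipient_region: str,
    region_of_group: dict,
    groups: list,
    local_regions_extra: dict | None = None,
    **globetrotter_kwargs,
) -> AdmixtureEvent:
    """Re-run inference with a restricted surrogate set.

    ``mask_spec`` is one of ``no-local``, ``no-local-east-or-south``,
    ``no-local-or-west``, ``no-local-or-malawi`` (extra exclusions beyond
    the recipient's own region are resolved through
    ``local_regions_extra``, a mapping from mask_spec to a list of
    regions/groups to exclude).  Masked groups receive exactly zero weight
    in the inferred compositions.
    """
    local_regions_extra = local_regions_extra or {
        "no-local": [],
        "no-local-east-or-south": [
            "East Africa Niger-Congo", "South Africa Niger-Congo"
        ],
        "no-local-or-west": [
            "West Africa Niger-Congo", "Central West Africa Niger-Congo"
        ],
        "no-local-or-malawi": ["East Africa Niger-Congo", "Malawi"],
    }
    if mask_spec not in local_regions_extra:
        raise ValueError(f"unknown surrogate mask {mask_spec!r}")
    excluded_regions = {recipient_region} | set(local_regions_extra[mask_spec])
    allowed = [
        g for g in groups
        if region_of_group.get(g, g) not in excluded_regions
        and g not in excluded_regions
    ]
    if len(allowed) < 2:
        raise ValueError("surrogate mask leaves fewer than 2 surrogates")
    return run_globetrotter(
        groups=groups, allowed_surrogates=allowed, **globetrotter_kwargs
    )


def apply_region_rules(
    event: AdmixtureEvent,
    recipient_region: str,
    rules: dict | None = None,
) -> AdmixtureEvent:
    """Region-specific post-filters applied to a characterised event.

    ``rules`` maps a region name to a dict with optional keys
    ``collapse_two_dates: "older"`` (report only the older of two dates,
    the West African Niger-Congo convention) and ``standardise_null:
    True`` (mark the event as standardised by the null-individual run,
    the Southern African / Afroasiatic convention).  Regions without a
    rule pass through unchanged.
    """
    rules = rules or {}
    known = {"collapse_two_dates", "standardise_null"}
    for region, spec in rules.items():
        extra = set(spec) - known
        if extra:
            raise ValueError(f"unknown rule key(s) {sorted(extra)} for {region!r}")
    spec = rules.get(recipient_region)
    if spec is None:
        return event
    ev = AdmixtureEvent(
        classification=event.classification,
        dates=list(event.dates),
        date_ci=list(event.date_ci),
        alpha=event.alpha,
        sources=list(event.sources),
        metrics=dict(event.metrics),
        p_value=event.p_value,
        bootstrap_dates=list(event.bootstrap_dates),
        surrogates=list(event.surrogates),
        standardised=event.standardised,
        notes=list(event.notes),
    )
    if spec.get("collapse_two_dates") == "older" and len(ev.dates) == 2:
        older = int(np.argmax(ev.dates))
        ev.dates = [ev.dates[older]]
        ev.date_ci = [ev.date_ci[older]]
        ev.sources = [ev.sources[older]]
        ev.alpha = ev.sources[0]["alpha"]
        if ev.classification == "multiple dates":
            ev.classification = "one date"
        ev.notes.append("two dates collapsed to the older (regional rule)")
    if spec.get("standardise_null"):
        ev.standardised = True
        ev.notes.append("standardised by the null individual (regional rule)")
    return ev
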