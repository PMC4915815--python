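"""Chromosome painting under the Li & Stephens haplotype copying model.

Each recipient haploid is modelled as an imperfect mosaic of the donor
haplotypes: a hidden Markov chain whose states are donors, whose switch
probability between adjacent sites at genetic distance d Morgans is
1 - exp(-Ne * d) (the new donor drawn from the prior copying probabilities
pi, so a "switch" may return to the same donor), and whose emissions allow
miscopying with probability theta.  Forward–backward gives per-site copying
posteriors, expected chunk counts and expected copied lengths per donor;
stochastic traceback yields sampled chunk mosaics.  Expected copied lengths
for one haploid always sum to the chromosome's genetic length.

A "chunk" is a maximal run of consecutive sites copied from one donor
haplotype; chunk boundaries are counted only where the donor identity
actually changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

from .panel import HaplotypePanel

__all__ = [
    "PaintingParameters",
    "PaintingResult",
    "paint_haploid",
    "paint_panel",
    "estimate_painting_parameters",
    "summarise_copying_vectors",
    "build_chunkcount_matrix",
    "select_nonlocal_donors",
]

# data-scale defaults; EM refines them for any particular panel
DEFAULT_NE = 190.82
DEFAULT_THETA = 0.00045


@dataclass
class PaintingParameters:
    """Copying-model parameters: switch-rate scale Ne (per Morgan),
    miscopy probability theta, and prior copying probabilities pi."""

    ne: float = DEFAULT_NE
    theta: float = DEFAULT_THETA
    pi: np.ndarray | None = None  # per-donor prior; None = uniform

    def __post_init__(self) -> None:
        if not self.ne > 0:
            raise ValueError("Ne must be positive")
        if not (0 < self.theta < 0.5):
            raise ValueError("theta must lie in (0, 0.5)")
        if self.pi is not None:
            pi = np.asarray(self.pi, dtype=np.float64)
            if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
                raise ValueError("pi must be a probability vector")
            self.pi = pi / pi.sum()


@njit(cache=True)
def _forward_backward(donors, rec, a, pi, theta):
    """Scaled forward-backward for one chromosome.

    donors: (D, T) uint8; rec: (T,) uint8; a: (T,) stay probabilities
    (a[0] unused); pi: (D,) prior.  Returns (gamma, alpha, scale, loglik,
    exp_switch, exp_newchunk, mismatch_exp) where exp_newchunk[t, j] sums
    into per-donor expected chunk starts.
    """
    D, T = donors.shape
    alpha = np.empty((T, D))
    scale = np.empty(T)
    # emissions on the fly
    e = np.empty(D)
    for j in range(D):
        e[j] = (1.0 - theta) if donors[j, 0] == rec[0] else theta
    s = 0.0
    for j in range(D):
        alpha[0, j] = pi[j] * e[j]
        s += alpha[0, j]
    scale[0] = s
    for j in range(D):
        alpha[0, j] /= s
    for t in range(1, T):
        at = a[t]
        for j in range(D):
            e[j] = (1.0 - theta) if donors[j, t] == rec[t] else theta
        s = 0.0
        for j in range(D):
            alpha[t, j] = (at * alpha[t - 1, j] + (1.0 - at) * pi[j]) * e[j]
            s += alpha[t, j]
        scale[t] = s
        for j in range(D):
            alpha[t, j] /= s

    gamma = np.empty((T, D))
    beta = np.ones(D)
    for j in range(D):
        gamma[T - 1, j] = alpha[T - 1, j]
    chunk_counts = np.zeros(D)
    exp_switch = np.zeros(T)
    mismatch = 0.0
    for j in range(D):
        if donors[j, T - 1] != rec[T - 1]:
            mismatch += gamma[T - 1, j]
    for t in range(T - 1, 0, -1):
        at = a[t]
        for j in range(D):
            e[j] = (1.0 - theta) if donors[j, t] == rec[t] else theta
        # joint transition expectations use alpha[t-1], e, beta
        S = 0.0
        for j in range(D):
            S += pi[j] * e[j] * beta[j]
        # recombination-event expectation between t-1 and t
        exp_switch[t] = (1.0 - at) * S / scale[t]
        # expected chunk starts at t per donor: new donor j != previous
        for j in range(D):
            chunk_counts[j] += (
                (1.0 - at) * pi[j] * (1.0 - alpha[t - 1, j]) * e[j] * beta[j]
                / scale[t]
            )
        # backward recursion to t-1
        newb = np.empty(D)
        for j in range(D):
            newb[j] = (at * e[j] * beta[j] + (1.0 - at) * S) / scale[t]
        beta = newb
        s = 0.0
        for j in range(D):
            gamma[t - 1, j] = alpha[t - 1, j] * beta[j]
            s += gamma[t - 1, j]
        for j in range(D):
            gamma[t - 1, j] /= s
            if donors[j, t - 1] != rec[t - 1]:
                mismatch += gamma[t - 1, j]
    for j in range(D):
        chunk_counts[j] += gamma[0, j]  # chunk open at the first site
    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
    return gamma, alpha, scale, loglik, exp_switch, chunk_counts, mismatch


@njit(cache=True)
def _sample_paths(alpha, a, pi, n_samples, seed):
    """Stochastic traceback: sample donor paths from the posterior."""
    T, D = alpha.shape
    paths = np.empty((n_samples, T), dtype=np.int32)
    np.random.seed(seed)
    for s in range(n_samples):
        # final state
        u = np.random.random()
        acc = 0.0
        j = D - 1
        for k in range(D):
            acc += alpha[T - 1, k]
            if u <= acc:
                j = k
                break
        paths[s, T - 1] = j
        for t in range(T - 2, -1, -1):
            at = a[t + 1]
            # P(X_t = i | X_{t+1} = j) propto alpha[t,i] * T(i,j)
            tot = 0.0
            w = np.empty(D)
            for i in range(D):
                w[i] = alpha[t, i] * (1.0 - at) * pi[j]
            w[j] += alpha[t, j] * at
            for i in range(D):
                tot += w[i]
            u = np.random.random() * tot
            acc = 0.0
            i = D - 1
            for k in range(D):
                acc += w[k]
                if u <= acc:
                    i = k
                    break
            paths[s, t] = i
            j = i
    return paths


@dataclass
class PaintingResult:
    """Painting summary for one recipient haploid.

    ``mosaics`` holds one array per painting sample, each of shape
    (n_chunks, 4): columns are chromosome index (into ``chrom_labels``),
    start site index, end site index (exclusive, global indices into the
    painted site array), donor haploid index.
    """

    donor_ids: list
    exp_counts: np.ndarray
    exp_lengths_cm: np.ndarray
    mosaics: list[np.ndarray]
    chrom_labels: list
    params: PaintingParameters
    loglik: float
    site_cm_weights: np.ndarray | None = None

    @property
    def total_length_cm(self) -> float:
        return float(self.exp_lengths_cm.sum())


def _site_weights_cm(cm: np.ndarray) -> np.ndarray:
    """Half-interval cM weight per site; sums to the site span in cM."""
    w = np.empty_like(cm)
    w[0] = (cm[1] - cm[0]) / 2
    w[-1] = (cm[-1] - cm[-2]) / 2
    if cm.size > 2:
        w[1:-1] = (cm[2:] - cm[:-2]) / 2
    return w


def _paths_to_chunks(path: np.ndarray, chrom_idx: int, offset: int) -> np.ndarray:
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    out = np.empty((starts.size, 4), dtype=np.int64)
    out[:, 0] = chrom_idx
    out[:, 1] = starts + offset
    out[:, 2] = ends + offset
    out[:, 3] = path[starts]
    return out


def paint_haploid(
    recipient: np.ndarray,
    donors: HaplotypePanel,
    params: PaintingParameters | None = None,
    n_samples: int = 10,
    seed: int | None = None,
) -> PaintingResult:
    """Paint one recipient haploid against a donor panel.

    ``recipient`` is a 0/1 allele vector over exactly the donor panel's
    sites.  Chromosomes are painted independently and combined.
    """
    params = params or PaintingParameters()
    rec = np.asarray(recipient, dtype=np.uint8)
    if rec.shape != (donors.n_sites,):
        raise ValueError("recipient alleles must match the donor panel's sites")
    if donors.n_hap == 0:
        raise ValueError("donor set is empty")
    if np.shares_memory(rec, donors.haps):
        raise ValueError(
            "recipient haploid is part of the donor panel; exclude the "
            "recipient's own haploids from the donors before painting"
        )
    D = donors.n_hap
    pi = params.pi if params.pi is not None else np.full(D, 1.0 / D)
    if pi.size != D:
        raise ValueError("pi must have one entry per donor haploid")

    rng = np.random.default_rng(seed)
    exp_counts = np.zeros(D)
    exp_lengths = np.zeros(D)
    loglik = 0.0
    chrom_labels = donors.chromosomes
    per_sample_chunks: list[list[np.ndarray]] = [[] for _ in range(n_samples)]
    for ci, c in enumerate(chrom_labels):
        sel = donors.sites_on(c)
        dmat = np.ascontiguousarray(donors.haps[:, sel])
        cm = donors.cm[sel]
        a = np.ones(sel.size)
        a[1:] = np.exp(-params.ne * np.diff(cm) / 100.0)
        gamma, alpha, _, ll, _, counts, _ = _forward_backward(
            dmat, rec[sel], a, pi, params.theta
        )
        loglik += ll
        exp_counts += counts
        exp_lengths += _site_weights_cm(cm) @ gamma
        if n_samples > 0:
            sub = int(rng.integers(0, 2**31 - 1))
            paths = _sample_paths(alpha, a, pi, n_samples, sub)
            for s in range(n_samples):
                per_sample_chunks[s].append(
                    _paths_to_chunks(paths[s], ci, offset=int(sel[0]))
                )
    mosaics = [np.vstack(chs) for chs in per_sample_chunks] if n_samples else []
    return PaintingResult(
        donor_ids=list(range(D)),
        exp_counts=exp_counts,
        exp_lengths_cm=exp_lengths,
        mosaics=mosaics,
        chrom_labels=chrom_labels,
        params=params,
        loglik=loglik,
    )


def paint_panel(
    recipients: HaplotypePanel,
    donors: HaplotypePanel,
    params: PaintingParameters | None = None,
    n_samples: int = 10,
    seed: int | None = None,
) -> list[PaintingResult]:
    """Paint every haploid of ``recipients`` against ``donors``."""
    rng = np.random.default_rng(seed)
    out = []
    for h in range(recipients.n_hap):
        out.append(
            paint_haploid(
                recipients.haps[h],
                donors,
                params=params,
                n_samples=n_samples,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def estimate_painting_parameters(
    panel: HaplotypePanel,
    n_em: int = 10,
    subset_per_group: int = 5,
    chromosomes=None,
    init: PaintingParameters | None = None,
    recipient_groups=None,
    seed: int | None = None,
) -> tuple[PaintingParameters, dict]:
    """Jointly estimate Ne and theta by EM on a subset of recipients.

    Each selected haploid is painted against all haploids of other
    individuals; the E step accumulates expected recombination events and
    miscopies, the M step maximises the expected complete-data
    log-likelihood (1-D numeric solve for Ne, closed form for theta).
    Per-chromosome estimates are combined by a cM-weighted average.
    Returns the parameters and a history dict with per-chromosome
    log-likelihood sequences (nondecreasing by the EM property).
    """
    if panel.n_hap < 4:
        raise ValueError("EM needs at least two diploid individuals")
    rng = np.random.default_rng(seed)
    init = init or PaintingParameters()
    chroms = list(chromosomes) if chromosomes is not None else panel.chromosomes

    # pick recipients: up to subset_per_group haploids per group
    rec_idx = []
    paint_groups = (
        panel.group_list() if recipient_groups is None else list(recipient_groups)
    )
    for g in paint_groups:
        members = panel.haploids_of_group(g)
        k = min(subset_per_group, members.size)
        rec_idx.extend(rng.choice(members, size=k, replace=False))
    rec_idx = np.array(sorted(rec_idx))

    ne_by_chrom, theta_by_chrom, w_by_chrom = [], [], []
    history: dict = {"loglik": {}}
    for c in chroms:
        sel = panel.sites_on(c)
        cm = panel.cm[sel]
        d_morgan = np.diff(cm) / 100.0
        ne, theta = init.ne, init.theta
        logliks = []
        for _ in range(n_em):
            a = np.ones(sel.size)
            a[1:] = np.exp(-ne * d_morgan)
            tot_mismatch = 0.0
            tot_sites = 0
            r_acc = np.zeros(sel.size)  # expected switches per interval
            ll = 0.0
            for h in rec_idx:
                mate = h ^ 1  # other haploid of the same individual
                keep = np.array(
                    [j for j in range(panel.n_hap) if j not in (h, mate)]
                )
                dmat = np.ascontiguousarray(panel.haps[np.ix_(keep, sel)])
                pi = np.full(keep.size, 1.0 / keep.size)
                _, _, _, ll_h, exp_switch, _, mismatch = _forward_backward(
                    dmat, panel.haps[h, sel], a, pi, theta
                )
                ll += ll_h
                r_acc += exp_switch
                tot_mismatch += mismatch
                tot_sites += sel.size
            logliks.append(ll)
            # M step
            theta = min(max(tot_mismatch / tot_sites, 1e-7), 0.49)
            r = r_acc[1:] / len(rec_idx)

            def neg_q(log_ne, r=r, d=d_morgan, n_rec=len(rec_idx)):
                ne_ = np.exp(log_ne)
                p_sw = -np.expm1(-ne_ * d)
                p_sw = np.clip(p_sw, 1e-300, 1.0)
                return -n_rec * float(
                    np.sum(r * np.log(p_sw) - (1.0 - r) * ne_ * d)
                )

            res = minimize_scalar(
                neg_q, bounds=(np.log(1e-2), np.log(1e5)), method="bounded"
            )
            ne = float(np.exp(res.x))
        ne_by_chrom.append(ne)
        theta_by_chrom.append(theta)
        w_by_chrom.append(cm[-1] - cm[0])
        history["loglik"][c] = logliks
    w = np.asarray(w_by_chrom)
    w = w / w.sum()
    params = PaintingParameters(
        ne=float(np.dot(w, ne_by_chrom)),
        theta=float(np.clip(np.dot(w, theta_by_chrom), 1e-7, 0.49)),
    )
    return params, history


def summarise_copying_vectors(
    results: list[PaintingResult],
    donor_groups,
    group_order=None,
    use_lengths: bool = True,
) -> tuple[np.ndarray, list]:
    """Average copying vectors over recipients, per donor group.

    ``donor_groups`` gives the group label of each donor haploid (all
    results must share the donor set).  Chunk lengths (or counts) donated
    by all haploids of a group are summed, then the vector is normalised
    for each recipient and averaged across recipients.  Returns
    ``(vector, group_order)``.
    """
    donor_groups = np.asarray(donor_groups)
    if group_order is None:
        _, idx = np.unique(donor_groups, return_index=True)
        group_order = list(donor_groups[np.sort(idx)])
    missing = set(donor_groups) - set(group_order)
    if missing:
        raise ValueError(f"donor haploid(s) with unknown group: {sorted(missing)}")
    acc = np.zeros(len(group_order))
    for res in results:
        per_donor = res.exp_lengths_cm if use_lengths else res.exp_counts
        if per_donor.size != donor_groups.size:
            raise ValueError("donor group labels do not match painting results")
        v = np.array(
            [per_donor[donor_groups == g].sum() for g in group_order]
        )
        acc += v / v.sum()
    return acc / len(results), group_order


def build_chunkcount_matrix(
    panel: HaplotypePanel,
    params: PaintingParameters | None = None,
    continent_groups: dict[str, list] | None = None,
) -> tuple[np.ndarray, list, list]:
    """All-vs-all expected chunk-count matrix (clustering input).

    Each individual is painted against all haploids of all other
    individuals; the two haploids' expected counts are summed per donor
    individual.  ``continent_groups`` maps a label to a list of sample ids
    collapsed into a single donor column (their contributions summed), the
    "continental force" grouping.  Returns (matrix, row_ids, col_ids).
    """
    continent_groups = continent_groups or {}
    assigned: dict[str, str] = {}
    for label, members in continent_groups.items():
        for s in members:
            if s in assigned:
                raise ValueError(
                    f"sample {s} appears in continent groups "
                    f"{assigned[s]} and {label}"
                )
            assigned[s] = label

    samples = panel.sample_ids
    n_ind = len(samples)
    if panel.n_hap != 2 * n_ind:
        raise ValueError("chunk-count matrix requires diploid individuals")
    solo = [s for s in samples if s not in assigned]
    col_ids = solo + list(continent_groups)
    col_of = {s: col_ids.index(assigned.get(s, s)) for s in samples}

    mat = np.zeros((n_ind, len(col_ids)))
    for i in range(n_ind):
        donor_haps = np.array(
            [h for h in range(panel.n_hap) if h // 2 != i]
        )
        donors = panel.take_haploids(donor_haps)
        for h in (2 * i, 2 * i + 1):
            res = paint_haploid(
                panel.haps[h], donors, params=params, n_samples=0
            )
            for k, dh in enumerate(donor_haps):
                mat[i, col_of[samples[dh // 2]]] += res.exp_counts[k]
    return mat, list(samples), col_ids


def select_nonlocal_donors(
    target_group,
    region_of_group: dict,
    donor_groups,
    joint_regions=frozenset({"Nilo-Saharan", "Afroasiatic"}),
) -> np.ndarray:
    """Boolean mask over donor group labels excluding the target's region.

    Groups from the target's own ancestry region are excluded; if the
    target's region is one of ``joint_regions`` (by default the
    Nilo-Saharan / Afroasiatic pairing), groups from *all* joint regions
    are excluded together.
    """
    donor_groups = list(donor_groups)
    for g in set(donor_groups) | {target_group}:
        if g not in region_of_group:
            raise ValueError(f"group {g!r} has no ancestry-region assignment")
    target_region = region_of_group[target_group]
    excluded = (
        set(joint_regions) if target_region in joint_regions else {target_region}
    )
    mask = np.array(
        [region_of_group[g] not in excluded for g in donor_groups], dtype=bool
    )
    if not mask.any():
        raise ValueError(
            "non-local donor mask is empty: every donor group shares the "
            "target's (excluded) ancestry region"
        )
    return mask
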