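import itertools

import numpy as np
import pytest

import haplomix as hm
from haplomix.genmap import make_genetic_map
from haplomix.painting import (
    PaintingParameters,
    _forward_backward,
    build_chunkcount_matrix,
    estimate_painting_parameters,
    paint_haploid,
    select_nonlocal_donors,
    summarise_copying_vectors,
)
from haplomix.panel import HaplotypePanel


def brute_force_posteriors(donors, rec, a, pi, theta):
    """Enumerate every donor path; exact posteriors, chunk-count
    expectations and log-likelihood.  Independent of the HMM recursions."""
    D, T = donors.shape
    paths = np.array(list(itertools.product(range(D), repeat=T)), dtype=np.int64)
    logp = np.log(pi[paths[:, 0]])
    for t in range(T):
        if t > 0:
            stay = paths[:, t] == paths[:, t - 1]
            logp += np.log(a[t] * stay + (1 - a[t]) * pi[paths[:, t]])
        match = donors[paths[:, t], t] == rec[t]
        logp += np.log(np.where(match, 1 - theta, theta))
    w = np.exp(logp - logp.max())
    w /= w.sum()
    post = np.zeros((T, D))
    for t in range(T):
        for d in range(D):
            post[t, d] = w[paths[:, t] == d].sum()
    counts = np.zeros(D)
    for d in range(D):
        starts = (paths[:, 0] == d).astype(float)
        starts += ((paths[:, 1:] == d) & (paths[:, :-1] != d)).sum(axis=1)
        counts[d] = np.dot(w, starts)
    from scipy.special import logsumexp

    return post, counts, float(logsumexp(logp))


def _panel_from(haps, cm, chrom="1"):
    haps = np.asarray(haps, dtype=np.uint8)
    n = haps.shape[0]
    pos = (np.asarray(cm) * 1e6).astype(np.int64)
    return HaplotypePanel(
        haps=haps,
        positions=pos,
        chrom=np.full(haps.shape[1], chrom),
        cm=np.asarray(cm, dtype=float),
        sample_ids=[f"d{i}" for i in range((n + 1) // 2)],
        groups=np.array([f"g{i}" for i in range(n)]),
    )


@pytest.mark.parametrize("n_sites,n_donors,seed", [(8, 3, 0), (20, 2, 1), (8, 5, 2)])
def test_forward_backward_matches_path_enumeration(n_sites, n_donors, seed):
    rng = np.random.default_rng(seed)
    donors = rng.integers(0, 2, (n_donors, n_sites)).astype(np.uint8)
    rec = rng.integers(0, 2, n_sites).astype(np.uint8)
    cm = np.sort(rng.uniform(0, 5, n_sites))
    a = np.ones(n_sites)
    a[1:] = np.exp(-80.0 * np.diff(cm) / 100)
    pi = rng.dirichlet(np.ones(n_donors))
    gamma, _, _, ll, _, counts, _ = _forward_backward(donors, rec, a, pi, 0.02)
    post, counts_bf, ll_bf = brute_force_posteriors(donors, rec, a, pi, 0.02)
    np.testing.assert_allclose(gamma, post, atol=1e-9)
    np.testing.assert_allclose(counts, counts_bf, atol=1e-9)
    assert ll == pytest.approx(ll_bf, abs=1e-9)


class TestPaintHaploid:
    def test_single_donor_single_chunk(self):
        cm = np.linspace(0, 10, 30)
        rng = np.random.default_rng(3)
        donor = rng.integers(0, 2, 30).astype(np.uint8)
        rec = donor.copy()
        rec[5] ^= 1
        panel = _panel_from(donor[None, :], cm)
        res = paint_haploid(rec, panel, PaintingParameters(ne=50, theta=0.01),
                            n_samples=3, seed=0)
        assert res.exp_counts[0] == pytest.approx(1.0)
        assert all(m.shape[0] == 1 for m in res.mosaics)
        assert res.total_length_cm == pytest.approx(10.0)

    def test_identical_twin_donor_dominates(self):
        rng = np.random.default_rng(4)
        cm = np.sort(rng.uniform(0, 50, 500))
        donors = rng.integers(0, 2, (50, 500)).astype(np.uint8)
        rec = donors[7].copy()
        panel = _panel_from(donors, cm)
        res = paint_haploid(rec, panel, PaintingParameters(ne=100, theta=0.001),
                            n_samples=0)
        assert res.exp_lengths_cm[7] / res.total_length_cm >= 0.99

    def test_expected_lengths_sum_to_map_length(self, small_sources):
        donors = small_sources.panels["A"]
        rec = small_sources.panels["B"].haps[0]
        res = paint_haploid(rec, donors, n_samples=0)
        span = sum(
            donors.cm[donors.sites_on(c)][-1] - donors.cm[donors.sites_on(c)][0]
            for c in donors.chromosomes
        )
        assert res.total_length_cm == pytest.approx(span, rel=1e-6)

    def test_self_painting_rejected(self, small_sources):
        panel = small_sources.panels["A"]
        with pytest.raises(ValueError, match="donor panel"):
            paint_haploid(panel.haps[0], panel)

    def test_sampled_mosaics_converge_to_expected_counts(self):
        rng = np.random.default_rng(5)
        cm = np.sort(rng.uniform(0, 20, 60))
        donors = rng.integers(0, 2, (4, 60)).astype(np.uint8)
        rec = rng.integers(0, 2, 60).astype(np.uint8)
        panel = _panel_from(donors, cm)
        res = paint_haploid(rec, panel, PaintingParameters(ne=60, theta=0.05),
                            n_samples=3000, seed=1)
        sampled = np.zeros(4)
        for m in res.mosaics:
            np.add.at(sampled, m[:, 3], 1)
        sampled /= len(res.mosaics)
        np.testing.assert_allclose(sampled, res.exp_counts, rtol=0.1, atol=0.05)

    def test_more_true_source_donors_increase_copying(self, toy_maps):
        src = hm.simulate_source_panels(
            2, 0.2, 800, 40, toy_maps, names=["A", "B"], seed=21
        )
        tgt, _ = hm.simulate_admixed_population(
            src, mix={"A": 1.0}, n_gen=5, n_ind=2, seed=22
        )
        fractions = []
        for k in (5, 30):
            donors = hm.concat_panels(
                [src.panels["A"].take_haploids(np.arange(k)),
                 src.panels["B"].take_haploids(np.arange(30))]
            )
            res = paint_haploid(tgt.haps[0], donors, n_samples=0)
            grp = donors.groups
            frac = res.exp_lengths_cm[grp == "A"].sum() / res.total_length_cm
            fractions.append(frac)
        assert fractions[1] > fractions[0]


class TestEstimateParameters:
    def test_exact_copies_drive_theta_to_floor(self, toy_maps):
        rng = np.random.default_rng(6)
        hap = rng.integers(0, 2, 400).astype(np.uint8)
        src = hm.simulate_source_panels(
            1, 0.0, 400, 4, toy_maps, names=["A"], seed=23
        )
        panel = src.panels["A"]
        panel.haps[:] = hap  # four identical haploids
        params, _ = estimate_painting_parameters(
            panel, n_em=4, subset_per_group=2, seed=0
        )
        assert params.theta <= 1e-4

    def test_em_recovers_generative_parameters(self):
        # recipients generated from the copying model itself
        rng = np.random.default_rng(7)
        n_sites, true_ne, true_theta = 5000, 100.0, 0.01
        cm = np.sort(rng.uniform(0, 100, n_sites))
        donors = rng.integers(0, 2, (20, n_sites)).astype(np.uint8)
        recs = []
        for _ in range(4):
            path = np.empty(n_sites, dtype=int)
            path[0] = rng.integers(20)
            a = np.exp(-true_ne * np.diff(cm) / 100)
            for t in range(1, n_sites):
                if rng.random() > a[t - 1]:
                    path[t] = rng.integers(20)
                else:
                    path[t] = path[t - 1]
            rec = donors[path, np.arange(n_sites)].copy()
            flip = rng.random(n_sites) < true_theta
            rec[flip] ^= 1
            recs.append(rec)
        panel = _panel_from(np.vstack([donors, recs]), cm)
        panel.groups[:] = "d"
        panel.groups[20:] = "r"
        params, hist = estimate_painting_parameters(
            panel, n_em=10, subset_per_group=4, recipient_groups=["r"], seed=1
        )
        assert true_ne / 2 <= params.ne <= true_ne * 2
        assert true_theta / 2 <= params.theta <= true_theta * 2
        lls = hist["loglik"]["1"]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


class TestCopyingVectors:
    def _results(self):
        r1 = hm.PaintingResult(
            donor_ids=[0, 1, 2], exp_counts=np.array([1, 2, 3.0]),
            exp_lengths_cm=np.array([2.0, 8.0, 0.0]), mosaics=[],
            chrom_labels=["1"], params=PaintingParameters(), loglik=0.0,
        )
        r2 = hm.PaintingResult(
            donor_ids=[0, 1, 2], exp_counts=np.array([1, 1, 2.0]),
            exp_lengths_cm=np.array([4.0, 6.0, 0.0]), mosaics=[],
            chrom_labels=["1"], params=PaintingParameters(), loglik=0.0,
        )
        return r1, r2

    def test_average_of_two_recipients(self):
        r1, r2 = self._results()
        v, order = summarise_copying_vectors(
            [r1, r2], ["x", "y", "y"], group_order=["x", "y"]
        )
        np.testing.assert_allclose(v, [0.3, 0.7])

    def test_merging_groups_adds_entries(self):
        r1, _ = self._results()
        v_split, _ = summarise_copying_vectors(
            [r1], ["x", "y", "z"], group_order=["x", "y", "z"]
        )
        v_merged, _ = summarise_copying_vectors(
            [r1], ["x", "w", "w"], group_order=["x", "w"]
        )
        assert v_merged[1] == pytest.approx(v_split[1] + v_split[2])

    def test_single_group_gives_unit_vector(self):
        r1, _ = self._results()
        v, _ = summarise_copying_vectors([r1], ["g", "g", "g"])
        np.testing.assert_allclose(v, [1.0])

    def test_unknown_group_rejected(self):
        r1, _ = self._results()
        with pytest.raises(ValueError, match="unknown group"):
            summarise_copying_vectors([r1], ["x", "y", "q"], group_order=["x", "y"])


@pytest.fixture(scope="module")
def chunkcount_panel(small_sources):
    return small_sources.panels["A"].take_haploids(np.arange(8))


class TestChunkcountMatrix:

    def test_columns_without_grouping(self, chunkcount_panel):
        mat, rows, cols = build_chunkcount_matrix(chunkcount_panel)
        assert len(rows) == 4
        assert cols == rows

    def test_continent_grouping_reduces_columns(self, chunkcount_panel):
        ids = chunkcount_panel.sample_ids
        mat, rows, cols = build_chunkcount_matrix(
            chunkcount_panel, continent_groups={"cont": ids[:3]}
        )
        assert len(cols) == len(ids) - 3 + 1
        mat0, _, _ = build_chunkcount_matrix(chunkcount_panel)
        np.testing.assert_allclose(mat.sum(axis=1), mat0.sum(axis=1), rtol=1e-9)

    def test_overlapping_groups_rejected(self, chunkcount_panel):
        ids = chunkcount_panel.sample_ids
        with pytest.raises(ValueError, match="continent groups"):
            build_chunkcount_matrix(
                chunkcount_panel,
                continent_groups={"c1": ids[:2], "c2": ids[1:3]},
            )


class TestNonlocalDonors:
    regions = {
        "jola": "West", "wollof": "West", "kauma": "East",
        "dinka": "Nilo-Saharan", "afar": "Afroasiatic", "gbr": "Eurasia",
    }

    def test_own_region_excluded(self):
        mask = select_nonlocal_donors("jola", self.regions, list(self.regions))
        kept = [g for g, m in zip(self.regions, mask) if m]
        assert "wollof" not in kept and "jola" not in kept
        assert "kauma" in kept

    def test_nilo_saharan_excludes_both_joint_regions(self):
        mask = select_nonlocal_donors("dinka", self.regions, list(self.regions))
        kept = [g for g, m in zip(self.regions, mask) if m]
        assert "afar" not in kept and "dinka" not in kept
        assert "gbr" in kept

    def test_single_region_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_nonlocal_donors(
                "jola", {"jola": "West", "wollof": "West"}, ["jola", "wollof"]
            )

    def test_unassigned_group_rejected(self):
        with pytest.raises(ValueError, match="region"):
            select_nonlocal_donors("jola", {"jola": "West"}, ["jola", "mystery"])
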