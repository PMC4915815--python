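import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplomix as hm
from haplomix.stats import f3_test, hudson_fst, ld_prune, pihat_filter, tvd


def hudson_site_oracle(p1, n1, p2, n2):
    """Direct per-site evaluation of the Hudson ratio-of-averages."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestHudsonFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 2000)
        res = hudson_fst(p, np.inf, p, np.inf, block=100)
        assert abs(res.estimate) < 1e-3

    def test_closed_form_two_frequencies(self):
        # p1=0.2, p2=0.8 in the infinite-sample limit: 0.36/0.68 = 9/17
        res = hudson_fst([0.2], np.inf, [0.8], np.inf)
        assert res.estimate == pytest.approx(9 / 17)

    def test_fixed_differences_give_one(self):
        res = hudson_fst(np.zeros(50), np.inf, np.ones(50), np.inf)
        assert res.estimate == pytest.approx(1.0)

    def test_matches_site_oracle_exactly(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0.1, 0.9, 10)
        p2 = rng.uniform(0.1, 0.9, 10)
        res = hudson_fst(p1, 40, p2, 60, block=5)
        assert res.estimate == pytest.approx(
            hudson_site_oracle(p1, 40, p2, 60), abs=1e-12
        )

    def test_small_samples_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="sample size"):
            res = hudson_fst(
                [0.2, 0.3], [np.inf, 1], [0.8, 0.4], [np.inf, np.inf]
            )
        assert res.estimate == pytest.approx(9 / 17)
        with pytest.raises(ValueError):
            hudson_fst([0.2], 1, [0.8], 1)

    def test_jackknife_se_shrinks_with_block_count(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.2, 0.8, 40_000)
        p2 = np.clip(p1 + rng.normal(0, 0.1, p1.size), 0.01, 0.99)
        se_few = hudson_fst(p1[:10_000], np.inf, p2[:10_000], np.inf, block=500).se
        se_many = hudson_fst(p1, np.inf, p2, np.inf, block=500).se
        # 4x the blocks: SE should fall roughly like 1/sqrt(4)
        assert se_many == pytest.approx(se_few / 2, rel=0.45)


class TestTvd:
    def test_known_values(self):
        assert tvd([0.5, 0.5, 0.0], [0.0, 0.5, 0.5]) == pytest.approx(0.5)
        assert tvd([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert tvd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_mismatched_supports_rejected(self):
        with pytest.raises(ValueError):
            tvd([0.5, 0.5], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            tvd([0.5, 0.5], [0.5, 0.5], labels_a=["x", "y"], labels_b=["x", "z"])
        with pytest.raises(ValueError):
            tvd([0.9, 0.3], [0.5, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6),
    )
    def test_metric_properties(self, xs, ys, zs):
        k = min(len(xs), len(ys), len(zs))
        a = np.array(xs[:k]) / np.sum(xs[:k])
        b = np.array(ys[:k]) / np.sum(ys[:k])
        c = np.array(zs[:k]) / np.sum(zs[:k])
        dab, dba = tvd(a, b), tvd(b, a)
        assert dab == pytest.approx(dba)
        assert 0.0 <= dab <= 1.0
        assert tvd(a, c) <= dab + tvd(b, c) + 1e-12


class TestF3:
    def test_zero_when_target_equals_reference(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.9, 1000)
        b = rng.uniform(0.1, 0.9, 1000)
        res = f3_test(a, a, b)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_exact_midpoint_is_negative_quarter_mean_square(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 0.9, 500)
        b = rng.uniform(0.1, 0.9, 500)
        x = (a + b) / 2
        res = f3_test(x, a, b)
        assert res.estimate == pytest.approx(-np.mean((a - b) ** 2) / 4)

    def test_admixed_population_strongly_negative(self, toy_maps):
        src = hm.simulate_source_panels(
            2, 0.15, 10_000, 60, toy_maps, names=["A", "B"], seed=31
        )
        tgt, _ = hm.simulate_admixed_population(
            src, mix={"A": 0.5, "B": 0.5}, n_gen=10, n_ind=30, seed=32
        )
        res = f3_test(
            tgt.allele_freq(), src.panels["A"].allele_freq(),
            src.panels["B"].allele_freq(),
        )
        assert res.z < -5

    def test_monomorphic_everywhere_rejected(self):
        z = np.zeros(100)
        with pytest.raises(ValueError):
            f3_test(z, z, z)


class TestLdPrune:
    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, (200, 30)).astype(float)
        pos = np.arange(30) * 1000
        kept = ld_prune(g, pos)
        assert kept.size == 30

    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, (100, 5)).astype(float)
        g[:, 3] = g[:, 1]
        kept = ld_prune(g, np.arange(5) * 1000)
        assert 1 in kept and 3 not in kept

    def test_triplicate_keeps_one(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, 100).astype(float)
        g = np.column_stack([col, col, col])
        kept = ld_prune(g, np.array([0, 10_000, 20_000]))
        assert kept.tolist() == [0]

    def test_postcondition_no_close_correlated_pair(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, (150, 10)).astype(float)
        noisy = np.column_stack([base, base + rng.normal(0, 0.3, base.shape)])
        pos = np.sort(rng.choice(100_000, 20, replace=False))
        kept = ld_prune(noisy, pos, r2_max=0.2, window_bp=50_000)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if pos[b] - pos[a] <= 50_000:
                    r = np.corrcoef(noisy[:, a], noisy[:, b])[0, 1] ** 2
                    assert r <= 0.2 + 1e-9


@pytest.fixture(scope="module")
def cohort():
    """Unrelated founders plus a duplicate and a parent-offspring pair."""
    rng = np.random.default_rng(9)
    p = rng.uniform(0.1, 0.9, 4000)
    founders = (rng.random((12, 2, 4000)) < p).astype(np.int8)
    geno = founders.sum(axis=1)
    dup = geno[0].copy()
    # child of founders 1 and 2: one random haplotype from each
    child = founders[1, rng.integers(0, 2, 4000), np.arange(4000)] + \
        founders[2, rng.integers(0, 2, 4000), np.arange(4000)]
    return np.vstack([geno, dup, child])


class TestPihat:

    def test_duplicate_detected_and_removed(self, cohort):
        est, removed = pihat_filter(cohort, threshold=0.2, seed=0)
        dup_row = est[(est.id1 == 0) & (est.id2 == 12)]
        assert dup_row.pi_hat.iloc[0] == pytest.approx(1.0, abs=0.05)
        assert 0 in removed or 12 in removed

    def test_parent_offspring_pihat_half(self, cohort):
        est, _ = pihat_filter(cohort, threshold=0.2, seed=0)
        po = est[(est.id1 == 1) & (est.id2 == 13)]
        assert po.pi_hat.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_unrelated_near_zero(self, cohort):
        est, removed = pihat_filter(cohort[3:12], threshold=0.2, seed=0)
        assert est.pi_hat.abs().max() < 0.05
        assert removed == []

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            pihat_filter(np.zeros((1, 100)))
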