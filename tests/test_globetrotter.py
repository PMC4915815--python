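import numpy as np
import pytest

from haplomix.globetrotter import (
    AdmixtureEvent,
    CoancestryCurveSet,
    _accumulate_pairs,
    apply_region_rules,
    classify_event,
    decompose_admixture_sources,
    fit_coancestry_dates,
    fit_mixture_model,
)


def curveset_from_ratio(ratio_fn, groups, min_g=0.0, max_g=20.0, bin_cm=0.1,
                        n_chrom=4, count=500.0):
    """CoancestryCurveSet whose observed/expected ratio follows
    ``ratio_fn(g_cm, a, b)`` exactly in every chromosome."""
    G = len(groups)
    edges = np.arange(min_g, max_g + bin_cm / 2, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    B = centers.size
    expected = np.full((1, n_chrom, B, G, G), count)
    counts = np.empty_like(expected)
    for a in range(G):
        for b in range(G):
            counts[0, :, :, a, b] = count * ratio_fn(centers, a, b)[None, :]
    f = np.full(G, 1.0 / G)
    return CoancestryCurveSet(
        edges=edges, groups=list(groups), counts=counts,
        expected=expected, f=f,
    )


class TestMixtureModel:
    def test_recipient_equal_to_one_surrogate(self):
        rng = np.random.default_rng(0)
        F = rng.dirichlet(np.ones(6), size=4)
        fit = fit_mixture_model(F[2], F, ["a", "b", "c", "d"])
        assert fit.beta[2] == pytest.approx(1.0, abs=1e-6)
        assert fit.beta.sum() == pytest.approx(1.0)

    def test_exact_mixture_of_orthogonal_vectors(self):
        v1 = np.array([0.5, 0.5, 0.0, 0.0])
        v2 = np.array([0.0, 0.0, 0.5, 0.5])
        rec = 0.3 * v1 + 0.7 * v2
        fit = fit_mixture_model(rec, np.vstack([v1, v2]), ["s1", "s2"])
        np.testing.assert_allclose(fit.beta, [0.3, 0.7], atol=1e-6)

    def test_tiny_coefficients_dropped_and_rescaled(self):
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.0, 1.0, 0.0])
        v3 = np.array([0.0, 0.0, 1.0])
        rec = np.array([0.6005, 0.399, 0.0005])
        fit = fit_mixture_model(rec, np.vstack([v1, v2, v3]), ["a", "b", "c"])
        assert "c" in fit.dropped
        assert fit.beta[2] == 0.0
        assert fit.beta.sum() == pytest.approx(1.0)

    def test_fewer_than_two_surrogates_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture_model(np.array([1.0]), np.array([[1.0]]), ["a"])


class TestPairCounting:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        n = 100
        chrom = rng.integers(0, 2, n)
        mid = rng.uniform(0, 30, n)
        grp = rng.integers(0, 3, n)
        edges = np.arange(0.0, 10.5, 0.5)
        B = edges.size - 1
        counts = np.zeros((2, B, 3, 3))
        ptot = np.zeros((2, B))
        _accumulate_pairs(counts, ptot, edges, 3, chrom, mid, grp)
        brute = np.zeros((2, B, 3, 3))
        for i in range(n):
            for j in range(i + 1, n):
                if chrom[i] != chrom[j]:
                    continue
                d = abs(mid[i] - mid[j])
                b = int(np.searchsorted(edges, d, side="right")) - 1
                if 0 <= b < B:
                    brute[chrom[i], b, grp[i], grp[j]] += 1
                    brute[chrom[i], b, grp[j], grp[i]] += 1
        np.testing.assert_array_equal(counts, brute)
        np.testing.assert_array_equal(ptot, brute.sum(axis=(2, 3)) / 2 * 2 / 1)


class TestDateFits:
    def test_common_rate_recovered(self):
        def ratio(g, a, b):
            sign = 1.0 if a == b else -1.0
            return 1.0 + sign * 0.4 * np.exp(-15.0 * g / 100)

        cs = curveset_from_ratio(ratio, ["A", "B"])
        fit = fit_coancestry_dates(cs, 1, 0.5, 20.0)
        assert fit["lambdas"][0] == pytest.approx(15.0, abs=1.0)
        assert fit["max_r1"] > 0.99

    def test_two_rates_recovered_with_high_m(self):
        def ratio(g, a, b):
            fast = 0.5 * np.exp(-40.0 * g / 100)
            slow = 0.3 * np.exp(-5.0 * g / 100)
            if a == b == 0:
                return 1.0 + fast
            if a == b == 1:
                return 1.0 + slow
            return 1.0 - 0.5 * (fast + slow)

        cs = curveset_from_ratio(ratio, ["A", "B"], max_g=40.0)
        fit = fit_coancestry_dates(cs, 2, 0.5, 40.0)
        lam = sorted(fit["lambdas"])
        assert lam[0] == pytest.approx(5.0, rel=0.3)
        assert lam[1] == pytest.approx(40.0, rel=0.3)
        m = float(np.max(fit["r2"] - fit["r2_one"]))
        assert m > 0.35

    def test_flat_curves_have_no_explained_variance(self):
        cs = curveset_from_ratio(lambda g, a, b: np.ones_like(g), ["A", "B"])
        fit = fit_coancestry_dates(cs, 1, 0.5, 20.0)
        assert fit["max_r1"] == pytest.approx(0.0, abs=1e-6)

    def test_insufficient_bins_rejected(self):
        cs = curveset_from_ratio(
            lambda g, a, b: np.ones_like(g), ["A", "B"], max_g=0.3
        )
        with pytest.raises(ValueError):
            fit_coancestry_dates(cs, 1, 0.0, 0.3)


class TestDecomposition:
    def test_exact_rank_one_matrix(self):
        delta = np.array([0.6, -0.5, -0.1])
        beta = np.array([0.3, 0.5, 0.2])
        alpha = 0.25
        mat = alpha * (1 - alpha) * np.outer(delta, delta)
        out = decompose_admixture_sources(mat, beta)
        assert out["fq1"] == pytest.approx(1.0)
        assert not out["degenerate"]
        # recovered contrast is parallel to delta
        d_hat = out["source1"] - out["source2"]
        cos = abs(d_hat @ delta) / (
            np.linalg.norm(d_hat) * np.linalg.norm(delta)
        )
        assert cos > 0.99
        assert 0 < out["alpha"] <= 0.5

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            decompose_admixture_sources(np.zeros((3, 3)), np.ones(3) / 3)

    def test_asymmetric_input_symmetrised(self):
        mat = np.array([[0.4, 0.1], [0.3, 0.2]])
        out = decompose_admixture_sources(mat, np.array([0.5, 0.5]))
        sym = decompose_admixture_sources(
            (mat + mat.T) / 2, np.array([0.5, 0.5])
        )
        assert out["alpha"] == pytest.approx(sym["alpha"])


class TestClassification:
    metrics = {"max_r1": 0.9, "fq1": 0.95, "fq2": 0.99, "m": 0.1}
    boots = np.linspace(8, 12, 100)

    def test_high_p_means_no_admixture(self):
        assert classify_event(self.metrics, 0.40, self.boots) == "no admixture"

    def test_large_m_means_multiple_dates(self):
        m = dict(self.metrics, m=0.5)
        assert classify_event(m, 0.01, self.boots) == "multiple dates"

    def test_rank_two_single_date_is_multiway(self):
        m = dict(self.metrics, fq1=0.5, fq2=0.95, m=0.1)
        assert classify_event(m, 0.01, self.boots) == "one date, multiway"

    def test_stable_single_date(self):
        assert classify_event(self.metrics, 0.01, self.boots) == "one date"

    def test_bound_hugging_bootstraps_are_uncertain(self):
        boots = np.concatenate([np.ones(40), np.linspace(5, 15, 60)])
        assert classify_event(self.metrics, 0.01, boots, point_date=10.0) == "uncertain"

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            classify_event({"max_r1": 0.9}, 0.01, self.boots)


def _dummy_event(**over):
    base = dict(
        classification="multiple dates",
        dates=[10.0, 40.0],
        date_ci=[(6.0, 14.0), (25.0, 60.0)],
        alpha=0.2,
        sources=[
            {"alpha": 0.2, "source1": np.array([1.0, 0.0]),
             "source2": np.array([0.0, 1.0])},
            {"alpha": 0.3, "source1": np.array([0.5, 0.5]),
             "source2": np.array([0.2, 0.8])},
        ],
        metrics={"max_r1": 0.9, "fq1": 0.9, "fq2": 0.95, "m": 0.4},
        p_value=0.01,
        bootstrap_dates=list(np.linspace(5, 50, 100)),
        surrogates=["A", "B"],
    )
    base.update(over)
    return AdmixtureEvent(**base)


class TestRegionRules:
    rules = {
        "West Africa Niger-Congo": {"collapse_two_dates": "older"},
        "Southern Africa": {"standardise_null": True},
    }

    def test_west_african_two_dates_collapse_to_older(self):
        ev = apply_region_rules(
            _dummy_event(), "West Africa Niger-Congo", self.rules
        )
        assert ev.dates == [40.0]
        assert ev.classification == "one date"
        assert ev.sources[0]["alpha"] == 0.3

    def test_region_without_rule_unchanged(self):
        ev0 = _dummy_event()
        ev = apply_region_rules(ev0, "East Africa", self.rules)
        assert ev.dates == ev0.dates and ev.classification == ev0.classification

    def test_null_standardisation_flagged(self):
        ev = apply_region_rules(_dummy_event(), "Southern Africa", self.rules)
        assert ev.standardised
        assert any("null individual" in n for n in ev.notes)

    def test_unknown_rule_key_rejected(self):
        with pytest.raises(ValueError):
            apply_region_rules(
                _dummy_event(), "West Africa Niger-Congo",
                {"West Africa Niger-Congo": {"frobnicate": True}},
            )
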