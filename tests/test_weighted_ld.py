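import numpy as np
import pytest

import haplomix as hm
from haplomix.scenarios import weighted_ld_study
from haplomix.simulate import split_panelset
from haplomix.weighted_ld import (
    WeightedLDCurve,
    assign_event_sources,
    curve_amplitude_zscore,
    fit_admixture_exponentials,
    min_shared_ld_distance,
    weighted_ld_curve,
)


def synthetic_curve(amplitudes, rates, intercept, noise=0.0, seed=0,
                    min_d=0.5, max_d=20.0, bin_cm=0.1, n_units=8):
    """Build a WeightedLDCurve whose bin values follow a known
    multi-exponential, split over pseudo-chromosome units."""
    rng = np.random.default_rng(seed)
    edges = np.arange(min_d, max_d + bin_cm / 2, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    d = centers / 100.0
    y = intercept + sum(
        c * np.exp(-r * d) for c, r in zip(amplitudes, rates)
    )
    B = centers.size
    sums = np.zeros((n_units, B))
    counts = np.full((n_units, B), 1000.0)
    for u in range(n_units):
        sums[u] = (y + rng.normal(0, noise, B)) * counts[u]
    return WeightedLDCurve(
        bin_edges=edges, sums=sums, counts=counts,
        unit_labels=[f"u{i}" for i in range(n_units)],
    )


class TestCurveConstruction:
    def test_equal_references_give_flagged_zero_curve(self, small_sources):
        a = small_sources.panels["A"]
        b = small_sources.panels["B"]
        curve = weighted_ld_curve(b, a, a, min_d=0.5, max_d=10, bin_cm=0.5)
        assert curve.zero_weights
        np.testing.assert_allclose(np.nan_to_num(curve.values()), 0.0, atol=1e-12)

    def test_reference_swap_symmetry(self, small_sources):
        a = small_sources.panels["A"]
        b = small_sources.panels["B"]
        tgt = a.take_haploids(np.arange(10))
        c1 = weighted_ld_curve(tgt, a, b, min_d=0.5, max_d=10, bin_cm=0.5)
        c2 = weighted_ld_curve(tgt, b, a, min_d=0.5, max_d=10, bin_cm=0.5)
        np.testing.assert_allclose(c1.values(), c2.values(), atol=1e-12)

    def test_invalid_range_rejected(self, small_sources):
        a = small_sources.panels["A"]
        with pytest.raises(ValueError):
            weighted_ld_curve(a, a, a, min_d=5.0, max_d=5.0)

    def test_single_pulse_rate_recovery(self):
        study = weighted_ld_study(seed=7)
        curve = weighted_ld_curve(
            study["target"], study["ref_a"], study["ref_b"],
            min_d=study["min_d"], max_d=study["max_d"], bin_cm=study["bin_cm"],
        )
        fit = fit_admixture_exponentials(curve, max_events=1)
        assert fit.n_events == 1
        assert fit.rates[0] == pytest.approx(10.0, rel=0.3)

    def test_one_reference_mode_detects_admixture_source(self):
        study = weighted_ld_study(seed=8)
        c = weighted_ld_curve(
            study["target"], study["ref_a"], None,
            min_d=0.5, max_d=14.0, bin_cm=0.1,
        )
        assert c.mode == "one-ref"
        fit = fit_admixture_exponentials(c, max_events=1)
        assert fit.n_events >= 1


class TestExponentialFits:
    def test_noiseless_single_exponential(self):
        curve = synthetic_curve([0.02], [15.0], 0.001)
        fit = fit_admixture_exponentials(curve, max_events=1)
        assert fit.rates[0] == pytest.approx(15.0, abs=0.5)
        assert fit.amplitudes[0] == pytest.approx(0.02, abs=0.002)

    def test_two_well_separated_exponentials(self):
        curve = synthetic_curve(
            [0.03, 0.01], [5.0, 40.0], 0.0005, noise=2e-5, seed=1,
            max_d=40.0,
        )
        fit = fit_admixture_exponentials(curve, max_events=2)
        assert fit.n_events == 2
        rates = sorted(fit.rates)
        assert rates[0] == pytest.approx(5.0, rel=0.3)
        assert rates[1] == pytest.approx(40.0, rel=0.3)

    def test_flat_curve_gives_no_events(self):
        curve = synthetic_curve([0.0], [10.0], 0.001, noise=1e-4, seed=2)
        fit = fit_admixture_exponentials(curve, max_events=2)
        assert fit.n_events == 0

    def test_too_few_bins_rejected(self):
        curve = synthetic_curve([0.02], [10.0], 0.0, max_d=0.8)
        with pytest.raises(ValueError):
            fit_admixture_exponentials(curve, max_events=2)


class TestAmplitudeZ:
    def test_printed_examples(self):
        assert curve_amplitude_zscore(5, 1, 3, 1) == pytest.approx(np.sqrt(2))
        assert curve_amplitude_zscore(4, 2, 4, 3) == 0.0
        assert curve_amplitude_zscore(10, 1, 2, 2) == pytest.approx(8 / np.sqrt(5))

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            curve_amplitude_zscore(5, 0, 3, 1)


class TestMinSharedLd:
    def test_override_returns_prescribed_distance(self, small_sources):
        d = min_shared_ld_distance(
            small_sources.panels["A"], small_sources.panels["B"],
            override_cm=0.5,
        )
        assert d == 0.5

    def test_same_object_rejected(self, small_sources):
        p = small_sources.panels["A"]
        with pytest.raises(ValueError):
            min_shared_ld_distance(p, p)

    def test_independent_panels_share_no_ld(self, toy_maps):
        src = hm.simulate_source_panels(
            2, 0.0, 3000, 60, toy_maps, ld_blockiness=0.3,
            names=["A", "B"], seed=41,
        )
        d = min_shared_ld_distance(
            src.panels["A"], src.panels["B"], bin_cm=0.25, max_d=5.0
        )
        assert d <= 0.5

    def test_split_panel_shares_long_range_ld(self, toy_maps):
        src = hm.simulate_source_panels(
            1, 0.0, 3000, 80, toy_maps, ld_blockiness=2.0,
            n_founders=6, names=["A"], seed=42,
        )
        half1, half2 = split_panelset(src, 40)
        d = min_shared_ld_distance(
            half1.panels["A"], half2.panels["A"], bin_cm=0.25, max_d=5.0
        )
        assert d > 0.5


class TestSourceAssignment:
    regions = {"ju": "Khoesan", "gbr": "Eurasia", "fula": "West",
               "kauma": "East"}

    def test_clear_winner_gives_singleton_sources(self):
        amps = {
            ("ju", "gbr"): (10.0, 0.5, True),
            ("fula", "gbr"): (4.0, 0.5, True),
            ("ju", "kauma"): (3.0, 0.5, True),
            ("fula", "kauma"): (1.0, 0.5, True),
        }
        sa = assign_event_sources(amps, self.regions)
        assert sa.best_pair == ("ju", "gbr")
        assert sa.source1_regions == ["Khoesan"]
        assert sa.source2_regions == ["Eurasia"]
        assert set(sa.major_regions) == {"Khoesan", "Eurasia"}

    def test_indistinguishable_substitutes_join_source_set(self):
        amps = {
            ("ju", "gbr"): (10.0, 1.0, True),
            ("fula", "gbr"): (9.5, 1.0, True),
            ("ju", "kauma"): (2.0, 1.0, True),
        }
        sa = assign_event_sources(amps, self.regions)
        assert set(sa.source1_regions) == {"Khoesan", "West"}

    def test_no_major_ancestry_when_balanced(self):
        amps = {
            ("ju", "gbr"): (10.0, 2.0, True),
            ("fula", "kauma"): (9.0, 2.0, True),
        }
        sa = assign_event_sources(amps, self.regions)
        assert sa.major_regions == []

    def test_no_significant_curves_rejected(self):
        with pytest.raises(ValueError):
            assign_event_sources(
                {("ju", "gbr"): (1.0, 1.0, False)}, self.regions
            )
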