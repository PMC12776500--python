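"""Embryo-level summaries, marker normalization and the Wasserstein-ratio test."""

import numpy as np
import pandas as pd
import pytest

from misalign import (
    EmbryoSample,
    angular_difference,
    gini_ratio_statistic,
    normalize_marker,
    permutation_test,
    sample_orientations,
    summarize_median,
    wasserstein_1d,
)


def wasserstein_oracle(a, b):
    """Independent oracle: integrate |F_a - F_b| between pooled breakpoints."""
    a, b = np.sort(a), np.sort(b)
    grid = np.unique(np.concatenate([a, b]))
    total = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        fa = np.searchsorted(a, lo, side="right") / len(a)
        fb = np.searchsorted(b, lo, side="right") / len(b)
        total += abs(fa - fb) * (hi - lo)
    return total


def goa_sample(sigma, n, rng, mean=90.0):
    theta = sample_orientations(n, "wrapped_normal", mean, sigma, rng)
    return angular_difference(theta, mean)


def cohort(sigma_a, sigma_b, rng, n_embryos=4, n_cells=200):
    samples = []
    for label, sigma in (("wt", sigma_a), ("mut", sigma_b)):
        for e in range(n_embryos):
            samples.append(
                EmbryoSample(f"{label}{e}", label, "pooled", goa_sample(sigma, n_cells, rng))
            )
    return samples


class TestSummarizeMedian:
    def test_odd_even_and_nan_conventions(self):
        scores = pd.Series([1, 2, 3, 1, 2, 3, 4, 1, np.nan, 3], dtype=float)
        embryos = pd.Series(["e1"] * 3 + ["e2"] * 4 + ["e3"] * 3)
        locations = pd.Series(["L"] * 10)
        out = summarize_median(scores, embryos, locations)
        assert out.loc["e1", "L"] == 2.0
        assert out.loc["e2", "L"] == 2.5  # midpoint convention
        assert out.loc["e3", "L"] == 2.0  # undefined values ignored

    def test_all_undefined_group_missing_with_warning(self, caplog):
        scores = pd.Series([np.nan, np.nan, 5.0])
        embryos = pd.Series(["e1", "e1", "e2"])
        locations = pd.Series(["L", "L", "L"])
        with caplog.at_level("WARNING"):
            out = summarize_median(scores, embryos, locations)
        assert np.isnan(out.loc["e1", "L"])
        assert out.loc["e2", "L"] == 5.0
        assert any("no defined scores" in r.message for r in caplog.records)


class TestNormalizeMarker:
    def test_reference_mean_maps_to_one(self):
        ref = [8.0, 12.0]  # mean 10
        assert normalize_marker(10.0, ref) == pytest.approx(1.0)
        assert normalize_marker(25.0, ref) == pytest.approx(2.5)

    def test_self_normalization_has_mean_one(self):
        rng = np.random.default_rng(0)
        ref = rng.gamma(5.0, 2.0, 500)
        assert np.mean(normalize_marker(ref, ref)) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_marker([1.0], [0.0, 0.0])


class TestWasserstein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [([0, 1], [0, 1], 0.0), ([0], [3], 3.0), ([0, 2], [1, 3], 1.0)],
    )
    def test_examples(self, a, b, expected):
        assert wasserstein_1d(a, b) == pytest.approx(expected)

    def test_matches_cdf_integral_oracle_unequal_sizes(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 40))
            b = rng.normal(0.5, 2, rng.integers(2, 40))
            assert wasserstein_1d(a, b) == pytest.approx(wasserstein_oracle(a, b))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b, c = (rng.uniform(0, 90, 25) for _ in range(3))
            dab, dbc, dac = wasserstein_1d(a, b), wasserstein_1d(b, c), wasserstein_1d(a, c)
            assert dab == pytest.approx(wasserstein_1d(b, a))
            assert dac <= dab + dbc + 1e-9
        assert wasserstein_1d(a, a) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestGiniRatio:
    def test_hand_computed_point_mass_toy(self):
        """2+2 embryos as point masses: all pairwise distances tabulated by hand."""
        samples = [
            EmbryoSample("a1", "A", "L", [0.0]),
            EmbryoSample("a2", "A", "L", [2.0]),
            EmbryoSample("b1", "B", "L", [10.0]),
            EmbryoSample("b2", "B", "L", [14.0]),
        ]
        # within: D(a1,a2)=2, D(b1,b2)=4 → mean 3
        # between: 10, 14, 8, 12 → mean 11
        assert gini_ratio_statistic(samples) == pytest.approx(11.0 / 3.0)

    def test_relabeling_and_order_invariance(self):
        rng = np.random.default_rng(1)
        samples = cohort(10, 20, rng, n_embryos=3)
        base = gini_ratio_statistic(samples)
        renamed = [
            EmbryoSample(s.embryo_id, {"wt": "g2", "mut": "g1"}[s.group_label],
                         s.location_label, s.values)
            for s in samples
        ]
        assert gini_ratio_statistic(renamed) == pytest.approx(base)
        rng.shuffle(samples)
        assert gini_ratio_statistic(samples) == pytest.approx(base)

    def test_null_ratio_near_one(self):
        rng = np.random.default_rng(2)
        vals = [gini_ratio_statistic(cohort(15, 15, rng, n_embryos=3)) for _ in range(40)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_separated_groups_much_greater_than_one(self):
        rng = np.random.default_rng(3)
        samples = []
        for label, mean in (("wt", 5.0), ("mut", 45.0)):
            for e in range(3):
                samples.append(
                    EmbryoSample(f"{label}{e}", label, "L",
                                 rng.normal(mean, 1.0, 200))
                )
        assert gini_ratio_statistic(samples) > 5.0

    def test_single_embryo_per_group_degenerate(self):
        samples = [
            EmbryoSample("a", "A", "L", [1.0, 2.0]),
            EmbryoSample("b", "B", "L", [3.0, 4.0]),
        ]
        with pytest.raises(ValueError):
            gini_ratio_statistic(samples)


class TestPermutationTest:
    def test_exhaustive_enumeration_for_small_designs(self):
        rng = np.random.default_rng(4)
        result = permutation_test(cohort(5, 40, rng), 999, seed=0)
        assert result.exhaustive
        assert result.n_permutations == 70  # C(8,4) distinct relabelings
        # swapping every label leaves the ratio unchanged, so the observed
        # assignment always ties its complement: minimum p is 2/70
        assert result.p_value == pytest.approx(2.0 / 70.0)

    def test_add_one_formula_on_large_separated_design(self):
        """7+7 embryos (3432 assignments > B): Monte-Carlo path, p = 1/(B+1)."""
        rng = np.random.default_rng(5)
        samples = []
        for label, mean in (("wt", 0.0), ("mut", 60.0)):
            for e in range(7):
                samples.append(
                    EmbryoSample(f"{label}{e}", label, "L", rng.normal(mean, 0.5, 50))
                )
        result = permutation_test(samples, 999, seed=1)
        assert not result.exhaustive
        assert result.p_value == pytest.approx(1.0 / 1000.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(6)
        samples = [
            EmbryoSample(f"{g}{e}", g, "L", rng.uniform(0, 90, 40))
            for g in ("a", "b") for e in range(6)
        ]
        r1 = permutation_test(samples, 199, seed=42)
        r2 = permutation_test(samples, 199, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_p_value_floor(self):
        rng = np.random.default_rng(7)
        result = permutation_test(cohort(10, 10, rng), 99, seed=0)
        assert result.p_value >= 1.0 / (result.n_permutations + 1)

    def test_degenerate_design_rejected(self):
        samples = [
            EmbryoSample("a", "A", "L", [1.0]),
            EmbryoSample("b", "B", "L", [2.0]),
        ]
        with pytest.raises(ValueError):
            permutation_test(samples, 99)
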