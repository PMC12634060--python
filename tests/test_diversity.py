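import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from firegraze import (
    DiversityConfig,
    detrended_richness,
    diversity_series,
    pie_evenness,
    rarefied_richness,
    spore_metrics,
)
from firegraze.model import ComputationError


class TestRarefiedRichness:
    def test_two_taxon_exhaustive_case(self):
        # counts {2,1}, n=2: the three unordered subsamples have richness 1,2,2
        assert rarefied_richness([2, 1], 2) == pytest.approx(5 / 3)

    def test_full_sample_returns_observed_richness(self):
        assert rarefied_richness([4, 7, 1, 3], 15) == pytest.approx(4.0)

    def test_single_draw_yields_one_taxon(self):
        assert rarefied_richness([5, 9, 2], 1) == pytest.approx(1.0)

    def test_undersized_sample_is_undefined_not_extrapolated(self):
        assert np.isnan(rarefied_richness([2, 1], 10))

    def test_large_counts_numerically_stable(self):
        # dominated by log-gamma terms; must stay finite and bounded by k
        val = rarefied_richness([50000, 30000, 1, 2], 92)
        assert 2.0 < val < 4.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(1, 30), min_size=2, max_size=6))
    def test_monotone_in_subsample_size(self, counts):
        N = sum(counts)
        values = [rarefied_richness(counts, n) for n in range(1, N + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestPIE:
    def test_two_even_taxa(self):
        # ordered draws without replacement: 2 * (5/10)(5/9) = 50/90
        assert pie_evenness([5, 5]) == pytest.approx(50 / 90)

    def test_monoculture_is_zero(self):
        assert pie_evenness([10]) == pytest.approx(0.0)

    def test_large_even_community_limit(self):
        # k equal taxa: PIE = N/(N-1) * (1 - 1/k)
        assert pie_evenness([100] * 4) == pytest.approx(400 / 399 * 0.75)

    def test_single_grain_undefined(self):
        assert np.isnan(pie_evenness([1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 50), min_size=2, max_size=8).filter(
        lambda c: sum(c) >= 2))
    def test_invariant_under_permutation(self, counts):
        rng = np.random.default_rng(0)
        perm = rng.permutation(counts)
        assert pie_evenness(counts) == pytest.approx(pie_evenness(perm))


class TestDetrendedRichness:
    def test_zero_slope_reduces_to_centering(self):
        pri = np.array([10.0, 12.0, 11.0, 13.0])
        pie = np.array([0.5, 0.6, 0.6, 0.5])  # chosen so OLS slope is 0
        d = detrended_richness(pri, pie)
        np.testing.assert_allclose(d, pri - pri.mean())

    def test_exactly_linear_gives_zero_residuals(self):
        pie = np.linspace(0.2, 0.9, 10)
        pri = 3.0 + 10.0 * pie
        np.testing.assert_allclose(detrended_richness(pri, pie), 0.0, atol=1e-10)

    def test_constant_evenness_warns_and_centers(self):
        pri = np.array([1.0, 2.0, 3.0])
        pie = np.array([0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="constant evenness"):
            d = detrended_richness(pri, pie)
        np.testing.assert_allclose(d, pri - 2.0)

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(3)
        pie = rng.uniform(0.3, 0.9, 200)
        pri = 5.0 + 10.0 * pie + rng.normal(0, 1.0, 200)
        from scipy import stats

        slope = stats.linregress(pie, pri).slope
        assert 9.5 <= slope <= 10.5
        resid = detrended_richness(pri, pie)
        assert abs(resid[np.isfinite(resid)].mean()) < 1e-9

    def test_nan_propagates_as_flag(self):
        pri = np.array([1.0, np.nan, 3.0, 4.0])
        pie = np.array([0.1, 0.2, 0.3, 0.4])
        d = detrended_richness(pri, pie)
        assert np.isnan(d[1]) and np.isfinite(d[[0, 2, 3]]).all()


class TestSporeMetrics:
    def test_richness_counts_present_types(self, tiny_dataset):
        counts, meta, chron = tiny_dataset
        from firegraze import influx_table

        m = spore_metrics(counts, meta, influx_table(counts, chron))
        assert m.loc["mid", "spore_richness"] == 0
        assert m.loc["bot", "spore_richness"] == 1
        assert m.loc["mid", "spore_influx"] == 0.0

    def test_reliable_subset_filters_both_metrics(self, default_dataset, default_influx):
        counts, meta, chron, _ = default_dataset
        all_m = spore_metrics(counts, meta, default_influx, "all")
        rel_m = spore_metrics(counts, meta, default_influx, "reliable_only")
        assert (rel_m["spore_richness"] <= all_m["spore_richness"]).all()
        assert (rel_m["spore_influx"] <= all_m["spore_influx"] + 1e-12).all()
        assert (rel_m["spore_influx"] < all_m["spore_influx"]).any()


class TestDiversitySeries:
    def test_defaults_use_min_terrestrial_sum(self, default_dataset, default_diversity):
        counts, meta, chron, _ = default_dataset
        from firegraze import terrestrial_sum

        assert default_diversity.attrs["rarefaction_n"] == int(
            terrestrial_sum(counts, meta).min()
        )
        assert (default_diversity["PIE"].dropna() <= 1.0).all()
        assert (default_diversity["PIE"].dropna() >= 0.0).all()

    def test_pri_never_exceeds_observed_richness(self, default_dataset, default_diversity):
        counts, meta, chron, _ = default_dataset
        terr = [t for t in meta.terrestrial_taxa if t in counts.counts.index]
        observed = (counts.counts.loc[terr] > 0).sum(axis=0)
        assert (default_diversity["PRI"] <= observed + 1e-9).all()


def test_rarefaction_agrees_with_small_monte_carlo():
    """Spot-check the expectation formula against subsampling on one vector."""
    rng = np.random.default_rng(11)
    counts = np.array([12, 7, 3, 1])
    draws = rng.multivariate_hypergeometric(counts, 8, size=50_000)
    richness = (draws > 0).sum(axis=1)
    mc, se = richness.mean(), richness.std(ddof=1) / np.sqrt(len(richness))
    assert abs(rarefied_richness(counts, 8) - mc) < 3 * se
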