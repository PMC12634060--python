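import numpy as np
import pandas as pd
import pytest

from firegraze import Chronology, CountTable, RoCConfig, TaxonMeta, chisq_dissimilarity, roc_series
from firegraze.model import ComputationError, ConfigError
from firegraze.turnover import age_weighted_smooth, bin_working_units, detect_peaks


def make_series_dataset(rows, ages):
    """CountTable/TaxonMeta/Chronology from a samples x taxa count array."""
    rows = np.asarray(rows)
    samples = [f"s{i:02d}" for i in range(rows.shape[0])]
    taxa = [f"t{j}" for j in range(rows.shape[1])]
    counts = pd.DataFrame(rows.T, index=taxa, columns=samples)
    ct = CountTable(
        counts,
        pd.Series(100.0, index=samples),
        pd.Series(1000.0, index=samples),
        pd.Series(2.0, index=samples),
    )
    meta = TaxonMeta(
        table=pd.DataFrame(
            {"group": "terrestrial_pollen", "habitat": "grassland"}, index=taxa
        )
    )
    chron = Chronology(
        table=pd.DataFrame(
            {
                "depth_cm": np.arange(len(samples)) + 1.0,
                "age_calBP": np.asarray(ages, dtype=float),
                "deposition_time_yr_per_cm": 20.0,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    return ct, meta, chron


TWO_REGIME = np.array([[80, 20, 0, 0]] * 10 + [[0, 0, 20, 80]] * 10)
TWO_REGIME_AGES = np.arange(20) * 100.0


class TestChisqDissimilarity:
    def test_identical_vectors(self):
        assert chisq_dissimilarity([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_support(self):
        assert chisq_dissimilarity([1, 0], [0, 1]) == pytest.approx(np.sqrt(2))

    def test_symmetry(self):
        p, q = [0.2, 0.5, 0.3], [0.6, 0.1, 0.3]
        assert chisq_dissimilarity(p, q) == chisq_dissimilarity(q, p)

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ComputationError):
            chisq_dissimilarity([-0.1, 1.1], [0.5, 0.5])
        with pytest.raises(ComputationError):
            chisq_dissimilarity([0.5, 0.4], [0.5, 0.5])


class TestBinning:
    def test_shift_offsets(self):
        ages = np.arange(0, 1001, 100)
        binnings = bin_working_units(ages, 200, 5)
        assert len(binnings) == 5
        first_mids = [b[0][0] for b in binnings]
        # bin edges move back by 40 yr per shift
        np.testing.assert_allclose(np.diff(first_mids), -40.0)

    def test_one_sample_per_bin_returns_samples(self):
        ages = np.array([0.0, 500.0, 1000.0])
        units = bin_working_units(ages, 200, 1)[0]
        assert [m for _, m in units] == [[0], [1], [2]]

    def test_empty_bins_are_skipped(self):
        ages = np.array([0.0, 100.0, 900.0, 1000.0])
        units = bin_working_units(ages, 200, 1)[0]
        # occupied bins [0,200), [800,1000), [1000,1200); bins 1-3 vanish
        assert [m for _, m in units] == [[0, 1], [2], [3]]
        assert [mid for mid, _ in units] == [100.0, 900.0, 1100.0]


class TestSmoothing:
    def test_isolated_sample_unchanged(self):
        x = np.array([[1.0, 2.0], [5.0, 6.0]])
        out = age_weighted_smooth(x, [0.0, 10_000.0], window=200)
        np.testing.assert_allclose(out, x)

    def test_identical_neighbors_fixed_point(self):
        x = np.array([[3.0, 7.0]] * 3)
        out = age_weighted_smooth(x, [0.0, 50.0, 100.0], window=200)
        np.testing.assert_allclose(out, x)

    def test_convex_pull_toward_neighbors(self):
        # compositions A, B, A at spacing d=50 inside the window:
        # middle -> (w*A + 1*B + w*A)/(1+2w) with w = 1/51
        A, B = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        out = age_weighted_smooth(np.array([A, B, A]), [0.0, 50.0, 100.0], window=200)
        w = 1.0 / 51.0
        expected = (2 * w * A + B) / (1 + 2 * w)
        np.testing.assert_allclose(out[1], expected)


class TestRoCSeries:
    def test_constant_composition_gives_zero(self):
        ct, meta, chron = make_series_dataset([[50, 30, 12]] * 12, np.arange(12) * 100.0)
        out = roc_series(ct, meta, chron, RoCConfig(seed=0, n_randomizations=10))
        assert out["roc_median"].max() == 0.0
        assert not out["peak"].any()

    def test_abrupt_switch_is_localized(self):
        ct, meta, chron = make_series_dataset(TWO_REGIME, TWO_REGIME_AGES)
        out = roc_series(ct, meta, chron, RoCConfig(seed=1))
        peak_age = out.loc[out["roc_median"].idxmax(), "age_calBP"]
        assert 800 <= peak_age <= 1200

    def test_time_standardisation_is_linear(self):
        ct, meta, chron = make_series_dataset(TWO_REGIME, TWO_REGIME_AGES)
        a = roc_series(ct, meta, chron, RoCConfig(seed=2, time_standardisation_yr=200))
        b = roc_series(ct, meta, chron, RoCConfig(seed=2, time_standardisation_yr=400))
        np.testing.assert_allclose(b["roc_median"], 2 * a["roc_median"])

    def test_deterministic_under_seed(self):
        ct, meta, chron = make_series_dataset(TWO_REGIME, TWO_REGIME_AGES)
        a = roc_series(ct, meta, chron, RoCConfig(seed=7))
        b = roc_series(ct, meta, chron, RoCConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_under_taxon_relabeling(self):
        ct, meta, chron = make_series_dataset(TWO_REGIME, TWO_REGIME_AGES)
        perm = [2, 0, 3, 1]
        ct2, meta2, _ = make_series_dataset(TWO_REGIME[:, perm], TWO_REGIME_AGES)
        a = roc_series(ct, meta, chron, RoCConfig(seed=3))
        b = roc_series(ct2, meta2, chron, RoCConfig(seed=3))
        np.testing.assert_allclose(a["roc_median"], b["roc_median"])

    def test_median_stabilizes_at_many_randomizations(self):
        rng = np.random.default_rng(0)
        probs = np.array([[0.5, 0.3, 0.15, 0.05]] * 10 + [[0.05, 0.15, 0.3, 0.5]] * 10)
        rows = np.array([rng.multinomial(rng.integers(150, 300), p) for p in probs])
        ct, meta, chron = make_series_dataset(rows, TWO_REGIME_AGES)
        a = roc_series(ct, meta, chron, RoCConfig(seed=10, n_randomizations=1000))
        b = roc_series(ct, meta, chron, RoCConfig(seed=99, n_randomizations=1000))
        denom = np.maximum(a["roc_median"].to_numpy(), 1e-12)
        rel = np.abs(a["roc_median"].to_numpy() - b["roc_median"].to_numpy()) / denom
        assert rel.max() < 0.05

    def test_too_few_working_units(self):
        ct, meta, chron = make_series_dataset([[10, 5]] * 3, [0.0, 50.0, 100.0])
        with pytest.raises(ComputationError, match="working units"):
            roc_series(ct, meta, chron, RoCConfig(seed=0))

    def test_bin_size_must_divide_by_shifts(self):
        with pytest.raises(ConfigError):
            RoCConfig(bin_size_yr=200, n_shifts=3)


class TestPeakDetection:
    def test_flat_series_has_no_peaks(self):
        ages = np.arange(10) * 200.0
        assert not detect_peaks(ages, np.ones(10)).any()

    def test_flags_shrink_with_threshold(self):
        rng = np.random.default_rng(5)
        ages = np.arange(40) * 200.0
        roc = 0.2 + rng.exponential(0.05, 40)
        roc[13] += 0.6
        roc[29] += 0.4
        flags = [detect_peaks(ages, roc, multiplier=m).sum() for m in (1.0, 1.96, 3.0)]
        assert flags[0] >= flags[1] >= flags[2]

    def test_needs_five_units(self):
        with pytest.raises(ComputationError):
            detect_peaks([0, 200, 400, 600], [1, 2, 1, 2])
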