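"""Preprocessing oracles: despiking, ALS baseline, smoothing, min-max."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersdx import (CohortPlan, NoiseModel, RamanSpectrum,
                    binary_signatures, simulate_cohort)
from sersdx.preprocess import (PreprocessConfig, als_baseline, despike_vector,
                               minmax_vector, normalize_minmax,
                               preprocess_pipeline, remove_cosmic_rays,
                               smooth_gaussian)

from conftest import SEED, single_peak_signature


def smoothing_oracle(x, sigma, truncate=4.0):
    """Direct O(n k) convolution with a renormalized truncated kernel and
    symmetric-reflect padding (independent of scipy.ndimage)."""
    radius = int(truncate * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    xp = np.concatenate([x[radius - 1::-1], x, x[:-radius - 1:-1]])
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        out[i] = float(np.dot(xp[i:i + 2 * radius + 1], k[::-1]))
    return out


class TestDespike:
    def test_noop_on_spike_free_noisy_spectrum(self, noisy_binary_small):
        x = simulate_cohort(
            CohortPlan(binary_signatures(), 2, 2,
                       noise=NoiseModel(spike_rate=0.0), seed=SEED)
        ).intensities[0]
        y, flags = despike_vector(x)
        assert not flags.any()
        np.testing.assert_array_equal(y, x)  # bit-identical

    def test_single_spike_removed_on_flat_region(self, grid):
        sig = single_peak_signature(center=1080.0, width=10.0, amplitude=1.0)
        clean = sig.clean_profile(grid)
        k = grid.index_of(500.0)  # far from any band: locally flat
        spiked = clean.copy()
        spiked[k] += 50.0
        y, flags = despike_vector(spiked)
        assert flags[k]
        assert abs(y[k] - clean[k]) < 1e-6
        off = np.ones_like(y, bool)
        off[k] = False
        np.testing.assert_array_equal(y[off], clean[off])

    def test_adjacent_spikes_flagged_and_interpolated(self, grid):
        sig = single_peak_signature()
        clean = sig.clean_profile(grid)
        rng = np.random.default_rng(SEED)
        noisy = clean + rng.normal(0, 0.03, clean.size)
        k = grid.index_of(600.0)
        spiked = noisy.copy()
        spiked[k] += 3.0
        spiked[k + 1] += 2.0
        y, flags = despike_vector(spiked)
        # brute-force truth: exactly the channels whose value was raised
        truth = np.zeros_like(flags)
        truth[[k, k + 1]] = True
        np.testing.assert_array_equal(flags, truth)
        expected = np.interp([k, k + 1], [k - 1, k + 2],
                             [spiked[k - 1], spiked[k + 2]])
        np.testing.assert_allclose(y[[k, k + 1]], expected)

    def test_recall_and_precision_against_ground_truth(self):
        plan = CohortPlan(binary_signatures(), samples_per_class=2,
                          spectra_per_sample=150,
                          noise=NoiseModel(spike_rate=1.0), seed=SEED)
        ds = simulate_cohort(plan)
        tp = fp = fn = 0
        total_spikes = 0
        for i in range(ds.n_spectra):
            truth = set(ds.meta["spike_channels"].iloc[i])
            total_spikes += len(truth)
            _, flags = despike_vector(ds.intensities[i])
            found = set(np.nonzero(flags)[0])
            tp += len(found & truth)
            fp += len(found - truth)
            fn += len(truth - found)
        assert total_spikes >= 300
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.95

    def test_window_exceeding_spectrum_is_error(self):
        from sersdx import WavenumberGrid
        tiny = WavenumberGrid(400, 404, 1)
        s = RamanSpectrum(tiny, np.ones(5))
        with pytest.raises(ValueError, match="window"):
            remove_cosmic_rays(s, PreprocessConfig(despike_window=11))


class TestBaseline:
    def test_zero_baseline_peaks_nearly_untouched(self, grid):
        sig = single_peak_signature(amplitude=1.0)
        clean = sig.clean_profile(grid)
        corrected = clean - als_baseline(clean)
        assert np.abs(corrected - clean).max() < 0.02

    def test_linear_ramp_removed(self):
        x = np.linspace(0.0, 2.0, 1401)
        corrected = x - als_baseline(x)
        interior = corrected[20:-20]
        assert np.abs(interior).max() < 0.01 * 2.0

    def test_constant_offset_removed(self):
        x = np.full(1401, 5.0)
        corrected = x - als_baseline(x)
        assert np.abs(corrected).max() < 0.01 * 5.0

    def test_nonfinite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            als_baseline(x)

    def test_recovers_peaks_over_curved_baseline(self, grid):
        sig = single_peak_signature(center=1080.0, amplitude=1.0)
        clean = sig.clean_profile(grid)
        t = np.linspace(0, 1, len(grid))
        drift = 0.5 + 0.3 * t - 0.2 * t**2
        corrected = (clean + drift) - als_baseline(clean + drift)
        k = grid.index_of(1080.0)
        assert corrected[k] == pytest.approx(1.0, abs=0.05)


class TestSmoothing:
    def test_constant_preserved(self, grid):
        s = RamanSpectrum(grid, np.full(len(grid), 3.5))
        out = smooth_gaussian(s, PreprocessConfig())
        np.testing.assert_allclose(out.intensity, 3.5, atol=1e-12)

    def test_impulse_reproduces_kernel(self, grid):
        sigma = 2.0
        radius = int(4.0 * sigma + 0.5)
        x = np.zeros(len(grid))
        mid = len(grid) // 2
        x[mid] = 1.0
        s = RamanSpectrum(grid, x)
        out = smooth_gaussian(s, PreprocessConfig(smooth_sigma=sigma))
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        np.testing.assert_allclose(
            out.intensity[mid - radius:mid + radius + 1], k, atol=1e-12)
        assert out.intensity.sum() == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, grid):
        rng = np.random.default_rng(SEED)
        x = rng.random(len(grid))
        s = RamanSpectrum(grid, x)
        out = smooth_gaussian(s, PreprocessConfig(smooth_sigma=2.0))
        np.testing.assert_allclose(out.intensity, smoothing_oracle(x, 2.0),
                                   atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_never_increases_max_for_nonnegative_input(self, seed):
        x = np.random.default_rng(seed).random(200)
        out = smoothing_oracle(x, 2.0)
        assert out.max() <= x.max() + 1e-12
        assert out.min() >= 0.0


class TestMinMax:
    def test_simple_vector(self):
        np.testing.assert_allclose(minmax_vector(np.array([2.0, 4.0, 6.0])),
                                   [0.0, 0.5, 1.0])

    def test_idempotent_on_normalized_input(self):
        x = np.array([0.0, 0.3, 1.0, 0.7])
        np.testing.assert_array_equal(minmax_vector(x), x)

    def test_constant_gives_zeros_and_warning(self, grid):
        s = RamanSpectrum(grid, np.full(len(grid), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_minmax(s)
        assert (out.intensity == 0).all()

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounds_attained_for_nonconstant(self, values):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        out = minmax_vector(x)
        assert out.min() == 0.0
        assert out.max() == 1.0
        assert ((out >= 0) & (out <= 1)).all()


class TestPipeline:
    def test_empty_dataset_passthrough(self, noiseless_binary):
        empty = noiseless_binary.subset(
            np.zeros(noiseless_binary.n_spectra, dtype=bool))
        out = preprocess_pipeline(empty)
        assert out.n_spectra == 0
        assert out.attrs["preprocessed"]

    def test_output_in_unit_interval(self, noisy_binary_small):
        out = preprocess_pipeline(noisy_binary_small)
        assert out.intensities.min() >= 0.0
        assert out.intensities.max() <= 1.0

    def test_marker_rank_order_preserved(self, noisy_binary_small):
        ds = noisy_binary_small
        out = preprocess_pipeline(ds)
        k = ds.grid.index_of(1080.0)
        cancer = (ds.meta["class_label"] == "cancer").to_numpy()
        assert (out.intensities[cancer, k].mean()
                > out.intensities[~cancer, k].mean())

    def test_ids_and_labels_preserved(self, noisy_binary_small):
        out = preprocess_pipeline(noisy_binary_small)
        assert out.meta["spectrum_id"].tolist() == \
            noisy_binary_small.meta["spectrum_id"].tolist()
        assert out.meta["class_label"].tolist() == \
            noisy_binary_small.meta["class_label"].tolist()

    def test_custom_order_baseline_first(self, noisy_binary_small):
        cfg = PreprocessConfig(step_order=("baseline", "despike", "smooth",
                                           "normalize"))
        out = preprocess_pipeline(noisy_binary_small, cfg)
        assert out.intensities.min() >= 0.0
        assert out.intensities.max() <= 1.0

    def test_step_error_carries_spectrum_id(self, grid):
        # a NaN intensity reaches the baseline step and names the spectrum
        import pandas as pd

        from sersdx import CohortDataset
        bad = np.ones((1, len(grid)))
        meta = pd.DataFrame({"spectrum_id": ["s0_r0"], "sample_id": ["s0"],
                             "class_label": ["cancer"], "stage": [""]})
        ds = CohortDataset(grid, bad, meta)
        ds.intensities[0, 5] = np.inf  # bypass RamanSpectrum validation
        with pytest.raises(ValueError, match="s0_r0"):
            preprocess_pipeline(ds, PreprocessConfig(
                step_order=("baseline",)))
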