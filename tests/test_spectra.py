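"""Spectrum preprocessing: dark subtraction, despiking, ALS baseline, peaks."""

import numpy as np
import pandas as pd
import pytest

from sesorsmc.errors import AlignmentError
from sesorsmc.spectra import (
    PeakDefinition,
    Spectrum,
    SynthParams,
    als_baseline,
    correct_baseline,
    peak_intensity,
    preprocess,
    read_spectrum,
    remove_cosmic_rays,
    subtract_dark,
    summarize_replicates,
    synth_spectrum,
    write_spectrum,
)


def _flat(n=500, level=100.0, start=400.0):
    wn = np.arange(start, start + n)
    return Spectrum(wn, np.full(n, level))


class TestSubtractDark:
    def test_raw_equals_dark_gives_zero(self):
        s = _flat()
        assert np.all(subtract_dark(s, s).intensities == 0.0)

    def test_zero_dark_is_identity(self):
        s = _flat()
        z = s.with_intensities(np.zeros(len(s)))
        assert np.array_equal(subtract_dark(s, z).intensities, s.intensities)

    def test_constant_offset_recovered(self):
        s = _flat(level=105.0)
        d = _flat(level=100.0)
        assert np.all(subtract_dark(s, d).intensities == 5.0)

    def test_mismatched_axes_rejected(self):
        with pytest.raises(AlignmentError):
            subtract_dark(_flat(start=400.0), _flat(start=401.0))


class TestRemoveCosmicRays:
    def _with_peak_and_spike(self):
        wn = np.arange(400.0, 1400.0)
        y = np.zeros_like(wn)
        y += 100.0 * np.exp(-0.5 * ((wn - 900) / 8.5) ** 2)  # ~20 cm-1 peak
        y[200] = 60.0  # 1-point spike, 60% of range
        return Spectrum(wn, y)

    def test_narrow_large_spike_removed_peak_preserved(self):
        s = self._with_peak_and_spike()
        out = remove_cosmic_rays(s)
        assert out.intensities[200] < 1.0
        m = np.abs(s.wavenumbers - 900) < 15
        assert np.array_equal(out.intensities[m], s.intensities[m])

    def test_wide_peak_untouched(self):
        wn = np.arange(400.0, 1400.0)
        y = 100.0 * np.exp(-0.5 * ((wn - 900) / 8.5) ** 2)
        out = remove_cosmic_rays(Spectrum(wn, y))
        assert np.array_equal(out.intensities, y)

    def test_small_spike_below_threshold_untouched(self):
        wn = np.arange(400.0, 900.0)
        y = np.zeros_like(wn)
        y[100] = 100.0     # defines the range
        y[300] = 10.0      # 10% of range: below the 15% rule
        out = remove_cosmic_rays(Spectrum(wn, y))
        assert out.intensities[300] == 10.0

    def test_two_point_spike_removed(self):
        wn = np.arange(400.0, 900.0)
        y = np.full_like(wn, 10.0)
        y[[250, 251]] = 110.0
        out = remove_cosmic_rays(Spectrum(wn, y))
        assert np.allclose(out.intensities[[250, 251]], 10.0)

    def test_idempotent_on_synthetic_fixtures(self):
        for seed in range(20):
            raw, dark, _ = synth_spectrum(np.random.default_rng(seed))
            s = subtract_dark(raw, dark)
            once = remove_cosmic_rays(s)
            twice = remove_cosmic_rays(once)
            assert np.array_equal(once.intensities, twice.intensities)


class TestAlsBaseline:
    def test_zero_spectrum_gives_zero_baseline(self):
        s = _flat(level=0.0)
        assert np.allclose(als_baseline(s).intensities, 0.0)

    def test_tracks_slowly_varying_input(self):
        wn = np.arange(400.0, 1400.0)
        y = 200.0 + 0.05 * (wn - 400.0)
        base = als_baseline(Spectrum(wn, y))
        rms = np.sqrt(np.mean((base.intensities - y) ** 2))
        assert rms / np.sqrt(np.mean(y**2)) < 0.01

    def test_baseline_stays_near_flat_level_under_peak(self):
        # a stiff smoother barely lifts under an isolated narrow peak
        wn = np.arange(400.0, 1400.0)
        b = 50.0
        y = b + 500.0 * np.exp(-0.5 * ((wn - 900) / 8.5) ** 2)
        base = als_baseline(Spectrum(wn, y), smoothness=1e8)
        under = np.abs(wn - 900) < 10
        assert np.all(np.abs(base.intensities[under] - b) < 0.02 * b)

    def test_matches_dense_reference_solver(self):
        # independent oracle: the same penalized system assembled dense
        rng = np.random.default_rng(3)
        wn = np.arange(400.0, 700.0)
        y = 100.0 + 0.1 * (wn - 400.0) + rng.normal(0, 1.0, wn.size)
        lam, p = 1e5, 0.01
        m = y.size
        d2 = np.diff(np.eye(m), 2, axis=0)
        w = np.ones(m)
        for _ in range(10):
            z = np.linalg.solve(np.diag(w) + lam * d2.T @ d2, w * y)
            w = np.where(y > z, p, 1 - p)
        ours = als_baseline(Spectrum(wn, y), lam, p, 10).intensities
        assert np.allclose(ours, z, atol=1e-6)

    def test_invalid_parameters_rejected(self):
        s = _flat()
        with pytest.raises(ValueError):
            als_baseline(s, smoothness=-1.0)
        with pytest.raises(ValueError):
            als_baseline(s, asymmetry=1.5)


class TestPeakIntensity:
    def test_delta_like_peak_height(self):
        wn = np.arange(1000.0, 1200.0)
        y = np.zeros_like(wn)
        y[72] = 42.0  # at 1072 cm-1
        assert peak_intensity(Spectrum(wn, y), PeakDefinition(1072.0)) == 42.0

    def test_zero_spectrum(self):
        wn = np.arange(1000.0, 1200.0)
        s = Spectrum(wn, np.zeros_like(wn))
        assert peak_intensity(s, PeakDefinition(1072.0)) == 0.0

    def test_window_covers_only_requested_peak(self):
        wn = np.arange(1000.0, 1700.0)
        y = np.zeros_like(wn)
        y[72] = 10.0   # 1072
        y[582] = 99.0  # 1582
        assert peak_intensity(Spectrum(wn, y), PeakDefinition(1072.0)) == 10.0

    def test_disjoint_window_rejected(self):
        wn = np.arange(1000.0, 1100.0)
        s = Spectrum(wn, np.zeros_like(wn))
        with pytest.raises(IndexError):
            peak_intensity(s, PeakDefinition(1702.0))


class TestSummarizeReplicates:
    def test_mean_min_max(self):
        frame = pd.DataFrame(
            {
                "offset_mm": [0, 0, 0, 1],
                "peak": [1072, 1072, 1072, 1072],
                "intensity": [1.0, 2.0, 3.0, 7.0],
            }
        )
        out = summarize_replicates(frame)
        row0 = out[out.offset_mm == 0].iloc[0]
        assert (row0["mean"], row0["min"], row0["max"], row0["n"]) == (2.0, 1.0, 3.0, 3)
        row1 = out[out.offset_mm == 1].iloc[0]
        assert row1["mean"] == row1["min"] == row1["max"] == 7.0

    def test_order_invariant(self):
        frame = pd.DataFrame(
            {
                "offset_mm": [0, 0],
                "peak": [1072, 1072],
                "intensity": [3.0, 1.0],
            }
        )
        out = summarize_replicates(frame)
        assert out.iloc[0]["min"] <= out.iloc[0]["mean"] <= out.iloc[0]["max"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates(pd.DataFrame({"intensity": [1.0]}))


class TestSynthAndEndToEnd:
    def test_fixed_seed_bit_identical(self):
        a_raw, a_dark, _ = synth_spectrum(np.random.default_rng(7))
        b_raw, b_dark, _ = synth_spectrum(np.random.default_rng(7))
        assert np.array_equal(a_raw.intensities, b_raw.intensities)
        assert np.array_equal(a_dark.intensities, b_dark.intensities)

    def test_noise_free_chain_recovers_peak_heights_within_2pct(self):
        p = SynthParams(noise_sd=0.0, dark_noise_sd=0.0, n_spikes=0)
        raw, dark, truth = synth_spectrum(np.random.default_rng(0), p)
        corrected = preprocess(raw, dark)
        for c, h in zip(truth["peak_centers"], truth["peak_heights"]):
            got = peak_intensity(corrected, PeakDefinition(c))
            assert abs(got - h) / h < 0.02

    def test_injected_spike_removed_and_peaks_survive(self):
        p = SynthParams(noise_sd=0.0, dark_noise_sd=0.0, n_spikes=2)
        raw, dark, truth = synth_spectrum(np.random.default_rng(5), p)
        s = subtract_dark(raw, dark)
        out = remove_cosmic_rays(s)
        for spike in truth["spikes"]:
            i = spike["index"]
            assert out.intensities[i] < s.intensities[i] - 0.5 * spike["amplitude"]
        for c, h in zip(truth["peak_centers"], truth["peak_heights"]):
            got = peak_intensity(correct_baseline(out)[0], PeakDefinition(c))
            assert abs(got - h) / h < 0.02

    def test_baseline_removal_does_not_inflate_peaks(self):
        # corrected peak height never exceeds injected height by more than
        # the injected baseline variation across the peak window
        p = SynthParams(noise_sd=0.0, dark_noise_sd=0.0, n_spikes=0)
        raw, dark, truth = synth_spectrum(np.random.default_rng(1), p)
        corrected = preprocess(raw, dark)
        base = truth["baseline"]
        wn = corrected.wavenumbers
        for c, h in zip(truth["peak_centers"], truth["peak_heights"]):
            m = np.abs(wn - c) <= 10
            variation = base[m].max() - base[m].min()
            got = peak_intensity(corrected, PeakDefinition(c))
            assert got <= h + variation + 1e-6

    def test_round_trip_io(self, tmp_path):
        raw, _, _ = synth_spectrum(np.random.default_rng(2))
        path = tmp_path / "spec.txt"
        write_spectrum(raw, path)
        back = read_spectrum(path)
        assert np.allclose(back.wavenumbers, raw.wavenumbers)
        assert np.allclose(back.intensities, raw.intensities)
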