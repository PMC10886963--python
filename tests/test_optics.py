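"""Stokes-shift bookkeeping and the optical-property table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sesorsmc.errors import ConfigurationError, InvalidShiftError, TableLookupError
from sesorsmc.optics import (
    DEFAULT_PEAK_SHIFTS,
    OpticalProperties,
    RamanPeakSet,
    WavelengthGrid,
    build_property_table,
    load_property_csv,
    select_stokes_peak,
    stokes_wavelength,
)


class TestStokesWavelength:
    @pytest.mark.parametrize(
        "excitation, shift, expected",
        [
            (785.0, 0.0, 785.0),          # zero shift is the identity
            (785.0, 1072.0, 857.13),      # 1e7/(1e7/785 - 1072)
            (785.0, 1582.0, 896.31),
        ],
    )
    def test_known_values(self, excitation, shift, expected):
        assert stokes_wavelength(excitation, shift) == pytest.approx(
            expected, abs=0.01
        )

    def test_shift_beyond_excitation_wavenumber_rejected(self):
        with pytest.raises(InvalidShiftError):
            stokes_wavelength(785.0, 1e7 / 785.0)

    @given(
        shifts=st.tuples(
            st.floats(min_value=0.0, max_value=4000.0),
            st.floats(min_value=0.0, max_value=4000.0),
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_in_shift(self, shifts):
        a, b = sorted(shifts)
        if b - a < 1e-3:  # below the float resolution of the conversion
            return
        assert stokes_wavelength(785.0, a) < stokes_wavelength(785.0, b)


class TestRamanPeakSet:
    def test_default_set_is_the_four_mba_peaks(self):
        peaks = RamanPeakSet.default()
        assert peaks.shifts == DEFAULT_PEAK_SHIFTS
        assert abs(peaks.branch_probs.sum() - 1.0) < 1e-12
        assert np.all(peaks.branch_probs >= 0)

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ConfigurationError, match="branch_probs"):
            RamanPeakSet((1072.0, 1582.0), np.array([0.5, 0.4]))

    def test_nonincreasing_shifts_rejected(self):
        with pytest.raises(ConfigurationError):
            RamanPeakSet((1582.0, 1072.0), np.array([0.5, 0.5]))

    def test_from_reference_spectrum_weights_follow_areas(self):
        wn = np.arange(900.0, 1800.0)
        sigma = 8.0
        y = 3.0 * np.exp(-0.5 * ((wn - 1072) / sigma) ** 2)
        y += 1.0 * np.exp(-0.5 * ((wn - 1582) / sigma) ** 2)
        peaks = RamanPeakSet.from_reference_spectrum(
            wn, y, shifts=(1072.0, 1582.0)
        )
        # equal widths: areas proportional to heights 3:1
        assert peaks.branch_probs[0] == pytest.approx(0.75, abs=0.01)


class TestSelectStokesPeak:
    def test_inverse_cdf_examples(self):
        peaks = RamanPeakSet.default()
        # CDF ≈ (0.3747, 0.4817, 0.9466, 1.0)
        assert select_stokes_peak(peaks, 0.0) == 0      # 1072
        assert select_stokes_peak(peaks, 0.5) == 2      # 1582
        assert select_stokes_peak(peaks, 0.99) == 3     # 1702
        assert select_stokes_peak(peaks, np.nextafter(1.0, 0.0)) == 3

    def test_empirical_fractions_match_probabilities(self, rng):
        peaks = RamanPeakSet.default()
        n = 1_000_000
        k = select_stokes_peak(peaks, rng.random(n))
        counts = np.bincount(k, minlength=4)
        for i, p in enumerate(peaks.branch_probs):
            se = np.sqrt(n * p * (1 - p))
            assert abs(counts[i] - n * p) < 3 * se


class TestPropertyTable:
    def test_dermis_calibration_anchors(self, table):
        assert table.mu_s_decrease_percent("dermis", 1) == pytest.approx(
            14.68, abs=1e-9
        )
        assert table.mu_s_decrease_percent("dermis", 3) == pytest.approx(
            15.4, abs=1e-9
        )

    def test_mu_s_decreases_at_every_stokes_index(self, table):
        for tissue in ("epidermis", "dermis"):
            mu0 = table.lookup(tissue, 0).mu_s
            for k in range(1, table.grid.n_indices):
                assert table.lookup(tissue, k).mu_s < mu0

    def test_lookup_is_pure_retrieval(self, table):
        p = table.lookup("dermis", 0)
        assert p == table.lookup("dermis", 0)
        assert p.mu_s == 200.0

    def test_unknown_tissue_raises(self, table):
        with pytest.raises(TableLookupError):
            table.lookup("bone", 0)
        with pytest.raises(TableLookupError):
            table.lookup("dermis", 99)

    def test_flat_table_needs_monotone_check_disabled(self):
        flat = {
            t: {"mu_a": 1.0, "mu_s": 100.0, "g": 0.9, "n": 1.4}
            for t in ("epidermis", "dermis", "inclusion", "base")
        }
        with pytest.raises(ConfigurationError):
            build_property_table(flat)
        tbl = build_property_table(flat, enforce_monotone=False)
        assert tbl.lookup("dermis", 2).mu_s == 100.0

    def test_missing_property_named_in_error(self):
        with pytest.raises(ConfigurationError, match="mu_s"):
            build_property_table({"dermis": {"mu_a": 1.0, "g": 0.9, "n": 1.4}})

    def test_csv_round_trip(self, table, tmp_path):
        path = tmp_path / "props.csv"
        table.to_csv(path)
        loaded = load_property_csv(path, table.grid)
        for tissue in table.tissues:
            for k in range(table.grid.n_indices):
                assert loaded.lookup(tissue, k) == table.lookup(tissue, k)

    def test_invalid_physical_values_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalProperties(mu_a=-1.0, mu_s=10.0, g=0.9, n=1.4)
        with pytest.raises(ConfigurationError):
            OpticalProperties(mu_a=1.0, mu_s=10.0, g=1.0, n=1.4)
        with pytest.raises(ConfigurationError):
            OpticalProperties(mu_a=1.0, mu_s=10.0, g=0.9, n=0.9)


class TestWavelengthGrid:
    def test_stokes_wavelengths_exceed_excitation_and_increase(self, table):
        grid = table.grid
        wls = grid.wavelengths_nm
        assert wls[0] == 785.0
        assert all(b > a for a, b in zip(wls[:-1], wls[1:]))

    def test_grid_from_custom_peaks(self):
        peaks = RamanPeakSet.from_weights((500.0, 2000.0), (1.0, 1.0))
        grid = WavelengthGrid.from_peaks(peaks, excitation_nm=633.0)
        assert grid.n_indices == 3
        assert grid.stokes_nm[0] == pytest.approx(
            1e7 / (1e7 / 633.0 - 500.0)
        )
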