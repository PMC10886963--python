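"""Raman spectrum preprocessing and synthetic fixtures.

The measurement chain this module emulates collects one dark spectrum and
fifteen raw spectra per detector offset.  Preprocessing runs in a fixed
order:

1. dark subtraction (pointwise, identical wavenumber axes required);
2. cosmic-ray removal — narrow detector spikes of breadth ≤ 2 wavenumbers
   and amplitude ≥ 15 % of the intensity range (max − min of the
   dark-subtracted spectrum) are excised and bridged by linear
   interpolation.  The breadth restriction is what separates spikes from
   genuine MBA peaks, which span roughly 20 wavenumbers;
3. asymmetric least-squares (Whittaker-smoother) baseline estimation and
   subtraction;
4. peak-intensity extraction: the maximum corrected intensity within a
   ± half-window around each MBA peak center.

The spike *detector* is operationalized as points whose residual from a
5-point running median exceeds the amplitude threshold, grouped into
contiguous runs whose breadth is measured on the wavenumber axis; the rule
gives thresholds, not a detector, so this is the package's choice.

:func:`synth_spectrum` generates raw/dark pairs with known injected peaks,
baseline, noise and spikes, and returns the ground truth for assertions; it
emulates instrument output, not any particular spectrometer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .errors import AlignmentError, ConfigurationError

__all__ = [
    "Spectrum",
    "PeakDefinition",
    "subtract_dark",
    "remove_cosmic_rays",
    "als_baseline",
    "correct_baseline",
    "peak_intensity",
    "summarize_replicates",
    "SynthParams",
    "synth_spectrum",
    "preprocess",
    "read_spectrum",
    "write_spectrum",
]


@dataclass(frozen=True)
class Spectrum:
    """Wavenumber/intensity pair arrays (axis strictly increasing, cm⁻¹)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.shape != wn.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1D")
        if wn.size >= 2 and np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(y))):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, y)


@dataclass(frozen=True)
class PeakDefinition:
    """A peak center and half-window (cm⁻¹) for intensity extraction.

    The default half-window of 10 cm⁻¹ brackets MBA peaks, which typically
    span ~20 wavenumbers.
    """

    center: float
    half_window: float = 10.0

    def __post_init__(self):
        if self.half_window <= 0:
            raise ValueError("half_window must be positive")


def subtract_dark(raw: Spectrum, dark: Spectrum) -> Spectrum:
    """Pointwise raw − dark; the axes must be identical."""
    if raw.wavenumbers.shape != dark.wavenumbers.shape or not np.array_equal(
        raw.wavenumbers, dark.wavenumbers
    ):
        raise AlignmentError("raw and dark spectra must share the wavenumber axis")
    return raw.with_intensities(raw.intensities - dark.intensities)


def remove_cosmic_rays(
    s: Spectrum,
    max_breadth: float = 2.0,
    min_fraction: float = 0.15,
    median_size: int = 5,
) -> Spectrum:
    """Excise narrow cosmic-ray spikes and bridge them by linear interpolation.

    A spike is a contiguous run of points whose positive residual from a
    running median is at least ``min_fraction`` of the spectrum's intensity
    range (max − min), with run breadth on the wavenumber axis at most
    ``max_breadth`` cm⁻¹.  Wider excursions — genuine Raman peaks — are left
    untouched.  The operation is idempotent: an interpolated bridge has zero
    residual on a second pass.
    """
    if len(s) < 3:
        raise ValueError("need at least 3 points")
    y = s.intensities
    wn = s.wavenumbers
    span = y.max() - y.min()
    if span <= 0:
        return s
    med = ndimage.median_filter(y, size=median_size, mode="nearest")
    resid = y - med
    spike = resid >= min_fraction * span
    if not spike.any():
        return s
    out = y.copy()
    # group flagged points into contiguous runs
    idx = np.flatnonzero(spike)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        breadth = wn[run[-1]] - wn[run[0]]
        if breadth > max_breadth:
            continue
        lo = run[0] - 1
        hi = run[-1] + 1
        if lo < 0 and hi >= len(s):
            continue
        if lo < 0:
            out[run] = out[hi]
        elif hi >= len(s):
            out[run] = out[lo]
        else:
            out[run] = np.interp(wn[run], [wn[lo], wn[hi]], [out[lo], out[hi]])
    return s.with_intensities(out)


def als_baseline(
    s: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    iterations: int = 10,
) -> Spectrum:
    """Asymmetric least-squares baseline (Whittaker smoother).

    Minimizes  Σ wᵢ (yᵢ − zᵢ)² + λ Σ (Δ²z)²  with weights reassigned each
    iteration: ``asymmetry`` for points above the fit (presumed peaks) and
    ``1 − asymmetry`` below.  λ is ``smoothness``; ten iterations converge
    for spectra of this kind.  Returns the baseline (same axis).
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must be in (0, 1)")
    y = s.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    m = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(m, m - 2))
    penalty = smoothness * (d @ d.T)
    w = np.ones(m)
    z = y
    for _ in range(iterations):
        wmat = sparse.diags(w)
        z = spsolve((wmat + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return s.with_intensities(z)


def correct_baseline(s: Spectrum, **als_kwargs) -> tuple[Spectrum, Spectrum]:
    """Return (baseline-corrected spectrum, estimated baseline)."""
    base = als_baseline(s, **als_kwargs)
    return s.with_intensities(s.intensities - base.intensities), base


def peak_intensity(corrected: Spectrum, peak: PeakDefinition) -> float:
    """Maximum corrected intensity within ``center ± half_window``."""
    wn = corrected.wavenumbers
    m = (wn >= peak.center - peak.half_window) & (wn <= peak.center + peak.half_window)
    if not m.any():
        raise IndexError(
            f"peak window around {peak.center} cm^-1 does not intersect the axis"
        )
    return float(corrected.intensities[m].max())


def summarize_replicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of replicate peak intensities per (offset, peak).

    ``frame`` is long-format with columns ``offset_mm``, ``peak`` and
    ``intensity`` (one row per replicate).  The returned frame has one row
    per (offset_mm, peak) with columns mean, min, max and n.
    """
    required = {"offset_mm", "peak", "intensity"}
    if not required.issubset(frame.columns):
        raise ValueError(f"frame must have columns {sorted(required)}")
    out = (
        frame.groupby(["offset_mm", "peak"])["intensity"]
        .agg(["mean", "min", "max", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass
class SynthParams:
    """Knobs of the synthetic raw/dark spectrum generator.

    Defaults emulate an MBA-like SERS spectrum: four Gaussian peaks of
    ~20 cm⁻¹ full width on a smooth quadratic baseline over a detector dark
    level, with white noise and optional 1–2-point cosmic-ray spikes of at
    least ``spike_min_fraction`` of the signal range.  Spike positions are
    kept clear of the peak windows so that truth-record assertions about
    peak recovery are meaningful.
    """

    wn_start: float = 400.0
    wn_stop: float = 1800.0
    wn_step: float = 1.0
    peak_centers: tuple = (1072.0, 1430.0, 1582.0, 1702.0)
    peak_heights: tuple = (1000.0, 300.0, 1250.0, 150.0)
    peak_fwhm: float = 20.0
    baseline_coeffs: tuple = (300.0, -0.15, 8e-5)  # c0 + c1·Δ + c2·Δ²
    dark_level: float = 100.0
    dark_noise_sd: float = 2.0
    noise_sd: float = 5.0
    n_spikes: int = 1
    spike_min_fraction: float = 0.2
    spike_max_fraction: float = 0.5
    spike_clearance: float = 30.0


def synth_spectrum(rng: np.random.Generator, params: SynthParams | None = None):
    """Generate (raw, dark, truth) for one synthetic acquisition.

    ``truth`` records every injected component: peak centers/heights, the
    noiseless baseline array, and spike positions/amplitudes.
    """
    p = params or SynthParams()
    wn = np.arange(p.wn_start, p.wn_stop + 0.5 * p.wn_step, p.wn_step)
    delta = wn - p.wn_start
    c0, c1, c2 = p.baseline_coeffs
    baseline = c0 + c1 * delta + c2 * delta * delta
    sigma = p.peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    peaks = np.zeros_like(wn)
    for c, h in zip(p.peak_centers, p.peak_heights):
        peaks += h * np.exp(-0.5 * ((wn - c) / sigma) ** 2)
    signal = baseline + peaks
    span = signal.max() - signal.min()

    spikes = np.zeros_like(wn)
    spike_truth = []
    clear = np.ones(wn.size, dtype=bool)
    for c in p.peak_centers:
        clear &= np.abs(wn - c) > p.spike_clearance
    clear[:3] = clear[-3:] = False  # keep spikes off the edges
    candidates = np.flatnonzero(clear)
    for _ in range(p.n_spikes):
        pos = int(rng.choice(candidates))
        width = int(rng.integers(1, 3))  # 1 or 2 points
        frac = float(rng.uniform(p.spike_min_fraction, p.spike_max_fraction))
        amp = frac * span
        for j in range(width):
            if pos + j < wn.size:
                spikes[pos + j] += amp
        spike_truth.append({"index": pos, "width": width, "amplitude": amp})

    dark = p.dark_level + rng.normal(0.0, p.dark_noise_sd, wn.size)
    raw = (
        p.dark_level
        + rng.normal(0.0, p.dark_noise_sd, wn.size)
        + signal
        + spikes
        + rng.normal(0.0, p.noise_sd, wn.size)
    )
    truth = {
        "peak_centers": tuple(p.peak_centers),
        "peak_heights": tuple(p.peak_heights),
        "baseline": baseline,
        "spikes": spike_truth,
        "signal_range": float(span),
    }
    return Spectrum(wn, raw), Spectrum(wn, dark), truth


def preprocess(
    raw: Spectrum,
    dark: Spectrum,
    despike: bool = True,
    **als_kwargs,
) -> Spectrum:
    """Full chain: dark subtraction → cosmic-ray removal → baseline correction."""
    s = subtract_dark(raw, dark)
    if despike:
        s = remove_cosmic_rays(s)
    corrected, _ = correct_baseline(s, **als_kwargs)
    return corrected


def read_spectrum(path) -> Spectrum:
    """Two-column delimited text (wavenumber, intensity)."""
    data = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns")
    return Spectrum(data[:, 0], data[:, 1])


def write_spectrum(s: Spectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([s.wavenumbers, s.intensities]),
        fmt="%.17g",
        header="wavenumber_cm1 intensity_au",
    )
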