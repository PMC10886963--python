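"""Exit-surface tallies: heatmaps, depth histograms, counters, offset profiles.

Photons transmitted through the top surface are binned on a 10 × 10 grid of
1 mm squares (the detection window).  The tally frame places the excitation
point at the center of column 1, on the boundary between rows 5 and 6:
physical coordinates (x, y) map to tally coordinates (x + 0.05, y + 0.5) cm,
and bins are half-open [lo, hi) so an exit exactly on an interior edge goes
to the higher bin.  Exits outside the window are counted separately per
wavelength so that binned + off-window always equals the total top exits.

For each exit bin a histogram of the photon's maximum depth is accumulated in
1 mm bins from 0 to 2 cm; photons that went deeper than the last bin are
clamped into it.

Offset profiles follow the two-row averaging rule: the value at lateral
offset d mm is the mean of the two bins straddling the beam line (tally rows
bounded by y = 4–6 mm) in the column d columns from the excitation column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TallyConfig",
    "ExitRecord",
    "RunCounters",
    "RunResult",
    "new_result",
    "assign_bins",
    "bin_exit",
    "depth_histogram",
    "offset_profile",
    "OffsetProfile",
    "percent_change",
    "total_decline",
]


@dataclass
class TallyConfig:
    """Frame and binning of the exit-surface tallies (lengths in cm)."""

    bin_size: float = 0.1
    n_bins: int = 10
    #: tally coordinates of the beam entry point
    beam_x: float = 0.05
    beam_y: float = 0.5
    depth_bin: float = 0.1
    depth_max: float = 2.0
    #: report weighted sums instead of raw packet counts in profiles
    weighted: bool = False

    @property
    def n_depth_bins(self) -> int:
        return int(round(self.depth_max / self.depth_bin))


@dataclass(frozen=True)
class ExitRecord:
    """One packet transmitted through the top surface."""

    x: float
    y: float
    wl_index: int
    max_depth: float
    weight: float


@dataclass
class RunCounters:
    """Aggregate event counts and weight ledgers of one simulation."""

    n_photons_launched: int = 0
    n_scatter_total: int = 0
    n_raman_total: int = 0
    per_peak: list = field(default_factory=list)
    n_additional_criteria: int = 0
    max_steps: int = 0
    n_top_exits: int = 0
    n_other_exits: int = 0
    absorbed_weight: float = 0.0
    top_exit_weight: float = 0.0
    other_exit_weight: float = 0.0
    roulette_killed_weight: float = 0.0
    roulette_boost_weight: float = 0.0
    lost_weight: float = 0.0

    def validate(self) -> None:
        if sum(self.per_peak) != self.n_raman_total:
            raise AssertionError("per-peak counts must sum to the Raman total")
        if self.n_raman_total > self.n_photons_launched:
            raise AssertionError("at most one Raman event per photon")

    def as_dict(self) -> dict:
        return {
            "n_photons_launched": self.n_photons_launched,
            "n_scatter_total": self.n_scatter_total,
            "n_raman_total": self.n_raman_total,
            "per_peak": list(self.per_peak),
            "n_additional_criteria": self.n_additional_criteria,
            "max_steps": self.max_steps,
            "n_top_exits": self.n_top_exits,
            "n_other_exits": self.n_other_exits,
            "absorbed_weight": self.absorbed_weight,
            "top_exit_weight": self.top_exit_weight,
            "other_exit_weight": self.other_exit_weight,
            "roulette_killed_weight": self.roulette_killed_weight,
            "roulette_boost_weight": self.roulette_boost_weight,
            "lost_weight": self.lost_weight,
        }


def assign_bins(x, y, config: TallyConfig):
    """Map physical exit coordinates to (row, col, in_window).

    Broadcastable; rows/cols are 0-based (row r covers tally
    y ∈ [r·bin, (r+1)·bin), col c covers tally x ∈ [c·bin, (c+1)·bin)).
    """
    tx = np.asarray(x, dtype=float) + config.beam_x
    ty = np.asarray(y, dtype=float) + config.beam_y
    col = np.floor(tx / config.bin_size).astype(np.int64)
    row = np.floor(ty / config.bin_size).astype(np.int64)
    n = config.n_bins
    in_window = (col >= 0) & (col < n) & (row >= 0) & (row < n)
    return row, col, in_window


class RunResult:
    """Tallies of one simulation: counters + per-wavelength grids.

    ``heatmap`` is (W, n, n) int64 packet counts (W wavelength indices,
    index 0 = unshifted); ``heatmap_weight`` the matching weight sums;
    ``off_window`` per-wavelength counts of top exits outside the window;
    ``depth_hist`` is (n, n, D) int64 over all wavelengths combined.
    """

    def __init__(self, n_wavelengths: int, config: TallyConfig):
        self.config = config
        n = config.n_bins
        d = config.n_depth_bins
        self.n_wavelengths = n_wavelengths
        self.counters = RunCounters(per_peak=[0] * (n_wavelengths - 1))
        self.heatmap = np.zeros((n_wavelengths, n, n), dtype=np.int64)
        self.heatmap_weight = np.zeros((n_wavelengths, n, n))
        self.off_window = np.zeros(n_wavelengths, dtype=np.int64)
        self.off_window_weight = np.zeros(n_wavelengths)
        self.depth_hist = np.zeros((n, n, d), dtype=np.int64)

    def record_exit(self, x, y, wl_index, max_depth, weight) -> None:
        """Tally a single top-surface transmission (scalar path)."""
        row, col, in_win = assign_bins(x, y, self.config)
        if in_win:
            r, c = int(row), int(col)
            self.heatmap[wl_index, r, c] += 1
            self.heatmap_weight[wl_index, r, c] += weight
            db = min(int(max_depth / self.config.depth_bin),
                     self.config.n_depth_bins - 1)
            self.depth_hist[r, c, db] += 1
        else:
            self.off_window[wl_index] += 1
            self.off_window_weight[wl_index] += weight

    def record_exits(self, x, y, wl_index, max_depth, weight) -> None:
        """Vectorized counterpart of :meth:`record_exit`."""
        row, col, in_win = assign_bins(x, y, self.config)
        wl = np.asarray(wl_index, dtype=np.int64)
        w = np.asarray(weight, dtype=float)
        r, c = row[in_win], col[in_win]
        np.add.at(self.heatmap, (wl[in_win], r, c), 1)
        np.add.at(self.heatmap_weight, (wl[in_win], r, c), w[in_win])
        db = np.minimum(
            (np.asarray(max_depth, dtype=float)[in_win]
             / self.config.depth_bin).astype(np.int64),
            self.config.n_depth_bins - 1,
        )
        np.add.at(self.depth_hist, (r, c, db), 1)
        out = ~in_win
        np.add.at(self.off_window, wl[out], 1)
        np.add.at(self.off_window_weight, wl[out], w[out])

    def finalize(self) -> "RunResult":
        self.counters.validate()
        return self

    # -- convenience views --------------------------------------------------

    def grid_for(self, wl_index: int) -> np.ndarray:
        return (
            self.heatmap_weight[wl_index]
            if self.config.weighted
            else self.heatmap[wl_index]
        )

    def mass_balance_ok(self) -> bool:
        """Binned + off-window top exits equal the top-exit counter."""
        return (
            int(self.heatmap.sum() + self.off_window.sum())
            == self.counters.n_top_exits
        )


def new_result(n_wavelengths: int, config: TallyConfig) -> RunResult:
    return RunResult(n_wavelengths, config)


def bin_exit(record: ExitRecord, result: RunResult) -> RunResult:
    """Functional form of the exit-binning operation."""
    result.record_exit(
        record.x, record.y, record.wl_index, record.max_depth, record.weight
    )
    return result


def depth_histogram(max_depths, config: TallyConfig | None = None) -> np.ndarray:
    """Histogram of maximum depths for one exit bin, 1 mm bins with the last
    bin clamping everything beyond ``depth_max``."""
    config = config or TallyConfig()
    d = np.asarray(max_depths, dtype=float)
    nb = config.n_depth_bins
    idx = np.minimum((d / config.depth_bin).astype(np.int64), nb - 1)
    return np.bincount(idx, minlength=nb).astype(np.int64)


@dataclass(frozen=True)
class OffsetProfile:
    """Value (count or weighted intensity) at each lateral offset, one peak."""

    offsets_mm: tuple
    values: np.ndarray
    wl_index: int = 0

    def __post_init__(self):
        off = tuple(float(o) for o in self.offsets_mm)
        if any(b <= a for a, b in zip(off[:-1], off[1:])):
            raise ValueError("offsets must be strictly increasing")
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0):
            raise ValueError("profile values must be non-negative")
        object.__setattr__(self, "offsets_mm", off)
        object.__setattr__(self, "values", vals)


def offset_profile(
    grid: np.ndarray,
    wl_index: int = 0,
    offsets_mm=range(6),
    rows=(4, 5),
) -> OffsetProfile:
    """Two-row averaged offset profile from a heatmap.

    ``grid`` is either the full (W, n, n) stack or a single (n, n) map; the
    value at offset d mm is the mean over ``rows`` (0-based; the default rows
    4 and 5 are the bins bounded by y = 4–6 mm in the tally frame) of the
    column d columns from the excitation column (column 0).
    """
    g = np.asarray(grid)
    if g.ndim == 3:
        g = g[wl_index]
    offsets = tuple(int(o) for o in offsets_mm)
    if max(offsets) >= g.shape[1] or min(offsets) < 0:
        raise IndexError("offset column outside the tally grid")
    vals = g[list(rows), :][:, list(offsets)].mean(axis=0)
    return OffsetProfile(tuple(float(o) for o in offsets), vals, wl_index)


def percent_change(profile_with: OffsetProfile, profile_without: OffsetProfile):
    """Per-offset percent change 100·(with − without)/without.

    Offsets must match; a zero baseline yields NaN (undefined marker), never a
    division error.
    """
    if profile_with.offsets_mm != profile_without.offsets_mm:
        raise ValueError("profiles must share offsets")
    a = profile_with.values
    b = profile_without.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (a - b) / b
    return np.where(b > 0, out, np.nan)


def total_decline(profile: OffsetProfile) -> float:
    """Percent loss from the first offset to the last: 100·(v0 − vmax)/v0."""
    v0 = profile.values[0]
    if v0 <= 0:
        return float("nan")
    return float(100.0 * (v0 - profile.values[-1]) / v0)
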