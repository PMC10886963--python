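"""Photon-packet transport: physics kernels and the scalar reference engine.

The engine is a classic weighted-packet multi-layer Monte Carlo (hop / drop /
spin with Henyey–Greenstein scattering, Fresnel top boundary and Russian
roulette) extended with the inelastic step that is the point of this package:
at each scattering event *inside the SERS inclusion*, an unshifted photon
undergoes a Raman (Stokes) event with probability ``p_raman``; the emission
peak is drawn from the branch probabilities; at most one shift is allowed per
photon; and — when property update is enabled — every subsequent optical-
property lookup uses the shifted wavelength index.  Disabling property update
(the control mode) keeps the wavelength index for tallying only, so paired
runs differ solely in the physics of the post-shift trajectory.

``p_raman`` is deliberately far above the physical Raman cross-section; this
standard variance trick makes the weak process observable.  Absolute exit
counts are therefore meaningful only relative to each other (spatial
distributions, paired percent changes), not as predicted fluence.

The per-event draw order is fixed and identical in both engines:
free-path (STEP) → Raman trigger (RAMAN, inclusion & unshifted only) →
peak choice (PEAK, on trigger) → roulette (ROULETTE, below threshold) →
deflection (SPIN × 2).  Boundary hits draw FRESNEL only at the top face.

:func:`run_scalar` below is the readable one-photon-at-a-time reference; the
production engine in :mod:`sesorsmc.engine` vectorizes the identical logic and
is checked against this one bit-for-bit.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from . import rng as _rng
from .errors import ConfigurationError
from .geometry import OUTSIDE, REGION_EPS, TissueModel
from .optics import (
    OpticalProperties,
    PropertyTable,
    RamanPeakSet,
    select_stokes_peak,
)
from .tally import RunCounters, RunResult, TallyConfig, assign_bins, new_result

__all__ = [
    "TransportConfig",
    "PhotonState",
    "launch",
    "sample_step",
    "drop_and_roulette",
    "spin",
    "maybe_raman",
    "fresnel_reflectance",
    "hg_cos_theta",
    "rotate_direction",
    "run_scalar",
]


@dataclass
class TransportConfig:
    """Knobs of the Monte Carlo engine.

    n_photons : photon packets to launch
    p_raman : per-scattering-event probability of a Stokes shift inside the
        inclusion (default 1e-2, artificially high by design — see module
        docstring)
    peaks : the Stokes channels and branch probabilities
    launch_theta_deg : polar launch angle from the vertical (45° matches a
        tilted excitation fiber)
    launch_azimuth_deg : azimuth of the tilt plane; 0° tilts toward +x (the
        axis along which detection offsets are measured), the default 180°
        tilts away from the detection columns, which keeps the exit maximum
        at the zero-offset bin
    seed : RNG seed expanded into named substreams
    roulette_threshold / roulette_survive : packet weight below the threshold
        enters Russian roulette and survives with the given chance (weight
        rescaled 1/chance); threshold 0 disables roulette
    property_update : if False, a Stokes shift changes the tallied wavelength
        index but not the optical properties (control mode)
    additional_event_mode : what the additional-criteria counter counts —
        "scatter" (scattering events inside the inclusion by already-shifted
        photons; default) or "draw" (p_raman successes drawn by shifted
        photons, consuming an extra deviate)
    max_photon_steps : hard safety cap per photon
    """

    n_photons: int = 100_000
    p_raman: float = 1e-2
    peaks: RamanPeakSet = field(default_factory=RamanPeakSet.default)
    launch_theta_deg: float = 45.0
    launch_azimuth_deg: float = 180.0
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    property_update: bool = True
    additional_event_mode: str = "scatter"
    max_photon_steps: int = 1_000_000

    def __post_init__(self):
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")
        if not 0.0 < self.p_raman < 1.0:
            raise ConfigurationError("p_raman must be in (0, 1)")
        if not 0.0 < self.roulette_survive <= 1.0:
            raise ConfigurationError("roulette_survive must be in (0, 1]")
        if self.roulette_threshold < 0:
            raise ConfigurationError("roulette_threshold must be >= 0")
        if self.additional_event_mode not in ("scatter", "draw"):
            raise ConfigurationError(
                "additional_event_mode must be 'scatter' or 'draw'"
            )


@dataclass
class PhotonState:
    """One photon packet in flight."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    wl_index: int = 0
    shifted: bool = False
    max_depth: float = 0.0
    steps: int = 0
    alive: bool = True


def launch(config: TransportConfig) -> PhotonState:
    """Initial packet: unit weight at the origin just below the surface,
    heading ``launch_theta_deg`` from the vertical in the
    ``launch_azimuth_deg`` tilt plane.

    No convolution over a finite beam profile is performed; the source is an
    ideal point/pencil beam.
    """
    th = math.radians(config.launch_theta_deg)
    az = math.radians(config.launch_azimuth_deg)
    direction = np.array(
        [math.cos(az) * math.sin(th), math.sin(az) * math.sin(th), math.cos(th)]
    )
    return PhotonState(position=np.zeros(3), direction=direction)


# ---------------------------------------------------------------------------
# Physics kernels (numpy-broadcastable; shared by both engines)
# ---------------------------------------------------------------------------

def sample_step(u, props_or_mu_t):
    """Free path s = −ln(u) / µt for u in (0, 1]; never pass u = 0."""
    mu_t = (
        props_or_mu_t.mu_t
        if isinstance(props_or_mu_t, OpticalProperties)
        else props_or_mu_t
    )
    return -np.log(u) / mu_t


def hg_cos_theta(u, g):
    """Henyey–Greenstein deflection cosine via the inverse CDF.

    g = 0 reduces to isotropic sampling cosθ = 2u − 1; E[cosθ] = g.
    """
    u = np.asarray(u, dtype=float)
    g = np.asarray(g, dtype=float)
    g_safe = np.where(g == 0.0, 1.0, g)
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    aniso = (1.0 + g * g - tmp * tmp) / (2.0 * g_safe)
    cos_t = np.where(g == 0.0, 2.0 * u - 1.0, aniso)
    return np.clip(cos_t, -1.0, 1.0)


def rotate_direction(direction, cos_theta, phi):
    """Rotate unit direction(s) by polar angle θ about themselves, azimuth φ.

    Standard multi-layer MC update; the near-vertical branch avoids the
    1/sqrt(1−uz²) singularity.  Norm is preserved to round-off.
    """
    d = np.asarray(direction, dtype=float)
    cos_t = np.asarray(cos_theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    ux, uy, uz = d[..., 0], d[..., 1], d[..., 2]
    vertical = np.abs(uz) > 0.99999
    # general branch
    den = np.sqrt(np.maximum(1.0 - uz * uz, 1e-300))
    gx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
    gy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
    gz = -sin_t * cos_p * den + uz * cos_t
    # near-vertical branch
    sign = np.where(uz >= 0.0, 1.0, -1.0)
    vx = sin_t * cos_p
    vy = sin_t * sin_p
    vz = sign * cos_t
    out = np.empty(np.broadcast(d[..., 0], cos_t).shape + (3,))
    out[..., 0] = np.where(vertical, vx, gx)
    out[..., 1] = np.where(vertical, vy, gy)
    out[..., 2] = np.where(vertical, vz, gz)
    return out


def fresnel_reflectance(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i`` from
    medium n1 into n2.  Matched media give 0; beyond the critical angle, 1."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    cos_i = np.abs(np.asarray(cos_i, dtype=float))
    sin_i = np.sqrt(np.maximum(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    tir = sin_t >= 1.0
    sin_t = np.where(tir, 0.0, sin_t)
    cos_t = np.sqrt(np.maximum(0.0, 1.0 - sin_t * sin_t))
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    r = 0.5 * (rs * rs + rp * rp)
    r = np.where(tir, 1.0, r)
    return np.where(n1 == n2, 0.0, r)  # matched media reflect exactly nothing


# ---------------------------------------------------------------------------
# Single-photon operations (used by the scalar engine and unit tests)
# ---------------------------------------------------------------------------

def drop_and_roulette(
    state: PhotonState,
    props: OpticalProperties,
    u: float,
    threshold: float = 1e-4,
    survive: float = 0.1,
    counters: RunCounters | None = None,
) -> PhotonState:
    """Absorb the µa/µt fraction of the packet weight, then play roulette.

    The absorbed weight is added to ``counters.absorbed_weight``.  Below the
    threshold the packet survives with probability ``survive`` and its weight
    is divided by that chance (unbiased in expectation), otherwise it dies.
    """
    dw = state.weight * props.mu_a / props.mu_t
    if counters is not None:
        counters.absorbed_weight += dw
    state.weight -= dw
    if threshold > 0.0 and state.weight < threshold:
        if u < survive:
            if counters is not None:
                counters.roulette_boost_weight += state.weight * (1.0 / survive - 1.0)
            state.weight /= survive
        else:
            if counters is not None:
                counters.roulette_killed_weight += state.weight
            state.weight = 0.0
            state.alive = False
    return state


def spin(state: PhotonState, g: float, u1: float, u2: float) -> PhotonState:
    """Deflect the packet direction by a Henyey–Greenstein draw."""
    cos_t = hg_cos_theta(u1, g)
    phi = 2.0 * np.pi * np.asarray(u2, dtype=float)
    state.direction = rotate_direction(state.direction, cos_t, phi)
    return state


def maybe_raman(
    state: PhotonState,
    region: str,
    peaks: RamanPeakSet,
    p_raman: float,
    u1: float,
    u2: float,
    counters: RunCounters,
    additional_event_mode: str = "scatter",
) -> PhotonState:
    """The inelastic step, applied once per scattering event before the spin.

    Only scattering events inside the inclusion can shift, and only for
    photons that have not yet shifted (one Raman event per photon).  On a
    trigger the wavelength index becomes 1 + peak index and the per-peak and
    total counters advance.  A scattering event in the inclusion by an
    already-shifted photon increments the additional-criteria counter (in the
    default "scatter" mode) and changes nothing else.
    """
    if region != "inclusion":
        return state
    if state.shifted:
        if additional_event_mode == "scatter":
            counters.n_additional_criteria += 1
        elif u1 < p_raman:
            counters.n_additional_criteria += 1
        return state
    if u1 < p_raman:
        k = select_stokes_peak(peaks, u2)
        state.shifted = True
        state.wl_index = k + 1
        counters.n_raman_total += 1
        counters.per_peak[k] += 1
    return state


# ---------------------------------------------------------------------------
# Scalar reference engine
# ---------------------------------------------------------------------------

class _Ledger:
    """Per-photon weight/exit buffers shared by both engines.

    Float tallies are accumulated per photon and summed once in photon order
    at the end, so the scalar and vectorized engines — which visit photons in
    different orders — produce bit-identical counters and weighted grids.
    """

    def __init__(self, n_photons: int):
        self.n = n_photons
        self.absorbed = np.zeros(n_photons)
        self.boost = np.zeros(n_photons)
        self.killed = np.zeros(n_photons)
        self.lost = np.zeros(n_photons)
        self.other_w = np.zeros(n_photons)
        self.other_exit = np.zeros(n_photons, dtype=bool)
        self.steps = np.zeros(n_photons, dtype=np.int64)
        self.exit_pid: list = []
        self.exit_x: list = []
        self.exit_y: list = []
        self.exit_wl: list = []
        self.exit_depth: list = []
        self.exit_w: list = []

    def add_exit(self, pid, x, y, wl, depth, w) -> None:
        self.exit_pid.append(pid)
        self.exit_x.append(x)
        self.exit_y.append(y)
        self.exit_wl.append(wl)
        self.exit_depth.append(depth)
        self.exit_w.append(w)

    def finalize(self, result: RunResult) -> RunResult:
        c = result.counters
        order = np.argsort(np.asarray(self.exit_pid, dtype=np.int64),
                           kind="stable")
        ex = np.asarray(self.exit_x, dtype=float)[order]
        ey = np.asarray(self.exit_y, dtype=float)[order]
        ewl = np.asarray(self.exit_wl, dtype=np.int64)[order]
        ed = np.asarray(self.exit_depth, dtype=float)[order]
        ew = np.asarray(self.exit_w, dtype=float)[order]
        result.record_exits(ex, ey, ewl, ed, ew)
        c.n_top_exits = int(order.size)
        c.n_other_exits = int(self.other_exit.sum())
        c.top_exit_weight = float(np.sum(ew))
        c.other_exit_weight = float(np.sum(self.other_w))
        c.absorbed_weight = float(np.sum(self.absorbed))
        c.roulette_boost_weight = float(np.sum(self.boost))
        c.roulette_killed_weight = float(np.sum(self.killed))
        c.lost_weight = float(np.sum(self.lost))
        c.max_steps = int(self.steps.max()) if self.n else 0
        return result.finalize()


def run_scalar(
    config: TransportConfig,
    model: TissueModel,
    table: PropertyTable,
    tally_config: TallyConfig | None = None,
) -> RunResult:
    """Simulate ``config.n_photons`` packets one at a time.

    This is the brute-force reference implementation: a plain per-photon loop
    over hop / boundary / Raman / drop / roulette / spin.  It produces the
    same :class:`~sesorsmc.tally.RunResult` as the vectorized engine and, for
    a shared seed, identical trajectories and tallies bit-for-bit.
    """
    tally_config = tally_config or TallyConfig()
    arrays = table.as_arrays(model.region_names)
    _check_uniform_tissue_n(arrays["n"])
    # plain nested lists: python-float arithmetic is IEEE-identical to the
    # vectorized engine's float64 array operations
    mu_a = arrays["mu_a"].tolist()
    mu_s = arrays["mu_s"].tolist()
    g_arr = arrays["g"].tolist()
    n_arr = arrays["n"].tolist()
    result = new_result(table.grid.n_indices, tally_config)
    counters = result.counters
    ledger = _Ledger(config.n_photons)
    streams = _rng.RandomStreams(config.seed)
    peaks = config.peaks
    cdf = peaks.cdf.tolist()
    n_peaks = len(peaks)
    p_raman = config.p_raman
    incl_code = model.inclusion_code
    draw_mode = config.additional_event_mode == "draw"
    update = config.property_update
    thresh = config.roulette_threshold
    survive = config.roulette_survive
    n_amb = model.n_ambient
    eps = REGION_EPS
    uniform = streams.uniform_scalar
    proto = launch(config)
    lx, ly, lz = (float(v) for v in proto.position)
    lux, luy, luz = (float(v) for v in proto.direction)

    for pid in range(config.n_photons):
        cnt = [0, 0, 0, 0, 0, 0]
        counters.n_photons_launched += 1
        px, py, pz = lx, ly, lz
        ux, uy, uz = lux, luy, luz
        weight = 1.0
        wl = 0
        shifted = False
        max_depth = 0.0
        steps = 0
        alive = True

        while alive:
            if steps >= config.max_photon_steps:
                ledger.lost[pid] += weight
                break
            reg = model.region_code_scalar(
                px + eps * ux, py + eps * uy, pz + eps * uz
            )
            if reg == OUTSIDE:
                # Should not occur: exits are handled at the crossing below.
                ledger.lost[pid] += weight
                break
            wl_eff = wl if update else 0
            mu_a_v = mu_a[reg][wl_eff]
            mu_t = mu_a_v + mu_s[reg][wl_eff]
            u = uniform(_rng.STEP, pid, cnt[_rng.STEP])
            cnt[_rng.STEP] += 1
            s = sample_step(1.0 - u, mu_t)
            t_b = model.boundary_distance_scalar(px, py, pz, ux, uy, uz)
            if t_b <= s:
                px = px + t_b * ux
                py = py + t_b * uy
                pz = pz + t_b * uz
                if pz > max_depth:
                    max_depth = pz
                steps += 1
                qx, qy, qz = px + eps * ux, py + eps * uy, pz + eps * uz
                if model.region_code_scalar(qx, qy, qz) == OUTSIDE:
                    if qz < 0.0:
                        # top face: Fresnel reflect/transmit
                        r = _fresnel_scalar(n_arr[reg][wl_eff], n_amb, uz)
                        u = uniform(_rng.FRESNEL, pid, cnt[_rng.FRESNEL])
                        cnt[_rng.FRESNEL] += 1
                        if u < r:
                            uz = -uz
                        else:
                            ledger.add_exit(pid, px, py, wl, max_depth, weight)
                            alive = False
                    else:
                        ledger.other_exit[pid] = True
                        ledger.other_w[pid] += weight
                        alive = False
                # internal crossing (index-matched): resample the step
                continue

            px = px + s * ux
            py = py + s * uy
            pz = pz + s * uz
            if pz > max_depth:
                max_depth = pz
            steps += 1
            counters.n_scatter_total += 1
            # Raman step
            if reg == incl_code:
                if not shifted:
                    u = uniform(_rng.RAMAN, pid, cnt[_rng.RAMAN])
                    cnt[_rng.RAMAN] += 1
                    if u < p_raman:
                        u = uniform(_rng.PEAK, pid, cnt[_rng.PEAK])
                        cnt[_rng.PEAK] += 1
                        k = min(bisect_right(cdf, u), n_peaks - 1)
                        shifted = True
                        wl = k + 1
                        counters.n_raman_total += 1
                        counters.per_peak[k] += 1
                elif draw_mode:
                    u = uniform(_rng.RAMAN, pid, cnt[_rng.RAMAN])
                    cnt[_rng.RAMAN] += 1
                    if u < p_raman:
                        counters.n_additional_criteria += 1
                else:
                    counters.n_additional_criteria += 1
            # drop
            dw = weight * mu_a_v / mu_t
            ledger.absorbed[pid] += dw
            weight = weight - dw
            # roulette
            if thresh > 0.0 and weight < thresh:
                u = uniform(_rng.ROULETTE, pid, cnt[_rng.ROULETTE])
                cnt[_rng.ROULETTE] += 1
                if u < survive:
                    ledger.boost[pid] += weight * (1.0 / survive - 1.0)
                    weight = weight / survive
                else:
                    ledger.killed[pid] += weight
                    weight = 0.0
                    alive = False
                    continue
            # spin
            u1 = uniform(_rng.SPIN, pid, cnt[_rng.SPIN])
            cnt[_rng.SPIN] += 1
            u2 = uniform(_rng.SPIN, pid, cnt[_rng.SPIN])
            cnt[_rng.SPIN] += 1
            cos_t = _hg_cos_scalar(u1, g_arr[reg][wl_eff])
            phi = 2.0 * np.pi * u2
            ux, uy, uz = _rotate_scalar(ux, uy, uz, cos_t, phi)

        ledger.steps[pid] = steps

    return ledger.finalize(result)


# Scalar replicas of the array kernels for the reference engine's inner loop.
# Every expression mirrors its vectorized counterpart; the four arithmetic
# operations and sqrt are IEEE-exact, and the transcendentals (cos, sin, log)
# go through the same numpy scalar kernels, so results stay bit-identical.

def _hg_cos_scalar(u: float, g: float) -> float:
    if g == 0.0:
        cos_t = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cos_t < -1.0:
        return -1.0
    if cos_t > 1.0:
        return 1.0
    return cos_t


def _rotate_scalar(ux, uy, uz, cos_t, phi):
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz >= 0.0 else -1.0
        return sin_t * cos_p, sin_t * sin_p, sign * cos_t
    den = math.sqrt(max(1.0 - uz * uz, 1e-300))
    gx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
    gy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
    gz = -sin_t * cos_p * den + uz * cos_t
    return gx, gy, gz


def _fresnel_scalar(n1: float, n2: float, cos_i: float) -> float:
    if n1 == n2:
        return 0.0
    cos_i = abs(cos_i)
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t * sin_t))
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def _check_uniform_tissue_n(n_arr: np.ndarray) -> None:
    """Internal interfaces are modeled as index-matched; require one tissue n."""
    if not np.all(n_arr == n_arr.flat[0]):
        raise ConfigurationError(
            "all tissue refractive indices must be equal (internal interfaces "
            "are index-matched; only the tissue-air surface is refracting)"
        )
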