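"""Vectorized Monte Carlo engine.

Propagates all live photon packets in lockstep with numpy array operations,
compacting the active set as packets terminate.  Every physics kernel, the
deviate order, and the per-photon counter-based random streams are shared
with the scalar reference engine in :mod:`sesorsmc.transport`, so for the
same seed the two produce identical trajectories and bit-identical tallies;
the scalar loop is the oracle, this module is the production path.
"""

from __future__ import annotations

import logging

import numpy as np

from . import rng as _rng
from .geometry import OUTSIDE, REGION_EPS, TissueModel
from .optics import PropertyTable
from .tally import RunResult, TallyConfig, new_result
from .transport import (
    TransportConfig,
    _Ledger,
    _check_uniform_tissue_n,
    fresnel_reflectance,
    hg_cos_theta,
    launch,
    rotate_direction,
    sample_step,
)

__all__ = ["run"]

logger = logging.getLogger(__name__)


def run(
    config: TransportConfig,
    model: TissueModel,
    table: PropertyTable,
    tally_config: TallyConfig | None = None,
) -> RunResult:
    """Simulate ``config.n_photons`` packets (vectorized; production engine)."""
    tally_config = tally_config or TallyConfig()
    arrays = table.as_arrays(model.region_names)
    mu_a_t, mu_s_t = arrays["mu_a"], arrays["mu_s"]
    g_t, n_t = arrays["g"], arrays["n"]
    _check_uniform_tissue_n(n_t)
    result = new_result(table.grid.n_indices, tally_config)
    counters = result.counters
    n = config.n_photons
    ledger = _Ledger(n)
    streams = _rng.RandomStreams(config.seed)
    cdf = config.peaks.cdf
    n_peaks = len(config.peaks)
    p_raman = config.p_raman
    incl_code = model.inclusion_code
    draw_mode = config.additional_event_mode == "draw"
    update = config.property_update
    roulette_on = config.roulette_threshold > 0.0

    proto = launch(config)
    counters.n_photons_launched = n

    pid = np.arange(n, dtype=np.uint64)
    pos = np.tile(proto.position, (n, 1))
    dirn = np.tile(proto.direction, (n, 1))
    weight = np.ones(n)
    wl = np.zeros(n, dtype=np.int64)
    shifted = np.zeros(n, dtype=bool)
    max_depth = np.zeros(n)
    steps = np.zeros(n, dtype=np.int64)
    cnt = np.zeros((n, 6), dtype=np.uint64)
    one = np.uint64(1)

    iteration = 0
    while pid.size:
        iteration += 1
        # safety cap
        capped = steps >= config.max_photon_steps
        if capped.any():
            cp = capped.nonzero()[0]
            ledger.lost[pid[cp].astype(np.int64)] += weight[cp]
            ledger.steps[pid[cp].astype(np.int64)] = steps[cp]
            keep = ~capped
            (pid, pos, dirn, weight, wl, shifted, max_depth, steps, cnt) = (
                pid[keep], pos[keep], dirn[keep], weight[keep], wl[keep],
                shifted[keep], max_depth[keep], steps[keep], cnt[keep],
            )
            if not pid.size:
                break

        reg = model.region_codes(pos + REGION_EPS * dirn)
        stray = reg == OUTSIDE
        if stray.any():
            sp = stray.nonzero()[0]
            ledger.lost[pid[sp].astype(np.int64)] += weight[sp]
            ledger.steps[pid[sp].astype(np.int64)] = steps[sp]
            keep = ~stray
            (pid, pos, dirn, weight, wl, shifted, max_depth, steps, cnt, reg) = (
                pid[keep], pos[keep], dirn[keep], weight[keep], wl[keep],
                shifted[keep], max_depth[keep], steps[keep], cnt[keep], reg[keep],
            )
            if not pid.size:
                break

        # copy: the Raman step may rewrite wl below, but this event's lookups
        # (drop, spin) must use the pre-shift index, as in the scalar engine
        wl_eff = wl.copy() if update else np.zeros_like(wl)
        mu_a = mu_a_t[reg, wl_eff]
        mu_t = mu_a + mu_s_t[reg, wl_eff]
        u = streams.uniform(_rng.STEP, pid, cnt[:, _rng.STEP])
        cnt[:, _rng.STEP] += one
        s = sample_step(1.0 - u, mu_t)
        t_b = model.boundary_distance(pos, dirn)
        hit = t_b <= s
        move = np.where(hit, t_b, s)
        pos = pos + move[:, None] * dirn
        max_depth = np.maximum(max_depth, pos[:, 2])
        steps += 1

        dead = np.zeros(pid.size, dtype=bool)

        # ---- boundary hops -------------------------------------------------
        h_idx = hit.nonzero()[0]
        if h_idx.size:
            probe = pos[h_idx] + REGION_EPS * dirn[h_idx]
            reg2 = model.region_codes(probe)
            outed = reg2 == OUTSIDE
            top_m = outed & (probe[:, 2] < 0.0)
            top_idx = h_idx[top_m]
            if top_idx.size:
                r = fresnel_reflectance(
                    n_t[reg[top_idx], wl_eff[top_idx]],
                    model.n_ambient,
                    dirn[top_idx, 2],
                )
                uf = streams.uniform(
                    _rng.FRESNEL, pid[top_idx], cnt[top_idx, _rng.FRESNEL]
                )
                cnt[top_idx, _rng.FRESNEL] += one
                refl = uf < r
                rf = top_idx[refl]
                dirn[rf, 2] = -dirn[rf, 2]
                tr = top_idx[~refl]
                for j in tr:
                    ledger.add_exit(
                        int(pid[j]), pos[j, 0], pos[j, 1], int(wl[j]),
                        max_depth[j], weight[j],
                    )
                dead[tr] = True
            oth_idx = h_idx[outed & ~top_m]
            if oth_idx.size:
                op = pid[oth_idx].astype(np.int64)
                ledger.other_exit[op] = True
                ledger.other_w[op] += weight[oth_idx]
                dead[oth_idx] = True
            # internal crossings: nothing to do; the step is resampled.

        # ---- scattering interactions ---------------------------------------
        i_idx = (~hit).nonzero()[0]
        if i_idx.size:
            counters.n_scatter_total += int(i_idx.size)
            in_incl = reg[i_idx] == incl_code
            was_shifted = shifted[i_idx]
            # Raman trigger for unshifted photons in the inclusion
            cand = i_idx[in_incl & ~was_shifted]
            if cand.size:
                u1 = streams.uniform(_rng.RAMAN, pid[cand], cnt[cand, _rng.RAMAN])
                cnt[cand, _rng.RAMAN] += one
                trig = cand[u1 < p_raman]
                if trig.size:
                    u2 = streams.uniform(
                        _rng.PEAK, pid[trig], cnt[trig, _rng.PEAK]
                    )
                    cnt[trig, _rng.PEAK] += one
                    k = np.minimum(
                        np.searchsorted(cdf, u2, side="right"), n_peaks - 1
                    )
                    shifted[trig] = True
                    wl[trig] = k + 1
                    counters.n_raman_total += int(trig.size)
                    for kk, ck in zip(*np.unique(k, return_counts=True)):
                        counters.per_peak[int(kk)] += int(ck)
            # additional-criteria counter for already-shifted photons
            prev = i_idx[in_incl & was_shifted]
            if prev.size:
                if draw_mode:
                    u1 = streams.uniform(
                        _rng.RAMAN, pid[prev], cnt[prev, _rng.RAMAN]
                    )
                    cnt[prev, _rng.RAMAN] += one
                    counters.n_additional_criteria += int((u1 < p_raman).sum())
                else:
                    counters.n_additional_criteria += int(prev.size)
            # drop
            dw = weight[i_idx] * mu_a[i_idx] / mu_t[i_idx]
            np.add.at(ledger.absorbed, pid[i_idx].astype(np.int64), dw)
            weight[i_idx] = weight[i_idx] - dw
            # roulette
            if roulette_on:
                low = i_idx[weight[i_idx] < config.roulette_threshold]
                if low.size:
                    ur = streams.uniform(
                        _rng.ROULETTE, pid[low], cnt[low, _rng.ROULETTE]
                    )
                    cnt[low, _rng.ROULETTE] += one
                    surv = ur < config.roulette_survive
                    sv = low[surv]
                    ledger.boost[pid[sv].astype(np.int64)] += weight[sv] * (
                        1.0 / config.roulette_survive - 1.0
                    )
                    weight[sv] = weight[sv] / config.roulette_survive
                    kl = low[~surv]
                    ledger.killed[pid[kl].astype(np.int64)] += weight[kl]
                    weight[kl] = 0.0
                    dead[kl] = True
            # spin (only packets still alive after roulette)
            sp = i_idx[~dead[i_idx]]
            if sp.size:
                u1 = streams.uniform(_rng.SPIN, pid[sp], cnt[sp, _rng.SPIN])
                cnt[sp, _rng.SPIN] += one
                u2 = streams.uniform(_rng.SPIN, pid[sp], cnt[sp, _rng.SPIN])
                cnt[sp, _rng.SPIN] += one
                cos_t = hg_cos_theta(u1, g_t[reg[sp], wl_eff[sp]])
                phi = 2.0 * np.pi * u2
                dirn[sp] = rotate_direction(dirn[sp], cos_t, phi)

        # ---- retire dead packets ------------------------------------------
        if dead.any():
            dp = dead.nonzero()[0]
            ledger.steps[pid[dp].astype(np.int64)] = steps[dp]
            keep = ~dead
            (pid, pos, dirn, weight, wl, shifted, max_depth, steps, cnt) = (
                pid[keep], pos[keep], dirn[keep], weight[keep], wl[keep],
                shifted[keep], max_depth[keep], steps[keep], cnt[keep],
            )
        if iteration % 2000 == 0:
            logger.info(
                "iteration %d: %d packets alive, %d Raman events so far",
                iteration, pid.size, counters.n_raman_total,
            )

    return ledger.finalize(result)
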