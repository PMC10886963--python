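"""Counter-based uniform random streams.

Every deviate is a pure function of ``(seed, stream, photon, counter)``: a
64-bit key is assembled from the four fields and passed through the SplitMix64
finalizer twice.  This buys three properties the simulator depends on:

* the scalar reference engine and the vectorized engine consume *identical*
  deviate sequences, so their trajectories can be compared bit-for-bit;
* paired runs that differ only in a physics switch (e.g. post-Raman property
  update on/off) share random numbers draw-for-draw — common random numbers —
  which makes percent-change estimates low-variance;
* there is no hidden global state; reproducibility is total for a fixed seed.

Streams are named per draw purpose so that a conditional draw in one part of
the step never shifts the deviates used elsewhere.
"""

from __future__ import annotations

import numpy as np

# Named substreams (one per kind of decision in the transport step).
STEP = 0       # free-path length
RAMAN = 1      # inelastic-event trigger
PEAK = 2       # Stokes-peak selection
ROULETTE = 3   # Russian-roulette survival
SPIN = 4       # scattering deflection (two draws per spin)
FRESNEL = 5    # boundary reflect/transmit

_U64 = np.uint64
_PHI = _U64(0x9E3779B97F4A7C15)       # golden-ratio increment
_STREAM_MULT = _U64(0xBF58476D1CE4E5B9)
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)
_S30 = _U64(30)
_S27 = _U64(27)
_S31 = _U64(31)
_S11 = _U64(11)
_INV53 = np.float64(1.0 / (1 << 53))


_MASK_INT = 0xFFFFFFFFFFFFFFFF
_PHI_INT = int(_PHI)
_M1_INT = int(_M1)
_M2_INT = int(_M2)
_INV53_FLOAT = 1.0 / (1 << 53)


def _mix(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer (vectorized, wrapping uint64 arithmetic)."""
    x = (x ^ (x >> _S30)) * _M1
    x = (x ^ (x >> _S27)) * _M2
    return x ^ (x >> _S31)


def _mix_int(x: int) -> int:
    """SplitMix64 finalizer on masked Python ints (exact uint64 emulation)."""
    m = _MASK_INT
    x = ((x ^ (x >> 30)) * _M1_INT) & m
    x = ((x ^ (x >> 27)) * _M2_INT) & m
    return x ^ (x >> 31)


class RandomStreams:
    """Seedable family of counter-based uniform streams on [0, 1).

    ``uniform(stream, photon, counter)`` accepts scalars or equally shaped
    arrays for ``photon``/``counter`` and returns float64 deviates with 53
    random mantissa bits.  The same arguments always return the same value.
    """

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        with np.errstate(over="ignore"):
            self._key = _mix(np.asarray(seed, dtype=np.uint64) * _PHI + _M2)
        self._key_int = int(self._key)
        self._stream_terms = [
            np.uint64((int(s) * int(_M2)) & 0xFFFFFFFFFFFFFFFF) for s in range(8)
        ]

    def uniform(self, stream: int, photon, counter) -> np.ndarray:
        photon = np.asarray(photon, dtype=np.uint64)
        counter = np.asarray(counter, dtype=np.uint64)
        with np.errstate(over="ignore"):
            h = _mix(self._key + photon * _PHI)
            h = _mix(h ^ (counter * _M1 + self._stream_terms[stream]))
        return (h >> _S11) * _INV53

    def uniform_scalar(self, stream: int, photon: int, counter: int) -> float:
        """Pure-Python fast path; bit-identical to :meth:`uniform`.

        Replicates the wrapping uint64 arithmetic with masked Python ints
        (exact), so the scalar engine avoids per-draw array overhead while
        drawing the very same deviates as the vectorized engine.
        """
        m = _MASK_INT
        h = (self._key_int + photon * _PHI_INT) & m
        h = _mix_int(h)
        h = h ^ ((counter * _M1_INT + stream * _M2_INT) & m)
        h = _mix_int(h)
        return (h >> 11) * _INV53_FLOAT
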