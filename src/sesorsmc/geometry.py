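"""Geometry of the simulated tissue volume.

The model is a 2 × 2 × 2 cm box of layered skin (z positive downward, the
beam entry point at the origin on the top surface) containing a cylindrical
SERS-active inclusion: a 6 mm diameter, 1 mm thick disc with its top face
2 mm below the surface, laterally centered under the beam.  The 10 × 10 mm
detection window is a tally concept (see :mod:`sesorsmc.tally`); the physical
volume is the full box and photons that leave any outer face terminate.

Containment uses half-open intervals [lo, hi) everywhere so that every
interior point maps to exactly one region and bin/region assignment on an
edge is unambiguous (the higher bin wins).

Both the region query and the boundary-distance query are numpy-broadcastable
over a leading batch axis; the scalar and vectorized transport engines share
these routines, which is what makes their trajectories comparable
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Layer",
    "Inclusion",
    "TissueModel",
    "region_at",
    "distance_to_boundary",
    "OUTSIDE",
]

#: Region code for points outside the volume.
OUTSIDE = -1

#: Minimum ray parameter considered a genuine crossing (cm); excludes the
#: surface the photon is currently sitting on.
_T_EPS = 1e-12

#: Probe offset used to ask "which region is the photon entering" (cm).
REGION_EPS = 1e-9

# Boundary kind labels for the public distance query.
_KIND_TOP = "top"
_KIND_BOTTOM = "bottom"
_KIND_SIDE = "side"
_KIND_INTERFACE = "interface"


@dataclass(frozen=True)
class Layer:
    """A horizontal tissue slab occupying depths [z_top, z_bottom)."""

    tissue: str
    z_top: float
    z_bottom: float

    def __post_init__(self):
        if not self.z_top < self.z_bottom:
            raise ConfigurationError(
                f"layer {self.tissue!r}: z_top must be < z_bottom"
            )


@dataclass(frozen=True)
class Inclusion:
    """Cylindrical SERS-active disc implanted in the layer stack."""

    center_xy: tuple = (0.0, 0.0)
    diameter: float = 0.6
    z_top: float = 0.2
    thickness: float = 0.1
    tissue: str = "inclusion"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ConfigurationError("inclusion diameter must be positive")
        if self.thickness <= 0:
            raise ConfigurationError("inclusion thickness must be positive")
        if self.z_top < 0:
            raise ConfigurationError("inclusion z_top must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def z_bottom(self) -> float:
        return self.z_top + self.thickness


class TissueModel:
    """Layer stack + inclusion + bounding box, with region/boundary queries.

    Parameters
    ----------
    layers : ordered sequence of Layer tiling [0, depth] without gaps
    inclusion : the implanted disc (must lie fully inside the volume)
    half_extent : lateral half-width (cm); the box spans [-h, h) in x and y
    depth : total depth (cm)
    n_ambient : refractive index of the medium above the top surface
    """

    def __init__(
        self,
        layers: Sequence[Layer],
        inclusion: Inclusion,
        half_extent: float = 1.0,
        depth: float = 2.0,
        n_ambient: float = 1.0,
    ):
        if half_extent <= 0 or depth <= 0:
            raise ConfigurationError("volume extents must be positive")
        layers = tuple(layers)
        if not layers:
            raise ConfigurationError("at least one layer is required")
        if abs(layers[0].z_top) > 0:
            raise ConfigurationError("first layer must start at z = 0")
        for a, b in zip(layers[:-1], layers[1:]):
            if abs(a.z_bottom - b.z_top) > 1e-12:
                raise ConfigurationError(
                    f"layers {a.tissue!r} and {b.tissue!r} do not tile contiguously"
                )
        if abs(layers[-1].z_bottom - depth) > 1e-12:
            raise ConfigurationError("layers must tile the full model depth")
        r = inclusion.radius
        cx, cy = inclusion.center_xy
        if (
            inclusion.z_bottom > depth
            or abs(cx) + r > half_extent
            or abs(cy) + r > half_extent
        ):
            raise ConfigurationError("inclusion must lie fully inside the volume")

        self.layers = layers
        self.inclusion = inclusion
        self.half_extent = float(half_extent)
        self.depth = float(depth)
        self.n_ambient = float(n_ambient)

        # Region codes: layers in order, inclusion last.
        self.region_names = tuple(l.tissue for l in layers) + (inclusion.tissue,)
        self.inclusion_code = len(layers)
        self._layer_bounds = np.array([l.z_bottom for l in layers[:-1]])

        # Internal z-planes: layer interfaces plus the inclusion faces
        # (modeled as full planes; a crossing that does not change region is
        # harmless — the exponential step is memoryless, so stopping at a
        # pseudo-boundary and resampling introduces no bias).
        internal_z = [l.z_bottom for l in layers[:-1]]
        internal_z += [inclusion.z_top, inclusion.z_bottom]
        z_planes = [0.0] + sorted(set(internal_z)) + [depth]
        self._z_planes = np.array(z_planes)
        kinds = [_KIND_INTERFACE] * len(z_planes)
        kinds[0] = _KIND_TOP
        kinds[-1] = _KIND_BOTTOM
        self._kinds = (
            kinds
            + [_KIND_SIDE] * 4
            + [_KIND_INTERFACE, _KIND_INTERFACE]  # two cylinder roots
        )

    @classmethod
    def default(cls, epidermis_thickness: float = 0.01, **kwargs) -> "TissueModel":
        """The packaged geometry: thin epidermis over dermis, disc at 2–3 mm."""
        depth = kwargs.pop("depth", 2.0)
        layers = (
            Layer("epidermis", 0.0, epidermis_thickness),
            Layer("dermis", epidermis_thickness, depth),
        )
        return cls(layers, Inclusion(), depth=depth, **kwargs)

    # -- region query -------------------------------------------------------

    def region_codes(self, position: np.ndarray) -> np.ndarray:
        """Integer region codes for positions of shape (..., 3).

        Codes index :attr:`region_names`; OUTSIDE (-1) for points above the
        surface, below the bottom or beyond the lateral extent.
        """
        p = np.asarray(position, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        h = self.half_extent
        inside = (z >= 0.0) & (z < self.depth)
        inside &= (x >= -h) & (x < h) & (y >= -h) & (y < h)
        codes = np.searchsorted(self._layer_bounds, z, side="right")
        inc = self.inclusion
        rx = x - inc.center_xy[0]
        ry = y - inc.center_xy[1]
        in_inc = (
            (z >= inc.z_top)
            & (z < inc.z_bottom)
            & (rx * rx + ry * ry < inc.radius * inc.radius)
        )
        codes = np.where(in_inc, self.inclusion_code, codes)
        return np.where(inside, codes, OUTSIDE)

    # -- boundary distances -------------------------------------------------

    def boundary_candidates(self, position, direction):
        """Ray parameters to every candidate surface, +inf where not hit."""
        p = np.asarray(position, dtype=float)
        d = np.asarray(direction, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]
        h = self.half_extent
        with np.errstate(divide="ignore", invalid="ignore"):
            tz = (self._z_planes - z[..., None]) / dz[..., None]
            tx = (np.array([-h, h]) - x[..., None]) / dx[..., None]
            ty = (np.array([-h, h]) - y[..., None]) / dy[..., None]
            inc = self.inclusion
            rx = x - inc.center_xy[0]
            ry = y - inc.center_xy[1]
            a = dx * dx + dy * dy
            b = rx * dx + ry * dy
            c = rx * rx + ry * ry - inc.radius * inc.radius
            disc = b * b - a * c
            sq = np.sqrt(np.maximum(disc, 0.0))
            t1 = (-b - sq) / a
            t2 = (-b + sq) / a
            bad = (disc < 0.0) | (a == 0.0)
            t1 = np.where(bad, np.inf, t1)
            t2 = np.where(bad, np.inf, t2)
        cand = np.concatenate(
            [tz, tx, ty, t1[..., None], t2[..., None]], axis=-1
        )
        return np.where((cand > _T_EPS) & np.isfinite(cand), cand, np.inf)

    def boundary_distance(self, position, direction) -> np.ndarray:
        """Smallest positive distance to any candidate surface (broadcastable)."""
        return np.min(self.boundary_candidates(position, direction), axis=-1)

    # -- scalar fast paths (pure-float replicas of the array routines; every
    #    expression mirrors the vectorized form so results are bit-identical,
    #    sqrt and the four arithmetic ops being IEEE-exact) ------------------

    def region_code_scalar(self, x: float, y: float, z: float) -> int:
        h = self.half_extent
        if not (0.0 <= z < self.depth and -h <= x < h and -h <= y < h):
            return OUTSIDE
        inc = self.inclusion
        if inc.z_top <= z < inc.z_bottom:
            rx = x - inc.center_xy[0]
            ry = y - inc.center_xy[1]
            if rx * rx + ry * ry < inc.radius * inc.radius:
                return self.inclusion_code
        code = 0
        for b in self._layer_bounds:
            if z >= b:
                code += 1
            else:
                break
        return code

    def boundary_distance_scalar(self, x, y, z, dx, dy, dz) -> float:
        best = math.inf
        if dz != 0.0:
            for zp in self._z_planes:
                t = (zp - z) / dz
                if _T_EPS < t < best:
                    best = t
        h = self.half_extent
        if dx != 0.0:
            t = (-h - x) / dx
            if _T_EPS < t < best:
                best = t
            t = (h - x) / dx
            if _T_EPS < t < best:
                best = t
        if dy != 0.0:
            t = (-h - y) / dy
            if _T_EPS < t < best:
                best = t
            t = (h - y) / dy
            if _T_EPS < t < best:
                best = t
        inc = self.inclusion
        a = dx * dx + dy * dy
        if a != 0.0:
            rx = x - inc.center_xy[0]
            ry = y - inc.center_xy[1]
            b = rx * dx + ry * dy
            c = rx * rx + ry * ry - inc.radius * inc.radius
            disc = b * b - a * c
            if disc >= 0.0:
                sq = math.sqrt(max(disc, 0.0))
                t = (-b - sq) / a
                if _T_EPS < t < best:
                    best = t
                t = (-b + sq) / a
                if _T_EPS < t < best:
                    best = t
        return best


def region_at(model: TissueModel, position) -> str:
    """Region name at a single position: a tissue id, the inclusion, or 'outside'."""
    code = int(model.region_codes(np.asarray(position, dtype=float)))
    return "outside" if code == OUTSIDE else model.region_names[code]


def distance_to_boundary(model: TissueModel, position, direction, max_hops: int = 64):
    """Distance (cm) and kind ('top'|'bottom'|'side'|'interface') of the
    nearest *region-changing* surface along a unit-direction ray.

    The transport engines stop at every candidate surface (including the
    analytic extensions of the inclusion faces, which is unbiased because the
    exponential step is memoryless); this public query walks past any
    candidate that does not actually change the region, so marching the
    returned distance plus ε always lands in a different region (or outside).
    """
    p = np.asarray(position, dtype=float)
    d = np.asarray(direction, dtype=float)
    start = int(model.region_codes(p + REGION_EPS * d))
    total = 0.0
    kind = _KIND_INTERFACE
    for _ in range(max_hops):
        cand = model.boundary_candidates(p, d)
        idx = int(np.argmin(cand))
        t = float(cand[idx])
        if not np.isfinite(t):
            break
        total += t
        p = p + t * d
        kind = model._kinds[idx]
        if int(model.region_codes(p + REGION_EPS * d)) != start:
            return total, kind
    return total, kind
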