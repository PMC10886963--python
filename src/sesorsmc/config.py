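"""Run configuration, validation, and result serialization.

A run is described by four blocks — geometry, optics, transport, tally —
each with packaged defaults that reproduce the reference scenario: the
2 × 2 × 2 cm skin model with a 6 mm × 1 mm SERS disc at 2 mm depth, a 45°
point-source launch, per-scatter Raman probability 1e-2 with the four-peak
MBA branch set, and the 10 × 10 mm tally window.  Configurations load from
YAML or JSON (or a plain dict); every validation failure names the offending
key.  Outputs are plain CSV/JSON, byte-identical across runs with the same
seed, plus a manifest carrying the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError
from .geometry import Inclusion, Layer, TissueModel
from .optics import (
    DEFAULT_EXCITATION_NM,
    PropertyTable,
    RamanPeakSet,
    build_property_table,
)
from .tally import RunResult, TallyConfig, offset_profile
from .transport import TransportConfig

__all__ = ["RunConfig", "load_and_validate", "write_outputs", "config_hash"]


@dataclass
class GeometryConfig:
    """Geometry block (lengths in cm)."""

    epidermis_thickness: float = 0.01
    depth: float = 2.0
    half_extent: float = 1.0
    inclusion_diameter: float = 0.6
    inclusion_z_top: float = 0.2
    inclusion_thickness: float = 0.1
    inclusion_center: tuple = (0.0, 0.0)
    n_ambient: float = 1.0

    def to_model(self) -> TissueModel:
        try:
            layers = (
                Layer("epidermis", 0.0, self.epidermis_thickness),
                Layer("dermis", self.epidermis_thickness, self.depth),
            )
            inclusion = Inclusion(
                center_xy=tuple(self.inclusion_center),
                diameter=self.inclusion_diameter,
                z_top=self.inclusion_z_top,
                thickness=self.inclusion_thickness,
            )
            return TissueModel(
                layers,
                inclusion,
                half_extent=self.half_extent,
                depth=self.depth,
                n_ambient=self.n_ambient,
            )
        except ConfigurationError as e:
            raise ConfigurationError(f"geometry: {e}") from None


@dataclass
class OpticsConfig:
    """Optics block: excitation, peak set and (optionally) explicit tables."""

    excitation_nm: float = DEFAULT_EXCITATION_NM
    peak_shifts: tuple = ()
    peak_weights: tuple = ()
    ph_label: str = "pH 7.0"
    #: explicit per-tissue property blocks; empty → packaged default table
    tissues: dict = field(default_factory=dict)
    enforce_monotone: bool = True

    def to_peaks(self) -> RamanPeakSet:
        if not self.peak_shifts:
            return RamanPeakSet.default()
        if not self.peak_weights:
            raise ConfigurationError("optics.peak_weights: required with peak_shifts")
        try:
            return RamanPeakSet.from_weights(
                self.peak_shifts, self.peak_weights, self.ph_label
            )
        except ConfigurationError as e:
            raise ConfigurationError(f"optics.branch_probs: {e}") from None

    def to_table(self, peaks: RamanPeakSet) -> PropertyTable:
        return build_property_table(
            self.tissues or None,
            peaks=peaks,
            excitation_nm=self.excitation_nm,
            enforce_monotone=self.enforce_monotone,
        )


@dataclass
class RunConfig:
    """The full run description."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    tally: TallyConfig = field(default_factory=TallyConfig)
    out_dir: str = "results"

    def build(self):
        """Materialize (model, table, transport config) and cross-validate."""
        model = self.geometry.to_model()
        peaks = self.transport.peaks
        table = self.optics.to_table(peaks)
        return model, table

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        d = {
            "geometry": asdict(self.geometry),
            "optics": asdict(self.optics),
            "transport": {
                k: v
                for k, v in asdict(self.transport).items()
                if k != "peaks"
            },
            "tally": asdict(self.tally),
            "out_dir": self.out_dir,
        }
        d["transport"]["peaks"] = {
            "shifts": list(self.transport.peaks.shifts),
            "branch_probs": [float(b) for b in self.transport.peaks.branch_probs],
            "ph_label": self.transport.peaks.ph_label,
        }
        return listify(d)


_BLOCKS = ("geometry", "optics", "transport", "tally", "out_dir")


def load_and_validate(source=None) -> RunConfig:
    """Build a validated RunConfig from a file path, dict, or nothing.

    ``source=None`` (or an empty file/dict) yields the packaged defaults.
    Unknown keys and invariant violations raise :class:`ConfigurationError`
    naming the offending key.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{source}: config must be a mapping")

    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")

    def block(name, cls):
        sub = dict(data.get(name, {}))
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(sub) - valid
        if bad:
            raise ConfigurationError(f"{name}: unknown keys {sorted(bad)}")
        try:
            return cls(**sub)
        except (ConfigurationError, TypeError) as e:
            raise ConfigurationError(f"{name}: {e}") from None

    geometry = block("geometry", GeometryConfig)
    optics = block("optics", OpticsConfig)
    tally = block("tally", TallyConfig)

    tsub = dict(data.get("transport", {}))
    valid = {f for f in TransportConfig.__dataclass_fields__}
    bad = set(tsub) - valid
    if bad:
        raise ConfigurationError(f"transport: unknown keys {sorted(bad)}")
    if "peaks" in tsub and isinstance(tsub["peaks"], dict):
        p = tsub["peaks"]
        try:
            label = p.get("ph_label", "pH 7.0")
            if "branch_probs" in p:
                # explicit probabilities are validated as-is (must sum to 1)
                tsub["peaks"] = RamanPeakSet(
                    tuple(p["shifts"]), p["branch_probs"], label
                )
            else:
                tsub["peaks"] = RamanPeakSet.from_weights(
                    p["shifts"], p["weights"], label
                )
        except (ConfigurationError, KeyError, TypeError) as e:
            raise ConfigurationError(f"transport.peaks.branch_probs: {e}") from None
    elif "peaks" not in tsub:
        tsub["peaks"] = optics.to_peaks()
    try:
        transport = TransportConfig(**tsub)
    except ConfigurationError as e:
        raise ConfigurationError(f"transport: {e}") from None

    cfg = RunConfig(
        geometry=geometry,
        optics=optics,
        transport=transport,
        tally=tally,
        out_dir=str(data.get("out_dir", "results")),
    )
    cfg.build()  # cross-validation: geometry consistency, table completeness
    return cfg


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form; changes iff the config changes."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _peak_label(config: RunConfig, wl_index: int) -> str:
    if wl_index == 0:
        return "exc"
    return f"{config.transport.peaks.shifts[wl_index - 1]:.0f}"


def write_outputs(result: RunResult, config: RunConfig, out_dir=None) -> dict:
    """Serialize counters, heatmaps, profiles, depth histograms and manifest.

    Integers are written exactly; floats with 17 significant digits, so two
    runs with equal seeds produce byte-identical files.  Returns the
    manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    counters_path = out / "counters.json"
    counters_path.write_text(
        json.dumps(result.counters.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    files.append(counters_path.name)

    n = result.config.n_bins
    header = (
        "# 10x10 exit-surface heatmap, 1 mm bins, row-major; "
        "beam entry at tally (x=0.05, y=0.5) cm = center of column 1, "
        "boundary of rows 5/6; half-open bins [lo, hi)\n"
    )
    for w in range(result.n_wavelengths):
        label = _peak_label(config, w)
        path = out / f"heatmap_{label}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            for r in range(n):
                fh.write(",".join(str(int(v)) for v in result.heatmap[w, r]) + "\n")
        files.append(path.name)

    for w in range(1, result.n_wavelengths):
        label = _peak_label(config, w)
        prof = offset_profile(result.grid_for(w), 0)
        path = out / f"profile_{label}.csv"
        with open(path, "w") as fh:
            fh.write("offset_mm,value\n")
            for o, v in zip(prof.offsets_mm, prof.values):
                fh.write(f"{o:.17g},{v:.17g}\n")
        files.append(path.name)

    path = out / "depth_hist.csv"
    with open(path, "w") as fh:
        fh.write("row,col,depth_mm_lo,count\n")
        nb = result.config.n_depth_bins
        for r in range(n):
            for c in range(n):
                for b in range(nb):
                    v = int(result.depth_hist[r, c, b])
                    if v:
                        fh.write(f"{r + 1},{c + 1},{b},{v}\n")
    files.append(path.name)

    manifest = {
        "package": "sesorsmc",
        "version": __version__,
        "seed": config.transport.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "counters": result.counters.as_dict(),
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
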