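"""Plain-text file formats: TSV data + JSON sidecars, YAML configuration.

Conventions (stated in every file header): angles in degrees on disk,
lengths in Angstrom, tab-separated with '.' decimal, UTF-8. Each data file
``X.tsv`` may carry a JSON sidecar ``X.tsv.meta.json`` holding provenance
(instrument, condition, seed, flags).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .forward_sim import InstrumentConfig, MembraneProfileSpec
from .nsld import NSLDProfile
from .reduction import Diffractogram1D, ReciprocalMap

__all__ = [
    "read_diffractogram",
    "write_diffractogram",
    "read_map",
    "write_map",
    "read_profile",
    "write_profile",
    "write_metrics",
    "validate_metrics_record",
    "read_profile_spec",
    "write_profile_spec",
    "RunConfig",
]

_SCHEMA_PATH = Path(__file__).parent / "schemas" / "metrics.schema.json"


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_sidecar(path, metadata: dict):
    def default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    _sidecar(path).write_text(json.dumps(metadata, indent=2, default=default))


def _read_sidecar(path) -> dict:
    sc = _sidecar(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# -- diffractograms ---------------------------------------------------------

def write_diffractogram(diff: Diffractogram1D, path):
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# 1D neutron diffractogram; angles in degrees, counts raw\n")
        fh.write("two_theta_deg\tcounts\tsigma_counts\n")
        for t, c, s in zip(diff.two_theta_deg, diff.counts, diff.sigma):
            fh.write(f"{t:.12g}\t{c:.17g}\t{s:.17g}\n")
    _write_sidecar(path, diff.metadata)


def read_diffractogram(path) -> Diffractogram1D:
    """Parse a 3-column TSV (two_theta_deg, counts, sigma_counts).

    A missing sigma column falls back to sqrt(counts) with a warning;
    malformed rows raise with their line number.
    """
    path = Path(path)
    tts, counts, sigmas = [], [], []
    have_sigma = True
    with path.open() as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols[0] != "two_theta_deg" or "counts" not in cols:
                    raise InputError(
                        f"{path}:{lineno}: expected header "
                        "'two_theta_deg\\tcounts[\\tsigma_counts]'"
                    )
                have_sigma = "sigma_counts" in cols
                header_seen = True
                continue
            parts = line.split("\t")
            try:
                t = float(parts[0])
                c = float(parts[1])
                s = float(parts[2]) if have_sigma else np.nan
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if c < 0:
                raise InputError(f"{path}:{lineno}: negative count {c}")
            if tts and t <= tts[-1]:
                raise InputError(f"{path}:{lineno}: non-monotonic two_theta {t}")
            tts.append(t)
            counts.append(c)
            sigmas.append(s)
    if not have_sigma:
        warnings.warn("no sigma_counts column; using sqrt(counts)", stacklevel=2)
        sigmas = [np.sqrt(c) if c > 0 else 1.0 for c in counts]
    return Diffractogram1D(
        np.array(tts), np.array(counts), np.array(sigmas), _read_sidecar(path)
    )


# -- reciprocal-space maps --------------------------------------------------

def write_map(rmap: ReciprocalMap, path):
    path = Path(path)
    frame = pd.DataFrame(
        rmap.intensity,
        index=pd.Index(rmap.omega_deg, name="omega_deg"),
        columns=[f"{t:.12g}" for t in rmap.two_theta_deg],
    )
    with path.open("w") as fh:
        fh.write("# rocking-scan map: rows = Omega (deg), columns = 2theta (deg)\n")
        frame.to_csv(fh, sep="\t")
    _write_sidecar(path, rmap.metadata)


def read_map(path) -> ReciprocalMap:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    omega = frame.index.to_numpy(dtype=float)
    two_theta = np.array([float(c) for c in frame.columns])
    intensity = frame.to_numpy(dtype=float)
    if intensity.shape != (omega.size, two_theta.size):
        raise InputError(f"{path}: matrix shape does not match axes")
    return ReciprocalMap(omega, two_theta, intensity, _read_sidecar(path))


# -- density profiles -------------------------------------------------------

def write_profile(profile: NSLDProfile, path):
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# NSLD profile; z in Angstrom, rho in arbitrary units\n")
        fh.write("z_angstrom\trho\n")
        for z, r in zip(profile.z_grid, profile.rho):
            fh.write(f"{z:.17g}\t{r:.17g}\n")
    meta = dict(profile.metadata)
    meta.update(
        {
            "d_spacing_A": profile.d_spacing,
            "n_orders": profile.n_orders,
            "contrast_d2o": profile.contrast_d2o,
        }
    )
    _write_sidecar(path, meta)


def read_profile(path) -> NSLDProfile:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    meta = _read_sidecar(path)
    if "d_spacing_A" not in meta:
        raise InputError(f"{path}: missing sidecar with d_spacing_A")
    return NSLDProfile(
        frame["z_angstrom"].to_numpy(),
        frame["rho"].to_numpy(),
        float(meta["d_spacing_A"]),
        int(meta.get("n_orders", 0)),
        float(meta.get("contrast_d2o", 0.08)),
        meta,
    )


# -- metrics tables ---------------------------------------------------------

def _load_schema() -> dict:
    return json.loads(_SCHEMA_PATH.read_text())


def validate_metrics_record(record: dict):
    """Check one metrics record against the packaged schema (minimal validator)."""
    schema = _load_schema()
    types = {"number": (int, float), "string": str, "integer": int,
             "array": list, "boolean": bool}
    for key in schema["required"]:
        if key not in record:
            raise InputError(f"metrics record missing required key {key!r}")
    for key, spec in schema["properties"].items():
        if key not in record or record[key] is None:
            continue
        expected = types[spec["type"]]
        value = record[key]
        if spec["type"] == "number" and isinstance(value, float) and np.isnan(value):
            continue
        if not isinstance(value, expected):
            raise InputError(
                f"metrics key {key!r}: expected {spec['type']}, got {type(value).__name__}"
            )


def write_metrics(frame: pd.DataFrame, path):
    """Metrics table as JSON records (validated) plus a TSV twin."""
    path = Path(path)
    records = frame.to_dict(orient="records")
    for rec in records:
        for k, v in list(rec.items()):
            if isinstance(v, np.generic):
                rec[k] = v.item()
        validate_metrics_record(rec)
    path.write_text(json.dumps(records, indent=2, default=str))
    frame.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


# -- membrane specs and run configuration -----------------------------------

def write_profile_spec(spec: MembraneProfileSpec, path):
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def read_profile_spec(path) -> MembraneProfileSpec:
    return MembraneProfileSpec.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class RunConfig:
    """Complete, file-round-trippable configuration of an analysis run."""

    instrument: InstrumentConfig = dataclasses.field(default_factory=InstrumentConfig)
    min_prominence: float = 5e-5
    max_orders: int = 8
    phase_window: tuple = (0.5, 0.95)
    n_grid: int = 512
    seed: int = 0

    def to_dict(self):
        return {
            "instrument": self.instrument.to_dict(),
            "min_prominence": self.min_prominence,
            "max_orders": self.max_orders,
            "phase_window": list(self.phase_window),
            "n_grid": self.n_grid,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data) -> "RunConfig":
        data = dict(data or {})
        inst = data.pop("instrument", {})
        pw = data.pop("phase_window", (0.5, 0.95))
        return cls(
            instrument=InstrumentConfig(**inst),
            phase_window=tuple(pw),
            **data,
        )

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the full configuration (logged on every run)."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
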