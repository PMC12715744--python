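"""File I/O shared by all stages: CSV time series, TOML spin systems,
JSON reports.

Column names carry their unit as a suffix (``_s``, ``_us``, ``_hz``);
schemas are enforced strictly so a mislabeled export fails loudly rather
than fitting garbage.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .field_characterization import NutationCurve
from .relaxometry import CpmgSeries
from .spin_core import SpinSystem, Spectrum, build_spin_system

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_timeseries",
    "write_timeseries",
    "read_spin_system",
    "write_report",
    "write_spectrum",
]


class SchemaError(ValueError):
    """A CSV file does not match its declared schema."""


#: Required columns per schema.
SCHEMAS: dict[str, list[str]] = {
    "nutation": ["t_pulse_us", "signal"],
    "cpmg": ["tau_s", "echo_index", "amplitude"],
    "ope": ["tau_s", "integral"],
    "injection": ["series", "rep", "integral"],
}


def _check_columns(df: pd.DataFrame, schema: str, path: Path) -> None:
    want = SCHEMAS[schema]
    missing = [c for c in want if c not in df.columns]
    extra = [c for c in df.columns if c not in want]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema "
                          f"{schema!r} (expected exactly {want})")
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra} for schema "
                          f"{schema!r} (expected exactly {want})")


def read_timeseries(path: str | Path, schema: str):
    """Read a typed table from CSV.

    Returns a :class:`NutationCurve`, a list of :class:`CpmgSeries`, or a
    validated DataFrame (``ope``, ``injection``), depending on ``schema``.
    Any ground-truth sidecar ``<path>.meta.json`` is attached as metadata.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    _check_columns(df, schema, path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if schema == "nutation":
        t = df["t_pulse_us"].to_numpy(dtype=float) * 1e-6
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: column t_pulse_us must be strictly "
                              "increasing")
        return NutationCurve(t, df["signal"].to_numpy(dtype=float), meta=meta)
    if schema == "cpmg":
        series = []
        for tau, grp in df.groupby("tau_s", sort=True):
            idx = grp["echo_index"].to_numpy(dtype=int)
            if np.any(np.diff(idx) <= 0):
                raise SchemaError(f"{path}: column echo_index must be strictly "
                                  f"increasing within tau_s={tau}")
            series.append(CpmgSeries(tau=float(tau), echo_index=idx,
                                     amplitude=grp["amplitude"].to_numpy(float),
                                     meta=meta))
        return series
    if schema == "ope":
        if np.any(np.diff(df["tau_s"].to_numpy(float)) <= 0):
            raise SchemaError(f"{path}: column tau_s must be strictly increasing")
    if meta:
        df.attrs["truth"] = meta
    return df


def write_timeseries(obj, path: str | Path, schema: str,
                     meta: dict | None = None) -> None:
    """Write a typed table as CSV (+ optional ``.meta.json`` truth sidecar)."""
    path = Path(path)
    if schema == "nutation":
        df = pd.DataFrame({"t_pulse_us": obj.t_pulse * 1e6, "signal": obj.signal})
        meta = meta if meta is not None else obj.meta
    elif schema == "cpmg":
        frames = [pd.DataFrame({"tau_s": s.tau, "echo_index": s.echo_index,
                                "amplitude": s.amplitude}) for s in obj]
        df = pd.concat(frames, ignore_index=True)
        if meta is None and obj and obj[0].meta:
            meta = obj[0].meta
    elif schema in ("ope", "injection"):
        df = obj[SCHEMAS[schema]]
        if meta is None:
            meta = obj.attrs.get("truth")
    else:
        raise ValueError(f"unknown schema {schema!r}")
    df.to_csv(path, index=False)
    if meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_spin_system(path: str | Path) -> SpinSystem:
    """Read a spin system from a TOML file.

    Expected layout::

        [field]
        b0_t = 0.4454
        ref_freq_hz = 1.8717e7

        [spins]
        labels = ["CH3", "OCH2"]      # optional
        shifts_ppm = [1.26, 4.12]

        [couplings]
        pairs = [[0, 1, 7.1]]         # i, j, J in Hz
        model = "isotropic"           # optional; or "weak"
    """
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        shifts = doc["spins"]["shifts_ppm"]
        b0 = doc["field"]["b0_t"]
        ref = doc["field"]["ref_freq_hz"]
    except KeyError as exc:
        raise SchemaError(f"{path}: missing required key {exc}") from exc
    labels = doc["spins"].get("labels")
    n = len(shifts)
    j = np.zeros((n, n))
    for i, k, val in doc.get("couplings", {}).get("pairs", []):
        j[int(i), int(k)] = j[int(k), int(i)] = float(val)
    coupling = doc.get("couplings", {}).get("model", "isotropic")
    return build_spin_system(shifts, j, b0=b0, ref_freq=ref, labels=labels,
                             coupling=coupling)


def _config_hash(config: dict | None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(results: dict, path: str | Path,
                 config: dict | None = None, seed: int | None = None) -> None:
    """Write a JSON analysis report.

    The report carries the package version, a hash of the configuration
    and the seed, so a result can always be traced to the exact run that
    produced it.  Output is byte-identical for identical inputs (sorted
    keys, no timestamps).
    """
    from . import __version__

    doc = {
        "package": "phipkit",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "results": results,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Spectrum as CSV (axis, real, imag) with a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"ppm": spectrum.ppm, "freq_hz": spectrum.freq_hz,
                       "real": spectrum.values.real,
                       "imag": spectrum.values.imag})
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(spectrum.meta, indent=1, sort_keys=True) + "\n")
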