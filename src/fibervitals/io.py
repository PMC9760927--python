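"""CSV readers/writers and structured configuration.

Coupler records and phase series travel as plain CSV with a minimal metadata
header: comment lines `# key=value` (at least `# fs=<Hz>`) followed by a
column header. Records are small (minutes at a few hundred S/s), so an
inspectable text format beats a binary container.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError
from .synth import CouplerParams, CouplerRecord, PhaseSeries, PhysioParams, SamplingSpec
from .vitals import BandConfig

__all__ = ["write_coupler_csv", "read_coupler_csv", "write_phase_csv",
           "read_phase_csv", "write_vitals_csv", "read_pairs_csv", "write_pairs_csv",
           "load_config", "physio_from_config", "sampling_from_config",
           "coupler_from_config", "band_from_config"]


def _read_meta(path: Path) -> tuple[dict, int]:
    """Parse leading `# key=value` lines; return (meta, number of such lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n


def _require_fs(meta: dict, path: Path) -> float:
    if "fs" not in meta:
        raise FormatError(f"{path}: missing '# fs=<Hz>' header line")
    try:
        return float(meta["fs"])
    except ValueError as e:
        raise FormatError(f"{path}: bad fs value {meta['fs']!r}") from e


def write_coupler_csv(record: CouplerRecord, path, meta: dict | None = None) -> None:
    path = Path(path)
    lines = [f"# fs={record.fs}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    t = record.times()
    df = pd.DataFrame({"t": t, "u1": record.u[0], "u2": record.u[1], "u3": record.u[2]})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_coupler_csv(path) -> CouplerRecord:
    path = Path(path)
    meta, skip = _read_meta(path)
    fs = _require_fs(meta, path)
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as e:
        raise FormatError(f"{path}: unreadable CSV ({e})") from e
    for col in ("t", "u1", "u2", "u3"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["u1", "u2", "u3"]].isna().any(axis=1)
    if bad.any():
        # +2 for the column-header line and 1-based numbering
        raise FormatError(f"{path}: non-numeric value at line {int(bad.idxmax()) + skip + 2}")
    t0 = float(df["t"].iloc[0]) if len(df) else 0.0
    return CouplerRecord(u=df[["u1", "u2", "u3"]].to_numpy().T, fs=fs, t0=t0)


def write_phase_csv(phase: PhaseSeries, path, meta: dict | None = None) -> None:
    path = Path(path)
    lines = [f"# fs={phase.fs}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    df = pd.DataFrame({"t": phase.times(), "phase_rad": phase.values})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_phase_csv(path) -> PhaseSeries:
    path = Path(path)
    meta, skip = _read_meta(path)
    fs = _require_fs(meta, path)
    df = pd.read_csv(path, skiprows=skip)
    if "phase_rad" not in df.columns:
        raise FormatError(f"{path}: missing column 'phase_rad'")
    t0 = float(df["t"].iloc[0]) if "t" in df.columns and len(df) else 0.0
    return PhaseSeries(values=df["phase_rad"].to_numpy(), fs=fs, t0=t0)


def write_vitals_csv(table: pd.DataFrame, path) -> None:
    cols = ["minute", "rr_bpm", "hr_bpm", "valid_rr", "valid_hr", "distorted"]
    table[cols].to_csv(path, index=False)


PAIRS_COLUMNS = ["subject", "sex", "weight_kg", "vital", "minute", "reference", "efos"]


def write_pairs_csv(pairs: pd.DataFrame, path) -> None:
    pairs[PAIRS_COLUMNS].to_csv(path, index=False)


def read_pairs_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"{path}: unreadable CSV ({e})") from e
    missing = [c for c in PAIRS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def _build(cls, section: dict | None, tuple_fields=()):
    section = dict(section or {})
    for f in tuple_fields:
        if f in section:
            section[f] = tuple(section[f])
    return cls(**section)


def sampling_from_config(cfg: dict) -> SamplingSpec:
    return _build(SamplingSpec, cfg.get("sampling"))


def physio_from_config(cfg: dict) -> PhysioParams:
    return _build(PhysioParams, cfg.get("physio"),
                  tuple_fields=("breath_harmonics", "cardiac_harmonics"))


def coupler_from_config(cfg: dict) -> CouplerParams:
    return _build(CouplerParams, cfg.get("coupler"), tuple_fields=("C", "A", "delta"))


def band_from_config(cfg: dict) -> BandConfig:
    return _build(BandConfig, cfg.get("band"))
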