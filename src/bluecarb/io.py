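"""Reading and writing core tables and configuration.

The canonical interchange format is a pair of delimited-text tables keyed
by ``core_id``:

* a **slice table** with one row per depth interval
  (``core_id, depth_top, depth_bottom, dry_bulk_density, pb210_total,
  pb210_total_err, pb210_supported, caco3_pct, corg_pct``), and
* a **core metadata table** with one row per core
  (``core_id, ecosystem, latitude, longitude, coring_year, location_key,
  climate_class, is_tropical, coral_reef_present, lithogenic_present``).

Published compilations use many different headers, so both readers accept
a column mapping from canonical names to the file's column names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .model import Constants, CoreSlice, SedimentCore, ValidationError

__all__ = [
    "SchemaError",
    "ConfigError",
    "SLICE_COLUMNS",
    "META_COLUMNS",
    "read_core_table",
    "write_core_table",
    "load_config",
    "cores_to_frames",
]


class SchemaError(ValueError):
    """A required column is missing or a column mapping is inconsistent."""


class ConfigError(ValueError):
    """A configuration override is malformed or out of range."""


#: Canonical slice-table columns (required first, optional after).
SLICE_REQUIRED = ("core_id", "depth_top", "depth_bottom", "dry_bulk_density",
                  "pb210_total", "caco3_pct")
SLICE_OPTIONAL = ("pb210_total_err", "pb210_supported", "corg_pct")
SLICE_COLUMNS = SLICE_REQUIRED + SLICE_OPTIONAL

META_REQUIRED = ("core_id", "ecosystem", "latitude", "longitude",
                 "coring_year", "location_key")
META_OPTIONAL = ("climate_class", "is_tropical", "coral_reef_present",
                 "lithogenic_present")
META_COLUMNS = META_REQUIRED + META_OPTIONAL

_BOOL_META = ("is_tropical", "coral_reef_present", "lithogenic_present")


def _remap(df: pd.DataFrame, schema: Mapping[str, str] | None,
           required: Sequence[str], where: str) -> pd.DataFrame:
    """Rename file columns to canonical names and check required ones."""
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing_src = [v for v in schema.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(f"{where}: mapped columns not found in file: {missing_src}")
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing required columns {missing}")
    return df


def _opt_float(row, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if pd.isna(v):
        return None
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes", "y")
    if pd.isna(v):
        return False
    return bool(v)


def read_core_table(
    slices_path: str | Path,
    metadata_path: str | Path,
    slice_schema: Mapping[str, str] | None = None,
    meta_schema: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[SedimentCore]:
    """Read a slice table and a metadata table into validated cores.

    Parameters
    ----------
    slices_path, metadata_path
        Delimited-text files (slice rows / one row per core).
    slice_schema, meta_schema
        Optional mappings ``{canonical_name: file_column_name}`` for files
        whose headers differ from the canonical names.
    sep
        Field delimiter.

    Returns
    -------
    list of SedimentCore, sorted by core_id, slices sorted by depth.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row violates a slice/core invariant; the message names the
        core and the offending 1-based data row of the slice table.
    """
    # round_trip parsing: re-reading written cores must be bit-identical
    sl = pd.read_csv(slices_path, sep=sep, float_precision="round_trip")
    sl = _remap(sl, slice_schema, SLICE_REQUIRED, f"slice table {slices_path}")
    meta = pd.read_csv(metadata_path, sep=sep, float_precision="round_trip")
    meta = _remap(meta, meta_schema, META_REQUIRED, f"metadata table {metadata_path}")

    meta = meta.set_index(meta["core_id"].astype(str))
    cores: list[SedimentCore] = []
    for core_id, grp in sl.groupby(sl["core_id"].astype(str), sort=True):
        if core_id not in meta.index:
            raise SchemaError(f"core {core_id}: present in slice table but not in metadata table")
        grp = grp.sort_values("depth_top")
        slices = []
        for idx, row in grp.iterrows():
            try:
                slices.append(CoreSlice(
                    depth_top=float(row["depth_top"]),
                    depth_bottom=float(row["depth_bottom"]),
                    dry_bulk_density=float(row["dry_bulk_density"]),
                    pb210_total=float(row["pb210_total"]),
                    caco3_pct=float(row["caco3_pct"]),
                    pb210_total_err=_opt_float(row, "pb210_total_err"),
                    pb210_supported=_opt_float(row, "pb210_supported"),
                    corg_pct=_opt_float(row, "corg_pct"),
                ))
            except (ValidationError, ValueError, TypeError) as exc:
                raise ValidationError(
                    f"core {core_id}, slice-table row {int(idx) + 1}: {exc}"
                ) from exc
        m = meta.loc[core_id]
        try:
            cores.append(SedimentCore(
                core_id=core_id,
                ecosystem=str(m["ecosystem"]),
                latitude=float(m["latitude"]),
                longitude=float(m["longitude"]),
                coring_year=int(m["coring_year"]),
                location_key=str(m["location_key"]),
                climate_class=str(m["climate_class"]) if "climate_class" in m.index
                and not pd.isna(m["climate_class"]) else "",
                is_tropical=_as_bool(m.get("is_tropical", False)),
                coral_reef_present=_as_bool(m.get("coral_reef_present", False)),
                lithogenic_present=_as_bool(m.get("lithogenic_present", False)),
                slices=tuple(slices),
            ))
        except ValidationError as exc:
            raise ValidationError(f"core {core_id}: {exc}") from exc
    return cores


def cores_to_frames(cores: Sequence[SedimentCore]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten cores into (slice table, metadata table) DataFrames."""
    srows, mrows = [], []
    for c in cores:
        mrows.append({
            "core_id": c.core_id, "ecosystem": c.ecosystem,
            "latitude": c.latitude, "longitude": c.longitude,
            "coring_year": c.coring_year, "location_key": c.location_key,
            "climate_class": c.climate_class, "is_tropical": c.is_tropical,
            "coral_reef_present": c.coral_reef_present,
            "lithogenic_present": c.lithogenic_present,
        })
        for s in c.slices:
            srows.append({"core_id": c.core_id, **dataclasses.asdict(s)})
    scols = ["core_id", *[f.name for f in dataclasses.fields(CoreSlice)]]
    return (pd.DataFrame(srows, columns=scols),
            pd.DataFrame(mrows, columns=list(META_COLUMNS)))


def write_core_table(
    cores: Sequence[SedimentCore],
    slices_path: str | Path,
    metadata_path: str | Path,
    sep: str = ",",
) -> None:
    """Write cores as the canonical two-table layout.

    Floats are serialised at full IEEE-double precision so that
    ``read_core_table(write_core_table(cores))`` reproduces every numeric
    field bit-identically.
    """
    sl, meta = cores_to_frames(cores)
    # %.17g is lossless for IEEE doubles; pandas' default print drops a digit
    sl.to_csv(slices_path, sep=sep, index=False, float_format="%.17g")
    meta.to_csv(metadata_path, sep=sep, index=False, float_format="%.17g")


def load_config(path: str | Path | None = None) -> Constants:
    """Load accounting constants, optionally overridden from a YAML file.

    With no file the documented defaults apply (carbon fraction 0.12,
    CO2-release ratio 0.6, seagrass area 150,000-600,000 km^2, mangrove
    area 137,760 km^2, tropical fraction 2/3, lambda = ln 2 / 22.3 yr).
    A user file overrides individual fields by name.

    Raises
    ------
    ConfigError
        For unknown keys, non-numeric values or out-of-range overrides.
    """
    if path is None:
        return Constants()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dataclasses.fields(Constants)}
    overrides = {}
    for key, value in raw.items():
        if key not in valid:
            raise ConfigError(f"unknown constant {key!r} (valid: {sorted(valid)})")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"constant {key!r} must be numeric, got {value!r}")
        overrides[key] = float(value)
    try:
        return Constants(**overrides)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
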