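"""Reading and writing event tables, and configuration loading.

Event tables are plain pandas DataFrames with canonical role columns
(``dna_area``, ``dna_width``, ``mcm_signal``, ``rb1_signal``, optionally
``barcode_signal``) plus, for synthetic data, ground-truth columns. On disk
the measurement channels use instrument short names (``FL2-A``, ``FL2-W``,
``MCM-FITC``, ``RB1-A647``, ``PB-450``) in either FCS 3.1 (float) or CSV;
ground truth is written to a sidecar CSV keyed by event index, never into
the cytometry file itself.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs
from .errors import ConfigurationError, InputError
from .simulate import MEASUREMENT_COLUMNS, TRUTH_COLUMNS, OpticsConfig, ScenarioConfig, get_scenario

#: default role -> channel short-name mapping
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "dna_area": "FL2-A",
    "dna_width": "FL2-W",
    "mcm_signal": "MCM-FITC",
    "rb1_signal": "RB1-A647",
    "barcode_signal": "PB-450",
}
_REQUIRED_ROLES = ("dna_area", "dna_width")


def parse_channel_map(spec: str) -> dict[str, str]:
    """Parse ``role=NAME,role=NAME`` CLI syntax into a channel map."""
    out = dict(DEFAULT_CHANNEL_MAP)
    aliases = {"dna_a": "dna_area", "dna_w": "dna_width",
               "mcm": "mcm_signal", "rb1": "rb1_signal", "barcode": "barcode_signal"}
    for item in filter(None, (s.strip() for s in spec.split(","))):
        if "=" not in item:
            raise ConfigurationError(f"bad channel mapping {item!r}; expected role=NAME")
        role, name = item.split("=", 1)
        role = aliases.get(role.strip(), role.strip())
        if role not in DEFAULT_CHANNEL_MAP:
            raise ConfigurationError(
                f"unknown channel role {role!r}; roles: {sorted(DEFAULT_CHANNEL_MAP)}")
        out[role] = name.strip()
    return out


def _validate_map(channel_map: dict[str, str]) -> dict[str, str]:
    for role in _REQUIRED_ROLES:
        if role not in channel_map:
            raise ConfigurationError(f"channel map must include {role!r}")
    names = list(channel_map.values())
    if len(set(names)) != len(names):
        raise ConfigurationError(f"channel map assigns one name to two roles: {channel_map}")
    return channel_map


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("fcs", "csv"):
            raise ConfigurationError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".fcs":
        return "fcs"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ConfigurationError(f"cannot infer format from {path.name!r}; pass format=")


def read_events(path, fmt: str | None = None,
                channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an FCS or CSV file into a canonical event table.

    Mapped channels are renamed to their roles; for FCS both ``$PnN`` and
    ``$PnS`` are honored when matching. Values are passed through unscaled.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = _detect_format(path, fmt)
    channel_map = _validate_map(dict(channel_map or DEFAULT_CHANNEL_MAP))
    if fmt == "csv":
        raw = pd.read_csv(path)
        available = {c: c for c in raw.columns}
    else:
        raw, meta = fcs.read_fcs(path)
        available = {c: c for c in raw.columns}
        n_par = int(meta.get("$PAR", 0))
        for i in range(1, n_par + 1):  # $PnS long names as aliases
            long = meta.get(f"$P{i}S")
            short = meta.get(f"$P{i}N", f"P{i}")
            if long and long not in available:
                available[long] = short

    out = {}
    for role, name in channel_map.items():
        if name in available:
            out[role] = raw[available[name]].to_numpy(dtype=float)
    missing = [r for r in _REQUIRED_ROLES if r not in out]
    if missing:
        raise InputError(
            f"{path.name}: mapped channels for roles {missing} not found; "
            f"available channels: {sorted(available)}")
    # pass through any non-channel columns (ground truth in CSVs)
    mapped_names = {available.get(n, n) for n in channel_map.values() if n in available}
    events = pd.DataFrame(out)
    for col in raw.columns:
        if col not in mapped_names and col not in events.columns:
            events[col] = raw[col]
    events.attrs["source"] = str(path)
    events.attrs["channel_map"] = channel_map
    return events


def truth_sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".truth.csv")


def write_events(events: pd.DataFrame, path, fmt: str | None = None) -> Path:
    """Write the measurement channels of an event table to FCS 3.1 or CSV.

    Ground-truth columns, when present, go to a ``<stem>.truth.csv`` sidecar
    keyed by event index — never into the cytometry channels.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    channels = [c for c in MEASUREMENT_COLUMNS if c in events.columns]
    if not channels:
        raise InputError("event table has no measurement channels to write")
    table = events[channels].rename(columns=DEFAULT_CHANNEL_MAP)
    if fmt == "csv":
        table.to_csv(path, index=False)
    else:
        fcs.write_fcs(path, table)
    truth_cols = [c for c in TRUTH_COLUMNS if c in events.columns]
    if truth_cols:
        truth = events[truth_cols].copy()
        truth.insert(0, "event_index", np.arange(len(events)))
        truth.to_csv(truth_sidecar_path(path), index=False)
    return path


def _from_mapping(cls, mapping: dict, context: str):
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    valid = {f.name for f in cls.__dataclass_fields__.values()}
    unknown = sorted(set(mapping) - valid)
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {unknown}; valid keys: {sorted(valid)}")
    return cls(**mapping)


def load_scenario(obj) -> ScenarioConfig:
    """Build a ScenarioConfig from a preset name, YAML path, or mapping."""
    if isinstance(obj, ScenarioConfig):
        return obj
    if isinstance(obj, str) and not obj.endswith((".yaml", ".yml")):
        return get_scenario(obj)
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            obj = yaml.safe_load(fh)
        if "scenario" in obj and isinstance(obj["scenario"], dict):
            obj = obj["scenario"]
    if isinstance(obj, dict) and "preset" in obj:
        obj = dict(obj)
        name = obj.pop("preset")
        return get_scenario(name, **obj)
    if isinstance(obj, dict) and "timepoints" in obj:
        obj = {**obj, "timepoints": tuple(obj["timepoints"])}
    return _from_mapping(ScenarioConfig, obj, "scenario")


def load_optics(obj) -> OpticsConfig:
    """Build an OpticsConfig from a YAML path or mapping (None = defaults)."""
    if obj is None:
        return OpticsConfig()
    if isinstance(obj, OpticsConfig):
        return obj
    if isinstance(obj, (str, Path)):
        with open(obj) as fh:
            obj = yaml.safe_load(fh)
        if isinstance(obj, dict) and "optics" in obj:
            obj = obj["optics"]
    if isinstance(obj, dict) and "barcode_levels" in obj:
        obj = {**obj, "barcode_levels": tuple(obj["barcode_levels"])}
    return _from_mapping(OpticsConfig, obj, "optics")
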