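"""YAML analysis configuration.

Externalizes the GUI-style settings (peak thresholds, seizure parameters,
band edges, channel groups, time range, optional filter) into a file with
a strict schema: unknown keys are rejected so a typo cannot silently fall
back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .dsp import BandDefinition, DEFAULT_BANDS, FilterSpec
from .lfp import DetectionParams
from .recording import ChannelGroup, ChannelID, TimeRange, ValidationError
from .seizure import SeizureParams

CONFIG_VERSION = 1

_TOP_KEYS = {"version", "detection", "seizure", "bands", "groups", "time_range", "filter", "paths"}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _dataclass_from(section: dict, cls, where: str):
    allowed = {f.name for f in dc_fields(cls)}
    _check_keys(section, allowed, where)
    try:
        return cls(**section)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"invalid {where}: {exc}")


def _parse_channel(entry) -> ChannelID:
    if isinstance(entry, int):
        return ChannelID.from_linear(entry)
    if isinstance(entry, (list, tuple)) and len(entry) == 2:
        return ChannelID(int(entry[0]), int(entry[1]))
    raise ConfigError(f"cannot parse channel {entry!r}: use a linear index or [row, col]")


@dataclass
class AnalysisConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    seizure: SeizureParams = field(default_factory=SeizureParams)
    bands: List[BandDefinition] = field(default_factory=lambda: list(DEFAULT_BANDS))
    groups: List[ChannelGroup] = field(default_factory=list)
    time_range: Optional[TimeRange] = None
    filter: Optional[FilterSpec] = None
    paths: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys(raw, _TOP_KEYS, "config")
        version = raw.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        cfg = cls()
        if "detection" in raw:
            cfg.detection = _dataclass_from(raw["detection"], DetectionParams, "detection")
        if "seizure" in raw:
            cfg.seizure = _dataclass_from(raw["seizure"], SeizureParams, "seizure")
        if "bands" in raw:
            bands = []
            for b in raw["bands"]:
                _check_keys(b, {"name", "lo_hz", "hi_hz"}, "bands entry")
                bands.append(BandDefinition(b["name"], float(b["lo_hz"]), float(b["hi_hz"])))
            cfg.bands = bands
        if "groups" in raw:
            groups = []
            for name, members in raw["groups"].items():
                groups.append(ChannelGroup(name, [_parse_channel(m) for m in members]))
            names = [g.name for g in groups]
            if len(set(names)) != len(names):
                raise ConfigError("duplicate group names")
            all_members = [c for g in groups for c in g.members]
            if len(set(all_members)) != len(all_members):
                raise ConfigError("groups must be pairwise disjoint")
            cfg.groups = groups
        if "time_range" in raw:
            tr = raw["time_range"]
            _check_keys(tr, {"start_s", "end_s"}, "time_range")
            try:
                cfg.time_range = TimeRange(float(tr["start_s"]), float(tr["end_s"]))
            except (KeyError, ValidationError) as exc:
                raise ConfigError(f"invalid time_range: {exc}")
        if "filter" in raw:
            f = raw["filter"]
            _check_keys(f, {"kind", "cutoff_hz", "order"}, "filter")
            try:
                cfg.filter = FilterSpec(f["kind"], f["cutoff_hz"], int(f.get("order", 4)))
            except (KeyError, ValidationError) as exc:
                raise ConfigError(f"invalid filter: {exc}")
        if "paths" in raw:
            cfg.paths = {str(k): str(v) for k, v in raw["paths"].items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})
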