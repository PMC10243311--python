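"""Application configuration: one YAML file covering detection, tolerances,
the audit-log location, and the clinical-table scenarios.

All defaults are embedded; ``breathqa config show`` dumps them. The config
hash logged with every audit is the SHA-256 of the canonical YAML dump, so
two audits with the same hash ran under identical settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .breath_signal import DetectionConfig
from .errors import ConfigError
from .qa_audit import ToleranceConfig


@dataclass(frozen=True)
class TableScenarios:
    """Inputs of the displacement and margin tables."""

    phi: float = 0.19  # phase shift, fraction of cycle (2 bins of 10%)
    amplitudes: tuple[float, ...] = tuple(np.round(np.arange(0.25, 3.001, 0.25), 2))
    phases: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.91, 0.1), 1))
    mip_lengths: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)  # cm
    epsilon: float = -11.4  # percent, cohort-median voluming error


@dataclass(frozen=True)
class AppConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    tables: TableScenarios = field(default_factory=TableScenarios)
    audit_log_path: str = "breathqa_audit.csv"


def _section(cls, data: dict, name: str):
    raw = data.get(name, {})
    if not isinstance(raw, dict):
        raise ConfigError(f"config section {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None) -> AppConfig:
    """Load an AppConfig from YAML; missing sections/keys use defaults."""
    if path is None:
        return AppConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return AppConfig(
        detection=_section(DetectionConfig, data, "detection"),
        tolerances=_section(ToleranceConfig, data, "tolerances"),
        tables=_section(TableScenarios, data, "tables"),
        audit_log_path=str(data.get("audit_log_path", AppConfig().audit_log_path)),
    )


def dump_config(config: AppConfig) -> str:
    """Canonical YAML rendering (sorted keys, plain types)."""
    data = asdict(config)

    def plain(obj):
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return yaml.safe_dump(plain(data), sort_keys=True)


def config_hash(config: AppConfig) -> str:
    """Short SHA-256 of the canonical dump."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]
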