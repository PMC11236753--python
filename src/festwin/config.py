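"""Run configuration: YAML loading, defaults and validation."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError

_REQUIRED: dict[str, tuple[str, ...]] = {
    "phantom": ("leh_rsp_length_mm", "skin_thickness_mm"),
    "solver": ("resolution_mm",),
    "electrodes": ("muscle",),
    "fibers": ("n_fibers", "seed"),
    "stimulation": ("pulse_widths_us",),
}


def default_config() -> dict:
    """The shipped default configuration as a dict."""
    ref = resources.files("festwin") / "data" / "default_config.yaml"
    with resources.as_file(ref) as p:
        return yaml.safe_load(p.read_text())


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a YAML config; missing keys fall back to defaults."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Check required sections/fields; raise ConfigError naming the gap."""
    for section, keys in _REQUIRED.items():
        if section not in cfg or not isinstance(cfg[section], dict):
            raise ConfigError(f"missing config section: {section!r}")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigError(f"missing config field: {section}.{key}")
    if cfg["solver"]["resolution_mm"] <= 0:
        raise ConfigError("solver.resolution_mm must be > 0")
    if cfg["fibers"]["n_fibers"] < 1:
        raise ConfigError("fibers.n_fibers must be >= 1")
    pws = cfg["stimulation"]["pulse_widths_us"]
    if not pws or any(p <= 0 for p in pws):
        raise ConfigError("stimulation.pulse_widths_us must be positive")
    mode = cfg["stimulation"].get("mode", "continuous")
    if mode not in ("continuous", "grid"):
        raise ConfigError(f"stimulation.mode must be continuous|grid, got {mode!r}")
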