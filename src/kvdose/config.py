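"""Pipeline configuration: complete defaults, YAML overlay, dotted overrides.

An empty user config runs; every knob below has a default stated in the
methods note.  ``--set a.b=c`` style overrides are applied on top of the
YAML document.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "kvdose_out",
    "cohort": {
        "n_patients": 30,
        "stress": 0.9,
        "spacing_mm": 2.5,
        # (rx_total Gy, n_fractions, count)
        "prescription_mix": [[48.0, 4, 26], [60.0, 8, 3], [60.0, 15, 1]],
    },
    "imaging": {
        "enabled": True,
        "frequency_hz": 1.67,
        "grid_spacing_mm": 5.0,  # ray-march resolution of the kV surrogate
        "n_samples": 96,
        "source_distance_mm": 1400.0,
        "field_halfangle_deg": 10.0,
        "bone_factor": 4.0,
        "air_kerma_ref": 2.5e-4,  # Gy per mAs at ref_distance
        "ref_distance_mm": 1000.0,
        # per-tube gantry-angle intervals blocked by the gantry head (deg)
        "blocked_ranges": {"A": [[95.0, 215.0]], "B": [[145.0, 265.0]]},
    },
    "dvh": {
        "bin_width_gy": 0.01,
        "strict_threshold": False,  # True: V_D counts dose > D instead of >= D
    },
}


def _deep_update(base: dict, overlay: dict) -> dict:
    for k, v in overlay.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


@dataclass
class PipelineConfig:
    """Validated configuration document with attribute-style section access."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path: str | Path | None = None,
             sets: list[str] | None = None) -> "PipelineConfig":
        cfg = cls()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            if not isinstance(user, dict):
                raise ValueError(f"config {path} must be a YAML mapping")
            _deep_update(cfg.data, user)
        for item in sets or []:
            cfg.set_override(item)
        cfg.validate()
        return cfg

    def set_override(self, item: str) -> None:
        """Apply one ``dotted.key=value`` override (YAML-parsed value)."""
        if "=" not in item:
            raise ValueError(f"override {item!r} must look like key.path=value")
        key, raw = item.split("=", 1)
        node = self.data
        parts = key.strip().split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(raw)

    def validate(self) -> None:
        if self.data["imaging"]["frequency_hz"] <= 0:
            raise ValueError("imaging.frequency_hz must be > 0")
        if self.data["cohort"]["spacing_mm"] <= 0:
            raise ValueError("cohort.spacing_mm must be > 0")
        if not (0 <= self.data["cohort"]["stress"] <= 1):
            raise ValueError("cohort.stress must be in [0, 1]")

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=False)
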