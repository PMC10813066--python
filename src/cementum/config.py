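"""Pipeline configuration: one layered key-value (YAML) file, CLI overridable.

Every threshold the source scoring guidelines leave qualitative lives here
with its default, so a study can tighten or recalibrate without touching
code.  Unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # thickness mapping
    pref_ratio: float = 1.5            # side-mean max/min ratio => preferential
    min_ratio: float = 1.5             # ratio needed to report a thinnest side
    report_fraction: float = 0.85      # cell-mean fraction reported in LOC MAX
    prominence_um: float = 300.0       # shape component prominence over median
    spike_threshold_um: float = 75.0   # LSP spike residual
    # composite hypercementosis score
    baseline_um: float = 500.0         # per-third mean above this => affected
    marked_um: float = 1500.0          # MAX THI at or above this => marked (M)
    # topography
    pixel_um: float = 0.65
    highpass_cutoff_um: float = 4.0    # roughness band high-pass
    rough_rms_um: float = 5.0          # RMS above this => rough (R)
    peak_density_cut: float = 0.5      # relief peaks per (100 um)^2 => frequent (1)
    # published-tree cut points
    max_thi_cut_um: float = 1295.0
    max_ve_cut_um: float = 190.0
    # misc
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("seed", "verbosity"):
                continue
            if not isinstance(v, (int, float)) or v <= 0:
                raise ValueError(f"config key {f.name} must be positive, got {v!r}")

    @classmethod
    def load(cls, path=None, **overrides) -> "PipelineConfig":
        data = {}
        if path is not None:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
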