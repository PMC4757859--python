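"""Declarative YAML configuration.

One file can override reaction defaults, primer parameters, the assembly
minimum overlap, screening settings and the enzyme-panel table; CLI flags
override file values, which override the built-in protocol constants.

Example::

    reaction:
      backbone_mass: 150
      confidence: 0.995
    primers:
      tm_target: 60
    assembly:
      min_overlap: 25
    screening:
      tolerance: 0.08
      read_length: 800
    enzymes: /path/to/extra_enzymes.tsv
    efficiency:
      2: 0.8
      4: 0.65
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .digest import EnzymeSpec, load_enzyme_panel
from .errors import GmapError
from .primers import PrimerParams
from .reaction import EfficiencyTable, ReactionDefaults


@dataclass
class Config:
    reaction: ReactionDefaults = field(default_factory=ReactionDefaults)
    primers: PrimerParams = field(default_factory=PrimerParams)
    min_overlap: int = 30
    tolerance: float = 0.10
    read_length: int = 700
    enzyme_panel: dict[str, EnzymeSpec] = field(default_factory=load_enzyme_panel)
    efficiency: EfficiencyTable | None = None


def load_config(path: str | Path | None = None) -> Config:
    """Build a Config from an optional YAML file."""
    cfg = Config()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise GmapError(f"config {path} must be a mapping, got {type(data).__name__}")
    if "reaction" in data:
        cfg.reaction = ReactionDefaults(**data["reaction"])
    if "primers" in data:
        cfg.primers = PrimerParams(**data["primers"])
    assembly = data.get("assembly", {})
    cfg.min_overlap = int(assembly.get("min_overlap", cfg.min_overlap))
    screening = data.get("screening", {})
    cfg.tolerance = float(screening.get("tolerance", cfg.tolerance))
    cfg.read_length = int(screening.get("read_length", cfg.read_length))
    if "enzymes" in data:
        extra = load_enzyme_panel(data["enzymes"])
        cfg.enzyme_panel = {**cfg.enzyme_panel, **extra}
    if "efficiency" in data:
        cfg.efficiency = EfficiencyTable(
            {int(k): float(v) for k, v in data["efficiency"].items()}
        )
    return cfg
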