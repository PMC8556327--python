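"""Run configuration: validated parameter sets for the CLI pipelines."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .energetics import DEFAULT_DG_DISS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Unknown keys in a config file are rejected outright rather than ignored,
    so a typo cannot silently fall back to a default.
    """

    structure: str | None = None
    scans: str | None = None
    out_dir: str = "results"
    seed: int = 0
    verbosity: int = 1
    pairing: str = "by_contact"
    bend_anchors: tuple[int, int, int] = (70, 30, 70)
    adjacent_anchors: tuple[int, int, int] = (70, 69, 69)
    chromophore_names: tuple[str, ...] = ("CYC", "PCB", "BLA")
    max_thioether: float = 2.5
    sasa_probe: float = 1.4
    sasa_points: int = 960
    dg_diss: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DG_DISS))
    buffer_rho: float = 1.00980
    buffer_eta: float = 0.01029
    vbar: float = 0.73149
    temperature: float = 293.15
    rotor_speed: float = 60000.0
    s_min: float = 1.0
    s_max: float = 15.0
    s_points: int = 100
    f_ratio: str | float = 1.2
    lambda_reg: float = 0.02

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("sasa_probe", "max_thioether", "buffer_rho", "buffer_eta",
                     "vbar", "temperature", "rotor_speed", "lambda_reg"):
            if float(getattr(self, name)) <= 0 and name != "lambda_reg":
                raise ValueError(f"{name} must be positive")
        if self.s_min <= 0 or self.s_max <= self.s_min or self.s_points < 3:
            raise ValueError("s-grid must satisfy 0 < s_min < s_max, >= 3 points")
        self.bend_anchors = tuple(int(x) for x in self.bend_anchors)
        self.adjacent_anchors = tuple(int(x) for x in self.adjacent_anchors)
        self.chromophore_names = tuple(self.chromophore_names)
        self.dg_diss = {int(k): float(v) for k, v in self.dg_diss.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)
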