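"""Run configuration: YAML-backed defaults for the command-line interface.

A run configuration collects the knobs shared by the CLI subcommands
(geometry, drive-field amplitudes in gauss, sweep, seed, output directory).
It validates strictly — unknown keys are rejected with a schema report — and
hashes canonically so outputs can embed a provenance block sufficient to
regenerate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults applied to CLI subcommands (explicit flags win).

    Field amplitudes are given in gauss here (the unit used at the bench)
    and converted to tesla at the library boundary.
    """

    shape: str = "C"
    seed: int = 0
    bx_gauss: float = 30.0
    bz_gauss: float = 35.0
    species: str = "monomer"
    sweep: str = "2:60:2"
    grid_step_um: float = 0.1
    cell_size_um: float = 0.5
    frequency_hz: float = 10.0
    n: int = 200
    dimer_fraction: float = 0.3
    stick_prob: float = 0.0
    out: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if self.shape not in ("C", "S", "T", "R"):
            raise ValueError(f"shape must be one of C, S, T, R; got {self.shape!r}")
        if self.species not in ("monomer", "dimer"):
            raise ValueError("species must be 'monomer' or 'dimer'")
        if self.bx_gauss < 0 or self.bz_gauss < 0:
            raise ValueError("field amplitudes must be >= 0")
        if not 0.0 <= self.dimer_fraction <= 1.0 or not 0.0 <= self.stick_prob <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(
                f"unknown config keys {unknown}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]

    def default_map(self) -> dict:
        """click-style default map: per-subcommand defaults from this config."""
        d = asdict(self)
        common = {k: d[k] for k in ("shape", "seed", "bx_gauss", "bz_gauss", "out")}
        return {
            "landscape": {**common, "grid_step_um": d["grid_step_um"],
                          "cell_size_um": d["cell_size_um"]},
            "profile": {**common, "species": d["species"], "sweep": d["sweep"]},
            "simulate": {**common, "species": d["species"],
                         "frequency_hz": d["frequency_hz"]},
            "characteristics": {**common, "species": d["species"], "sweep": d["sweep"]},
            "separate": {**common, "n": d["n"], "dimer_fraction": d["dimer_fraction"],
                         "stick_prob": d["stick_prob"]},
            "assay-stats": {"seed": d["seed"], "out": d["out"]},
        }
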