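"""Run configuration: caller thresholds, simulation settings, cohort sizes.

Loaded from YAML for the command-line interface; every field has the
package default so an empty file is a valid configuration.  A single
top-level seed fans out to per-stage seeds by fixed offsets so each stage
is individually reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort_stats import CohortSpec
from .dipdetector import DetectorConfig
from .synthetic_traces import SimulationConfig

_STAGE_OFFSETS = {"simulate": 0, "detect": 101, "somatic": 202, "stats": 303}
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_cases: int = 10
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSETS[stage]) % _SEED_MOD

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {"seed", "n_cases", "detector", "simulation", "cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        seed = int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("simulation", {}))
        sim_kwargs.setdefault("seed", seed)
        return cls(
            seed=seed,
            n_cases=int(raw.get("n_cases", 10)),
            detector=DetectorConfig(**raw.get("detector", {})),
            simulation=SimulationConfig(**sim_kwargs),
            cohort=CohortSpec(**raw.get("cohort", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
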