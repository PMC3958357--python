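"""Run configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationDesign

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters in one serializable bundle."""

    seed: int = 0
    # GIMME
    gamma: float = 0.75
    alpha: float = 0.05
    rules_needed: int = 2
    standardize: bool = False
    # threshold scan
    scan_runs: int = 100
    # robustness
    robustness_levels_step: float = 0.025
    robustness_reps: int = 100
    detection_runs: int = 100
    run_robustness: bool = True
    # scrubbing
    fd_threshold: float = 0.2
    # subgroup comparison
    comparison_alpha: float = 0.05
    fdr_method: str = "storey"
    # inputs: either a directory of time-series files or a simulation design
    input_dir: str | None = None
    design: SimulationDesign | None = field(default_factory=SimulationDesign)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.design is not None:
            dd = asdict(self.design)
            dd["group_paths"] = [list(pq) for pq in dd["group_paths"]]
            dd["unique_paths"] = [list(pq) for pq in dd["unique_paths"]]
            dd["subgroup_deviations"] = [
                [[list(pq), s] for pq, s in dev]
                for dev in dd["subgroup_deviations"]
            ]
            d["design"] = dd
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = d.pop("design", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__},
                  design=None)
        if design is not None:
            design = dict(design)
            if "group_paths" in design:
                design["group_paths"] = [tuple(pq) for pq in design["group_paths"]]
            if "unique_paths" in design:
                design["unique_paths"] = [tuple(pq) for pq in design["unique_paths"]]
            if design.get("subgroup_deviations") is not None:
                design["subgroup_deviations"] = [
                    [(tuple(pq), int(s)) for pq, s in dev]
                    for dev in design["subgroup_deviations"]
                ]
            cfg.design = SimulationDesign(**design)
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
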