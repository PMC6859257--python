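"""Run configuration: serializable settings for the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitting import FitConfig
from .postprocessing import FilterSpec

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a screen run needs, round-trippable through YAML/JSON.

    ``times``, ``populations`` and ``prototypes`` are optional subsets;
    ``None`` means the full grid (all database time points, the seven
    canonical populations, all six prototypes).
    """

    input: str = ""
    output_dir: str = "pairscreen_out"
    fit: FitConfig = field(default_factory=FitConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    times: tuple[int, ...] | None = None
    populations: tuple[str, ...] | None = None
    prototypes: tuple[str, ...] | None = None
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("times", "populations", "prototypes"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fit" in d and not isinstance(d["fit"], FitConfig):
            d["fit"] = FitConfig(**d["fit"])
        if "filter" in d and not isinstance(d["filter"], FilterSpec):
            d["filter"] = FilterSpec(**d["filter"])
        if d.get("times") is not None:
            d["times"] = tuple(int(t) for t in d["times"])
        for k in ("populations", "prototypes"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    """Read YAML (JSON is a YAML subset, so both work)."""
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
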