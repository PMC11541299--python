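"""Study configuration: the machine twin of the factorial design table."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .grm import ItemParameters, default_item_parameters, load_item_parameters
from .simulate import FACTOR_LEVELS, DesignPoint, build_design_grid
from .evaluate import METHODS

__all__ = ["StudyConfig", "load_config"]

_TOP_KEYS = {
    "grid", "replicates", "n", "master_seed", "item_parameters",
    "methods", "out_dir", "conversion_n", "tr_reliability", "lirt",
}
_LIRT_KEYS = {"n_quad", "tol", "max_cycles", "grid_span"}


@dataclass
class StudyConfig:
    grid: dict = field(default_factory=dict)       # factor -> allowed levels
    replicates: int = 5
    n: int = 2000
    master_seed: int = 0
    item_parameters: str = "default"
    methods: tuple = ("mc", "roc", "pm", "apm")
    out_dir: str = "study-out"
    conversion_n: int = 500_000
    tr_reliability: str | float = "estimate"
    lirt: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for factor, values in self.grid.items():
            if factor not in FACTOR_LEVELS:
                raise ValueError(
                    f"unknown design factor {factor!r}; "
                    f"expected one of {sorted(FACTOR_LEVELS)}"
                )
            allowed = FACTOR_LEVELS[factor]
            for v in values:
                if not any(np.isclose(v, a) for a in allowed):
                    raise ValueError(
                        f"{factor}={v!r} not allowed; valid levels: {allowed}"
                    )
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
        bad = set(self.lirt) - _LIRT_KEYS
        if bad:
            raise ValueError(f"unknown lirt option(s): {sorted(bad)}")
        if not isinstance(self.tr_reliability, str):
            if not 0.0 < float(self.tr_reliability) <= 1.0:
                raise ValueError("tr_reliability must be in (0, 1]")
        elif self.tr_reliability not in ("estimate", "true"):
            raise ValueError("tr_reliability must be a number, 'estimate' or 'true'")

    def design_points(self) -> list[DesignPoint]:
        """The configured subset of the full grid, replicated.

        Cell indices are inherited from the full 648-cell grid so that
        per-sample seeds agree between subset and full runs.
        """
        full = build_design_grid(self.replicates)
        keep = []
        for point in full:
            ok = all(
                any(np.isclose(getattr(point, f), v) for v in values)
                for f, values in self.grid.items()
            )
            if ok:
                keep.append(point)
        return keep

    def load_item_parameters(self) -> ItemParameters:
        if self.item_parameters == "default":
            return default_item_parameters()
        return load_item_parameters(self.item_parameters)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


def load_config(path) -> StudyConfig:
    """Read and validate a YAML (or JSON) study configuration."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return StudyConfig(**raw)
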