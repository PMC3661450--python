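"""Run configuration: stimulus spec + model parameter overrides + outputs.

A run config is a YAML or JSON mapping with keys

    stimulus:  {generator: <name>, args: {...}}  or  {image: <path>}
    params:    {<ModelParams field>: value, ...}
    out:       output directory
    seed:      RNG seed

Every run writes a resolved-config snapshot (all defaults filled in) and a
plain-text log next to its artifacts, so any two runs with identical
resolved config and seed are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import stimuli
from .network import ModelParams

__all__ = ["RunConfig", "GENERATORS", "load_config", "resolve_params"]

GENERATORS = {
    "sbc": stimuli.make_sbc,
    "grating_induction": stimuli.make_grating_induction,
    "white": stimuli.make_white,
    "mach": stimuli.make_mach,
    "chevreul": stimuli.make_chevreul,
    "rossi_paradiso": stimuli.make_rossi_paradiso,
    "sine_grating": stimuli.make_sine_grating,
}


@dataclass
class RunConfig:
    stimulus: dict = field(default_factory=lambda: {"generator": "sbc", "args": {}})
    params: dict = field(default_factory=dict)
    out: str = "runs/out"
    seed: int = 0

    def make_stimulus(self):
        if "image" in self.stimulus:
            from .io import read_image

            return read_image(self.stimulus["image"])
        name = self.stimulus.get("generator")
        if name not in GENERATORS:
            raise KeyError(
                f"unknown generator {name!r}; choose from {sorted(GENERATORS)}"
            )
        args = dict(self.stimulus.get("args", {}))
        # YAML lists for tuple-valued arguments
        for k, v in args.items():
            if isinstance(v, list):
                args[k] = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        return GENERATORS[name](**args)

    def model_params(self) -> ModelParams:
        return resolve_params(self.params, seed=self.seed)

    def snapshot(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        resolved = {
            "stimulus": self.stimulus,
            "params": self.model_params().to_dict(),
            "out": str(self.out),
            "seed": self.seed,
        }
        path = directory / "resolved_config.json"
        path.write_text(json.dumps(resolved, indent=2))
        return path


def resolve_params(overrides: dict | None = None, seed: int | None = None) -> ModelParams:
    p = ModelParams()
    if overrides:
        fixed = dict(overrides)
        for key in ("gy_slopes", "psi"):
            if key in fixed and isinstance(fixed[key], list):
                fixed[key] = tuple(fixed[key])
        p = replace(p, **fixed)
    if seed is not None:
        p = replace(p, seed=seed)
    return p


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw[k] for k in ("stimulus", "params", "out", "seed") if k in raw}
    return RunConfig(**known)
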