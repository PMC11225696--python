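"""Single-file YAML configuration covering all module configs.

Every random element derives from one master seed.  Example::

    seed: 7
    burn_in: {mode: fixed}
    gp: {length_scale: 0.5, n_restarts: 2}
    acquisition: {xi: 0.1, tie_break: lowest-index}
    preprocess: {validity_threshold: 0.16}
    infant:
      surface: {family: corner-peak, peak: Angry-0, contrast: 6.0,
                baseline_depth: -4.0}
      noise_sd: 10.0
      artifact_prob: 0.05
      flat_prob: 0.02
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bo, preproc, synth
from .stimspace import ANGRY_0, StimulusCoord


@dataclass
class RunConfig:
    seed: int = 0
    burn_in_mode: str = "fixed"
    gp: bo.GPConfig = field(default_factory=bo.GPConfig)
    acquisition: bo.AcquisitionConfig = field(default_factory=bo.AcquisitionConfig)
    preprocess: preproc.PreprocessConfig = field(
        default_factory=preproc.PreprocessConfig
    )
    infant_kwargs: dict = field(default_factory=dict)
    surface_kwargs: dict = field(
        default_factory=lambda: {
            "family": "corner-peak",
            "peak_coord": ANGRY_0,
            "contrast": 6.0,
            "baseline_depth": -4.0,
        }
    )

    def make_profile(self, seed: int | None = None) -> synth.InfantProfile:
        surface = synth.make_surface(**self.surface_kwargs)
        return synth.InfantProfile(
            surface=surface, seed=self.seed if seed is None else seed,
            **self.infant_kwargs,
        )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(seed=int(raw.get("seed", 0)))
    if "burn_in" in raw:
        cfg.burn_in_mode = raw["burn_in"].get("mode", "fixed")
    if "gp" in raw:
        cfg.gp = bo.GPConfig(seed=cfg.seed, **raw["gp"])
    else:
        cfg.gp = bo.GPConfig(seed=cfg.seed)
    if "acquisition" in raw:
        cfg.acquisition = bo.AcquisitionConfig(seed=cfg.seed, **raw["acquisition"])
    else:
        cfg.acquisition = bo.AcquisitionConfig(seed=cfg.seed)
    if "preprocess" in raw:
        cfg.preprocess = preproc.PreprocessConfig(**raw["preprocess"])
    infant = dict(raw.get("infant", {}))
    surface = infant.pop("surface", None)
    if surface is not None:
        surface = dict(surface)
        peak = surface.pop("peak", None)
        if peak is not None:
            surface["peak_coord"] = StimulusCoord.from_label(peak)
        cfg.surface_kwargs = surface
    cfg.infant_kwargs = infant
    return cfg
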