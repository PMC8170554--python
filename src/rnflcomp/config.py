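"""Run configuration and seeded reproducibility.

A single JSON config drives the whole pipeline; unknown keys are
rejected so typos fail loudly.  One global seed fans out to per-stage
child seeds derived stably from the stage name, so any stage can be
rerun in isolation and still agree with the end-to-end run.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .simulate import EffectSizes, ProfileTemplate

__all__ = ["RunConfig", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All defaults of the pipeline, overridable from a JSON file."""

    P: int = 768
    seed: int = 0
    n_train: int = 2223
    n_val_normal: int = 254
    n_val_glaucoma: int = 254
    min_quality: float = 15.0
    template: dict = field(default_factory=dict)   # ProfileTemplate overrides
    effects: dict = field(default_factory=dict)    # EffectSizes overrides
    age: dict = field(default_factory=dict)        # AgeCompensator kwargs
    fcn: dict = field(default_factory=dict)        # ScaleShiftCompensator kwargs
    rbfn: dict = field(default_factory=dict)       # ResidualCompensator kwargs
    limit_method: str = "empirical_p5"
    detection_threshold: int = 10
    subgroup_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 1.0)

    _NESTED_FIELDS = {
        "template": [f.name for f in dataclasses.fields(ProfileTemplate)],
        "effects": [f.name for f in dataclasses.fields(EffectSizes)],
        "age": ["reference_age", "smoothing_lambda", "check_labels"],
        "fcn": [
            "hidden_layer_sizes",
            "learning_rate",
            "max_iter",
            "mean_penalty",
            "weight_decay",
            "s_max",
            "delta_max",
            "tol",
            "random_state",
        ],
        "rbfn": [
            "n_covariate_centers",
            "n_angular_centers",
            "angular_width_factor",
            "ridge",
            "random_state",
        ],
    }

    def __post_init__(self):
        if self.P < 4:
            raise ConfigurationError("P must be >= 4")
        self.subgroup_fractions = tuple(self.subgroup_fractions)
        for name, allowed in self._NESTED_FIELDS.items():
            unknown = set(getattr(self, name)) - set(allowed)
            if unknown:
                raise ConfigurationError(
                    f"unknown key(s) in {name!r}: {sorted(unknown)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroup_fractions"] = list(self.subgroup_fractions)
        return d

    def make_template(self) -> ProfileTemplate:
        tpl = dict(self.template)
        for key in ("peak_amplitudes", "peak_angles", "peak_widths"):
            if key in tpl:
                tpl[key] = tuple(tpl[key])
        return ProfileTemplate(**tpl)

    def make_effects(self) -> EffectSizes:
        return EffectSizes(**self.effects)
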