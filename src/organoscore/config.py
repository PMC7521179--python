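"""Run configuration: YAML file with flag overrides.

Recognized keys::

    scoring.rect_fraction  scoring.alpha  scoring.beta  scoring.pixel_threshold
    io.channel             io.pattern
    calibration.quantile_level
    analytics.split_axis   analytics.split_boundary
    seed

Every default is overridable; unknown keys are rejected so typos surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .plate_io import DEFAULT_PATTERN, ValidationError
from .scoring import ScoringParams

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "scoring": {"rect_fraction", "alpha", "beta", "pixel_threshold"},
    "io": {"channel", "pattern"},
    "calibration": {"quantile_level"},
    "analytics": {"split_axis", "split_boundary"},
}


@dataclass
class RunConfig:
    scoring: ScoringParams = field(default_factory=ScoringParams)
    channel: str = "green"
    pattern: str = DEFAULT_PATTERN
    quantile_level: float = 0.95
    split_axis: str = "column"
    split_boundary: int | None = None
    seed: int = 0

    def describe(self) -> str:
        return (
            f"scoring(rect_fraction={self.scoring.rect_fraction}, "
            f"alpha={self.scoring.alpha}, beta={self.scoring.beta}, "
            f"pixel_threshold={self.scoring.pixel_threshold}) "
            f"io(channel={self.channel!r}, pattern={self.pattern!r}) "
            f"calibration(quantile_level={self.quantile_level}) "
            f"analytics(split_axis={self.split_axis!r}, "
            f"split_boundary={self.split_boundary}) seed={self.seed}"
        )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Overrides use the flat names of :class:`RunConfig` fields (plus the
    four scoring parameter names) and win over the file.  ``None``
    overrides are ignored so CLI flags can default to "unset".
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config root must be a mapping: {path}")
        data = loaded

    flat: dict = {}
    for section, keys in _SECTIONS.items():
        sub = data.get(section, {}) or {}
        if not isinstance(sub, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        unknown = set(sub) - keys
        if unknown:
            raise ValidationError(f"unknown keys in {section!r}: {sorted(unknown)}")
        flat.update(sub)
    unknown_top = set(data) - set(_SECTIONS) - {"seed"}
    if unknown_top:
        raise ValidationError(f"unknown config sections: {sorted(unknown_top)}")
    if "seed" in data:
        flat["seed"] = data["seed"]

    for key, value in overrides.items():
        if value is not None:
            flat[key] = value

    scoring_kwargs = {
        k: flat.pop(k)
        for k in ("rect_fraction", "alpha", "beta", "pixel_threshold")
        if k in flat
    }
    cfg = RunConfig(scoring=ScoringParams(**scoring_kwargs))
    for key, value in flat.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown config key: {key}")
        setattr(cfg, key, value)
    return cfg
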