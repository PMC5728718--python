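"""Pipeline configuration: defaults, YAML round-trip, and validation.

Defaults mirror the acquisition and quantification parameters the
analyses assume: a 2 μm sliding window for extrema detection, 40 nm
serial sections, a 100 nm DP search radius for docked vesicles, and a
five-pulse 20 Hz (50 ms interpulse) stimulus train.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "DEFAULT_CUTOFF_PCT", "PRESETS"]

#: Default punctate/diffuse enrichment cutoff, % ΔF/F.  Calibrated once as
#: the midpoint between the mean enrichment of the punctate
#: (diffuse_fraction 0) and diffuse (diffuse_fraction 0.9) synthetic
#: generators at their default study conditions (scripts/calibrate_cutoff.py).
DEFAULT_CUTOFF_PCT = 287.2


@dataclass
class LinescanConfig:
    window_um: float = 2.0
    puncta_threshold: str = "mean+2sd"
    cutoff_pct: float = DEFAULT_CUTOFF_PCT


@dataclass
class EMConfig:
    flank_sections: int = 1
    contact_tolerance_nm: float = 0.0
    dp_radius_nm: float = 100.0
    section_thickness_nm: float = 40.0


@dataclass
class EphysConfig:
    k_mad: float = 3.5
    baseline_window_s: float = 0.5
    refractory_s: float = 0.005
    polarity: str = "negative"
    smooth_ms: float = 3.0
    min_above_ms: float = 3.0
    interpulse_interval_s: float = 0.05
    n_pulses: int = 5


@dataclass
class PipelineConfig:
    """Versioned configuration for all pipeline stages."""

    schema_version: int = 1
    seed: int = 0
    linescan: LinescanConfig = field(default_factory=LinescanConfig)
    em: EMConfig = field(default_factory=EMConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.linescan.window_um <= 0:
            raise ValueError("linescan.window_um must be > 0")
        if self.linescan.cutoff_pct <= 0:
            raise ValueError("linescan.cutoff_pct must be > 0")
        if self.em.flank_sections < 0 or self.em.dp_radius_nm <= 0:
            raise ValueError("em parameters out of range")
        if self.em.section_thickness_nm <= 0 or self.em.contact_tolerance_nm < 0:
            raise ValueError("em parameters out of range")
        if self.ephys.k_mad <= 0 or self.ephys.baseline_window_s <= 0:
            raise ValueError("ephys parameters out of range")
        if self.ephys.polarity not in ("negative", "positive"):
            raise ValueError("ephys.polarity must be 'negative' or 'positive'")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        out = {}
        sub = {"linescan": LinescanConfig, "em": EMConfig, "ephys": EphysConfig}
        for name, klass in sub.items():
            block = data.pop(name, {})
            known = {f.name for f in fields(klass)}
            unknown = set(block) - known
            if unknown:
                raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
            out[name] = klass(**block)
        known = {f.name for f in fields(cls)} - set(sub)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data, **out)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _preset(**overrides) -> PipelineConfig:
    cfg = PipelineConfig()
    for dotted, v in overrides.items():
        section, key = dotted.split(".")
        setattr(getattr(cfg, section), key, v)
    cfg.validate()
    return cfg


#: Named analysis presets bundling the relevant defaults.
PRESETS = {
    "linescan_enrichment": _preset(),
    "em_morphometry": _preset(),
    "mini_analysis": _preset(),
    "evoked_train": _preset(),
}
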