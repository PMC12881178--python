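"""Analysis configuration: every filtering threshold and numeric rule in one place.

All thresholds default to the trial protocol values (FGM valid day strictly
> 70% coverage; activPAL valid day >= 10 h wear, >= 500 steps, < 95% of wear
in a single activity; MVPA cadence cut-point 100 steps/min) so a run is
auditable from a single object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import time

import yaml


@dataclass
class FgmConfig:
    epoch_minutes: int = 15
    dedup: str = "keep-first"          # {"keep-first", "mean", "error"}
    unit: str = "mmol_l"               # {"mmol_l", "mg_dl"} — mg/dL is converted on read
    sensor_min: float = 1.1            # physical sensor range, mmol/L
    sensor_max: float = 27.8
    out_of_range: str = "drop"         # {"drop", "error"}

    def __post_init__(self) -> None:
        if self.dedup not in {"keep-first", "mean", "error"}:
            raise ValueError(f"unknown dedup rule {self.dedup!r}")
        if self.unit not in {"mmol_l", "mg_dl"}:
            raise ValueError(f"unknown glucose unit {self.unit!r}")
        if self.out_of_range not in {"drop", "error"}:
            raise ValueError(f"unknown out_of_range rule {self.out_of_range!r}")


@dataclass
class ActivpalConfig:
    nonwear_gap_s: float = 0.0         # gaps longer than this become non-wear
    overlap_tolerance_s: float = 0.5


@dataclass
class ValidityConfig:
    fgm_coverage_min: float = 0.70     # strict: coverage must EXCEED this
    wear_min_h: float = 10.0           # inclusive
    steps_min: float = 500.0           # inclusive
    single_activity_max: float = 0.95  # strict: fraction must stay BELOW this

    def __post_init__(self) -> None:
        for name in ("fgm_coverage_min", "single_activity_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")


@dataclass
class WakingConfig:
    min_sleep_hours: float = 3.0
    anchor_start: time = time(22, 0)   # nocturnal anchor window 22:00–10:00
    anchor_end: time = time(10, 0)
    fallback_wake: time = time(7, 0)
    fallback_sleep: time = time(23, 0)
    normalise_hours: float = 16.0


@dataclass
class GlucoseMetricConfig:
    tir_low: float = 3.9               # time-in-range band, mmol/L
    tir_high: float = 10.0
    tbr: float = 3.0                   # hypoglycaemia cut
    max_gap_min: float = 60.0          # longest gap bridged linearly in AUC
    meal_window_h: float = 2.0
    baseline_lookback_min: float = 60.0
    cv_as_percent: bool = False        # tables print CV as a fraction (0.2)


@dataclass
class ActivityMetricConfig:
    mvpa_cadence: float = 100.0        # steps/min; >= is moderate-to-vigorous


@dataclass
class AnalysisConfig:
    fgm: FgmConfig = field(default_factory=FgmConfig)
    activpal: ActivpalConfig = field(default_factory=ActivpalConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    waking: WakingConfig = field(default_factory=WakingConfig)
    glucose: GlucoseMetricConfig = field(default_factory=GlucoseMetricConfig)
    activity: ActivityMetricConfig = field(default_factory=ActivityMetricConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("anchor_start", "anchor_end", "fallback_wake", "fallback_sleep"):
            d["waking"][k] = d["waking"][k].isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        w = dict(d.get("waking", {}))
        for k in ("anchor_start", "anchor_end", "fallback_wake", "fallback_sleep"):
            if k in w and isinstance(w[k], str):
                w[k] = time.fromisoformat(w[k])
        kwargs = {}
        for name, sub in (
            ("fgm", FgmConfig), ("activpal", ActivpalConfig),
            ("validity", ValidityConfig), ("waking", WakingConfig),
            ("glucose", GlucoseMetricConfig), ("activity", ActivityMetricConfig),
        ):
            src = w if name == "waking" else d.get(name, {})
            kwargs[name] = sub(**src)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
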