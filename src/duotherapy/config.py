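"""Configuration objects for every pipeline stage.

Each stage owns a small frozen-ish dataclass validated on construction.
:class:`RunConfig` bundles them, resolves sensitivity variants as pure
parameter overrides (never separate code paths), and can be loaded from
a YAML file for the CLI.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .dates import to_day
from .errors import ConfigError

#: The five antihypertensive drug classes under study.
DRUG_CLASSES = ("ACEi", "ARB", "CCB", "TZD", "BB")

#: Initial two-class regimens considered valid combinations.
DUO_PAIRS = (
    ("ACEi", "CCB"), ("ACEi", "TZD"), ("ACEi", "BB"),
    ("ARB", "CCB"), ("ARB", "TZD"), ("ARB", "BB"),
    ("CCB", "TZD"), ("CCB", "BB"), ("TZD", "BB"),
)

SENSITIVITY_VARIANTS = ("gap90", "overlap60", "washout365")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic EHR generator.

    ``true_log_hr_bp_control`` / ``true_log_hr_mace`` are the conditional
    (covariate-level) log hazard ratios of two-drug vs monotherapy
    initiation. ``confounding_strength`` scales the covariate effects
    shared between the treatment-assignment and outcome models; 0 turns
    confounding off entirely. ``duo_target_fraction`` is the marginal
    share of two-drug initiators the assignment intercept is calibrated
    to. Distributional defaults are documented in docs/methods.md.
    """

    n_patients: int = 20_000
    study_start: int | str = "2006-01-01"
    study_end: int | str = "2014-12-31"
    followup_hard_end: int | str = "2016-02-29"
    true_log_hr_bp_control: float = 0.157  # ln(1.17)
    true_log_hr_mace: float = 0.0
    confounding_strength: float = 1.0
    unmeasured_confounding: float = 0.0
    duo_target_fraction: float = 0.06
    visit_rate: float = 8.0  # BP visits per year after the index date
    supply_days_distribution: Mapping = field(
        default_factory=lambda: {"values": (28, 56, 84), "probs": (0.7, 0.2, 0.1)}
    )
    refill_gap_distribution: Mapping = field(
        default_factory=lambda: {
            "mean": 2.0, "sd": 8.0, "p_long": 0.04, "long_min": 61, "long_max": 120,
        }
    )
    # Per-month hazards of the competing regimen transitions. ``switch``
    # replaces one class by another (not a regimen change: count unchanged).
    regimen_change_hazards: Mapping = field(
        default_factory=lambda: {"add": 0.035, "remove": 0.04,
                                 "discontinue": 0.045, "switch": 0.02}
    )
    change_time_weibull_shape: float = 0.45
    #: After the first regimen change the BP-control hazard contrast between
    #: arms is removed (both arms share one post-change hazard).
    equalize_post_change: bool = True
    p_restart_after_discontinuation: float = 0.3
    # Outcome model baselines (per month at covariate mean).
    bp_control_rate: float = 0.075
    mi_rate: float = 0.00045
    stroke_rate: float = 0.00045
    cv_death_rate: float = 0.0003
    noncv_death_rate: float = 0.0011
    p_fatal_mi: float = 0.15
    p_fatal_stroke: float = 0.20
    # Eligibility-noise fractions (exercise the attrition cascade).
    p_short_history: float = 0.03
    p_no_recent_bp: float = 0.04
    p_secondary_hypertension: float = 0.01
    p_heart_failure: float = 0.02
    p_recent_prior_rx: float = 0.08
    p_triple_index: float = 0.01
    # Direct survival-benchmark mode.
    benchmark_event_rate: float = 0.06  # per month
    benchmark_censor_rate: float = 0.01  # per month; 0 disables random censoring
    benchmark_admin_censor_months: float | None = 36.0
    seed: int = 0

    def __post_init__(self):
        self.study_start = to_day(self.study_start)
        self.study_end = to_day(self.study_end)
        self.followup_hard_end = to_day(self.followup_hard_end)
        _require(self.n_patients > 0, "n_patients must be positive")
        _require(self.study_start < self.study_end, "empty study window")
        _require(self.study_end < self.followup_hard_end,
                 "study window must end before the hard follow-up end")
        _require(0.0 < self.duo_target_fraction < 1.0,
                 "duo_target_fraction must lie in (0, 1)")
        _require(self.confounding_strength >= 0, "confounding_strength < 0")
        _require(self.visit_rate > 0, "visit_rate must be positive")
        for name in ("bp_control_rate", "mi_rate", "stroke_rate", "cv_death_rate",
                     "noncv_death_rate", "benchmark_event_rate",
                     "benchmark_censor_rate"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(all(v >= 0 for v in self.regimen_change_hazards.values()),
                 "regimen change hazards must be nonnegative")
        _require(sum(self.regimen_change_hazards.values()) > 0,
                 "at least one regimen-change hazard must be positive")
        sd = self.supply_days_distribution
        _require(len(sd["values"]) == len(sd["probs"]), "supply distribution shape")
        _require(abs(sum(sd["probs"]) - 1.0) < 1e-9, "supply probs must sum to 1")
        _require(all(v >= 1 for v in sd["values"]), "supply_days must be >= 1")
        _require(self.change_time_weibull_shape > 0, "Weibull shape must be > 0")
        for p in ("p_fatal_mi", "p_fatal_stroke", "p_short_history",
                  "p_no_recent_bp", "p_secondary_hypertension", "p_heart_failure",
                  "p_recent_prior_rx", "p_triple_index",
                  "p_restart_after_discontinuation"):
            _require(0 <= getattr(self, p) <= 1, f"{p} must lie in [0, 1]")


@dataclass
class EligibilityConfig:
    """Eligibility-cascade thresholds (all durations in days)."""

    washout_days: int = 183
    min_history_days: int = 365
    elevated_bp_lookback_days: int = 92
    repeated_bp_lookback_days: int = 365
    min_repeated_elevated: int = 2
    mi_stroke_exclusion_days: int = 365
    #: Whether a TIA in the exclusion window is also exclusionary.
    tia_exclusion: bool = False
    study_start: int | str = "2006-01-01"
    study_end: int | str = "2014-12-31"
    followup_hard_end: int | str = "2016-02-29"

    def __post_init__(self):
        self.study_start = to_day(self.study_start)
        self.study_end = to_day(self.study_end)
        self.followup_hard_end = to_day(self.followup_hard_end)
        for name in ("washout_days", "min_history_days",
                     "elevated_bp_lookback_days", "repeated_bp_lookback_days",
                     "mi_stroke_exclusion_days"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.min_repeated_elevated >= 1, "min_repeated_elevated >= 1")
        _require(self.study_end < self.followup_hard_end,
                 "study window must end before followup_hard_end")


@dataclass
class EpisodeConfig:
    """Treatment-episode construction thresholds."""

    discontinuation_gap_days: int = 60
    min_concomitant_overlap_days: int = 30

    def __post_init__(self):
        _require(self.discontinuation_gap_days > 0, "gap must be positive")
        _require(self.min_concomitant_overlap_days > 0, "overlap must be positive")
        _require(self.min_concomitant_overlap_days <= self.discontinuation_gap_days,
                 "overlap threshold must not exceed the discontinuation gap")


@dataclass
class MatchSpec:
    """Greedy caliper-matching parameters.

    The caliper is ``caliper_multiplier`` times the SD of logit(PS)
    computed on the pooled cohort. Matching runs as ``ratio`` sequential
    1:1 passes; treated subjects are processed in descending logit order
    with ties broken by a seeded shuffle.
    """

    ratio: int = 2
    caliper_multiplier: float = 0.2
    replacement: bool = False
    order_rule: str = "logit_desc"
    seed: int = 0

    def __post_init__(self):
        _require(self.ratio >= 1, "ratio must be >= 1")
        _require(self.caliper_multiplier > 0, "caliper_multiplier must be > 0")
        _require(self.order_rule in ("logit_desc", "logit_asc", "random"),
                 f"unknown order_rule {self.order_rule!r}")
        if self.replacement:
            raise ConfigError("matching with replacement is not implemented")


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    match: MatchSpec = field(default_factory=MatchSpec)
    mode: str = "as_treated"
    subgroups: Sequence[str] = ("all",)
    variants: Sequence[str] = ()
    seed: int = 0
    outdir: str = "output"

    def __post_init__(self):
        _require(self.mode in ("as_treated", "itt"), f"unknown mode {self.mode!r}")
        for s in self.subgroups:
            _require(s in ("all", "grade1", "grade23", "acei_ccb"),
                     f"unknown subgroup {s!r}")
        for v in self.variants:
            _require(v in SENSITIVITY_VARIANTS, f"unknown variant {v!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for key, sub in (("generator", GeneratorConfig),
                         ("eligibility", EligibilityConfig),
                         ("episode", EpisodeConfig), ("match", MatchSpec)):
            if key in data:
                kwargs[key] = sub(**data.pop(key))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_variant(self, variant: str) -> "RunConfig":
        """Return a copy with one sensitivity variant's overrides applied."""
        overrides = {
            "gap90": ("episode", {"discontinuation_gap_days": 90}),
            "overlap60": ("episode", {"min_concomitant_overlap_days": 60}),
            "washout365": ("eligibility", {"washout_days": 365}),
        }
        if variant not in overrides:
            raise ConfigError(f"unknown variant {variant!r}")
        section, changes = overrides[variant]
        new = dataclasses.replace(self)
        new_section = dataclasses.replace(getattr(self, section), **changes)
        setattr(new, section, new_section)
        new.variants = ()
        return new

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("generator",):
            for mkey in ("supply_days_distribution", "refill_gap_distribution",
                         "regimen_change_hazards"):
                out[key][mkey] = {k: list(v) if isinstance(v, (tuple, list)) else v
                                  for k, v in dict(out[key][mkey]).items()}
        out["subgroups"] = list(self.subgroups)
        out["variants"] = list(self.variants)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
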