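"""Configuration objects for simulation and the end-to-end pipeline.

``SimConfig`` holds every ground-truth parameter of the synthetic claims
generator: population size, drug mix, per-class supply/refill behaviour,
piecewise-constant fracture hazards (an early-treatment baseline, then one
multiplicative rate ratio per on-treatment window) and censoring rates.  The
defaults describe the study conditions emulated by the package: women >= 50 on
seven osteoporosis treatment classes, observed 2011-2018, indexed 2013-2017.

``RunConfig`` wires a simulation block or four input CSV paths, a code map and
the stage parameters into one reproducible run (see :mod:`osteoepi.pipeline`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

DRUG_CLASSES = (
    "denosumab",
    "iv_ibandronate",
    "iv_zoledronate",
    "oral_bisphosphonate",
    "teriparatide",
    "raloxifene",
    "hrt",
)

#: Hierarchical assignment tiers, highest priority first.  Intravenous
#: bisphosphonates form one tier; the first-filled sub-class wins within it.
HIERARCHY = (
    ("denosumab",),
    ("iv_ibandronate", "iv_zoledronate"),
    ("oral_bisphosphonate",),
    ("teriparatide",),
    ("raloxifene",),
    ("hrt",),
)

#: On-treatment analysis windows (months after index) and their day bounds.
#: Closed-open [lo, hi) in days since index; "early" is the 0-3 month
#: own-control baseline window.
WINDOW_BOUNDS = (
    ("early", 0, 90),
    ("m4_12", 90, 365),
    ("m13_24", 365, 730),
    ("m25_36", 730, 1095),
    ("m37_48", 1095, 1460),
)
ON_TREATMENT_WINDOWS = ("m4_12", "m13_24", "m25_36", "m37_48")
FOLLOWUP_CAP_DAYS = 1460

_DEFAULT_DRUG_MIX = {
    "denosumab": 0.084,
    "iv_ibandronate": 0.043,
    "iv_zoledronate": 0.009,
    "oral_bisphosphonate": 0.313,
    "teriparatide": 0.001,
    "raloxifene": 0.003,
    "hrt": 0.547,
}

_DEFAULT_DAYS_SUPPLIED = {
    "denosumab": 180,
    "iv_ibandronate": 90,
    "iv_zoledronate": 365,
    "oral_bisphosphonate": 30,
    "teriparatide": 28,
    "raloxifene": 30,
    "hrt": 90,
}

# Mean extra delay (days) beyond the supplied period before the next fill.
_DEFAULT_REFILL_GAP_MEAN = {
    "denosumab": 20.0,
    "iv_ibandronate": 15.0,
    "iv_zoledronate": 30.0,
    "oral_bisphosphonate": 8.0,
    "teriparatide": 10.0,
    "raloxifene": 10.0,
    "hrt": 10.0,
}

# Per-refill-opportunity probability of stopping therapy; calibrated so that
# median persistence per class sits near real-world values (e.g. ~580 d for
# six-monthly denosumab vs ~260 d for monthly-pack oral bisphosphonates).
_DEFAULT_STOP_PROB = {
    "denosumab": 0.25,
    "iv_ibandronate": 0.18,
    "iv_zoledronate": 0.55,
    "oral_bisphosphonate": 0.095,
    "teriparatide": 0.06,
    "raloxifene": 0.18,
    "hrt": 0.45,
}

# Mean age at index per treatment class (years); HRT initiators are younger.
_DEFAULT_AGE_MEAN = {
    "denosumab": 72.8,
    "iv_ibandronate": 71.9,
    "iv_zoledronate": 69.5,
    "oral_bisphosphonate": 71.9,
    "teriparatide": 72.2,
    "raloxifene": 68.0,
    "hrt": 56.4,
}

# Baseline (early-treatment) fracture hazard per person-year, by site.
# Totals 0.0876/PY, the all-fracture baseline of a high-risk initiator cohort.
_DEFAULT_BASELINE_HAZARD = {
    "clinical_vertebral": 0.0507,
    "hip": 0.0100,
    "wrist_forearm": 0.0120,
    "humerus": 0.0050,
    "clavicle": 0.0030,
    "pelvis": 0.0040,
    "femur": 0.0029,
}

_NULL_RATIOS = {"m4_12": 1.0, "m13_24": 1.0, "m25_36": 1.0, "m37_48": 1.0}


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic claims generator."""

    n_patients: int = 1000
    seed: int = 0
    study_start: str = "2011-01-01"
    study_end: str = "2018-12-31"
    inclusion_start: str = "2013-01-01"
    inclusion_end: str = "2017-12-31"

    age_mean: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_MEAN))
    age_sd: float = 9.0
    min_age: float = 42.0

    drug_mix: dict = field(default_factory=lambda: dict(_DEFAULT_DRUG_MIX))
    days_supplied: dict = field(default_factory=lambda: dict(_DEFAULT_DAYS_SUPPLIED))
    refill_gap_mean: dict = field(default_factory=lambda: dict(_DEFAULT_REFILL_GAP_MEAN))
    persistence_stop_prob: dict = field(default_factory=lambda: dict(_DEFAULT_STOP_PROB))

    baseline_hazard: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_HAZARD))
    hazard_ratio_by_window: dict = field(default_factory=lambda: dict(_NULL_RATIOS))
    #: multiplier on the baseline hazard before the index date
    pre_index_rate_mult: float = 1.0
    #: per-year-of-age rate ratio applied relative to age at index
    age_rate_ratio_per_year: float = 1.0

    #: fraction of patients forced to carry a pre-index fracture and whose
    #: hazard is multiplied by ``prior_fracture_hazard_mult`` (for stratified
    #: scenarios; 0 disables the mechanism and prior fractures arise only from
    #: the pre-index event process)
    prior_fracture_frac: float = 0.0
    prior_fracture_hazard_mult: float = 1.0

    exclusion_prev: float = 0.16
    washout_violation_prob: float = 0.40
    short_history_prob: float = 0.08
    prior_treatment_prob: float = 0.20
    estrogen_only_frac: float = 0.25
    hysterectomy_frac: float = 0.70

    death_rate: float = 0.03
    disenroll_rate: float = 0.01

    p_inpatient: float = 0.60
    duplicate_dx_prob: float = 0.25
    noise_outpatient_prob: float = 0.05

    # ------------------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        start, end = pd.Timestamp(self.study_start), pd.Timestamp(self.study_end)
        if not start < end:
            raise ValueError("study_start must precede study_end")
        if not (start <= pd.Timestamp(self.inclusion_start)
                < pd.Timestamp(self.inclusion_end) <= end):
            raise ValueError("inclusion_start/inclusion_end must lie inside the study period")
        mix_sum = sum(self.drug_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"drug_mix must sum to 1 (got {mix_sum!r})")
        for cls, p in self.drug_mix.items():
            if cls not in DRUG_CLASSES:
                raise ValueError(f"drug_mix contains unknown class {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"drug_mix[{cls!r}] must be in [0, 1]")
        for cls in self.drug_mix:
            if self.days_supplied.get(cls, 0) <= 0:
                raise ValueError(f"days_supplied[{cls!r}] must be > 0")
            if not 0.0 <= self.persistence_stop_prob.get(cls, 0.0) <= 1.0:
                raise ValueError(f"persistence_stop_prob[{cls!r}] must be in [0, 1]")
            if self.refill_gap_mean.get(cls, 0.0) < 0:
                raise ValueError(f"refill_gap_mean[{cls!r}] must be >= 0")
        for site, rate in self.baseline_hazard.items():
            if rate < 0:
                raise ValueError(f"baseline_hazard[{site!r}] must be >= 0")
        for w, r in self.hazard_ratio_by_window.items():
            if r < 0:
                raise ValueError(f"hazard_ratio_by_window[{w!r}] must be >= 0")
        for name in ("exclusion_prev", "washout_violation_prob", "short_history_prob",
                     "prior_treatment_prob", "estrogen_only_frac", "hysterectomy_frac",
                     "p_inpatient", "duplicate_dx_prob", "noise_outpatient_prob",
                     "prior_fracture_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("death_rate", "disenroll_rate", "pre_index_rate_mult",
                     "age_rate_ratio_per_year", "prior_fracture_hazard_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        base = cls()
        for key, value in d.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown SimConfig field {key!r}")
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(base, key, value)
        return base

    # -- scenario presets ----------------------------------------------

    @classmethod
    def single_class(cls, drug_class: str, **overrides) -> "SimConfig":
        """A cohort where every patient initiates one treatment class."""
        mix = {c: 0.0 for c in DRUG_CLASSES}
        mix[drug_class] = 1.0
        cfg = cls(drug_mix=mix, **overrides)
        if drug_class != "hrt":
            cfg.estrogen_only_frac = 0.0
        return cfg

    @classmethod
    def denosumab_effect_preset(cls, **overrides) -> "SimConfig":
        """Single-class denosumab scenario with on-treatment rate ratios
        {0.62, 0.50, 0.44, 0.33} over the four on-treatment windows."""
        cfg = cls.single_class("denosumab", **overrides)
        cfg.hazard_ratio_by_window = {
            "m4_12": 0.62, "m13_24": 0.50, "m25_36": 0.44, "m37_48": 0.33,
        }
        return cfg


@dataclass
class SelectionParams:
    inclusion_start: str = "2013-01-01"
    inclusion_end: str = "2017-12-31"
    min_age: float = 50.0
    lookback_days: int = 730          # 24-month history / washout window
    min_followup_days: int = 183      # 6-month minimum follow-up flag
    admin_censor_date: str = "2018-12-31"


@dataclass
class EpisodeParams:
    gap_days: int = 60
    switch_window_days: int = 60
    #: 'supply_end' ends a discontinued episode at the expected refill date;
    #: 'grace_end' at expected refill + gap_days
    discontinuation_at: str = "supply_end"


@dataclass
class AnalysisParams:
    proc_window_days: int = 30
    ci_method: str = "auto"           # 'wald' | 'exact' | 'auto'
    small_count_threshold: int = 5
    trend_weights: str = "person_years"  # 'person_years' | 'equal'


@dataclass
class RunConfig:
    """One end-to-end run: either a simulation block or four input CSVs."""

    seed: int = 0
    output_dir: str = "osteoepi_run"
    simulate: SimConfig | None = None
    inputs: dict | None = None        # paths: enrollment/prescriptions/diagnoses/procedures
    code_map_path: str | None = None
    selection: SelectionParams = field(default_factory=SelectionParams)
    episodes: EpisodeParams = field(default_factory=EpisodeParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be provided")
        if self.inputs is not None:
            required = {"enrollment", "prescriptions", "diagnoses", "procedures"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing tables: {sorted(missing)}")
            for name, path in self.inputs.items():
                if not Path(path).exists():
                    raise ValueError(f"inputs[{name!r}] does not exist: {path}")
        if self.code_map_path is not None and not Path(self.code_map_path).exists():
            raise ValueError(f"code_map_path does not exist: {self.code_map_path}")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "osteoepi_run")),
            code_map_path=raw.get("code_map"),
        )
        if "simulate" in raw:
            cfg.simulate = SimConfig.from_dict(raw["simulate"] or {})
            cfg.simulate.seed = cfg.seed
        if "inputs" in raw:
            cfg.inputs = dict(raw["inputs"])
        for section, target in (("selection", cfg.selection),
                                ("episodes", cfg.episodes),
                                ("analysis", cfg.analysis)):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown {section} option {key!r}")
                setattr(target, key, value)
        return cfg

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "code_map": self.code_map_path,
            "selection": asdict(self.selection),
            "episodes": asdict(self.episodes),
            "analysis": asdict(self.analysis),
        }
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        return d
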