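"""Configuration objects: drug taxonomy, coverage rules, grids, simulation settings.

All calendar arithmetic in the package uses integer day offsets from a fixed
epoch (:data:`EPOCH`, 1996-01-01).  Tables on disk carry ISO-8601 dates; the
readers and writers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Day 0 of the internal calendar.
EPOCH = np.datetime64("1996-01-01")

#: Length of the trailing adherence window, in days.
YEAR_DAYS = 365

#: Average calendar-month length used for the 12 trailing month blocks.
MONTH_DAYS = 30.44


def to_day(dates) -> np.ndarray:
    """ISO date strings / datetime64 -> integer day offsets from EPOCH."""
    return (np.asarray(dates, dtype="datetime64[D]") - EPOCH).astype(np.int64)


def to_date(days) -> np.ndarray:
    """Integer day offsets -> datetime64[D]."""
    return EPOCH + np.asarray(days, dtype=np.int64)


# ---------------------------------------------------------------------------
# Drug taxonomy
# ---------------------------------------------------------------------------

#: Lipid-lowering drug classes; statins are singled out for the sublevels.
LLT_CLASSES = ("statin", "fibrate", "fish_oil", "ezetimibe", "niacin")
NS_LLT_CLASSES = ("fibrate", "fish_oil", "ezetimibe", "niacin")
#: Antihypertensive subclasses (angiotensin antagonists, beta blockers,
#: calcium channel blockers, non-loop diuretics).
AHT_CLASSES = ("ace_arb", "beta_blocker", "ccb", "diuretic")
ASA_CLASSES = ("asa",)
ARV_CLASS = "arv"

#: The three cardiovascular class groups carried through the exposure model.
CLASS_GROUPS: Mapping[str, tuple] = {
    "llt": LLT_CLASSES,
    "aht": AHT_CLASSES,
    "asa": ASA_CLASSES,
}

#: Exposure level codes shared by the classifier, the generator and the models.
LEVEL_NEVER, LEVEL_REMOTE, LEVEL_RECENT, LEVEL_CONSISTENT = 0, 1, 2, 3
LEVEL_NAMES = ("never", "remote", "recent_inconsistent", "consistent")
LEVEL_CODES = {name: code for code, name in enumerate(LEVEL_NAMES)}


@dataclass(frozen=True)
class CoverageRules:
    """Day-to-day pill-stock rules for refill reconstruction.

    Parameters
    ----------
    stock_cap_days
        Maximum carry-over of unused same-drug supply at an early refill.
    switch_resets
        A fill of a *different* drug in the same class resets the class stock
        to that fill's days supply (no stacking across drugs).
    inpatient_covered
        Hospital days after the first fill of a class count as covered and do
        not decrement the outpatient stock.
    incompatible
        Optional map ``class -> set of classes``; a fill of a key class
        truncates the stock of the mapped classes at the fill date.
    """

    stock_cap_days: int = 90
    switch_resets: bool = True
    inpatient_covered: bool = True
    incompatible: Mapping[str, frozenset] = field(default_factory=dict)


@dataclass(frozen=True)
class GridSpec:
    """Anchor grid for time-updated covariates: weekly plus event days."""

    interval_days: int = 7


@dataclass(frozen=True)
class LevelRules:
    """Thresholds of the four-level exposure classifier."""

    #: trailing-PDC gate for the consistent level (strict inequality).
    consistent_pdc: float = 0.91
    #: months (of 12 trailing blocks) with >= 1 covered day required.
    consistent_months: int = 11
    #: require a covered day within this many days of the anchor for
    #: the consistent level; None disables the recency gate.
    consistent_recency_days: int | None = 30
    #: threshold of the since-initiation sensitivity definition.
    sensitivity_pdc: float = 0.915


@dataclass(frozen=True)
class FollowUpRules:
    """Entry/exit rules: suppression entry, care-gap and administrative censoring."""

    #: viral loads below this many copies/mL count as undetectable.
    undetectable_copies: float = 50.0
    #: a gap between consecutive care contacts longer than this censors
    #: (">13 months" operationalized as 396 days).
    gap_days: int = 396
    #: censor date convention for gap censoring: "last_contact" or "gap_end".
    gap_censor_at: str = "last_contact"


DEFAULT_TRUE_LOG_HR: Mapping[tuple, float] = {}


def _default_event_rates() -> dict:
    # per-day baseline hazards of the explanatory endpoints, set to mirror
    # observed crude incidence (coronary ~6.4, cerebrovascular ~3.3,
    # serious infection ~60, cancer ~27 events per 1000 patient-years).
    return {
        "ascvd_coronary": 1.75e-5,
        "ascvd_cerebrovascular": 0.9e-5,
        "infection": 1.6e-4,
        "cancer": 7.5e-5,
    }


@dataclass
class SimulationConfig:
    """Settings of the synthetic veteran-like cohort generator.

    The defaults emulate the shape of the source registry cohort at a
    scaled-down horizon: staggered entry after virologic suppression, crude
    mortality near 33 per 1000 patient-years, roughly 16% gap censoring, and
    ever-use rates near 42%/63%/35% for LLT/AHT/ASA.
    """

    n_patients: int = 2000
    horizon_days: int = 2922  # 8 years of calendar time
    seed: int = 0

    #: map (class_group, level_name) -> true conditional log hazard ratio on death.
    true_log_hr: dict = field(default_factory=dict)
    #: map endpoint -> {(class_group, level_name): log HR} for explanatory endpoints.
    endpoint_log_hr: dict = field(default_factory=dict)

    #: effect of the latent frailty score (per SD) on the treatment-start log rate.
    confounding_strength: float = 0.8
    #: effect of frailty (per SD) on the death log hazard.
    frailty_death_coef: float = 0.6
    #: correlation between frailty and poor adherence (healthy-adherer knob).
    adherence_frailty_corr: float = 0.0

    #: proportions of (high, intermittent, poor) refill persistence classes,
    #: set to reproduce the source cohort's printed adherence moments
    #: (median one-year HAART adherence ~0.8, statin persistence ~0.54 of
    #: follow-up time after first fill).
    adherence_mixture: tuple = (0.55, 0.30, 0.15)

    #: death hazard per person-day at frailty 0 / age 53 / never exposed.
    baseline_hazard: float = 7.2e-5
    #: per-day probability of permanently leaving care (gap censoring driver).
    ltfu_rate: float = 1.0e-4
    #: effect of frailty on the loss-to-follow-up log rate (0 = uninformative).
    ltfu_frailty_coef: float = 0.0

    #: per-endpoint baseline hazards (per person-day).
    event_rates: dict = field(default_factory=_default_event_rates)

    #: probability a patient ever achieves an undetectable viral load.
    suppression_prob: float = 0.85
    #: mean days from care start to virologic suppression.
    suppression_mean_days: float = 240.0
    #: care starts are uniform on [0, entry_spread_days).
    entry_spread_days: int = 1095

    #: per-day start rates of the three CV drug-class groups at frailty 0.
    start_rates: dict = field(
        default_factory=lambda: {"llt": 2.7e-4, "aht": 5.0e-4, "asa": 2.1e-4}
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.horizon_days < YEAR_DAYS:
            raise ValueError(
                "horizon shorter than 365 days: trailing one-year PDC undefined"
            )
        mix = np.asarray(self.adherence_mixture, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("adherence_mixture must be nonnegative and sum to 1")
        for name, rate in [
            ("baseline_hazard", self.baseline_hazard),
            ("ltfu_rate", self.ltfu_rate),
            *[(f"event_rates[{k}]", v) for k, v in self.event_rates.items()],
            *[(f"start_rates[{k}]", v) for k, v in self.start_rates.items()],
        ]:
            if rate < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "true_log_hr" in raw:
            raw["true_log_hr"] = {
                (k.split(":")[0], k.split(":")[1]): v
                for k, v in raw["true_log_hr"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_log_hr"] = {f"{g}:{l}": v for (g, l), v in self.true_log_hr.items()}
        d["endpoint_log_hr"] = {
            ep: {f"{g}:{l}": v for (g, l), v in m.items()}
            for ep, m in self.endpoint_log_hr.items()
        }
        return d


@dataclass(frozen=True)
class AdjudicationConfig:
    """Code sets and corroboration rules for ASCVD event adjudication.

    A diagnosis code becomes an event only if corroborating evidence (a
    procedure code, a qualifying biomarker value, or a neuroimaging record)
    occurs within ``window_days`` of it.
    """

    coronary_dx: frozenset = frozenset({"icd_mi", "icd_acs"})
    cerebrovascular_dx: frozenset = frozenset({"icd_stroke", "icd_tia"})
    coronary_procedures: frozenset = frozenset({"ptca", "cabg"})
    cerebrovascular_imaging: frozenset = frozenset({"ct_head", "mri_brain"})
    #: lab corroboration: analyte -> minimum qualifying value.
    lab_criteria: Mapping[str, float] = field(
        default_factory=lambda: {"troponin": 0.1}
    )
    window_days: int = 7


@dataclass(frozen=True)
class EndpointCodes:
    """Include/exclude ICD-style code sets for a coded first-event endpoint."""

    include: frozenset
    exclude: frozenset = frozenset()


DEFAULT_INFECTION_CODES = EndpointCodes(
    include=frozenset({"icd_pneumonia", "icd_sepsis", "icd_endocarditis",
                       "icd_meningitis", "icd_pyelonephritis"}),
    exclude=frozenset({"icd_cellulitis", "icd_uri", "icd_cystitis"}),
)
DEFAULT_CANCER_CODES = EndpointCodes(
    include=frozenset({"icd_lung_ca", "icd_lymphoma", "icd_liver_ca",
                       "icd_colon_ca", "icd_prostate_ca"}),
    exclude=frozenset({"icd_squamous_skin_ca", "icd_basal_skin_ca"}),
)


@dataclass
class PipelineConfig:
    """End-to-end analysis settings shared by the CLI and the study drivers."""

    rules: CoverageRules = field(default_factory=CoverageRules)
    grid: GridSpec = field(default_factory=GridSpec)
    levels: LevelRules = field(default_factory=LevelRules)
    followup: FollowUpRules = field(default_factory=FollowUpRules)
    adjudication: AdjudicationConfig = field(default_factory=AdjudicationConfig)
    endpoint_codes: dict = field(
        default_factory=lambda: {
            "infection": DEFAULT_INFECTION_CODES,
            "cancer": DEFAULT_CANCER_CODES,
        }
    )
    #: endpoints to build person-period datasets and fits for.
    endpoints: Sequence[str] = ("death",)
    #: candidate covariates screened into the propensity/censoring models.
    candidate_covariates: Sequence[str] = (
        "comorbidity_index", "age", "haart_pdc", "ldl_avg",
    )
    #: p-value threshold of the predictor screen.
    screen_alpha: float = 0.05
    #: weight truncation percentiles.
    truncation_pct: tuple = (5.0, 95.0)
    #: accepted ARV combinations (sets of drug codes) for HAART adherence.
    accepted_combos: Sequence[frozenset] = (
        frozenset({"tdf", "ftc", "efv"}),
    )
    #: expand LLT levels into statin-only/combination/statin-free sublevels.
    llt_sublevels: bool = False
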