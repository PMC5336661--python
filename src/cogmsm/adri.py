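"""Additive dementia risk index (ANU-ADRI style) scoring engine.

The index sums integer points over up to eleven demographic, lifestyle and
medical sub-indices; protective factors (education, light-to-moderate
drinking, physical, social and cognitive activity) carry negative points, so
the raw total spans a declared range (−13..+19 by default) and a constant
shift of +13 maps it onto 0..32 for readability. Per-category point values
live in a YAML config; the engine owns the categorisation rules that are fixed
by the instrument itself: sex-specific alcohol bounds, the PHQ-9 depression
cut-off, the 1/2/3-weighted physical-activity hours, and the pro-rata fifth
social-engagement domain.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: light-to-moderate weekly-drinks bounds, by sex (national guideline bands)
ALCOHOL_BOUNDS = {"M": (0.25, 20.5), "F": (0.25, 13.5)}

#: PHQ-9 score strictly above this flags depression
PHQ9_CUTOFF = 10

ACTIVITY_WEIGHTS = (1.0, 2.0, 3.0)  # mild, moderate, vigorous


class ScoringError(ValueError):
    """A profile value cannot be mapped onto the configured categories."""


def categorize_alcohol(sex: str, drinks_per_week: float) -> str:
    """Sex-specific alcohol category: abstainer / light_moderate / heavy.

    Intake below the lower guideline bound (0.25 drinks/week) counts as
    abstaining; above the sex-specific upper bound as heavy.
    """
    if drinks_per_week < 0:
        raise ScoringError("drinks_per_week must be non-negative")
    if sex not in ALCOHOL_BOUNDS:
        raise ScoringError(f"sex must be 'M' or 'F', got {sex!r}")
    lo, hi = ALCOHOL_BOUNDS[sex]
    if drinks_per_week < lo:
        return "abstainer"
    if drinks_per_week <= hi:
        return "light_moderate"
    return "heavy"


def weighted_activity_hours(mild: float, moderate: float, vigorous: float) -> float:
    """Physical-activity hours weighted 1/2/3 for mild/moderate/vigorous."""
    if min(mild, moderate, vigorous) < 0:
        raise ScoringError("activity hours must be non-negative")
    w1, w2, w3 = ACTIVITY_WEIGHTS
    return mild * w1 + moderate * w2 + vigorous * w3


def social_engagement_score(domains) -> float:
    """Five-domain social-engagement composite from four observed domains.

    The unobserved fifth domain (living arrangements) is computed pro rata as
    the mean of the four observed domains; the composite is the sum over all
    five, i.e. 1.25 × the sum of the observed four.
    """
    domains = list(domains)
    if len(domains) != 4:
        raise ScoringError(f"exactly 4 social-engagement domains required, got {len(domains)}")
    fifth = sum(domains) / 4.0
    return sum(domains) + fifth


def depression_flag(phq9_score: int) -> bool:
    """True iff the PHQ-9 score is strictly above the cut-off (10)."""
    if not 0 <= phq9_score <= 27:
        raise ScoringError(f"PHQ-9 score must lie in [0, 27], got {phq9_score}")
    return phq9_score > PHQ9_CUTOFF


@dataclass
class AdriConfig:
    """Per-sub-index category→points tables plus the additive shift.

    ``min_raw``/``max_raw`` declare the attainable raw range and are checked
    against the per-sub-index minima/maxima at load time.
    """

    sub_indices: dict
    shift_constant: int = 13
    min_raw: int = -13
    max_raw: int = 19

    def __post_init__(self) -> None:
        lo = sum(min(si["points"].values()) for si in self.sub_indices.values())
        hi = sum(max(si["points"].values()) for si in self.sub_indices.values())
        if lo != self.min_raw or hi != self.max_raw:
            raise ScoringError(
                f"declared raw range ({self.min_raw}, {self.max_raw}) does not match "
                f"point-table extremes ({lo}, {hi})"
            )
        for name, si in self.sub_indices.items():
            missing = set(si.get("categories", si["points"])) - set(si["points"])
            if missing:
                raise ScoringError(f"sub-index {name!r} lacks points for {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "AdriConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(sub_indices=doc["sub_indices"],
                   shift_constant=doc.get("shift_constant", 13),
                   min_raw=doc.get("min_raw", -13),
                   max_raw=doc.get("max_raw", 19))

    def _bin(self, sub_index: str, value: float) -> str:
        si = self.sub_indices[sub_index]
        cats, breaks = si["categories"], si.get("breaks")
        if breaks is None:
            raise ScoringError(f"sub-index {sub_index!r} has no numeric bins")
        for cat, ub in zip(cats, breaks):
            if value < ub:
                return cat
        return cats[-1]


def load_default_config() -> AdriConfig:
    """The synthetic default point tables shipped with the package."""
    ref = importlib.resources.files("cogmsm.data") / "adri_default.yaml"
    with importlib.resources.as_file(ref) as path:
        return AdriConfig.from_yaml(path)


@dataclass
class AdriProfile:
    """One subject's raw inputs to the risk index; any field may be None."""

    age: Optional[float] = None
    sex: Optional[str] = None
    alcohol_drinks_per_week: Optional[float] = None
    education_years: Optional[float] = None
    diabetes: Optional[bool] = None
    depression_phq9: Optional[int] = None
    tbi_with_loc: Optional[bool] = None
    smoking: Optional[str] = None
    social_domains: Optional[tuple] = None
    activity_hours: Optional[tuple] = None  # (mild, moderate, vigorous)
    cognitive_activities: Optional[int] = None
    bmi: Optional[float] = None


@dataclass
class AdriScore:
    """Scored index: per-sub-index points, raw and shifted totals."""

    points: dict[str, int]
    raw_total: int
    shifted_total: int
    absent: tuple[str, ...] = field(default_factory=tuple)


def _yesno(flag: bool) -> str:
    return "yes" if flag else "no"


def compute_adri(profile: AdriProfile, config: AdriConfig | None = None) -> AdriScore:
    """Score a profile against a config; absent variables contribute 0 points.

    Category derivation per sub-index: age band (age_sex), education-years
    bins, sex-specific alcohol bands, smoking status as given, yes/no medical
    flags (diabetes, PHQ-9 depression, TBI with loss of consciousness), BMI
    bins, weighted activity-hours bins, five-domain social composite bins and
    cognitive-activity-count bins. Raises :class:`ScoringError` naming the
    sub-index when a value falls outside the configured categories.
    """
    if config is None:
        config = load_default_config()
    points: dict[str, int] = {}
    absent: list[str] = []

    def categorical(sub_index: str, category: str | None) -> None:
        if sub_index not in config.sub_indices:
            return
        if category is None:
            absent.append(sub_index)
            return
        table = config.sub_indices[sub_index]["points"]
        if category not in table:
            raise ScoringError(f"sub-index {sub_index!r}: no points for category {category!r}")
        points[sub_index] = int(table[category])

    def binned(sub_index: str, value: float | None) -> None:
        if sub_index not in config.sub_indices:
            return
        if value is None:
            absent.append(sub_index)
            return
        categorical(sub_index, config._bin(sub_index, value))

    binned("age_sex", profile.age)
    binned("education", profile.education_years)
    if profile.alcohol_drinks_per_week is None or profile.sex is None:
        if "alcohol" in config.sub_indices:
            absent.append("alcohol")
    else:
        categorical("alcohol", categorize_alcohol(profile.sex, profile.alcohol_drinks_per_week))
    categorical("smoking", profile.smoking)
    categorical("diabetes", None if profile.diabetes is None else _yesno(profile.diabetes))
    categorical("depression",
                None if profile.depression_phq9 is None
                else _yesno(depression_flag(profile.depression_phq9)))
    categorical("tbi", None if profile.tbi_with_loc is None else _yesno(profile.tbi_with_loc))
    binned("bmi", profile.bmi)
    binned("physical_activity",
           None if profile.activity_hours is None
           else weighted_activity_hours(*profile.activity_hours))
    binned("social_engagement",
           None if profile.social_domains is None
           else social_engagement_score(profile.social_domains))
    binned("cognitive_activity", profile.cognitive_activities)

    raw = sum(points.values())
    return AdriScore(points=points, raw_total=raw,
                     shifted_total=raw + config.shift_constant,
                     absent=tuple(absent))
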