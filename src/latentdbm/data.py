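"""Child anthropometry records: reading, validation, filtering and classification.

The analysis operates on tabular records of children aged 6-59 months,
each carrying a height-for-age z-score (HAZ) and a BMI-for-age z-score
(BAZ) relative to the WHO growth reference, plus identifiers linking the
child to a household and a subpopulation (municipality x rural/urban
area).  This module implements the cleaning rules used before any model
is fitted:

* duplicate field measurements are averaged;
* biologically implausible z-scores (HAZ outside [-6, 6], BAZ outside
  [-5, 5]) and age-ineligible children are excluded, with reason codes;
* stunting is HAZ < -2 (strict), overweight is BAZ > 2 (strict), and the
  individual-level double burden of malnutrition (DBM) is their
  co-occurrence in the same child.

Records are held in a pandas DataFrame with the canonical columns
``child_id, household_id, municipality, area, age_months, haz, baz``;
:class:`SubpopulationSample` wraps one municipality x area slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ChildRecord",
    "Thresholds",
    "NutritionFlags",
    "SubpopulationSample",
    "read_cohort",
    "validate_cohort",
    "average_duplicates",
    "filter_plausible",
    "classify",
    "classify_frame",
    "observed_prevalence",
    "group_by_subpopulation",
]

COLUMNS = ["child_id", "household_id", "municipality", "area", "age_months", "haz", "baz"]

AGE_MIN, AGE_MAX = 6, 59

#: exclusion reason codes, in the priority order applied when several hold
EXCLUSION_REASONS = (
    "age_ineligible",
    "haz_missing",
    "baz_missing",
    "haz_implausible",
    "baz_implausible",
)


class ValidationError(ValueError):
    """Raised when input records violate the cohort schema."""


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs and plausibility bounds on the z-score scale.

    ``t1`` is the stunting cutoff on HAZ (child is stunted iff HAZ < t1)
    and ``t2`` the overweight cutoff on BAZ (overweight iff BAZ > t2);
    both comparisons are strict, so a z-score exactly at a cutoff is not a
    case.  The plausibility bounds are inclusive: only values strictly
    outside are discarded as measurement artefacts.
    """

    t1: float = -2.0
    t2: float = 2.0
    haz_bounds: tuple[float, float] = (-6.0, 6.0)
    baz_bounds: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self):
        if not self.haz_bounds[0] < self.t1 < self.haz_bounds[1]:
            raise ValueError("stunting cutoff must lie inside the HAZ plausibility bounds")
        if not self.baz_bounds[0] < self.t2 < self.baz_bounds[1]:
            raise ValueError("overweight cutoff must lie inside the BAZ plausibility bounds")


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    household_id: str
    municipality: str
    area: str
    age_months: int
    haz: float
    baz: float

    def __post_init__(self):
        if self.area not in ("rural", "urban"):
            raise ValidationError(f"area must be 'rural' or 'urban', got {self.area!r}")
        if not self.household_id:
            raise ValidationError(f"record {self.child_id!r}: empty household_id")


@dataclass(frozen=True)
class NutritionFlags:
    stunted: bool
    overweight: bool

    @property
    def dbm(self) -> bool:
        return self.stunted and self.overweight


@dataclass
class SubpopulationSample:
    """All kept records for one municipality x area cell.

    The subpopulation is the unit at which the bivariate model is fitted;
    ``household_index`` maps each row to a 0-based household index used by
    the clustered (random-effect) likelihood.
    """

    municipality: str
    area: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)

    @property
    def n_children(self) -> int:
        return len(self.records)

    @property
    def n_households(self) -> int:
        return self.records["household_id"].nunique()

    @property
    def household_index(self) -> np.ndarray:
        codes, _ = pd.factorize(self.records["household_id"])
        return codes

    @property
    def y(self) -> np.ndarray:
        """(n, 2) array of (HAZ, BAZ) observations."""
        return self.records[["haz", "baz"]].to_numpy(dtype=float)

    @property
    def key(self) -> tuple[str, str]:
        return (self.municipality, self.area)

    @property
    def label(self) -> str:
        return f"{self.area}_{self.municipality}"


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV and validate its schema.

    Expects UTF-8, comma separation, a header row, and the columns
    ``child_id, household_id, municipality, area, age_months, haz, baz``
    with ``area`` in {rural, urban} (case-insensitive).
    """
    df = pd.read_csv(path, dtype={"child_id": str, "household_id": str, "municipality": str})
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise ValidationError(f"unknown column(s): {', '.join(extra)}")
    df = df.copy()
    df["area"] = df["area"].astype(str).str.strip().str.lower()
    bad_area = ~df["area"].isin(["rural", "urban"])
    if bad_area.any():
        raise ValidationError(
            f"column 'area' must be rural/urban; offending values: "
            f"{sorted(df.loc[bad_area, 'area'].unique())}"
        )
    if df["household_id"].isna().any() or (df["household_id"].astype(str) == "").any():
        raise ValidationError("column 'household_id' contains empty values")
    for col in ("municipality",):
        if df[col].isna().any():
            raise ValidationError(f"column {col!r} contains missing values")
    df["age_months"] = pd.to_numeric(df["age_months"], errors="raise")
    df["haz"] = pd.to_numeric(df["haz"], errors="coerce")
    df["baz"] = pd.to_numeric(df["baz"], errors="coerce")
    inf = np.isinf(df["haz"].to_numpy(dtype=float)) | np.isinf(df["baz"].to_numpy(dtype=float))
    if inf.any():
        raise ValidationError(
            f"non-finite z-scores for child_id(s): {df.loc[inf, 'child_id'].tolist()}"
        )
    return df[COLUMNS]


def average_duplicates(m1: float, m2: float) -> float:
    """Average two duplicate field measurements of the same quantity."""
    if not (math.isfinite(m1) and math.isfinite(m2)):
        raise ValidationError(f"non-finite duplicate measurements: ({m1}, {m2})")
    return (m1 + m2) / 2.0


def filter_plausible(
    df: pd.DataFrame, thresholds: Thresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into kept and excluded, tagging exclusions with a reason.

    Exclusion reasons (first matching one wins, in this order):
    ``age_ineligible`` (outside 6-59 months), ``haz_missing``/``baz_missing``
    (no z-score recorded), ``haz_implausible``/``baz_implausible`` (outside
    the inclusive plausibility bounds).  The union of the two outputs is the
    input; filtering never errors.
    """
    thresholds = thresholds or Thresholds()
    age = df["age_months"].to_numpy(dtype=float)
    haz = df["haz"].to_numpy(dtype=float)
    baz = df["baz"].to_numpy(dtype=float)
    lo1, hi1 = thresholds.haz_bounds
    lo2, hi2 = thresholds.baz_bounds

    reason = np.full(len(df), "", dtype=object)
    checks = [
        ("age_ineligible", (age < AGE_MIN) | (age > AGE_MAX)),
        ("haz_missing", np.isnan(haz)),
        ("baz_missing", np.isnan(baz)),
        ("haz_implausible", (haz < lo1) | (haz > hi1)),
        ("baz_implausible", (baz < lo2) | (baz > hi2)),
    ]
    for code, mask in checks:
        reason[(reason == "") & mask] = code

    excluded = df[reason != ""].copy()
    excluded["exclusion_reason"] = reason[reason != ""]
    kept = df[reason == ""].copy().reset_index(drop=True)
    return kept, excluded.reset_index(drop=True)


def classify(haz: float, baz: float, thresholds: Thresholds | None = None) -> NutritionFlags:
    """Classify one child: stunted iff HAZ < t1, overweight iff BAZ > t2 (strict)."""
    thresholds = thresholds or Thresholds()
    return NutritionFlags(stunted=haz < thresholds.t1, overweight=baz > thresholds.t2)


def classify_frame(df: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Vectorized classification; returns a copy with stunted/overweight/dbm columns."""
    thresholds = thresholds or Thresholds()
    out = df.copy()
    out["stunted"] = out["haz"] < thresholds.t1
    out["overweight"] = out["baz"] > thresholds.t2
    out["dbm"] = out["stunted"] & out["overweight"]
    return out


def observed_prevalence(
    sample: SubpopulationSample, thresholds: Thresholds | None = None
) -> tuple[int, float]:
    """Frequentist (case-counting) DBM prevalence in one subpopulation.

    Returns the DBM case count and the proportion of children classified
    as both stunted and overweight.  This is the quantity a conventional
    survey table reports; the latent model exists precisely because this
    estimator collapses to 0% in small samples with few or no cases.
    """
    if sample.n_children == 0:
        raise ValueError(f"empty subpopulation sample {sample.key}")
    flags = classify_frame(sample.records, thresholds)
    count = int(flags["dbm"].sum())
    return count, count / sample.n_children


def group_by_subpopulation(df: pd.DataFrame) -> list[SubpopulationSample]:
    """Partition records into municipality x area subpopulation samples.

    The partition is exhaustive and disjoint; groups are ordered area-first
    (rural before urban), then alphabetically by municipality, to make
    report ordering deterministic.
    """
    if df["municipality"].isna().any() or df["area"].isna().any():
        raise ValidationError("municipality/area must be present on every record")
    samples = [
        SubpopulationSample(municipality=muni, area=area, records=g)
        for (area, muni), g in df.groupby(["area", "municipality"], sort=True)
    ]
    samples.sort(key=lambda s: (s.area, s.municipality))
    return samples
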