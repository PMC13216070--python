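"""Household wild-meat recall surveys: data model and standardization rules.

The survey data live at four levels — study, location, household, recall
event — and arrive in heterogeneous shapes (24-h to 365-day recall windows,
categorical or count-based frequencies, quantities in kg or local units).
This module turns raw records into the three model-ready tables the joint
model consumes:

* consumption/non-consumption flags, one row per recall event;
* frequency of consumption, one row per household, as the proportion of
  monitored days with a consumption event (in [0, 1]);
* daily undressed quantity (kg) consumed per household, one row per recall
  event, standardized to a 24-h window.

Household size is expressed in adult-male equivalents (AME), a rescaling of
household composition by age/sex energy multipliers so that per-capita
quantities are comparable across households.

Missing values are carried as NaN internally.  The legacy "-1" missing code
is accepted on ingestion and translated; it never survives into model-ready
output where it could be summed by mistake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

__all__ = [
    "AME_MULTIPLIERS",
    "CATEGORY_FREQUENCIES",
    "FRACTION_UNITS",
    "EARTH_RADIUS_KM",
    "StudyRecord",
    "LocationRecord",
    "HouseholdRecord",
    "RecallEvent",
    "UnitConversionTable",
    "SurveyTables",
    "aggregate_within_day",
    "compute_frequency",
    "standardize_daily_quantity",
    "convert_local_units",
    "compute_ame",
    "build_distance_matrix",
    "ingest_tables",
]

#: Energy multipliers converting household members into adult-male
#: equivalents.  Adults of unspecified sex use the male/female average;
#: children of unspecified age use the average of the three child classes.
AME_MULTIPLIERS = {
    "adult_male": 1.0,
    "adult_female": 0.86,
    "child_10_15": 0.96,
    "child_6_10": 0.85,
    "child_0_5": 0.52,
    "child_unspecified": 0.78,
    "adult_unspecified": 0.93,
}

#: Categorical frequency labels mapped onto the proportion-of-days scale.
#: "monthly" means 12 consumption days out of 365; weekly and yearly follow
#: the same convention.
CATEGORY_FREQUENCIES = {
    "daily": 1.0,
    "weekly": 52.0 / 365.0,
    "monthly": 12.0 / 365.0,
    "yearly": 1.0 / 365.0,
}

#: Carcass-fraction units: multiples of the species whole-body mass.
#: "gigot" (hind leg) is taken as one fifth of the carcass by convention;
#: override via :class:`UnitConversionTable`.
FRACTION_UNITS = {"entire": 1.0, "half": 0.5, "quarter": 0.25, "gigot": 0.2}

#: Mean Earth radius used for great-circle distances.
EARTH_RADIUS_KM = 6371.0088

_MISSING_CODES = {"-1", "-1.0", "", "na", "nan", "none"}

LOCATION_TYPES = ("village", "town", "city")
EDUCATION_LEVELS = ("primary_or_none", "secondary_or_higher", "unknown")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, (int, float)) and value == -1:
        return True
    return str(value).strip().lower() in _MISSING_CODES


@dataclass(frozen=True)
class StudyRecord:
    """One survey study: a single methodology over one study area and timeframe.

    ``study_type`` 1 = short-recall quantity study (24-72 h window),
    2 = long-recall (week to year), 3 = cooking-pot study (records what was
    cooked, not eaten).  ``period`` 1 = 2000-2010, 2 = 2011-2021.
    """

    study_id: str
    study_type: int
    period: int

    def __post_init__(self):
        if self.study_type not in (1, 2, 3):
            raise ValueError(f"study_type must be 1, 2 or 3, got {self.study_type}")
        if self.period not in (1, 2):
            raise ValueError(f"period must be 1 or 2, got {self.period}")


@dataclass(frozen=True)
class LocationRecord:
    """A surveyed settlement with coordinates, type, and site covariates."""

    location_id: str
    lon: float
    lat: float
    location_type: str
    hpd: float = math.nan  # human population density, people/km^2
    rem: float = math.nan  # remoteness score
    hdi: float = math.nan  # human development index, in [0, 1]
    fci: float = math.nan  # forest condition index

    def __post_init__(self):
        if self.location_type not in LOCATION_TYPES:
            raise ValueError(f"unknown location_type {self.location_type!r}")
        if not math.isnan(self.hdi) and not 0.0 <= self.hdi <= 1.0:
            raise ValueError(f"hdi must lie in [0, 1], got {self.hdi}")
        if not math.isnan(self.hpd) and self.hpd < 0:
            raise ValueError(f"hpd must be non-negative, got {self.hpd}")


@dataclass(frozen=True)
class HouseholdRecord:
    """One household: monitored days, observed frequency, education, AME."""

    household_id: str
    location_id: str
    mdays: int
    frequency: float = math.nan
    education: str = "unknown"
    ame: float = math.nan

    def __post_init__(self):
        if not 1 <= self.mdays <= 365:
            raise ValueError(f"mdays must lie in [1, 365], got {self.mdays}")
        if not math.isnan(self.frequency):
            if self.mdays < 2:
                raise ValueError("frequency requires at least 2 monitored days")
            if not 0.0 <= self.frequency <= 1.0:
                raise ValueError(f"frequency must lie in [0, 1], got {self.frequency}")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(f"unknown education level {self.education!r}")
        if not math.isnan(self.ame) and self.ame <= 0:
            raise ValueError(f"ame must be positive, got {self.ame}")


@dataclass(frozen=True)
class RecallEvent:
    """One recall event: a household's consumption over ``days`` days."""

    recall_id: str
    household_id: str
    days: float
    consumed: int
    quantity_kg: float = math.nan
    ame: float = math.nan

    def __post_init__(self):
        if self.days < 1:
            raise ValueError(f"recall duration must be >= 1 day, got {self.days}")
        if self.consumed not in (0, 1):
            raise ValueError(f"consumed must be 0 or 1, got {self.consumed}")
        if not math.isnan(self.quantity_kg):
            if self.quantity_kg < 0:
                raise ValueError("quantity_kg must be non-negative")
            if self.consumed == 0 and self.quantity_kg != 0:
                raise ValueError("non-consumption recall with positive quantity")


@dataclass
class UnitConversionTable:
    """Local measurement units resolved into kilograms.

    ``species_mass_kg`` maps a species label to its whole-body mass; carcass
    fractions (entire/half/quarter/gigot) multiply it.  ``unit_kg`` maps
    other unit labels (piece, pile, plate, ...) directly to kg per unit.
    """

    species_mass_kg: dict = field(default_factory=dict)
    unit_kg: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=lambda: dict(FRACTION_UNITS))

    def __post_init__(self):
        for name, kg in {**self.species_mass_kg, **self.unit_kg}.items():
            if kg <= 0:
                raise ValueError(f"conversion for {name!r} must be positive, got {kg}")


# ---------------------------------------------------------------------------
# Standardization operations
# ---------------------------------------------------------------------------


def aggregate_within_day(meal_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-meal entries into one 24-h recall row per household-day.

    ``meal_records`` needs columns ``household_id``, ``day`` (calendar day
    label), ``consumed`` (0/1 per meal) and optionally ``quantity_kg``.
    A day counts as a consumption event if any meal that day contained wild
    meat, and its quantity is the sum of that day's quantities.  Rows with a
    negative quantity are rejected with a diagnostic.
    """
    required = {"household_id", "day", "consumed"}
    missing = required - set(meal_records.columns)
    if missing:
        raise ValueError(f"meal records lack columns: {sorted(missing)}")
    records = meal_records.copy()
    if "quantity_kg" not in records.columns:
        records["quantity_kg"] = 0.0
    bad = records["quantity_kg"] < 0
    if bad.any():
        raise ValueError(
            f"negative quantities in meal records at rows {list(records.index[bad])}"
        )
    grouped = (
        records.groupby(["household_id", "day"], sort=True)
        .agg(consumed=("consumed", "max"), quantity_kg=("quantity_kg", "sum"))
        .reset_index()
    )
    grouped["days"] = 1.0
    return grouped


def compute_frequency(
    events: int | None = None,
    monitored_days: int | None = None,
    category: str | None = None,
) -> float:
    """Frequency of consumption as a proportion of days, in [0, 1].

    Either a categorical label (daily/weekly/monthly/yearly) or a pair of
    (consumption events, monitored days) with at least 2 monitored days.
    """
    if category is not None:
        try:
            return CATEGORY_FREQUENCIES[category]
        except KeyError:
            raise ValueError(f"unknown frequency category {category!r}") from None
    if events is None or monitored_days is None:
        raise ValueError("need either a category or (events, monitored_days)")
    if monitored_days < 2:
        raise ValueError("frequency from repeated recalls needs >= 2 monitored days")
    if events < 0 or events > monitored_days:
        raise ValueError(
            f"events ({events}) must lie in [0, monitored_days={monitored_days}]"
        )
    return events / monitored_days


def standardize_daily_quantity(total_kg: float, recall_days: float) -> float:
    """Quantity consumed per day: reported total divided by recall duration."""
    if recall_days < 1:
        raise ValueError(f"recall duration must be >= 1 day, got {recall_days}")
    if total_kg < 0:
        raise ValueError(f"quantity must be non-negative, got {total_kg}")
    return total_kg / recall_days


def convert_local_units(
    unit_records: pd.DataFrame, table: UnitConversionTable
) -> tuple[pd.Series, pd.DataFrame]:
    """Resolve local-unit quantity records into kilograms.

    ``unit_records`` needs columns ``unit`` and ``count``, plus ``species``
    for carcass-fraction units.  Returns the kg series (NaN where
    unresolvable) and a frame of flagged rows with the reason; flagged rows
    are meant to be excluded downstream, never silently zeroed.
    """
    kg = pd.Series(np.nan, index=unit_records.index, dtype=float)
    reasons = {}
    for idx, row in unit_records.iterrows():
        unit = str(row["unit"]).strip().lower()
        count = float(row["count"])
        if unit in table.fractions:
            species = row.get("species")
            if _is_missing(species):
                reasons[idx] = f"fraction unit {unit!r} without species"
                continue
            mass = table.species_mass_kg.get(species)
            if mass is None:
                reasons[idx] = f"species {species!r} not in conversion table"
                continue
            kg.loc[idx] = count * table.fractions[unit] * mass
        elif unit in table.unit_kg:
            kg.loc[idx] = count * table.unit_kg[unit]
        else:
            reasons[idx] = f"unit {unit!r} not in conversion table"
    flagged = unit_records.loc[list(reasons)].copy()
    flagged["reason"] = [reasons[i] for i in flagged.index]
    return kg, flagged


def compute_ame(
    n_adult_male: int = 0,
    n_adult_female: int = 0,
    n_child_10_15: int = 0,
    n_child_6_10: int = 0,
    n_child_0_5: int = 0,
    n_child_unspecified: int = 0,
    n_adult_unspecified: int = 0,
) -> float:
    """Adult-male equivalents of a household from its age/sex composition.

    Returns NaN (missing, to be imputed) when no members are recorded —
    an absent roster is not an empty household.
    """
    counts = {
        "adult_male": n_adult_male,
        "adult_female": n_adult_female,
        "child_10_15": n_child_10_15,
        "child_6_10": n_child_6_10,
        "child_0_5": n_child_0_5,
        "child_unspecified": n_child_unspecified,
        "adult_unspecified": n_adult_unspecified,
    }
    if any(c < 0 for c in counts.values()):
        raise ValueError(f"member counts must be non-negative: {counts}")
    if all(c == 0 for c in counts.values()):
        return math.nan
    return sum(AME_MULTIPLIERS[k] * c for k, c in counts.items())


def build_distance_matrix(
    locations: pd.DataFrame, method: str = "haversine"
) -> np.ndarray:
    """Pairwise distance matrix (km) between locations.

    ``locations`` needs ``lon``/``lat`` columns in decimal degrees.  The
    default is the great-circle (haversine) distance, appropriate for
    geographic coordinates; ``method="euclidean"`` treats the coordinates as
    planar (already-projected, km units).  Duplicate coordinates are legal
    and yield off-diagonal zeros.
    """
    if len(locations) < 2:
        raise ValueError("need at least 2 locations for a distance matrix")
    lon = np.asarray(locations["lon"], dtype=float)
    lat = np.asarray(locations["lat"], dtype=float)
    if np.isnan(lon).any() or np.isnan(lat).any():
        raise ValueError("locations with missing coordinates")
    if method == "haversine":
        pts = np.radians(np.column_stack([lat, lon]))
        dist = haversine_distances(pts) * EARTH_RADIUS_KM
    elif method == "euclidean":
        xy = np.column_stack([lon, lat])
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown distance method {method!r}")
    np.fill_diagonal(dist, 0.0)
    return 0.5 * (dist + dist.T)


# ---------------------------------------------------------------------------
# Table ingestion
# ---------------------------------------------------------------------------


@dataclass
class SurveyTables:
    """Validated survey tables plus the ingestion report.

    ``studies``/``locations``/``households``/``recalls`` are the cleaned
    frames; ``report`` counts rows ingested, flags raised and records
    excluded, and is serializable to JSON.
    """

    studies: pd.DataFrame
    locations: pd.DataFrame
    households: pd.DataFrame
    recalls: pd.DataFrame
    report: dict

    def model_ready(self) -> dict:
        """Tidy per-submodel frames: consumption, frequency, quantity."""
        hh = self.households.set_index("household_id")
        rec = self.recalls.copy()
        rec["location_id"] = hh["location_id"].reindex(rec["household_id"]).values
        consumption = rec[["recall_id", "household_id", "location_id", "days", "consumed"]]
        freq = self.households.loc[
            self.households["frequency"].notna(),
            ["household_id", "location_id", "mdays", "frequency"],
        ]
        qty = rec.loc[
            rec["quantity_kg"].notna() & (rec["consumed"] == 1),
            ["recall_id", "household_id", "location_id", "days", "quantity_kg", "ame"],
        ]
        return {"consumption": consumption, "frequency": freq, "quantity": qty}


def _to_numeric(series: pd.Series) -> pd.Series:
    cleaned = series.map(lambda v: np.nan if _is_missing(v) else v)
    return pd.to_numeric(cleaned)


def ingest_tables(
    studies: pd.DataFrame,
    locations: pd.DataFrame,
    households: pd.DataFrame,
    recalls: pd.DataFrame,
) -> SurveyTables:
    """Validate raw CSV-shaped tables and produce model-ready frames.

    Enforces the schema invariants: study type and period codes, location
    types and covariate ranges, monitored-day bounds, the frequency /
    monitored-days relationship, and the consumption/quantity consistency of
    recall events.  Missing values (empty or "-1") are translated to NaN.
    Duplicate recall identifiers are rejected and logged — the provenance of
    conflicting duplicates cannot be resolved automatically.
    """
    report: dict = {"flags": [], "excluded": {}, "counts": {}}

    studies = studies.copy()
    for col in ("study_type", "period"):
        studies[col] = _to_numeric(studies[col]).astype(int)
    for _, row in studies.iterrows():
        StudyRecord(str(row["study_id"]), int(row["study_type"]), int(row["period"]))

    locations = locations.copy()
    for col in ("lon", "lat", "hpd", "rem", "hdi", "fci"):
        if col in locations.columns:
            locations[col] = _to_numeric(locations[col])
    if "location_type" in locations.columns:
        bad_lt = ~locations["location_type"].isin(LOCATION_TYPES)
        if bad_lt.any():
            raise ValueError(
                f"unknown location types: {sorted(locations.loc[bad_lt, 'location_type'].unique())}"
            )
    if "hdi" in locations.columns:
        hdi = locations["hdi"]
        if ((hdi < 0) | (hdi > 1)).any():
            raise ValueError("hdi outside [0, 1]")
    if "hpd" in locations.columns and (locations["hpd"] < 0).any():
        raise ValueError("negative hpd")

    households = households.copy()
    households["mdays"] = _to_numeric(households["mdays"]).astype(int)
    households["frequency"] = _to_numeric(households["frequency"])
    households["ame"] = _to_numeric(households["ame"])
    if "education" not in households.columns:
        households["education"] = "unknown"
    households["education"] = households["education"].map(
        lambda v: "unknown" if _is_missing(v) else str(v)
    )
    if (~households["education"].isin(EDUCATION_LEVELS)).any():
        raise ValueError("unknown education levels in household table")
    bad_mdays = (households["mdays"] < 1) | (households["mdays"] > 365)
    if bad_mdays.any():
        raise ValueError("mdays outside [1, 365]")
    # Frequency needs repeated monitoring: drop single-day frequencies, flag.
    single_day_freq = households["frequency"].notna() & (households["mdays"] < 2)
    if single_day_freq.any():
        report["flags"].append(
            f"{int(single_day_freq.sum())} household frequencies dropped (mdays < 2)"
        )
        households.loc[single_day_freq, "frequency"] = np.nan
    bad_freq = households["frequency"].notna() & (
        (households["frequency"] < 0) | (households["frequency"] > 1)
    )
    if bad_freq.any():
        raise ValueError("frequency outside [0, 1]")
    if (households["ame"].dropna() <= 0).any():
        raise ValueError("non-positive AME")

    recalls = recalls.copy()
    dup = recalls["recall_id"].duplicated(keep=False)
    if dup.any():
        dup_ids = sorted(recalls.loc[dup, "recall_id"].unique())
        report["excluded"]["duplicate_recall_ids"] = [str(d) for d in dup_ids]
        report["flags"].append(f"{len(dup_ids)} duplicate recall ids rejected")
        recalls = recalls.loc[~dup]
    recalls["days"] = _to_numeric(recalls["days"])
    recalls["consumed"] = _to_numeric(recalls["consumed"]).astype(int)
    recalls["quantity_kg"] = _to_numeric(recalls["quantity_kg"])
    recalls["ame"] = _to_numeric(recalls["ame"])
    if (recalls["days"] < 1).any():
        raise ValueError("recall duration < 1 day")
    if (~recalls["consumed"].isin([0, 1])).any():
        raise ValueError("consumed flags must be 0/1")
    if (recalls["quantity_kg"].dropna() < 0).any():
        raise ValueError("negative quantity")
    inconsistent = (
        recalls["quantity_kg"].notna()
        & (recalls["quantity_kg"] > 0)
        & (recalls["consumed"] == 0)
    )
    if inconsistent.any():
        report["excluded"]["inconsistent_recalls"] = [
            str(r) for r in recalls.loc[inconsistent, "recall_id"]
        ]
        report["flags"].append(
            f"{int(inconsistent.sum())} recalls with quantity > 0 but consumed = 0 excluded"
        )
        recalls = recalls.loc[~inconsistent]

    unknown_hh = ~recalls["household_id"].isin(households["household_id"])
    if unknown_hh.any():
        raise ValueError(
            f"recalls reference unknown households: "
            f"{sorted(recalls.loc[unknown_hh, 'household_id'].unique())[:5]}"
        )
    unknown_loc = ~households["location_id"].isin(locations["location_id"])
    if unknown_loc.any():
        raise ValueError("households reference unknown locations")

    report["counts"] = {
        "studies": int(len(studies)),
        "locations": int(len(locations)),
        "households": int(len(households)),
        "recalls": int(len(recalls)),
        "households_with_frequency": int(households["frequency"].notna().sum()),
        "recalls_with_quantity": int(recalls["quantity_kg"].notna().sum()),
        "households_missing_ame": int(households["ame"].isna().sum()),
    }
    return SurveyTables(studies, locations, households, recalls, report)
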