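"""Survey-dialect harmonization.

Raw DHS/MICS-style exports code the four delivery-care components in
survey-specific ways (numeric place-of-delivery codes, attendant codes,
stay durations in hours or days, postnatal-check timing).  This module
recodes them into the harmonized categories of :mod:`delivcare.records`
via a per-survey mapping configuration, applies the eligibility window
(most recent live birth within two years of the survey), and removes
design strata containing a single primary sampling unit, which would make
cluster-resampling variance estimation degenerate.

Native DHS/MICS labelled binary formats and the country-specific recode
tables themselves are out of scope: the mapping config is the extension
point where those tables plug in.

Boundary conventions (configurable in :class:`MappingConfig`):

* facility stay: exactly 24 hours counts as a 24+ hour stay (inclusive);
* postnatal check: exactly 48 hours counts as within 48 h (inclusive);
* eligibility: ``months_since_birth < 24`` (strictly within two years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .records import (
    MISSING,
    NO,
    PLACE_HOME,
    PLACE_HOSPITAL,
    PLACE_LOWER,
    WOMAN_COLUMNS,
    YES,
)

logger = logging.getLogger("delivcare")

RAW_REQUIRED_COLUMNS = [
    "survey_id",
    "country_id",
    "stratum",
    "psu",
    "weight",
    "wealth_quintile",
    "months_since_birth",
    "place_code",
    "attendant_code",
    "stay_value",
    "stay_unit",
    "pnc_value",
    "pnc_unit",
]

# Mapping-config values normalized to the harmonized place categories.
# Combined private hospitals and clinics count as hospital delivery.
_PLACE_ALIASES = {
    "home": PLACE_HOME,
    "lower": PLACE_LOWER,
    "hospital": PLACE_HOSPITAL,
    "private_hospital": PLACE_HOSPITAL,
    "private_clinic": PLACE_HOSPITAL,
}

_DEFAULT_UNIT_HOURS = {
    "h": 1.0, "hr": 1.0, "hrs": 1.0, "hour": 1.0, "hours": 1.0,
    "d": 24.0, "day": 24.0, "days": 24.0,
}


class SchemaError(ValueError):
    """Raised when an input file does not carry the declared columns."""


@dataclass
class MappingConfig:
    """Per-survey code maps and unit/boundary conventions.

    ``place_maps[survey_id]`` maps dialect place codes to one of
    home/lower/hospital/private_hospital/private_clinic (private
    facilities are normalized to hospital); ``attendant_maps[survey_id]``
    maps attendant codes to skilled/unskilled.  Codes absent from a map
    recode to the explicit missing category and are logged, never dropped.
    A ``"*"`` survey key supplies a fallback map.
    """

    place_maps: dict[str, dict[str, str]]
    attendant_maps: dict[str, dict[str, str]]
    unit_hours: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_UNIT_HOURS)
    )
    stay_cutoff_hours: float = 24.0
    stay_cutoff_inclusive: bool = True
    pnc_cutoff_hours: float = 48.0
    pnc_cutoff_inclusive: bool = True

    def __post_init__(self) -> None:
        for survey, pmap in self.place_maps.items():
            for code, cat in pmap.items():
                if cat not in _PLACE_ALIASES:
                    raise ValueError(
                        f"survey {survey!r}: place code {code!r} maps to "
                        f"unknown category {cat!r}"
                    )
        for survey, amap in self.attendant_maps.items():
            for code, cat in amap.items():
                if cat not in ("skilled", "unskilled"):
                    raise ValueError(
                        f"survey {survey!r}: attendant code {code!r} maps to "
                        f"unknown category {cat!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MappingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        surveys = raw.get("surveys", {})
        place_maps = {
            str(s): {str(k): str(v) for k, v in sec.get("place", {}).items()}
            for s, sec in surveys.items()
        }
        attendant_maps = {
            str(s): {str(k): str(v) for k, v in sec.get("attendant", {}).items()}
            for s, sec in surveys.items()
        }
        kwargs = {}
        for key in ("stay_cutoff_hours", "stay_cutoff_inclusive",
                    "pnc_cutoff_hours", "pnc_cutoff_inclusive"):
            if key in raw:
                kwargs[key] = raw[key]
        if "unit_hours" in raw:
            kwargs["unit_hours"] = {
                str(k): float(v) for k, v in raw["unit_hours"].items()
            }
        return cls(place_maps=place_maps, attendant_maps=attendant_maps, **kwargs)

    def _map_for(self, maps: dict[str, dict[str, str]], survey_id: str) -> dict[str, str]:
        return maps.get(survey_id, maps.get("*", {}))

    def place_category(self, survey_id: str, code: str) -> str:
        cat = self._map_for(self.place_maps, survey_id).get(str(code))
        if cat is None:
            return MISSING
        return _PLACE_ALIASES[cat]

    def attendant_category(self, survey_id: str, code: str) -> str:
        cat = self._map_for(self.attendant_maps, survey_id).get(str(code))
        if cat is None:
            return MISSING
        return YES if cat == "skilled" else NO


class ReadResult(NamedTuple):
    records: pd.DataFrame
    n_read: int
    n_malformed: int


def read_records(path: str | Path, dialect: MappingConfig) -> ReadResult:
    """Read a raw survey CSV, dropping (and counting) malformed rows.

    A row is malformed if its weight is missing or non-positive, or its
    stratum/PSU identifier is blank.  Raises :class:`SchemaError` when a
    required column is absent and ``ValueError`` on an empty file.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RAW_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"input file {path} missing required columns: {missing}")
    if df.empty:
        raise ValueError(f"input file {path} contains no records")
    n_read = len(df)
    weight = pd.to_numeric(df["weight"], errors="coerce")
    ok = (weight > 0) & (df["stratum"].str.strip() != "") & (df["psu"].str.strip() != "")
    n_malformed = int((~ok).sum())
    if n_malformed:
        logger.warning("%d malformed rows dropped from %s", n_malformed, path)
    out = df.loc[ok].copy()
    out["weight"] = weight[ok]
    return ReadResult(out.reset_index(drop=True), n_read, n_malformed)


def _threshold(hours: pd.Series, cutoff: float, inclusive: bool) -> pd.Series:
    meets = hours >= cutoff if inclusive else hours > cutoff
    return pd.Series(np.where(hours.isna(), MISSING, np.where(meets, YES, NO)),
                     index=hours.index, dtype=object)


def _duration_hours(value: pd.Series, unit: pd.Series, unit_hours: dict[str, float],
                    what: str) -> pd.Series:
    val = pd.to_numeric(value, errors="coerce")
    factor = unit.str.strip().str.lower().map(unit_hours)
    unknown = unit[val.notna() & factor.isna() & (unit.str.strip() != "")]
    if len(unknown):
        logger.warning("unmapped %s units treated as missing: %s",
                       what, sorted(unknown.unique()))
    return val * factor


def recode(raw: pd.DataFrame, mapping: MappingConfig) -> pd.DataFrame:
    """Recode raw dialect records into the harmonized woman table.

    Record counts are conserved: every input row yields exactly one output
    row, with unmapped codes recoded to the missing category and logged.
    Inverts duration thresholds: a facility stay of ``stay_cutoff_hours``
    or more (days converted to hours first) is a 24+ hour stay; a
    postnatal check at or before ``pnc_cutoff_hours`` counts as within
    48 h, and the literal ``pnc_value`` "none" (no check at all) counts as
    no.  A home birth reporting a qualifying facility-stay duration is
    logically inconsistent and recodes to stay24=no with a warning.
    """
    out = pd.DataFrame(index=raw.index)
    out["country_id"] = raw["country_id"]
    out["stratum"] = raw["stratum"]
    out["psu"] = raw["psu"]
    out["weight"] = pd.to_numeric(raw["weight"])
    out["wealth_quintile"] = pd.to_numeric(
        raw["wealth_quintile"], errors="coerce"
    ).astype("Int64")

    pairs = list(zip(raw["survey_id"], raw["place_code"]))
    out["place"] = [mapping.place_category(s, c) for s, c in pairs]
    unmapped = raw.loc[[p == MISSING for p in out["place"]], "place_code"]
    unmapped = unmapped[unmapped.str.strip() != ""]
    if len(unmapped):
        logger.warning("unmapped place codes recoded to missing: %s",
                       sorted(unmapped.unique()))
    out["sba"] = [
        mapping.attendant_category(s, c)
        for s, c in zip(raw["survey_id"], raw["attendant_code"])
    ]

    stay_hours = _duration_hours(raw["stay_value"], raw["stay_unit"],
                                 mapping.unit_hours, "stay")
    out["stay24"] = _threshold(stay_hours, mapping.stay_cutoff_hours,
                               mapping.stay_cutoff_inclusive)

    pnc_none = raw["pnc_value"].str.strip().str.lower() == "none"
    pnc_hours = _duration_hours(raw["pnc_value"].where(~pnc_none, ""),
                                raw["pnc_unit"], mapping.unit_hours, "pnc")
    meets = pnc_hours <= mapping.pnc_cutoff_hours if mapping.pnc_cutoff_inclusive \
        else pnc_hours < mapping.pnc_cutoff_hours
    out["pnc48"] = pd.Series(
        np.where(pnc_none, NO, np.where(pnc_hours.notna(),
                                        np.where(meets, YES, NO), MISSING)),
        index=raw.index, dtype=object)

    # No facility stay without a facility birth: structural zero.
    inconsistent = (out["place"] == PLACE_HOME) & (out["stay24"] == YES)
    if inconsistent.any():
        logger.warning(
            "%d home births reported a qualifying facility stay; recoded to no",
            int(inconsistent.sum()),
        )
    out.loc[out["place"] == PLACE_HOME, "stay24"] = out.loc[
        out["place"] == PLACE_HOME, "stay24"
    ].replace(YES, NO)

    out["months_since_birth"] = pd.to_numeric(
        raw["months_since_birth"], errors="coerce"
    )
    return out[WOMAN_COLUMNS + ["months_since_birth"]]


class FilterResult(NamedTuple):
    records: pd.DataFrame
    n_kept: int
    n_dropped: int


def filter_eligible(
    records: pd.DataFrame, months_col: str = "months_since_birth",
    window_months: int = 24,
) -> FilterResult:
    """Keep women whose most recent birth was within the last two years.

    The boundary is strict (``months < 24``); records with negative or
    missing months are dropped with a warning.  Idempotent.
    """
    months = pd.to_numeric(records[months_col], errors="coerce")
    negative = months < 0
    if negative.any():
        logger.warning("%d records with negative months_since_birth dropped",
                       int(negative.sum()))
    keep = (months >= 0) & (months < window_months)
    kept = records.loc[keep].reset_index(drop=True)
    return FilterResult(kept, int(keep.sum()), int(len(records) - keep.sum()))


class DropStrataResult(NamedTuple):
    records: pd.DataFrame
    dropped_strata: list[tuple[str, str]]


def drop_single_psu_strata(records: pd.DataFrame) -> DropStrataResult:
    """Remove strata in which only one PSU was sampled.

    Variance estimation resamples PSUs within strata, which requires at
    least two PSUs per (country, stratum) cell; singleton strata are
    removed wholesale and reported.
    """
    if records.empty:
        return DropStrataResult(records.copy(), [])
    n_psu = records.groupby(["country_id", "stratum"])["psu"].nunique()
    single = n_psu[n_psu < 2].index
    if len(single):
        logger.warning("dropping %d single-PSU strata: %s",
                       len(single), list(single))
    if len(single) == len(n_psu):
        logger.warning("all strata are single-PSU; output is empty")
    key = pd.MultiIndex.from_frame(records[["country_id", "stratum"]])
    kept = records.loc[~key.isin(single)].reset_index(drop=True)
    return DropStrataResult(kept, list(single))
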