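"""Harmonized woman-level record schema shared by all pipeline stages.

One row = one woman aged 15-49 whose most recent live birth occurred in the
two years before the survey.  Every stage downstream of harmonization
consumes exactly these columns; the synthetic generator emits them directly.

Columns
-------
country_id : str
    Survey/country identifier.
stratum : str
    Design stratum (e.g. region x urban/rural).
psu : str
    Primary sampling unit (cluster) within the stratum.
weight : float > 0
    Sampling weight.  By convention weights sum to the country sample size
    within each country; pooling relies on this (see
    :func:`delivcare.estimation.pooled_weights`).
wealth_quintile : int 1-5, nullable
    Household wealth quintile (1 = poorest, 5 = richest).
place : {"home", "lower", "hospital", "missing"}
    Place of delivery; private hospitals/clinics are harmonized to
    "hospital", other facilities to "lower".
sba : {"yes", "no", "missing"}
    Skilled attendant at birth (country definition).
stay24 : {"yes", "no", "missing"}
    Facility stay of 24 or more hours after delivery.  Structurally "no"
    for home births.
pnc48 : {"yes", "no", "missing"}
    First postnatal health check within 48 hours of delivery.
"""

from __future__ import annotations

import pandas as pd

PLACE_HOME = "home"
PLACE_LOWER = "lower"
PLACE_HOSPITAL = "hospital"
MISSING = "missing"
YES = "yes"
NO = "no"

PLACE_CATEGORIES = (PLACE_HOME, PLACE_LOWER, PLACE_HOSPITAL, MISSING)
BINARY_CATEGORIES = (YES, NO, MISSING)
FACILITY_PLACES = (PLACE_LOWER, PLACE_HOSPITAL)

DESIGN_COLUMNS = ["country_id", "stratum", "psu", "weight", "wealth_quintile"]
COMPONENT_COLUMNS = ["place", "sba", "stay24", "pnc48"]
WOMAN_COLUMNS = DESIGN_COLUMNS + COMPONENT_COLUMNS


def validate_woman_table(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` if ``df`` is not a valid harmonized woman table."""
    missing_cols = [c for c in WOMAN_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"woman table missing columns: {missing_cols}")
    if len(df) and (df["weight"] <= 0).any():
        raise ValueError("weights must be strictly positive")
    bad_place = set(df["place"].unique()) - set(PLACE_CATEGORIES)
    if bad_place:
        raise ValueError(f"unrecognized place categories: {sorted(bad_place)}")
    for col in ("sba", "stay24", "pnc48"):
        bad = set(df[col].unique()) - set(BINARY_CATEGORIES)
        if bad:
            raise ValueError(f"unrecognized {col} categories: {sorted(bad)}")


def is_facility(place: pd.Series) -> pd.Series:
    """Boolean mask: delivery took place in any health facility."""
    return place.isin(FACILITY_PLACES)
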