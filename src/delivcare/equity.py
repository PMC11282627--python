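"""Wealth-equity gaps in delivery-care coverage.

Two gap families:

* the Q5-Q1 gap — weighted delivery-care coverage among the richest
  quintile minus the poorest, per country, averaged (unweighted across
  countries) within obstetric-transition MMR phases;
* the facility-vs-care gap — facility-delivery coverage minus
  delivery-care coverage per country.  Positive gaps mean facility births
  miss other components; negative gaps arise where home births are
  attended by skilled personnel or receive postnatal checks.

Records with a missing wealth quintile contribute to coverage estimates
but are excluded from quintile gaps; a country missing quintile 1 or 5
entirely is flagged and excluded from phase averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import weighted_coverage
from .mmr_association import PHASE_LABELS, assign_phases

Q_POOREST = 1
Q_RICHEST = 5


@dataclass
class GapResult:
    country_id: str
    gap_pp: float
    first: float   # Q5 coverage, or facility-delivery coverage
    second: float  # Q1 coverage, or delivery-care coverage

    def __post_init__(self) -> None:
        if abs(self.gap_pp - (self.first - self.second)) > 1e-9:
            raise ValueError("gap must equal first - second")


def quintile_gap(records: pd.DataFrame, country_id: str = "") -> GapResult:
    """Richest-minus-poorest gap in delivery-care coverage, one country."""
    cid = country_id or str(records["country_id"].iloc[0])
    parts = {}
    for q in (Q_RICHEST, Q_POOREST):
        # nullable quintiles: a missing quintile never matches
        mask = (records["wealth_quintile"] == q).fillna(False).astype(bool)
        sub = records.loc[mask]
        if sub.empty:
            raise ValueError(f"country {cid}: wealth quintile {q} absent")
        parts[q] = weighted_coverage(sub, "delivery_care", country_id=cid).point
    return GapResult(cid, parts[Q_RICHEST] - parts[Q_POOREST],
                     parts[Q_RICHEST], parts[Q_POOREST])


def quintile_gaps(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-country Q5-Q1 gap table; countries lacking a quintile flagged.

    Flagged countries carry NaN gaps and are excluded from phase averages.
    """
    rows = []
    for cid, grp in scored.groupby("country_id", sort=True):
        try:
            g = quintile_gap(grp, str(cid))
            rows.append({"country_id": cid, "gap_pp": g.gap_pp,
                         "q5": g.first, "q1": g.second, "flagged": False})
        except ValueError:
            rows.append({"country_id": cid, "gap_pp": np.nan,
                         "q5": np.nan, "q1": np.nan, "flagged": True})
    return pd.DataFrame(rows)


def phase_average_gap(
    gaps: pd.DataFrame, mmr: pd.DataFrame, absolute: bool = False
) -> pd.Series:
    """Unweighted mean country gap per MMR phase.

    Signed gaps by default (richest minus poorest); ``absolute=True``
    averages absolute gaps instead.  Phases with no contributing country
    are absent from the result, never reported as zero.
    """
    phases = assign_phases(mmr)
    merged = gaps.loc[~gaps["flagged"]].merge(
        phases[["country_id", "phase"]], on="country_id", how="left"
    )
    unknown = merged.loc[merged["phase"].isna(), "country_id"].tolist()
    if unknown:
        raise ValueError(f"countries missing from MMR table: {unknown}")
    vals = merged["gap_pp"].abs() if absolute else merged["gap_pp"]
    means = vals.groupby(merged["phase"]).mean()
    order = [p for p in PHASE_LABELS if p in means.index]
    return means.loc[order].rename("mean_gap_pp")


def facility_vs_care_gap(records: pd.DataFrame, country_id: str = "") -> GapResult:
    """Facility-delivery coverage minus delivery-care coverage, one country."""
    cid = country_id or str(records["country_id"].iloc[0])
    fac = weighted_coverage(records, "facility", country_id=cid).point
    care = weighted_coverage(records, "delivery_care", country_id=cid).point
    return GapResult(cid, fac - care, fac, care)


def facility_vs_care_gaps(scored: pd.DataFrame) -> pd.DataFrame:
    rows = [
        {"country_id": cid,
         "facility": (g := facility_vs_care_gap(grp, str(cid))).first,
         "delivery_care": g.second, "gap_pp": g.gap_pp}
        for cid, grp in scored.groupby("country_id", sort=True)
    ]
    return pd.DataFrame(rows)
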