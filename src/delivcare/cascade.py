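"""Effective-coverage cascades for delivery care.

The cascade tracks the population in need (women with a live birth in the
two years before the survey) through four successively conjoined
conditions:

1. population in need (100% by definition);
2. delivered in a facility;
3. ... with a skilled attendant;
4. ... and stayed in the facility 24+ hours;
5. ... and had a postnatal health check within 48 h.

Every level is a weighted percentage of the population in need (never of
the previous bar), so bars are monotone non-increasing and drop-offs read
directly as percentage-point losses.  Missing component responses fail
their condition, consistent with missing-as-zero scoring.

Stratified variants rebase the denominator within stratum: facility-type
cascades are computed among hospital (or lower-level) births only, and
MMR-phase cascades pool the countries of a phase with inverse-proportion
country weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import pooled_weights
from .records import PLACE_HOSPITAL, PLACE_LOWER, YES, is_facility
from .mmr_association import assign_phases

CASCADE_LEVELS = [
    "population_in_need",
    "facility",
    "facility_sba",
    "facility_sba_stay24",
    "facility_sba_stay24_pnc48",
]


@dataclass
class CascadeResult:
    """Five nested coverage levels, percent of the population in need."""

    stratum: str
    levels: np.ndarray  # shape (5,)
    n: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (5,):
            raise ValueError("a cascade has exactly five levels")
        if not np.isclose(self.levels[0], 100.0):
            raise ValueError("population in need must be 100%")
        if np.any(np.diff(self.levels) > 1e-9):
            raise ValueError("cascade levels must be monotone non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum": self.stratum,
            "level": CASCADE_LEVELS,
            "percent": self.levels,
        })


def _conditions(records: pd.DataFrame) -> np.ndarray:
    """Stacked boolean conditions, shape (4, n): facility, sba, stay, pnc."""
    return np.vstack([
        is_facility(records["place"]).to_numpy(),
        (records["sba"] == YES).to_numpy(),
        (records["stay24"] == YES).to_numpy(),
        (records["pnc48"] == YES).to_numpy(),
    ])


def build_cascade(
    records: pd.DataFrame,
    weights: np.ndarray | None = None,
    stratum: str = "pooled",
) -> CascadeResult:
    """Cascade over ``records`` with optional explicit weights."""
    if records.empty:
        raise ValueError("cannot build a cascade for an empty population")
    w = records["weight"].to_numpy(float) if weights is None else np.asarray(weights, float)
    conds = _conditions(records)
    nested = np.cumprod(conds, axis=0).astype(float)
    levels = np.concatenate(([1.0], nested @ w / w.sum())) * 100.0
    return CascadeResult(stratum, levels, len(records))


def stratify_cascade(
    records: pd.DataFrame,
    stratifier: str,
    mmr: pd.DataFrame | None = None,
) -> dict[str, CascadeResult]:
    """Cascades per stratum of ``stratifier``.

    ``facility_type`` restricts to facility births and rebases each
    cascade within the hospital / lower-level stratum (levels 1 and 2 are
    then 100 by construction).  ``mmr_phase`` requires the country MMR
    table, assigns obstetric-transition phases, and pools the countries of
    each phase with inverse-proportion weights.  ``country`` produces one
    cascade per country.
    """
    if stratifier == "facility_type":
        out = {}
        for place in (PLACE_LOWER, PLACE_HOSPITAL):
            sub = records.loc[records["place"] == place]
            if len(sub):
                out[place] = build_cascade(sub, stratum=place)
        return out
    if stratifier == "country":
        return {
            str(cid): build_cascade(grp, stratum=str(cid))
            for cid, grp in records.groupby("country_id", sort=True)
        }
    if stratifier == "mmr_phase":
        if mmr is None:
            raise ValueError("mmr_phase stratification requires the MMR table")
        phases = assign_phases(mmr)
        absent = sorted(set(records["country_id"]) - set(phases["country_id"]))
        if absent:
            raise ValueError(f"countries missing from MMR table: {absent}")
        phase_of = dict(zip(phases["country_id"], phases["phase"]))
        rec = records.assign(_phase=records["country_id"].map(phase_of))
        out = {}
        for phase, grp in rec.groupby("_phase", sort=False):
            w = pooled_weights(grp)
            out[str(phase)] = build_cascade(grp, weights=w, stratum=str(phase))
        return out
    raise ValueError(f"unknown stratifier {stratifier!r}")


def cascades_to_frame(cascades: dict[str, CascadeResult]) -> pd.DataFrame:
    """Long-format table (stratum, level, percent) for CSV output."""
    if not cascades:
        return pd.DataFrame(columns=["stratum", "level", "percent"])
    return pd.concat([c.to_frame() for c in cascades.values()], ignore_index=True)
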