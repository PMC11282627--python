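"""Additive delivery-care score.

Each woman's score sums four component point assignments:

=======================  =========================  ======
Component                Category                   Points
=======================  =========================  ======
Facility delivery type   hospital                   2
                         lower-level facility       1
                         home                       0
Skilled attendant        skilled                    1
                         unskilled                  0
Facility stay            24+ hours                  1
                         < 24 h                     0
First postnatal care     within 48 h of delivery    1
                         later / none               0
=======================  =========================  ======

Totals range 0-5 and are rescaled to 0-100 (total x 20) so the weighted
mean can be read as quality-approximating coverage.  A missing component
response scores zero: a woman is assumed not to have received an
intervention she did not report (missing-as-zero imputation at the
component level, never record exclusion).  An audit column records how
many components were imputed per record.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .records import (
    COMPONENT_COLUMNS,
    PLACE_CATEGORIES,
    PLACE_HOSPITAL,
    PLACE_LOWER,
    YES,
    validate_woman_table,
)

PLACE_POINTS = {PLACE_HOSPITAL: 2, PLACE_LOWER: 1}
MAX_SCORE = 5
RESCALE = 100 / MAX_SCORE

SCORE_COLUMNS = [
    "place_points",
    "sba_points",
    "stay_points",
    "pnc_points",
    "score",
    "rescaled",
    "n_imputed",
]


class ComponentScores(NamedTuple):
    place_points: int
    sba_points: int
    stay_points: int
    pnc_points: int


def score_components(place: str, sba: str, stay24: str, pnc48: str) -> ComponentScores:
    """Component points for one harmonized record.

    Missing categories score zero.  Raises ``ValueError`` on categories a
    harmonized record cannot carry.
    """
    if place not in PLACE_CATEGORIES:
        raise ValueError(f"unrecognized place category: {place!r}")
    for name, val in (("sba", sba), ("stay24", stay24), ("pnc48", pnc48)):
        if val not in ("yes", "no", "missing"):
            raise ValueError(f"unrecognized {name} category: {val!r}")
    return ComponentScores(
        place_points=PLACE_POINTS.get(place, 0),
        sba_points=int(sba == YES),
        stay_points=int(stay24 == YES),
        pnc_points=int(pnc48 == YES),
    )


def total_score(components: ComponentScores) -> tuple[int, float]:
    """(total 0-5, rescaled 0-100) for one set of component points."""
    total = sum(components)
    return total, total * RESCALE


def score_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scorer: append component points, total and rescaled value.

    Returns a copy of ``records`` with the :data:`SCORE_COLUMNS` appended.
    ``n_imputed`` counts components answered "missing" (hence imputed as
    zero) for each record.
    """
    validate_woman_table(records)
    out = records.copy()
    place = records["place"]
    out["place_points"] = place.map(PLACE_POINTS).fillna(0).astype(int)
    out["sba_points"] = (records["sba"] == YES).astype(int)
    out["stay_points"] = (records["stay24"] == YES).astype(int)
    out["pnc_points"] = (records["pnc48"] == YES).astype(int)
    out["score"] = (
        out["place_points"] + out["sba_points"] + out["stay_points"] + out["pnc_points"]
    )
    out["rescaled"] = out["score"] * RESCALE
    out["n_imputed"] = sum(
        (records[c] == "missing").astype(int) for c in COMPONENT_COLUMNS
    )
    return out


def imputation_audit(scored: pd.DataFrame) -> dict[str, int]:
    """How many records had at least one component imputed as zero."""
    n_any = int((scored["n_imputed"] > 0).sum())
    return {"n_records": len(scored), "n_with_imputed_component": n_any,
            "n_imputed_components": int(scored["n_imputed"].sum())}
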