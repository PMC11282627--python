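"""Shared fixtures and independent oracles for the delivcare suite."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from delivcare import GeneratorConfig, generate_population, score_table

PLACES = ["home", "lower", "hospital", "missing"]
BINARY = ["yes", "no", "missing"]

#: Full cross-product of harmonized component categories.
ALL_COMPONENT_COMBOS = list(itertools.product(PLACES, BINARY, BINARY, BINARY))


def brute_force_score(place: str, sba: str, stay24: str, pnc48: str) -> int:
    """Independent per-record scorer: literal category-by-category lookup.

    Kept deliberately naive (chained ifs, no shared tables) so it cannot
    inherit a defect from the vectorized implementation.
    """
    total = 0
    if place == "hospital":
        total += 2
    elif place == "lower":
        total += 1
    if sba == "yes":
        total += 1
    if stay24 == "yes":
        total += 1
    if pnc48 == "yes":
        total += 1
    return total


def make_women(rows, country_id="C00", weight=1.0) -> pd.DataFrame:
    """Harmonized woman table from (place, sba, stay24, pnc48[, quintile]) rows."""
    recs = []
    for i, row in enumerate(rows):
        q = row[4] if len(row) > 4 else (i % 5) + 1
        recs.append({
            "country_id": country_id,
            "stratum": f"S{i % 2}",
            "psu": f"P{i % 4}",
            "weight": weight,
            "wealth_quintile": q,
            "place": row[0], "sba": row[1], "stay24": row[2], "pnc48": row[3],
        })
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def study_population():
    """Default study conditions: 71 countries, stratified two-stage design."""
    cfg = GeneratorConfig(seed=20_240)
    women, truth = generate_population(cfg)
    return cfg, women, truth


@pytest.fixture(scope="session")
def study_scored(study_population):
    cfg, women, truth = study_population
    return cfg, score_table(women), truth
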