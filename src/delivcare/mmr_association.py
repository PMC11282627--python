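"""Maternal mortality ratio: obstetric-transition phases and the linear
association with delivery-care coverage.

Countries are grouped by MMR (maternal deaths per 100,000 live births)
into the five obstetric-transition phases >=700, 300-699, 100-299, 20-99
and <20.  The bands are half-open on the real line — [700, inf), [300,
700), [100, 300), [20, 100), [0, 20) — so every non-negative MMR belongs
to exactly one phase; a non-integer value between two printed ranges
(e.g. 699.5) falls in the lower-mortality band by this rule.

The cross-country association is an ordinary least-squares fit of MMR on
delivery-care coverage (0-100 scale): the slope is deaths per 100,000
live births per percentage point of coverage, unweighted across
countries, with heteroskedasticity-robust (HC1) standard errors reported
as auxiliary output.  No causal interpretation is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

PHASE_LABELS = [">=700", "300-699", "100-299", "20-99", "<20"]
_PHASE_LOWER_BOUNDS = [700.0, 300.0, 100.0, 20.0, 0.0]


def assign_phase(mmr: float) -> str:
    """Obstetric-transition phase for one MMR value."""
    if mmr < 0 or not np.isfinite(mmr):
        raise ValueError(f"MMR must be finite and >= 0, got {mmr}")
    for label, low in zip(PHASE_LABELS, _PHASE_LOWER_BOUNDS):
        if mmr >= low:
            return label
    raise AssertionError("unreachable: phase bands partition [0, inf)")


def assign_phases(mmr: pd.DataFrame) -> pd.DataFrame:
    """MMR table (country_id, mmr) with a ``phase`` column appended."""
    out = mmr.copy()
    out["phase"] = [assign_phase(v) for v in out["mmr"].astype(float)]
    return out


@dataclass
class RegressionFit:
    slope: float            # deaths per 100,000 per coverage percentage point
    intercept: float
    r_squared: float
    n_countries: int
    slope_se: float
    slope_se_robust: float
    slope_ci_low: float
    slope_ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    @property
    def slope_per_10pp(self) -> float:
        """Slope expressed per 10 percentage points of coverage."""
        return self.slope * 10.0


def fit_linear(countries: pd.DataFrame) -> RegressionFit:
    """OLS of ``mmr`` on ``coverage`` across countries.

    ``countries`` needs columns ``coverage`` (0-100) and ``mmr``.  Raises
    on fewer than 3 countries or a degenerate (constant-coverage) design.
    """
    cov = countries["coverage"].to_numpy(float)
    mmr = countries["mmr"].to_numpy(float)
    if len(cov) < 3:
        raise ValueError("need at least 3 countries to fit the association")
    if np.ptp(cov) == 0:
        raise ValueError("coverage is constant; the linear fit is degenerate")
    res = sm.OLS(mmr, sm.add_constant(cov)).fit()
    robust = res.get_robustcov_results(cov_type="HC1")
    ci = res.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_countries=len(cov),
        slope_se=float(res.bse[1]),
        slope_se_robust=float(robust.bse[1]),
        slope_ci_low=float(ci[1, 0]),
        slope_ci_high=float(ci[1, 1]),
    )
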