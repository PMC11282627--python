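"""Survey-weighted coverage estimation.

Point estimates are weighted percentages; for the composite delivery-care
indicator the per-woman value is the rescaled score divided by 100, so
coverage is the weighted mean score on the 0-100 scale.  Confidence
intervals use a stratified cluster bootstrap with Rao-Wu rescaling
(resample m-1 of the m PSUs in each stratum with replacement, scale
weights by m/(m-1), percentile interval), chosen over Taylor
linearization for transparency; point estimates do not depend on the
variance method.

Pooling across countries uses the inverse proportion of women each
country contributes as a multiplicative adjustment weight, after
normalizing within-country weights to sum to the country sample size.
Under that convention the pooled estimate is exactly the unweighted mean
of the country estimates, and is invariant to replicating any country's
records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import FACILITY_PLACES, YES
from .scoring import MAX_SCORE

#: Indicators resolvable by name on a scored woman table.
INDICATORS = (
    "delivery_care",
    "facility",
    "hospital",
    "lower",
    "home",
    "sba",
    "stay24",
    "pnc48",
    "score5",
)


@dataclass
class CoverageEstimate:
    country_id: str
    indicator: str
    point: float
    ci_low: float | None
    ci_high: float | None
    n: int
    weight_sum: float

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (
            self.ci_low - 1e-9 <= self.point <= self.ci_high + 1e-9
        ):
            raise ValueError("confidence interval does not bracket the point")


def indicator_values(scored: pd.DataFrame, indicator: str) -> np.ndarray:
    """Per-woman indicator value in [0, 1].

    Binary indicators are membership indicators; ``delivery_care`` is the
    rescaled score / 100.  Missing component responses count as not
    received, consistent with missing-as-zero scoring.
    """
    if indicator == "delivery_care":
        return scored["rescaled"].to_numpy(float) / 100.0
    if indicator == "facility":
        return scored["place"].isin(FACILITY_PLACES).to_numpy(float)
    if indicator in ("hospital", "lower", "home"):
        return (scored["place"] == indicator).to_numpy(float)
    if indicator in ("sba", "stay24", "pnc48"):
        return (scored[indicator] == YES).to_numpy(float)
    if indicator == "score5":
        return (scored["score"] == MAX_SCORE).to_numpy(float)
    if indicator in scored.columns:
        vals = scored[indicator].to_numpy(float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"column {indicator!r} is not a [0,1] indicator")
        return vals
    raise KeyError(f"unknown indicator {indicator!r}")


def weighted_coverage(
    scored: pd.DataFrame,
    indicator: str,
    weight_col: str = "weight",
    country_id: str = "",
) -> CoverageEstimate:
    """Weighted percentage of women covered by ``indicator``."""
    if scored.empty:
        raise ValueError("cannot estimate coverage from an empty table")
    w = scored[weight_col].to_numpy(float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    y = indicator_values(scored, indicator)
    point = float(w @ y / wsum * 100.0)
    return CoverageEstimate(country_id or _single_country(scored), indicator,
                            point, None, None, len(scored), float(wsum))


def _single_country(scored: pd.DataFrame) -> str:
    ids = scored["country_id"].unique() if "country_id" in scored.columns else []
    return str(ids[0]) if len(ids) == 1 else "ALL"


def bootstrap_ci(
    scored: pd.DataFrame,
    indicator: str,
    b: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    weight_col: str = "weight",
) -> tuple[float, float]:
    """Stratified cluster-bootstrap percentile interval for the coverage.

    Within each stratum of m PSUs, each replicate draws m-1 PSUs with
    replacement and rescales their weights by m/(m-1) (Rao-Wu), so the
    replicate weight totals are unbiased for the stratum total.  Requires
    at least two PSUs per stratum (guaranteed after dropping single-PSU
    strata).  Deterministic given ``seed``.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    y = indicator_values(scored, indicator)
    w = scored[weight_col].to_numpy(float)
    # Collapse to PSU totals: the estimate is a ratio of stratum-summable totals.
    key = scored["stratum"].astype(str) + "\x1f" + scored["psu"].astype(str)
    psu_tab = pd.DataFrame({
        "stratum": scored["stratum"].astype(str).to_numpy(),
        "key": key.to_numpy(),
        "wy": w * y,
        "w": w,
    }).groupby(["stratum", "key"], sort=True)[["wy", "w"]].sum().reset_index()

    rng = np.random.default_rng(seed)
    num = np.zeros(b)
    den = np.zeros(b)
    for _, grp in psu_tab.groupby("stratum", sort=True):
        m = len(grp)
        if m < 2:
            raise ValueError(
                f"stratum {grp['stratum'].iat[0]!r} has a single PSU; "
                "drop single-PSU strata before bootstrapping"
            )
        idx = rng.integers(0, m, size=(b, m - 1))
        scale = m / (m - 1)
        wy = grp["wy"].to_numpy()
        wv = grp["w"].to_numpy()
        num += scale * wy[idx].sum(axis=1)
        den += scale * wv[idx].sum(axis=1)
    est = num / den * 100.0
    lo, hi = np.percentile(est, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def estimate_with_ci(
    scored: pd.DataFrame, indicator: str, b: int = 1000,
    seed: int | None = None, alpha: float = 0.05,
) -> CoverageEstimate:
    est = weighted_coverage(scored, indicator)
    lo, hi = bootstrap_ci(scored, indicator, b=b, seed=seed, alpha=alpha)
    # Percentile intervals can sit fractionally off the point estimate in
    # tiny samples; clamp to keep the bracket invariant.
    est.ci_low, est.ci_high = min(lo, est.point), max(hi, est.point)
    return est


def pooled_weights(scored: pd.DataFrame, weight_col: str = "weight") -> np.ndarray:
    """Adjusted weights giving every country equal pooled contribution.

    Within-country weights are renormalized to sum to the country sample
    size n_c, then multiplied by the inverse proportion of women the
    country contributes (N / n_c).  Every country's adjusted weights then
    sum to N.
    """
    w = scored[weight_col].to_numpy(float)
    n_total = len(scored)
    grouped = scored.groupby("country_id", sort=False)
    n_c = grouped["country_id"].transform("size").to_numpy(float)
    wsum_c = grouped[weight_col].transform("sum").to_numpy(float)
    return w * (n_c / wsum_c) * (n_total / n_c)


def pooled_estimate(
    scored: pd.DataFrame, indicator: str, weight_col: str = "weight"
) -> CoverageEstimate:
    """Inverse-proportion-weighted pooled coverage across countries."""
    if scored.empty:
        raise ValueError("cannot pool an empty table")
    adj = pooled_weights(scored, weight_col)
    y = indicator_values(scored, indicator)
    point = float(adj @ y / adj.sum() * 100.0)
    return CoverageEstimate("POOLED", indicator, point, None, None,
                            len(scored), float(adj.sum()))


def country_estimates(
    scored: pd.DataFrame, indicator: str, b: int = 0, seed: int | None = None,
) -> pd.DataFrame:
    """Per-country coverage table; bootstrap CIs when ``b > 0``."""
    rows = []
    rng = np.random.default_rng(seed)
    for cid, grp in scored.groupby("country_id", sort=True):
        if b:
            est = estimate_with_ci(grp, indicator, b=b,
                                   seed=int(rng.integers(2**31)))
        else:
            est = weighted_coverage(grp, indicator, country_id=str(cid))
        rows.append({"country_id": cid, "indicator": indicator,
                     "point": est.point,
                     "ci_low": np.nan if est.ci_low is None else est.ci_low,
                     "ci_high": np.nan if est.ci_high is None else est.ci_high,
                     "n": est.n})
    return pd.DataFrame(rows)


def country_summary(points: "pd.Series | np.ndarray | list[float]") -> tuple[float, float, float]:
    """(median, q1, q3) of country point estimates, countries unweighted.

    Quantiles use linear interpolation.
    """
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("no country estimates to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def score_distribution(
    scored: pd.DataFrame, weight_col: str = "weight"
) -> pd.Series:
    """Weighted proportion of births at each score 0-5 (sums to 1)."""
    w = scored[weight_col].to_numpy(float)
    counts = np.bincount(scored["score"].to_numpy(int), weights=w,
                         minlength=MAX_SCORE + 1)
    props = counts / counts.sum()
    return pd.Series(props, index=pd.RangeIndex(MAX_SCORE + 1, name="score"),
                     name="proportion")
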