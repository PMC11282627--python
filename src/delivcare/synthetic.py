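"""Synthetic multi-country household-survey microdata.

Emulates the structure of DHS/MICS delivery-care data: a stratified
two-stage cluster sample per country, four intervention responses per woman
(place of delivery, skilled attendant, 24+ hour facility stay, postnatal
check within 48 h), a wealth gradient in facility delivery, item
missingness, and a country-level maternal mortality ratio (MMR) linked
linearly to true delivery-care coverage.

The response model is hierarchical: facility delivery is drawn from a
logistic model in wealth quintile, the remaining components are drawn
conditionally on facility status (hospital vs lower-level facility only
among facility births; a 24+ hour facility stay is structurally impossible
for home births; skilled attendance and postnatal checks have separate
facility/home probabilities, so home births can still be attended or
checked).  Conditioning on facility status is what produces the cascade's
drop-off structure; richer dependence (e.g. a latent copula) is an
extension point, not implemented.

All closed-form expectations used by tests are computed by
:func:`compute_truth` from the same configuration, never from the drawn
sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .records import (
    MISSING,
    NO,
    PLACE_HOME,
    PLACE_HOSPITAL,
    PLACE_LOWER,
    WOMAN_COLUMNS,
    YES,
)

_PROB_FIELDS = (
    "p_facility",
    "p_hospital_given_facility",
    "p_sba_given_facility",
    "p_sba_given_home",
    "p_stay24_given_facility",
    "p_pnc48_given_facility",
    "p_pnc48_given_home",
)

QUINTILES = np.arange(1, 6)


def _default_p_facility(n_countries: int) -> np.ndarray:
    """Deterministic per-country facility-delivery probabilities.

    Quantiles of a Beta(3.8, 1.2) distribution (mean 0.76), giving a
    left-skewed spread from roughly 0.25 to 0.99 across countries — a
    pooled facility-delivery level of about 76% with wide between-country
    variation, as observed in multi-country survey compilations.
    """
    grid = (np.arange(n_countries) + 0.5) / n_countries
    return beta_dist.ppf(grid, 3.8, 1.2)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Defaults describe the study conditions the package is exercised under:
    71 countries, a stratified two-stage design with 8 strata x 4 PSUs per
    country, component probabilities whose pooled values sit near the
    levels typical of DHS/MICS delivery care (facility ~76%, skilled
    attendance ~78%, 24+ h stay ~68%, postnatal check ~91%), a positive
    wealth gradient in facility delivery, 3% item missingness, and an MMR
    declining by 8 deaths per 100,000 live births per percentage point of
    delivery-care coverage.
    """

    n_countries: int = 71
    women_per_country: int | Sequence[int] = 600
    n_strata_per_country: int = 8
    n_psu_per_stratum: int = 4
    p_facility: float | Sequence[float] | None = None
    p_hospital_given_facility: float | Sequence[float] = 0.5
    p_sba_given_facility: float | Sequence[float] = 0.987
    p_sba_given_home: float | Sequence[float] = 0.125
    p_stay24_given_facility: float | Sequence[float] = 0.895
    p_pnc48_given_facility: float | Sequence[float] = 0.93
    p_pnc48_given_home: float | Sequence[float] = 0.85
    wealth_gradient: float = 0.5
    missingness_rate: float = 0.03
    psu_effect_sd: float = 0.0
    mmr_intercept: float = 900.0
    mmr_slope: float = -8.0
    mmr_noise_sd: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be a positive integer")
        if self.n_strata_per_country < 1:
            raise ValueError("n_strata_per_country must be a positive integer")
        if self.n_psu_per_stratum < 2:
            raise ValueError("n_psu_per_stratum must be >= 2")
        if self.p_facility is None:
            self.p_facility = _default_p_facility(self.n_countries)
        for name in _PROB_FIELDS:
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
            if vals.size not in (1, self.n_countries):
                raise ValueError(
                    f"{name} must be a scalar or length-{self.n_countries} sequence"
                )
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must lie in [0, 1)")
        if self.psu_effect_sd < 0:
            raise ValueError("psu_effect_sd must be >= 0")
        if self.mmr_intercept < 0:
            raise ValueError("mmr_intercept must be >= 0")
        if self.mmr_noise_sd < 0:
            raise ValueError("mmr_noise_sd must be >= 0")
        n = np.atleast_1d(np.asarray(self.women_per_country))
        if np.any(n < 1) or n.size not in (1, self.n_countries):
            raise ValueError(
                "women_per_country must be positive, scalar or per-country"
            )

    def per_country(self, name: str) -> np.ndarray:
        """Value of a (possibly scalar) field broadcast to one per country."""
        vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
        if vals.size == 1:
            vals = np.repeat(vals, self.n_countries)
        return vals

    def country_sizes(self) -> np.ndarray:
        n = np.atleast_1d(np.asarray(self.women_per_country, dtype=int))
        if n.size == 1:
            n = np.repeat(n, self.n_countries)
        return n

    def country_ids(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def facility_prob_by_quintile(config: GeneratorConfig) -> np.ndarray:
    """P(facility delivery | quintile q), shape (n_countries, 5).

    logit P = b + wealth_gradient * (q - 3), with the base log-odds ``b``
    solved per country so that the quintile-marginal probability (uniform
    quintile distribution) equals the configured ``p_facility`` exactly.
    The configured value is therefore the country's facility-delivery
    coverage, not a single quintile's probability.
    """
    p = config.per_country("p_facility")
    shift = config.wealth_gradient * (QUINTILES - 3)
    if config.wealth_gradient == 0:
        return np.repeat(p[:, None], 5, axis=1)
    # Bisection on the base log-odds: mean_q expit(b + shift_q) is strictly
    # increasing in b, so the root is unique.
    lo = np.full_like(p, -40.0)
    hi = np.full_like(p, 40.0)
    for _ in range(80):
        mid = (lo + hi) / 2
        marg = expit(mid[:, None] + shift[None, :]).mean(axis=1)
        too_low = marg < p
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    base = (lo + hi) / 2
    out = expit(base[:, None] + shift[None, :])
    # Degenerate coverages have no finite base logit.
    out[p == 0.0] = 0.0
    out[p == 1.0] = 1.0
    return out


def expected_components(
    config: GeneratorConfig, p_fac: np.ndarray | None = None
) -> pd.DataFrame:
    """Closed-form component coverages implied by the hierarchical model.

    ``p_fac`` defaults to the quintile-marginal facility probability
    (uniform quintile distribution).  Probabilities are pre-missingness.
    """
    if p_fac is None:
        p_fac = facility_prob_by_quintile(config).mean(axis=1)
    p_hosp = config.per_country("p_hospital_given_facility")
    out = pd.DataFrame({"country_id": config.country_ids()})
    out["p_facility"] = p_fac
    out["p_hospital"] = p_fac * p_hosp
    out["p_lower"] = p_fac * (1 - p_hosp)
    out["p_sba"] = p_fac * config.per_country("p_sba_given_facility") + (
        1 - p_fac
    ) * config.per_country("p_sba_given_home")
    out["p_stay24"] = p_fac * config.per_country("p_stay24_given_facility")
    out["p_pnc48"] = p_fac * config.per_country("p_pnc48_given_facility") + (
        1 - p_fac
    ) * config.per_country("p_pnc48_given_home")
    return out


def _mean_rescaled(components: pd.DataFrame, missingness_rate: float) -> np.ndarray:
    # Each component is independently blanked (and scored zero) with
    # probability missingness_rate, so expectations scale by (1 - rate).
    keep = 1.0 - missingness_rate
    return (
        20.0
        * keep
        * (
            2 * components["p_hospital"]
            + components["p_lower"]
            + components["p_sba"]
            + components["p_stay24"]
            + components["p_pnc48"]
        )
    ).to_numpy()


def compute_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Per-country closed-form truth table.

    Columns: marginal component coverages, ``mean_rescaled`` (the true mean
    delivery-care score on the 0-100 scale, after missing-as-zero
    imputation at the configured missingness rate) and ``q5_q1_gap`` (the
    true richest-minus-poorest difference in mean rescaled score).

    ``mean_rescaled`` equals the score-weight combination
    ``20 * (2 P(hospital) + P(lower) + P(sba) + P(stay24) + P(pnc48))``
    scaled by the per-component response probability.
    """
    by_q = facility_prob_by_quintile(config)
    truth = expected_components(config)
    truth["mean_rescaled"] = _mean_rescaled(truth, config.missingness_rate)
    gap = np.zeros(config.n_countries)
    for q, sign in ((5, 1.0), (1, -1.0)):
        comp_q = expected_components(config, p_fac=by_q[:, q - 1])
        gap += sign * _mean_rescaled(comp_q, config.missingness_rate)
    truth["q5_q1_gap"] = gap
    return truth


def _draw_binary(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    return rng.random(p.shape) < p


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the woman-level table and return it with the truth table.

    Women are allocated round-robin over the stratum x PSU grid, assigned a
    uniform wealth quintile and a lognormal sampling weight normalized to
    sum to the country sample size, then run through the hierarchical
    response model.  Item missingness is MCAR, independent per component,
    recorded as the explicit ``"missing"`` category.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.country_sizes()
    ids = config.country_ids()
    p_fac_q = facility_prob_by_quintile(config)
    p_hosp = config.per_country("p_hospital_given_facility")
    p_sba_f = config.per_country("p_sba_given_facility")
    p_sba_h = config.per_country("p_sba_given_home")
    p_stay_f = config.per_country("p_stay24_given_facility")
    p_pnc_f = config.per_country("p_pnc48_given_facility")
    p_pnc_h = config.per_country("p_pnc48_given_home")

    frames = []
    for c in range(config.n_countries):
        n = int(sizes[c])
        n_strata = config.n_strata_per_country
        n_psu = config.n_psu_per_stratum
        grid = np.arange(n) % (n_strata * n_psu)
        stratum_idx = grid // n_psu
        psu_idx = grid % n_psu
        quintile = rng.integers(1, 6, size=n)

        p_q = p_fac_q[c, quintile - 1]
        if config.psu_effect_sd > 0:
            psu_effects = rng.normal(0.0, config.psu_effect_sd, n_strata * n_psu)
            p_q = expit(logit(np.clip(p_q, 1e-12, 1 - 1e-12)) + psu_effects[grid])
        facility = rng.random(n) < p_q

        hospital = facility & _draw_binary(rng, np.full(n, p_hosp[c]))
        sba = np.where(
            facility,
            _draw_binary(rng, np.full(n, p_sba_f[c])),
            _draw_binary(rng, np.full(n, p_sba_h[c])),
        )
        stay24 = facility & _draw_binary(rng, np.full(n, p_stay_f[c]))
        pnc48 = np.where(
            facility,
            _draw_binary(rng, np.full(n, p_pnc_f[c])),
            _draw_binary(rng, np.full(n, p_pnc_h[c])),
        )

        place = np.where(hospital, PLACE_HOSPITAL, np.where(facility, PLACE_LOWER, PLACE_HOME))
        cols = {
            "place": place.astype(object),
            "sba": np.where(sba, YES, NO).astype(object),
            "stay24": np.where(stay24, YES, NO).astype(object),
            "pnc48": np.where(pnc48, YES, NO).astype(object),
        }
        if config.missingness_rate > 0:
            for name in cols:
                blank = rng.random(n) < config.missingness_rate
                cols[name][blank] = MISSING

        raw_w = rng.lognormal(mean=0.0, sigma=0.25, size=n)
        weight = raw_w * n / raw_w.sum()

        frames.append(
            pd.DataFrame(
                {
                    "country_id": ids[c],
                    "stratum": pd.Series(stratum_idx).map("S{:02d}".format),
                    "psu": pd.Series(grid).map("P{:03d}".format),
                    "weight": weight,
                    "wealth_quintile": quintile,
                    **cols,
                }
            )
        )
    women = pd.concat(frames, ignore_index=True)[WOMAN_COLUMNS]
    return women, compute_truth(config)


def generate_mmr(truth: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Country MMR linked linearly to true delivery-care coverage.

    MMR_c = max(0, intercept + slope * coverage_c + eps_c) with Gaussian
    noise, coverage on the 0-100 scale.  Deterministic given the seed (a
    stream independent of the population draw).
    """
    if "mean_rescaled" not in truth.columns:
        raise ValueError("truth table must carry mean_rescaled coverage")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    coverage = truth["mean_rescaled"].to_numpy(float)
    eps = rng.normal(0.0, config.mmr_noise_sd, coverage.size) if config.mmr_noise_sd else 0.0
    mmr = np.maximum(0.0, config.mmr_intercept + config.mmr_slope * coverage + eps)
    return pd.DataFrame({"country_id": truth["country_id"], "mmr": mmr})
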