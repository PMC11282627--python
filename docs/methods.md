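# Methods

## The measure

The unit of analysis is a woman aged 15–49 whose most recent live birth
occurred strictly within the 24 months before the survey. Her
delivery-care score is the sum of four component point assignments —
place of delivery (hospital 2, lower-level facility 1, home 0), skilled
attendant at birth (1/0), facility stay of 24 or more hours (1/0), and a
first postnatal check within 48 hours (1/0) — rescaled from 0–5 to
0–100. The heavier weight on place of delivery reflects the assumption
that hospitals are better equipped for obstetric emergencies than
lower-level facilities; no alternative weighting is offered in this
version.

Missing component responses are imputed as zero at the component level:
a woman who did not answer an item is assumed not to have received that
intervention. Records are never dropped for item missingness, and
`scoring.imputation_audit` reports how many records had at least one
imputed component. The same convention propagates everywhere a component
acts as a condition: a missing response fails its cascade condition and
counts as "not covered" in binary indicators.

Because the score is additive, the weighted mean rescaled score obeys an
exact identity with the component coverages,

    C = (2·P(hospital) + P(lower) + P(SBA) + P(stay24) + P(PNC48)) / 5 × 100,

for any weights. The test suite asserts this to 1e-9; it is the main
internal consistency check between the scoring and estimation modules.

## Harmonization conventions

Survey dialects are recoded through a YAML mapping config (per-survey
place and attendant code maps, duration unit table). Choices the source
conventions leave open, fixed here and configurable in `MappingConfig`:

- **24 h stay boundary inclusive** — exactly 24 hours counts as a 24+
  hour stay.
- **48 h postnatal boundary inclusive** — a check at exactly 48 hours
  counts as within two days; the literal response "none" counts as no
  check.
- **Eligibility strict** — `months_since_birth < 24`; negative or
  missing months are dropped with a warning.
- Unmapped codes recode to an explicit `missing` category and are
  logged, never silently dropped; a home birth reporting a qualifying
  facility-stay duration is logically inconsistent and recodes to
  `stay24 = no` with a warning (a facility stay requires a facility
  birth).
- Records with a missing wealth quintile keep contributing to coverage
  estimates but are excluded from quintile gaps.

Strata containing a single primary sampling unit are removed wholesale
before estimation, since cluster resampling within a one-PSU stratum is
degenerate.

## Estimation

Coverage is the weighted mean of the per-woman indicator (the rescaled
score / 100 for the composite), times 100. Confidence intervals use a
stratified cluster bootstrap: within each stratum of m PSUs, each
replicate resamples m−1 PSUs with replacement and rescales their weights
by m/(m−1) (Rao–Wu), and the 2.5/97.5 percentiles of B replicate
estimates form the interval. B defaults to 1000. The percentile interval
can in tiny samples sit fractionally off the point estimate; intervals
are clamped to bracket it. Taylor linearization would give similar
intervals; the bootstrap was chosen for implementation transparency, and
point estimates are method-independent.

Pooling across countries multiplies each woman's weight by the inverse
proportion of women her country contributes (N/n_c), after renormalizing
within-country weights to sum to n_c. Every country's adjusted weights
then sum to N, making the pooled estimate exactly the unweighted mean of
country estimates and invariant to replicating any one country — both
asserted to 1e-9 in tests. Cross-country summaries (median, IQR) treat
countries as unweighted observations and use linear-interpolation
quantiles.

## Cascade

Five bars, each a weighted percentage **of the population in need**
(never of the preceding bar): 100%, facility delivery, +skilled
attendant, +24 h stay, +postnatal check ≤ 48 h. Bars are therefore
monotone non-increasing by construction, and the class validates this.
Facility-type stratification restricts to hospital (or lower-level)
births and rebases the denominator within the stratum, so bars 1–2 are
100 by construction; the stratified bars recombine exactly to the pooled
cascade when averaged with stratum weight shares taken over the full
population. MMR-phase stratification pools the countries of a phase with
the inverse-proportion weights above.

## Equity gaps and the MMR association

The Q5–Q1 gap is weighted delivery-care coverage among the richest
quintile minus the poorest, per country; phase averages are unweighted
means of signed country gaps (an `absolute=True` flag averages absolute
gaps instead; the default is signed because the richest quintile is
ahead in essentially all settings of interest). A country missing either
extreme quintile is flagged and excluded from phase averages, and an
empty phase is reported as absent, never as zero. The facility-vs-care
gap (facility-delivery coverage minus delivery-care coverage) is bounded
in [−60, +80] percentage points by score arithmetic: the extremes are a
population of home births with skilled attendance and postnatal checks
(score 2/5) versus lower-level facility births with nothing else (1/5).

Obstetric-transition phases partition the non-negative MMR line into
half-open bands [700, ∞), [300, 700), [100, 300), [20, 100), [0, 20)
(deaths per 100,000 live births); a fractional value such as 699.5 falls
in the lower-mortality band. The cross-country association is an
unweighted OLS of MMR on coverage (0–100), so the slope reads as deaths
per 100,000 per coverage percentage point (×10 for the per-10-point
phrasing); HC1-robust standard errors are reported alongside. The
direction of regression (MMR on coverage) matches how the relationship
is usually quoted; no causal claim is attached.

## Synthetic-data generator

The generator emulates the structure of a multi-country DHS/MICS
compilation: per country, a stratified two-stage design (women allocated
round-robin over a strata × PSU grid), uniform wealth quintiles,
lognormal sampling weights normalized to sum to the country sample size
(the convention the pooling identity relies on), and hierarchical
responses:

- facility delivery ~ Bernoulli with logit P = b_c + γ·(q − 3), where q
  is the wealth quintile, γ the log-odds gradient per quintile step, and
  the base b_c is solved numerically (bisection, 80 iterations) so that
  the quintile-marginal probability equals the configured `p_facility`
  exactly — configured probabilities therefore *are* the planted
  coverages, even with a gradient;
- hospital vs lower-level drawn only among facility births; a 24+ hour
  stay is structurally impossible for home births; skilled attendance
  and postnatal checks have separate facility/home probabilities, so
  home births can be attended or checked (observed in real data, and the
  source of negative facility-vs-care gaps);
- item missingness is MCAR, independent per component, recorded as the
  explicit missing category. Informative missingness is out of scope.

Correlation between components is induced solely by conditioning on
facility status. That reproduces the cascade's drop-off structure but
understates the extra within-woman correlation real data shows (e.g.
women with skilled attendance are also likelier to stay 24 h *given*
facility type), which is why the generator's pooled composite coverage
runs a few points higher than a real compilation with the same
marginals. Passing tests demonstrate the pipeline's algebra and
calibration under this model, not fidelity to any particular country's
microdata.

Closed forms (`compute_truth`) give per-country component coverages, the
mean rescaled score — each component scaled by (1 − missingness rate)
because a blanked component scores zero — and the true Q5–Q1 gap from
the logistic model evaluated at q = 5 and q = 1.

Country MMR is max(0, intercept + slope·coverage + ε), ε ~ N(0, σ), on
the 0–100 coverage scale, drawn from a noise stream independent of the
population draw.

### Defaults (the study conditions)

| Parameter | Default | Rationale |
|---|---|---|
| countries × women | 71 × 600 | 71 national surveys; 600 women/country keeps the full pipeline and test suite at desk scale (a real compilation has hundreds of thousands of women; only Monte-Carlo error changes) |
| design | 8 strata × 4 PSUs per country | small but resampling-friendly two-stage layout |
| `p_facility` | Beta(3.8, 1.2) quantiles across countries | mean 0.76 with a wide left-skewed spread (~0.25–0.99), mimicking observed between-country variation in facility delivery |
| `p_hospital_given_facility` | 0.5 | facility births split evenly hospital / lower-level |
| `p_sba_given_facility` / `given_home` | 0.987 / 0.125 | near-universal skilled attendance at facility births; pooled SBA ≈ 78% |
| `p_stay24_given_facility` | 0.895 | pooled 24 h+ stay ≈ 68% |
| `p_pnc48_given_facility` / `given_home` | 0.93 / 0.85 | pooled postnatal check ≈ 91% |
| `wealth_gradient` | 0.5 | Q5–Q1 facility gaps of ~35 pp at mid coverage, shrinking toward the ceiling — the narrowing-equity-gap pattern |
| `missingness_rate` | 0.03 | a few percent item nonresponse per component |
| `psu_effect_sd` | 0.0 | optional log-odds PSU random effect; zero keeps closed forms exact |
| MMR link | 900 − 8·coverage, σ = 120 | slope of 8 deaths/100k per coverage point; noise chosen to make the linear fit deliberately weak (r² ≈ 0.3–0.4) |

## Numerical choices

- Base-logit bisection runs 80 iterations on [−40, 40] (beyond float
  resolution of expit); degenerate coverages 0 and 1 are special-cased.
- Quantiles: linear interpolation throughout.
- Bootstrap determinism: PSU totals are accumulated in sorted stratum
  order, so a seed fully determines the interval.
- The MMR noise stream is seeded from `(seed, 7919)` so population and
  MMR draws never share a stream.
- Degenerate inputs raise informative errors rather than returning NaN:
  empty tables, zero weight sums, constant-coverage regression designs,
  <3 countries, single-PSU strata inside the bootstrap.

## Test problem sizes

The suite exercises: the exhaustive scorer cross-product (108 category
combinations) against a brute-force oracle; the linearity and pooling
identities at 1e-9 on the 71 × 600 study population; cascade structure
on 50,000 women; bootstrap calibration over 200 simulated surveys of 960
women (B = 200), with empirical 95% CI coverage required in [0.90,
0.99]; slope recovery of the planted −8 over 200 seeded replicates of
the 71-country design (CI coverage ≥ 90%); and Q5–Q1 gap recovery
against closed forms within 3 Monte-Carlo standard errors at 10,000
women per country.

## Limitations

- The composite equally trusts self-reported components with different
  recall properties (postnatal-check timing is the most fragile).
- Quality of care is approximated by contact co-coverage only; no
  individual-level clinical content is modelled.
- The generator's weights are a simple stand-in: nonresponse adjustment,
  post-stratification and multi-phase sampling are not modelled.
- MMR enters as given country-level values; its estimation uncertainty
  is ignored by the OLS fit.
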