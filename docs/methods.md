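# Methods

## The model

`crtdcost` implements a discrete-time decision-analytic cohort model of
generator-replacement economics for CRT-D devices from a payer (Medicare)
perspective. One patient is implanted at year 0 and followed to horizon
`H` (default 6 years). Three hazards operate on an annual grid:

- **Patient mortality**, from an annual survival curve `S_p(t)` shared by
  all devices. Death is independent of battery state; dead patients
  accrue no further costs.
- **Battery end of service**, from a device-specific event-free battery
  survival curve `S_b(a)` indexed by device age `a`, with
  `S_b(0) = S_b(1) = 1`: a battery cannot end service in its implant year
  or the year after (the "grace period"). Replacements occur only for
  battery depletion — no electronic failures, no lead revisions.
- **Procedure complications**: a replacement (and the initial implant)
  carries independent probabilities of a device-related complication and
  of an infection in the first year after the procedure, costed at their
  per-event Medicare amounts.

A replaced generator is statistically identical to the original: the same
`S_b` restarts at age 0. The number of k-th replacements at calendar year
`t` is therefore a discrete renewal process,

    g_1(t) = f(t),   g_k(t) = sum_{tau < t} g_{k-1}(tau) f(t - tau),
    f(a) = S_b(a-1) - S_b(a),  f(0) = 0,

truncated at `t <= H` and `k <= max_replacements` (default 3; with the
two-year grace structure the earliest k-th replacement is year `2k`, so a
4th cannot occur within 6 years regardless). The engine computes `g_k` by
convolution (`numpy.convolve`); the test suite checks it against an
independent path-enumeration oracle and against the microsimulation.

Expected alive-weighted replacements are `R(t) = S_p(t) * sum_k g_k(t)`:
a replacement at year `t` is performed only if the patient is alive at
`t`, and death and depletion are independent.

### Cost accounting

All amounts are 2023 USD. With discount rate `r` (default 3%/year) and
end-of-year discounting `d(t) = (1+r)^-t`:

| category | accrual |
|---|---|
| initial procedure | `C_impl` at year 0, undiscounted |
| initial complications | `p_c^prim C_c + p_i^prim C_i` at year 0 |
| initial follow-up | `v_post * C_visit` at year 0 |
| replacement procedures | `sum_t R(t) C_repl d(t)` |
| replacement complications | `sum_t R(t) (p_c^repl C_c + p_i^repl C_i) d(t+lag)` |
| replacement follow-ups | `sum_t R(t) v_post C_visit d(t)` |
| routine follow-ups | `sum_{t=1..H} v_routine C_visit S_p(t) d(t)` |

Totals are sums of their parts by construction. Base-case inputs: 34,436 /
32,123 / 82 USD for initial implant, replacement, and per visit; 4 routine
visits/year; 1 post-procedure visit; complication/infection costs 1,112 /
29,550 USD with incidences 4%/2% after the primary implant and 2%/3% after
a replacement.

### Timing conventions (deliberate choices)

The source analysis does not state its event-timing conventions, so the
package fixes them explicitly:

- **End-of-year discounting, no half-cycle correction.** All year-`t`
  events are costed at `t`; year 0 is undiscounted. This reproduces the
  published replacement-category results to the dollar.
- **Replacement eligibility is survival at year `t`** (multiplication by
  `S_p(t)`, not `S_p(t-1)`); the residual effect of the alternative is
  ~1% on replacement rows.
- **Complications are expected-value costs attached to the procedure
  year.** The incidences are "first year after the procedure";
  `settings.complication_lag_years` (default 0) shifts their discounting
  by whole years and changes totals by well under 1%.
- **Routine follow-ups accrue to survivors at years 1..H.** Taken
  literally, 4 × $82 × discounted survivors ≈ $1,488/patient. The
  original analysis prints $1,367 without stating its accrual rule; we
  keep the literal convention, which leaves our per-patient totals ≈0.3%
  above the printed ones. Every other category matches to ~$1, and the
  acceptance layer uses a ±2% band on table-derived quantities for this
  reason.

### Population roll-up

Annual cohorts of `annual_implants` patients (base 15,577) enter in each
of `C` consecutive years (base 7, i.e. 109,039 patients); the cohort
entering at year `e` is followed for `(C-1) - e` years, so follow-up is
truncated, not shifted. The published cumulative row counts only
replacement-category costs; `include_all_categories=True` reports full
totals instead. Each cohort is discounted to its own entry year and the
cohort sums are added nominally — the source gives no cross-cohort
discount convention; applying one would lower later cohorts by up to
`(1+r)^-(C-1)`. This convention reproduces the printed cumulative figures
to ~0.002%.

### Sensitivity analysis

Scenarios are univariate by construction: a `ScenarioSpec` carries exactly
one transform (replace a curve, scale the initial or replacement cost,
swap the complication model, extend the horizon). Horizon extension uses a
geometric conditional-survival tail by default — each added year
multiplies the last value by the final observed annual ratio
`S(H)/S(H-1)`, floored at 0 — with explicit user tails as an override;
the source describes its extension only as following a "similar reduction
rate", so the rule is a documented choice. Tornado rows are ordered by
descending swing of the reference device's total, ties broken
alphabetically for deterministic output. The ±20% initial-implant-cost
scenarios bound the reference total by exactly `±0.2 × C_impl` (a year-0
arithmetic identity the tests assert); the ±20% replacement-cost scenarios
reproduce the published savings endpoints ($18,054 vs 1.0 Ah, $8,344 vs
1.6 Ah). Scenario inputs that the source keeps in an appendix (alternative
trial-based patient survival, upper-bound complications, the 15-year
curves) are supported as user-supplied config, never hard-coded.

## Synthetic data and the microsimulation oracle

`generate_parameters` draws structurally valid random input bundles for
property tests: patient survival from independent annual death
probabilities (uniform on 4–9%/year, bracketing the base case's ~5–6%);
battery curves equal to 1 through the grace period and then a discretised
Weibull tail `exp(-((a-1)/(s·Ah))^k)` with shape `k = 2` and a per-bundle
scale multiplier `s` uniform on 3–5 years/Ah — calibrated so a ~2-Ah
device keeps most of its survival at year 6 while a ~1-Ah device is
mostly depleted, as in the base-case curves. Because `s` is shared across
devices within a bundle, higher capacity is pointwise at least as durable
by construction. Costs and incidences are uniform draws bracketing the
base-case magnitudes. The generator emulates the *structure* of real
inputs (monotone curves, grace period, capacity ordering), not their
correlations — real battery curves come from registry Kaplan–Meier
estimates with shapes no two-parameter tail reproduces — so passing
property tests demonstrates algebraic correctness of the engine, not
clinical realism of any particular synthetic bundle.

`microsimulate` restates the cohort model at patient level: each year,
death is drawn first (hazard `1 - S_p(t)/S_p(t-1)`); survivors accrue
routine visits and then face battery depletion at the current device age
(hazard `1 - S_b(a)/S_b(a-1)`); a depletion triggers a replacement with
procedure cost, independent Bernoulli complication and infection draws,
and the post-procedure visit, all discounted to that year, and resets the
device age — up to the replacement cap, after which depletions are
uncosted. Drawing death before depletion matches the engine's
`S_p(t)`-weighting, making the two routes estimands of the same quantity;
the suite requires agreement within 3 Monte-Carlo standard errors on
every cost category at n = 200,000 for the base case and twenty seeded
synthetic bundles. All draws come from a single PCG64 stream per run,
filled into one fixed-shape `(n, H+1, 4)` uniform tensor in C order, so
patient `i`'s draws are invariant to `n` and runs are exactly
reproducible for a given seed.

## Numerical choices and degenerate inputs

- Probabilities are fractions internally; config tables may declare
  `percent: true` to supply printed percentages, resolved once at the
  boundary. Config files are versioned (`schema_version`).
- Money is float64 internally; rounding (half away from zero, whole
  dollars) happens only in CSV/console presentation. JSON output is never
  rounded. Serialisation writes fractions at full precision, so
  load∘save is exact identity.
- A curve that reaches 0 extends geometrically to all-0 (absorbing). A
  conditional hazard with zero denominator is defined as 1.
- Horizon 0 in the truncated-cohort computation yields initial-implant
  costs only; an empty device list, non-monotone curve, negative cost, or
  probability outside [0,1] is a validation error naming the field.

## Problem sizes

The base-case pipeline (3 devices, 6-year horizon) is microseconds per
run; the acceptance script completes in ~1 s. Microsimulation at
n = 200,000 takes well under a second per device, so the full validation
layer (23 runs) stays within a couple of minutes including test overhead.

## Known limitations

- The routine-follow-up accrual gap above (~0.3% on totals).
- No probabilistic sensitivity analysis; scenarios are univariate and
  deterministic, as in the source analysis.
- No demographic structure, market-share mixing, lead-related failure
  modes, or societal costs; patient survival does not depend on the
  number of procedures undergone.
- The 15-year extension is an extrapolation rule, not data; published
  15-year totals used appendix inputs not in the main text and are not
  reproduced here.
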