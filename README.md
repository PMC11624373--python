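# crtdcost

A decision-analytic cohort model of the Medicare cost of battery longevity
in cardiac resynchronization therapy defibrillators (CRT-D). Patients
receive an initial implant at year 0 and are followed for six years; the
pulse generator is replaced whenever its battery reaches end of service,
and every procedure carries reimbursement, complication, and follow-up
costs. Because battery capacity (ampere-hours, Ah) drives longevity, the
model quantifies how much an extended-longevity device (2.1 Ah) saves the
payer relative to lower-capacity alternatives (1.6 Ah, 1.0 Ah).

The package is aimed at health-economics and outcomes-research analysts:
it is a library first (with a thin `crtdcost` CLI), ships the full
base-case input set as a built-in fixture, supports user-supplied inputs
via YAML/JSON or CSV tables, and validates its cohort engine against an
internal patient-level Monte-Carlo microsimulation.

## Model

Let `S_p(t)` be patient survival at year `t` (device-independent) and
`S_b(a)` event-free battery survival at device age `a`, with
`S_b(0) = S_b(1) = 1` (a two-year grace period after every implant). The
first-depletion mass is `f(a) = S_b(a-1) − S_b(a)`, and the k-th
replacement follows the discrete renewal convolution

```
g_1(t) = f(t),    g_k(t) = Σ_{τ<t} g_{k−1}(τ) · f(t − τ),
```

truncated at the horizon `H = 6` and at `max_replacements = 3` (the grace
structure makes a 4th replacement impossible within 6 years). Expected
alive-weighted replacements are `R(t) = S_p(t) · Σ_k g_k(t)`. Year-`t`
costs (replacement procedure, its expected complications, the
post-procedure visit, and routine follow-up visits for survivors) are
discounted by `(1+r)^−t` at `r = 3%`; year-0 initial-implant costs are
undiscounted. Population roll-ups sum replacement costs over seven annual
entry cohorts of 15,577 implants with follow-up truncated at the
observation window. Univariate sensitivity analysis applies exactly one
declarative parameter edit per scenario and re-runs the engine.

## Worked example

```python
from crtdcost import builtin_base_case, per_patient_costs, compare_devices

params = builtin_base_case()
for label in params.device_labels:
    print(label, f"${per_patient_costs(params, label).total:,.0f}")
print("saving vs 1.0 Ah:",
      f"${compare_devices(params, '2.1 Ah', '1.0 Ah').absolute['total']:,.0f}")
```

prints

```
2.1 Ah $41,647
1.0 Ah $56,767
1.6 Ah $48,635
saving vs 1.0 Ah: $15,120
```

i.e. discounted expected 6-year cost per implanted patient (2023 USD) for
each device profile, and the per-patient saving from choosing the
2.1-Ah device over the 1.0-Ah one. The initial-implant block
($34,436 + $635 expected complications + $82 post-procedure visit) and
routine follow-ups are identical across devices, so the whole difference
is replacement spend: $5,006 (2.1 Ah) vs $11,994 (1.6 Ah) vs $20,126
(1.0 Ah). See `examples/` for population roll-ups (the 2.1-vs-1.0-Ah gap
exceeds $0.5 billion over 109,039 patients), sensitivity tornados, custom
inputs, and microsimulation validation; each script prints the numbers it
computes with a note on what they mean. The same computations are exposed
on the command line:

```sh
crtdcost run --builtin-base-case --out results/
crtdcost simulate --builtin-base-case --device "2.1 Ah" --n 200000 --seed 1
```

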