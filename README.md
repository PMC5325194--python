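# oxytitrate

How much medical oxygen does routine flow titration conserve during pediatric
oxygen therapy?

Oxygen is a life-saving treatment for children with hypoxemic pneumonia, and
in low-resource settings it is chronically scarce. As a child recovers, the
flow needed to keep SpO₂ in the target range declines — but unless someone
re-titrates the flow, the child keeps receiving the starting rate and the
excess is wasted. `oxytitrate` is a Monte Carlo model of that waste: it
samples synthetic cohorts of hypoxemic-pneumonia patients, computes the
oxygen each consumes under different titration schedules, and quantifies the
savings, with every simulated number validated against an exact
closed-form oracle.

## Model

Each patient *i* has a starting flow *V₀* ∈ {0.5, 1.0, 2.0} L/min (uniform),
a treatment duration *D* ∈ {1,…,5} days with P(D) = {0.32, 0.27, 0.18, 0.12,
0.11}, and one of two equiprobable piecewise-linear need profiles with
weaning constant *k* = 0.125 L/min/day:

- **Profile A**: v(t) = V₀ − kt for 0 ≤ t < 3, then V₀ − 3k (plateau),
- **Profile B**: v(t) = V₀ for t < 1, V₀ − k(t−1) for 1 ≤ t < 3, then V₀ − 2k.

Titration every Δt minutes is a zero-order hold: the delivered flow is re-set
to the patient's current need at each titration instant and held until the
next one, so per-patient consumption is

O₂,ᵢ(Δt) = Σⱼ v(tⱼ) · Δt,  tⱼ = j·Δt, last step truncated at *D*,

in liters (L/min × minutes). Three scenarios are compared on identical
cohorts (common random numbers): no routine titration (Δt = D, the
reference), titration every 24 h (a daily ward round), and every 3 min
(an automated closed-loop system). Savings = 1 − O₂,total(Δt)/O₂,total(D).
Because the parameter support is finite (30 combinations), exact expectations
and variances of all of these quantities are available by enumeration
(`oxytitrate.oracle`) and are used to validate every simulated output.

## Worked example

```
$ python analysis/02_titration_scenarios.py --seed 1
3 replicates of 100 patients, base seed 1
Scenario I (initial-only): 409 ± 5 kL
Scenario II (dt=1440 min): 376 ± 3 kL, savings 8.1% ± 1.3%
Scenario III (dt=3 min): 361 ± 3 kL, savings 11.7% ± 1.4%
24-hour titration saves 33 kL per 100 patients (= 555 h at 1 L/min)
3-minute titration saves 48 kL per 100 patients (= 801 h at 1 L/min)
```

Read: with no routine titration, 100 patients consume ≈409 kL of oxygen
(mean ± SEM over 3 replicate cohorts). Re-titrating once a day on the same
patients cuts that by 8.1%; near-continuous titration by 11.7% — i.e. a
once-daily ward round already captures about two-thirds of the maximum
achievable savings. The hour-equivalents express the saved volume as therapy
time at a standard 1 L/min flow. `analysis/01_sample_cohort.py` inspects the
cohort sampling stage, and `analysis/03_oracle_audit.py` compares every
simulated mean with its exact enumeration expectation (they agree within
a few hundredths of a predicted SEM):

```
$ python analysis/03_oracle_audit.py --seed 1
               I: E =   4082.4 L/patient, savings =  0.00%, predicted SEM = 19.4 kL
              II: E =   3757.5 L/patient, savings =  7.96%, predicted SEM = 17.9 kL
             III: E =   3614.7 L/patient, savings = 11.46%, predicted SEM = 17.7 kL
continuous-limit: E =   3614.4 L/patient, savings = 11.46%, predicted SEM = 17.7 kL
```

The same computations are exposed as a CLI: `oxytitrate simulate --n 100
--replicates 3 --scenarios none,1440,3 --seed 1 --out results` and
`oxytitrate expect --out results/expectations.json`, with a YAML/JSON config
file (`--config`) overriding any distribution (`v0_support`, `v0_probs`,
`duration_support`, `duration_probs`, `profile_probs`, `k`).

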