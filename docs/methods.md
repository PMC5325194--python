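# Methods

## The model

The package estimates oxygen conserved by routinely re-titrating the
delivered flow during oxygen therapy for children with hypoxemic pneumonia.
A patient's *need* for oxygen is a deterministic, piecewise-linear function
of time since admission; what the patient *receives* depends on the
titration policy. The gap between the two is the conservable waste.

A patient is the triple (V₀, D, profile):

- **V₀** (L/min), the appropriate starting flow, uniform on
  {0.5, 1.0, 2.0} — 0.5 L/min is the recommended starting rate for infants,
  1–2 L/min for older children.
- **D** (days), the treatment duration, on {1,…,5} with probabilities
  {0.32, 0.27, 0.18, 0.12, 0.11}, a declining distribution consistent with
  published weaning times for hypoxemic children.
- **profile** ∈ {A, B}, equiprobable. Profile A weans from the start:
  v(t) = V₀ − k·min(t, 3). Profile B holds the starting flow for one day and
  then weans: v(t) = V₀ − k·clip(t − 1, 0, 2). Both are continuous,
  non-increasing, and plateau after day 3.
- **k** = 0.125 L/min/day, the weaning rate, shared by both profiles.

V₀, D and profile are sampled independently; no joint structure is modeled.
The distribution invariant 3k < min(V₀) guarantees strictly positive flows
over the five-day horizon (0.375 < 0.5 for the defaults), so every consumed
volume is positive and savings fractions are well defined.

### Sign of the weaning term

The profiles describe recovering patients, so flows decline at rate k. The
plateau levels are the endpoints of the declining segments — V₀ − 3k for
profile A, V₀ − 2k for profile B — which is the only choice that keeps the
profiles continuous. This decreasing/endpoint-plateau reading is also the
one the enumeration oracle singles out: it alone yields expected savings
(7.96% at 24 h, 11.46% continuous) compatible with both reported savings
bands simultaneously, which the acceptance suite asserts.

### Titration as zero-order hold

A policy either sets the flow once at t = 0 and never again ("initial-only",
Δt = D, the reference scenario), or re-sets it every Δt minutes. Between
titrations the delivered flow is held constant at the need sampled at the
step start (zero-order hold); the last step is truncated so delivery ends
exactly at D. Two idealizations are inherited from the scenario definitions:
titration takes effect instantaneously, and the starting rate is always
appropriate, so the t = 0 flow equals V₀ under either profile. A periodic
interval longer than the treatment degenerates gracefully to a single
truncated step, i.e. initial-only.

Consequences used as test invariants:

- initial-only consumption is exactly V₀ · D · 1440 liters;
- consumption is non-decreasing in Δt, bounded below by the exact profile
  integral (the Δt → 0 limit, available in closed form as the `continuous`
  policy kind) and above by initial-only;
- the hold excess obeys |ZOH − integral| ≤ span · k · Δt/2 with span ≤ 3
  declining days, so a 3-min interval is within 0.6 L of the continuum per
  patient — the 3-min scenario and the continuous limit are operationally
  interchangeable (their expected totals differ by < 0.01%).

Internal time is minutes (1 day = 1440 min); profile math is in days and the
engine converts at the boundary. Volumes are liters = (L/min) × minutes with
no rescaling anywhere; reporting rounds to whole kL and one-decimal percent
only at serialization.

## Cohort simulation and summaries

A cohort of N = 100 patients is sampled once per replicate and **every**
scenario is evaluated on that identical patient list (common random
numbers), so scenario contrasts are free of sampling noise. Savings are
1 − total(Δt)/total(reference), computed within each replicate; R = 3
replicates (seeds base_seed + 0, 1, 2) are summarized as mean ± SEM with the
n−1 sample SD. N, R and the scenario set (never / 24 h / 3 min) are the
study conditions and are the package defaults; all are overridable.

All randomness lives in cohort sampling, consumed in a fixed documented
order (all starting flows, then all durations, then all profiles) from one
`numpy` Generator per replicate, so a run is bit-reproducible from
(base_seed, N, distributions, scenarios).

## Exact oracle

The joint support has 3 × 5 × 2 = 30 points and consumption is a
deterministic function of the combination, so the mean and variance of
per-patient consumption under any policy are finite weighted sums
(`expected_patient_consumption`), and the SEM of the replicate-mean cohort
total is √(N · Var/R) (`predicted_replicate_sem`). Under the defaults:
E[initial-only] = 4082.4 L/patient with SD 3352 L, expected savings
0.225625/2.835 ≈ 7.96% at 24 h and 0.325/2.835 ≈ 11.46% in the continuous
limit, and predicted replicate-mean SEM ≈ 19.4 kL for (N=100, R=3). The test
suite verifies these against independently hand-derived closed forms and
requires Monte Carlo means at n = 10⁵ to land within 4 CLT standard errors.

With only three replicates, a mean cohort total is itself noisy: single
published runs of the same design can plausibly sit an analytic SD
(~34 kL for one cohort; ~19 kL for the 3-replicate mean) away from the exact
expectation of 408.2 kL for the reference scenario. The savings fractions
are far more stable than the totals because the paired design cancels the
shared cohort noise.

## What the generator does and does not emulate

The generator reproduces the stated study population: discrete starting
flows, a 1–5 day duration mix, two weaning shapes, one weaning rate. It does
not model SpO₂/FiO₂ dynamics, titration response lags, desaturation
episodes, device efficiency, altitude or age structure, or any correlation
between severity and duration. Passing tests therefore demonstrate that the
pipeline computes this idealized model exactly and reproducibly — not that
real wards would realize these savings; if desaturations occur, the model
overestimates savings by construction.

## Numerical and design choices

- **Savings convention**: reported as the saved fraction 1 − ratio, in
  [0, 1); a policy total exceeding the reference raises (only possible for
  increasing profiles, which the invariants exclude).
- **SEM of savings**: computed per replicate then summarized, not by error
  propagation from the totals.
- **Step construction**: n = ceil(D/Δt) steps from t = 0; day boundaries
  (profile breakpoints at days 1 and 3) are exact multiples of both default
  intervals, so no step straddling error arises for the study scenarios.
- **Degenerate inputs**: single-point supports are legal (variance 0);
  k = 0 makes every policy identical and all savings exactly 0, which tests
  assert without tolerance.
- **Config surface**: finite supports only (lists in YAML/JSON); enumeration
  is therefore always exact and no Monte Carlo fallback is needed.
- **Problem sizes**: the default run (3 × 100 patients × 3 scenarios) takes
  well under a second; the heaviest checks (10⁶-draw frequency audit,
  10⁵-patient oracle agreement) complete in seconds, since per-patient
  volumes are cached over the 30-point support.

## Known limitations

The duration distribution is treated as exact rather than re-derived from
the underlying clinical counts; profiles end at day 5 and durations beyond
it are rejected; concurrent-patient logistics (ward demand over time,
cylinder logistics, costing) are out of scope.
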