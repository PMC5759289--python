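# Methods

## Model

`thyrotx` simulates antithyroid (methimazole, MMI) therapy of Graves'
hyperthyroidism with a four-compartment ODE system:

```
dx/dt = s(t) - k1*z*x/(ka + x) - k2*x        serum MMI          (mg/L)
dy/dt = k3*z*w/(kd + w) - k4*y               serum FT4          (pg/mL)
dz/dt = k5*(w/z - N) - k6*z*x                functional size    (mL)
dw/dt = k7 - k7*x/(kb + x) - k8*w            serum TRAb         (U/mL)
```

The biology behind the terms: TSH-receptor antibodies (TRAb, `w`) mimic TSH
and drive both hormone secretion and growth of the *functional* thyroid mass
(`z`, the hormonally active tissue volume — a hidden compartment, not
anatomical gland size).  MMI (`x`) is taken up by the gland saturably
(Michaelis–Menten, half-saturation `ka`), inactivates functional tissue
(`k6*z*x`) and suppresses TRAb production (Michaelis–Menten, half-saturation
`kb`).  FT4 (`y`) is secreted in proportion to functional mass with
Michaelis–Menten dependence on TRAb (half-saturation `kd`) and cleared
first-order.  There is no TSH compartment: in Graves' disease TSH is
suppressed and the feedback loop is short-circuited by TRAb.  FT3 dynamics
and intraday absorption kinetics (peak serum MMI within 0.5–3 h of a dose)
are below the model's daily resolution and are not represented.

Time is in days throughout.

### Treatment input

The oral input rate is piecewise constant: during a treatment period of
`T` days at dose `D` mg/day,

```
s(t) = c = f * D * T / V          f = 0.93 (bioavailability), V = 59.71 L
```

held at that constant value for the whole period.  Note the convention: `c`
scales with the period length, so the same daily dose produces a larger
input rate when prescribed as one long period than as several short ones.
This is deliberate — it is the convention under which the packaged per-period
`c` values (e.g. 21.027 for 30 mg/day over 45 days) and the clinical
validation courses are defined, and period boundaries are therefore part of
the study conditions.  Off-treatment periods inside a replayed course use
the floor `c = 0.001` (the convention of the packaged relapse runs);
untreated baselines use `s = 0`.

The initial serum MMI level is `x0 = loading dose / 3 L` (volume of
distribution in serum).

### Parameters

| name | meaning | default | units | origin |
|------|---------|---------|-------|--------|
| k1 | max relative MMI uptake | 8.374e-3 | mg/(mL·L·day) | 15 mg/day uptake ceiling / (30 mL × 59.71 L) |
| k2 | MMI elimination | 3.3271 | 1/day | ln 2 / 5 h |
| ka | MMI uptake half-saturation | 0.358068 | mg/L | fixed (tuned by simulation) |
| k3 | max relative FT4 secretion | 0.119 | pg/(mL²·day) | first-visit equilibrium (below) |
| kd | FT4-secretion half-saturation | 0.05 | U/mL | fitted in [0.05, 0.1] |
| k4 | FT4 elimination | 0.099021 | 1/day | ln 2 / 7 d |
| k5 | functional-size growth rate | 1e6 | mL³/(U·day) | fixed (tuned by simulation) |
| N | maximal growth ratio | 0.833 | U/mL² | w0 / z0 |
| k6 | thyroid inactivation by MMI | 0.001 | mL/(mg·day) | fixed (tuned by simulation) |
| k7 | max TRAb production | 0.875 | U/(mL·day) | k8 · w0 |
| kb | TRAb-inhibition half-saturation | 1.5 | mg/L | fitted in [3, 12] for patients |
| k8 | TRAb elimination | 0.035 | 1/day | ln 2 / 20 d, quoted to 2 figures |

`ka`, `k5`, `k6` and the default `kd`, `kb` are fixed constants and are not
re-estimated.  (The source material is ambiguous about `k5`, `k6` — one
passage reads them as 1 — but the tabulated values 1e6 and 0.001 are the
ones consistent with the per-patient runs, so those are the defaults; both
are overridable.)

Patient-specific calibration uses the requirement that the first clinical
visit `(y0, w0)` with assumed functional size `z0 = 30 mL` and no drug on
board is a steady state:

```
k3 = k4*y0*(kd + w0) / (z0*w0),   N = w0/z0,   k7 = k8*w0
```

Because `k3` depends on `kd`, the time-course fit re-derives `k3` from each
trial `kd` (this reproduces the packaged patients' tabulated `k3`/`kd`
pairs).  Lab helpers convert SI to conventional units (FT4 pmol/L × 0.7769
→ pg/mL, FT3 pmol/L × 0.651 → ng/L) and recenter FT4 values measured
against a lab-specific reference range `(L, U)` onto the common (7–18)
pg/mL scale by `y = 11(x − L)/(U − L) + 7`.

## Numerics

**Stiffness.** `k5 = 1e6` makes the size equation a fast slaved mode: `z`
tracks `w/N` on a ~10⁻⁵-day timescale while the slowest mode (TRAb) relaxes
over `1/k8 ≈ 29` days.  Integration uses `scipy.integrate.solve_ivp` with
LSODA, `rtol = 1e-8`, `atol = 1e-10`; halving the tolerances moves terminal
states by < 1e-6 relative.  Trajectories are sampled at 1-day resolution
plus period endpoints and any requested observation days; predictions at
observation days are taken from those exact samples, never interpolated.
Components in `(-1e-8, 0)` from solver round-off are snapped to 0; anything
more negative raises.  Fitting uses `rtol = 1e-6` (the objective is noisy at
the 0.01 pg/mL level at most, far below assay noise).

**Untreated steady state.** Closed form: `x1 = 0`, `w1 = k7/k8`,
`z1 = k7/(k8 N)`, `y1 = k3 k7² / (k4 k8 N (k8 kd + k7))`.  With the default
constants this is (0, 36.0, 30.0, 25) — the canonical hyperthyroid start.
Its local stability is certified by the Routh–Hurwitz conditions on the
quartic characteristic polynomial (`a1, a3, a4 > 0` and
`a3² + a1²a4 − a1a2a3 < 0`, the latter provably negative for any positive
parameters); the closed-form coefficients are regression-tested against the
numeric characteristic polynomial and the verdict against numeric
eigenvalues over random positive parameter draws.

**Treated steady state.** Found by a bracketed Brent search on the drug
balance: for trial `x2`, `w2` and `y2` are explicit and `z2` is the unique
positive root of `k6 x2 z² + N k5 z − k5 w2 = 0`, evaluated in the
cancellation-free form `z2 = 2 k5 w2 / (N k5 + sqrt((N k5)² + 4 k6 x2 k5 w2))`.
The residual of the drug balance is `c·ka > 0` at `x2 = 0` and `< 0` at
`x2 = c/k2`, so the bracket `(0, c/k2]` always contains the root (widened
once by 1.5× if rounding spoils the endpoint sign).  Steady-state residuals
are at rounding level, but note the size-balance residual is amplified by
`k5`, so "zero" means ≲ 1e-10 with the default constants.

**Sensitivity to the treatment rate.** Implicit differentiation of the
steady-state equations gives `∂x2/∂c > 0` and, under a stated upper bound on
`c`, `∂y2/∂c, ∂z2/∂c, ∂w2/∂c < 0` (more drug, lower hormone, antibody and
functional mass).  Two published expressions contain slips that the
implementation exposes rather than hides: the size-balance bracket term
prints `kb·z2²` where the differentiation yields `k6·z2²`, and the FT4
partial prints an extra factor `k4`.  The default `variant="derived"`
matches central finite differences to ~1e-9 relative; `variant="as-printed"`
reproduces the published expressions verbatim.

**Energy decay under treatment.** The quadratic form
`V = x̄²/2 + x̄w̄ + w̄²/2` in the drug/antibody deviations from the treated
steady state is evaluated along stored trajectories and checked to be
non-increasing past its transient peak (tolerance `1e-10·max V` plus a
round-off floor quadratic in the state's representation error).  This is a
numerical diagnostic, not a proof; the published transformed-coordinates
system for the analytical argument contains undefined quantities (`f1, f2,
f3`) and is not implemented.

## Packaged clinical courses

Four real MMI treatment courses (ids 20, 31, 55, 70) ship as plain-text
data: per-patient parameters, per-period `(dose, duration, c)` rows and
sparse FT4/TRAb observations, each with a clinical-narrative provenance
note.  Period durations were recovered from the published per-period `c`
values by inverting the input-rate formula (giving the mixed 30/31/89/182/
330/690-day periods), and observation days follow the cumulative period
boundaries.  Two reading choices are recorded in the data rather than
buried in code: patient 20's final lab falls 2 days past the 545-day course
(the replay extends off-drug, `s = 0`, to cover it), and patient 31's
2-years-later follow-up visit is out of course (the model, correctly,
predicts relapse toward ~26 pg/mL for an untreated patient whose TRAb
production is unchanged — the record's scored observations end with
treatment).  Replaying the courses gives per-analyte RMSEs of 1.00/2.82
(patient 20, published 0.889/2.388), 2.30/0.20 (31; 1.9892/0.2303),
7.39/2.13 (55; 7.3931/2.1257) and 1.90/2.20 (70; 1.7006/1.5084); the
differences are consistent with unstated month-length and solver
conventions, and the replay makes all its own conventions explicit.

## Synthetic patients

The generator emulates the shape of the clinical courses: first-visit labs
drawn uniformly (FT4 20–40 pg/mL, TRAb 1–25 U/mL), `kd`/`kb` drawn from
their admissible boxes, `k3`/`N`/`k7` derived from the first visit, a
tapering regimen mirroring the scenario courses (30 mg/day loading month
tapered one tablet per month, then 10 mg/day maintenance; 540 days total),
11 follow-up visits (monthly early, roughly bimonthly late), and additive
Gaussian assay noise truncated at zero (σ = 0.5 pg/mL FT4, 0.3 U/mL TRAb).
What it does *not* emulate: missing TRAb visits, lab-to-lab reference-range
drift, dose nonadherence, and any within-patient parameter drift — so
passing recovery tests demonstrate estimator correctness under the model,
not robustness to real-data pathologies.

### Identifiability of (kd, kb)

The bounded fit minimises the unweighted sum of per-analyte RMSEs with a
Nelder–Mead search in `u = sin²θ` transformed coordinates (unit scaling of
the two bounds boxes; smooth at the bounds, where hard clipping collapses
the simplex), started from the best of five deterministic screening points
(midpoint and the 25/75% corners).  The procedure is deterministic and, on
noise-free synthetic courses, recovers the generating `(kd, kb)` to ~1e-5.

Under realistic noise the two constants behave very differently.  `kb` is
well identified: TRAb observations constrain the suppressed level
`w2 = k7 kb / (k8 (kb + x2))` directly (median absolute error ≈ 0.17 mg/L
across a 50-patient cohort, against an admissible width of 9).  `kd` is
essentially unidentified: FT4 enters through `w/(kd + w)` and serum TRAb
stays one to two orders of magnitude above `kd ∈ [0.05, 0.1]` for most of
the cohort, so a 0.01 change in `kd` moves predicted FT4 by only
~0.005–0.03 pg/mL against 0.5 pg/mL assay noise.  The Cramér–Rao bound
computed from the FT4 sensitivity along the observation design gives a
median `kd` standard error of ≈ 0.13 — larger than the entire admissible
interval — so the measured median absolute error of ≈ 0.02 is mostly bound
truncation of an unidentified parameter, and no realistic visit schedule
changes this by the order of magnitude that precise `kd` recovery would
require.  The corresponding cohort-level recovery assertion for `kd` is
expected to fail and is retained as an honest negative result.

## Known limitations

* Validation is limited to the four packaged courses; the 90-patient cohort
  behind the published RMSE reference intervals is not packaged, so
  `rmse_reference_interval` is exercised on synthetic cohorts only.
* The input-rate convention couples `c` to period length (see above);
  figure-level agreement with other implementations depends on matching
  period boundaries exactly.
* The FT4 classifier knows only the three FT4 bands; subclinical
  hyperthyroidism (suppressed TSH, normal FT4) has no TSH state to hang on
  and is approximated by the "undershooting" regime (FT4 still above 18
  after a stated course).
* No global bifurcation or multistability analysis: the treated steady
  state is provably unique and the solver exploits that.
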