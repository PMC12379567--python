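# Methods

## Scope and model structure

`alpbtk` simulates the whole-body kinetics of aluminium (Al) in a growing
female individual from birth to age 50 and, on top of that, in virtual
populations of such individuals. Two exposure routes are modelled: a
continuous, age-tiered dietary intake (the background every person carries)
and repeated subcutaneous injections of adjuvant-bound Al as given in
allergen immunotherapy (SCIT), each injection forming a slowly draining
depot at the injection site. The package's purpose is exposure
quantification against tissue reference levels; toxicodynamics are out of
scope.

The kinetic model is a linear, time-varying compartment system on amounts
(ug Al): plasma, bone, brain, liver, kidney, rest-of-body, a cumulative
urine state, and analytically-tracked injection-site depots. With
`C = A_plasma / V_plasma(a)` (ug/L) at age `a`:

    dA_plasma/dt = u_diet(a) + u_depot(t)
                   + sum_i k_out,i * A_i + k_rel(a) * A_bone
                   - [ sum_i CL_i(a) + CL_brain(a) + kappa * F_Ca(a)
                       + fE * GFR(a) ] * C
    dA_bone/dt   = kappa * F_Ca(a) * C - k_rel(a) * A_bone
    dA_brain/dt  = CL_brain(a) * C                        (sink, no efflux)
    dA_i/dt      = CL_i(a) * C - k_out,i * A_i            (i = liver, kidney, rest)
    dA_urine/dt  = fE * GFR(a) * C

Key structural commitments:

* **Amount-based states.** Concentrations are amounts divided by growing
  organ masses, so the dilution of a fixed body burden by body growth is
  implicit rather than an extra term. This is what produces the neonatal
  concentration decline under dietary exposure alone.
* **Bone follows calcium.** Uptake into bone is proportional to the
  calcium accretion flux `F_Ca(a)` (mg Ca/day) and to plasma concentration,
  with one proportionality constant `kappa`; release is first-order at the
  fractional calcium release rate `k_rel(a)`. Because childhood bone
  turnover is high and adult turnover slow, treatment-induced bone excess
  is transient, with a washout time set by `k_rel` at the ages following
  treatment.
* **Brain is a sink.** Brain has an uptake clearance and no return flux,
  so any Al that reaches brain stays; brain burden is non-decreasing under
  any exposure.
* **Renal elimination only.** Elimination is `fE x GFR(a) x C` into urine;
  there is no other loss route, reflecting the almost exclusively renal
  clearance of systemic Al.
* **Zero-order depots.** Each injected dose releases `k x dose` per day
  until exhaustion at `1/k` days; 100% of the release reaches plasma.
  `k` is 0.0024864/day for commercial aluminium hydroxide (Ahy; depot
  lifetime ~402 days ~ one year) and 0.0082392/day for in-situ
  precipitated hydroxide (Ains; ~121 days ~ four months). "Zero-order
  rate (1/day)" is read as fraction-of-dose per day because only that
  reading reproduces both depot lifetimes.

Since the system is linear in amounts and inputs, dose linearity and
superposition (diet + SCIT = diet-run plus SCIT-only-run) hold exactly up
to solver error, and the test suite verifies both.

## Physiology

Body weight, wet organ masses (bone including marrow, cartilage-free),
and plasma volume are tabulated for a reference female at 11 age knots
(`src/alpbtk/data/growth_female.csv`, adult weight 60 kg, constant from
20 to 50 y — no senescence is modelled) and interpolated with monotone
piecewise-cubic splines on log-mass, which keeps masses positive and the
ODE right-hand side smooth. GFR combines allometric size scaling
(BW^0.75 relative to adult, adult value 110 mL/min) with a Hill-type
maturation function. A maturation sigmoid on *postnatal* age would send
GFR to zero at birth and produce unphysiological neonatal plasma spikes,
so the sigmoid acts on postmenstrual age (offset 0.77 y ~ 40 weeks,
halftime 1.06 y PMA ~ 55 weeks, Hill 3.4), the standard renal-maturation
parametrization in paediatric pharmacokinetics; the maturation fraction is
~0.25 at term birth.

Tissue uptake clearances for liver, kidney and rest scale with organ mass
relative to the adult organ (brain likewise), so a newborn's liver does
not clear plasma like an adult's. Return rates `k_out` are age-constant.

## Calcium turnover curves

The packaged female curves (`ca_female.csv`) are parametric:
accretion `F_Ca(a) = 150 + 250 exp(-(a - 12.5)^2 / (2 x 1.5^2))` mg/day —
an adult remodeling baseline plus a pubertal peak centred at 12.5 y — and
release `k_rel(a) = (0.15 + 2.35 exp(-a / 9.83)) / 365.25` per day,
declining from the very high turnover of infancy (~2.5/year) to an adult
plateau of 0.15/year (turnover time ~6.7 y at age 35). The shapes are
anchored qualitatively (pubertal accretion peak; children remodel much
faster than adults; adult bone returns to baseline within 5-15 years
after an exposure excursion); the exact functional forms of the source
calcium model are not published, so these are the package's own curves
and can be replaced via `CaKinetics.from_csv`.

## Dosing

Dietary intake tiers are 0.1, 0.2, 0.4 and 0.8 mg Al/kg/week for months
0-3, 4-6, 7-9 and 10-12, then 0.8 mg/kg/week for life (80% of the
tolerable weekly intake of 1 mg/kg/week); oral bioavailability is 0.17%.
Intake is continuous (zero-order), not discrete meals.

SCIT schedules use the highest authorized dose (1.25 mg Al) at the
shortest recommended interval (28 days). A treatment-year is defined as
13 doses = 364 days so that 5-, 2x5-, and 40-year schedules contain
exactly 65, 130 and 520 doses (81.25, 162.5 and 650 mg Al) — the only
convention consistent with all three counts. Whether the first dose falls
at treatment start or one interval later is not specified anywhere; the
first dose is placed at treatment start. Consecutive blocks follow
back-to-back with no gap. Parallel products share the individual's depot
release-rate draw, and one draw is shared across a person's depots
(simplest consistent choice). Updosing phases carry negligible Al and are
omitted.

## Parameter values and calibration

The dietary tiers, oral bioavailability, depot release rates, depot-rate
CV of 50%, dry-to-wet conversion factors and all tissue thresholds are
fixed constants of the problem. The remaining rate constants of the
whole-body model are not published. They were fixed in two steps:

1. **Analytic start values** from steady-state identities
   (`ModelParameters.analytic_start`): an adult female on the default diet
   absorbs ~11.7 ug/day, so plasma 1.4 ug/L requires renal clearance
   ~8.3 L/day (`fE ~ 0.052` of a 158 L/day GFR); adult tissue/plasma
   amount ratios implied by normal adult tissue levels fix `k_in/k_out`
   per organ; the brain uptake clearance follows from the adult brain
   accumulation rate, and `kappa` from the adult bone level and release
   rate. `k_out` values (liver 0.003, kidney 0.0102, rest 0.001 per day)
   and the rest-of-body clearance (10 L/day) are fixed by convention:
   they set equilibration times (months to ~3 years) that make liver and
   kidney reach adult steady state while plasma transients during a 5-year
   treatment are partially buffered.
2. **Calibration** (`alpbtk.calibration`): a deterministic Nelder-Mead
   least-squares fit on the log scale of five free constants
   (`renal_extraction`, `k_brain_in`, `kappa_bone`, `k_in.liver`,
   `k_in.kidney`) against population-typical dietary-only medians: plasma
   1.4 ug/L at 40 y; bone 0.6 ug/g ww at 40 and 50 y; brain 0.23 and 0.28
   ug/g ww at 40 and 50 y; liver 1.0 and kidney 0.5 ug/g ww at adult
   steady state. The fit lands within 11% on every target and ships as
   `data/default_parameters.json`, with provenance notes separating
   anchored from calibrated constants. A synthetic-recovery test (targets
   generated from known parameters, fit restarted from a perturbed start)
   shows the identifiable subset {renal extraction, bone coupling, brain
   clearance} is recovered within 5%; the conventions of step 1 pin the
   rest.

Birth amounts (plasma 0.4, bone 300, brain 80, liver 50, kidney 8, rest
160 ug; ~600 ug total) represent the burden built up in utero and are
chosen so that neonatal concentrations start high and dip as growth
dilutes them — the characteristic dietary-only life-course shape — while
keeping the newborn whole-body burden in the few-hundred-microgram range
reported for neonates.

Because only dietary-exposure medians constrain the fit, the *increments*
during a SCIT window are genuine model predictions with no anchor: this
implementation buffers an injection stream less strongly than the source
model evidently does, so predicted plasma and brain increments during and
after treatment are larger than the published ones (e.g. plasma roughly
triples during a childhood treatment here versus roughly doubling there).
Conclusions that rest on washout — bone returning to baseline by age 50,
the p95 ratio 50/50 of 1.0 — are robust to this, because they depend on
the bone and depot release rates, not on the plasma increment. Pediatric
dietary-only bone medians also sit below the published ones (~0.12 vs
~0.4 ug/g ww at age 10): with uptake proportional to calcium accretion
and release at the full childhood turnover rate, childhood bone cannot
hold as much Al as the source model predicts unless the coupling itself
is age-dependent. All shape claims about childhood are therefore asserted
as inequalities, not absolute levels.

## Population simulation

Inter-individual variability is lognormal with median exactly 1
(`sigma^2 = ln(1 + CV^2)`): CV 0.50 on the depot release rate and 0.30
(configurable) on oral bioavailability, GFR and tissue distribution; the
distribution multiplier scales *all* uptake clearances including brain
and bone coupling. Draws are independent; one `(n, 4)` standard-normal
block per seed, so a population is identical no matter which scenario
consumes it (common random numbers), and every treated-versus-baseline
contrast is paired individual by individual. The default population is
N = 500 females.

## Numerics

* Time unit days; 1 year = 365.25 days (the 364-day treatment-year is
  used only for schedule construction). Horizon 50 years.
* Adaptive LSODA with rtol 1e-8, atol 1e-10 ug, analytic Jacobian,
  restarted at every dietary tier boundary, dose time and depot
  exhaustion time, so the piecewise-constant inputs are exact.
* Age-dependent coefficients are pre-sampled on a daily grid and
  interpolated linearly inside the right-hand side; this costs < 1e-3
  relative accuracy (verified against the independent fixed-step
  integrator) and makes a 500-individual, two-scenario comparison run in
  minutes on one CPU.
* Mass balance — birth amounts + absorbed diet + depot release versus
  final amounts + urine, with the dietary integral computed exactly on
  the same piecewise-linear body-weight curve the solver sees — holds to
  < 1e-6 relative and is asserted for every tested scenario.
* The fixed-step verification oracle (explicit RK4) halves its step and
  restarts when it detects instability; the calibrated model's neonatal
  phase (fast clearances, small plasma volume) is too stiff for 0.25-day
  explicit steps, so the life-course comparison typically runs at
  0.125 days.
* Quantiles use linear interpolation between order statistics (numpy
  default); the p95 confidence interval is a seeded nonparametric
  bootstrap (percentile method, B = 1000). An order-statistic interval
  was considered and dropped: at N = 500 the bootstrap is equally
  distribution-free and simpler to seed reproducibly.
* Rounding in report tables follows the display convention of one decimal
  for ratios (two for the brain 50/50 ratio); raw values are retained.

## Problem sizes used in tests

Exact arithmetic checks are instantaneous. Structural ODE properties use
the population-typical individual. The full washout check (bone p95 ratio
50/50 = 1.0 for the five-year childhood treatment) runs both scenarios at
N = 500 on one shared population; qualitative life-course shape checks
(neonatal dip-then-rise, transient bone peak, 40-year accumulation above
the bone ULN of 5 ug/g ww) run at N = 50, which is ample for
median/percentile inequalities.

## Known limitations

* No renal impairment, pregnancy, obesity or senescence; ages beyond 50
  are outside the model's validity.
* Absolute SCIT-window increments in plasma, brain, liver and kidney are
  overestimated relative to the source predictions (see calibration
  section); ratios built on washout are unaffected.
* The calcium curves are qualitative stand-ins with the right peak
  location and turnover ordering, not fitted to calcium balance data.
* Depot kinetics are zero-order with 100% bioavailability — a worst-case
  reading; no lymphatic lag or local transformation at the injection site.
* Thresholds enter only the assessment layer; nothing in the simulation
  depends on them.
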