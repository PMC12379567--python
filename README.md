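# alpbtk — population toxicokinetics of aluminium from diet and SCIT adjuvants

`alpbtk` is a physiologically-based toxicokinetic (PBTK) simulator for
aluminium (Al) exposure over the human life course, written for
pharmacometricians and regulatory toxicologists who need to quantify how
much Al accumulates in tissues when repeated subcutaneous allergen
immunotherapy (SCIT) with aluminium-hydroxide adjuvants is added to the
dietary background everyone carries.

SCIT products are injected four-weekly for years, each dose carrying up to
1.25 mg Al that drains slowly from the injection-site depot. There are no
clinical toxicokinetic studies of this exposure in children, so the
question — does a treatment started at age 5 leave a mark on the bone and
brain Al burden decades later? — can only be answered by simulation.

## Model

A linear, age-dependent compartment model on Al amounts (plasma, bone,
brain, liver, kidney, rest-of-body, urine), integrated from birth to age
50 for a reference female:

* growth dilution is implicit (concentration = amount / growing organ
  mass), renal elimination is `fE · GFR(a) · C_plasma` with GFR maturing
  after birth;
* bone uptake is proportional to the age-dependent calcium accretion flux
  `κ · F_Ca(a) · C_plasma` (pubertal peak included) and bone release is
  first-order at the calcium turnover rate `k_rel(a)` — high in
  childhood, slow in adults — which makes treatment-induced bone excess
  transient;
* brain has uptake but no efflux (a sink), so brain burden accumulates
  for life;
* each injection is a zero-order depot releasing `k · dose` per day until
  exhaustion at `1/k` days (`k` = 0.0024864/day for commercial hydroxide,
  0.0082392/day for in-situ precipitated hydroxide);
* virtual populations (default N = 500 females) draw lognormal
  multipliers (median 1) on oral bioavailability, GFR, tissue
  distribution (CV 30%) and depot release rate (CV 50%), and the same
  population is reused across scenarios so contrasts are paired.

Eight scenarios are built in: dietary exposure only (`food_only`) and
seven `FOOD+SCIT` variants (five-year treatments started at 5/10/35 years,
an in-situ adjuvant variant, two consecutive blocks, a 40-year treatment,
and two products in parallel). Population results are summarised as
median/p5/p95 with bootstrap confidence intervals, p95 ratios against the
paired baseline, dry-to-wet-weight conversions and exceedance fractions
against literature tissue thresholds (bone ULN 5, critical 7, disease
30 µg/g ww). See `docs/methods.md` for assumptions, parameter provenance
and limitations.

## Worked example

```python
import numpy as np
from alpbtk import (Simulator, ModelParameters, get_scenario, sample_population,
                    run_population, percentile_summary, bootstrap_p95_ci,
                    convert_dw_ww, margin_of_safety)

params = ModelParameters.default()
scen = get_scenario("child_high_ahy_5")        # 5-year SCIT started at age 5
print("dose events:", len(scen.events()), "| cumulative dose:",
      scen.cumulative_dose_mg(), "mg Al")

pop = sample_population(n=50, seed=1)          # one population, reused below
grid = Simulator(scen, params=params).default_grid()
food = run_population(pop, get_scenario("food_only"), params=params, grid=grid)
scit = run_population(pop, scen, params=params, grid=grid)

bone50_food = food.values_at("bone", 50.0)
bone50_scit = scit.values_at("bone", 50.0)
s = percentile_summary(bone50_scit)
lo, hi = bootstrap_p95_ci(bone50_scit, seed=1)
print(f"bone at age 50 (FOOD+SCIT): median {s['median']:.2f}, "
      f"p95 {s['p95']:.2f} (90% CI {lo:.2f}-{hi:.2f}) ug/g ww")
ratio = np.quantile(bone50_scit, 0.95) / np.quantile(bone50_food, 0.95)
print(f"bone p95 ratio 50/50: {ratio:.3f} -> reported as {round(ratio, 1)}")
print(f"bone ULN {convert_dw_ww(10.0, 'bone'):.2f} ug/g ww; "
      f"safety margin to overt disease: {margin_of_safety(30.0, 7.0):.1f}-fold")
```

Output:

```
dose events: 65 | cumulative dose: 81.25 mg Al
bone at age 50 (FOOD+SCIT): median 0.71, p95 1.28 (90% CI 1.13-1.79) ug/g ww
bone p95 ratio 50/50: 1.038 -> reported as 1.0
bone ULN 4.97 ug/g ww; safety margin to overt disease: 4.3-fold
```

The 65 four-weekly doses (81.25 mg Al in total) raise bone Al during the
treatment window, but childhood bone remodeling releases the excess: by
age 50 the treated population's 95th percentile is indistinguishable from
the untreated one (ratio 1.0), while the depot-derived Al that reached
brain remains there. The bone level itself stays far below the 5 µg/g ww
upper limit of normal.

A thin CLI wraps the same functionality:

```bash
alpbtk schedule --scenario child_high_ahy_5
alpbtk run --scenario food_only --n 500 --seed 1 --out runs/food
alpbtk run --scenario child_high_ahy_5 --n 500 --seed 1 --out runs/child
alpbtk report --baseline runs/food --treated runs/child --out table1.csv
alpbtk calibrate --out params.json
```

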