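import numpy as np
import pytest

from alpbtk import ModelParameters, Simulator, get_scenario, mass_balance
from alpbtk.dosing import DietaryScheme
from alpbtk.pbtk_core import COMPARTMENTS
from alpbtk.scenarios import Scenario

from conftest import one_compartment_params

NEGLIGIBLE_DIET = DietaryScheme(
    tiers=((0.0, float("inf"), 1e-12),), oral_bioavailability=0.0017
)


def _zero_params():
    p = ModelParameters.analytic_start()
    p.birth_amounts = {c: 0.0 for c in COMPARTMENTS[:-1]}
    return p


def test_zero_input_gives_identically_zero_trajectories():
    scen = Scenario(name="nothing", dietary=NEGLIGIBLE_DIET)
    res = Simulator(scen, params=_zero_params()).run()
    assert np.all(np.abs(res.amounts) < 1e-6)


def test_rhs_conserves_mass_and_brain_has_no_efflux(params):
    sim = Simulator(get_scenario("food_only"), params=params)
    seg = [0.8, 5.0]  # diet tier, depot release rate
    rhs, jac = sim._make_rhs((1.0, 1.0, 1.0, 1.0), seg)
    rng = np.random.default_rng(0)
    for t in (10.0, 2000.0, 15000.0):
        y = rng.uniform(0.0, 100.0, size=7)
        dy = rhs(t, y)
        # total derivative equals external input (diet + depot): internal
        # exchange and elimination cancel because urine is a state
        diet = rhs(t, np.zeros(7))[0] - seg[1]
        assert dy.sum() == pytest.approx(diet + seg[1], rel=1e-9)
        # brain gains only via plasma; zero plasma -> zero brain derivative
        y0 = y.copy()
        y0[0] = 0.0
        assert rhs(t, y0)[2] == 0.0
        # jacobian row for brain has no dependence on brain itself (sink)
        assert jac(t, y)[2, 2] == 0.0


def test_mass_balance_default_scenarios(typical_food, typical_child):
    assert mass_balance(typical_food) < 1e-6
    assert mass_balance(typical_child) < 1e-6


def test_no_input_run_balance_is_exact():
    scen = Scenario(name="decay_only", dietary=NEGLIGIBLE_DIET)
    p = _zero_params()
    p.birth_amounts["bone"] = 1000.0
    res = Simulator(scen, params=p).run()
    # everything that left bone is in other compartments or urine
    assert mass_balance(res) < 1e-6
    assert res.inputs["sc_injected_total"] == 0.0


def test_plasma_plateau_and_brain_sink_under_dietary_exposure(typical_food):
    res = typical_food
    c30 = res.value_at("plasma", 30.0)
    for age in np.arange(30.0, 50.0, 1.0):
        slope = res.value_at("plasma", age + 1.0) - res.value_at("plasma", age)
        assert abs(slope) / c30 < 0.01  # < 1 %/year
    brain = res.amount("brain")
    assert np.all(np.diff(brain) >= -1e-9)


def test_non_negative_states_everywhere(typical_food, typical_child):
    for res in (typical_food, typical_child):
        assert np.all(res.amounts >= 0.0)


def test_dose_linearity_of_the_scit_increment(params):
    """Scaling every SCIT dose by c scales (treated - baseline) by c."""
    from dataclasses import replace

    base = Simulator(get_scenario("food_only"), params=params)
    scen1 = get_scenario("child_high_ahy_5")
    grid = Simulator(scen1, params=params).default_grid()
    r0 = base.run(grid=grid)
    r1 = Simulator(scen1, params=params).run(grid=grid)
    blocks3 = tuple(replace(b, dose_mg=3 * b.dose_mg) for b in scen1.scit_blocks)
    scen3 = Scenario(name="child_x3", scit_blocks=blocks3)
    r3 = Simulator(scen3, params=params).run(grid=grid)
    d1 = r1.amounts - r0.amounts
    d3 = r3.amounts - r0.amounts
    scale = np.max(np.abs(d3))
    assert np.max(np.abs(d3 - 3.0 * d1)) / scale < 1e-5


def test_superposition_of_diet_and_scit(params):
    """FOOD+SCIT equals FOOD ONLY plus a SCIT-only run, compartmentwise."""
    scen = get_scenario("child_high_ahy_5")
    grid = Simulator(scen, params=params).default_grid()
    food = Simulator(get_scenario("food_only"), params=params).run(grid=grid)
    both = Simulator(scen, params=params).run(grid=grid)
    p0 = params.copy()
    p0.birth_amounts = {c: 0.0 for c in COMPARTMENTS[:-1]}
    scit_only = Simulator(
        Scenario(name="scit_only", dietary=NEGLIGIBLE_DIET, scit_blocks=scen.scit_blocks),
        params=p0,
    ).run(grid=grid)
    lhs = both.amounts
    rhs = food.amounts + scit_only.amounts
    assert np.max(np.abs(lhs - rhs)) / np.max(np.abs(lhs)) < 1e-5


def test_bone_excess_transient_but_brain_excess_permanent(params):
    scen = get_scenario("child_high_ahy_5")
    grid = Simulator(scen, params=params).default_grid()
    food = Simulator(get_scenario("food_only"), params=params).run(grid=grid)
    both = Simulator(scen, params=params).run(grid=grid)
    ages = food.age_years
    bone_excess = both.amount("bone") - food.amount("bone")
    brain_excess = both.amount("brain") - food.amount("brain")
    peak = bone_excess.max()
    assert bone_excess[np.searchsorted(ages, 49.9)] < 0.02 * peak
    in_or_after = ages >= 5.0
    assert np.all(np.diff(brain_excess[in_or_after]) >= -1e-9)
    assert brain_excess[-1] > 0


def test_grid_validation_and_solver_reporting(params):
    sim = Simulator(get_scenario("food_only"), params=params)
    with pytest.raises(ValueError):
        sim.run(grid=np.array([10.0, 20.0]))  # does not start at 0


def test_one_compartment_collapse_matches_closed_form(flat_profile, ca):
    from alpbtk.oracles import analytic_one_compartment

    p = one_compartment_params()
    scen = Scenario(name="flat_food", dietary=DietaryScheme(tiers=((0.0, float("inf"), 0.8),)))
    sim = Simulator(scen, params=p, profile=flat_profile, ca=ca)
    res = sim.run()
    k_el = p.renal_extraction * (100.0 * 1.44) / 2.5  # fE * GFR[L/day] / V_pl
    rate = 0.8 * 60.0 * 1000.0 / 7.0 * 0.0017
    expected = analytic_one_compartment(
        k_el, [(0.0, res.age_days[-1], rate)], a0=100.0, times=res.age_days
    )
    err = np.max(np.abs(res.amount("plasma") - expected) / np.max(expected))
    assert err < 1e-6
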