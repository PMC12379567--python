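import numpy as np
import pytest

from alpbtk import (
    ModelParameters,
    Simulator,
    default_ca_kinetics,
    default_profile,
    get_scenario,
    run_population,
    sample_population,
)

POP_SEED = 20260923


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def ca():
    return default_ca_kinetics()


@pytest.fixture(scope="session")
def params():
    return ModelParameters.default()


@pytest.fixture(scope="session")
def typical_food(params):
    """Population-typical individual, dietary exposure only."""
    return Simulator(get_scenario("food_only"), params=params).run()


@pytest.fixture(scope="session")
def typical_child(params):
    """Population-typical individual, five-year childhood SCIT on top of diet."""
    return Simulator(get_scenario("child_high_ahy_5"), params=params).run()


@pytest.fixture(scope="session")
def common_grid(params):
    """One output grid usable for every scenario (includes child dose times)."""
    return Simulator(get_scenario("child_high_ahy_5"), params=params).default_grid()


@pytest.fixture(scope="session")
def pop50(params):
    return sample_population(50, seed=POP_SEED)


@pytest.fixture(scope="session")
def runs50(pop50, params, common_grid):
    """Smoke-scale population runs shared across qualitative shape tests."""
    out = {}
    for name in ("food_only", "child_high_ahy_5", "child_high_ains_5", "adol_high_ahy_40"):
        grid = common_grid if name != "adol_high_ahy_40" else None
        out[name] = run_population(pop50, get_scenario(name), params=params, grid=grid)
    return out


@pytest.fixture(scope="session")
def pop500(params):
    return sample_population(500, seed=POP_SEED)


@pytest.fixture(scope="session")
def runs500(pop500, params, common_grid):
    """Full-scale paired runs for the washout ratio check."""
    return {
        name: run_population(pop500, get_scenario(name), params=params, grid=common_grid)
        for name in ("food_only", "child_high_ahy_5")
    }


@pytest.fixture(scope="session")
def recovery_report(params):
    """Synthetic parameter recovery: refit free constants against targets
    generated by a known parameter set, from a perturbed start."""
    from alpbtk.calibration import (
        CalibrationTarget,
        CalibrationTargets,
        calibrate,
        predict_targets,
    )

    free = ("renal_extraction", "kappa_bone", "k_brain_in")
    sim_kw = {"rtol": 1e-6, "atol": 1e-8}
    truth = params.copy()
    base_targets = CalibrationTargets.default()
    vals = predict_targets(truth, base_targets, **sim_kw)
    synth = CalibrationTargets(
        tuple(
            CalibrationTarget(t.tissue, t.age_y, float(v))
            for t, v in zip(base_targets.targets, vals)
        )
    )
    start = truth.copy()
    start.renal_extraction *= 1.3
    start.kappa_bone *= 0.7
    start.k_brain_in *= 1.25
    fitted, report = calibrate(synth, free_params=free, start=start, maxiter=250, **sim_kw)
    return truth, fitted, report


@pytest.fixture(scope="session")
def flat_profile():
    """Growth-frozen adult profile: constant physiology, instant GFR maturation."""
    from alpbtk.physiology import GFRModel, GrowthTable, PhysiologyProfile

    knots = np.array([0.0, 25.0, 50.0])
    const = lambda v: np.full(3, v)
    growth = GrowthTable(
        age_knots=knots,
        body_weight=const(60.0),
        organ_mass={
            "bone": const(6800.0),
            "brain": const(1300.0),
            "liver": const(1400.0),
            "kidney": const(275.0),
            "rest": const(47645.0),
        },
        plasma_volume=const(2.5),
    )
    gfr = GFRModel(adult_gfr=100.0, maturation_halftime=1e-9)
    return PhysiologyProfile(sex="female", growth=growth, gfr_model=gfr)


def one_compartment_params(k_brain=1e-30):
    """Parameters that collapse the model to plasma with renal loss only."""
    return ModelParameters(
        k_in={"liver": 0.0, "kidney": 0.0, "rest": 0.0},
        k_out={"liver": 0.0, "kidney": 0.0, "rest": 0.0},
        k_brain_in=k_brain,
        kappa_bone=0.0,
        renal_extraction=0.05,
        birth_amounts={"plasma": 100.0},
    )
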