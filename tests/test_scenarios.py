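import json

import numpy as np
import pytest

from alpbtk import REGISTRY, get_scenario
from alpbtk.scenarios import scenario_from_config


@pytest.mark.parametrize(
    "name,n_events,total_mg,start",
    [
        ("food_only", 0, 0.0, None),
        ("child_high_ahy_5", 65, 81.25, 5.0),
        ("adol_high_ahy_5", 65, 81.25, 10.0),
        ("adult_high_ahy_5", 65, 81.25, 35.0),
        ("child_high_ains_5", 65, 81.25, 5.0),
        ("child_high_ahy_2x5", 130, 162.5, 5.0),
        ("adol_high_ahy_40", 520, 650.0, 10.0),
        ("child_2xhigh_ahy_5", 130, 162.5, 5.0),
    ],
)
def test_registry_dose_counts_and_cumulative_amounts(name, n_events, total_mg, start):
    scen = get_scenario(name)
    events = scen.events()
    assert len(events) == n_events
    assert scen.cumulative_dose_mg() == pytest.approx(total_mg, abs=1e-9)
    assert scen.start_age_y == start
    if events:
        assert events[0].time == pytest.approx(start * 365.25)
        assert all(e.amount == 1.25 for e in events)


def test_adjuvant_assignment_in_registry():
    assert {e.adjuvant for e in get_scenario("child_high_ains_5").events()} == {"Ains"}
    assert {e.adjuvant for e in get_scenario("child_high_ahy_5").events()} == {"Ahy"}


def test_consecutive_blocks_are_back_to_back():
    scen = get_scenario("child_high_ahy_2x5")
    b1, b2 = scen.scit_blocks
    assert b2.start_age_y * 365.25 == pytest.approx(b1.end_day)


def test_unknown_scenario_lists_alternatives():
    with pytest.raises(KeyError) as err:
        get_scenario("child_high_ahy5")
    assert "child_high_ahy_5" in str(err.value)


def test_scenario_from_config_roundtrip(tmp_path):
    cfg = {
        "name": "custom",
        "blocks": [{"start_age_y": 7.0, "years": 3, "dose_mg": 0.5, "adjuvant": "Ains"}],
    }
    path = tmp_path / "scen.yaml"
    path.write_text(json.dumps(cfg))  # JSON is valid YAML
    scen = scenario_from_config(path)
    assert len(scen.events()) == 39
    assert scen.cumulative_dose_mg() == pytest.approx(19.5)


def test_in_situ_adjuvant_reaches_similar_bone_levels(runs50):
    """Faster depot release changes the rise, not the 5-year bone level."""
    ahy = runs50["child_high_ahy_5"]
    ains = runs50["child_high_ains_5"]
    p95 = lambda prun: np.quantile(prun.values_at("bone", 10.0), 0.95)
    assert p95(ains) == pytest.approx(p95(ahy), rel=0.10)
    # steeper early rise with the faster adjuvant, one year into treatment
    med = lambda prun, a: np.median(prun.values_at("bone", a))
    base = runs50["food_only"]
    assert med(ains, 6.0) - med(base, 6.0) > med(ahy, 6.0) - med(base, 6.0)


def test_persisted_run_is_deterministic(tmp_path, params):
    from alpbtk import sample_population
    from alpbtk.scenarios import run

    pop = sample_population(3, seed=5)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    run("food_only", pop, d1, params=params)
    run("food_only", pop, d2, params=params)
    for fn in ("summary_timecourses.csv", "timepoint_values.csv", "population.csv", "manifest.json"):
        assert (d1 / fn).read_bytes() == (d2 / fn).read_bytes()
    man = json.loads((d1 / "manifest.json").read_text())
    assert man["seed"] == 5 and man["n"] == 3 and man["failures"] == []


def test_all_builtins_share_dose_and_interval():
    for name, scen in REGISTRY.items():
        for b in scen.scit_blocks:
            assert b.interval_days == 28.0 and b.dose_mg == 1.25
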