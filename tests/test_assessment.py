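import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpbtk import (
    ThresholdTable,
    bootstrap_p95_ci,
    convert_dw_ww,
    exceedance_fraction,
    margin_of_safety,
    p95_ratios,
    percentile_summary,
)


def test_percentile_summary_linear_interpolation_convention():
    s = percentile_summary(np.arange(1.0, 101.0))
    assert s["p95"] == pytest.approx(95.05)
    assert s["median"] == pytest.approx(50.5)
    assert s["p5"] == pytest.approx(5.95)


def test_percentile_summary_degenerate_and_errors():
    s = percentile_summary(np.full(10, 3.3))
    assert s["p5"] == s["median"] == s["p95"] == 3.3
    with pytest.raises(ValueError):
        percentile_summary([1.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.001, 1e6), min_size=2, max_size=200))
def test_percentile_summary_ordered_and_permutation_invariant(vals):
    v = np.array(vals)
    s = percentile_summary(v)
    assert s["p5"] <= s["median"] <= s["p95"]
    assert percentile_summary(v[::-1]) == s


def test_bootstrap_ci_seeded_and_contains_point_estimate():
    rng = np.random.default_rng(5)
    v = rng.lognormal(0.0, 0.5, size=500)
    ci1 = bootstrap_p95_ci(v, seed=42)
    ci2 = bootstrap_p95_ci(v, seed=42)
    assert ci1 == ci2
    p95 = np.quantile(v, 0.95)
    assert ci1[0] <= p95 <= ci1[1]
    assert bootstrap_p95_ci(np.full(50, 2.0), seed=0) == (2.0, 2.0)
    with pytest.raises(ValueError):
        bootstrap_p95_ci(v[:10])


def test_bootstrap_ci_width_shrinks_with_sample_size():
    rng = np.random.default_rng(1)
    widths = []
    for n in (125, 500, 2000):
        v = rng.lognormal(0.0, 0.5, size=n)
        lo, hi = bootstrap_p95_ci(v, seed=9)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_p95_ratio_definitions():
    base5 = np.linspace(1.0, 2.0, 100)
    base50 = np.linspace(2.0, 4.0, 100)
    same = p95_ratios(base5, base50, base5, base50)
    assert (same.ratio_5_5, same.ratio_50_50) == (1.0, 1.0)
    doubled = p95_ratios(2.0 * base5, base50, base5, base50)
    assert doubled.ratio_5_5 == pytest.approx(2.0)
    assert doubled.ratio_50_50 == pytest.approx(1.0)
    # 5.5 / 5.2 = 1.058 -> reported as 1.1 at one decimal
    r = p95_ratios(np.full(100, 5.5), base50, np.full(100, 5.2), base50)
    assert round(r.ratio_5_5, 1) == 1.1
    with pytest.raises(ValueError):
        p95_ratios(base5[:10], base50, base5, base50)


def test_dry_to_wet_weight_conversions():
    assert convert_dw_ww(10.0, "bone") == pytest.approx(4.97)
    assert convert_dw_ww(14.0, "bone") == pytest.approx(6.958)
    assert convert_dw_ww(4.5, "brain") == pytest.approx(1.035)
    with pytest.raises(KeyError):
        convert_dw_ww(1.0, "kidney")  # no factor is published for kidney


def test_threshold_table_ordering_enforced():
    t = ThresholdTable()
    assert t.uln_ww["bone"] < t.bone_critical < t.bone_disease
    with pytest.raises(ValueError):
        ThresholdTable(bone_critical=40.0)


def test_exceedance_fraction():
    v = np.arange(1.0, 1001.0)
    assert exceedance_fraction(v, v.max() + 1) == 0.0
    assert exceedance_fraction(v, np.quantile(v, 0.95)) == pytest.approx(0.05, abs=0.005)
    rng = np.random.default_rng(2)
    base = rng.lognormal(0.0, 0.4, 2000)
    treated = base * 1.3
    assert exceedance_fraction(treated, float(np.quantile(base, 0.95))) > 0.05


def test_margin_of_safety():
    assert margin_of_safety(30.0, 7.0) == pytest.approx(4.29, abs=0.01)
    assert margin_of_safety(30.0, 5.0) == 6.0
    assert margin_of_safety(7.0, 7.0) == 1.0
    with pytest.raises(ValueError):
        margin_of_safety(30.0, 0.0)


def test_build_table1_layout_and_population_guard(runs50):
    from alpbtk import build_table1

    runs = {k: runs50[k] for k in ("food_only", "child_high_ahy_5")}
    df = build_table1(runs, ci_seed=1)
    base_rows = df[df.scenario == "food_only"]
    assert base_rows["ratio_5_5"].isna().all()
    treated = df[df.scenario == "child_high_ahy_5"]
    assert set(treated["tissue"]) == {"plasma", "bone", "brain"}
    assert (treated["ratio_5_5"].astype(float) >= 1.0).all()
    # identical populations are required
    from alpbtk import sample_population, run_population, get_scenario

    other = run_population(sample_population(10, seed=999), get_scenario("food_only"))
    with pytest.raises(ValueError):
        build_table1({"food_only": other, "child_high_ahy_5": runs50["child_high_ahy_5"]})


def test_table1_deterministic_for_fixed_seed(runs50):
    from alpbtk import build_table1

    runs = {k: runs50[k] for k in ("food_only", "child_high_ahy_5")}
    df1 = build_table1(runs, ci_seed=3)
    df2 = build_table1(runs, ci_seed=3)
    assert df1.equals(df2)
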