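"""Screen effect estimation, call rules and cross-tabulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqmod.screen import (
    CONTROL,
    EffectEstimate,
    ModifierCall,
    call_aggregation,
    call_toxicity,
    classify_screen,
    cross_tabulate,
    normalize_activity,
    relative_effects,
    validate_plate_table,
)
from polyqmod.synthetic import gen_screen_plate


def make_plate(control_means, modifier_means, n_reps=3, modifier="M1"):
    """Deterministic plate: replicate values equal to the requested means
    plus a fixed +/- spread so variances are non-zero."""
    rows = []
    spread = np.linspace(-0.01, 0.01, n_reps)
    for exp, (cm, mm) in enumerate(zip(control_means, modifier_means), start=1):
        for rep in range(n_reps):
            rows.append([exp, rep + 1, CONTROL, "with_reporter", cm + spread[rep], 1])
            rows.append([exp, rep + 1, modifier, "with_reporter", mm + spread[rep], 1])
    return pd.DataFrame(
        rows,
        columns=["experiment", "replicate", "modifier", "condition",
                 "fluorescence", "cell_count"],
    )


# ---------------------------------------------------------------------------
# normalize_activity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fl, cells, expected", [(1000, 1000, 1.0), (0, 500, 0.0), (1500, 750, 2.0)]
)
def test_normalize_activity(fl, cells, expected):
    assert normalize_activity(fl, cells) == pytest.approx(expected)


def test_normalize_activity_rejects_nonpositive_cells():
    with pytest.raises(ValueError):
        normalize_activity(100, 0)


# ---------------------------------------------------------------------------
# relative_effects
# ---------------------------------------------------------------------------


def test_per_experiment_effects_from_means():
    plate = make_plate([1.0, 1.0, 1.0], [1.35, 1.28, 1.41])
    est = relative_effects(plate, "M1")
    assert est.effects == pytest.approx([0.35, 0.28, 0.41], abs=1e-9)


def test_identical_modifier_has_zero_effect_and_p_one():
    plate = make_plate([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    est = relative_effects(plate, "M1")
    assert est.effects == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)
    assert est.p_value == pytest.approx(1.0)


def test_pooled_t_matches_scipy_oracle():
    rng = np.random.default_rng(3)
    plate, _ = gen_screen_plate(
        effect_map={"M1": (1.4, 1.0)}, cv=0.05, n_control_replicates=3, seed=3
    )
    est = relative_effects(plate, "M1")
    sub = plate[plate["condition"] == "with_reporter"]
    mod = sub[sub["modifier"] == "M1"]
    ctl = sub[sub["modifier"] == CONTROL]
    t, p = stats.ttest_ind(
        mod["fluorescence"] / mod["cell_count"],
        ctl["fluorescence"] / ctl["cell_count"],
        equal_var=True,
    )
    assert est.t_statistic == pytest.approx(float(t))
    assert est.p_value == pytest.approx(float(p))


def test_recovers_planted_effect_within_ten_points():
    plate, _ = gen_screen_plate(effect_map={"M1": (1.4, 1.0)}, cv=0.05, seed=12)
    est = relative_effects(plate, "M1")
    assert np.all(np.abs(np.array(est.effects) - 0.40) < 0.10)


def test_missing_control_rejected():
    plate = make_plate([1.0], [1.2])
    plate = plate[plate["modifier"] != CONTROL]
    with pytest.raises(ValueError, match="no control"):
        relative_effects(plate, "M1")


def test_zero_control_mean_rejected():
    plate = make_plate([0.0], [1.2])
    # exact zeros in all control replicates
    plate.loc[plate["modifier"] == CONTROL, "fluorescence"] = 0.0
    with pytest.raises(ValueError, match="control mean is zero"):
        relative_effects(plate, "M1")


def test_single_replicate_rejected():
    plate = make_plate([1.0], [1.2], n_reps=1)
    with pytest.raises(ValueError, match="2 replicates"):
        relative_effects(plate, "M1")


# ---------------------------------------------------------------------------
# call_toxicity
# ---------------------------------------------------------------------------


def _est(effects, pooled=None, p=1.0):
    pooled = float(np.mean(effects)) if pooled is None else pooled
    return EffectEstimate("M1", list(effects), pooled, 0.0, p, 9)


def test_enhancer_requires_all_three_experiments():
    assert call_toxicity(_est([0.35, 0.28, 0.41])) == "enhancer"
    assert call_toxicity(_est([0.35, 0.15, 0.41])) == "none"


def test_suppressor_rule_and_sign_consistency():
    assert call_toxicity(_est([-0.30, -0.25, -0.22])) == "suppressor"
    assert call_toxicity(_est([-0.30, -0.25, 0.22])) == "none"


def test_exclusion_on_significant_alone_effect():
    alone = _est([0.5, 0.5, 0.5], pooled=0.5, p=0.001)
    assert call_toxicity(_est([-0.30, -0.25, -0.22]), alone) == "excluded"
    # alone effect large but not significant: keep the call
    alone_ns = _est([0.5, 0.5, 0.5], pooled=0.5, p=0.20)
    assert call_toxicity(_est([-0.30, -0.25, -0.22]), alone_ns) == "suppressor"


def test_threshold_is_inclusive():
    assert call_toxicity(_est([0.20, 0.20, 0.20])) == "enhancer"


def test_fewer_than_three_experiments_rejected():
    with pytest.raises(ValueError, match="3 required"):
        call_toxicity(_est([0.3, 0.3]))


def test_calls_are_scale_invariant():
    plate, _ = gen_screen_plate(
        effect_map={"M1": (1.4, 1.0), "M2": (1.0, 1.0)}, cv=0.08, seed=21
    )
    scaled = plate.assign(fluorescence=plate["fluorescence"] * 137.5)
    a = {c.modifier_id: c.toxicity_call for c in classify_screen(plate)}
    b = {c.modifier_id: c.toxicity_call for c in classify_screen(scaled)}
    assert a == b


# ---------------------------------------------------------------------------
# call_aggregation
# ---------------------------------------------------------------------------


def agg_plate(control_vals, modifier_vals):
    rows = []
    for exp, (cvs, mvs) in enumerate(zip(control_vals, modifier_vals), start=1):
        for rep, v in enumerate(cvs, start=1):
            rows.append([exp, rep, CONTROL, "with_reporter", 1.0, 1, v])
        for rep, v in enumerate(mvs, start=1):
            rows.append([exp, rep, "M1", "with_reporter", 1.0, 1, v])
    return pd.DataFrame(
        rows,
        columns=["experiment", "replicate", "modifier", "condition",
                 "fluorescence", "cell_count", "densitometry"],
    )


def test_aggregation_identical_to_control_is_none():
    plate = agg_plate([[100, 100, 100]] * 3, [[100, 100, 100]] * 3)
    call, percent, p = call_aggregation(plate, "M1")
    assert call == "none"
    assert percent == pytest.approx(100.0)


def test_aggregation_enhancer_with_t_oracle():
    ctl = [[100, 101, 99]] * 3
    mod = [[155, 150, 160]] * 3
    plate = agg_plate(ctl, mod)
    call, percent, p = call_aggregation(plate, "M1")
    t, want_p = stats.ttest_ind(np.ravel(mod), np.ravel(ctl), equal_var=True)
    assert call == "enhancer"
    assert percent == pytest.approx(100 * np.mean(mod) / np.mean(ctl))
    assert p == pytest.approx(float(want_p))


def test_aggregation_single_replicate_rejected():
    plate = agg_plate([[100]] * 3, [[150]] * 3)
    with pytest.raises(ValueError, match="2 replicates"):
        call_aggregation(plate, "M1")


def test_aggregation_inconsistent_direction_is_none():
    plate = agg_plate(
        [[100, 100, 100]] * 3, [[150, 151, 149], [152, 150, 148], [50, 51, 49]]
    )
    call, _, _ = call_aggregation(plate, "M1")
    assert call == "none"


# ---------------------------------------------------------------------------
# cross_tabulate
# ---------------------------------------------------------------------------


def test_cross_table_counts_and_conservation():
    calls = (
        [ModifierCall(f"e{i}", "enhancer", "enhancer") for i in range(9)]
        + [ModifierCall(f"x{i}", "enhancer", "none") for i in range(3)]
        + [ModifierCall(f"s{i}", "suppressor", "suppressor") for i in range(2)]
        + [ModifierCall(f"y{i}", "suppressor", "none") for i in range(3)]
        + [ModifierCall(f"z{i}", "suppressor", "enhancer") for i in range(4)]
    )
    tab = cross_tabulate(calls)
    assert tab.loc["enhancer", "enhancer"] == 9
    assert tab.to_numpy().sum() == len(calls)
    assert tab.sum(axis=1)["enhancer"] == 12
    assert tab.sum(axis=1)["suppressor"] == 9


def test_cross_table_empty_input():
    tab = cross_tabulate([])
    assert tab.to_numpy().sum() == 0


def test_cross_table_rejects_excluded_calls():
    with pytest.raises(ValueError, match="excluded"):
        cross_tabulate([ModifierCall("m", "excluded", "none")])


def test_plate_schema_validation():
    with pytest.raises(ValueError, match="missing column"):
        validate_plate_table(pd.DataFrame({"experiment": [1]}))
    bad = make_plate([1.0], [1.0])
    bad.loc[0, "condition"] = "mystery"
    with pytest.raises(ValueError, match="unknown condition"):
        validate_plate_table(bad)
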