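"""Effect classification for the modifier overexpression screen.

The screen co-expresses each candidate modifier with a pathogenic,
aggregation-prone ataxin-1 fragment and reads out apoptosis (caspase-3/7
fluorescence, normalised to cell number) and SDS-insoluble aggregate load
(filter-retardation densitometry).  A modifier is a toxicity *enhancer*
(resp. *suppressor*) when it raises (lowers) normalised caspase activity
relative to the empty-vector control by at least 20% in each of three
independent experiments; hits whose expression alone perturbs caspase
activity are excluded as assay artefacts.  Aggregation effects are called
from densitometry relative to the control (set to 100%) with a two-sample
Student's t-test at alpha = 0.05, requiring a consistent direction across
experiments.  Toxicity and aggregation calls are finally cross-tabulated
on a 3 x 3 grid (enhancer / suppressor / none on each axis).

Input is a tidy ``PlateTable``: one row per well with columns
``experiment``, ``replicate``, ``modifier``, ``condition``
(``with_reporter`` / ``modifier_alone`` / ``reporter_alone``),
``fluorescence``, ``cell_count`` and optional ``densitometry``.  The
control rows use the reserved modifier id ``CONTROL``.

No multiple-testing correction is applied across the screen: each
modifier is called on its own three-experiment rule and per-modifier
t-test, mirroring common practice for small targeted overexpression
screens.  Interpret screen-wide hit lists accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONTROL",
    "PLATE_COLUMNS",
    "EffectEstimate",
    "ModifierCall",
    "validate_plate_table",
    "normalize_activity",
    "relative_effects",
    "call_toxicity",
    "call_aggregation",
    "classify_screen",
    "cross_tabulate",
]

CONTROL = "CONTROL"
PLATE_COLUMNS = [
    "experiment",
    "replicate",
    "modifier",
    "condition",
    "fluorescence",
    "cell_count",
]
CONDITIONS = {"with_reporter", "modifier_alone", "reporter_alone"}
CALLS = ["enhancer", "suppressor", "none"]


@dataclass
class EffectEstimate:
    """Relative effect of one modifier vs control across experiments.

    ``effects[k]`` is the per-experiment relative change of the mean
    normalised activity (+0.35 means +35% over control); the t statistic
    and p-value come from a pooled two-sample test of all normalised
    replicate values, modifier vs control.
    """

    modifier_id: str
    effects: list[float]
    pooled_effect: float
    t_statistic: float
    p_value: float
    n_replicates: int


@dataclass
class ModifierCall:
    """Combined toxicity x aggregation classification of one modifier."""

    modifier_id: str
    toxicity_call: str  # enhancer | suppressor | none | excluded
    aggregation_call: str  # enhancer | suppressor | none
    aggregation_percent: float = float("nan")
    combined_class: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.toxicity_call == "excluded":
            self.combined_class = None
        else:
            self.combined_class = f"{self.toxicity_call}/{self.aggregation_call}"


def validate_plate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the PlateTable schema; returns the table unchanged."""
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plate table is missing column(s) {missing}")
    bad_cond = set(table["condition"].unique()) - CONDITIONS
    if bad_cond:
        raise ValueError(f"unknown condition value(s) {sorted(bad_cond)}")
    if (table["cell_count"] <= 0).any():
        raise ValueError("cell_count must be positive in every row")
    if (table["fluorescence"] < 0).any():
        raise ValueError("fluorescence must be non-negative")
    return table


def normalize_activity(fluorescence, cell_count):
    """Caspase activity per cell: fluorescence / cell_count."""
    cell_count = np.asarray(cell_count, dtype=float)
    if np.any(cell_count <= 0):
        raise ValueError("cell_count must be positive")
    return np.asarray(fluorescence, dtype=float) / cell_count


def _ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Student's t, Welch fallback on zero variance."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test requires >= 2 replicates per group")
    # a group is degenerate when its spread is at rounding level relative to
    # its magnitude (exact zero, or last-ulp differences from normalisation)
    def _degenerate(v: np.ndarray) -> bool:
        scale = max(float(np.max(np.abs(v))), 1e-300)
        return bool(np.ptp(v) <= 1e-9 * scale)

    vx, vy = _degenerate(x), _degenerate(y)
    if vx and vy:
        # noise-free limit: groups are exactly equal or perfectly separated
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    if vx or vy:
        # one degenerate group: the pooled-variance assumption is violated
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def relative_effects(
    table: pd.DataFrame,
    modifier_id: str,
    condition: str = "with_reporter",
    value: str = "normalized",
) -> EffectEstimate:
    """Per-experiment relative effects of a modifier vs control.

    ``value='normalized'`` uses fluorescence / cell_count (the default for
    caspase readouts); ``value='densitometry'`` uses the densitometry
    column directly.
    """
    sub = table[table["condition"] == condition]
    if value == "normalized":
        sub = sub.assign(
            _value=normalize_activity(sub["fluorescence"], sub["cell_count"])
        )
    elif value == "densitometry":
        if "densitometry" not in sub.columns or sub["densitometry"].isna().all():
            raise ValueError("densitometry values are not present in the table")
        sub = sub.assign(_value=sub["densitometry"].astype(float))
    else:
        raise ValueError(f"unknown value kind {value!r}")

    effects: list[float] = []
    mod_all: list[np.ndarray] = []
    ctl_all: list[np.ndarray] = []
    for exp_id, grp in sub.groupby("experiment", sort=True):
        ctl = grp.loc[grp["modifier"] == CONTROL, "_value"].to_numpy()
        mod = grp.loc[grp["modifier"] == modifier_id, "_value"].to_numpy()
        if len(ctl) == 0:
            raise ValueError(f"experiment {exp_id!r} has no control rows")
        if len(mod) == 0:
            continue
        if len(mod) < 2 or len(ctl) < 2:
            raise ValueError(
                f"experiment {exp_id!r}: >= 2 replicates required "
                f"(control {len(ctl)}, {modifier_id!r} {len(mod)})"
            )
        ctl_mean = ctl.mean()
        if ctl_mean == 0:
            raise ValueError(f"experiment {exp_id!r}: control mean is zero")
        effects.append(mod.mean() / ctl_mean - 1.0)
        mod_all.append(mod)
        ctl_all.append(ctl)
    if not effects:
        raise ValueError(f"modifier {modifier_id!r} not found in condition {condition!r}")
    mod_cat = np.concatenate(mod_all)
    ctl_cat = np.concatenate(ctl_all)
    t, p = _ttest(mod_cat, ctl_cat)
    return EffectEstimate(
        modifier_id=modifier_id,
        effects=effects,
        pooled_effect=float(mod_cat.mean() / ctl_cat.mean() - 1.0),
        t_statistic=t,
        p_value=p,
        n_replicates=len(mod_cat),
    )


def call_toxicity(
    effects: EffectEstimate,
    alone_effects: EffectEstimate | None = None,
    threshold: float = 0.20,
    alpha: float = 0.05,
    n_experiments: int = 3,
) -> str:
    """Toxicity call from per-experiment effects plus the control re-test.

    enhancer: every experiment's effect >= +threshold;
    suppressor: every experiment's effect <= -threshold;
    excluded: the modifier-alone re-test itself shows a significant effect
    (|pooled effect| >= threshold and p < alpha);
    none otherwise.
    """
    if len(effects.effects) < n_experiments:
        raise ValueError(
            f"{effects.modifier_id!r}: {len(effects.effects)} experiments present, "
            f"{n_experiments} required"
        )
    if alone_effects is not None and (
        abs(alone_effects.pooled_effect) >= threshold
        and alone_effects.p_value < alpha
    ):
        return "excluded"
    eff = np.asarray(effects.effects)
    if np.all(eff >= threshold):
        return "enhancer"
    if np.all(eff <= -threshold):
        return "suppressor"
    return "none"


def call_aggregation(
    table: pd.DataFrame,
    modifier_id: str,
    alpha: float = 0.05,
    condition: str = "with_reporter",
) -> tuple[str, float, float]:
    """Aggregation call from filter-assay densitometry.

    Returns (call, percent_of_control, p_value) with the control set to
    100%.  enhancer/suppressor requires t-test p < alpha and a direction
    consistent across experiments; otherwise none.
    """
    est = relative_effects(table, modifier_id, condition=condition, value="densitometry")
    percent = 100.0 * (1.0 + est.pooled_effect)
    eff = np.asarray(est.effects)
    consistent_up = np.all(eff > 0)
    consistent_down = np.all(eff < 0)
    if est.p_value < alpha and consistent_up:
        return "enhancer", percent, est.p_value
    if est.p_value < alpha and consistent_down:
        return "suppressor", percent, est.p_value
    return "none", percent, est.p_value


def classify_screen(
    table: pd.DataFrame,
    threshold: float = 0.20,
    alpha: float = 0.05,
    n_experiments: int = 3,
) -> list[ModifierCall]:
    """Full screen classification: one ModifierCall per modifier.

    Runs the toxicity rule (with the modifier-alone exclusion re-test when
    those rows are present) and, when densitometry is available, the
    aggregation rule.
    """
    validate_plate_table(table)
    calls: list[ModifierCall] = []
    modifiers = [m for m in table["modifier"].unique() if m != CONTROL]
    has_dens = "densitometry" in table.columns and table["densitometry"].notna().any()
    for mod in modifiers:
        eff = relative_effects(table, mod, condition="with_reporter")
        alone = None
        alone_rows = table[
            (table["condition"] == "modifier_alone") & (table["modifier"] == mod)
        ]
        if len(alone_rows) > 0:
            alone = relative_effects(table, mod, condition="modifier_alone")
        tox = call_toxicity(
            eff, alone, threshold=threshold, alpha=alpha, n_experiments=n_experiments
        )
        if has_dens and table.loc[table["modifier"] == mod, "densitometry"].notna().any():
            agg, percent, _ = call_aggregation(table, mod, alpha=alpha)
        else:
            agg, percent = "none", float("nan")
        calls.append(ModifierCall(mod, tox, agg, percent))
    return calls


def cross_tabulate(calls: list[ModifierCall]) -> pd.DataFrame:
    """3 x 3 cross-table of toxicity (rows) vs aggregation (columns).

    Excluded modifiers are not admitted: drop them before tabulating.
    """
    if any(c.toxicity_call == "excluded" for c in calls):
        raise ValueError("excluded modifiers must be dropped before cross-tabulation")
    tab = pd.DataFrame(0, index=CALLS, columns=CALLS, dtype=int)
    for c in calls:
        tab.loc[c.toxicity_call, c.aggregation_call] += 1
    tab.index.name = "toxicity"
    tab.columns.name = "aggregation"
    return tab
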