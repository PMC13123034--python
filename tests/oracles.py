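"""Independent oracles and hand-built fixtures used across the test suite.

These implementations deliberately avoid the package's own code paths:
the score oracle re-derives the diet-quality rule point by point, the
iAUC oracle integrates on a dense sampling grid, and the eligibility
fixture is constructed and verified by hand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# --- diet-quality score oracle ---------------------------------------------

HEALTHY_POINTS = ["whole_grains", "seafood", "vegetables", "fruit", "dairy"]
UNHEALTHY_POINTS = ["refined_grains", "red_meat", "deep_fried", "sweet_dessert"]


def brute_force_score(food_groups, ssb_flag=None, include_ssb=False) -> int:
    """Diet-quality score recomputed verbatim from the verbal rule:
    +1 per healthy group consumed (legumes/soy jointly worth at most 1),
    +1 per unhealthy group NOT consumed; chicken/eggs ignored."""
    s = 0
    for g in HEALTHY_POINTS:
        if g in food_groups:
            s += 1
    if "soy" in food_groups or "legumes_nuts_seeds" in food_groups:
        s += 1
    for g in UNHEALTHY_POINTS:
        if g not in food_groups:
            s += 1
    if include_ssb and not ssb_flag:
        s += 1
    return s


# --- iAUC fine-grid oracle ---------------------------------------------------

def fine_grid_iauc(rel_min: np.ndarray, incr: np.ndarray,
                   convention: str) -> float:
    """Numerical integration of the piecewise-linear incremental curve on a
    1-second grid, with local mesh refinement around sign changes so the
    positive-part integral is resolved well below 1e-6 mmol/L·min."""
    rel = np.asarray(rel_min, float)
    y = np.asarray(incr, float)
    grid = np.arange(rel[0], rel[-1] + 1e-12, 1.0 / 60.0)
    grid = np.clip(grid, rel[0], rel[-1])
    vals = np.interp(grid, rel, y)
    if convention == "net":
        return float(np.trapezoid(vals, grid))
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    extra = [np.linspace(grid[i], grid[i + 1], 1001) for i in sign_change]
    if extra:
        grid = np.unique(np.concatenate([grid, *extra]))
        vals = np.interp(grid, rel, y)
    return float(np.trapezoid(np.maximum(vals, 0.0), grid))


def random_trace(rng, n_readings: int = 12):
    """A randomized piecewise-linear incremental curve over [0, 120] min
    with 15-min knots, guaranteed to include sign changes often."""
    rel = np.arange(0.0, 120.1, 15.0)
    incr = rng.normal(0.0, 1.5, rel.size)
    incr[0] = rng.normal(0.0, 0.5)
    return rel, incr


# --- eligibility fixture ------------------------------------------------------

DAY1 = pd.Timestamp("2024-03-04")
DAY2 = DAY1 + pd.Timedelta(days=1)


def eligibility_fixture():
    """Ten hand-verified meals across two participants.

    Expected verdicts (worked out by hand from the rules: open 2-h fasting
    intervals, anchor reading within 15 min at or before the meal, closing
    reading at or after +120 min, no gap > 20 min in the window):

    PA (readings every 15 min from 00:00, day 1):
      M01 07:00 eligible
      M02 10:00 ineligible (M03 90 min later)        meal_within_post_window
      M03 11:30 ineligible (M02 90 min earlier)      meal_within_pre_window
      M04 14:00 ineligible (14:45/15:00 deleted -> 45-min gap)  cgm_incomplete
      M05 17:00 eligible (M06 exactly 120 min later: open interval)
      M06 19:00 eligible
      M07 21:30 eligible
    PB (readings every 15 min from 00:07, day 2; 07:37 and 07:52 deleted):
      M08 08:00 ineligible (no anchor within 15 min)  cgm_incomplete
      M09 16:00 eligible
      M10 20:00 eligible
    """
    pa_times = [DAY1 + pd.Timedelta(minutes=15 * k) for k in range(96)]
    pa_times = [t for t in pa_times
                if t not in (DAY1 + pd.Timedelta("14:45:00"),
                             DAY1 + pd.Timedelta("15:00:00"))]
    pb_times = [DAY2 + pd.Timedelta(minutes=7 + 15 * k) for k in range(96)]
    pb_times = [t for t in pb_times
                if t not in (DAY2 + pd.Timedelta("07:37:00"),
                             DAY2 + pd.Timedelta("07:52:00"))]
    cgm = pd.DataFrame({
        "participant_id": ["PA"] * len(pa_times) + ["PB"] * len(pb_times),
        "timestamp": pa_times + pb_times,
        "glucose_mmol_l": [5.0] * len(pa_times) + [5.6] * len(pb_times),
    })
    meal_times = {
        "M01": DAY1 + pd.Timedelta("07:00:00"),
        "M02": DAY1 + pd.Timedelta("10:00:00"),
        "M03": DAY1 + pd.Timedelta("11:30:00"),
        "M04": DAY1 + pd.Timedelta("14:00:00"),
        "M05": DAY1 + pd.Timedelta("17:00:00"),
        "M06": DAY1 + pd.Timedelta("19:00:00"),
        "M07": DAY1 + pd.Timedelta("21:30:00"),
        "M08": DAY2 + pd.Timedelta("08:00:00"),
        "M09": DAY2 + pd.Timedelta("16:00:00"),
        "M10": DAY2 + pd.Timedelta("20:00:00"),
    }
    owner = {m: ("PA" if m <= "M07" else "PB") for m in meal_times}
    meals = pd.DataFrame({
        "meal_id": list(meal_times),
        "participant_id": [owner[m] for m in meal_times],
        "eat_time": list(meal_times.values()),
    })
    expected_eligible = {"M01", "M05", "M06", "M07", "M09", "M10"}
    expected_reasons = {
        "M02": "meal_within_post_window",
        "M03": "meal_within_pre_window",
        "M04": "cgm_incomplete",
        "M08": "cgm_incomplete",
    }
    return meals, cgm, expected_eligible, expected_reasons
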