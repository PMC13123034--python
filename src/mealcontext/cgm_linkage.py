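"""Match CGM traces to meals and compute the 2-h postprandial incremental AUC.

A meal's postprandial response is summarized as the incremental area under
the glucose curve (iAUC) over the two hours after the reported eating
time, relative to a baseline obtained by linear interpolation of the
readings bracketing the meal.  Two conventions are provided: ``net``
integrates the signed incremental curve by the trapezoidal rule at the
reading knots; ``positive_only`` integrates only the above-baseline
portion, splitting segments at zero-crossings (Brouns-style).  Units are
mmol/L·minute throughout.

Eligibility mirrors the study restrictions: at least 2 h without another
reported meal on either side (open intervals), and complete CGM coverage
of the 2-h window — a reading within 15 min at or before the meal, a
reading at or after +120 min, and no inter-reading gap above 20 min inside
the window (nominal 15-min cadence plus jitter tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EligibilityError, InvariantError

POST_WINDOW_MIN = 120.0
FASTING_WINDOW_MIN = 120.0
PRE_READING_TOLERANCE_MIN = 15.0
MAX_GAP_MIN = 20.0

CONVENTIONS = ("net", "positive_only")

REASONS = ("cgm_incomplete", "meal_within_pre_window", "meal_within_post_window")


@dataclass
class CgmSeries:
    """One participant's time-ordered 15-min interstitial glucose trace.

    ``times_min`` are minutes since the Unix epoch (float), strictly
    increasing; ``glucose`` in mmol/L, positive.
    """

    participant_id: str
    times_min: np.ndarray
    glucose: np.ndarray

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times_min.shape != self.glucose.shape:
            raise InvariantError("cgm series: times/glucose length mismatch")
        if np.any(np.diff(self.times_min) <= 0):
            raise InvariantError("cgm series: timestamps not strictly increasing")
        if np.any(self.glucose <= 0):
            raise InvariantError("cgm series: non-positive glucose")


def to_minutes(ts: pd.Series | pd.Timestamp) -> np.ndarray | float:
    """Timestamps → float minutes since the Unix epoch."""
    if isinstance(ts, pd.Timestamp):
        return ts.value / 60e9
    return pd.to_datetime(ts).astype("int64").to_numpy() / 60e9


def cgm_series_by_participant(cgm: pd.DataFrame) -> dict[str, CgmSeries]:
    """Split a validated cgm table into per-participant series."""
    out: dict[str, CgmSeries] = {}
    for pid, grp in cgm.groupby("participant_id", sort=False):
        out[str(pid)] = CgmSeries(
            participant_id=str(pid),
            times_min=to_minutes(grp["timestamp"]),
            glucose=grp["glucose_mmol_l"].to_numpy(dtype=float),
        )
    return out


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def check_eligibility(eat_min: float, participant_meal_mins: np.ndarray,
                      series: CgmSeries | None) -> tuple[bool, str | None]:
    """Eligibility verdict for one meal.

    ``participant_meal_mins`` are ALL reported meal times (minutes) of the
    same participant, possibly including the index meal itself.  Fasting
    windows are open intervals, so a neighbouring meal exactly 120 min away
    does not disqualify.
    """
    others = np.asarray(participant_meal_mins, dtype=float)
    others = others[others != eat_min]
    if np.any((others > eat_min - FASTING_WINDOW_MIN) & (others < eat_min)):
        return False, "meal_within_pre_window"
    if np.any((others > eat_min) & (others < eat_min + POST_WINDOW_MIN)):
        return False, "meal_within_post_window"
    if series is None or not _cgm_window_complete(eat_min, series.times_min):
        return False, "cgm_incomplete"
    return True, None


def _cgm_window_complete(eat_min: float, times: np.ndarray) -> bool:
    t_end = eat_min + POST_WINDOW_MIN
    # anchor reading at or before the meal, at most 15 min old
    i0 = np.searchsorted(times, eat_min, side="right") - 1
    if i0 < 0 or eat_min - times[i0] > PRE_READING_TOLERANCE_MIN:
        return False
    # closing reading at or after +120 min
    i1 = np.searchsorted(times, t_end, side="left")
    if i1 >= times.size:
        return False
    knots = times[i0:i1 + 1]
    return bool(np.all(np.diff(knots) <= MAX_GAP_MIN))


# ---------------------------------------------------------------------------
# Baseline and iAUC
# ---------------------------------------------------------------------------

def baseline_glucose(eat_min: float, series: CgmSeries) -> float:
    """Glucose at meal time by linear interpolation of bracketing readings."""
    t, g = series.times_min, series.glucose
    if eat_min < t[0] or eat_min > t[-1]:
        raise EligibilityError(
            "no bracketing CGM readings around the meal time")
    return float(np.interp(eat_min, t, g))


def _window_curve(eat_min: float, series: CgmSeries,
                  baseline: float) -> tuple[np.ndarray, np.ndarray]:
    """Knots of the piecewise-linear incremental curve on [0, 120] min."""
    t, g = series.times_min, series.glucose
    t_end = eat_min + POST_WINDOW_MIN
    if eat_min < t[0] or t_end > t[-1]:
        raise EligibilityError("CGM trace does not span the 2-h window")
    inner = (t > eat_min) & (t < t_end)
    knot_t = np.concatenate(([eat_min], t[inner], [t_end]))
    knot_g = np.concatenate((
        [np.interp(eat_min, t, g)], g[inner], [np.interp(t_end, t, g)]))
    return knot_t - eat_min, knot_g - baseline


def iauc_from_curve(rel_min: np.ndarray, incremental: np.ndarray,
                    convention: str) -> float:
    """Trapezoidal iAUC of a piecewise-linear incremental curve.

    ``net`` integrates the signed curve; ``positive_only`` integrates
    max(curve, 0), splitting segments at zero-crossings exactly.
    """
    if convention not in CONVENTIONS:
        raise ConfigError(
            f"unknown iAUC convention {convention!r}; use one of {CONVENTIONS}")
    t = np.asarray(rel_min, dtype=float)
    y = np.asarray(incremental, dtype=float)
    dt = np.diff(t)
    y0, y1 = y[:-1], y[1:]
    if convention == "net":
        return float(np.sum(dt * (y0 + y1) / 2.0))
    # positive part, segment by segment
    both_pos = (y0 >= 0) & (y1 >= 0)
    area = np.where(both_pos, dt * (y0 + y1) / 2.0, 0.0)
    crossing = (y0 > 0) != (y1 > 0)
    crossing &= (y0 != y1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(crossing, y0 / (y0 - y1), 0.0)
    # triangle above zero on the positive side of the crossing
    pos_down = crossing & (y0 > 0)
    pos_up = crossing & (y1 > 0)
    area = np.where(pos_down, 0.5 * y0 * frac * dt, area)
    area = np.where(pos_up, 0.5 * y1 * (1.0 - frac) * dt, area)
    return float(np.sum(area))


def iauc_2h(eat_min: float, series: CgmSeries, convention: str = "net",
            baseline: float | None = None) -> float:
    """2-h postprandial iAUC (mmol/L·min) for one meal."""
    if baseline is None:
        baseline = baseline_glucose(eat_min, series)
    rel, incr = _window_curve(eat_min, series, baseline)
    return iauc_from_curve(rel, incr, convention)


# ---------------------------------------------------------------------------
# Dataset-level linkage
# ---------------------------------------------------------------------------

def link_all(meals: pd.DataFrame, cgm: pd.DataFrame) -> pd.DataFrame:
    """Per-meal eligibility, baseline, and iAUC under both conventions.

    Returns one row per input meal: ``meal_id, eligible, reason,
    baseline_glucose, iauc_net, iauc_positive``; ineligible meals carry the
    reason and NaN values.
    """
    series_map = cgm_series_by_participant(cgm)
    rows = []
    for pid, grp in meals.groupby("participant_id", sort=False):
        series = series_map.get(str(pid))
        eat_mins = to_minutes(grp["eat_time"])
        for meal_id, t in zip(grp["meal_id"], np.atleast_1d(eat_mins)):
            ok, reason = check_eligibility(float(t), eat_mins, series)
            if ok:
                base = baseline_glucose(float(t), series)
                rel, incr = _window_curve(float(t), series, base)
                rows.append((meal_id, True, None, base,
                             iauc_from_curve(rel, incr, "net"),
                             iauc_from_curve(rel, incr, "positive_only")))
            else:
                rows.append((meal_id, False, reason, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=[
        "meal_id", "eligible", "reason", "baseline_glucose",
        "iauc_net", "iauc_positive"])
    # preserve input meal order
    order = pd.Index(meals["meal_id"])
    return out.set_index("meal_id").loc[order].reset_index()


def eligible_fraction(results: pd.DataFrame) -> float:
    if results.empty:
        return float("nan")
    return float(results["eligible"].mean())
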