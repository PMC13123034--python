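"""Synthetic EMA + CGM cohort generator with injectable ground truth.

The generator emulates the statistical structure of a nine-day intensive
digital-phenotyping protocol in free-living adults: six smartphone prompts
per day inside fixed time windows with a ~91% response rate, meal events
with location-conditional food-group draws, check-all-that-apply
companions and activities, 0-6 psychophysiological ratings, a 1-6 fullness
rating, and a parallel 15-minute CGM trace on which each meal writes a
unimodal glucose excursion.

Ground-truth context effects on the latent outcomes (fullness expectation
and 2-h net iAUC) are injected additively and stored alongside the
dataset, so estimator recovery is exactly testable.  Diet-quality
differences between locations are NOT injected directly: they emerge
mechanistically from the location-conditional food-group probabilities,
and the generator reports the implied analytic expectation per location.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configs produce byte-identical
fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diet_quality
from .data_model import (
    ACTIVITIES,
    COMPANIONS,
    FOOD_GROUPS,
    LOCATIONS,
    Bundle,
    validate_cgm,
    validate_meals,
    validate_participants,
    validate_surveys,
)
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Default parameterization (the emulated study conditions)
# ---------------------------------------------------------------------------

#: EMA prompt windows, minutes since midnight (start, end)
PROMPT_WINDOWS: tuple[tuple[int, int], ...] = (
    (8 * 60, 9 * 60 + 30),
    (10 * 60 + 30, 12 * 60),
    (13 * 60, 14 * 60 + 30),
    (15 * 60 + 30, 17 * 60),
    (18 * 60, 19 * 60 + 30),
    (20 * 60 + 30, 21 * 60 + 30),
)

DEFAULT_LOCATION_PROBS = {
    "home": 0.60, "hawker": 0.14, "workplace": 0.11, "other_restaurant": 0.09,
    "fast_food": 0.02, "friend_relative_home": 0.01, "other": 0.03,
}

#: overall food-group consumption frequencies (share of meals); the joint
#: legumes-or-nuts frequency 1-(1-p_soy)(1-p_legumes) ~= 0.17
_OVERALL_FOODS = {
    "refined_grains": 0.69, "vegetables": 0.43, "chicken": 0.24,
    "red_meat": 0.23, "seafood": 0.21, "eggs": 0.21, "whole_grains": 0.17,
    "soy": 0.08, "legumes_nuts_seeds": 0.10, "fruit": 0.15,
    "deep_fried": 0.09, "dairy": 0.08, "sweet_dessert": 0.07,
}

_FOOD_OVERRIDES = {
    "hawker": {"refined_grains": 0.83, "red_meat": 0.31, "whole_grains": 0.08,
               "fruit": 0.07, "dairy": 0.02},
    "fast_food": {"refined_grains": 0.47, "whole_grains": 0.10,
                  "vegetables": 0.27, "fruit": 0.04, "soy": 0.02,
                  "legumes_nuts_seeds": 0.02, "deep_fried": 0.49,
                  "chicken": 0.39},
    "other_restaurant": {"red_meat": 0.39, "seafood": 0.39, "chicken": 0.32,
                         "vegetables": 0.50, "fruit": 0.09,
                         "whole_grains": 0.08},
}


def default_food_group_probs() -> dict[str, dict[str, float]]:
    out = {}
    for loc in LOCATIONS:
        probs = dict(_OVERALL_FOODS)
        probs.update(_FOOD_OVERRIDES.get(loc, {}))
        out[loc] = probs
    return out


#: per-location (alone probability, marginal probabilities of the other
#: companions); the "other" location uses the all-locations row
DEFAULT_COMPANION_PROBS = {
    "home": (0.39, {"spouse": 0.30, "children": 0.20, "other_family": 0.26,
                    "friends": 0.02, "colleagues": 0.005}),
    "workplace": (0.44, {"spouse": 0.01, "children": 0.01, "other_family": 0.01,
                         "friends": 0.08, "colleagues": 0.47}),
    "hawker": (0.28, {"spouse": 0.28, "children": 0.10, "other_family": 0.14,
                      "friends": 0.18, "colleagues": 0.15}),
    "fast_food": (0.22, {"spouse": 0.33, "children": 0.18, "other_family": 0.15,
                         "friends": 0.23, "colleagues": 0.10}),
    "other_restaurant": (0.09, {"spouse": 0.34, "children": 0.13,
                                "other_family": 0.21, "friends": 0.33,
                                "colleagues": 0.13}),
    "friend_relative_home": (0.04, {"spouse": 0.34, "children": 0.19,
                                    "other_family": 0.57, "friends": 0.33,
                                    "colleagues": 0.01}),
    "other": (0.34, {"spouse": 0.27, "children": 0.15, "other_family": 0.21,
                     "friends": 0.09, "colleagues": 0.09}),
}

DEFAULT_ACTIVITY_PROBS = {
    "home": (0.24, {"work": 0.05, "leisure_screen": 0.45, "talking": 0.33,
                    "leisure_reading_writing": 0.04}),
    "workplace": (0.17, {"work": 0.35, "leisure_screen": 0.26, "talking": 0.35,
                         "leisure_reading_writing": 0.03}),
    "hawker": (0.26, {"work": 0.04, "leisure_screen": 0.17, "talking": 0.57,
                      "leisure_reading_writing": 0.02}),
    "fast_food": (0.15, {"work": 0.03, "leisure_screen": 0.17, "talking": 0.67,
                         "leisure_reading_writing": 0.02}),
    "other_restaurant": (0.11, {"work": 0.03, "leisure_screen": 0.10,
                                "talking": 0.79,
                                "leisure_reading_writing": 0.01}),
    "friend_relative_home": (0.11, {"work": 0.01, "leisure_screen": 0.16,
                                    "talking": 0.82,
                                    "leisure_reading_writing": 0.005}),
    "other": (0.22, {"work": 0.08, "leisure_screen": 0.34, "talking": 0.42,
                     "leisure_reading_writing": 0.03}),
}

DEFAULT_PSYCH_STATE_MEANS_SDS = {
    "stress": (1.57, 1.37), "hunger": (2.25, 1.52),
    "tiredness": (2.25, 1.48), "happiness": (3.63, 1.36),
}

EFFECT_FAMILIES = {"location": LOCATIONS, "companion": COMPANIONS,
                   "activity": ACTIVITIES}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_participants: int = 100
    n_days: int = 9
    prompts_per_day: int = 6
    response_rate: float = 0.91
    #: probability a responded prompt reports a meal (~16 meals / 9 days)
    meal_prob: float = 0.33
    location_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_PROBS))
    food_group_probs: dict[str, dict[str, float]] = field(
        default_factory=default_food_group_probs)
    companion_probs: dict = field(
        default_factory=lambda: {k: (a, dict(p)) for k, (a, p)
                                 in DEFAULT_COMPANION_PROBS.items()})
    activity_probs: dict = field(
        default_factory=lambda: {k: (a, dict(p)) for k, (a, p)
                                 in DEFAULT_ACTIVITY_PROBS.items()})
    psych_state_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PSYCH_STATE_MEANS_SDS))
    fullness_mean: float = 3.80
    fullness_sd: float = 1.04
    ssb_prob: float = 0.15
    baseline_glucose_mean: float = 5.1
    baseline_glucose_sd: float = 0.9
    iauc_mean: float = 143.28
    iauc_sd: float = 137.52
    #: intra-class (participant) correlation of the latent outcomes
    icc: float = 0.10
    #: additive ground-truth shifts, keys like "location:hawker",
    #: "companion:friends", "activity:work"
    excursion_effects: dict[str, float] = field(default_factory=dict)
    fullness_effects: dict[str, float] = field(default_factory=dict)
    cgm_complete_rate: float = 0.61
    premeal_state_rate: float = 0.57
    cgm_noise_sd: float = 0.10
    diurnal_amplitude: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_days <= 0:
            raise ConfigError("n_participants and n_days must be positive")
        if not 1 <= self.prompts_per_day <= len(PROMPT_WINDOWS):
            raise ConfigError(
                f"prompts_per_day must be in 1..{len(PROMPT_WINDOWS)}")
        for name in ("response_rate", "meal_prob", "cgm_complete_rate",
                     "premeal_state_rate", "ssb_prob", "icc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.location_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("location_probs must sum to 1")
        if set(self.location_probs) != set(LOCATIONS):
            raise ConfigError("location_probs must cover every location")
        for loc, probs in self.food_group_probs.items():
            if set(probs) != set(FOOD_GROUPS):
                raise ConfigError(f"food_group_probs[{loc!r}] must cover all "
                                  "13 food groups")
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigError(f"food_group_probs[{loc!r}] out of [0, 1]")
        for effects in (self.excursion_effects, self.fullness_effects):
            for key in effects:
                fam, _, level = key.partition(":")
                if fam not in EFFECT_FAMILIES or level not in EFFECT_FAMILIES[fam]:
                    raise ConfigError(f"unknown effect term {key!r}")


def null_config(**overrides) -> SimulationConfig:
    """Global-null configuration: no injected effects and location-invariant
    food-group probabilities, for type-I error and coverage studies."""
    shared = {loc: dict(_OVERALL_FOODS) for loc in LOCATIONS}
    return SimulationConfig(food_group_probs=shared, excursion_effects={},
                            fullness_effects={}, **overrides)


@dataclass
class GroundTruth:
    """Everything needed to test estimator recovery on a generated dataset."""

    excursion_effects: dict[str, float]
    fullness_effects: dict[str, float]
    icc: float
    expected_score_by_location: dict[str, float]
    participant_iauc_intercepts: dict[str, float]
    participant_fullness_intercepts: dict[str, float]
    #: per-meal latent outcomes: meal_id, iauc_target, spacing_ok, cgm_dropped
    meal_truth: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "excursion_effects": self.excursion_effects,
            "fullness_effects": self.fullness_effects,
            "icc": self.icc,
            "expected_score_by_location": self.expected_score_by_location,
            "participant_iauc_intercepts": self.participant_iauc_intercepts,
            "participant_fullness_intercepts":
                self.participant_fullness_intercepts,
            "meal_truth": self.meal_truth.to_dict(orient="list"),
        }


# ---------------------------------------------------------------------------
# Internal draws
# ---------------------------------------------------------------------------

_BASE_DATE = pd.Timestamp("2024-01-01")  # a Monday


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are loose here)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_participants(cfg: SimulationConfig, rng) -> pd.DataFrame:
    n = cfg.n_participants
    age = np.round(_truncated_normal(rng, 41.0, 14.1, 21, 69, n)).astype(int)
    sex = np.where(rng.random(n) < 0.62, "female", "male")
    ethnicity = rng.choice(["chinese", "malay", "indian"], size=n,
                           p=[0.64, 0.21, 0.15])
    education = rng.choice(["below_a_level", "a_level", "university"],
                           size=n, p=[0.14, 0.32, 0.54])
    glycemia = rng.choice(["normal", "prediabetes", "diabetes"], size=n,
                          p=[0.71, 0.25, 0.04])
    # labs drawn consistently with the assigned glycemic status
    fg = np.empty(n)
    a1c = np.empty(n)
    m_norm = glycemia == "normal"
    m_pre = glycemia == "prediabetes"
    m_dia = glycemia == "diabetes"
    fg[m_norm] = _truncated_normal(rng, cfg.baseline_glucose_mean,
                                   cfg.baseline_glucose_sd, 3.0, 5.59,
                                   int(m_norm.sum()))
    a1c[m_norm] = _truncated_normal(rng, 5.4, 0.3, 4.0, 5.69,
                                    int(m_norm.sum()))
    # prediabetes can be met by either criterion: half are identified by
    # HbA1c alone (fasting glucose still below 5.6), half by glucose
    n_pre = int(m_pre.sum())
    by_a1c = rng.random(n_pre) < 0.5
    fg_pre = np.empty(n_pre)
    a1c_pre = np.empty(n_pre)
    fg_pre[by_a1c] = _truncated_normal(rng, 5.2, 0.4, 3.5, 5.59,
                                       int(by_a1c.sum()))
    a1c_pre[by_a1c] = _truncated_normal(rng, 5.9, 0.2, 5.7, 6.49,
                                        int(by_a1c.sum()))
    fg_pre[~by_a1c] = _truncated_normal(rng, 5.8, 0.4, 5.6, 6.99,
                                        int((~by_a1c).sum()))
    a1c_pre[~by_a1c] = _truncated_normal(rng, 5.6, 0.3, 4.5, 6.49,
                                         int((~by_a1c).sum()))
    fg[m_pre] = fg_pre
    a1c[m_pre] = a1c_pre
    fg[m_dia] = _truncated_normal(rng, 7.8, 1.0, 7.0, 13.0, int(m_dia.sum()))
    a1c[m_dia] = _truncated_normal(rng, 7.2, 0.8, 6.5, 12.0, int(m_dia.sum()))
    return pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "education": education,
        "smoking": rng.random(n) < 0.13,
        "heavy_alcohol": rng.random(n) < 0.08,
        "working": rng.random(n) < 0.78,
        "married_or_partnered": rng.random(n) < 0.51,
        "bmi": np.round(_truncated_normal(rng, 24.9, 5.6, 14, 55, n), 1),
        "glycemic_status": glycemia,
        "fasting_glucose": np.round(fg, 2),
        "hba1c": np.round(a1c, 2),
        # study start rotated across the week so weekday share ~ 5/7
        "start_offset_days": rng.integers(0, 7, n),
    })


def _checkall_matrix(rng, loc_idx: np.ndarray, loc_names: list[str],
                     probs_by_loc: dict, tokens: tuple[str, ...],
                     exclusive: str) -> list[frozenset]:
    """Vectorized check-all-that-apply sets with an exclusive token.

    The exclusive token (``alone``/``nothing``) fires with its configured
    probability; otherwise each remaining token fires independently with
    its marginal rescaled by 1/(1 - p_exclusive); an empty draw falls back
    to the exclusive token.
    """
    others = [t for t in tokens if t != exclusive]
    m = loc_idx.size
    alone_p = np.array([probs_by_loc[l][0] for l in loc_names])[loc_idx]
    cond = np.array([
        [min(1.0, probs_by_loc[l][1].get(t, 0.0)
             / max(1e-12, 1.0 - probs_by_loc[l][0])) for t in others]
        for l in loc_names])[loc_idx]
    is_excl = rng.random(m) < alone_p
    draws = rng.random((m, len(others))) < cond
    draws[is_excl] = False
    out = []
    excl_set = frozenset([exclusive])
    for row in draws:
        if row.any():
            out.append(frozenset(t for t, d in zip(others, row) if d))
        else:
            out.append(excl_set)
    return out


def _effect_shift(effects: dict[str, float], location: np.ndarray,
                  companions: list[frozenset],
                  activities: list[frozenset]) -> np.ndarray:
    shift = np.zeros(len(location))
    for key, val in effects.items():
        fam, _, level = key.partition(":")
        if fam == "location":
            shift += np.where(location == level, val, 0.0)
        elif fam == "companion":
            shift += np.array([val if level in c else 0.0 for c in companions])
        elif fam == "activity":
            shift += np.array([val if level in a else 0.0 for a in activities])
    return shift


def _neighbour_gaps(pid_idx: np.ndarray,
                    eat_min: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-participant gaps (minutes) to the previous and next meal."""
    m = eat_min.size
    prev_gap = np.full(m, np.inf)
    next_gap = np.full(m, np.inf)
    if m < 2:
        return prev_gap, next_gap
    order = np.lexsort((eat_min, pid_idx))
    sp, se = pid_idx[order], eat_min[order]
    same = sp[1:] == sp[:-1]
    gaps = se[1:] - se[:-1]
    prev_gap[order[1:][same]] = gaps[same]
    next_gap[order[:-1][same]] = gaps[same]
    return prev_gap, next_gap


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig,
                    include_cgm: bool = True) -> tuple[Bundle, GroundTruth]:
    """Generate a full dataset bundle plus its ground truth.

    Deterministic given ``config.seed``.  With ``include_cgm=False`` the
    bundle's cgm table is empty (cheap mode for estimator studies that fit
    on the latent iAUC targets directly); :func:`simulate_cgm` can render
    traces later from the same meal truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants = _draw_participants(config, rng)
    n = config.n_participants
    ppd = config.prompts_per_day
    windows = np.array(PROMPT_WINDOWS[:ppd], dtype=float)

    # --- responded prompts -------------------------------------------------
    n_slots = n * config.n_days * ppd
    pid_idx = np.repeat(np.arange(n), config.n_days * ppd)
    day = np.tile(np.repeat(np.arange(config.n_days), ppd), n)
    widx = np.tile(np.arange(ppd), n * config.n_days)
    responded = rng.random(n_slots) < config.response_rate
    u = rng.uniform(0, 1, n_slots)
    prompt_min = (day * 1440.0 + windows[widx, 0]
                  + u * (windows[widx, 1] - windows[widx, 0]))
    pid_idx, day, widx, prompt_min = (a[responded] for a in
                                      (pid_idx, day, widx, prompt_min))
    n_resp = pid_idx.size

    # --- meals --------------------------------------------------------------
    has_meal = rng.random(n_resp) < config.meal_prob
    m_pid = pid_idx[has_meal]
    m_prompt = prompt_min[has_meal]
    eat_min = np.floor(m_prompt - rng.uniform(5, 60, m_pid.size))
    m = m_pid.size
    if m == 0:
        raise ConfigError("configuration produced no meals; increase "
                          "n_participants, n_days or meal_prob")

    loc_names = list(LOCATIONS)
    loc_p = np.array([config.location_probs[l] for l in loc_names])
    loc_idx = np.searchsorted(np.cumsum(loc_p), rng.random(m), side="right")
    loc_idx = np.minimum(loc_idx, len(loc_names) - 1)
    locations = np.array(loc_names, dtype=object)[loc_idx]

    food_mat = np.array([[config.food_group_probs[l][g] for g in FOOD_GROUPS]
                         for l in loc_names])
    food_draws = rng.random((m, len(FOOD_GROUPS))) < food_mat[loc_idx]
    foods = [frozenset(g for g, d in zip(FOOD_GROUPS, row) if d)
             for row in food_draws]

    comps = _checkall_matrix(rng, loc_idx, loc_names, config.companion_probs,
                             COMPANIONS, "alone")
    acts = _checkall_matrix(rng, loc_idx, loc_names, config.activity_probs,
                            ACTIVITIES, "nothing")

    # --- latent outcomes ----------------------------------------------------
    iauc_b = rng.normal(0, np.sqrt(config.icc) * config.iauc_sd, n)
    full_b = rng.normal(0, np.sqrt(config.icc) * config.fullness_sd, n)
    full_shift = _effect_shift(config.fullness_effects, locations, comps, acts)
    fullness = np.clip(np.round(
        config.fullness_mean + full_b[m_pid] + full_shift
        + rng.normal(0, np.sqrt(1 - config.icc) * config.fullness_sd, m)),
        1, 6).astype(int)
    iauc_shift = _effect_shift(config.excursion_effects, locations, comps, acts)
    iauc_target = (config.iauc_mean + iauc_b[m_pid] + iauc_shift
                   + rng.normal(0, np.sqrt(1 - config.icc) * config.iauc_sd, m))
    ssb = rng.random(m) < config.ssb_prob

    # --- premeal ratings ----------------------------------------------------
    # Hit meals carry ratings on their own survey, lagged to stay inside
    # their own 2-h look-back window and OUTSIDE the windows of
    # neighbouring meals, so the configured availability rate is realized
    # exactly by the extraction rule.
    prev_gap, next_gap = _neighbour_gaps(m_pid, eat_min)
    hit = rng.random(m) < config.premeal_state_rate
    lag_lo = np.full(m, 2.0)
    close_next = next_gap <= 120.0
    lag_lo[close_next] = np.minimum(115.0, np.maximum(
        2.0, 121.0 - next_gap[close_next]))
    lag_hi = np.full(m, 115.0)
    close_prev = prev_gap <= 116.0
    lag_hi[close_prev] = np.minimum(115.0, prev_gap[close_prev] - 1.0)
    lag_hi = np.maximum(lag_hi, lag_lo)
    lag = lag_lo + rng.random(m) * (lag_hi - lag_lo)
    rating_min = np.where(hit, eat_min - lag, np.nan)

    state_names = list(config.psych_state_means_sds)
    ratings = {}
    for s in state_names:
        mean, sd = config.psych_state_means_sds[s]
        vals = np.clip(np.round(rng.normal(mean, sd, m)), 0, 6)
        ratings[s] = np.where(hit, vals, np.nan)

    # --- spacing eligibility and CGM-completeness calibration ---------------
    spacing_ok = (prev_gap >= 120.0) & (next_gap >= 120.0)
    frac_ok = float(spacing_ok.mean())
    p_drop = 0.0
    if frac_ok > 0:
        p_drop = float(np.clip(1.0 - config.cgm_complete_rate / frac_ok, 0, 1))
    cgm_dropped = spacing_ok & (rng.random(m) < p_drop)

    # --- assemble tables -----------------------------------------------------
    pid_str = participants["participant_id"].to_numpy()
    start_day = participants["start_offset_days"].to_numpy()
    base_ns = _BASE_DATE.value

    def to_ts(pidx: np.ndarray, minutes: np.ndarray,
              resolution_s: bool) -> pd.Series:
        total_min = start_day[pidx] * 1440.0 + minutes
        sec = np.round(total_min * 60.0).astype("int64")
        if not resolution_s:
            sec = (sec // 60) * 60
        return pd.Series(pd.to_datetime(base_ns + sec * 10 ** 9))

    survey_ids = np.array([f"S{pid_str[p]}_{d}_{w + 1}"
                           for p, d, w in zip(pid_idx, day, widx)])
    meal_survey_row = np.flatnonzero(has_meal)

    surveys = pd.DataFrame({
        "survey_id": survey_ids,
        "participant_id": pid_str[pid_idx],
        "prompt_time": to_ts(pid_idx, prompt_min, True),
        "window_index": widx + 1,
    })
    for s in state_names:
        col = np.full(n_resp, np.nan)
        col[meal_survey_row] = ratings[s]
        surveys[s] = col
    rt = np.full(n_resp, np.nan)
    rt[meal_survey_row] = rating_min
    rt_ts = pd.Series(pd.NaT, index=range(n_resp), dtype="datetime64[ns]")
    ok = ~np.isnan(rt)
    rt_ts[ok] = to_ts(pid_idx[ok], rt[ok], True).to_numpy()
    surveys["rating_time"] = rt_ts

    # per-participant meal counter for stable meal ids
    counter = np.zeros(m, dtype=int)
    order = np.lexsort((eat_min, m_pid))
    pos = np.arange(m)
    grp_start = np.r_[0, np.flatnonzero(np.diff(m_pid[order]) != 0) + 1]
    within = pos - np.repeat(grp_start, np.diff(np.r_[grp_start, m]))
    counter[order] = within
    meal_ids = np.array([f"M{pid_str[p]}_{k:03d}"
                         for p, k in zip(m_pid, counter)])

    meals = pd.DataFrame({
        "meal_id": meal_ids,
        "participant_id": pid_str[m_pid],
        "survey_id": survey_ids[meal_survey_row],
        "eat_time": to_ts(m_pid, eat_min, False),
        "food_groups": foods,
        "location": locations,
        "companions": comps,
        "activities": acts,
        "fullness": fullness,
        "ssb_with_survey": ssb,
    })
    meal_truth = pd.DataFrame({
        "meal_id": meal_ids,
        "participant_id": pid_str[m_pid],
        "iauc_target": iauc_target,
        "spacing_ok": spacing_ok,
        "cgm_dropped": cgm_dropped,
    })

    truth = GroundTruth(
        excursion_effects=dict(config.excursion_effects),
        fullness_effects=dict(config.fullness_effects),
        icc=config.icc,
        expected_score_by_location={
            loc: diet_quality.expected_score(config.food_group_probs[loc])
            for loc in LOCATIONS},
        participant_iauc_intercepts=dict(zip(pid_str, iauc_b)),
        participant_fullness_intercepts=dict(zip(pid_str, full_b)),
        meal_truth=meal_truth,
    )

    participants_out = participants.drop(columns=["start_offset_days"])
    if include_cgm:
        cgm = simulate_cgm(meals, participants, truth, config, rng)
        cgm = validate_cgm(cgm)
    else:
        cgm = pd.DataFrame(columns=["participant_id", "timestamp",
                                    "glucose_mmol_l"])
    bundle = Bundle(
        participants=validate_participants(participants_out),
        surveys=validate_surveys(surveys),
        meals=validate_meals(meals),
        cgm=cgm,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# CGM rendering
# ---------------------------------------------------------------------------

#: net 2-h iAUC of the unit-peak excursion shape (rise over [0, 45] min,
#: decay over [45, 150]): 45/2 + (105^2 - 30^2)/(2*105) = 495/7 min
EXCURSION_SHAPE_IAUC = 495.0 / 7.0
EXCURSION_PEAK_MIN = 45.0
EXCURSION_END_MIN = 150.0
GLUCOSE_FLOOR = 0.3


def excursion_value(tau, amplitude: float = 1.0) -> np.ndarray:
    """Piecewise-linear excursion: rise to ``amplitude`` at 45 min, decay
    back to zero at 150 min; zero outside [0, 150]."""
    tau = np.asarray(tau, dtype=float)
    rise = amplitude * tau / EXCURSION_PEAK_MIN
    decay = amplitude * (EXCURSION_END_MIN - tau) / (
        EXCURSION_END_MIN - EXCURSION_PEAK_MIN)
    out = np.where(tau <= EXCURSION_PEAK_MIN, rise, decay)
    return np.where((tau >= 0) & (tau <= EXCURSION_END_MIN), out, 0.0)


def measured_unit_iauc(grid: np.ndarray, t: float) -> float:
    """Net 2-h iAUC the analysis pipeline would measure for a unit-peak
    excursion at time ``t`` sampled on reading grid ``grid`` (minutes).

    Accounts for the sampling of the piecewise-linear shape at the grid
    knots, interpolated window endpoints, and the contamination of the
    interpolated meal-time baseline by the excursion's early rise.  Linear
    in the amplitude, so the generator can invert it exactly.
    """
    t_end = t + 120.0
    i0 = np.searchsorted(grid, t, side="right") - 1
    i1 = np.searchsorted(grid, t_end, side="left")
    sampled = excursion_value(grid - t)
    # interpolated values of the sampled series at t and t+120
    e_t = float(np.interp(t, grid, sampled))
    e_end = float(np.interp(t_end, grid, sampled))
    inner = (grid > t) & (grid < t_end)
    knots = np.concatenate(([t], grid[inner], [t_end]))
    vals = np.concatenate(([e_t], sampled[inner], [e_end]))
    return float(np.trapezoid(vals, knots) - 120.0 * e_t)


def simulate_cgm(meals: pd.DataFrame, participants: pd.DataFrame,
                 truth: GroundTruth, config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Render 15-min-cadence CGM traces realizing each meal's latent iAUC.

    Per participant the trace is the fasting baseline plus a slow diurnal
    sinusoid, reading noise, and one excursion per meal.  The excursion
    amplitude is calibrated per meal by inverting
    :func:`measured_unit_iauc` on the participant's actual reading grid,
    so that in the absence of noise the pipeline-measured net iAUC equals
    the meal's ``iauc_target`` almost exactly.  Timestamps carry a
    per-participant uniform 0-15 min phase offset so baseline
    interpolation is exercised.  Readings over [meal+40, meal+70] are
    deleted at meals flagged ``cgm_dropped`` in the ground truth, which
    makes exactly those meals CGM-incomplete.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    truth_idx = truth.meal_truth.set_index("meal_id")
    rows = []
    part = participants.set_index("participant_id")
    for pid, grp in meals.groupby("participant_id", sort=False):
        if "start_offset_days" in part.columns:
            start = _BASE_DATE + pd.Timedelta(
                days=int(part.loc[pid, "start_offset_days"]))
        else:
            start = pd.to_datetime(grp["eat_time"]).min().normalize()
        phase = rng.uniform(0, 15)
        grid = phase + 15.0 * np.arange(config.n_days * 96)
        baseline = float(part.loc[pid, "fasting_glucose"])
        tod_hours = (grid / 60.0) % 24.0
        values = (baseline
                  + config.diurnal_amplitude
                  * np.sin(2 * np.pi * (tod_hours - 10.0) / 24.0)
                  + rng.normal(0, config.cgm_noise_sd, grid.size))
        eat_rel = ((pd.to_datetime(grp["eat_time"]) - start)
                   .dt.total_seconds().to_numpy() / 60.0)
        keep = np.ones(grid.size, dtype=bool)
        targets = truth_idx.loc[grp["meal_id"], "iauc_target"].to_numpy()
        dropped = truth_idx.loc[grp["meal_id"], "cgm_dropped"].to_numpy()
        for t, target, drop in zip(eat_rel, targets, dropped):
            amp = float(target) / measured_unit_iauc(grid, float(t))
            lo = np.searchsorted(grid, t)
            hi = np.searchsorted(grid, t + EXCURSION_END_MIN, side="right")
            values[lo:hi] += excursion_value(grid[lo:hi] - t, amp)
            if drop:
                keep &= ~((grid >= t + 40.0) & (grid <= t + 70.0))
        values = np.maximum(values, GLUCOSE_FLOOR)
        ts = start + pd.to_timedelta(
            np.round(grid[keep] * 60.0).astype(np.int64), unit="s")
        rows.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": ts,
            "glucose_mmol_l": np.round(values[keep], 3),
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(bundle: Bundle, truth: GroundTruth,
                  out_dir) -> dict[str, Path]:
    """Write the four CSV inputs plus ground_truth.json to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["participants"] = out / "participants.csv"
    bundle.participants.to_csv(paths["participants"], index=False)

    surveys = bundle.surveys.copy()
    surveys["prompt_time"] = surveys["prompt_time"].dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    surveys["rating_time"] = surveys["rating_time"].dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    paths["surveys"] = out / "surveys.csv"
    surveys.to_csv(paths["surveys"], index=False)

    meals = bundle.meals.copy()
    meals["eat_time"] = meals["eat_time"].dt.strftime("%Y-%m-%dT%H:%M")
    for col in ("food_groups", "companions", "activities"):
        meals[col] = meals[col].map(lambda s: "|".join(sorted(s)))
    paths["meals"] = out / "meals.csv"
    meals.to_csv(paths["meals"], index=False)

    cgm = bundle.cgm.copy()
    if not cgm.empty:
        cgm["timestamp"] = cgm["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    paths["cgm"] = out / "cgm.csv"
    cgm.to_csv(paths["cgm"], index=False)

    paths["ground_truth"] = out / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, default=float)
    return paths


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain (JSON/YAML-loaded) mapping."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimulationConfig(**d)
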