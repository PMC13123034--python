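"""Entity types, ingest, inclusion filters, and meal-level covariate derivation.

The study design: free-living adults answer up to six smartphone EMA
(ecological momentary assessment) prompts per day over nine days.  Each
responded prompt may report one or more eating occasions with a food-group
checklist, the meal's location, companions, concurrent activities, and a
post-meal fullness rating; each prompt also carries momentary
psychophysiological ratings (stress, hunger, tiredness, happiness, each
0-6) with an app-recorded timestamp.  A masked continuous glucose monitor
records interstitial glucose every 15 minutes in parallel.

Tables are carried as pandas DataFrames with fixed column schemas (see
``REQUIRED_COLUMNS``); set-valued survey answers (food groups, companions,
activities) are encoded as pipe-delimited token strings in a single column
and exposed to Python as frozensets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    InvariantError,
    ReferentialIntegrityError,
    SchemaError,
    VocabularyError,
)

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

FOOD_GROUPS: tuple[str, ...] = (
    "refined_grains",
    "whole_grains",
    "seafood",
    "chicken",
    "red_meat",
    "eggs",
    "dairy",
    "soy",
    "legumes_nuts_seeds",
    "vegetables",
    "fruit",
    "deep_fried",
    "sweet_dessert",
)

LOCATIONS: tuple[str, ...] = (
    "home",
    "workplace",
    "hawker",
    "fast_food",
    "other_restaurant",
    "friend_relative_home",
    "other",
)

COMPANIONS: tuple[str, ...] = (
    "alone",
    "spouse",
    "children",
    "other_family",
    "friends",
    "colleagues",
)

ACTIVITIES: tuple[str, ...] = (
    "nothing",
    "work",
    "leisure_screen",
    "talking",
    "leisure_reading_writing",
)

SEXES = ("male", "female")
ETHNICITIES = ("chinese", "malay", "indian")
EDUCATIONS = ("below_a_level", "a_level", "university")
GLYCEMIC_STATUSES = ("normal", "prediabetes", "diabetes")

MEALTIMES = ("breakfast", "lunch", "dinner")

PSYCH_STATES = ("stress", "hunger", "tiredness", "happiness")

#: analysis day window, minutes since midnight: [05:00, 24:00)
DAY_WINDOW_START_MIN = 5 * 60
DAY_WINDOW_END_MIN = 24 * 60

#: premeal look-back window in minutes, closed at both ends
PREMEAL_WINDOW_MIN = 120

#: locations accounting for strictly less than this share of retained meals
#: are flagged out of location-based analyses
RARE_LOCATION_THRESHOLD = 0.01

REQUIRED_COLUMNS = {
    "participants": [
        "participant_id", "age", "sex", "ethnicity", "education", "smoking",
        "heavy_alcohol", "working", "married_or_partnered", "bmi",
        "glycemic_status",
    ],
    "surveys": [
        "survey_id", "participant_id", "prompt_time", "window_index",
        "stress", "hunger", "tiredness", "happiness", "rating_time",
    ],
    "meals": [
        "meal_id", "participant_id", "survey_id", "eat_time", "food_groups",
        "location", "companions", "activities", "fullness",
    ],
    "cgm": ["participant_id", "timestamp", "glucose_mmol_l"],
}


@dataclass
class Bundle:
    """Validated dataset bundle: the four study tables."""

    participants: pd.DataFrame
    surveys: pd.DataFrame
    meals: pd.DataFrame
    cgm: pd.DataFrame

    def __post_init__(self) -> None:
        validate_bundle(self)


@dataclass(frozen=True)
class PremealState:
    """Latest psychophysiological ratings recorded within 2 h before a meal."""

    meal_id: str
    stress: float
    hunger: float
    tiredness: float
    happiness: float
    lag_min: float


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def parse_token_set(cell: object) -> frozenset[str]:
    """Decode a pipe-delimited token cell into a frozenset (empty allowed).

    Already-parsed sets pass through unchanged, so validation is idempotent.
    """
    if isinstance(cell, (set, frozenset)):
        return frozenset(cell)
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    s = str(cell).strip()
    if not s:
        return frozenset()
    return frozenset(t.strip() for t in s.split("|") if t.strip())


def encode_token_set(tokens: Iterable[str]) -> str:
    return "|".join(sorted(tokens))


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _check_vocab(series: pd.Series, vocab: tuple[str, ...], table: str,
                 column: str) -> None:
    bad = ~series.isin(vocab)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise VocabularyError(
            f"{table} row {row}: unknown {column} token "
            f"{series.iloc[row]!r} (allowed: {sorted(vocab)})"
        )


def _check_token_sets(series: pd.Series, vocab: tuple[str, ...], table: str,
                      column: str, exclusive: str | None = None) -> pd.Series:
    parsed = series.map(parse_token_set)
    vocab_set = set(vocab)
    for row, (idx, tokens) in enumerate(parsed.items()):
        unknown = tokens - vocab_set
        if unknown:
            raise VocabularyError(
                f"{table} row {row}: unknown {column} token(s) "
                f"{sorted(unknown)}"
            )
        if exclusive and exclusive in tokens and len(tokens) > 1:
            raise InvariantError(
                f"{table} row {row}: {column} contains exclusive token "
                f"{exclusive!r} alongside {sorted(tokens - {exclusive})}"
            )
    return parsed


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, "participants")
    df = df.copy()
    if df["participant_id"].duplicated().any():
        raise InvariantError("participants: duplicated participant_id")
    _check_vocab(df["sex"], SEXES, "participants", "sex")
    _check_vocab(df["ethnicity"], ETHNICITIES, "participants", "ethnicity")
    _check_vocab(df["education"], EDUCATIONS, "participants", "education")
    _check_vocab(df["glycemic_status"], GLYCEMIC_STATUSES, "participants",
                 "glycemic_status")
    age = pd.to_numeric(df["age"], errors="raise")
    if ((age < 21) | (age > 69)).any():
        row = int(np.flatnonzero(((age < 21) | (age > 69)).to_numpy())[0])
        raise InvariantError(f"participants row {row}: age outside 21-69")
    bmi = pd.to_numeric(df["bmi"], errors="raise")
    if (bmi <= 0).any():
        raise InvariantError("participants: non-positive bmi")
    for col in ("smoking", "heavy_alcohol", "working", "married_or_partnered"):
        df[col] = df[col].astype(bool)
    # glycemic status must agree with the labs when both are present:
    # prediabetes iff not diabetes and (HbA1c >= 5.7 or glucose >= 5.6)
    if {"fasting_glucose", "hba1c"} <= set(df.columns):
        fg = pd.to_numeric(df["fasting_glucose"], errors="coerce")
        a1c = pd.to_numeric(df["hba1c"], errors="coerce")
        labs = fg.notna() & a1c.notna()
        pre_cond = (a1c >= 5.7) | (fg >= 5.6)
        bad = labs & (
            ((df["glycemic_status"] == "prediabetes") & ~pre_cond)
            | ((df["glycemic_status"] == "normal") & pre_cond))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InvariantError(
                f"participants row {row}: glycemic_status "
                f"{df['glycemic_status'].iloc[row]!r} inconsistent with "
                f"HbA1c {a1c.iloc[row]} / fasting glucose {fg.iloc[row]}")
    return df


def validate_surveys(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, "surveys")
    df = df.copy()
    if df["survey_id"].duplicated().any():
        raise InvariantError("surveys: duplicated survey_id")
    df["prompt_time"] = pd.to_datetime(df["prompt_time"])
    df["rating_time"] = pd.to_datetime(df["rating_time"], errors="coerce")
    wi = pd.to_numeric(df["window_index"], errors="raise")
    if (~wi.isin(range(1, 7))).any():
        raise InvariantError("surveys: window_index outside 1..6")
    ratings = df[list(PSYCH_STATES)].apply(pd.to_numeric, errors="coerce")
    out_of_range = ((ratings < 0) | (ratings > 6)).any(axis=1)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise InvariantError(f"surveys row {row}: rating outside [0, 6]")
    any_rating = ratings.notna().any(axis=1)
    has_time = df["rating_time"].notna()
    if (any_rating != has_time).any():
        row = int(np.flatnonzero((any_rating != has_time).to_numpy())[0])
        raise InvariantError(
            f"surveys row {row}: rating_time must be present iff any "
            "psychophysiological rating is present"
        )
    df[list(PSYCH_STATES)] = ratings
    return df


def validate_meals(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, "meals")
    df = df.copy()
    if df["meal_id"].duplicated().any():
        raise InvariantError("meals: duplicated meal_id")
    df["eat_time"] = pd.to_datetime(df["eat_time"]).dt.floor("min")
    df["food_groups"] = _check_token_sets(
        df["food_groups"], FOOD_GROUPS, "meals", "food_groups")
    df["companions"] = _check_token_sets(
        df["companions"], COMPANIONS, "meals", "companions", exclusive="alone")
    df["activities"] = _check_token_sets(
        df["activities"], ACTIVITIES, "meals", "activities",
        exclusive="nothing")
    _check_vocab(df["location"], LOCATIONS, "meals", "location")
    fullness = pd.to_numeric(df["fullness"], errors="raise")
    if ((fullness < 1) | (fullness > 6)).any():
        row = int(np.flatnonzero(((fullness < 1) | (fullness > 6)).to_numpy())[0])
        raise InvariantError(f"meals row {row}: fullness outside [1, 6]")
    df["fullness"] = fullness
    if "ssb_with_survey" not in df.columns:
        df["ssb_with_survey"] = False
    else:
        df["ssb_with_survey"] = df["ssb_with_survey"].fillna(False).astype(bool)
    return df


def validate_cgm(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, "cgm")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["glucose_mmol_l"] = pd.to_numeric(df["glucose_mmol_l"], errors="raise")
    if (df["glucose_mmol_l"] <= 0).any():
        raise InvariantError("cgm: non-positive glucose reading")
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    dup = df.duplicated(["participant_id", "timestamp"])
    if dup.any():
        raise InvariantError("cgm: duplicated (participant, timestamp) reading")
    return df.reset_index(drop=True)


def validate_bundle(bundle: "Bundle") -> None:
    """Cross-table referential integrity; per-table checks are assumed done."""
    pids = set(bundle.participants["participant_id"])
    sids = set(bundle.surveys["survey_id"])
    bad_pid = ~bundle.surveys["participant_id"].isin(pids)
    if bad_pid.any():
        row = int(np.flatnonzero(bad_pid.to_numpy())[0])
        raise ReferentialIntegrityError(
            f"surveys row {row}: unknown participant_id "
            f"{bundle.surveys['participant_id'].iloc[row]!r}"
        )
    for col, ref, name in (("participant_id", pids, "participant"),
                           ("survey_id", sids, "survey")):
        bad = ~bundle.meals[col].isin(ref)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ReferentialIntegrityError(
                f"meals row {row}: unknown {name} reference "
                f"{bundle.meals[col].iloc[row]!r}"
            )
    bad_cgm = ~bundle.cgm["participant_id"].isin(pids)
    if bad_cgm.any():
        row = int(np.flatnonzero(bad_cgm.to_numpy())[0])
        raise ReferentialIntegrityError(
            f"cgm row {row}: unknown participant_id "
            f"{bundle.cgm['participant_id'].iloc[row]!r}"
        )


def load_tables(participants_path, surveys_path, meals_path,
                cgm_path) -> Bundle:
    """Read and validate the four CSV inputs into a typed bundle.

    Raises :class:`SchemaError`, :class:`VocabularyError`,
    :class:`InvariantError` or :class:`ReferentialIntegrityError` with
    row-level diagnostics on malformed input.
    """
    participants = validate_participants(pd.read_csv(participants_path))
    surveys = validate_surveys(pd.read_csv(surveys_path))
    meals = validate_meals(pd.read_csv(meals_path))
    cgm = validate_cgm(pd.read_csv(cgm_path))
    return Bundle(participants, surveys, meals, cgm)


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

def _minutes_since_midnight(eat_time: pd.Series) -> pd.Series:
    return eat_time.dt.hour * 60 + eat_time.dt.minute


def filter_meals(meals: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis-day and rare-location inclusion rules.

    Meals with clock time in [05:00, 24:00) are retained; the rest are
    dropped with reason ``outside_05_24``.  Among retained meals, any
    location category covering strictly less than 1% of retained meals is
    flagged ``location_excluded`` (the meal stays in the table for
    non-location analyses).  Returns ``(included, exclusion_log)`` where the
    log has columns ``meal_id, reason`` and lists both dropped and flagged
    meals.
    """
    if meals.empty:
        empty_log = pd.DataFrame(columns=["meal_id", "reason"])
        included = meals.copy()
        included["location_excluded"] = pd.Series(dtype=bool)
        return included, empty_log

    mins = _minutes_since_midnight(meals["eat_time"])
    in_day = (mins >= DAY_WINDOW_START_MIN) & (mins < DAY_WINDOW_END_MIN)
    dropped = meals.loc[~in_day, ["meal_id"]].assign(reason="outside_05_24")
    included = meals.loc[in_day].copy()

    if included.empty:
        included["location_excluded"] = pd.Series(dtype=bool)
        return included, dropped.reset_index(drop=True)

    shares = included["location"].value_counts(normalize=True)
    rare = set(shares[shares < RARE_LOCATION_THRESHOLD].index)
    included["location_excluded"] = included["location"].isin(rare)
    flagged = included.loc[included["location_excluded"], ["meal_id"]].assign(
        reason="location_excluded")
    log = pd.concat([dropped, flagged], ignore_index=True)
    return included.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Mealtime category
# ---------------------------------------------------------------------------

def mealtime_category(eat_time) -> str:
    """Half-open clock-time binning: [05:00, 11:00) breakfast,
    [11:00, 17:00) lunch, [17:00, 24:00) dinner."""
    t = pd.Timestamp(eat_time)
    mins = t.hour * 60 + t.minute
    if not (DAY_WINDOW_START_MIN <= mins < DAY_WINDOW_END_MIN):
        raise InvariantError(
            f"eat_time {t} outside the analysis window [05:00, 24:00)")
    if mins < 11 * 60:
        return "breakfast"
    if mins < 17 * 60:
        return "lunch"
    return "dinner"


def mealtime_categories(eat_times: pd.Series) -> pd.Series:
    """Vectorized :func:`mealtime_category`."""
    mins = _minutes_since_midnight(eat_times)
    if ((mins < DAY_WINDOW_START_MIN) | (mins >= DAY_WINDOW_END_MIN)).any():
        raise InvariantError("eat_time outside the analysis window [05:00, 24:00)")
    out = np.where(mins < 11 * 60, "breakfast",
                   np.where(mins < 17 * 60, "lunch", "dinner"))
    return pd.Series(pd.Categorical(out, categories=list(MEALTIMES)),
                     index=eat_times.index, name="mealtime")


# ---------------------------------------------------------------------------
# Premeal psychophysiological states
# ---------------------------------------------------------------------------

def extract_premeal_states(meals: pd.DataFrame,
                           surveys: pd.DataFrame) -> pd.DataFrame:
    """Latest ratings recorded within 2 h before each meal.

    For every meal, among the same participant's rating records with
    ``rating_time`` in the closed window ``[eat_time - 120 min, eat_time]``,
    the record with the latest ``rating_time`` is taken.  Meals with no
    qualifying record are absent from the result.  Returns a frame with
    columns ``meal_id, stress, hunger, tiredness, happiness, lag_min``.
    """
    cols = ["meal_id"] + list(PSYCH_STATES) + ["lag_min"]
    rated = surveys.loc[surveys["rating_time"].notna(),
                        ["participant_id", "rating_time", *PSYCH_STATES]]
    if meals.empty or rated.empty:
        return pd.DataFrame(columns=cols)

    left = (meals[["meal_id", "participant_id", "eat_time"]]
            .sort_values("eat_time", kind="stable"))
    right = rated.sort_values("rating_time", kind="stable")
    merged = pd.merge_asof(
        left, right,
        left_on="eat_time", right_on="rating_time",
        by="participant_id",
        direction="backward",
        tolerance=pd.Timedelta(minutes=PREMEAL_WINDOW_MIN),
        allow_exact_matches=True,
    )
    merged = merged.loc[merged["rating_time"].notna()].copy()
    merged["lag_min"] = (
        (merged["eat_time"] - merged["rating_time"]).dt.total_seconds() / 60.0)
    return merged[cols].reset_index(drop=True)


def extract_premeal_state(meal: pd.Series,
                          surveys: pd.DataFrame) -> PremealState | None:
    """Single-meal convenience wrapper around :func:`extract_premeal_states`."""
    res = extract_premeal_states(meal.to_frame().T, surveys)
    if res.empty:
        return None
    row = res.iloc[0]
    return PremealState(
        meal_id=row["meal_id"],
        stress=float(row["stress"]),
        hunger=float(row["hunger"]),
        tiredness=float(row["tiredness"]),
        happiness=float(row["happiness"]),
        lag_min=float(row["lag_min"]),
    )
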