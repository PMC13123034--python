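"""Meal-level diet-quality score adapted from the DASH food-group logic.

Each meal earns one point for consuming each of six healthy groups
(whole grains, seafood, legumes-or-nuts, vegetables, fruit, dairy) and one
point for NOT consuming each of four unhealthy groups (refined grains, red
meat, deep-fried foods, sweet desserts); the score is the component sum,
range 0-10.  Soy products and beans/peas/nuts/seeds jointly feed a single
legumes-or-nuts component, so either earns at most one point.  Chicken and
eggs appear in the intake checklist but in neither scoring list: they are
score-neutral.

An optional eleventh component (``no_ssb``) credits non-consumption of
sugar-sweetened beverages, proxied by beverage intake reported in the same
survey as the meal; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import FOOD_GROUPS
from .errors import ConfigError, VocabularyError

HEALTHY_SIMPLE = ("whole_grains", "seafood", "vegetables", "fruit", "dairy")
LEGUME_SOURCES = ("soy", "legumes_nuts_seeds")
UNHEALTHY = ("refined_grains", "red_meat", "deep_fried", "sweet_dessert")

#: component order of the score vector
COMPONENTS = (
    "whole_grains", "seafood", "legumes_or_nuts", "vegetables", "fruit",
    "dairy", "no_refined_grains", "no_red_meat", "no_deep_fried",
    "no_sweet_dessert",
)
SSB_COMPONENT = "no_ssb"


@dataclass(frozen=True)
class DietQualityScore:
    meal_id: str | None
    components: Mapping[str, bool]
    score: int

    def __post_init__(self):
        assert self.score == sum(self.components.values())


def score_meal(food_groups: Iterable[str], ssb_flag: bool | None = None,
               include_ssb: bool = False) -> DietQualityScore:
    """Score one meal from its food-group set.

    ``include_ssb`` adds the eleventh ``no_ssb`` component and requires
    ``ssb_flag`` (True if a sugar-sweetened beverage was reported with the
    meal's survey).
    """
    groups = frozenset(food_groups)
    unknown = groups - set(FOOD_GROUPS)
    if unknown:
        raise VocabularyError(f"unknown food group token(s): {sorted(unknown)}")
    comps: dict[str, bool] = {}
    for g in HEALTHY_SIMPLE:
        comps[g] = g in groups
    comps["legumes_or_nuts"] = any(g in groups for g in LEGUME_SOURCES)
    for g in UNHEALTHY:
        comps[f"no_{g}"] = g not in groups
    comps = {k: comps[k] for k in COMPONENTS}
    if include_ssb:
        if ssb_flag is None:
            raise ConfigError("include_ssb=True requires an ssb_flag per meal")
        comps[SSB_COMPONENT] = not bool(ssb_flag)
    return DietQualityScore(meal_id=None, components=comps,
                            score=int(sum(comps.values())))


def score_dataset(meals: pd.DataFrame,
                  include_ssb: bool = False) -> pd.DataFrame:
    """Score every meal; order-preserving.

    Expects a validated meal table whose ``food_groups`` column holds
    frozensets (see ``data_model.validate_meals``).  Returns one row per
    meal with the 0/1 component columns and the total ``score``.
    """
    out = pd.DataFrame({"meal_id": meals.get("meal_id", pd.Series(dtype=object))})
    groups = meals["food_groups"] if "food_groups" in meals else pd.Series(dtype=object)
    for g in HEALTHY_SIMPLE:
        out[g] = groups.map(lambda s, g=g: g in s).astype(int)
    out["legumes_or_nuts"] = groups.map(
        lambda s: any(g in s for g in LEGUME_SOURCES)).astype(int)
    for g in UNHEALTHY:
        out[f"no_{g}"] = groups.map(lambda s, g=g: g not in s).astype(int)
    out = out[["meal_id", *COMPONENTS]]
    if include_ssb:
        if "ssb_with_survey" not in meals:
            raise ConfigError("include_ssb=True requires an ssb_with_survey column")
        out[SSB_COMPONENT] = (~meals["ssb_with_survey"].astype(bool)).astype(int).to_numpy()
    score_cols = list(COMPONENTS) + ([SSB_COMPONENT] if include_ssb else [])
    out["score"] = out[score_cols].sum(axis=1)
    return out


def summarize_scores(scores: pd.DataFrame) -> dict[str, float]:
    """Mean and SD of the meal scores; NaN-safe on empty input."""
    if scores.empty:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    s = scores["score"].to_numpy(dtype=float)
    return {"n": int(s.size), "mean": float(np.mean(s)),
            "sd": float(np.std(s, ddof=1)) if s.size > 1 else float("nan")}


def expected_score(food_group_probs: Mapping[str, float],
                   ssb_prob: float | None = None) -> float:
    """Analytic expectation of the score under independent Bernoulli intake.

    With each food group consumed independently with its configured
    probability, E[score] = sum of component probabilities; the
    legumes-or-nuts component fires with 1 - (1-p_soy)(1-p_legumes).
    """
    p = food_group_probs
    e = sum(p[g] for g in HEALTHY_SIMPLE)
    e += 1.0 - np.prod([1.0 - p[g] for g in LEGUME_SOURCES])
    e += sum(1.0 - p[g] for g in UNHEALTHY)
    if ssb_prob is not None:
        e += 1.0 - ssb_prob
    return float(e)
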