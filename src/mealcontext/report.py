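"""End-to-end pipeline orchestration and table-style summaries.

``run_pipeline`` executes ingest (or simulation) → inclusion filters →
diet-quality scoring → CGM linkage → premeal-state extraction → GEE
models, and writes every stage output as CSV plus a JSON-lines run log
recording counts at each filter.  ``descriptives`` renders the
participant/meal characteristics summary and the companion/activity-by-
location percentage matrix (check-all-that-apply rows may exceed 100%).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cgm_linkage, data_model, diet_quality, synthetic_data
from .errors import ConfigError


@dataclass
class RunConfig:
    """One pipeline run: either four input CSV paths or a simulation config."""

    input_dir: str | None = None
    simulation: synthetic_data.SimulationConfig | None = None
    iauc_convention: str = "net"
    include_ssb: bool = False
    working_correlations: tuple[str, ...] = ("independent",)
    bootstrap_n: int = 10_000
    bootstrap_unit: str = "cluster"
    out_dir: str = "run_output"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of input_dir / simulation must be set")
        if self.iauc_convention not in cgm_linkage.CONVENTIONS:
            raise ConfigError(
                f"unknown iAUC convention {self.iauc_convention!r}")


def _log(fh, **kv):
    fh.write(json.dumps(kv) + "\n")


def descriptives(participants: pd.DataFrame, meals: pd.DataFrame,
                 scores: pd.DataFrame | None = None,
                 postprandial: pd.DataFrame | None = None,
                 premeal: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Participant/meal summary plus the context-by-location matrix."""
    part_rows = {
        "n_participants": len(participants),
        "age_mean": participants["age"].mean(),
        "age_sd": participants["age"].std(),
        "female_pct": 100 * (participants["sex"] == "female").mean(),
        "bmi_mean": participants["bmi"].mean(),
        "bmi_sd": participants["bmi"].std(),
    }
    for e in data_model.ETHNICITIES:
        part_rows[f"ethnicity_{e}_pct"] = \
            100 * (participants["ethnicity"] == e).mean()
    for g in data_model.GLYCEMIC_STATUSES:
        part_rows[f"glycemia_{g}_pct"] = \
            100 * (participants["glycemic_status"] == g).mean()

    meal_rows = {"n_meals": len(meals)}
    if len(meals):
        mt = data_model.mealtime_categories(meals["eat_time"])
        for m in data_model.MEALTIMES:
            meal_rows[f"mealtime_{m}_pct"] = 100 * (mt == m).mean()
        meal_rows["weekday_pct"] = \
            100 * (meals["eat_time"].dt.dayofweek < 5).mean()
        meal_rows["fullness_mean"] = meals["fullness"].mean()
        meal_rows["fullness_sd"] = meals["fullness"].std()
        for loc in data_model.LOCATIONS:
            meal_rows[f"location_{loc}_pct"] = \
                100 * (meals["location"] == loc).mean()
    if scores is not None and len(scores):
        meal_rows["diet_quality_mean"] = scores["score"].mean()
        meal_rows["diet_quality_sd"] = scores["score"].std()
    if premeal is not None and len(meals):
        meal_rows["premeal_state_pct"] = 100 * len(premeal) / len(meals)
        for s in data_model.PSYCH_STATES:
            meal_rows[f"premeal_{s}_mean"] = premeal[s].mean()
            meal_rows[f"premeal_{s}_sd"] = premeal[s].std()
    if postprandial is not None and len(postprandial):
        elig = postprandial.loc[postprandial["eligible"]]
        meal_rows["cgm_eligible_pct"] = 100 * postprandial["eligible"].mean()
        if len(elig):
            meal_rows["iauc_net_mean"] = elig["iauc_net"].mean()
            meal_rows["iauc_net_sd"] = elig["iauc_net"].std()
        else:
            meal_rows["iauc_net_mean"] = np.nan
            meal_rows["iauc_net_sd"] = np.nan

    # companion/activity percentages by location (non-exclusive rows)
    ctx_rows = []
    if len(meals):
        loc_meals = meals
        if "location_excluded" in meals.columns:
            loc_meals = meals.loc[~meals["location_excluded"]]
        groups = [("all", loc_meals)] + [
            (loc, loc_meals.loc[loc_meals["location"] == loc])
            for loc in data_model.LOCATIONS
            if (loc_meals["location"] == loc).any()]
        for name, grp in groups:
            row = {"location": name, "n": len(grp),
                   "share_pct": 100 * len(grp) / max(len(loc_meals), 1)}
            for c in data_model.COMPANIONS:
                row[f"comp_{c}_pct"] = 100 * grp["companions"].map(
                    lambda s, c=c: c in s).mean() if len(grp) else np.nan
            for a in data_model.ACTIVITIES:
                row[f"act_{a}_pct"] = 100 * grp["activities"].map(
                    lambda s, a=a: a in s).mean() if len(grp) else np.nan
            ctx_rows.append(row)

    return {
        "participants": pd.DataFrame([part_rows]).T.rename(columns={0: "value"}),
        "meals": pd.DataFrame([meal_rows]).T.rename(columns={0: "value"}),
        "context_by_location": pd.DataFrame(ctx_rows),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    results: dict = {}
    with open(log_path, "w") as log:
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            bundle, truth = synthetic_data.simulate_cohort(sim_cfg)
            synthetic_data.write_fixture(bundle, truth, out / "fixture")
            _log(log, stage="simulate", n_participants=len(bundle.participants),
                 n_surveys=len(bundle.surveys), n_meals=len(bundle.meals))
        else:
            d = Path(config.input_dir)
            bundle = data_model.load_tables(
                d / "participants.csv", d / "surveys.csv", d / "meals.csv",
                d / "cgm.csv")
            _log(log, stage="ingest", n_participants=len(bundle.participants),
                 n_surveys=len(bundle.surveys), n_meals=len(bundle.meals))

        meals, exclusions = data_model.filter_meals(bundle.meals)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        _log(log, stage="filter_meals", n_in=len(bundle.meals),
             n_included=len(meals),
             n_dropped=int((exclusions["reason"] == "outside_05_24").sum()),
             n_location_flagged=int(meals["location_excluded"].sum()))

        scores = diet_quality.score_dataset(meals,
                                            include_ssb=config.include_ssb)
        scores.to_csv(out / "scores.csv", index=False)
        summary = diet_quality.summarize_scores(scores)
        _log(log, stage="score", **summary)

        postprandial = cgm_linkage.link_all(meals, bundle.cgm)
        postprandial.to_csv(out / "postprandial.csv", index=False)
        _log(log, stage="link_cgm", n_meals=len(postprandial),
             eligible_fraction=cgm_linkage.eligible_fraction(postprandial))

        premeal = data_model.extract_premeal_states(meals, bundle.surveys)
        premeal.to_csv(out / "premeal_states.csv", index=False)
        _log(log, stage="premeal_states", n_meals=len(meals),
             n_with_state=len(premeal),
             availability=len(premeal) / max(len(meals), 1))

        desc = descriptives(bundle.participants, meals, scores, postprandial,
                            premeal)
        desc["participants"].to_csv(out / "table1_participants.csv")
        desc["meals"].to_csv(out / "table1_meals.csv")
        desc["context_by_location"].to_csv(out / "table2_context.csv",
                                           index=False)

        analysis = association.build_analysis_table(
            bundle.participants, meals, scores, postprandial, premeal)

        # companion/activity vs location Wald tests (logit, one per indicator)
        wald_rows = []
        ctx = analysis.loc[~analysis["location_excluded"]]
        loc_terms = [t for t in association.LOCATION_TERMS
                     if ctx[t].sum() > 0]
        for term in association.COMPANION_TERMS + association.ACTIVITY_TERMS:
            if ctx[term].nunique() < 2:
                continue
            w = association.wald_compare(ctx, term, loc_terms, link="logit")
            wald_rows.append({"outcome": term, "statistic": w.statistic,
                              "df": w.df, "p": w.p})
        wald = pd.DataFrame(wald_rows)
        wald.to_csv(out / "wald.csv", index=False)
        _log(log, stage="wald", n_tests=len(wald))

        table3 = association.run_table3(
            analysis, working_correlations=config.working_correlations)
        table3.to_csv(out / "results.csv", index=False)
        _log(log, stage="table3", n_models=int(
            table3.groupby(["model_id", "working_correlation",
                            "outcome"]).ngroups))

        # premeal-state bootstrap correlations with diet quality
        boot_rows = []
        if len(premeal):
            merged = analysis.dropna(subset=["premeal_hunger", "diet_quality"])
            for s in data_model.PSYCH_STATES:
                sub = analysis.dropna(subset=[f"premeal_{s}", "diet_quality"])
                if sub[f"premeal_{s}"].nunique() < 2 or len(sub) < 3:
                    continue
                bc = association.bootstrap_correlation(
                    sub[f"premeal_{s}"], sub["diet_quality"],
                    sub["participant_id"], n_boot=config.bootstrap_n,
                    seed=config.seed + 17, unit=config.bootstrap_unit)
                boot_rows.append({"state": s, "outcome": "diet_quality",
                                  "r": bc.r, "ci_lo": bc.ci_lo,
                                  "ci_hi": bc.ci_hi, "p": bc.p,
                                  "n_obs": bc.n_obs,
                                  "n_clusters": bc.n_clusters})
        boot = pd.DataFrame(boot_rows)
        boot.to_csv(out / "bootstrap.csv", index=False)

        # adjusted marginal diet-quality estimate per location
        marg_terms = association.prunable_terms(
            ctx, association.BASELINE_ADJUSTMENT_TERMS
            + association.COMPANION_TERMS + association.ACTIVITY_TERMS
            + tuple(loc_terms))
        prim = association.ModelSpec(outcome="diet_quality", terms=marg_terms)
        fit = association.fit_gee(ctx, prim)
        assigns = {k: {c: v for c, v in a.items() if c in loc_terms}
                   for k, a in association.location_level_assignments().items()
                   if k == "home" or f"loc_{k}" in loc_terms}
        marg = association.marginal_estimates(fit, ctx, assigns)
        marginals = pd.DataFrame([dataclasses.asdict(m) for m in marg])
        marginals.to_csv(out / "marginals.csv", index=False)
        _log(log, stage="marginals", n_levels=len(marginals))

        manifest = {
            "seed": config.seed,
            "iauc_convention": config.iauc_convention,
            "include_ssb": config.include_ssb,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    results.update({
        "bundle": bundle, "meals": meals, "scores": scores,
        "postprandial": postprandial, "premeal": premeal,
        "descriptives": desc, "analysis": analysis, "table3": table3,
        "wald": wald, "bootstrap": boot, "marginals": marginals,
    })
    return results
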