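"""Context-outcome association estimation for clustered meal-level data.

Meals are the observations and participants the clusters.  Coefficients
come from generalized estimating equations (GEE) with a working
correlation structure (independent by default; exchangeable and AR(1) as
sensitivity re-runs) and cluster-robust sandwich standard errors; 95%
confidence intervals are normal-theory (beta +/- 1.96 SE).  Context blocks
are compared against null models with robust Wald chi-square tests, crude
premeal-state correlations are tested with a cluster bootstrap, adjusted
marginal (G-computation) estimates are derived from fitted models, and
variance inflation factors screen the multivariable design for
collinearity.

Estimation is delegated to statsmodels' GEE; the inference layers around
it (Wald block comparison, cluster bootstrap, marginal standardization,
VIF) are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    ACTIVITIES,
    COMPANIONS,
    ETHNICITIES,
    EDUCATIONS,
    GLYCEMIC_STATUSES,
    LOCATIONS,
    MEALTIMES,
    PSYCH_STATES,
    mealtime_categories,
)
from .errors import DegenerateDataError, SpecError

Z95 = 1.959963984540054  # normal 97.5% quantile

WORKING_CORRELATIONS = ("independent", "exchangeable", "ar1")
LINKS = ("identity", "logit")

#: reference levels are omitted from the indicator expansions
LOCATION_TERMS = tuple(f"loc_{l}" for l in LOCATIONS if l != "home")
COMPANION_TERMS = tuple(f"comp_{c}" for c in COMPANIONS if c != "alone")
ACTIVITY_TERMS = tuple(f"act_{a}" for a in ACTIVITIES if a != "nothing")
MEALTIME_TERMS = tuple(f"mealtime_{m}" for m in MEALTIMES if m != "breakfast")
STATE_TERMS = tuple(f"premeal_{s}" for s in PSYCH_STATES)

BASELINE_ADJUSTMENT_TERMS = (
    "age", "sex_female", "eth_malay", "eth_indian", "edu_a_level",
    "edu_university", "smoking", "heavy_alcohol", "working", "married",
    "bmi", "gly_prediabetes", "gly_diabetes", "weekend",
) + MEALTIME_TERMS

CONTEXT_TERMS = COMPANION_TERMS + ACTIVITY_TERMS + LOCATION_TERMS


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    terms: tuple[str, ...]
    link: str = "identity"
    working_correlation: str = "independent"
    cluster: str = "participant_id"

    def __post_init__(self):
        if self.link not in LINKS:
            raise SpecError(f"unknown link {self.link!r}")
        if self.working_correlation not in WORKING_CORRELATIONS:
            raise SpecError(
                f"unknown working correlation {self.working_correlation!r}")
        # an empty term tuple is allowed: intercept-only model


@dataclass
class GeeFit:
    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_clusters: int
    degenerate: bool = False

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.params, "se": self.se, "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi, "p": self.pvalues,
        })


@dataclass
class WaldComparison:
    added_terms: tuple[str, ...]
    statistic: float
    df: int
    p: float


@dataclass
class BootstrapCorrelation:
    r: float
    n_boot: int
    ci_lo: float
    ci_hi: float
    p: float
    n_obs: int
    n_clusters: int
    unit: str = "cluster"


@dataclass
class MarginalEstimate:
    level: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float


# ---------------------------------------------------------------------------
# Analysis table
# ---------------------------------------------------------------------------

def build_analysis_table(participants: pd.DataFrame, meals: pd.DataFrame,
                         scores: pd.DataFrame | None = None,
                         postprandial: pd.DataFrame | None = None,
                         premeal: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the meal-level modelling table.

    One row per meal with outcome columns (``diet_quality``, ``fullness``,
    ``iauc_net``/``iauc_positive`` where eligible, premeal state ratings
    where available) and the full indicator-expanded covariate set.
    Check-all-that-apply predictors become separate non-exclusive
    indicators with ``alone``/``nothing`` as all-zero reference patterns.
    """
    df = meals.copy()
    part = participants.set_index("participant_id")
    df = df.join(part, on="participant_id")

    out = pd.DataFrame({
        "meal_id": df["meal_id"],
        "participant_id": df["participant_id"],
        "fullness": df["fullness"].astype(float),
        "age": df["age"].astype(float),
        "bmi": df["bmi"].astype(float),
        "sex_female": (df["sex"] == "female").astype(float),
        "smoking": df["smoking"].astype(float),
        "heavy_alcohol": df["heavy_alcohol"].astype(float),
        "working": df["working"].astype(float),
        "married": df["married_or_partnered"].astype(float),
        "weekend": (df["eat_time"].dt.dayofweek >= 5).astype(float),
        "location": df["location"],
    })
    for e in ETHNICITIES[1:]:
        out[f"eth_{e}"] = (df["ethnicity"] == e).astype(float)
    for e in EDUCATIONS[1:]:
        out[f"edu_{e}"] = (df["education"] == e).astype(float)
    for g in GLYCEMIC_STATUSES[1:]:
        out[f"gly_{g}"] = (df["glycemic_status"] == g).astype(float)
    mt = mealtime_categories(df["eat_time"])
    for m in MEALTIMES[1:]:
        out[f"mealtime_{m}"] = (mt == m).astype(float)
    for l in LOCATIONS:
        if l != "home":
            out[f"loc_{l}"] = (df["location"] == l).astype(float)
    for c in COMPANIONS:
        if c != "alone":
            out[f"comp_{c}"] = df["companions"].map(
                lambda s, c=c: float(c in s))
    for a in ACTIVITIES:
        if a != "nothing":
            out[f"act_{a}"] = df["activities"].map(
                lambda s, a=a: float(a in s))
    if "location_excluded" in df.columns:
        out["location_excluded"] = df["location_excluded"].astype(bool)
    else:
        out["location_excluded"] = False

    if scores is not None:
        out = out.merge(scores[["meal_id", "score"]].rename(
            columns={"score": "diet_quality"}), on="meal_id", how="left")
        out["diet_quality"] = out["diet_quality"].astype(float)
    if postprandial is not None:
        out = out.merge(
            postprandial[["meal_id", "eligible", "iauc_net", "iauc_positive"]],
            on="meal_id", how="left")
        out["eligible"] = out["eligible"].fillna(False).astype(bool)
    if premeal is not None:
        pm = premeal[["meal_id", *PSYCH_STATES]].rename(
            columns={s: f"premeal_{s}" for s in PSYCH_STATES})
        out = out.merge(pm, on="meal_id", how="left")
    return out


# ---------------------------------------------------------------------------
# GEE fitting
# ---------------------------------------------------------------------------

def supported_terms(data: pd.DataFrame, terms) -> tuple[str, ...]:
    """Drop terms that are constant in ``data`` (e.g. an indicator for a
    covariate class with no observations); they would alias the intercept."""
    return tuple(t for t in terms if data[t].nunique(dropna=True) > 1)


def prunable_terms(data: pd.DataFrame, terms) -> tuple[str, ...]:
    """Supported terms minus any residually aliased columns, checked on the
    complete cases of ``data`` over ``terms``."""
    cc = data.loc[:, list(terms)].dropna()
    keep = supported_terms(cc, terms)
    X = _design(cc, keep)
    if np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]:
        return keep
    aliased = _aliased_columns(X)
    return tuple(t for t in keep if t not in aliased)


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    missing = [t for t in terms if t not in data.columns]
    if missing:
        raise SpecError(f"term column(s) not in data: {missing}")
    X = data[list(terms)].astype(float)
    X.insert(0, "intercept", 1.0)
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Column names made redundant by earlier columns (via incremental rank)."""
    aliased = []
    arr = X.to_numpy()
    rank = 0
    kept: list[int] = []
    for j in range(arr.shape[1]):
        cand = arr[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            kept.append(j)
        else:
            aliased.append(X.columns[j])
    return aliased


def _cov_struct(name: str):
    if name == "independent":
        return sm.cov_struct.Independence()
    if name == "exchangeable":
        return sm.cov_struct.Exchangeable()
    return sm.cov_struct.Autoregressive(grid=True)


def fit_gee(data: pd.DataFrame, spec: ModelSpec) -> GeeFit:
    """Fit a marginal GEE with cluster-robust sandwich covariance.

    Rows with any missing value among the outcome, terms, or cluster are
    dropped (complete-case per model).
    """
    cols = [spec.outcome, *spec.terms, spec.cluster]
    d = data.loc[:, cols].dropna()
    if d[spec.cluster].nunique() < 2:
        raise SpecError("GEE requires at least 2 clusters")
    y = d[spec.outcome].astype(float)
    if spec.link == "logit" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise SpecError("logit link requires a binary 0/1 outcome")
    X = _design(d, spec.terms)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SpecError(
            f"singular design; aliased term(s): {_aliased_columns(X)}")

    names = list(X.columns)
    n_clusters = int(d[spec.cluster].nunique())
    if float(np.var(y.to_numpy())) == 0.0:
        # constant outcome: intercept = the constant, all slopes 0/0-SE
        params = pd.Series(0.0, index=names)
        params["intercept"] = float(y.iloc[0]) if spec.link == "identity" else (
            np.inf if y.iloc[0] > 0 else -np.inf)
        zeros = pd.Series(0.0, index=names)
        ones = pd.Series(1.0, index=names)
        return GeeFit(spec, params, zeros, params, params, ones,
                      pd.DataFrame(0.0, index=names, columns=names),
                      n_obs=len(d), n_clusters=n_clusters, degenerate=True)

    family = sm.families.Gaussian() if spec.link == "identity" \
        else sm.families.Binomial()
    kwargs = {}
    if spec.working_correlation == "ar1":
        # AR(1) needs within-cluster ordering; use the row rank per cluster
        kwargs["time"] = d.groupby(spec.cluster).cumcount().to_numpy()[:, None]
    model = sm.GEE(y.to_numpy(), X.to_numpy(), groups=d[spec.cluster].to_numpy(),
                   family=family,
                   cov_struct=_cov_struct(spec.working_correlation), **kwargs)
    res = model.fit()
    params = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(res.params / res.bse)),
                      index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return GeeFit(spec, params, se, params - Z95 * se, params + Z95 * se,
                  pvals, cov, n_obs=len(d), n_clusters=n_clusters)


def wald_compare(data: pd.DataFrame, outcome: str,
                 added_terms: tuple[str, ...] | list[str],
                 null_terms: tuple[str, ...] | list[str] = (),
                 link: str = "identity",
                 working_correlation: str = "independent",
                 cluster: str = "participant_id") -> WaldComparison:
    """Robust Wald chi-square comparing a null GEE with the model adding
    ``added_terms`` (quadratic form in the sandwich covariance block)."""
    added = tuple(added_terms)
    if not added:
        raise SpecError("wald_compare requires a non-empty added term set")
    overlap = set(added) & set(null_terms)
    if overlap:
        raise SpecError(f"added terms already in the null model: {overlap}")
    spec = ModelSpec(outcome=outcome, terms=tuple(null_terms) + added,
                     link=link, working_correlation=working_correlation,
                     cluster=cluster)
    fit = fit_gee(data, spec)
    b = fit.params[list(added)].to_numpy()
    V = fit.cov.loc[list(added), list(added)].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    df = len(added)
    return WaldComparison(added_terms=added, statistic=stat, df=df,
                          p=float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Cluster bootstrap correlation
# ---------------------------------------------------------------------------

def bootstrap_correlation(x, y, cluster_ids, n_boot: int = 10_000,
                          seed: int = 0,
                          unit: str = "cluster") -> BootstrapCorrelation:
    """Pearson correlation with cluster-bootstrap inference.

    Clusters (participants) are resampled with replacement and r is
    recomputed per resample via per-cluster sufficient statistics (exactly
    equivalent to concatenating the resampled rows).  The two-sided
    p-value is ``2 * min(P(r* <= 0), P(r* >= 0))`` with an add-one
    continuity correction over ``n_boot + 1``; the CI is percentile 2.5 /
    97.5.  ``unit='meal'`` degrades to a plain case-resampling bootstrap
    by treating every row as its own cluster.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, cluster_ids = x[keep], y[keep], cluster_ids[keep]
    if x.size < 3:
        raise DegenerateDataError("fewer than 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    if unit not in ("cluster", "meal"):
        raise SpecError(f"unknown bootstrap unit {unit!r}")
    if unit == "meal":
        cluster_ids = np.arange(x.size)

    codes, _ = pd.factorize(cluster_ids)
    n_clusters = int(codes.max()) + 1
    if n_clusters < 2:
        raise DegenerateDataError("bootstrap requires at least 2 clusters")

    r_obs = float(np.corrcoef(x, y)[0, 1])

    # per-cluster sufficient statistics
    stats_mat = np.zeros((n_clusters, 6))
    np.add.at(stats_mat, codes, np.column_stack(
        [np.ones_like(x), x, y, x * x, y * y, x * y]))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_clusters, size=(n_boot, n_clusters))
    agg = stats_mat[idx].sum(axis=1)  # (n_boot, 6)
    n, sx, sy, sxx, syy, sxy = agg.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r_star = cov / np.sqrt(vx * vy)
    r_star = r_star[np.isfinite(r_star)]
    nb = r_star.size
    p = 2.0 * (min(np.sum(r_star <= 0), np.sum(r_star >= 0)) + 1) / (nb + 1)
    ci_lo, ci_hi = np.percentile(r_star, [2.5, 97.5])
    return BootstrapCorrelation(
        r=r_obs, n_boot=n_boot, ci_lo=float(ci_lo), ci_hi=float(ci_hi),
        p=float(min(p, 1.0)), n_obs=int(x.size), n_clusters=n_clusters,
        unit=unit)


# ---------------------------------------------------------------------------
# Adjusted marginal estimates (G-computation)
# ---------------------------------------------------------------------------

def location_level_assignments() -> dict[str, dict[str, float]]:
    """Focal-term column assignments for each meal location level."""
    out = {}
    for loc in LOCATIONS:
        out[loc] = {t: (1.0 if t == f"loc_{loc}" else 0.0)
                    for t in LOCATION_TERMS}
    return out


def marginal_estimates(fit: GeeFit, data: pd.DataFrame,
                       level_assignments: dict[str, dict[str, float]],
                       ) -> list[MarginalEstimate]:
    """Adjusted marginal outcome per focal level.

    For each level, every row's focal columns are set to the level's
    indicator pattern, the model's predicted outcome is averaged over the
    observed covariate distribution, and the delta-method CI is taken from
    the robust covariance.
    """
    cols = [t for t in fit.spec.terms]
    d = data.loc[:, [fit.spec.outcome, *cols, fit.spec.cluster]].dropna()
    beta = fit.params.to_numpy()
    out = []
    for level, assign in level_assignments.items():
        unknown = set(assign) - set(cols)
        if unknown:
            raise SpecError(f"focal column(s) not in model: {sorted(unknown)}")
        dd = d.copy()
        for col, val in assign.items():
            dd[col] = val
        X = _design(dd, fit.spec.terms).to_numpy()
        eta = X @ beta
        if fit.spec.link == "identity":
            est = float(np.mean(eta))
            grad = X.mean(axis=0)
        else:
            mu = 1.0 / (1.0 + np.exp(-eta))
            est = float(np.mean(mu))
            grad = (mu * (1 - mu))[:, None].T @ X / X.shape[0]
            grad = grad.ravel()
        var = float(grad @ fit.cov.to_numpy() @ grad)
        se = np.sqrt(max(var, 0.0))
        out.append(MarginalEstimate(level=level, estimate=est, se=se,
                                    ci_lo=est - Z95 * se,
                                    ci_hi=est + Z95 * se))
    return out


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def vif(data: pd.DataFrame, terms: tuple[str, ...] | list[str]) -> pd.Series:
    """Variance inflation factors from auxiliary regressions (with
    intercept); perfect collinearity yields ``inf``."""
    terms = list(terms)
    if len(terms) < 2:
        raise SpecError("vif requires at least 2 terms")
    d = data.loc[:, terms].dropna().astype(float)
    out = {}
    for t in terms:
        others = [o for o in terms if o != t]
        X = np.column_stack([np.ones(len(d))] + [d[o].to_numpy() for o in others])
        ytarget = d[t].to_numpy()
        coef, *_ = np.linalg.lstsq(X, ytarget, rcond=None)
        resid = ytarget - X @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((ytarget - ytarget.mean()) ** 2))
        if ss_tot == 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Primary multivariable analysis
# ---------------------------------------------------------------------------

def run_table3(analysis: pd.DataFrame,
               working_correlations: tuple[str, ...] = ("independent",
                                                        "exchangeable", "ar1"),
               include_state_models: bool = True) -> pd.DataFrame:
    """Fit the primary multivariable GEE models for the three outcomes.

    For each outcome (diet quality, fullness, net iAUC) the model adjusts
    for the demographic/lifestyle/clinical covariates, day of week,
    mealtime, and simultaneously for meal location, companions, and
    activities; rare-location meals are excluded, and glucose models are
    restricted to CGM-eligible meals.  Premeal-state models add the four
    state ratings and restrict to meals with available states.  The first
    working correlation is the primary model; the rest are sensitivity
    re-runs.  Returns a long coefficient table.
    """
    d = analysis.loc[~analysis["location_excluded"]].copy()
    # drop indicators with no support (e.g. rare-location levels, covariate
    # classes absent from a small cohort)
    base_terms = supported_terms(
        d, BASELINE_ADJUSTMENT_TERMS + COMPANION_TERMS + ACTIVITY_TERMS
        + LOCATION_TERMS)
    rows = []
    outcomes = {"diet_quality": "diet_quality", "fullness": "fullness",
                "iauc": "iauc_net"}
    for model_id, extra in (("primary", ()),
                            ("premeal_states", STATE_TERMS)):
        if extra and not include_state_models:
            continue
        terms = base_terms + extra
        for label, col in outcomes.items():
            if col not in d.columns:
                continue
            sub = d
            if label == "iauc" and "eligible" in d.columns:
                sub = d.loc[d["eligible"]]
            # complete-case per model; re-check indicator support and
            # aliasing on the rows the model will actually use
            cc = sub.loc[:, [col, *terms, "participant_id"]].dropna()
            model_terms = prunable_terms(cc, terms)
            for wc in working_correlations:
                spec = ModelSpec(outcome=col, terms=model_terms,
                                 working_correlation=wc)
                fit = fit_gee(cc, spec)
                tab = fit.table().reset_index(names="term")
                tab["outcome"] = label
                tab["model_id"] = model_id
                tab["working_correlation"] = wc
                tab["n_obs"] = fit.n_obs
                tab["n_clusters"] = fit.n_clusters
                rows.append(tab)
    return pd.concat(rows, ignore_index=True)[
        ["model_id", "working_correlation", "outcome", "term", "beta", "se",
         "ci_lo", "ci_hi", "p", "n_obs", "n_clusters"]]
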