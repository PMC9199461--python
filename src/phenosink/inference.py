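"""Mixed-effects inference on the derived metrics.

Endpoint metrics (day of 50 % senescence, total autumn photosynthesis,
total relative carbon gain) are modeled with linear mixed-effects
models carrying the leaf- and bud-removal percentages as continuous
covariates (0-75), their interaction, and a random block intercept; the
longitudinal senescence-index model adds day of year and a random plant
intercept.  Restricted maximum likelihood throughout.

Workflow mirrors common field practice: non-significant interactions
are pruned (highest order first, refitting after each removal) before
treatment effects are evaluated with Type II Wald chi-square tests;
variance explained is summarized as marginal / conditional R-squared
(Nakagawa-Schielzeth decomposition); prediction uncertainty comes from
a model-based (parametric) bootstrap whose 95 % limits are the point
prediction plus/minus 1.96 times the bootstrap standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelResult",
    "FitError",
    "fit_lmm",
    "prune_interactions",
    "effect_tests",
    "r2_mixed",
    "bootstrap_ci",
    "recovery_study",
    "endpoint_spec",
    "longitudinal_spec",
]

_TRANSFORMS = {
    "identity": (lambda y: y, lambda y: y),
    "log": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
}

_FIT_METHODS = ("powell", "lbfgs", "cg", "nm")


class FitError(RuntimeError):
    """Raised when a model cannot be fit at all."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` uses formula syntax (``a``, ``a:b``); ``random_terms``
    lists grouping columns — the first becomes the random intercept's
    grouping factor, any further ones enter as crossed variance
    components.  ``transform`` is applied to the response before
    fitting and undone on predictions.
    """

    response: str
    fixed_terms: tuple[str, ...] = ("leaf_pct", "bud_pct", "leaf_pct:bud_pct")
    random_terms: tuple[str, ...] = ("block_id",)
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform '{self.transform}'")
        if len(self.random_terms) < 1:
            raise ValueError("at least one random grouping factor is required")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"_response ~ {rhs}"

    def drop_term(self, term: str) -> "ModelSpec":
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))


def endpoint_spec(response: str, transform: str = "identity") -> ModelSpec:
    """The study's endpoint model: removal gradients, interaction, block."""
    return ModelSpec(response=response, transform=transform)


def longitudinal_spec(response: str = "index", transform: str = "identity") -> ModelSpec:
    """The senescence-over-time model: adds DOY and a plant intercept."""
    return ModelSpec(
        response=response,
        fixed_terms=(
            "doy", "leaf_pct", "bud_pct",
            "leaf_pct:bud_pct", "doy:leaf_pct", "doy:bud_pct",
        ),
        random_terms=("block_id", "tree_id"),
        transform=transform,
    )


@dataclass
class ModelResult:
    """A fitted mixed model and everything downstream steps need."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    variance_components: dict[str, float]
    converged: bool
    flagged: bool
    notes: tuple[str, ...] = ()
    pruned_terms: tuple[str, ...] = ()
    n_obs: int = 0
    _design_info: object | None = field(default=None, repr=False)
    _exog: np.ndarray | None = field(default=None, repr=False)
    _data: pd.DataFrame | None = field(default=None, repr=False)
    _sm_result: object | None = field(default=None, repr=False)

    @property
    def residual_variance(self) -> float:
        return self.variance_components["residual"]

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse, "p": self.pvalues})


def _prepare(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    cols = {spec.response, *spec.random_terms}
    for term in spec.fixed_terms:
        cols.update(term.split(":"))
    missing = cols - set(data.columns)
    if missing:
        raise FitError(f"data lacks columns {sorted(missing)}")
    df = data.dropna(subset=[spec.response]).copy()
    fwd, _ = _TRANSFORMS[spec.transform]
    y = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "log" and np.any(y <= 0):
        raise FitError("log transform requires a strictly positive response")
    if spec.transform == "sqrt" and np.any(y < 0):
        raise FitError("sqrt transform requires a non-negative response")
    df["_response"] = fwd(y)
    for g in spec.random_terms:
        if df[g].nunique() < 2:
            raise FitError(f"random factor '{g}' needs at least 2 levels")
    return df


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """REML fit of a mixed model described by *spec*.

    Removal percentages enter as continuous covariates.  The optimizer
    is delegated to statsmodels' MixedLM with a sequence of fallback
    methods; a non-converged or boundary fit is returned flagged, never
    silently.  Data with (numerically) zero residual variance are fit
    exactly by least squares, with all variance components at zero.
    """
    df = _prepare(spec, data)
    y_t, X = patsy.dmatrices(spec.formula, df, return_type="dataframe")
    y_arr = np.asarray(y_t).ravel()
    design_info = X.design_info

    # degenerate noiseless data: the mixed model collapses to exact OLS
    ols = sm.OLS(y_arr, np.asarray(X)).fit()
    if np.var(y_arr) == 0 or (ols.ssr / max(len(y_arr), 1)) < 1e-12 * max(np.var(y_arr), 1.0):
        params = pd.Series(ols.params, index=X.columns)
        zeros = pd.Series(0.0, index=X.columns)
        vc = {g: 0.0 for g in spec.random_terms}
        vc["residual"] = 0.0
        return ModelResult(
            spec=spec, params=params, bse=zeros, pvalues=zeros,
            variance_components=vc, converged=True, flagged=False,
            notes=("noiseless data; exact least-squares solution",),
            n_obs=len(df), _design_info=design_info, _exog=np.asarray(X), _data=df,
        )

    groups = df[spec.random_terms[0]]
    vc_formula = {g: f"0 + C({g})" for g in spec.random_terms[1:]} or None
    model = sm.MixedLM.from_formula(
        spec.formula, df, groups=groups, re_formula="1", vc_formula=vc_formula
    )
    res = None
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _FIT_METHODS:
            try:
                candidate = model.fit(reml=True, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                notes.append(f"{method}: {exc}")
                continue
            res = candidate
            if candidate.converged:
                break
    if res is None:
        raise FitError("all optimizers failed: " + "; ".join(notes))

    vc = {spec.random_terms[0]: float(np.asarray(res.cov_re)[0, 0])}
    for name, v in zip(spec.random_terms[1:], np.atleast_1d(getattr(res, "vcomp", []))):
        vc[name] = float(v)
    vc["residual"] = float(res.scale)
    fe = list(X.columns)
    flagged = not res.converged or any(v < 0 for v in vc.values())
    if not res.converged:
        notes.append("optimizer did not report convergence")
    return ModelResult(
        spec=spec,
        params=res.params[fe],
        bse=res.bse[fe],
        pvalues=res.pvalues[fe],
        variance_components=vc,
        converged=bool(res.converged),
        flagged=flagged,
        notes=tuple(notes),
        n_obs=len(df),
        _design_info=design_info,
        _exog=np.asarray(X),
        _data=df,
        _sm_result=res,
    )


def _term_components(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def _contains(outer: str, inner: str) -> bool:
    return outer != inner and _term_components(outer) >= _term_components(inner)


def _wald_term(result: ModelResult, term: str) -> tuple[float, int, float]:
    """Wald chi-square for one formula term of a fitted model."""
    di = result._design_info
    sl = di.term_name_slices[term]
    names = di.column_names[sl]
    b = result.params[names].to_numpy()
    if result._sm_result is not None:
        cov = pd.DataFrame(
            np.asarray(result._sm_result.cov_params()),
            index=result._sm_result.params.index,
            columns=result._sm_result.params.index,
        ).loc[names, names].to_numpy()
    else:  # degenerate noiseless fit: zero SEs, infinite evidence
        stat = np.inf if np.any(b != 0) else 0.0
        return stat, len(names), 0.0 if stat else 1.0
    stat = float(b @ np.linalg.solve(cov, b))
    df = len(names)
    return stat, df, float(stats.chi2.sf(stat, df))


def effect_tests(result: ModelResult, data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-term Type II Wald chi-square tests.

    A term is tested in the model that contains every other term except
    those marginal to it (i.e. interactions containing a main effect
    are excluded when testing that main effect), honoring marginality
    the way car-style Type II ANOVA does.  Continuous covariates carry
    one degree of freedom.
    """
    data = result._data if data is None else data
    rows = []
    for term in result.spec.fixed_terms:
        higher = [t for t in result.spec.fixed_terms if _contains(t, term)]
        if higher:
            reduced = result.spec
            for t in higher:
                reduced = reduced.drop_term(t)
            sub = fit_lmm(reduced, data)
            stat, df, p = _wald_term(sub, term)
        else:
            stat, df, p = _wald_term(result, term)
        rows.append((term, stat, df, p))
    return pd.DataFrame(rows, columns=["term", "statistic", "df", "p"]).set_index("term")


def prune_interactions(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelSpec, list[tuple[str, float]]]:
    """Drop non-significant interaction terms before effect evaluation.

    Highest-order interactions are considered first; the least
    significant one is removed and the model refit, repeating until
    every remaining interaction is significant at *alpha*.  Main
    effects are never pruned.  Returns the reduced spec and a log of
    ``(term, p)`` removals.
    """
    log: list[tuple[str, float]] = []
    current = spec
    while True:
        interactions = [t for t in current.fixed_terms if ":" in t]
        if not interactions:
            break
        max_order = max(t.count(":") for t in interactions)
        # only terms not nested in a surviving higher-order term are removable
        candidates = [
            t for t in interactions
            if t.count(":") == max_order
            and not any(_contains(o, t) for o in current.fixed_terms)
        ]
        if not candidates:
            break
        fitted = fit_lmm(current, data)
        # candidates are maximal-order terms, so their Type II test is the
        # Wald test in the full current model
        pvals = {t: _wald_term(fitted, t)[2] for t in candidates}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            break
        log.append((worst, pvals[worst]))
        current = current.drop_term(worst)
    return current, log


def r2_mixed(result: ModelResult) -> tuple[float, float]:
    """Marginal and conditional R-squared (Nakagawa-Schielzeth).

    Marginal: variance of the fixed-effect predictions over the total
    (fixed + random + residual) variance; conditional adds the random
    variances to the numerator.  Negative variance estimates are
    clamped to zero with a warning.
    """
    var_fixed = float(np.var(result._exog @ result.params.to_numpy()))
    var_random = 0.0
    resid = result.variance_components["residual"]
    for name, v in result.variance_components.items():
        if name == "residual":
            continue
        if v < 0:
            warnings.warn(f"negative variance for '{name}' clamped to 0")
            v = 0.0
        var_random += v
    if resid < 0:
        warnings.warn("negative residual variance clamped to 0")
        resid = 0.0
    total = var_fixed + var_random + resid
    if total == 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_random) / total


def _default_conditions(result: ModelResult) -> pd.DataFrame:
    covariates = sorted({c for t in result.spec.fixed_terms for c in t.split(":")})
    if not covariates:
        return pd.DataFrame({"_const": [1]})
    return (
        result._data[covariates].drop_duplicates().sort_values(covariates).reset_index(drop=True)
    )


def bootstrap_ci(
    result: ModelResult,
    n_sim: int = 1000,
    seed: int | None = None,
    conditions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Model-based bootstrap confidence intervals for predictions.

    Responses are simulated from the fitted model (fixed-effect means
    plus Gaussian draws for every random term and the residual), the
    model is refit on each simulated response, and per-condition
    population-level predictions are collected.  The 95 % limits are
    the original prediction plus/minus 1.96 times the bootstrap
    standard deviation, computed on the model (transformed) scale and
    back-transformed afterwards.  Failed refits are dropped and
    counted; more than 10 % failures is an error.

    Returns the condition grid with columns ``fit``, ``se_boot``,
    ``lower95``, ``upper95`` (response scale) and attrs
    ``n_failed`` / ``param_draws`` (bootstrap draws of the fixed
    effects, for coefficient-level intervals).
    """
    rng = np.random.default_rng(seed)
    spec = result.spec
    data = result._data
    conditions = _default_conditions(result) if conditions is None else conditions.copy()
    (X_cond,) = patsy.build_design_matrices([result._design_info], conditions)
    X_cond = np.asarray(X_cond)
    beta = result.params.to_numpy()
    point_t = X_cond @ beta
    _, back = _TRANSFORMS[spec.transform]

    mean_t = result._exog @ beta
    groups = [data[g].to_numpy() for g in spec.random_terms]
    sds = [np.sqrt(max(result.variance_components[g], 0.0)) for g in spec.random_terms]
    resid_sd = np.sqrt(max(result.variance_components["residual"], 0.0))
    total_sd = sum(sds) + resid_sd

    if total_sd < 1e-10:
        # every simulated response equals the fitted mean: all bootstrap
        # replicates coincide and the interval has zero width
        out = conditions.copy()
        out["fit"] = back(point_t)
        out["se_boot"] = 0.0
        out["lower95"] = out["fit"]
        out["upper95"] = out["fit"]
        out.attrs["n_failed"] = 0
        out.attrs["param_draws"] = pd.DataFrame(
            np.tile(beta, (n_sim, 1)), columns=result.params.index
        )
        return out

    draws = []
    param_draws = []
    n_failed = 0
    for _ in range(n_sim):
        y = mean_t.copy()
        for g, sd in zip(groups, sds):
            if sd > 0:
                levels, inverse = np.unique(g, return_inverse=True)
                y = y + rng.normal(0.0, sd, len(levels))[inverse]
        if resid_sd > 0:
            y = y + rng.normal(0.0, resid_sd, len(y))
        sim = data.copy()
        _, inv = _TRANSFORMS[spec.transform]
        sim[spec.response] = inv(y)  # fit_lmm re-applies the transform
        try:
            refit = fit_lmm(spec, sim)
        except FitError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        b = refit.params.to_numpy()
        draws.append(X_cond @ b)
        param_draws.append(b)
    if n_failed > 0.1 * n_sim:
        raise FitError(f"{n_failed}/{n_sim} bootstrap refits failed")

    draws_arr = np.asarray(draws)
    se = draws_arr.std(axis=0, ddof=1)
    out = conditions.copy()
    out["fit"] = back(point_t)
    out["se_boot"] = se
    out["lower95"] = back(point_t - 1.96 * se)
    out["upper95"] = back(point_t + 1.96 * se)
    out.attrs["n_failed"] = n_failed
    out.attrs["param_draws"] = pd.DataFrame(np.asarray(param_draws), columns=result.params.index)
    return out


def recovery_study(
    config,
    n_reps: int,
    seed: int,
    n_boot: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Repeat simulate -> QC -> metrics -> fit and summarize recovery.

    Per replicate the full 81-tree experiment is generated with a fresh
    child seed, cleaned, summarized, and the endpoint model of the day
    of 50 % senescence is fit (interactions pruned at *alpha* before
    the leaf-percent slope is read off).  Also records the percent
    difference in total leaf-level autumn photosynthesis between the
    75 % leaf-removal group and the control.  With ``n_boot > 0``,
    a model-based bootstrap interval for the leaf slope is computed per
    replicate and its empirical coverage of the configured truth is
    reported.

    Returns a dict with the per-replicate table and summary statistics
    (mean, SD, Monte-Carlo SE and bias for each recovered quantity).
    """
    from .design import generate_design
    from .metrics import compute_tree_metrics
    from .qc import MeasurementSchedule, run_qc
    from .simulate import simulate_experiment

    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF
    rows = []
    for r in range(n_reps):
        child = int(child_seeds[r])
        cfg = config.replace(seed=child)
        design = generate_design(child)
        tables = simulate_experiment(design, cfg)
        schedule = MeasurementSchedule.from_config(cfg)
        clean, _ = run_qc(tables["photosynthesis"], schedule)
        met = compute_tree_metrics(
            clean, tables["counts"], tables["spad"], cfg.leaf_removal_1_doy
        )
        frame = met.merge(tables["trees"], on="tree_id")
        frame = frame.rename(
            columns={"leaf_removal_pct": "leaf_pct", "bud_removal_pct": "bud_pct"}
        )

        model_data = frame[frame["doy_50pct_defined"]]
        spec = endpoint_spec("doy_50pct")
        pruned_spec, _ = prune_interactions(spec, model_data, alpha=alpha)
        fit = fit_lmm(pruned_spec, model_data)
        slope = float(fit.params["leaf_pct"])

        is75 = (frame["leaf_pct"] == 75) & (frame["bud_pct"] == 0)
        isctl = (frame["leaf_pct"] == 0) & (frame["bud_pct"] == 0)
        m75 = frame.loc[is75, "total_autumn_photo"].mean()
        mctl = frame.loc[isctl, "total_autumn_photo"].mean()
        photo_pct = 100.0 * (m75 / mctl - 1.0)

        covered = np.nan
        if n_boot > 0:
            ci = bootstrap_ci(fit, n_sim=n_boot, seed=child)
            b = ci.attrs["param_draws"]["leaf_pct"]
            half = 1.96 * float(b.std(ddof=1))
            covered = float(
                slope - half <= config.true_senescence_delay_per_pct <= slope + half
            )
        rows.append(
            (r, child, slope, 75.0 * slope, photo_pct,
             int((~frame["doy_50pct_defined"]).sum()), covered)
        )

    reps = pd.DataFrame(
        rows,
        columns=["rep", "seed", "leaf_slope", "delay_75pct", "photo_effect_pct",
                 "n_undefined", "slope_ci_covers_truth"],
    )

    def summarize(col: str, truth: float) -> dict:
        v = reps[col].to_numpy()
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "mc_se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "truth": truth,
            "bias": float(v.mean() - truth),
        }

    out = {
        "replicates": reps,
        "leaf_slope": summarize("leaf_slope", config.true_senescence_delay_per_pct),
        "delay_75pct": summarize("delay_75pct", 75.0 * config.true_senescence_delay_per_pct),
        "photo_effect_pct": summarize("photo_effect_pct", config.true_photo_effect_pct),
    }
    if n_boot > 0:
        out["slope_ci_coverage"] = float(reps["slope_ci_covers_truth"].mean())
    return out
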