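"""Estimators of monitoring targets under missing data.

Five routes to the landscape mean abundance are implemented, mirroring the
strategies commonly compared for covariate-driven sampling gaps:

``naive``
    intercept-only Poisson GLM on the observed units — correct only under
    MCAR.
``subsampled``
    balanced subsampling (k units per covariate stratum) followed by the
    naive estimator, equalizing the covariate distribution at the cost of
    throwing data away.
``weighted_glm``
    Hájek-type inverse-probability weighting: an intercept-only Poisson GLM
    with weights 1/pi and a sandwich (model-robust) variance.
``poststrat``
    post-stratification to known population stratum sizes, renormalized
    over the strata actually observed.
``impute``
    Bayesian posterior-predictive imputation: a Poisson regression on the
    available covariate fitted by random-walk Metropolis, missing cells
    filled per posterior draw, and the finite-population mean summarized
    across draws.

A Poisson trend model with site fixed effects estimates the mean
log-linear trend of a multi-year panel.  Every estimator returns an
:class:`~biogaps.datatypes.Estimate` with a 95% interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceData, Estimate, Landscape, Mask, PropensityFit
from .exceptions import (
    EstimationError,
    InvalidDesignError,
    SamplerError,
    SubsamplingError,
    WeightingError,
)
from .glm import fit_logistic, fit_poisson

__all__ = [
    "estimate_naive",
    "fit_sampling_model",
    "estimate_ipw",
    "estimate_poststrat",
    "subsample_balanced",
    "MCMCSettings",
    "estimate_impute_bayes",
    "estimate_trend",
]

_Z95 = 1.959963984540054


def _wald_log_estimate(method: str, coef: float, var: float, n_used: int,
                       warnings: list[str] | None = None,
                       extras: dict | None = None) -> Estimate:
    se_log = float(np.sqrt(var))
    point = float(np.exp(coef))
    return Estimate(
        method=method,
        target="landscape_mean_abundance",
        point=point,
        se=point * se_log,  # delta method on the natural scale
        ci_low=float(np.exp(coef - _Z95 * se_log)),
        ci_high=float(np.exp(coef + _Z95 * se_log)),
        n_used=n_used,
        warnings=warnings or [],
        extras=extras or {},
    )


def estimate_naive(observed: AbundanceData, method: str = "naive") -> Estimate:
    """Mean abundance from the observed units only (intercept-only GLM).

    The point estimate is the plain sample mean (the Poisson MLE); the 95%
    Wald interval is formed on the log scale and back-transformed.
    """
    y = observed.counts
    if len(y) == 0:
        raise EstimationError("cannot estimate from zero observed units")
    X = np.ones((len(y), 1))
    fit = fit_poisson(y, X)
    return _wald_log_estimate(method, float(fit.params[0]), float(fit.cov[0, 0]),
                              n_used=len(y), warnings=list(fit.warnings))


def fit_sampling_model(
    mask: Mask,
    covariates: pd.DataFrame,
    floor: float = 0.01,
    ridge: float = 1e-4,
) -> PropensityFit:
    """Estimate inclusion probabilities from inclusion status of ALL units.

    Logistic regression of the inclusion indicator on the covariates
    (which must be available for sampled and unsampled units alike).
    Fitted probabilities are floored at ``floor`` before any inversion into
    weights, with a warning when flooring occurs.  Complete separation
    triggers a ridge-penalized refit and a separation flag.
    """
    y = mask.included.astype(float)
    X = covariates.reindex(y.index).astype(float)
    if X.isna().any().any():
        raise EstimationError("covariates missing for some units")
    Xc = np.column_stack([np.ones(len(y)), X.to_numpy()])
    warnings: list[str] = []
    fit = fit_logistic(y.to_numpy(), Xc)
    separation = (not fit.converged) or np.max(np.abs(fit.params)) > 15
    if separation:
        fit = fit_logistic(y.to_numpy(), Xc, ridge=ridge)
        warnings.append("separation_ridge_refit")
    pi_hat = np.clip(fit.fitted, None, 1.0)
    if np.any(pi_hat < floor):
        warnings.append("pi_hat_floored")
    pi_hat = np.maximum(pi_hat, floor)
    return PropensityFit(
        pi_hat=pd.Series(pi_hat, index=y.index, name="pi_hat"),
        coefficients=fit.params,
        converged=fit.converged,
        separation=separation,
        warnings=warnings,
    )


def estimate_ipw(
    observed: AbundanceData,
    pi_hat,
    truncate_quantile: float | None = None,
    method: str = "weighted_glm",
) -> Estimate:
    """Hájek inverse-probability-weighted mean with sandwich variance.

    ``pi_hat`` is aligned to the observed units (a Series indexed by the
    unit key, or an array in row order).  The point estimate solves the
    weighted Poisson score equation, i.e. equals sum(w y) / sum(w) with
    w = 1/pi; the sandwich covariance accounts for the weighting.
    """
    y = observed.counts
    if len(y) == 0:
        raise EstimationError("cannot estimate from zero observed units")
    if isinstance(pi_hat, pd.Series):
        pi = pi_hat.reindex(observed.unit_index()).to_numpy(dtype=float)
        if np.any(~np.isfinite(pi)):
            raise WeightingError("pi_hat missing for some observed units")
    else:
        pi = np.asarray(pi_hat, dtype=float)
        if len(pi) != len(y):
            raise WeightingError("pi_hat length does not match observed units")
    if np.any(pi <= 0):
        raise WeightingError("inclusion probabilities must be positive")
    w = 1.0 / pi
    warnings: list[str] = []
    if truncate_quantile is not None:
        cap = float(np.quantile(w, truncate_quantile))
        if np.any(w > cap):
            warnings.append("weights_truncated")
        w = np.minimum(w, cap)
    X = np.ones((len(y), 1))
    fit = fit_poisson(y, X, weights=w, variance="sandwich")
    extras = {"max_weight": float(w.max()), "sum_weights": float(w.sum())}
    return _wald_log_estimate(method, float(fit.params[0]), float(fit.cov[0, 0]),
                              n_used=len(y), warnings=warnings + list(fit.warnings),
                              extras=extras)


def estimate_poststrat(
    observed: AbundanceData,
    strata,
    population_sizes,
    method: str = "poststrat",
) -> Estimate:
    """Post-stratified mean with renormalization over observed strata.

    ``strata`` labels each observed unit; ``population_sizes`` maps every
    population stratum to its size N_h.  The point estimate is
    sum_h N_h ybar_h / sum_h N_h over the observed strata; population
    strata with no observations are listed in the warnings (renormalization
    is exactly the failure mode that biases the estimate when the sample
    misses part of the covariate range).  Variance uses the stratified-
    sampling formula sum_h Nshare_h^2 s_h^2 / n_h with singleton strata
    collapsed into the nearest (by stratum order) non-singleton stratum for
    the variance only.
    """
    y = observed.counts
    if len(y) == 0:
        raise EstimationError("cannot estimate from zero observed units")
    s = pd.Series(np.asarray(strata), name="stratum")
    if len(s) != len(y):
        raise EstimationError("stratum labels must match observed units")
    pop = pd.Series(population_sizes, dtype=float).sort_index()
    obs = pd.DataFrame({"y": y, "stratum": s.to_numpy()})
    bad = set(obs["stratum"]) - set(pop.index)
    if bad:
        raise EstimationError(f"observed strata {sorted(bad)} not in population table")

    grp = obs.groupby("stratum")["y"]
    means = grp.mean()
    sizes = grp.size()
    observed_strata = means.index
    warnings: list[str] = []
    empty = [h for h in pop.index if h not in set(observed_strata)]
    if empty:
        warnings.append("unrepresented_strata:" + ",".join(str(h) for h in empty))

    n_obs_pop = pop.loc[observed_strata]
    shares = n_obs_pop / n_obs_pop.sum()
    point = float((shares * means).sum())

    # variance: collapse singleton strata into the nearest non-singleton one
    order = list(observed_strata)
    non_single = [h for h in order if sizes[h] > 1]
    groups: dict[object, list[object]] = {}
    if not non_single:
        warnings.append("all_strata_singletons_pooled_variance")
        groups["__pooled__"] = order
    else:
        pos = {h: i for i, h in enumerate(order)}
        for h in order:
            if sizes[h] > 1:
                groups.setdefault(h, []).insert(0, h)
        for h in order:
            if sizes[h] == 1:
                host = min(non_single, key=lambda g: abs(pos[g] - pos[h]))
                groups[host].append(h)
                warnings.append(f"singleton_stratum_collapsed:{h}->{host}")
    var = 0.0
    for members in groups.values():
        sel = obs["stratum"].isin(members)
        yy = obs.loc[sel, "y"].to_numpy()
        share = float(shares.loc[[m for m in members]].sum())
        if len(yy) > 1:
            var += share**2 * yy.var(ddof=1) / len(yy)
        # a pooled group of size 1 (single observation overall) contributes
        # no estimable variance; the SE is then reported as 0 with warning
        elif len(yy) == 1:
            warnings.append("variance_inestimable_single_observation")
    se = float(np.sqrt(var))
    return Estimate(
        method=method,
        target="landscape_mean_abundance",
        point=point,
        se=se,
        ci_low=point - _Z95 * se,
        ci_high=point + _Z95 * se,
        n_used=len(y),
        warnings=warnings,
        extras={"n_observed_strata": int(len(observed_strata)),
                "n_empty_strata": len(empty)},
    )


def subsample_balanced(
    observed: AbundanceData,
    strata,
    k: int = 1,
    seed: int = 0,
) -> AbundanceData:
    """Draw min(k, n_h) units uniformly without replacement per stratum.

    The downstream estimate is :func:`estimate_naive` on the result with
    method label ``subsampled``.  Equalizing the per-stratum sample sizes
    flattens the covariate distribution of the sample — the subsampling
    route to representativeness.
    """
    if k < 1:
        raise SubsamplingError(f"k must be >= 1, got {k}")
    if len(observed.table) == 0:
        raise SubsamplingError("cannot subsample an empty dataset")
    s = np.asarray(strata)
    if len(s) != len(observed.table):
        raise SubsamplingError("stratum labels must match observed units")
    rng = np.random.default_rng(seed)
    take: list[int] = []
    for h in pd.unique(s):
        rows = np.flatnonzero(s == h)
        chosen = rng.choice(rows, size=min(k, len(rows)), replace=False)
        take.extend(chosen.tolist())
    take = sorted(take)
    table = observed.table.iloc[take].reset_index(drop=True)
    meta = dict(observed.meta)
    meta.update({"subsampled": True, "subsample_k": k, "subsample_seed": seed})
    return AbundanceData(table=table, unit_cols=observed.unit_cols, meta=meta)


@dataclass
class MCMCSettings:
    """Random-walk Metropolis settings for the Bayesian imputer."""

    n_iter: int = 4000
    n_burn: int = 2000
    n_chains: int = 2
    step_a: float = 0.1
    step_b: float = 0.1
    adapt_every: int = 50
    target_accept: tuple[float, float] = (0.20, 0.45)


def _run_chain(rng, sy, sxy, u_obs, m_obs, prior_sd, settings):
    """One adaptive RW-Metropolis chain on (a, b); returns draws + accept rate.

    The Poisson-regression log posterior only needs the sufficient
    statistics sum(y), sum(x y) and the per-unique-covariate-value counts,
    so each iteration costs O(#unique values).
    """
    inv2v = 1.0 / (2.0 * prior_sd**2)

    def logpost(a, b):
        lin = a + b * u_obs
        if np.any(lin > 600):
            return -np.inf
        return a * sy + b * sxy - float(m_obs @ np.exp(lin)) - inv2v * (a * a + b * b)

    a = float(np.log(max(sy / m_obs.sum(), 1e-3)))
    b = 0.0
    lp = logpost(a, b)
    sa, sb = settings.step_a, settings.step_b
    lo, hi = settings.target_accept
    draws = np.empty((settings.n_iter - settings.n_burn, 2))
    acc_window = 0
    acc_post = 0
    for it in range(settings.n_iter):
        prop_a = a + sa * rng.standard_normal()
        prop_b = b + sb * rng.standard_normal()
        lp_prop = logpost(prop_a, prop_b)
        if np.log(rng.random()) < lp_prop - lp:
            a, b, lp = prop_a, prop_b, lp_prop
            acc_window += 1
            if it >= settings.n_burn:
                acc_post += 1
        if it < settings.n_burn and (it + 1) % settings.adapt_every == 0:
            rate = acc_window / settings.adapt_every
            if rate < lo:
                sa *= 0.7
                sb *= 0.7
            elif rate > hi:
                sa *= 1.4
                sb *= 1.4
            acc_window = 0
        elif (it + 1) % settings.adapt_every == 0:
            acc_window = 0
        if it >= settings.n_burn:
            draws[it - settings.n_burn] = (a, b)
    accept_rate = acc_post / max(settings.n_iter - settings.n_burn, 1)
    return draws, accept_rate


def estimate_impute_bayes(
    observed: AbundanceData,
    landscape: Landscape,
    covariate: str = "x_proxy",
    prior_sd: float = 10.0,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    method: str = "impute",
) -> Estimate:
    """Bayesian posterior-predictive imputation of unsampled cells.

    Fits count ~ Poisson(exp(a + b * covariate)) to the observed cells by
    random-walk Metropolis with Normal(0, prior_sd^2) priors on (a, b);
    per retained draw, each unsampled cell receives a Poisson
    posterior-predictive count and the finite-population mean
    (sum of observed + imputed counts) / n_cells is recorded.  The point
    estimate is the posterior mean of that quantity and the interval its
    2.5/97.5 percentiles.  ``extras`` carries the split-chain potential-
    scale-reduction statistic (warning above 1.1), acceptance rates, and
    posterior summaries of (a, b).
    """
    import arviz as az

    mcmc = mcmc or MCMCSettings()
    if len(observed.table) == 0:
        raise EstimationError("cannot impute from zero observed units")
    if covariate not in landscape.table.columns:
        raise EstimationError(f"landscape lacks covariate {covariate!r}")
    land = landscape.table
    obs_ids = set(observed.table["cell_id"])
    obs_x = observed.table[covariate].to_numpy(dtype=float)
    y = observed.counts.astype(float)
    unsampled = land.loc[~land["cell_id"].isin(obs_ids)]
    x_mis = unsampled[covariate].to_numpy(dtype=float)
    n_cells = len(land)

    u_obs, inv = np.unique(obs_x, return_inverse=True)
    m_obs = np.bincount(inv, minlength=len(u_obs)).astype(float)
    sy = float(y.sum())
    sxy = float(obs_x @ y)

    ss = np.random.SeedSequence(seed)
    chains = []
    accept_rates = []
    for child in ss.spawn(mcmc.n_chains):
        rng = np.random.default_rng(child)
        draws, acc = _run_chain(rng, sy, sxy, u_obs, m_obs, prior_sd, mcmc)
        chains.append(draws)
        accept_rates.append(acc)
    if max(accept_rates) == 0.0:
        raise SamplerError("zero Metropolis acceptance after adaptation")

    arr = np.stack(chains)  # (chains, draws, 2)
    rhat_a = float(az.rhat(arr[:, :, 0]))
    rhat_b = float(az.rhat(arr[:, :, 1]))
    ess_a = float(az.ess(arr[:, :, 0]))
    warnings = []
    if max(rhat_a, rhat_b) > 1.1:
        warnings.append("rhat_above_1.1")

    all_draws = arr.reshape(-1, 2)
    a_d, b_d = all_draws[:, 0], all_draws[:, 1]
    pred_rng = np.random.default_rng(ss.spawn(1)[0])
    if len(x_mis):
        u_mis, inv_m = np.unique(x_mis, return_inverse=True)
        c_mis = np.bincount(inv_m, minlength=len(u_mis)).astype(float)
        # total of independent Poisson cells == one Poisson at the summed rate
        lam_tot = np.exp(a_d[:, None] + np.outer(b_d, u_mis)) @ c_mis
        imputed_tot = pred_rng.poisson(lam_tot)
        targets = (sy + imputed_tot) / n_cells
    else:
        targets = np.full(len(all_draws), sy / n_cells)

    point = float(targets.mean())
    lo_q, hi_q = np.percentile(targets, [2.5, 97.5])
    extras = {
        "rhat_a": rhat_a,
        "rhat_b": rhat_b,
        "ess_a": ess_a,
        "accept_rates": accept_rates,
        "a_mean": float(a_d.mean()),
        "a_ci": (float(np.percentile(a_d, 2.5)), float(np.percentile(a_d, 97.5))),
        "b_mean": float(b_d.mean()),
        "b_ci": (float(np.percentile(b_d, 2.5)), float(np.percentile(b_d, 97.5))),
        "n_imputed_cells": int(len(x_mis)),
    }
    return Estimate(
        method=method,
        target="landscape_mean_abundance",
        point=point,
        se=float(targets.std(ddof=1)) if len(x_mis) else 0.0,
        ci_low=float(lo_q),
        ci_high=float(hi_q),
        n_used=len(y),
        warnings=warnings,
        extras=extras,
    )


def estimate_trend(
    panel: AbundanceData,
    year_as_factor: bool = False,
    method: str = "trend_glm",
) -> Estimate:
    """Mean log-linear trend from a (possibly gappy) site x year panel.

    Poisson GLM of count on centered continuous year plus one indicator
    per site (site fixed effects; both fixed and random intercepts
    condition on site, which is what the bias argument requires).  The
    point estimate is the year coefficient in log-units per year with a
    95% Wald interval.  Sites observed in a single year still contribute
    to their own intercept but carry no trend information; they are
    flagged.  With ``year_as_factor`` the year effects are estimated
    freely and the returned slope is the OLS slope through them.
    """
    t = panel.table
    if len(t) == 0:
        raise EstimationError("cannot estimate a trend from zero observations")
    years = np.sort(t["year"].unique())
    if len(years) < 2:
        raise InvalidDesignError("trend estimation needs >= 2 distinct years")
    warnings: list[str] = []
    per_site_years = t.groupby("site_id")["year"].nunique()
    single = per_site_years[per_site_years == 1]
    if len(single):
        warnings.append(f"single_year_sites:{len(single)}")

    site_d = pd.get_dummies(t["site_id"], dtype=float).to_numpy()
    y = t["count"].to_numpy(dtype=float)
    yr = t["year"].to_numpy(dtype=float)
    yr_c = yr - yr.mean()

    if not year_as_factor:
        X = np.column_stack([yr_c, site_d])
        fit = fit_poisson(y, X)
        coef = float(fit.params[0])
        var = float(fit.cov[0, 0])
    else:
        # free year effects (first year as reference), slope via OLS through them
        yd = pd.get_dummies(t["year"], dtype=float)
        yd = yd.iloc[:, 1:]  # drop reference year
        X = np.column_stack([yd.to_numpy(), site_d])
        fit = fit_poisson(y, X)
        eff = np.concatenate([[0.0], fit.params[: yd.shape[1]]])
        xs = years - years.mean()
        denom = float(xs @ xs)
        wvec = xs / denom
        coef = float(wvec @ eff)
        var = float(wvec[1:] @ fit.cov[: yd.shape[1], : yd.shape[1]] @ wvec[1:])
        warnings.append("year_as_factor_ols_slope")

    se = float(np.sqrt(var))
    return Estimate(
        method=method,
        target="trend_slope",
        point=coef,
        se=se,
        ci_low=coef - _Z95 * se,
        ci_high=coef + _Z95 * se,
        n_used=len(y),
        warnings=warnings + list(fit.warnings),
        extras={"n_sites": int(t["site_id"].nunique()), "n_years": int(len(years))},
    )
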