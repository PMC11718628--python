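"""Monte-Carlo experiment harness.

Composes the generator, missingness mechanisms and estimators into the
four simulation designs the package exists to study:

``fig5``
    landscape mean abundance: 400 cells, one covariate driving both
    abundance and (logistically) sampling probability; five estimators
    compared on mean bias, interval width and coverage, sweeping the
    sampling fraction at fixed proxy correlation and vice versa.
``fig3``
    mean population trend from a 50-site multi-year panel, MCAR versus
    MNAR annual gaps (retention increasing in the same site covariate that
    drives the trends, so stable/increasing sites are under-sampled).
``fig2``
    the covariate-effect slope itself: threshold and linear missingness
    along the covariate, linear versus quadratic truth, comparing the
    slope fitted to the full versus the masked data.
``figS1``
    the fig5 design plus an extra abundance covariate the imputation
    model does not know about.

Within a run every estimator is scored against the same realized
landscape quantity (finite-population truth), so a census estimator has
bias exactly zero; the expectation-based truth is available as a switch.
Per-run seeds are derived from the master seed by a counter scheme so
runs are independent and individually replayable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .datatypes import AbundanceData, Estimate, TrendPanelSpec, standardize
from .estimators import (
    MCMCSettings,
    estimate_impute_bayes,
    estimate_ipw,
    estimate_naive,
    estimate_poststrat,
    estimate_trend,
    fit_sampling_model,
    subsample_balanced,
)
from .exceptions import ConfigError
from .glm import fit_poisson
from .missingness import apply_mask, draw_mask, inclusion_probs
from .simulate import (
    attach_covariate,
    attach_proxy,
    make_landscape,
    simulate_counts,
    simulate_trend_panel,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_fig2",
    "run_fig3",
    "run_fig5",
    "run_figS1",
    "run_scenario",
    "summarize",
    "FIG5_METHODS",
]

SCENARIOS = ("fig2", "fig3", "fig5", "figS1")
FIG5_METHODS = ("naive", "subsampled", "weighted_glm", "poststrat", "impute")
CORRECTING_METHODS = ("subsampled", "weighted_glm", "poststrat", "impute")


@dataclass
class ExperimentConfig:
    """All knobs of the four scenarios; defaults mirror the study designs."""

    scenario: str = "fig5"
    n_runs: int = 100
    seed: int = 1
    # landscape generator
    n_cells: int = 400
    n_levels: int = 20
    alpha: float = 1.0
    beta: float = 0.8
    # missingness
    mechanism: str = "logistic"
    sampling_slope: float = 2.0
    fraction: float = 0.35
    rho: float = 0.75
    fractions: tuple = (0.15, 0.25, 0.35, 0.5, 0.75)
    rhos: tuple = (0.25, 0.5, 0.75, 1.0)
    sweep: str = "both"  # "fraction", "rho", "both", or "fixed"
    # estimator switches; weight_mode: "design_proxy" inverts the known
    # mechanism probabilities evaluated at the available (proxy) covariate,
    # "estimated" fits a propensity model to inclusion status, "true" uses
    # the generating probabilities themselves (pure design weights)
    weight_mode: str = "design_proxy"
    subsample_k: int = 1
    truth: str = "realized"  # or "expected"
    mcmc_iter: int = 2000
    mcmc_burn: int = 1000
    mcmc_chains: int = 2
    # fig3 panel
    n_sites: int = 50
    n_years: int = 15
    a0: float = 2.0
    a_sd: float = 0.3
    b0: float = 0.02
    b1: float = -0.10
    retention: float = 0.5
    mnar_slope: float = 2.0
    # fig2
    beta2: float = -0.5
    linear_slope: float = -0.7
    # figS1
    extra_effect: float = 0.5

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        for f in (self.fraction, *self.fractions, self.retention):
            if not 0.0 < f <= 1.0:
                raise ConfigError(f"sampling fraction {f} outside (0, 1]")
        for r in (self.rho, *self.rhos):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"proxy correlation {r} outside [0, 1]")
        if self.truth not in ("realized", "expected"):
            raise ConfigError("truth must be 'realized' or 'expected'")
        if self.weight_mode not in ("design_proxy", "estimated", "true"):
            raise ConfigError(
                "weight_mode must be 'design_proxy', 'estimated' or 'true'"
            )

    def mcmc_settings(self) -> MCMCSettings:
        return MCMCSettings(
            n_iter=self.mcmc_iter, n_burn=self.mcmc_burn, n_chains=self.mcmc_chains
        )


@dataclass
class ExperimentResult:
    """Tidy per-(setting, method) summary of a Monte-Carlo sweep."""

    table: pd.DataFrame
    config: ExperimentConfig
    per_run: Optional[pd.DataFrame] = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def sidecar(self) -> dict:
        from . import __version__

        return {
            "config": asdict(self.config),
            "master_seed": self.config.seed,
            "package_version": __version__,
        }


def _run_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-run seeds (< 2^31) derived from the master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31, size=n)


def _aggregate(rows: list[dict], keys: list[str]) -> pd.DataFrame:
    """Per-(setting, method) mean bias, MC SE, CI width, coverage, failures."""
    df = pd.DataFrame(rows)
    out = []
    for gkey, g in df.groupby(keys, dropna=False, sort=True):
        ok = g[g["ok"]]
        n_ok = len(ok)
        rec = dict(zip(keys, gkey if isinstance(gkey, tuple) else (gkey,)))
        rec.update(
            {
                "mean_bias": ok["bias"].mean() if n_ok else np.nan,
                "mc_se_bias": (
                    ok["bias"].std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan
                ),
                "mean_ci_width": ok["ci_width"].mean() if n_ok else np.nan,
                "coverage": ok["covered"].mean() if n_ok else np.nan,
                "n_runs": int(len(g)),
                "failures": int((~g["ok"]).sum()),
            }
        )
        if "unrepresented" in g.columns:
            rec["unrepresented_rate"] = (
                ok["unrepresented"].astype(float).mean() if n_ok else np.nan
            )
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fig5: landscape mean abundance
# ---------------------------------------------------------------------------

def fig5_single_run(
    config: ExperimentConfig,
    fraction: float,
    rho: float,
    seed: int,
    extra_effect: float = 0.0,
    methods: tuple = FIG5_METHODS,
) -> tuple[dict[str, Estimate | None], float]:
    """One replicate of the landscape design; returns estimates and truth.

    The same covariate drives abundance (log-linearly, coefficient beta)
    and inclusion (per ``config.mechanism``); the analyst only sees the
    proxy at correlation ``rho``.  Estimator failures are returned as None
    entries, never raised.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31, size=6)]
    land = make_landscape(config.n_cells, config.n_levels, seed=sub[0])
    land = attach_proxy(land, rho, seed=sub[1])
    extra = {}
    if extra_effect != 0.0:
        land = attach_covariate(land, "z_extra", seed=sub[2])
        extra = {"z_extra": extra_effect}
    dense = simulate_counts(land, config.alpha, config.beta, extra_effects=extra,
                            seed=sub[3])

    x_true = dense.table.set_index("cell_id")["x_true"]
    if config.mechanism == "preferential":
        driver = pd.Series(
            standardize(np.log(dense.table["lambda"].to_numpy())),
            index=x_true.index,
        )
    else:
        driver = x_true
    design = inclusion_probs(
        driver,
        config.mechanism,
        {"slope": config.sampling_slope},
        target_fraction=fraction,
        covariate_name="x_true",
    )
    mask = draw_mask(design, dimension="spatial", seed=sub[4])
    observed = apply_mask(dense, mask)

    if config.truth == "realized":
        truth = float(dense.table["count"].mean())
    else:
        truth = float(dense.table["lambda"].mean())

    proxy_cov = land.table.set_index("cell_id")[["x_proxy"]]
    pop_sizes = land.table["x_proxy_level"].value_counts().sort_index()

    results: dict[str, Estimate | None] = {}
    for m in methods:
        try:
            if m == "naive":
                results[m] = estimate_naive(observed)
            elif m == "subsampled":
                sub_data = subsample_balanced(
                    observed, observed.table["x_proxy_level"].to_numpy(),
                    k=config.subsample_k, seed=sub[5],
                )
                results[m] = estimate_naive(sub_data, method="subsampled")
            elif m == "weighted_glm":
                if config.weight_mode == "true":
                    pi = design.pi
                elif (config.weight_mode == "design_proxy"
                      and config.mechanism != "preferential"):
                    # known design, imperfect covariate: the mechanism's
                    # probabilities evaluated at the proxy the analyst holds
                    pi = inclusion_probs(
                        land.table.set_index("cell_id")["x_proxy"],
                        config.mechanism, {"slope": config.sampling_slope},
                        target_fraction=fraction, covariate_name="x_proxy",
                    ).pi
                else:
                    pi = fit_sampling_model(mask, proxy_cov).pi_hat
                results[m] = estimate_ipw(observed, pi)
            elif m == "poststrat":
                results[m] = estimate_poststrat(
                    observed, observed.table["x_proxy_level"].to_numpy(), pop_sizes
                )
            elif m == "impute":
                results[m] = estimate_impute_bayes(
                    observed, land, covariate="x_proxy",
                    mcmc=config.mcmc_settings(), seed=sub[5] + 1,
                )
            else:
                raise ConfigError(f"unknown method {m!r}")
        except Exception:
            results[m] = None
    return results, truth


def _sweep_fig5(config: ExperimentConfig, settings: list[tuple[float, float, str]],
                extra_effect: float = 0.0, scenario: str = "fig5") -> pd.DataFrame:
    rows = []
    seeds = _run_seeds(config.seed, config.n_runs * len(settings))
    i = 0
    for fraction, rho, sweep_label in settings:
        for _ in range(config.n_runs):
            ests, truth = fig5_single_run(
                config, fraction, rho, int(seeds[i]), extra_effect=extra_effect
            )
            i += 1
            for m, est in ests.items():
                if est is None:
                    rows.append(
                        dict(scenario=scenario, sweep=sweep_label, fraction=fraction,
                             rho=rho, extra_effect=extra_effect, method=m, ok=False,
                             bias=np.nan, ci_width=np.nan, covered=np.nan)
                    )
                else:
                    rows.append(
                        dict(scenario=scenario, sweep=sweep_label, fraction=fraction,
                             rho=rho, extra_effect=extra_effect, method=m, ok=True,
                             bias=est.point - truth, ci_width=est.ci_width,
                             covered=est.covers(truth),
                             warned=bool(est.warnings),
                             unrepresented=any(
                                 w.startswith("unrepresented_strata")
                                 for w in est.warnings))
                    )
    return pd.DataFrame(rows)


def run_fig5(config: ExperimentConfig) -> ExperimentResult:
    """Sweep sampling fraction (at fixed rho) and proxy quality (at fixed
    fraction) for the five landscape estimators."""
    settings: list[tuple[float, float, str]] = []
    if config.sweep in ("fraction", "both"):
        settings += [(f, config.rho, "fraction") for f in config.fractions]
    if config.sweep in ("rho", "both"):
        settings += [(config.fraction, r, "rho") for r in config.rhos]
    if config.sweep == "fixed" or not settings:
        settings = [(config.fraction, config.rho, "fixed")]
    per_run = _sweep_fig5(config, settings)
    keys = ["scenario", "sweep", "fraction", "rho", "method"]
    table = _aggregate(per_run.to_dict("records"), keys)
    return ExperimentResult(table=table, config=config, per_run=per_run)


# ---------------------------------------------------------------------------
# fig3: trend bias
# ---------------------------------------------------------------------------

def fig3_single_run(config: ExperimentConfig, seed: int) -> dict[str, float | None]:
    """One replicate: dense trend estimate vs MCAR- and MNAR-masked ones."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31, size=3)]
    spec = TrendPanelSpec(
        n_sites=config.n_sites, n_years=config.n_years,
        a0=config.a0, a_sd=config.a_sd, b0=config.b0, b1=config.b1,
    )
    panel = simulate_trend_panel(spec, seed=sub[0])
    dense_est = estimate_trend(panel)

    site_year = pd.MultiIndex.from_frame(panel.table[["site_id", "year"]])
    u_sy = pd.Series(standardize(panel.table["u"].to_numpy()), index=site_year)

    out: dict[str, float | None] = {"dense": dense_est.point}
    arms = {
        "mcar": inclusion_probs(u_sy, "constant", {}, config.retention, "u"),
        "mnar": inclusion_probs(
            u_sy, "logistic", {"slope": config.mnar_slope}, config.retention, "u"
        ),
    }
    for arm, design in arms.items():
        mask = draw_mask(design, dimension="annual", seed=sub[1] + (arm == "mnar"))
        try:
            obs = apply_mask(panel, mask)
            est = estimate_trend(obs)
            out[arm] = est.point
            out[arm + "_ciw"] = est.ci_width
            out[arm + "_covered"] = est.covers(dense_est.point)
        except Exception:
            out[arm] = None
    return out


def run_fig3(config: ExperimentConfig) -> ExperimentResult:
    """MCAR vs MNAR annual gaps in a multi-year panel; bias of the mean
    trend relative to the dense-panel estimate."""
    rows = []
    seeds = _run_seeds(config.seed, config.n_runs)
    for s in seeds:
        r = fig3_single_run(config, int(s))
        for arm in ("mcar", "mnar"):
            ok = r[arm] is not None
            rows.append(
                dict(scenario="fig3", sweep="mechanism", setting=arm,
                     method="trend_glm", ok=ok,
                     bias=(r[arm] - r["dense"]) if ok else np.nan,
                     ci_width=r.get(arm + "_ciw", np.nan) if ok else np.nan,
                     covered=r.get(arm + "_covered", np.nan) if ok else np.nan)
            )
    table = _aggregate(rows, ["scenario", "setting", "method"])
    return ExperimentResult(table=table, config=config,
                            per_run=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fig2: covariate-effect slope under truncation
# ---------------------------------------------------------------------------

FIG2_ARMS = ("linear_threshold_high", "linear_threshold_low",
             "linear_linear", "quadratic_threshold_high")


def _fit_slope(data: AbundanceData) -> float:
    t = data.table
    X = np.column_stack([np.ones(len(t)), t["x_true"].to_numpy()])
    fit = fit_poisson(t["count"].to_numpy(dtype=float), X)
    return float(fit.params[1])


def fig2_single_run(config: ExperimentConfig, arm: str, seed: int) -> float | None:
    """Slope difference (masked minus full fit) for one replicate of an arm.

    The quadratic arm generates curvature (beta2 < 0 on the standardized
    squared covariate) but the analyst still fits a linear-term-only model
    — the misspecification that makes covariate-range truncation bite.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31, size=3)]
    land = make_landscape(config.n_cells, config.n_levels, seed=sub[0])
    extra = {}
    if arm.startswith("quadratic"):
        land = attach_covariate(
            land, "x_sq", values=land.table["x_true"].to_numpy() ** 2
        )
        extra = {"x_sq": config.beta2}
    dense = simulate_counts(land, config.alpha, config.beta, extra_effects=extra,
                            seed=sub[1])
    x = dense.table.set_index("cell_id")["x_true"]
    if arm.endswith("threshold_high"):
        design = inclusion_probs(x, "threshold_high", {}, config.fraction, "x_true")
    elif arm.endswith("threshold_low"):
        design = inclusion_probs(x, "threshold_low", {}, config.fraction, "x_true")
    else:
        design = inclusion_probs(
            x, "linear", {"slope": config.linear_slope}, config.fraction, "x_true"
        )
    mask = draw_mask(design, dimension="spatial", seed=sub[2])
    observed = apply_mask(dense, mask)
    try:
        return _fit_slope(observed) - _fit_slope(dense)
    except Exception:
        return None


def run_fig2(config: ExperimentConfig) -> ExperimentResult:
    """Full-vs-masked covariate slope under threshold / linear missingness,
    linear and (misspecified) quadratic truth."""
    rows = []
    seeds = _run_seeds(config.seed, config.n_runs * len(FIG2_ARMS))
    i = 0
    for arm in FIG2_ARMS:
        for _ in range(config.n_runs):
            d = fig2_single_run(config, arm, int(seeds[i]))
            i += 1
            rows.append(
                dict(scenario="fig2", setting=arm, method="poisson_slope",
                     ok=d is not None, bias=d if d is not None else np.nan,
                     ci_width=np.nan, covered=np.nan)
            )
    table = _aggregate(rows, ["scenario", "setting", "method"])
    return ExperimentResult(table=table, config=config, per_run=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# figS1: unmodelled extra covariate
# ---------------------------------------------------------------------------

def run_figS1(config: ExperimentConfig) -> ExperimentResult:
    """fig5 design with an extra abundance covariate omitted from the
    imputation model; compares estimator performance with and without it."""
    settings = [(config.fraction, config.rho, "extra")]
    frames = []
    for delta in (0.0, config.extra_effect):
        per = _sweep_fig5(config, settings, extra_effect=delta, scenario="figS1")
        frames.append(per)
    per_run = pd.concat(frames, ignore_index=True)
    keys = ["scenario", "extra_effect", "fraction", "rho", "method"]
    table = _aggregate(per_run.to_dict("records"), keys)
    return ExperimentResult(table=table, config=config, per_run=per_run)


def run_scenario(config: ExperimentConfig) -> ExperimentResult:
    runner: dict[str, Callable[[ExperimentConfig], ExperimentResult]] = {
        "fig2": run_fig2,
        "fig3": run_fig3,
        "fig5": run_fig5,
        "figS1": run_figS1,
    }
    return runner[config.scenario](config)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(result: ExperimentResult) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Rank methods per setting and evaluate the headline orderings.

    Rankings are by |mean bias| and by mean CI width.  The flags report,
    at the fixed default setting when present (otherwise over all
    settings), whether (i) weighting has the smallest |mean bias| of all
    methods, (ii) subsampling the largest |mean bias| among the correcting
    methods, and (iii) subsampling the widest mean interval.
    """
    df = result.table.copy()
    if df.empty:
        raise ValueError("cannot summarize an empty result")
    setting_cols = [c for c in df.columns
                    if c not in ("method", "mean_bias", "mc_se_bias",
                                 "mean_ci_width", "coverage", "n_runs", "failures")]
    df["abs_bias"] = df["mean_bias"].abs()
    df["bias_rank"] = df.groupby(setting_cols, dropna=False)["abs_bias"].rank(
        method="min"
    )
    df["ci_width_rank"] = df.groupby(setting_cols, dropna=False)[
        "mean_ci_width"
    ].rank(method="min")

    flags: dict[str, bool] = {}
    methods = set(df["method"])
    if set(FIG5_METHODS) <= methods:
        sel = df
        if {"fraction", "rho"} <= set(df.columns):
            fixed = df[(df["fraction"] == result.config.fraction)
                       & (df["rho"] == result.config.rho)]
            if len(fixed):
                sel = fixed
        by_m = sel.groupby("method").agg(
            abs_bias=("abs_bias", "mean"), ciw=("mean_ci_width", "mean")
        )
        corr = by_m.loc[[m for m in CORRECTING_METHODS if m in by_m.index]]
        flags["weighting_best_bias"] = by_m["abs_bias"].idxmin() == "weighted_glm"
        flags["subsampling_worst_correction_bias"] = (
            corr["abs_bias"].idxmax() == "subsampled"
        )
        flags["subsampling_widest_ci"] = by_m["ciw"].idxmax() == "subsampled"
    return df, flags
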