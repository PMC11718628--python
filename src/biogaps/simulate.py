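"""Synthetic ground-truth generators.

The generators emulate the two virtual-ecologist designs used throughout
the package: a single-season landscape whose one cell-varying covariate
(think habitat quality) drives expected abundance log-linearly, and a
multi-year site panel whose site covariate (think urban cover) drives
site-level log-linear trends.  Counts are Poisson everywhere; there is no
spatial autocorrelation, overdispersion or detection error by design —
those are features of real data the simulations deliberately omit.

All randomness flows through ``numpy.random.default_rng(seed)`` so that
identical seeds regenerate bit-identical datasets.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import AbundanceData, Landscape, TrendPanelSpec, standardize
from .exceptions import GenerationError, InvalidDesignError

__all__ = [
    "make_landscape",
    "attach_proxy",
    "attach_covariate",
    "simulate_counts",
    "simulate_trend_panel",
    "simulate_visits",
]


def _level_values(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Standardized value of stratum label k: (k - 0.5)/K, then z-scored.

    With equal-count strata the raw values are an equally spaced grid on
    (0, 1), so the standardization is exact and deterministic.
    """
    raw = (levels - 0.5) / n_levels
    grid = (np.arange(1, n_levels + 1) - 0.5) / n_levels
    return (raw - grid.mean()) / grid.std(ddof=0)


def make_landscape(n_cells: int, n_levels: int, seed: int = 0) -> Landscape:
    """Build a landscape of ``n_cells`` cells in ``n_levels`` equal strata.

    The covariate level of stratum k takes raw value (k - 0.5)/K which is
    standardized into ``x_true``.  The landscape is deterministic given
    (n_cells, n_levels); the seed only shuffles which cell gets which level.
    """
    if n_levels < 2:
        raise InvalidDesignError(f"need at least 2 covariate levels, got {n_levels}")
    if n_cells % n_levels != 0:
        raise InvalidDesignError(
            f"n_levels={n_levels} does not divide n_cells={n_cells}"
        )
    per = n_cells // n_levels
    levels = np.repeat(np.arange(1, n_levels + 1), per)
    rng = np.random.default_rng(seed)
    rng.shuffle(levels)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_level": levels,
            "x_true": _level_values(levels, n_levels),
        }
    )
    return Landscape(table=table, n_levels=n_levels)


def attach_proxy(landscape: Landscape, rho: float, seed: int = 0) -> Landscape:
    """Attach a proxy covariate with target correlation ``rho`` to the truth.

    A latent value ``rho * x_true + sqrt(1 - rho^2) * eps`` (eps standard
    normal per cell) is binned into K equal-count bins, ties broken by
    cell_id; the standardized bin midpoints give ``x_proxy``.  The realized
    Pearson correlation is recorded on the returned landscape — it is
    reported, never forced.  With rho = 1 the proxy levels equal the true
    levels exactly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    out = landscape.copy()
    t = out.table
    n = len(t)
    k = out.n_levels
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    latent = rho * t["x_true"].to_numpy() + np.sqrt(1.0 - rho**2) * eps
    order = np.lexsort((t["cell_id"].to_numpy(), latent))
    proxy_level = np.empty(n, dtype=int)
    proxy_level[order] = np.repeat(np.arange(1, k + 1), n // k)
    t["x_proxy_level"] = proxy_level
    t["x_proxy"] = _level_values(proxy_level, k)
    out.proxy_rho = rho
    out.realized_proxy_corr = float(
        np.corrcoef(t["x_true"], t["x_proxy"])[0, 1]
    )
    return out


def attach_covariate(
    landscape: Landscape,
    name: str,
    values: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> Landscape:
    """Attach an extra standardized covariate column.

    If ``values`` is None, independent standard-normal values are drawn and
    standardized; otherwise the supplied values are standardized as given.
    """
    out = landscape.copy()
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(len(out.table))
    out.table[name] = standardize(values)
    if name not in out.extra_covariates:
        out.extra_covariates.append(name)
    return out


def simulate_counts(
    landscape: Landscape,
    alpha: float,
    beta: float,
    extra_effects: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> AbundanceData:
    """Draw one Poisson count per cell under a log-linear abundance model.

    lambda_i = exp(alpha + beta * x_true_i + sum_j delta_j * z_ij); the
    result is dense over all cells and carries both ``lambda`` and
    ``count`` plus every covariate column of the landscape.
    """
    extra_effects = dict(extra_effects or {})
    t = landscape.table
    eta = alpha + beta * t["x_true"].to_numpy()
    for name, delta in extra_effects.items():
        if name not in t.columns:
            raise GenerationError(f"extra covariate {name!r} not on landscape")
        eta = eta + delta * t[name].to_numpy()
    lam = np.exp(eta)
    if not np.all(np.isfinite(lam)):
        raise GenerationError("non-finite expected abundance; check coefficients")
    rng = np.random.default_rng(seed)
    table = t.copy()
    table["lambda"] = lam
    table["count"] = rng.poisson(lam)
    meta = {
        "kind": "landscape",
        "alpha": alpha,
        "beta": beta,
        "extra_effects": extra_effects,
        "seed": seed,
    }
    return AbundanceData(table=table, unit_cols=("cell_id",), meta=meta)


def simulate_trend_panel(
    spec: TrendPanelSpec | None = None, seed: int = 0
) -> AbundanceData:
    """Simulate a dense site x year count panel with covariate-driven trends.

    Site covariate u_i is equally spaced on [0, 1]; site intercepts are
    Normal(a0, a_sd^2); log lambda_it = a_i + (b0 + b1 u_i)(t - 1); counts
    are Poisson.  Years are labelled 1..n_years.
    """
    spec = spec or TrendPanelSpec()
    if spec.n_years < 2:
        raise InvalidDesignError(f"need at least 2 years, got {spec.n_years}")
    if spec.n_sites < 2:
        raise InvalidDesignError(f"need at least 2 sites, got {spec.n_sites}")
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, spec.n_sites)
    a = spec.a0 + spec.a_sd * rng.standard_normal(spec.n_sites)
    slope = spec.site_slope(u)
    years = np.arange(1, spec.n_years + 1)
    site_id = np.repeat(np.arange(spec.n_sites), spec.n_years)
    year = np.tile(years, spec.n_sites)
    loglam = a[site_id] + slope[site_id] * (year - 1)
    lam = np.exp(loglam)
    table = pd.DataFrame(
        {
            "site_id": site_id,
            "year": year,
            "u": u[site_id],
            "lambda": lam,
            "count": rng.poisson(lam),
        }
    )
    meta = {"kind": "panel", "spec": spec.__dict__.copy(), "seed": seed}
    return AbundanceData(table=table, unit_cols=("site_id", "year"), meta=meta)


def simulate_visits(
    panel: AbundanceData,
    n_visits: int,
    seed: int = 0,
    season: tuple[int, int] = (91, 273),
    weekday_prob: float = 5.0 / 7.0,
) -> AbundanceData:
    """Expand a dense site x year panel to visit-level rows.

    Each site-year becomes ``n_visits`` visit rows with a uniform
    day-of-year over the season window and a Bernoulli weekday flag.  The
    annual expectation is split evenly: each visit has expectation
    lambda_it / n_visits, so visit expectations sum back to lambda_it and
    independent Poisson visit counts sum to a Poisson(lambda_it) annual
    total in distribution.
    """
    if n_visits < 1:
        raise InvalidDesignError(f"need at least 1 visit, got {n_visits}")
    if not panel.is_dense_truth or panel.unit_cols != ("site_id", "year"):
        raise InvalidDesignError("simulate_visits requires a dense site x year panel")
    rng = np.random.default_rng(seed)
    base = panel.table
    rep = base.loc[base.index.repeat(n_visits)].reset_index(drop=True)
    rep["visit"] = np.tile(np.arange(1, n_visits + 1), len(base))
    rep["day_of_year"] = rng.integers(season[0], season[1] + 1, size=len(rep))
    rep["weekday"] = (rng.random(len(rep)) < weekday_prob).astype(int)
    rep["lambda"] = rep["lambda"].to_numpy() / n_visits
    rep["count"] = rng.poisson(rep["lambda"].to_numpy())
    cols = ["site_id", "year", "visit", "u", "day_of_year", "weekday", "lambda", "count"]
    table = rep[[c for c in cols if c in rep.columns]]
    meta = dict(panel.meta)
    meta.update({"kind": "visits", "n_visits": n_visits, "visit_seed": seed})
    return AbundanceData(table=table, unit_cols=("site_id", "year", "visit"), meta=meta)
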