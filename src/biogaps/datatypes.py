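"""Core data containers.

Tabular payloads are plain :class:`pandas.DataFrame` objects wrapped in
light dataclasses that carry the metadata needed for provenance and for
downstream alignment (unit key columns, mechanism parameters, seeds).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Landscape:
    """A single-season landscape of cells.

    ``table`` columns: ``cell_id`` (0-based), ``x_level`` (stratum label
    1..K), ``x_true`` (standardized covariate, mean 0 / sd 1 across cells),
    and after :func:`~biogaps.simulate.attach_proxy` also ``x_proxy_level``
    and ``x_proxy``.  Extra covariates are additional standardized columns
    registered in ``extra_covariates``.
    """

    table: pd.DataFrame
    n_levels: int
    proxy_rho: Optional[float] = None
    realized_proxy_corr: Optional[float] = None
    extra_covariates: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def copy(self) -> "Landscape":
        return Landscape(
            table=self.table.copy(),
            n_levels=self.n_levels,
            proxy_rho=self.proxy_rho,
            realized_proxy_corr=self.realized_proxy_corr,
            extra_covariates=list(self.extra_covariates),
        )


@dataclass
class AbundanceData:
    """Counts (and, for truth tables, expectations) on a unit grid.

    ``unit_cols`` names the key columns: ``("cell_id",)`` for a landscape,
    ``("site_id", "year")`` for a multi-year panel, and
    ``("site_id", "year", "visit")`` for visit-level data.  The dense
    (truth) version carries a ``lambda`` column; observed versions do not.
    """

    table: pd.DataFrame
    unit_cols: tuple[str, ...]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def is_dense_truth(self) -> bool:
        return "lambda" in self.table.columns

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    def unit_index(self) -> pd.Index:
        if len(self.unit_cols) == 1:
            return pd.Index(self.table[self.unit_cols[0]], name=self.unit_cols[0])
        return pd.MultiIndex.from_frame(self.table[list(self.unit_cols)])

    def copy(self) -> "AbundanceData":
        return AbundanceData(self.table.copy(), self.unit_cols, dict(self.meta))


@dataclass
class TrendPanelSpec:
    """Design of a multi-year monitoring panel with covariate-driven trends.

    Site ``i`` has intercept ``a_i ~ Normal(a0, a_sd^2)`` (log scale) and a
    deterministic log-linear trend slope ``b0 + b1 * u_i`` where ``u_i`` is
    the site covariate, equally spaced on [0, 1].  With the defaults the
    slope is non-negative at u=0 and negative at u=1, i.e. populations are
    stable or increasing in low-covariate sites and declining in
    high-covariate sites.
    """

    n_sites: int = 50
    n_years: int = 15
    a0: float = 2.0
    a_sd: float = 0.3
    b0: float = 0.02
    b1: float = -0.10

    def site_slope(self, u: float | np.ndarray) -> float | np.ndarray:
        return self.b0 + self.b1 * np.asarray(u, dtype=float)


@dataclass
class SamplingDesign:
    """Per-unit inclusion probabilities under a named missingness mechanism.

    ``pi`` is a Series indexed by the unit key (``cell_id``, ``site_id`` or
    a (site, year) MultiIndex).  Apart from the threshold mechanisms, whose
    mean is exact by algebra, ``mean(pi)`` equals ``target_fraction`` to
    within the calibration tolerance (1e-6).
    """

    pi: pd.Series
    mechanism: str
    params: dict[str, float]
    covariate_name: str
    target_fraction: float

    @property
    def mean_pi(self) -> float:
        return float(self.pi.mean())


@dataclass
class Mask:
    """A realized Bernoulli draw from a :class:`SamplingDesign`.

    ``dimension`` records which gap type the mask creates: ``spatial``
    (whole sites in or out), ``annual`` (site-years) or ``within_year``
    (visits).  For spatial masks the unit is the site and inclusion is
    broadcast to every record of the site when applied.
    """

    included: pd.Series
    design: SamplingDesign
    dimension: str
    seed: int

    @property
    def realized_fraction(self) -> float:
        return float(self.included.mean())

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass
class Estimate:
    """A point estimate of a monitoring target with a 95% interval."""

    method: str
    target: str  # "landscape_mean_abundance" or "trend_slope"
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int
    warnings: list[str] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def covers(self, truth: float) -> bool:
        return bool(self.ci_low <= truth <= self.ci_high)

    def to_row(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "target": self.target,
            "point": self.point,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_used": self.n_used,
            "warnings": ";".join(self.warnings),
        }


@dataclass
class PropensityFit:
    """Fitted sampling (propensity) model over all units."""

    pi_hat: pd.Series  # in (0, 1], after flooring
    coefficients: np.ndarray
    converged: bool
    separation: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class MissingnessDiagnostics:
    """Report of the (partial) statistical checks on a missingness pattern."""

    coefficients: pd.DataFrame  # index covariate, cols coef/se/z/p
    lrt_stat: float
    lrt_df: int
    lrt_pvalue: float
    separation: bool
    gap_summary: dict[str, float]
    caveat: str

    def rejects(self, level: float = 0.05) -> bool:
        return bool(self.lrt_pvalue < level)


def standardize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Center and scale to population (ddof=0) mean 0 / sd 1."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd
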