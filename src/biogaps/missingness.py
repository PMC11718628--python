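"""Missing-data mechanisms and diagnostics.

Dense truth becomes observed data through a two-step process: a
:class:`~biogaps.datatypes.SamplingDesign` assigns every unit an inclusion
probability pi under a named mechanism, and a :class:`Mask` realizes an
independent Bernoulli draw from those probabilities.  Mechanisms cover the
MCAR/MAR/MNAR taxonomy:

``constant``
    pi identical for all units (MCAR).
``logistic``
    pi = inverse-logit(g0 + g1 * covariate); MAR given the covariate.
``linear``
    pi = clip(c0 + c1 * rank-fraction(covariate), 0, 1); rank-fraction
    parameterization avoids clipping pathologies on heavy-tailed covariates.
``threshold_high`` / ``threshold_low``
    all-or-nothing truncation at the covariate mean: units above (below)
    the mean are never sampled; the retained side gets a flat pi solved so
    the overall mean hits the target fraction.
``preferential``
    logistic in the standardized log expected abundance itself — MNAR by
    construction, since the driver is the (unobservable) outcome surface.

Intercepts are calibrated by root-finding so that mean(pi) equals the
target sampling fraction to 1e-6 (threshold mechanisms are exact by
algebra).  Diagnostics regress inclusion on covariates; they can flag
covariate-dependent (non-MCAR) gaps but, as always with missing data,
MNAR cannot be tested directly from the observed data.
"""
from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import chi2, rankdata

from .datatypes import AbundanceData, Mask, MissingnessDiagnostics, SamplingDesign
from .exceptions import AlignmentError, CalibrationError, EstimationError

__all__ = [
    "MECHANISMS",
    "inclusion_probs",
    "calibrate_intercept",
    "draw_mask",
    "apply_mask",
    "diagnose_missingness",
    "gap_proportions",
]

MECHANISMS = (
    "constant",
    "logistic",
    "linear",
    "threshold_high",
    "threshold_low",
    "preferential",
)

MNAR_CAVEAT = (
    "MNAR cannot be tested directly from the observed data: these diagnostics "
    "can only detect dependence of missingness on the covariates supplied."
)

_CAL_TOL = 1e-6
_BRACKET = (-20.0, 20.0)


def _as_series(covariate) -> pd.Series:
    s = pd.Series(covariate) if not isinstance(covariate, pd.Series) else covariate
    if not np.all(np.isfinite(s.to_numpy(dtype=float))):
        raise ValueError("covariate must be finite")
    return s.astype(float)


def _pi_given_intercept(mechanism: str, intercept: float, slope: float,
                        cov: np.ndarray) -> np.ndarray:
    if mechanism in ("logistic", "preferential"):
        return expit(intercept + slope * cov)
    if mechanism == "linear":
        rf = (rankdata(cov) - 0.5) / len(cov)
        return np.clip(intercept + slope * rf, 0.0, 1.0)
    raise ValueError(f"no intercept parameterization for mechanism {mechanism!r}")


def calibrate_intercept(
    mechanism: str,
    slope_params: Mapping[str, float],
    covariate,
    target_fraction: float,
) -> float:
    """Solve for the intercept that makes mean(pi) hit the target fraction.

    Uses Brent root-finding on the bracket [-20, 20]; mean(pi) is monotone
    non-decreasing in the intercept for every supported mechanism.  For the
    degenerate target_fraction = 1 the upper bracket end is accepted (a
    census; every unit's pi is driven to its maximum).
    """
    cov = _as_series(covariate).to_numpy()
    slope = float(slope_params.get("slope", 0.0))
    if mechanism == "constant" or (mechanism in ("logistic", "preferential") and slope == 0.0):
        # closed form: inverse-logit intercept reproduces a flat fraction
        if target_fraction >= 1.0:
            return _BRACKET[1]
        return float(logit(target_fraction))

    def resid(g0: float) -> float:
        return float(np.mean(_pi_given_intercept(mechanism, g0, slope, cov))) - target_fraction

    lo, hi = _BRACKET
    r_lo, r_hi = resid(lo), resid(hi)
    if target_fraction >= 1.0:
        return hi
    if abs(r_lo) <= _CAL_TOL:
        return lo
    if abs(r_hi) <= _CAL_TOL:
        return hi
    if r_lo > 0 or r_hi < 0:
        raise CalibrationError(
            f"target fraction {target_fraction} unreachable for mechanism "
            f"{mechanism!r}: mean(pi) spans [{r_lo + target_fraction:.6f}, "
            f"{r_hi + target_fraction:.6f}] on the intercept bracket {_BRACKET}"
        )
    g0 = brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(resid(g0)) > _CAL_TOL:
        raise CalibrationError(
            f"calibration residual {resid(g0):.2e} exceeds tolerance {_CAL_TOL}"
        )
    return float(g0)


def inclusion_probs(
    covariate,
    mechanism: str,
    params: Optional[Mapping[str, float]] = None,
    target_fraction: float = 0.35,
    covariate_name: str = "covariate",
) -> SamplingDesign:
    """Build a sampling design: per-unit pi under a named mechanism.

    ``covariate`` is a Series indexed by the unit key (index values carry
    through to the design and any mask drawn from it).  For mechanism
    ``preferential`` pass the standardized log expected abundance as the
    covariate.  ``params['slope']`` sets the mechanism slope; the intercept
    is calibrated unless supplied explicitly via ``params['intercept']``.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}; choose from {MECHANISMS}")
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    s = _as_series(covariate)
    cov = s.to_numpy()
    params = dict(params or {})

    if mechanism == "constant":
        pi = np.full(len(cov), target_fraction)
        params.setdefault("intercept", float(logit(target_fraction)) if target_fraction < 1 else _BRACKET[1])
    elif mechanism in ("logistic", "preferential", "linear"):
        slope = float(params.get("slope", 1.0))
        params["slope"] = slope
        if "intercept" not in params:
            params["intercept"] = calibrate_intercept(
                mechanism, {"slope": slope}, s, target_fraction
            )
        if target_fraction >= 1.0:
            pi = np.ones(len(cov))
        else:
            pi = _pi_given_intercept(mechanism, params["intercept"], slope, cov)
    elif mechanism in ("threshold_high", "threshold_low"):
        thr = cov.mean()
        keep = cov <= thr if mechanism == "threshold_high" else cov >= thr
        n_keep = int(keep.sum())
        max_frac = n_keep / len(cov)
        p = target_fraction * len(cov) / n_keep if n_keep else np.inf
        if p > 1.0 + 1e-12:
            raise CalibrationError(
                f"{mechanism}: target fraction {target_fraction} exceeds the "
                f"retained-side bound {max_frac:.4f}"
            )
        pi = np.where(keep, min(p, 1.0), 0.0)
        params.update({"threshold": float(thr), "p_keep": float(min(p, 1.0))})
    else:  # pragma: no cover
        raise ValueError(mechanism)

    return SamplingDesign(
        pi=pd.Series(pi, index=s.index, name="pi"),
        mechanism=mechanism,
        params=params,
        covariate_name=covariate_name,
        target_fraction=target_fraction,
    )


def draw_mask(design: SamplingDesign, dimension: str = "spatial", seed: int = 0) -> Mask:
    """Realize a mask: independent Bernoulli(pi) per design unit.

    For ``dimension='spatial'`` the design unit should be the site (or
    cell); inclusion is broadcast to all records of the unit when the mask
    is applied to finer-grained data.
    """
    if dimension not in ("spatial", "annual", "within_year"):
        raise ValueError(f"unknown mask dimension {dimension!r}")
    rng = np.random.default_rng(seed)
    included = pd.Series(
        rng.random(len(design.pi)) < design.pi.to_numpy(),
        index=design.pi.index,
        name="included",
    )
    return Mask(included=included, design=design, dimension=dimension, seed=seed)


def apply_mask(data: AbundanceData, mask: Mask) -> AbundanceData:
    """Subset dense data to the units the mask includes.

    Covariate columns are retained; the truth ``lambda`` column is stripped
    from the observed table.  Provenance (mechanism, seed, dimension,
    realized fraction) is recorded in the result's ``meta``.
    """
    idx = mask.included.index
    if isinstance(idx, pd.MultiIndex):
        key_cols = [n for n in idx.names if n is not None]
    else:
        key_cols = [idx.name or data.unit_cols[0]]
    missing_cols = [c for c in key_cols if c not in data.table.columns]
    if missing_cols:
        raise AlignmentError(f"mask keys {missing_cols} absent from data columns")
    if len(key_cols) == 1:
        data_keys = pd.Index(data.table[key_cols[0]])
    else:
        data_keys = pd.MultiIndex.from_frame(data.table[key_cols])
    unknown = ~data_keys.isin(mask.included.index)
    if unknown.any():
        raise AlignmentError(
            f"{int(unknown.sum())} data units have no entry in the mask"
        )
    keep = mask.included.reindex(data_keys).to_numpy()
    table = data.table.loc[keep].reset_index(drop=True)
    table = table.drop(columns=[c for c in ("lambda",) if c in table.columns])
    meta = dict(data.meta)
    meta.update(
        {
            "mechanism": mask.design.mechanism,
            "mechanism_params": dict(mask.design.params),
            "target_fraction": mask.design.target_fraction,
            "mask_dimension": mask.dimension,
            "mask_seed": mask.seed,
            "realized_fraction": mask.realized_fraction,
            "observed": True,
        }
    )
    return AbundanceData(table=table, unit_cols=data.unit_cols, meta=meta)


def gap_proportions(mask: Mask) -> dict[str, float]:
    """Proportion of spatial / annual / within-year units that are gaps.

    What can be reported depends on the granularity of the mask's unit key:
    a plain site or cell index yields only the spatial gap proportion; a
    (site, year) key adds annual gaps (site-years missing among sites with
    at least one observed year); a (site, year, visit) key adds within-year
    gaps.
    """
    inc = mask.included
    idx = inc.index
    out: dict[str, float] = {}
    if not isinstance(idx, pd.MultiIndex):
        out["spatial"] = float(1.0 - inc.mean())
        return out
    names = list(idx.names)
    df = inc.rename("included").reset_index()
    site_col = names[0]
    by_site = df.groupby(site_col)["included"].any()
    out["spatial"] = float(1.0 - by_site.mean())
    if len(names) >= 2:
        year_col = names[1]
        observed_sites = by_site[by_site].index
        sub = df[df[site_col].isin(observed_sites)]
        by_sy = sub.groupby([site_col, year_col])["included"].any()
        out["annual"] = float(1.0 - by_sy.mean())
    if len(names) >= 3:
        observed_sy = by_sy[by_sy].index
        sub2 = df.set_index([site_col, year_col])
        sub2 = sub2.loc[sub2.index.isin(observed_sy)]
        out["within_year"] = float(1.0 - sub2["included"].mean())
    return out


def diagnose_missingness(mask: Mask, covariates: pd.DataFrame) -> MissingnessDiagnostics:
    """Regress inclusion on covariates and summarize the gap structure.

    Fits a logistic regression of the inclusion indicator on the supplied
    covariates (which must cover both included and excluded units), reports
    per-covariate Wald tests and one overall likelihood-ratio test against
    the intercept-only model, plus the gap-proportion summary.  Complete
    separation is flagged in the report (coefficients replaced by NaN), not
    raised.  No multiple-testing correction is applied — the report is a
    screen, not a decision rule.
    """
    import statsmodels.api as sm

    y = mask.included.astype(int)
    if y.nunique() < 2:
        raise EstimationError(
            "diagnosis needs both included and excluded units in the mask"
        )
    X = covariates.reindex(y.index)
    if X.isna().any().any():
        raise AlignmentError("covariates missing for some mask units")
    Xc = sm.add_constant(X.astype(float), has_constant="add")

    separation = False
    coefs = pd.DataFrame(
        np.nan, index=Xc.columns, columns=["coef", "se", "z", "p"]
    )
    lrt_stat = np.nan
    lrt_p = np.nan
    df_lrt = X.shape[1]
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation is flagged, not raised
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
        fitted = np.asarray(fit.fittedvalues)
        bse = np.asarray(fit.bse)
        if (
            not np.all(np.isfinite(bse))
            or np.abs(np.asarray(fit.params)).max() > 15
            or np.all((fitted < 1e-8) | (fitted > 1 - 1e-8))
        ):
            separation = True
        else:
            coefs.loc[:, "coef"] = np.asarray(fit.params)
            coefs.loc[:, "se"] = bse
            coefs.loc[:, "z"] = np.asarray(fit.params) / bse
            coefs.loc[:, "p"] = 2 * (1 - chi2.cdf((np.asarray(fit.params) / bse) ** 2, 1))
            p_bar = y.mean()
            ll_null = float(
                y.sum() * np.log(p_bar) + (len(y) - y.sum()) * np.log(1 - p_bar)
            )
            lrt_stat = float(2 * (fit.llf - ll_null))
            lrt_stat = max(lrt_stat, 0.0)
            lrt_p = float(chi2.sf(lrt_stat, df_lrt))
    except Exception:
        separation = True

    return MissingnessDiagnostics(
        coefficients=coefs,
        lrt_stat=lrt_stat,
        lrt_df=df_lrt,
        lrt_pvalue=lrt_p,
        separation=separation,
        gap_summary=gap_proportions(mask),
        caveat=MNAR_CAVEAT,
    )
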