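"""Recentred influence functions and the two-level inequality decomposition.

The recentred influence function (RIF) of a statistic attaches to every
observation the statistic's value plus its Gateaux derivative in the direction
of that observation; its weighted mean recovers the statistic exactly.
Regressing the per-person RIF of the concentration index on individual and
country-level covariates therefore decomposes income-related inequality into
the contributions associated with those covariates.

For the Erreygers index of a binary outcome, with weighted fractional ranks
``R`` and

    A   = sum_i w_i h_i R_i / W
    s_i = sum_j w_j h_j (1{y_j > y_i} + 1/2 * 1{y_j = y_i}) / W

the per-person value is ``RIF_i = 4 h_i (2 R_i - 1) + 8 (s_i - A)``.  Under
the block-midpoint tie convention the weighted mean of the RIF equals the
index with no remainder, which the decomposition relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm

from .concentration import fractional_rank, weighted_cov, _validate_hyw

__all__ = [
    "rif_erreygers",
    "rif_standard",
    "build_design_matrix",
    "DecompositionResult",
    "RIFDecomposition",
    "fit_two_level",
    "pool_rubin",
]

#: Categorical level vocabularies shared with the microdata schema.  The first
#: level of each block is the reference level of the decomposition model.
AGE_BANDS = ["55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
EDUCATION_LEVELS = [
    "less than upper secondary",
    "upper secondary and vocational training",
    "tertiary",
]
MACRO_VARIABLES = [
    "hospital_beds_per_1000",
    "sanitation_pct",
    "rural_pct",
    "health_exp_pct_gdp",
    "tertiary_enrolment_pct",
    "gdp",
]


def _upper_weight_share(h, y, w):
    """s_i = weighted share of outcome mass strictly above i's income plus
    half the mass tied with it (the tie term includes i itself)."""
    order = np.argsort(y, kind="stable")
    ys = y[order]
    whs = (w * h)[order]
    total = w.sum()

    uniq, start = np.unique(ys, return_index=True)
    block_wh = np.add.reduceat(whs, start)
    cum_incl = np.cumsum(block_wh)
    above = block_wh.sum() - cum_incl
    s_block = (above + block_wh / 2.0) / total

    s_sorted = s_block[np.searchsorted(uniq, ys)]
    out = np.empty_like(s_sorted)
    out[order] = s_sorted
    return out


def rif_erreygers_values(h, y, w, R=None) -> np.ndarray:
    """RIF of the Erreygers index for binary ``h`` with bounds (0, 1)."""
    if R is None:
        R = fractional_rank(y, w)
    total = w.sum()
    A = float(w @ (h * R) / total)
    s = _upper_weight_share(h, y, w)
    return 4.0 * h * (2.0 * R - 1.0) + 8.0 * (s - A)


def rif_standard_values(h, y, w, R=None) -> np.ndarray:
    """RIF of the standard concentration index C = 2*cov_w(h, R)/mu."""
    if R is None:
        R = fractional_rank(y, w)
    total = w.sum()
    mu = float(w @ h / total)
    if mu <= 0:
        raise ValueError("standard-index RIF undefined: weighted mean of h is 0")
    A = float(w @ (h * R) / total)
    C = 2.0 * weighted_cov(h, R, w) / mu
    s = _upper_weight_share(h, y, w)
    return C + (2.0 / mu) * (h * R + s - 2.0 * A) - (C + 1.0) * (h - mu) / mu


def rif_erreygers(h, y, w=None) -> np.ndarray:
    """Per-observation RIF of the Erreygers index (binary outcome)."""
    h, y, w = _validate_hyw(h, y, w)
    if not np.all(np.isin(h, (0.0, 1.0))):
        raise ValueError("Erreygers RIF requires a binary outcome in {0, 1}")
    return rif_erreygers_values(h, y, w)


def rif_standard(h, y, w=None) -> np.ndarray:
    """Per-observation RIF of the standard concentration index."""
    h, y, w = _validate_hyw(h, y, w)
    return rif_standard_values(h, y, w)


# ---------------------------------------------------------------------------
# Covariate design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(data: pd.DataFrame, macro_quartiles: pd.DataFrame,
                        macro_variables=None) -> pd.DataFrame:
    """Dummy-coded covariate table for the decomposition regression.

    Individual blocks: age band (reference 55-59), gender (reference male),
    marital status (reference married), education (reference less than upper
    secondary), chronic disease, current smoking and drinking (references 0).
    Country blocks: for each macro indicator, quartile dummies with quartile 1
    as reference.  With the default six indicators: 31 columns, no intercept.

    Parameters
    ----------
    data : DataFrame
        Completed (post-imputation) microdata; covariates must be nonmissing.
    macro_quartiles : DataFrame
        One row per country_code with integer quartile columns named after
        the macro indicators.
    macro_variables : sequence of str, optional
        Subset of macro indicators to include.  Each indicator costs three
        country-level columns, so with few countries the full set is not
        identifiable; default is all six.
    """
    covariate_cols = ["age_band", "gender", "marital", "education",
                      "chronic", "smoke", "drink"]
    missing = [c for c in covariate_cols if data[c].isna().any()]
    if missing:
        raise ValueError(f"covariates contain missing values (impute first): {missing}")

    X = pd.DataFrame(index=data.index)

    def _dummies(series, levels, prefix):
        cat = pd.Categorical(series, categories=levels)
        if cat.isna().any():
            bad = sorted(set(series[pd.isna(cat)].astype(str)))
            raise ValueError(f"unseen category in {prefix}: {bad}")
        for lev in levels[1:]:
            X[f"{prefix}[{lev}]"] = (cat == lev).astype(float)

    _dummies(data["age_band"], AGE_BANDS, "age_band")
    _dummies(data["gender"], ["male", "female"], "gender")
    _dummies(data["marital"], ["married", "other"], "marital")
    _dummies(data["education"], EDUCATION_LEVELS, "education")
    for col in ("chronic", "smoke", "drink"):
        vals = data[col].astype(float)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError(f"unseen category in {col}")
        X[col] = vals

    mq = macro_quartiles.set_index("country_code") if "country_code" in macro_quartiles else macro_quartiles
    for var in (MACRO_VARIABLES if macro_variables is None else list(macro_variables)):
        if var not in mq:
            raise ValueError(f"macro quartile table lacks column {var!r}")
        per_person = data["country_code"].map(mq[var])
        if per_person.isna().any():
            bad = sorted(set(data.loc[per_person.isna(), "country_code"]))
            raise ValueError(f"countries without a {var} quartile: {bad}")
        for q in (2, 3, 4):
            X[f"{var}[Q{q}]"] = (per_person == q).astype(float)

    return X


# ---------------------------------------------------------------------------
# Two-level regression and Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class DecompositionResult:
    """Pooled coefficient table of the inequality decomposition."""

    terms: pd.DataFrame  # index: term; columns: estimate, se, p_value
    model: str  # "random-intercept" or "cluster-robust"
    n_persons: int
    n_countries: int
    m_imputations: int = 1
    pooling: str = "none"
    reference_levels: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        p = self.terms["p_value"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    def significant(self, alpha: float = 0.05) -> pd.Series:
        return self.terms["p_value"] < alpha


_REFERENCE_LEVELS = {
    "age_band": AGE_BANDS[0],
    "gender": "male",
    "marital": "married",
    "education": EDUCATION_LEVELS[0],
    "chronic": "0",
    "smoke": "0",
    "drink": "0",
    **{var: "Q1" for var in MACRO_VARIABLES},
}


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted-QR style sweep
        aliased = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


class RIFDecomposition(BaseEstimator):
    """Two-level linear regression of per-person RIF values on covariates.

    The default model adds a country-level random intercept (REML).  If the
    random-intercept variance collapses to the boundary or the optimizer does
    not converge, the fit falls back to weighted least squares with
    country-cluster-robust standard errors and records the fallback.  Person
    weights enter the cluster-robust model as analytic weights; the
    random-intercept likelihood is unweighted (see the package methods note).

    Attributes
    ----------
    result_ : DecompositionResult
    params_, bse_, pvalues_ : Series indexed by term (including "Intercept").
    model_used_ : str
    """

    def __init__(self, model="random-intercept", use_weights=True, boundary_tol=1e-6):
        self.model = model
        self.use_weights = use_weights
        self.boundary_tol = boundary_tol

    def fit(self, X, y, groups, sample_weight=None):
        """Fit the decomposition regression.

        Parameters
        ----------
        X : DataFrame or 2-d array
            Covariates (no intercept column; one is added).
        y : array-like
            Per-person RIF values.
        groups : array-like
            Country identifier per person (the second level).
        sample_weight : array-like, optional
            Person-level analytic weights.
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            names = [f"x{j}" for j in range(Xm.shape[1])]
        yv = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if len({len(yv), len(groups), Xm.shape[0]}) != 1:
            raise ValueError("X, y and groups must have equal length")
        n_countries = len(np.unique(groups))
        if n_countries < 4:
            raise ValueError("need at least 4 countries for the two-level model")

        Xc = np.column_stack([np.ones(len(yv)), Xm])
        names_c = ["Intercept"] + names
        _check_full_rank(Xc, names_c)

        w = None
        if sample_weight is not None and self.use_weights:
            w = np.asarray(sample_weight, dtype=float)

        fallback = False
        if self.model == "random-intercept":
            if w is not None:
                warnings.warn(
                    "random-intercept REML ignores person weights; "
                    "use model='cluster-robust' for analytic weights",
                    UserWarning,
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = sm.MixedLM(yv, Xc, groups=groups)
                fit = mixed.fit(reml=True)
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
            if (not fit.converged) or re_var <= self.boundary_tol * max(yv.var(), 1e-12):
                fallback = True
            else:
                params = pd.Series(fit.fe_params, index=names_c)
                bse = pd.Series(fit.bse_fe, index=names_c)
                pvals = pd.Series(
                    2 * stats.norm.sf(np.abs(params / bse)), index=names_c
                )
                model_used = "random-intercept"
                converged = bool(fit.converged)
        elif self.model == "cluster-robust":
            fallback = True  # same code path, not a fallback semantically
        else:
            raise ValueError(f"unknown model {self.model!r}")

        if fallback:
            wls = sm.WLS(yv, Xc, weights=w if w is not None else 1.0)
            fit = wls.fit(cov_type="cluster", cov_kwds={"groups": groups})
            params = pd.Series(fit.params, index=names_c)
            bse = pd.Series(fit.bse, index=names_c)
            pvals = pd.Series(fit.pvalues, index=names_c)
            model_used = (
                "cluster-robust"
                if self.model == "cluster-robust"
                else "cluster-robust (boundary fallback)"
            )
            converged = True

        self.params_ = params
        self.bse_ = bse
        self.pvalues_ = pvals.clip(0.0, 1.0)
        self.model_used_ = model_used
        self.n_countries_ = n_countries
        self.result_ = DecompositionResult(
            terms=pd.DataFrame(
                {"estimate": self.params_, "se": self.bse_, "p_value": self.pvalues_}
            ),
            model=model_used,
            n_persons=len(yv),
            n_countries=n_countries,
            reference_levels=dict(_REFERENCE_LEVELS),
            converged=converged,
        )
        return self


def fit_two_level(rif, X, groups, weights=None, model="random-intercept") -> DecompositionResult:
    """Functional wrapper over :class:`RIFDecomposition`."""
    est = RIFDecomposition(model=model, use_weights=weights is not None)
    est.fit(X, rif, groups, sample_weight=weights)
    return est.result_


def pool_rubin(results: list[DecompositionResult]) -> DecompositionResult:
    """Pool decomposition fits over multiply-imputed datasets by Rubin's rules.

    Pooled estimate = mean of the m estimates; total variance = mean
    within-imputation variance + (1 + 1/m) * between-imputation variance.
    Degrees of freedom follow the Barnard-Rubin small-sample formula with
    complete-data df = n_persons - n_terms.
    """
    if not results:
        raise ValueError("no results to pool")
    m = len(results)
    terms = list(results[0].terms.index)
    for r in results[1:]:
        if list(r.terms.index) != terms:
            raise ValueError("imputation fits have mismatched term sets")
    if m == 1:
        r = results[0]
        return DecompositionResult(
            terms=r.terms.copy(), model=r.model, n_persons=r.n_persons,
            n_countries=r.n_countries, m_imputations=1, pooling="Rubin",
            reference_levels=r.reference_levels, converged=r.converged,
        )

    Q = np.column_stack([r.terms["estimate"].to_numpy() for r in results])
    U = np.column_stack([r.terms["se"].to_numpy() ** 2 for r in results])
    qbar = Q.mean(axis=1)
    ubar = U.mean(axis=1)
    B = Q.var(axis=1, ddof=1)
    T = ubar + (1.0 + 1.0 / m) * B

    se = np.sqrt(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1.0 + 1.0 / m) * B / T
        lam = np.where(T > 0, lam, 0.0)
        nu_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
        nu_com = results[0].n_persons - len(terms)
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        nu = np.where(np.isinf(nu_old), nu_obs, nu_old * nu_obs / (nu_old + nu_obs))
        tstat = np.where(se > 0, qbar / se, 0.0)
    pvals = np.where(se > 0, 2 * stats.t.sf(np.abs(tstat), np.maximum(nu, 1.0)), 0.0)

    pooled = pd.DataFrame({"estimate": qbar, "se": se, "p_value": pvals}, index=terms)
    r0 = results[0]
    return DecompositionResult(
        terms=pooled, model=r0.model, n_persons=r0.n_persons,
        n_countries=r0.n_countries, m_imputations=m, pooling="Rubin",
        reference_levels=r0.reference_levels,
        converged=all(r.converged for r in results),
    )
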