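"""Design-weighted, age-post-stratified prevalence and income quintiles.

Point estimates are ratio means ``sum(w*h)/sum(w)``; variances use Taylor
linearization over clusters within strata, and 95% intervals are built on the
logit scale and back-transformed (truncated to [0, 100]).  Post-stratification
is a single-margin (age band) per-country multiplicative adjustment to the
sampling weights so that weighted band shares match a reference population
composition while the country's total weight is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PrevalenceEstimate",
    "poststratify_weights",
    "PostStratifier",
    "weighted_prevalence",
    "assign_income_quintiles",
    "IncomeQuintiles",
    "percentage_difference",
    "assign_country_quartiles",
]


@dataclass
class PrevalenceEstimate:
    """A weighted prevalence (percent) with its 95% confidence interval."""

    domain: str
    group: str
    n: int
    prevalence: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 <= self.ci_low <= self.prevalence <= self.ci_high <= 100.0):
            raise ValueError("interval must satisfy 0 <= low <= point <= high <= 100")


# ---------------------------------------------------------------------------
# Post-stratification
# ---------------------------------------------------------------------------

def poststratify_weights(data: pd.DataFrame, ref: pd.Series,
                         group_col: str = "country_code",
                         band_col: str = "age_band",
                         weight_col: str = "sample_weight") -> pd.Series:
    """Per-band multiplicative weight adjustment, within each country.

    After adjustment the weighted age-band shares in every country equal the
    reference shares exactly and the country's total weight is unchanged.
    A reference band with positive share but zero sampled weight in some
    country is an error (no factor can create mass there).
    """
    ref = pd.Series(ref, dtype=float)
    if abs(ref.sum() - 1.0) > 1e-6:
        raise ValueError("reference shares must sum to 1")
    if (ref < 0).any():
        raise ValueError("reference shares must be nonnegative")

    unknown = set(data[band_col].unique()) - set(ref.index)
    if unknown:
        raise ValueError(f"sampled age bands absent from the reference: {sorted(unknown)}")

    w = data[weight_col].astype(float)
    out = pd.Series(np.nan, index=data.index, name=weight_col)
    for country, idx in data.groupby(group_col, sort=False).groups.items():
        sub_w = w.loc[idx]
        band = data.loc[idx, band_col]
        total = sub_w.sum()
        band_w = sub_w.groupby(band.values).sum()
        absent = [b for b in ref.index if ref[b] > 0 and band_w.get(b, 0.0) == 0.0]
        if absent:
            raise ValueError(
                f"country {country}: reference band(s) {absent} have positive "
                "share but no sampled weight")
        factors = (ref * total / band_w).reindex(band.values).to_numpy()
        out.loc[idx] = sub_w.to_numpy() * factors
    return out


class PostStratifier(BaseEstimator, TransformerMixin):
    """Transformer view of :func:`poststratify_weights`.

    ``fit`` stores the reference age structure; ``transform`` returns the
    microdata with ``sample_weight`` replaced by the adjusted weights.
    """

    def __init__(self, group_col="country_code", band_col="age_band",
                 weight_col="sample_weight"):
        self.group_col = group_col
        self.band_col = band_col
        self.weight_col = weight_col

    def fit(self, X, y=None, ref=None):
        if ref is None:
            raise ValueError("a reference age structure is required")
        self.ref_ = pd.Series(ref, dtype=float)
        return self

    def transform(self, X):
        out = X.copy()
        out[self.weight_col] = poststratify_weights(
            X, self.ref_, self.group_col, self.band_col, self.weight_col)
        return out


# ---------------------------------------------------------------------------
# Prevalence with design-based variance
# ---------------------------------------------------------------------------

def _taylor_variance(h, w, strata, clusters, p):
    """Variance of the ratio mean by Taylor linearization over PSUs."""
    z = w * (h - p) / w.sum()
    df = pd.DataFrame({"z": z, "s": strata, "c": clusters})
    var = 0.0
    for _, sub in df.groupby("s", sort=False):
        totals = sub.groupby("c", sort=False)["z"].sum().to_numpy()
        n_c = len(totals)
        if n_c < 2:
            return None  # caller falls back to SRS
        var += n_c / (n_c - 1) * np.sum((totals - totals.mean()) ** 2)
    return var


def _srs_variance(h, w, p):
    n = len(h)
    if n < 2:
        return 0.0
    z = w * (h - p) / w.sum()
    return n / (n - 1) * float(np.sum(z**2))


def weighted_prevalence(outcome, weights, strata=None, clusters=None,
                        domain: str = "", group: str = "") -> PrevalenceEstimate:
    """Design-weighted prevalence (percent) with a logit-scale 95% CI.

    Missing outcomes must be excluded upstream.  If any stratum contains a
    single cluster, the design variance is undefined and the estimator falls
    back to the SRS form with a warning.
    """
    h = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if h.size == 0:
        raise ValueError("empty outcome vector")
    if np.any(~np.isin(h, (0.0, 1.0))):
        raise ValueError("outcome must be binary in {0, 1} (drop missing first)")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    p = float(w @ h / w.sum())
    n = int(h.size)

    if strata is not None and clusters is not None:
        var = _taylor_variance(h, w, np.asarray(strata), np.asarray(clusters), p)
        if var is None:
            warnings.warn(
                "a stratum contains a single cluster; falling back to SRS variance",
                UserWarning)
            var = _srs_variance(h, w, p)
    else:
        var = _srs_variance(h, w, p)

    if p <= 0.0 or p >= 1.0 or var <= 0.0:
        lo = hi = p
    else:
        se_logit = np.sqrt(var) / (p * (1.0 - p))
        z = 1.959963984540054
        lo = float(expit(logit(p) - z * se_logit))
        hi = float(expit(logit(p) + z * se_logit))
    return PrevalenceEstimate(domain=domain, group=group, n=n,
                              prevalence=100.0 * p,
                              ci_low=max(0.0, 100.0 * lo),
                              ci_high=min(100.0, 100.0 * hi))


# ---------------------------------------------------------------------------
# Weighted quantile groups
# ---------------------------------------------------------------------------

def _weighted_quantile_groups(values, weights, n_groups):
    """Group labels 1..n_groups from the weighted empirical CDF.

    Cut point k is the smallest value whose weighted CDF reaches k/n_groups
    (right-closed intervals); a unit is assigned to the lowest group whose
    upper cut point is >= its value, so exact ties always share a group.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    uniq, start = np.unique(v[order], return_index=True)
    block_w = np.add.reduceat(w[order], start)
    cdf = np.cumsum(block_w) / w.sum()
    targets = np.arange(1, n_groups) / n_groups
    cut_idx = np.searchsorted(cdf, targets - 1e-12, side="left")
    cuts = uniq[np.minimum(cut_idx, len(uniq) - 1)]
    return 1 + np.searchsorted(cuts, v, side="left")


def assign_income_quintiles(data: pd.DataFrame,
                            income_col: str = "income_pc",
                            weight_col: str = "sample_weight",
                            group_col: str = "country_code") -> pd.Series:
    """Within-country weighted income quintiles (1 = poorest, 5 = richest)."""
    out = pd.Series(0, index=data.index, name="quintile", dtype=int)
    for country, idx in data.groupby(group_col, sort=False).groups.items():
        v = data.loc[idx, income_col].astype(float)
        if v.isna().any():
            raise ValueError(f"country {country}: missing income values")
        if v.nunique() < 5:
            raise ValueError(
                f"country {country}: fewer than 5 distinct income values; "
                "quintiles are degenerate")
        out.loc[idx] = _weighted_quantile_groups(
            v.to_numpy(), data.loc[idx, weight_col].to_numpy(dtype=float), 5)
    return out


class IncomeQuintiles(BaseEstimator, TransformerMixin):
    """Transformer adding a within-country ``quintile`` column to microdata."""

    def __init__(self, income_col="income_pc", weight_col="sample_weight",
                 group_col="country_code"):
        self.income_col = income_col
        self.weight_col = weight_col
        self.group_col = group_col

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        out = X.copy()
        out["quintile"] = assign_income_quintiles(
            X, self.income_col, self.weight_col, self.group_col)
        return out


def percentage_difference(p_q1: float, p_q5: float) -> float:
    """Relative prevalence gap ((Q1 - Q5)/Q1) * 100 between the poorest and
    richest quintiles, both given in percent."""
    if p_q1 <= 0:
        raise ValueError("percentage difference undefined for quintile-1 prevalence of 0")
    return (p_q1 - p_q5) / p_q1 * 100.0


def assign_country_quartiles(macro: pd.DataFrame, variable: str,
                             country_col: str = "country_code") -> pd.Series:
    """Unweighted country quartiles (1..4) of one macro indicator.

    Ties share the lower quartile; requires at least 4 countries with a
    nonmissing value.
    """
    vals = macro.set_index(country_col)[variable].astype(float).dropna()
    if len(vals) < 4:
        raise ValueError(f"need >= 4 countries with nonmissing {variable!r}")
    q = _weighted_quantile_groups(vals.to_numpy(), np.ones(len(vals)), 4)
    return pd.Series(q, index=vals.index, name=f"{variable}_quartile")
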