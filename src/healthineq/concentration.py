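"""Weighted fractional income ranks and rank-dependent concentration indices.

The standard concentration index ``C = 2*cov_w(h, R)/mu`` measures how a health
variable ``h`` is distributed over the income-rank distribution ``R`` (negative
values: the outcome is concentrated among the poor).  For bounded — in
particular binary — outcomes the Erreygers-corrected index

    E = 4*mu*C/(b - a) = 8*cov_w(h, R)/(b - a)

restores the mirror condition ``E(h) = -E(1 - h)``: inequality measured in
attainments equals minus inequality measured in shortfalls.  Standard errors
come from the recentred influence function (RIF) of the index, which this
module shares with the regression-decomposition machinery in
:mod:`healthineq.rif`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "fractional_rank",
    "weighted_cov",
    "standard_ci",
    "erreygers_ci",
    "IndexEstimate",
    "ConcentrationIndex",
]


def fractional_rank(y, w=None) -> np.ndarray:
    """Weighted fractional (midpoint) rank of ``y`` in (0, 1).

    Sorting by ``y`` ascending, every tie block of equal incomes receives the
    single rank ``(cumulative weight before the block + block weight/2) / W``.
    The weighted mean of the returned ranks is exactly 1/2 and the output is
    aligned to the input order.

    Parameters
    ----------
    y : array-like
        Ranking variable (per-capita household income).
    w : array-like, optional
        Strictly positive sampling weights; equal weights if omitted.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-d array")
    if w is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != y.shape:
            raise ValueError("y and w must have the same shape")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be strictly positive and finite")

    order = np.argsort(y, kind="stable")
    ys = y[order]
    ws = w[order]
    total = ws.sum()

    uniq, start = np.unique(ys, return_index=True)
    block_w = np.add.reduceat(ws, start)
    before = np.concatenate(([0.0], np.cumsum(block_w)[:-1]))
    block_rank = (before + block_w / 2.0) / total

    ranks_sorted = block_rank[np.searchsorted(uniq, ys)]
    out = np.empty_like(ranks_sorted)
    out[order] = ranks_sorted
    return out


def weighted_cov(a, b, w) -> float:
    """Weighted covariance with weights normalized to sum to one."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    am = w @ a / total
    bm = w @ b / total
    return float(w @ ((a - am) * (b - bm)) / total)


@dataclass
class IndexEstimate:
    """A concentration-index value with its RIF-based uncertainty.

    ``bounds`` records the (a, b) range of the health variable used by the
    Erreygers correction; for binary outcomes (0, 1).  Sign convention:
    negative = pro-poor concentration of the outcome.
    """

    index_type: str
    value: float
    se: float
    ci95: tuple[float, float]
    n: int
    bounds: tuple[float, float] = (0.0, 1.0)
    mean: float = field(default=float("nan"))

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")


def _validate_hyw(h, y, w):
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    if h.shape != y.shape or h.ndim != 1 or h.size == 0:
        raise ValueError("h and y must be non-empty 1-d arrays of equal length")
    if w is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights must align with h and y")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    return h, y, w


def _estimate(h, y, w, index_type, bounds):
    from .rif import rif_erreygers_values, rif_standard_values

    R = fractional_rank(y, w)
    total = w.sum()
    mu = float(w @ h / total)
    n = h.size
    a, b = bounds

    constant = np.all(h == h[0])
    if index_type == "standard":
        if mu <= 0:
            raise ValueError("standard concentration index undefined: weighted mean of h is 0")
        value = 0.0 if constant else 2.0 * weighted_cov(h, R, w) / mu
        rif = rif_standard_values(h, y, w, R=R)
    elif index_type == "erreygers":
        if not (a < b):
            raise ValueError("bounds must satisfy a < b")
        if h.min() < a or h.max() > b:
            raise ValueError("h takes values outside the declared bounds")
        # constant h is the algebraic no-inequality limit: return exact zero
        value = 0.0 if constant else 8.0 * weighted_cov(h, R, w) / (b - a)
        rif = rif_erreygers_values(h, y, w, R=R) / (b - a)
    else:
        raise ValueError(f"unknown index_type {index_type!r}")

    var_rif = float(w @ (rif - value) ** 2 / total)
    se = float(np.sqrt(var_rif / n))
    z = stats.norm.ppf(0.975)
    est = IndexEstimate(
        index_type=index_type,
        value=float(value),
        se=se,
        ci95=(float(value - z * se), float(value + z * se)),
        n=n,
        bounds=(float(a), float(b)),
        mean=mu,
    )
    return est, R, rif


def standard_ci(h, y, w=None) -> IndexEstimate:
    """Standard concentration index ``C = 2*cov_w(h, R)/mu`` with RIF-based SE."""
    h, y, w = _validate_hyw(h, y, w)
    return _estimate(h, y, w, "standard", (0.0, 1.0))[0]


def erreygers_ci(h, y, w=None, bounds=(0.0, 1.0)) -> IndexEstimate:
    """Erreygers-corrected concentration index ``E = 8*cov_w(h, R)/(b - a)``.

    Suitable for binary/bounded health outcomes; satisfies the mirror
    condition E(h) = -E(1-h) and lies in [-1, 1] for binary h.
    """
    h, y, w = _validate_hyw(h, y, w)
    return _estimate(h, y, w, "erreygers", bounds)[0]


class ConcentrationIndex(BaseEstimator):
    """Estimator for rank-dependent income-related inequality indices.

    Parameters
    ----------
    index_type : {"erreygers", "standard"}
        Which index to compute.  The Erreygers form is the default because the
        disability outcomes are binary.
    bounds : tuple of float
        (a, b) bounds of the health variable (Erreygers only).
    weighted : bool
        If False, sampling weights passed to :meth:`fit` are ignored.

    Attributes
    ----------
    value_ : float
        The index estimate.
    se_ : float
        RIF-based standard error (weighted SD of the RIF divided by sqrt(n)).
    ci95_ : tuple
        Normal-theory 95% confidence interval.
    rank_ : ndarray
        Weighted fractional income ranks, aligned to the input rows.
    rif_ : ndarray
        Per-observation recentred influence function of the index; its
        weighted mean equals ``value_`` exactly.
    mean_ : float
        Weighted prevalence of the outcome.
    estimate_ : IndexEstimate
        The full result record.
    """

    def __init__(self, index_type="erreygers", bounds=(0.0, 1.0), weighted=True):
        self.index_type = index_type
        self.bounds = bounds
        self.weighted = weighted

    def fit(self, X, y, sample_weight=None):
        """Estimate the index.

        Parameters
        ----------
        X : array-like, shape (n,)
            Ranking variable (income per capita).
        y : array-like, shape (n,)
            Health outcome, binary for the Erreygers index.
        sample_weight : array-like, optional
            Survey weights.
        """
        income = np.asarray(X, dtype=float).reshape(-1)
        h, income, w = _validate_hyw(y, income, sample_weight if self.weighted else None)
        est, R, rif = _estimate(h, income, w, self.index_type, tuple(self.bounds))
        self.estimate_ = est
        self.value_ = est.value
        self.se_ = est.se
        self.ci95_ = est.ci95
        self.mean_ = est.mean
        self.n_ = est.n
        self.rank_ = R
        self.rif_ = rif
        return self
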