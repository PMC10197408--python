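"""Multivariate imputation by chained equations for explanatory variables.

Each incomplete variable is visited in turn (default order: increasing
missingness) and imputed from a conditional model given all other explanatory
variables plus age band and country.  Model families: predictive mean
matching with k donors for continuous variables, logistic draws for binary
variables, multinomial draws for categoricals.  Initialization draws from the
observed marginal; observed cells are never altered; the whole procedure is
deterministic for a fixed seed.  Outcomes and income are out of bounds for
imputation by design — the analysis drops rows with missing outcomes instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputationSchema", "ChainedImputer", "mice"]

#: default predictor context added to every conditional model
_CONTEXT_COLUMNS = ["age_band", "country_code"]
_PROTECTED_COLUMNS = {"adl", "iadl", "mobility", "income_pc", "sample_weight"}


@dataclass
class ImputationSchema:
    """Configuration of the chained-equation imputer.

    families maps a variable to one of {"pmm", "logistic", "multinomial"};
    variables absent from the mapping are assigned a family automatically
    (continuous -> pmm, 2 levels -> logistic, otherwise multinomial).
    """

    families: dict = field(default_factory=dict)
    visit_order: str = "monotone"  # increasing missingness; ties by column order
    m: int = 5
    cycles: int = 10
    k_donors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        bad = {f for f in self.families.values()} - {"pmm", "logistic", "multinomial"}
        if bad:
            raise ValueError(f"unknown model families: {sorted(bad)}")


def _auto_family(series: pd.Series) -> str:
    obs = series.dropna()
    if pd.api.types.is_numeric_dtype(obs) and obs.nunique() > 10:
        return "pmm"
    return "logistic" if obs.nunique() <= 2 else "multinomial"


class ChainedImputer(BaseEstimator):
    """MICE imputer producing ``m`` completed datasets.

    Parameters mirror :class:`ImputationSchema`.  After :meth:`fit` the
    completed datasets are in ``imputations_`` (list of DataFrames);
    ``transform`` returns the first of them, so the class composes with
    sklearn pipelines when a single completion suffices.
    """

    def __init__(self, families=None, visit_order="monotone", m=5, cycles=10,
                 k_donors=5, seed=0, variables=None, context=None):
        self.families = families
        self.visit_order = visit_order
        self.m = m
        self.cycles = cycles
        self.k_donors = k_donors
        self.seed = seed
        self.variables = variables
        self.context = context

    # -- conditional models -------------------------------------------------

    def _predictors(self, df, target, impute_cols, context):
        """Dummy-coded predictor matrix from all other imputation variables
        plus the context columns (age band, country)."""
        cols = [c for c in impute_cols if c != target] + context
        blocks = [np.ones((len(df), 1))]
        for c in cols:
            s = df[c]
            if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
                blocks.append(s.to_numpy(dtype=float)[:, None])
            else:
                d = pd.get_dummies(s.astype(object), drop_first=True, dtype=float)
                if d.shape[1]:
                    blocks.append(d.to_numpy())
        return np.hstack(blocks)

    def _impute_one(self, df, target, family, impute_cols, context, rng):
        miss = df[target].isna() if not hasattr(self, "_miss_masks") else self._miss_masks[target]
        obs = ~miss
        X = self._predictors(df, target, impute_cols, context)
        Xo, Xm = X[obs.to_numpy()], X[miss.to_numpy()]
        y_obs = df.loc[obs, target]

        try:
            if family == "pmm":
                yo = y_obs.to_numpy(dtype=float)
                beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
                pred_obs = Xo @ beta
                pred_mis = Xm @ beta
                # k nearest observed predictions; one donor drawn per cell
                order = np.argsort(pred_obs, kind="stable")
                pos = np.searchsorted(pred_obs[order], pred_mis)
                k = min(self.k_donors, len(yo))
                lo = np.clip(pos - k // 2, 0, len(yo) - k)
                pick = lo + rng.integers(0, k, size=len(pred_mis))
                return yo[order][pick]
            else:
                codes, levels = pd.factorize(y_obs, sort=True)
                if len(levels) < 2:
                    raise ValueError("single observed level")
                with warnings.catch_warnings():
                    warnings.simplefilter("error", ConvergenceWarning)
                    model = LogisticRegression(
                        max_iter=200, C=1e4, solver="lbfgs",
                        fit_intercept=False)  # intercept is in X
                    model.fit(Xo, codes)
                probs = model.predict_proba(Xm)
                draws = (probs.cumsum(axis=1) >
                         rng.random(len(Xm))[:, None]).argmax(axis=1)
                return levels.take(draws)
        except (ConvergenceWarning, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"conditional model for {target!r} failed ({exc}); "
                "drawing from the observed marginal for this cycle", UserWarning)
            return y_obs.sample(
                n=int(miss.sum()), replace=True,
                random_state=np.random.RandomState(rng.integers(2**31 - 1)),
            ).to_numpy()

    # -- main loop ----------------------------------------------------------

    def fit(self, X, y=None):
        df = X
        context = [c for c in (self.context or _CONTEXT_COLUMNS) if c in df.columns]
        if self.variables is not None:
            impute_cols = list(self.variables)
        else:
            impute_cols = [c for c in df.columns
                           if df[c].isna().any() and c not in _PROTECTED_COLUMNS]
        bad = _PROTECTED_COLUMNS & set(impute_cols)
        if bad:
            raise ValueError(f"outcomes/income are never imputed: {sorted(bad)}")
        for c in df.columns:
            if c in _PROTECTED_COLUMNS and df[c].isna().any() and c != "mobility":
                # mobility may be missing wholesale (cohort without the block)
                raise ValueError(f"missingness in protected column {c!r}; drop rows upstream")
        fully_missing = [c for c in impute_cols if df[c].isna().all()]
        if fully_missing:
            raise ValueError(f"variables with 100% missingness cannot be imputed: {fully_missing}")

        miss_frac = {c: float(df[c].isna().mean()) for c in impute_cols}
        incomplete = [c for c in impute_cols if miss_frac[c] > 0]
        if self.visit_order == "monotone":
            order_cols = sorted(incomplete, key=lambda c: (miss_frac[c], impute_cols.index(c)))
        else:
            order_cols = incomplete

        schema = ImputationSchema(
            families=dict(self.families or {}), visit_order=self.visit_order,
            m=self.m, cycles=self.cycles, k_donors=self.k_donors, seed=self.seed)
        families = {c: schema.families.get(c) or _auto_family(df[c]) for c in incomplete}
        self.schema_ = schema
        self.families_ = families
        self.visit_sequence_ = order_cols
        self._miss_masks = {c: df[c].isna() for c in incomplete}

        if not incomplete:
            self.imputations_ = [df.copy() for _ in range(self.m)]
            return self

        seeds = np.random.SeedSequence(self.seed).spawn(self.m)
        completed = []
        for chain in range(self.m):
            rng = np.random.default_rng(seeds[chain])
            work = df.copy()
            # initialization: random draws from the observed marginal
            for c in order_cols:
                miss = self._miss_masks[c]
                obs_vals = df.loc[~miss, c].to_numpy()
                work.loc[miss, c] = obs_vals[rng.integers(0, len(obs_vals), int(miss.sum()))]
            for _ in range(self.cycles):
                for c in order_cols:
                    imputed = self._impute_one(work, c, families[c],
                                               impute_cols, context, rng)
                    work.loc[self._miss_masks[c], c] = imputed
            for c in incomplete:  # observed cells provably untouched
                assert work.loc[~self._miss_masks[c], c].equals(df.loc[~self._miss_masks[c], c])
            completed.append(work)
        self.imputations_ = completed
        return self

    def transform(self, X):
        if not hasattr(self, "imputations_"):
            raise ValueError("call fit first")
        return self.imputations_[0]


def mice(data: pd.DataFrame, schema: ImputationSchema,
         variables=None) -> list[pd.DataFrame]:
    """Run chained-equation imputation; returns ``schema.m`` completed copies."""
    imp = ChainedImputer(
        families=schema.families, visit_order=schema.visit_order, m=schema.m,
        cycles=schema.cycles, k_donors=schema.k_donors, seed=schema.seed,
        variables=variables)
    return imp.fit(data).imputations_
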