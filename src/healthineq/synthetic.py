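"""Synthetic multi-country ageing-survey generator with known inequality.

Emulates the structure of harmonized multi-country ageing cohorts: countries
in three World-Bank-style income tiers, households with lognormal income,
two-stage stratified-cluster sampling weights, individual covariates, and
binary disability outcomes (ADL / IADL / mobility) whose probability depends
on the person's within-country income rank.

In ``rank-linear`` mode the outcome probability is
``p(R) = p0 + b*(R - 1/2)`` in the weighted fractional income rank ``R``,
clipped to [0.01, 0.99].  Without clipping the population Erreygers index is
``8*b*Var(R) = 2b/3`` (ranks are uniform on (0,1)), giving every downstream
stage a closed-form ground truth.  The default intercepts and slopes are the
study conditions: overall prevalences 16.6% / 17.6% / 57.8% and Erreygers
indices -0.0857 / -0.0967 / -0.1375 for ADL, IADL and mobility.

Sampled age-band shares deliberately differ from the reference age structure
so that post-stratification is non-vacuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .concentration import fractional_rank

__all__ = [
    "GeneratorConfig",
    "generate_microdata",
    "generate_macro",
    "inject_missingness",
    "reference_age_structure",
    "DOMAINS",
    "TIERS",
    "AGE_BANDS",
    "EXPLANATORY_COLUMNS",
]

DOMAINS = ["adl", "iadl", "mobility"]
TIERS = ["lower-middle", "upper-middle", "high"]
AGE_BANDS = ["55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
EXPLANATORY_COLUMNS = ["marital", "education", "chronic", "smoke", "drink"]
EDUCATION_LEVELS = [
    "less than upper secondary",
    "upper secondary and vocational training",
    "tertiary",
]

# Global 55+ age composition used for post-stratification (shares sum to 1).
_REFERENCE_SHARES = [0.26, 0.22, 0.18, 0.13, 0.10, 0.06, 0.05]
# Band sampling distribution of the synthetic surveys: over-represents the
# oldest bands relative to the reference, so raw weighted shares differ from it.
_SAMPLING_SHARES = [0.18, 0.18, 0.17, 0.15, 0.13, 0.10, 0.09]

_BAND_AGE_RANGES = {
    "55-59": (55, 59), "60-64": (60, 64), "65-69": (65, 69),
    "70-74": (70, 74), "75-79": (75, 79), "80-84": (80, 84), "85+": (85, 95),
}


def reference_age_structure() -> pd.Series:
    """Reference population age composition by 5-year band (shares sum to 1)."""
    s = pd.Series(_REFERENCE_SHARES, index=pd.Index(AGE_BANDS, name="age_band"),
                  name="share", dtype=float)
    assert abs(s.sum() - 1.0) < 1e-9
    return s


def _per_domain(value, name) -> dict:
    if isinstance(value, dict):
        missing = [d for d in DOMAINS if d not in value]
        if missing:
            raise ValueError(f"{name} lacks domains {missing}")
        return {d: float(value[d]) for d in DOMAINS}
    return {d: float(value) for d in DOMAINS}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey data-generating process.

    ``p0`` and ``rank_slope`` may be a scalar (applied to all three domains)
    or a mapping domain -> value.  ``rank_slope`` is the slope ``b`` of the
    rank-linear outcome model; the implied Erreygers index is ``2b/3``.
    """

    n_countries: int = 6
    country_tiers: dict | None = None
    persons_per_country: int = 1000
    dgp_mode: str = "rank-linear"
    p0: object = field(default_factory=lambda: {"adl": 0.166, "iadl": 0.176, "mobility": 0.578})
    rank_slope: object = field(default_factory=lambda: {"adl": -0.12855, "iadl": -0.14505, "mobility": -0.20625})
    logit_coefficients: dict = field(default_factory=lambda: {
        "rank": -0.8, "education": -0.35, "chronic": 0.6,
        "age_trend": 0.25, "country_sd": 0.15,
        # higher education shifts people up the income-rank distribution ...
        "education_rank_gradient": 0.8,
        # ... and flattens their income-disability gradient (per level)
        "education_attenuation": 0.5,
    })
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    seed: int = 0
    strata_per_country: int = 2
    clusters_per_stratum: int = 20
    income_median_by_tier: dict = field(default_factory=lambda: {
        "lower-middle": 5000.0, "upper-middle": 12000.0, "high": 30000.0})
    income_sigma: float = 0.8
    household_size_probs: tuple = (0.3, 0.5, 0.2)

    def __post_init__(self):
        if self.persons_per_country < 50:
            raise ValueError("persons_per_country must be >= 50")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.dgp_mode not in ("rank-linear", "logistic"):
            raise ValueError(f"unknown dgp_mode {self.dgp_mode!r}")
        if self.missing_mechanism not in ("MCAR", "MAR-on-age"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        if self.country_tiers is None:
            codes = self.country_codes
            self.country_tiers = {c: TIERS[i % 3] for i, c in enumerate(codes)}
        else:
            uncovered = [c for c in self.country_codes if c not in self.country_tiers]
            if uncovered:
                raise ValueError(f"country_tiers does not cover {uncovered}")
            bad = sorted({t for t in self.country_tiers.values()} - set(TIERS))
            if bad:
                raise ValueError(f"unknown tiers {bad}")
        self.p0 = _per_domain(self.p0, "p0")
        self.rank_slope = _per_domain(self.rank_slope, "rank_slope")

    @property
    def country_codes(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["household_size_probs"] = list(self.household_size_probs)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "household_size_probs" in d:
            d["household_size_probs"] = tuple(d["household_size_probs"])
        return cls(**d)


def _country_frame(cc, tier, cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.persons_per_country

    # households: sizes drawn from {1,2,3}; last household trimmed to hit n
    sizes = rng.choice([1, 2, 3], size=n, p=cfg.household_size_probs)
    cum = np.cumsum(sizes)
    n_hh = int(np.searchsorted(cum, n) + 1)
    sizes = sizes[:n_hh]
    sizes[-1] -= int(cum[n_hh - 1] - n)
    hh_index = np.repeat(np.arange(n_hh), sizes)

    # two-stage design: stratum and cluster chosen per household
    hh_stratum = rng.integers(0, cfg.strata_per_country, size=n_hh)
    hh_cluster = rng.integers(0, cfg.clusters_per_stratum, size=n_hh)
    # unequal cluster inclusion probabilities; constant within-household stage
    pi_cluster = rng.uniform(0.3, 0.9, size=(cfg.strata_per_country, cfg.clusters_per_stratum))
    pi_within = 0.7
    hh_weight = 1.0 / (pi_cluster[hh_stratum, hh_cluster] * pi_within)

    # household income: lognormal with tier-specific median; per-capita share
    median = cfg.income_median_by_tier[tier]
    hh_income = np.exp(rng.normal(np.log(median), cfg.income_sigma, size=n_hh))
    income_pc = (hh_income / sizes)[hh_index]

    weights = hh_weight[hh_index]
    R = fractional_rank(income_pc, weights)

    band_idx = rng.choice(len(AGE_BANDS), size=n, p=_SAMPLING_SHARES)
    lo = np.array([_BAND_AGE_RANGES[AGE_BANDS[i]][0] for i in band_idx])
    hi = np.array([_BAND_AGE_RANGES[AGE_BANDS[i]][1] for i in band_idx])
    age = rng.integers(lo, hi + 1)

    female = rng.random(n) < 0.53
    married = rng.random(n) < np.clip(0.75 - 0.05 * band_idx, 0.05, 0.95)
    edu_probs = {
        "lower-middle": [0.70, 0.22, 0.08],
        "upper-middle": [0.50, 0.35, 0.15],
        "high": [0.30, 0.40, 0.30],
    }[tier]
    if cfg.dgp_mode == "logistic":
        # ordered-probit draw tilted by income rank: education climbs with R
        # while keeping the tier's marginal distribution at gradient 0
        g = cfg.logit_coefficients.get("education_rank_gradient", 0.8)
        cut = stats.norm.ppf(np.cumsum(edu_probs)[:2])
        latent = rng.normal(size=n) + g * 2.0 * (R - 0.5)
        edu_idx = (latent > cut[0]).astype(int) + (latent > cut[1]).astype(int)
    else:
        edu_idx = rng.choice(3, size=n, p=edu_probs)
    chronic = (rng.random(n) < np.clip(0.45 + 0.06 * band_idx, 0, 0.95)).astype(int)
    smoke = (rng.random(n) < 0.15).astype(int)
    drink = (rng.random(n) < 0.35).astype(int)

    df = pd.DataFrame({
        "country_code": cc,
        "household_id": [f"{cc}H{i:05d}" for i in hh_index],
        "stratum_id": [f"{cc}S{s + 1}" for s in hh_stratum[hh_index]],
        "cluster_id": [f"{cc}S{s + 1}K{k + 1:02d}"
                       for s, k in zip(hh_stratum[hh_index], hh_cluster[hh_index])],
        "sample_weight": hh_weight[hh_index],
        "age_years": age,
        "age_band": pd.Categorical.from_codes(band_idx, AGE_BANDS).astype(str),
        "gender": np.where(female, "female", "male"),
        "marital": np.where(married, "married", "other"),
        "education": np.array(EDUCATION_LEVELS, dtype=object)[edu_idx],
        "chronic": chronic,
        "smoke": smoke,
        "drink": drink,
        "income_pc": income_pc,
    })

    if cfg.dgp_mode == "rank-linear":
        clipped = False
        for d in DOMAINS:
            p = cfg.p0[d] + cfg.rank_slope[d] * (R - 0.5)
            pc = np.clip(p, 0.01, 0.99)
            clipped = clipped or bool(np.any(pc != p))
            df[d] = (rng.random(n) < pc).astype(int)
        if clipped:
            warnings.warn(
                f"rank-linear probabilities clipped in {cc}; "
                "closed-form index target 2b/3 is invalid", UserWarning)
    else:
        co = cfg.logit_coefficients
        country_eff = rng.normal(0.0, co.get("country_sd", 0.15))
        att = co.get("education_attenuation", 0.5)
        rank_slope = co["rank"] * (1.0 - att * edu_idx / 2.0)
        for d in DOMAINS:
            base = np.log(cfg.p0[d] / (1 - cfg.p0[d]))
            eta = (base
                   + co.get("age_trend", 0.25) * (band_idx - band_idx.mean())
                   + rank_slope * (R - 0.5)
                   + co["education"] * edu_idx
                   + co["chronic"] * chronic
                   + country_eff)
            df[d] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    for d in DOMAINS:
        df[d] = df[d].astype("Int64")
    for c in ("chronic", "smoke", "drink"):
        df[c] = df[c].astype("Int64")
    return df


def generate_microdata(config: GeneratorConfig) -> pd.DataFrame:
    """Generate person-level survey microdata for all configured countries.

    Deterministic for a fixed ``config.seed``.  Within a household every row
    carries the same per-capita income and sampling weight.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    frames = [
        _country_frame(cc, config.country_tiers[cc], config, rng)
        for cc in config.country_codes
    ]
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "person_id", np.arange(1, len(df) + 1))
    return df


# tier means spread enough for clear tier contrasts; within-tier noise large
# enough that the six indicators' country quartiles are not collinear
_MACRO_BASE = {
    #                      lower-middle  upper-middle   high       noise sd
    "hospital_beds_per_1000": (1.5,        2.8,          4.5,       1.1),
    "sanitation_pct":         (40.0,       70.0,         92.0,      14.0),
    "rural_pct":              (60.0,       40.0,         18.0,      13.0),
    "health_exp_pct_gdp":     (4.0,        6.5,          9.5,       1.8),
    "tertiary_enrolment_pct": (20.0,       45.0,         70.0,      15.0),
    "gdp":                    (6000.0,     18000.0,      45000.0,   8000.0),
}
_PCT_VARS = {"sanitation_pct", "rural_pct", "tertiary_enrolment_pct"}


def generate_macro(config: GeneratorConfig) -> pd.DataFrame:
    """Country-level macro indicators, correlated with country income tier."""
    rng = np.random.default_rng([int(config.seed), 2])
    rows = []
    for cc in config.country_codes:
        tier_idx = TIERS.index(config.country_tiers[cc])
        row = {"country_code": cc}
        for var, (*base, sd) in _MACRO_BASE.items():
            val = base[tier_idx] + rng.normal(0.0, sd)
            if var in _PCT_VARS:
                val = float(np.clip(val, 0.0, 100.0))
            row[var] = max(val, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def inject_missingness(data: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Set explanatory-variable cells missing; outcomes and income untouched.

    MCAR: each eligible cell independently missing with ``missing_rate``.
    MAR-on-age: the per-cell rate rises linearly across ordered age bands,
    from 0.5x to 1.5x the configured rate.
    """
    if config.missing_rate == 0.0:
        return data.copy()
    rng = np.random.default_rng([int(config.seed), 3])
    out = data.copy()
    band_idx = pd.Categorical(out["age_band"], categories=AGE_BANDS).codes
    if config.missing_mechanism == "MCAR":
        rate = np.full(len(out), config.missing_rate)
    else:  # MAR-on-age
        rate = config.missing_rate * (0.5 + band_idx / (len(AGE_BANDS) - 1))
        rate = np.clip(rate, 0.0, 0.99)
    for col in EXPLANATORY_COLUMNS:
        mask = rng.random(len(out)) < rate
        if out[col].dtype == object:
            out.loc[mask, col] = np.nan
        else:
            out[col] = out[col].astype("Int64")
            out.loc[mask, col] = pd.NA
    return out
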