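"""End-to-end orchestration: simulate -> impute -> prevalence -> inequality
-> decomposition, from one configuration with reproducible seeds.

Every stage reads and writes flat CSV/TSV so each step can also be run in
isolation on intermediate files; a JSON manifest records versions, seeds and
output checksums, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concentration import ConcentrationIndex
from .imputation import ChainedImputer
from .io import (read_macro, read_microdata, read_reference_ages, write_macro,
                 write_microdata, write_reference_ages, write_table)
from .prevalence import (assign_country_quartiles, assign_income_quintiles,
                         percentage_difference, poststratify_weights,
                         weighted_prevalence)
from .rif import (MACRO_VARIABLES, RIFDecomposition, build_design_matrix,
                  pool_rubin, rif_erreygers_values)
from .concentration import fractional_rank
from .synthetic import (DOMAINS, GeneratorConfig, generate_macro,
                        generate_microdata, inject_missingness,
                        reference_age_structure)

__all__ = ["PipelineConfig", "run_pipeline",
           "prevalence_tables", "inequality_table", "decompose_domain"]

log = logging.getLogger("healthineq")


@dataclass
class PipelineConfig:
    """One-file configuration of the full analysis pipeline."""

    out_dir: str = "results"
    microdata: str | None = None
    macro: str | None = None
    ref_ages: str | None = None
    simulate: dict | None = None  # GeneratorConfig kwargs; used when no paths
    domains: list = field(default_factory=lambda: list(DOMAINS))
    impute: bool = True
    imputation: dict = field(default_factory=dict)  # ChainedImputer kwargs
    model: str = "random-intercept"
    use_weights: bool = False
    pooled_ranks: bool = False
    macro_variables: list | None = None  # default: all six indicators
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.domains:
            raise ValueError("domains must be nonempty")
        bad = sorted(set(self.domains) - set(DOMAINS))
        if bad:
            raise ValueError(f"unknown domain(s) {bad}")
        if self.simulate is None and self.microdata is None:
            raise ValueError("either input paths or a simulate block is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Stage helpers (also backing the CLI subcommands)
# ---------------------------------------------------------------------------

def prevalence_tables(micro: pd.DataFrame, ref: pd.Series,
                      domains=DOMAINS) -> pd.DataFrame:
    """Post-stratified prevalence by country and by within-country income
    quintile, one row per (domain, group)."""
    micro = micro.copy()
    micro["ps_weight"] = poststratify_weights(micro, ref)
    micro["quintile"] = assign_income_quintiles(micro)
    rows = []

    def _add(sub, domain, group):
        h = sub[domain].astype("Float64")
        keep = h.notna()
        if keep.sum() == 0:
            return
        est = weighted_prevalence(
            h[keep].astype(float), sub.loc[keep, "ps_weight"],
            strata=sub.loc[keep, "stratum_id"], clusters=sub.loc[keep, "cluster_id"],
            domain=domain, group=group)
        rows.append(est)

    for domain in domains:
        _add(micro, domain, "overall")
        for country, sub in micro.groupby("country_code", sort=True):
            _add(sub, domain, country)
        for q in range(1, 6):
            _add(micro[micro["quintile"] == q], domain, f"quintile {q}")

    return pd.DataFrame([
        {"domain": e.domain, "group": e.group, "n": e.n,
         "prevalence": e.prevalence, "ci_low": e.ci_low, "ci_high": e.ci_high}
        for e in rows])


def percentage_difference_table(prev: pd.DataFrame) -> pd.DataFrame:
    """Quintile-1 vs quintile-5 percentage difference per domain."""
    rows = []
    for domain, sub in prev.groupby("domain", sort=False):
        sub = sub.set_index("group")
        if "quintile 1" in sub.index and "quintile 5" in sub.index:
            rows.append({
                "domain": domain,
                "p_q1": sub.loc["quintile 1", "prevalence"],
                "p_q5": sub.loc["quintile 5", "prevalence"],
                "pct_difference": percentage_difference(
                    sub.loc["quintile 1", "prevalence"],
                    sub.loc["quintile 5", "prevalence"]),
            })
    return pd.DataFrame(rows)


def inequality_table(micro: pd.DataFrame, domains=DOMAINS,
                     pooled_ranks: bool = False) -> pd.DataFrame:
    """Erreygers index per country and overall, one row per (domain, country).

    The overall row uses within-country ranks and weights each country's RIF
    by its weight share (``pooled_ranks=True`` ranks incomes across the whole
    pooled sample instead).
    """
    rows = []
    for domain in domains:
        total_w = rif_sum = n_all = 0.0
        for country, sub in micro.groupby("country_code", sort=True):
            h = sub[domain].astype("Float64")
            keep = h.notna()
            if keep.sum() == 0:
                continue
            est = ConcentrationIndex().fit(
                sub.loc[keep, "income_pc"], h[keep].astype(float),
                sample_weight=sub.loc[keep, "sample_weight"])
            rows.append({"domain": domain, "country": country, "n": est.n_,
                         "index": est.value_, "se": est.se_,
                         "ci_low": est.ci95_[0], "ci_high": est.ci95_[1]})
            w = sub.loc[keep, "sample_weight"].to_numpy(dtype=float)
            total_w += w.sum()
            rif_sum += float(w @ est.rif_)
            n_all += est.n_
        if pooled_ranks:
            h = micro[domain].astype("Float64")
            keep = h.notna()
            est = ConcentrationIndex().fit(
                micro.loc[keep, "income_pc"], h[keep].astype(float),
                sample_weight=micro.loc[keep, "sample_weight"])
            overall, se, n_all = est.value_, est.se_, est.n_
        elif total_w > 0:
            overall, se = rif_sum / total_w, float("nan")
        else:
            continue
        rows.append({"domain": domain, "country": "overall", "n": int(n_all),
                     "index": overall, "se": se,
                     "ci_low": float("nan"), "ci_high": float("nan")})
    return pd.DataFrame(rows)


def _within_country_rif(micro: pd.DataFrame, domain: str) -> pd.Series:
    """Erreygers RIF against each country's own ranks and index; rows whose
    outcome is missing (e.g. a cohort without the mobility block) get NA."""
    out = pd.Series(np.nan, index=micro.index, dtype=float)
    for _, sub in micro.groupby("country_code", sort=False):
        h = sub[domain].astype("Float64")
        keep = h.notna()
        if keep.sum() == 0:
            continue
        idx = sub.index[keep]
        out.loc[idx] = rif_erreygers_values(
            h[keep].astype(float).to_numpy(),
            sub.loc[idx, "income_pc"].to_numpy(dtype=float),
            sub.loc[idx, "sample_weight"].to_numpy(dtype=float))
    return out


def macro_quartile_table(macro: pd.DataFrame) -> pd.DataFrame:
    """Country quartile (1..4) of each macro indicator."""
    out = pd.DataFrame({"country_code": macro["country_code"]})
    for var in MACRO_VARIABLES:
        q = assign_country_quartiles(macro, var)
        out[var] = out["country_code"].map(q).astype(int)
    return out


def decompose_domain(micro: pd.DataFrame, macro: pd.DataFrame, domain: str,
                     m: int = 5, seed: int = 0, model: str = "random-intercept",
                     use_weights: bool = False, imputer_kwargs: dict | None = None,
                     macro_variables=None):
    """Impute (if needed), compute per-person RIFs and pool the two-level
    decomposition over the completed datasets with Rubin's rules."""
    micro = micro[micro[domain].notna()].reset_index(drop=True)
    quart = macro_quartile_table(macro)

    has_missing = micro[["marital", "education", "chronic", "smoke", "drink"]].isna().any().any()
    if has_missing:
        kwargs = {"m": m, "seed": seed, **(imputer_kwargs or {})}
        completed = ChainedImputer(**kwargs).fit(micro).imputations_
    else:
        completed = [micro]

    fits = []
    for data in completed:
        rif = _within_country_rif(data, domain)
        X = build_design_matrix(data, quart, macro_variables=macro_variables)
        est = RIFDecomposition(model=model, use_weights=use_weights)
        est.fit(X, rif.to_numpy(), data["country_code"].to_numpy(),
                sample_weight=data["sample_weight"].to_numpy() if use_weights else None)
        fits.append(est.result_)
    return pool_rubin(fits)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns the result bundle: prevalence, percentage-difference, index and
    decomposition tables plus the manifest dictionary.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    if config.simulate is not None:
        gen_kwargs = dict(config.simulate)
        gen_kwargs.setdefault("seed", config.seed)
        gen = GeneratorConfig(**gen_kwargs)
        micro = inject_missingness(generate_microdata(gen), gen)
        macro = generate_macro(gen)
        ref = reference_age_structure()
        write_microdata(micro, out / "microdata.csv")
        write_macro(macro, out / "macro.csv")
        write_reference_ages(ref, out / "reference_ages.csv")
        micro = read_microdata(out / "microdata.csv")  # round-trip = validation
        log.info("simulate: %d persons, %d countries", len(micro), gen.n_countries)
    else:
        micro = read_microdata(config.microdata)
        macro = read_macro(config.macro)
        ref = (read_reference_ages(config.ref_ages)
               if config.ref_ages else reference_age_structure())

    t0 = time.perf_counter()
    prev = prevalence_tables(micro, ref, config.domains)
    write_table(prev, out / "prevalence.tsv",
                {"prevalence": "percent", "ci_low": "percent", "ci_high": "percent"})
    pdiff = percentage_difference_table(prev)
    write_table(pdiff, out / "percentage_difference.tsv",
                {"p_q1": "percent", "p_q5": "percent", "pct_difference": "percent"})
    log.info("prevalence: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    ineq = inequality_table(micro, config.domains, config.pooled_ranks)
    write_table(ineq, out / "concentration_index.tsv",
                {"index": "index", "se": "index", "ci_low": "index", "ci_high": "index"})
    log.info("inequality: %.2fs", time.perf_counter() - t0)

    decompositions = {}
    for domain in config.domains:
        t0 = time.perf_counter()
        common = dict(seed=config.seed, model=config.model,
                      use_weights=config.use_weights,
                      macro_variables=config.macro_variables)
        if config.impute:
            res = decompose_domain(micro, macro, domain,
                                   imputer_kwargs=dict(config.imputation), **common)
        else:
            complete = micro.dropna(
                subset=["marital", "education", "chronic", "smoke", "drink"])
            res = decompose_domain(complete, macro, domain, **common)
        decompositions[domain] = res
        table = res.terms.rename_axis("term").reset_index()
        table["significant(0.05)"] = (table["p_value"] < 0.05).map({True: "yes", False: "no"})
        write_table(table, out / f"decomposition_{domain}.tsv",
                    {"estimate": "index", "se": "index", "p_value": "%.4g"})
        log.info("decompose %s [%s]: %.2fs", domain, res.model, time.perf_counter() - t0)

    manifest = {
        "package": "healthineq",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "domains": list(config.domains),
        "n_persons": int(len(micro)),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    stable = {k: v for k, v in manifest.items() if k != "runtime_s"}
    (out / "manifest.json").write_text(json.dumps(stable, indent=2) + "\n",
                                       encoding="utf-8")

    return {"prevalence": prev, "percentage_difference": pdiff,
            "concentration_index": ineq, "decomposition": decompositions,
            "manifest": manifest}
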