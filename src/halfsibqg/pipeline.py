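"""End-to-end orchestration of the analysis stages.

``run_pipeline`` chains respirometry processing, phenotypic ANOVA, animal-
model fits (per population x environment, univariate per trait and
bivariate per trait pair, complete ACRE vs constrained CRE), genetic-
parameter extraction and the between-environment G-matrix comparison, and
renders a human-readable report.  Every stochastic stage derives its seed
deterministically from the run seed, so a rerun reproduces all posterior
summaries exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .animal_model import AnimalModelSpec, MCMCConfig, dic, gibbs_fit
from .genetics import (
    GeneticParamEstimate,
    component_report,
    genetic_correlation,
    heritability,
    significance,
)
from .gmatrix import jackknife_pseudovalues, manova_compare, residualize
from .pedigree import Pedigree, write_pedigree
from .phenostats import AnovaSpec, fit_mixed_anova, slope_homogeneity
from .phenotypes import TRAITS, PhenotypeTable, log10_transform, write_phenotypes
from .simulate import SimulationConfig, simulate_design, simulate_respirometry_day

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, chain settings, simulation settings and analysis toggles."""

    out_dir: str = "out"
    seed: int = 0
    mcmc: MCMCConfig = None
    sim: SimulationConfig = None
    traits: tuple[str, ...] = TRAITS
    fit_pairs: bool = True
    populations: tuple[str, ...] | None = None   # None = all in the data
    environments: tuple[str, ...] | None = None
    force: bool = False

    def __post_init__(self):
        if self.mcmc is None:
            self.mcmc = MCMCConfig(seed=self.seed)
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)


def _subseed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31))


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    d = asdict(cfg)
    d.pop("out_dir", None)     # hash the scientific config, not paths/modes
    d.pop("force", None)
    blob = json.dumps(d, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
def run_simulate(cfg: RunConfig) -> dict:
    """Write synthetic pedigree/phenotype/trace/truth files plus a manifest."""
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not cfg.force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True / --force to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    ped, tab, truth = simulate_design(cfg.sim)
    write_pedigree(ped, out / "pedigree.csv")
    write_phenotypes(tab, out / "phenotypes.csv")
    truth.breeding_values.to_csv(out / "truth_breeding_values.csv")
    truth.dam_effects.to_csv(out / "truth_dam_effects.csv", index=False)
    truth.line_effects.to_csv(out / "truth_line_effects.csv", index=False)
    records = simulate_respirometry_day(seed=_subseed(cfg.sim.seed, 999))
    rows = []
    for k, rec in enumerate(records):
        for t, ch, v in zip(rec.times, rec.chambers, rec.ppm):
            rows.append((k, t, ch, v))
    pd.DataFrame(rows, columns=["record", "time", "chamber", "ppm"]).to_csv(
        out / "traces.csv", index=False
    )
    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "files": ["pedigree.csv", "phenotypes.csv", "traces.csv",
                  "truth_breeding_values.csv", "truth_dam_effects.csv",
                  "truth_line_effects.csv"],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ----------------------------------------------------------------------
def run_phenotypic_stats(tab_log: PhenotypeTable) -> dict:
    """Mixed ANOVA per trait plus slope-homogeneity checks for RMR."""
    # keep only factors with >=2 levels in these data
    usable = [
        f for f in ("population", "ethanol", "sex")
        if tab_log.df[f].nunique() >= 2
    ]
    interactions = tuple(
        (a, b) for k, a in enumerate(usable) for b in usable[k + 1:]
    )
    random_line = tab_log.df.groupby("population")["line"].nunique().min() >= 2
    anovas = {}
    for t in TRAITS:
        if tab_log.df[t].notna().sum() < 10:
            continue
        spec = AnovaSpec(
            response=t,
            fixed=tuple(usable),
            interactions=interactions,
            covariate="mb" if t == "rmr" else None,
            random_line=random_line,
        )
        anovas[t] = fit_mixed_anova(tab_log, spec)
    slopes = {}
    for factor in ("sex", "ethanol"):
        try:
            slopes[factor] = slope_homogeneity(tab_log, factor)
        except Exception as exc:   # degenerate subsets are fine to skip
            logger.warning("slope homogeneity for %s skipped: %s", factor, exc)
    return {"anova": anovas, "slopes": slopes}


def significant_main_effects(anovas: dict, alpha: float = 0.05) -> dict:
    """Per trait, the significant main-effect factors (for residualization)."""
    out = {}
    for trait, table in anovas.items():
        main = table[
            table["effect"].isin(["population", "ethanol", "sex", "chamber", "hour"])
        ]
        out[trait] = tuple(main.loc[main["p"] < alpha, "effect"])
    return out


# ----------------------------------------------------------------------
def fit_condition(
    tab_log: PhenotypeTable,
    ped: Pedigree,
    cfg: RunConfig,
    population: str,
    environment: str,
) -> dict:
    """All animal-model fits for one population x environment cell.

    Univariate ACRE+CRE per trait; bivariate ACRE+CRE per trait pair.
    Returns {"h2": {...}, "rg": {...}, "fits": {...}} with significance
    decisions attached.
    """
    mask = (tab_log.df["population"] == population) & (
        tab_log.df["ethanol"] == environment
    )
    sub = PhenotypeTable(df=tab_log.df[mask].reset_index(drop=True), scale="log10")
    results = {"h2": {}, "rg": {}, "fits": {}}
    fit_k = 0
    for t in cfg.traits:
        spec = AnimalModelSpec.for_trait(t)
        spec_cre = AnimalModelSpec.for_trait(t, include_additive=False)
        mc = MCMCConfig(**{**_mc_kwargs(cfg.mcmc), "seed": _subseed(cfg.seed, fit_k)})
        mc_cre = MCMCConfig(**{**_mc_kwargs(cfg.mcmc), "seed": _subseed(cfg.seed, fit_k + 1)})
        fit_k += 2
        acre = gibbs_fit(sub, ped, spec, mc, label=f"{population}/{environment}/{t}")
        cre = gibbs_fit(sub, ped, spec_cre, mc_cre)
        est = heritability(acre)
        est.dic_complete, est.dic_constrained = dic(acre)[0], dic(cre)[0]
        decision = significance(est, est.dic_complete, est.dic_constrained)
        results["h2"][t] = (est, decision)
        results["fits"][(population, environment, t)] = (acre, cre)
    if cfg.fit_pairs:
        for t1, t2 in combinations(cfg.traits, 2):
            spec = AnimalModelSpec.for_trait(t1, t2)
            spec_cre = AnimalModelSpec.for_trait(t1, t2, include_additive=False)
            mc = MCMCConfig(**{**_mc_kwargs(cfg.mcmc), "seed": _subseed(cfg.seed, fit_k)})
            mc_cre = MCMCConfig(**{**_mc_kwargs(cfg.mcmc), "seed": _subseed(cfg.seed, fit_k + 1)})
            fit_k += 2
            acre = gibbs_fit(sub, ped, spec, mc,
                             label=f"{population}/{environment}/{t1}-{t2}")
            cre = gibbs_fit(sub, ped, spec_cre, mc_cre)
            est = genetic_correlation(acre)
            est.dic_complete, est.dic_constrained = dic(acre)[0], dic(cre)[0]
            decision = significance(est, est.dic_complete, est.dic_constrained)
            results["rg"][(t1, t2)] = (est, decision)
            results["fits"][(population, environment, f"{t1}-{t2}")] = (acre, cre)
    return results


def _mc_kwargs(mc: MCMCConfig) -> dict:
    return {
        "n_iter": mc.n_iter,
        "burn_in": mc.burn_in,
        "thin": mc.thin,
        "prior_partition": mc.prior_partition,
    }


def parameter_table(conditions: dict) -> pd.DataFrame:
    """Table-1-style summary: one row per parameter per condition, with the
    significance flag standing in for the table's bolding."""
    rows = []
    for (pop, env), res in conditions.items():
        for t, (est, dec) in res["h2"].items():
            rows.append(
                (pop, env, "h2", t, est.mode, est.mean, est.hpd_low,
                 est.hpd_high, dec["significant"], est.delta_dic)
            )
        for (t1, t2), (est, dec) in res["rg"].items():
            rows.append(
                (pop, env, "rg", f"{t1}-{t2}", est.mode, est.mean,
                 est.hpd_low, est.hpd_high, dec["significant"], est.delta_dic)
            )
    return pd.DataFrame(
        rows,
        columns=["population", "environment", "parameter", "trait", "mode",
                 "mean", "hpd_low", "hpd_high", "significant", "delta_dic"],
    )


# ----------------------------------------------------------------------
def run_gmatrix_compare(
    tab_log: PhenotypeTable,
    ped: Pedigree,
    traits: tuple[str, ...],
    resid_factors: tuple[str, ...] = ("sex",),
) -> dict:
    """Per-population jackknife-MANOVA comparison of the two environments'
    G matrices, on trait residuals from significant nuisance effects."""
    out = {}
    for pop, sub in tab_log.df.groupby("population", sort=True):
        sub_tab = PhenotypeTable(df=sub.reset_index(drop=True), scale="log10")
        resid = residualize(sub_tab, resid_factors)
        ps = jackknife_pseudovalues(resid, ped, traits=traits)
        out[pop] = manova_compare(ps)
    return out


# ----------------------------------------------------------------------
def render_report(
    param_tab: pd.DataFrame,
    comp_tab: pd.DataFrame,
    manova: dict,
) -> str:
    lines = ["Genetic parameters (per population x environment)",
             "=" * 60]
    with pd.option_context("display.width", 120, "display.max_rows", None):
        lines.append(param_tab.round(4).to_string(index=False))
        lines.append("")
        lines.append("G-matrix comparison between environments (jackknife MANOVA)")
        lines.append("=" * 60)
        for pop, res in manova.items():
            lines.append(
                f"{pop}: Wilks' lambda = {res.wilks_lambda:.3f}, "
                f"F_{res.df_num},{res.df_den} = {res.F:.2f}, p = {res.p:.4g}"
            )
        lines.append("")
        lines.append("Variance/covariance components")
        lines.append("=" * 60)
        lines.append(comp_tab.round(5).to_string(index=False))
    return "\n".join(lines) + "\n"


def run_pipeline(
    cfg: RunConfig,
    ped: Pedigree,
    tab_raw: PhenotypeTable,
) -> dict:
    """Execute phenotypic stats -> animal models -> genetic parameters ->
    G-matrix comparison, write CSV outputs and a text report.

    Returns a dict with parameter_table, component_table, manova results
    and the phenotypic-stats tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab_log = log10_transform(tab_raw)
    tab_log.validate_against(ped)

    pheno = run_phenotypic_stats(tab_log)

    pops = cfg.populations or tuple(sorted(tab_log.df["population"].unique()))
    envs = cfg.environments or tuple(sorted(tab_log.df["ethanol"].unique()))
    conditions = {}
    for pop in pops:
        for env in envs:
            logger.info("fitting %s / %s%% ethanol", pop, env)
            conditions[(pop, env)] = fit_condition(tab_log, ped, cfg, pop, env)

    param_tab = parameter_table(conditions)
    all_fits = {}
    for res in conditions.values():
        all_fits.update(res["fits"])
    comp_tab = component_report(all_fits)

    manova = {}
    if len(envs) == 2 and cfg.fit_pairs and len(cfg.traits) >= 2:
        sub = tab_log.df[
            tab_log.df["population"].isin(pops) & tab_log.df["ethanol"].isin(envs)
        ]
        # residualize on the main effects the phenotypic ANOVA found
        # significant (sex always included; population/ethanol effects are
        # harmless to remove since each jackknife is within-group)
        sig = significant_main_effects(pheno["anova"])
        factors = {"sex"}
        for effs in sig.values():
            factors.update(e for e in effs if e in ("sex", "ethanol", "population"))
        manova = run_gmatrix_compare(
            PhenotypeTable(df=sub.reset_index(drop=True), scale="log10"),
            ped,
            traits=cfg.traits,
            resid_factors=tuple(sorted(factors)),
        )

    param_tab.to_csv(out / "parameter_table.csv", index=False)
    comp_tab.to_csv(out / "components.csv", index=False)
    if manova:
        pd.DataFrame(
            [
                (pop, r.wilks_lambda, r.F, r.df_num, r.df_den, r.p)
                for pop, r in manova.items()
            ],
            columns=["population", "wilks_lambda", "F", "df_num", "df_den", "p"],
        ).to_csv(out / "manova.csv", index=False)
    report = render_report(param_tab, comp_tab, manova)
    (out / "report.txt").write_text(report)
    return {
        "parameter_table": param_tab,
        "component_table": comp_tab,
        "manova": manova,
        "phenotypic": pheno,
        "report": report,
    }
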