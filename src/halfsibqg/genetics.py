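"""Genetic parameters from posterior samples.

Heritability is computed per retained draw as h2 = A/(A+C+R+E), so every
draw lies in (0, 1) by construction; the genetic correlation is computed
per draw from the bivariate additive matrix as cov_A/sqrt(VA1 VA2) and is
bounded in [-1, 1] for positive-definite draws.  Point estimates are the
kernel-density posterior mode (posterior mean also reported); intervals
are 95% highest-posterior-density.  A parameter is called significant only
if its HPD interval excludes zero (inclusive-boundary rule) *and* the
complete model beats the additive-free constrained model on DIC.

Note that the heritability of metabolic rate is computed from the model
that includes the body-mass covariate, i.e. it is a mass-adjusted
heritability, not the heritability of absolute metabolic rate.
"""

from __future__ import annotations

from dataclasses import dataclass
import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .animal_model import ModelError, PosteriorSample, dic


@dataclass
class GeneticParamEstimate:
    kind: str                       # "h2" or "rg"
    traits: tuple[str, ...]
    mode: float
    mean: float
    hpd_low: float
    hpd_high: float
    draws: np.ndarray
    dic_complete: float | None = None
    dic_constrained: float | None = None

    @property
    def delta_dic(self) -> float | None:
        if self.dic_complete is None or self.dic_constrained is None:
            return None
        return self.dic_complete - self.dic_constrained


def _posterior_mode(draws: np.ndarray) -> float:
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _hpd(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0]), float(draws[0])
    lo, hi = az.hdi(draws, hdi_prob=prob)
    return float(lo), float(hi)


def heritability(ps: PosteriorSample) -> GeneticParamEstimate:
    """h2 = A/(A+C+R+E) per draw, with posterior mode and 95% HPD."""
    if ps.n_draws == 0:
        raise ModelError("empty chain")
    if ps.traits is None or len(ps.traits) != 1:
        raise ModelError("heritability requires a univariate fit")
    if "A" not in ps.components:
        raise ModelError("fit has no additive component")
    total = sum(ps.components[c] for c in ps.components)
    draws = ps.components["A"] / total
    lo, hi = _hpd(draws)
    return GeneticParamEstimate(
        kind="h2",
        traits=ps.traits,
        mode=_posterior_mode(draws),
        mean=float(draws.mean()),
        hpd_low=lo,
        hpd_high=hi,
        draws=draws,
    )


def genetic_correlation(ps: PosteriorSample) -> GeneticParamEstimate:
    """r_g = cov_A / sqrt(VA1 VA2) per draw of the bivariate additive matrix."""
    if ps.n_draws == 0:
        raise ModelError("empty chain")
    if len(ps.traits) != 2:
        raise ModelError("genetic correlation requires a bivariate fit")
    G = ps.components["A"]
    det = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] ** 2
    if np.any(G[:, 0, 0] <= 0) or np.any(G[:, 1, 1] <= 0) or np.any(det < -1e-12):
        raise ModelError("non-positive-definite additive draw encountered")
    draws = G[:, 0, 1] / np.sqrt(G[:, 0, 0] * G[:, 1, 1])
    lo, hi = _hpd(draws)
    return GeneticParamEstimate(
        kind="rg",
        traits=ps.traits,
        mode=_posterior_mode(draws),
        mean=float(draws.mean()),
        hpd_low=lo,
        hpd_high=hi,
        draws=draws,
    )


def significance(
    est: GeneticParamEstimate,
    dic_complete: float,
    dic_constrained: float,
) -> dict:
    """Joint decision: HPD interval excludes zero AND DIC favours the
    complete model.  The zero boundary counts as overlap (conservative)."""
    ci_excludes_zero = (est.hpd_low > 0) or (est.hpd_high < 0)
    dic_favors = dic_complete < dic_constrained
    return {
        "parameter": est.kind,
        "traits": est.traits,
        "ci_excludes_zero": bool(ci_excludes_zero),
        "dic_favors_complete": bool(dic_favors),
        "significant": bool(ci_excludes_zero and dic_favors),
        "delta_dic": float(dic_complete - dic_constrained),
    }


def component_report(fits: dict) -> pd.DataFrame:
    """Long-format variance/covariance component table.

    ``fits`` maps a label tuple (population, environment, trait-or-pair
    string) to either a PosteriorSample or a (complete, constrained) pair
    of PosteriorSamples; the constrained fit supplies the comparison DIC.
    One row per fit with the posterior mode and HPD of each component.
    """
    if len(set(fits)) != len(fits):
        raise ValueError("duplicate fit labels")
    rows = []
    for label, fit in fits.items():
        if isinstance(fit, tuple):
            complete, constrained = fit
            dic_cre = dic(constrained)[0]
        else:
            complete, dic_cre = fit, np.nan
        dic_acre = dic(complete)[0]
        pop, env, trait = label
        for name, arr in complete.components.items():
            if arr.ndim == 1:
                entries = {name: arr}
            else:
                t1, t2 = complete.traits
                entries = {
                    f"{name}({t1},{t1})": arr[:, 0, 0],
                    f"{name}({t1},{t2})": arr[:, 0, 1],
                    f"{name}({t2},{t2})": arr[:, 1, 1],
                }
            for comp_label, draws in entries.items():
                lo, hi = _hpd(draws)
                rows.append(
                    (pop, env, trait, comp_label, _posterior_mode(draws),
                     float(draws.mean()), lo, hi, dic_acre, dic_cre)
                )
    return pd.DataFrame(
        rows,
        columns=["population", "environment", "trait", "component", "mode",
                 "mean", "hpd_low", "hpd_high", "dic_complete", "dic_constrained"],
    )
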