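"""Bayesian animal model fitted by Gibbs sampling.

The model for a trait y (log10 scale) is

    y = X b + Z_a a + Z_c c + Z_r r + e

with a ~ N(0, A sigma2_A) the breeding values (A the pedigree numerator
relationship matrix), c ~ N(0, I sigma2_C) the common-environment (dam)
effects, r ~ N(0, I sigma2_R) the replicate-line effects and e the
residual.  Fixed effects are sex, plus metabolic chamber, record hour and
a log10 body-mass covariate for metabolic rate.  The bivariate model
replaces each scalar variance with a 2x2 covariance matrix (inverse-
Wishart full conditionals) and supplies the additive covariance needed for
genetic correlations.

Sampling is blocked Gibbs on the latent-variable parameterization.  The
breeding-value block exploits a one-off spectral trick: with A = L L' and
L' Z_a' Z_a L = Q Lam Q', the transformed coordinates v (a = L Q v) have a
*diagonal* full-conditional precision Lam/sigma2_E + I/sigma2_A, so the
per-iteration cost is two dense matrix-vector products regardless of chain
length.  Variance components have conjugate scaled-inverse-chi-squared
(univariate) or inverse-Wishart (bivariate) full conditionals.

Priors follow the convention of partitioning the sample phenotypic
variance T equally among the random effects: each component's prior is
centred on T/k for k included random components, with belief nu = 1
(univariate) or nu = n_traits (bivariate).  The deviance trace stored for
DIC is conditional on the latent effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, additive_relationship
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2 * np.pi))


class ModelError(ValueError):
    pass


@dataclass
class AnimalModelSpec:
    """Which trait(s) to model and which effects to include."""

    traits: tuple[str, ...]
    fixed: tuple[str, ...] = ("sex",)
    covariate: str | None = None
    include_additive: bool = True   # False gives the constrained (CRE) model
    include_dam: bool = True
    include_line: bool = True

    def __post_init__(self):
        if isinstance(self.traits, str):
            self.traits = (self.traits,)
        if len(self.traits) not in (1, 2):
            raise ModelError("1 (univariate) or 2 (bivariate) traits required")
        if len(set(self.traits)) != len(self.traits):
            raise ModelError("bivariate spec must name two distinct traits")

    @classmethod
    def for_trait(cls, *traits: str, include_additive: bool = True) -> "AnimalModelSpec":
        """Default spec: sex fixed everywhere; chamber/hour/mass for RMR."""
        if "rmr" in traits:
            return cls(
                traits=tuple(traits),
                fixed=("sex", "chamber", "hour"),
                covariate="mb",
                include_additive=include_additive,
            )
        return cls(traits=tuple(traits), include_additive=include_additive)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class MCMCConfig:
    """Chain settings.  Desk-scale defaults; ``paper_scale`` gives the
    long-run settings (10^6 iterations, 10^5 burn-in, thin 500)."""

    n_iter: int = 60_000
    burn_in: int = 10_000
    thin: int = 25
    seed: int = 0
    prior_partition: int | None = None  # default: number of random components

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ModelError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_iter=1_000_000, burn_in=100_000, thin=500, seed=seed)

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class Prior:
    """Per-component prior: scaled-inv-chi2(nu, s2) or inv-Wishart(nu, Psi)."""

    components: dict
    n_traits: int
    phenotypic_variance: np.ndarray

    def expectation(self, name: str):
        nu, s = self.components[name]
        if self.n_traits == 1:
            return float(nu * s / (nu - 2)) if nu > 2 else float(s)
        return s / (nu - self.n_traits - 1) if nu > self.n_traits + 1 else s


def solve_prior_scale(target: float, nu: float) -> float:
    """Scale of a scaled-inv-chi2(nu, s2) whose centre is ``target``.

    For nu > 2 the inverse-gamma mean relation E = nu s2/(nu-2) is
    inverted; for nu <= 2 (no finite mean) the scale itself is the centre.
    """
    return target * (nu - 2) / nu if nu > 2 else target


def build_prior(
    tab: PhenotypeTable, spec: AnimalModelSpec, cfg: MCMCConfig
) -> Prior:
    """Equal-partition prior: each component centred on T / n_components."""
    comps = _component_names(spec)
    y = tab.df[list(spec.traits)].dropna()
    if len(y) < 2:
        raise ModelError("need >= 2 observations to set the prior")
    T = y.var(ddof=1).to_numpy()
    if np.any(T <= 0):
        raise ModelError("zero phenotypic variance")
    k = cfg.prior_partition or len(comps)
    out = {}
    for name in comps:
        if spec.n_traits == 1:
            out[name] = (1.0, solve_prior_scale(float(T[0]) / k, 1.0))
        else:
            out[name] = (float(spec.n_traits), np.diag(T / k))
    return Prior(components=out, n_traits=spec.n_traits, phenotypic_variance=T)


def _component_names(spec: AnimalModelSpec) -> list[str]:
    names = []
    if spec.include_additive:
        names.append("A")
    if spec.include_dam:
        names.append("C")
    if spec.include_line:
        names.append("R")
    names.append("E")
    return names


@dataclass
class PosteriorSample:
    """Retained Gibbs draws for one animal-model fit."""

    traits: tuple[str, ...]
    components: dict                 # name -> (k,) or (k, 2, 2) arrays
    fixed: np.ndarray                # (k, p) or (k, p, n_traits)
    fixed_names: list[str]
    deviance: np.ndarray | None
    d_at_mean: float | None
    n_obs: int
    spec: AnimalModelSpec
    cfg: MCMCConfig
    label: str = ""

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.components.values())))


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------
def _design(tab: PhenotypeTable, ped: Pedigree, spec: AnimalModelSpec):
    if tab.scale != "log10":
        raise ModelError("animal model expects a log10-transformed table")
    need = list(spec.traits) + [f for f in spec.fixed] + (
        [spec.covariate] if spec.covariate else []
    )
    df = tab.df
    keep = df[need].notna().all(axis=1)
    for f in spec.fixed:
        keep &= df[f].astype(str) != ""
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d rows with missing trait/factor values", dropped)
    df = df[keep]
    if len(df) < 3:
        raise ModelError("too few complete cases")

    Y = df[list(spec.traits)].to_numpy(dtype=float)
    cols = [np.ones((len(df), 1))]
    names = ["intercept"]
    for f in spec.fixed:
        dummies = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True)
        cols.append(dummies.to_numpy(dtype=float))
        names += list(dummies.columns)
    if spec.covariate:
        cov = df[spec.covariate].to_numpy(dtype=float)
        cols.append((cov - cov.mean())[:, None])
        names.append(spec.covariate)
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design matrix is rank deficient")

    ped_sub = ped.subset(df["id"].tolist())
    parent = {i: (s, d) for i, s, d in ped_sub.entries}
    obs_idx = np.array([ped_sub.index_of(i) for i in df["id"]])

    dam_idx = None
    if spec.include_dam:
        dams = [parent[i][1] for i in df["id"]]
        if any(d is None for d in dams):
            raise ModelError("dam unknown for some observations")
        dam_codes, _ = pd.factorize(pd.Series(dams))
        dam_idx = dam_codes
    line_idx = None
    if spec.include_line:
        line_codes, _ = pd.factorize(df["line"].astype(str))
        line_idx = line_codes
    return df, Y, X, names, ped_sub, obs_idx, dam_idx, line_idx


def _spectral_operator(ped_sub: Pedigree, obs_idx: np.ndarray):
    """T_obs such that a_obs = T_obs v with v having diagonal conditional
    precision Lam/sE + I/sA; also returns the eigenvalues Lam."""
    A = additive_relationship(ped_sub).values
    n = A.shape[0]
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    counts = np.bincount(obs_idx, minlength=n).astype(float)
    M = (L.T * counts) @ L
    lam, Q = np.linalg.eigh(M)
    lam = np.clip(lam, 0.0, None)
    T_full = L @ Q
    return T_full[obs_idx, :], lam


def _inv_chi2(rng, nu, s2, extra_df, ss):
    return (nu * s2 + ss) / rng.chisquare(nu + extra_df)


def _inv_wishart(rng, df, scale):
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


# ----------------------------------------------------------------------
def gibbs_fit(
    tab: PhenotypeTable,
    ped: Pedigree,
    spec: AnimalModelSpec,
    cfg: MCMCConfig,
    prior: Prior | None = None,
    label: str = "",
) -> PosteriorSample:
    """Fit the animal model by blocked Gibbs sampling.

    Returns the retained (post burn-in, thinned) draws of every variance
    component, the fixed effects, and a conditional deviance trace for DIC.
    Exactly reproducible from ``cfg.seed``.
    """
    if prior is None:
        prior = build_prior(tab, spec, cfg)
    df, Y, X, fixed_names, ped_sub, obs_idx, dam_idx, line_idx = _design(
        tab, ped, spec
    )
    if spec.n_traits == 1:
        return _gibbs_univariate(
            Y[:, 0], X, fixed_names, ped_sub, obs_idx, dam_idx, line_idx,
            spec, cfg, prior, label
        )
    return _gibbs_bivariate(
        Y, X, fixed_names, ped_sub, obs_idx, dam_idx, line_idx,
        spec, cfg, prior, label
    )


def _gibbs_univariate(
    y, X, fixed_names, ped_sub, obs_idx, dam_idx, line_idx, spec, cfg, prior, label
):
    rng = np.random.default_rng(cfg.seed)
    m, p = X.shape
    XtX = X.T @ X
    cholX = np.linalg.cholesky(XtX)

    use_a = spec.include_additive
    if use_a:
        T_obs, lam = _spectral_operator(ped_sub, obs_idx)
        n = T_obs.shape[1]
    use_c = spec.include_dam
    if use_c:
        nc = dam_idx.max() + 1
        counts_c = np.bincount(dam_idx, minlength=nc).astype(float)
    use_r = spec.include_line
    if use_r:
        nr = line_idx.max() + 1
        counts_r = np.bincount(line_idx, minlength=nr).astype(float)

    T_var = float(prior.phenotypic_variance[0])
    sA = sC = sR = sE = T_var / 4
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    a_obs = np.zeros(m)
    c = np.zeros(nc) if use_c else None
    r = np.zeros(nr) if use_r else None
    v = np.zeros(n) if use_a else None

    keep = cfg.n_retained
    out = {name: np.empty(keep) for name in _component_names(spec)}
    fixed_out = np.empty((keep, p))
    dev_out = np.empty(keep)
    fitted_sum = np.zeros(m)
    sE_sum = 0.0

    k = 0
    for it in range(cfg.n_iter):
        c_obs = c[dam_idx] if use_c else 0.0
        r_obs = r[line_idx] if use_r else 0.0
        xb = X @ b
        if use_a:
            resid = y - xb - c_obs - r_obs
            rhs = T_obs.T @ resid / sE
            prec = lam / sE + 1.0 / sA
            v = rhs / prec + rng.standard_normal(n) / np.sqrt(prec)
            a_obs = T_obs @ v
            nuA, sA0 = prior.components["A"]
            sA = _inv_chi2(rng, nuA, sA0, n, v @ v)
        if use_c:
            resid = y - xb - a_obs - r_obs
            sums = np.bincount(dam_idx, weights=resid, minlength=nc)
            prec = counts_c / sE + 1.0 / sC
            c = sums / sE / prec + rng.standard_normal(nc) / np.sqrt(prec)
            c_obs = c[dam_idx]
            nuC, sC0 = prior.components["C"]
            sC = _inv_chi2(rng, nuC, sC0, nc, c @ c)
        if use_r:
            resid = y - xb - a_obs - c_obs
            sums = np.bincount(line_idx, weights=resid, minlength=nr)
            prec = counts_r / sE + 1.0 / sR
            r = sums / sE / prec + rng.standard_normal(nr) / np.sqrt(prec)
            r_obs = r[line_idx]
            nuR, sR0 = prior.components["R"]
            sR = _inv_chi2(rng, nuR, sR0, nr, r @ r)
        resid = y - a_obs - c_obs - r_obs
        bm = np.linalg.solve(XtX, X.T @ resid)
        b = bm + np.sqrt(sE) * np.linalg.solve(cholX.T, rng.standard_normal(p))
        resid = resid - X @ b
        sse = resid @ resid
        nuE, sE0 = prior.components["E"]
        sE = _inv_chi2(rng, nuE, sE0, m, sse)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            if use_a:
                out["A"][k] = sA
            if use_c:
                out["C"][k] = sC
            if use_r:
                out["R"][k] = sR
            out["E"][k] = sE
            fixed_out[k] = b
            dev_out[k] = m * (LOG2PI + np.log(sE)) + sse / sE
            fitted = y - resid
            fitted_sum += fitted
            sE_sum += sE
            k += 1

    fitted_mean = fitted_sum / k
    sE_mean = sE_sum / k
    rme = y - fitted_mean
    d_at_mean = m * (LOG2PI + np.log(sE_mean)) + (rme @ rme) / sE_mean
    return PosteriorSample(
        traits=spec.traits,
        components={name: arr[:k] for name, arr in out.items()},
        fixed=fixed_out[:k],
        fixed_names=fixed_names,
        deviance=dev_out[:k],
        d_at_mean=float(d_at_mean),
        n_obs=m,
        spec=spec,
        cfg=cfg,
        label=label,
    )


def _gibbs_bivariate(
    Y, X, fixed_names, ped_sub, obs_idx, dam_idx, line_idx, spec, cfg, prior, label
):
    rng = np.random.default_rng(cfg.seed)
    m, p = X.shape
    XtX = X.T @ X
    cholX = np.linalg.cholesky(XtX)

    use_a = spec.include_additive
    if use_a:
        T_obs, lam = _spectral_operator(ped_sub, obs_idx)
        n = T_obs.shape[1]
    use_c = spec.include_dam
    if use_c:
        nc = dam_idx.max() + 1
        counts_c = np.bincount(dam_idx, minlength=nc).astype(float)
    use_r = spec.include_line
    if use_r:
        nr = line_idx.max() + 1
        counts_r = np.bincount(line_idx, minlength=nr).astype(float)

    T2 = np.diag(prior.phenotypic_variance / 4)
    Ga = Cc = Rr = Re = T2.copy()
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    a_obs = np.zeros((m, 2))
    c = np.zeros((nc, 2)) if use_c else None
    r = np.zeros((nr, 2)) if use_r else None

    keep = cfg.n_retained
    out = {name: np.empty((keep, 2, 2)) for name in _component_names(spec)}
    fixed_out = np.empty((keep, p, 2))
    dev_out = np.empty(keep)
    fitted_sum = np.zeros((m, 2))
    Re_sum = np.zeros((2, 2))

    def mvn_block(prec, rhs):
        """Sample rows v_i ~ N(prec_i^{-1} rhs_i, prec_i^{-1}) (batched 2x2)."""
        mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
        ch = np.linalg.cholesky(prec)
        z = rng.standard_normal(mean.shape)
        dev = np.linalg.solve(np.transpose(ch, (0, 2, 1)), z[:, :, None])[:, :, 0]
        return mean + dev

    k = 0
    for it in range(cfg.n_iter):
        Re_inv = np.linalg.inv(Re)
        c_obs = c[dam_idx] if use_c else 0.0
        r_obs = r[line_idx] if use_r else 0.0
        xb = X @ B
        if use_a:
            resid = Y - xb - c_obs - r_obs
            rhs = T_obs.T @ (resid @ Re_inv)
            prec = lam[:, None, None] * Re_inv[None] + np.linalg.inv(Ga)[None]
            v = mvn_block(prec, rhs)
            a_obs = T_obs @ v
            nuA, PsiA = prior.components["A"]
            Ga = _inv_wishart(rng, nuA + n, PsiA + v.T @ v)
        if use_c:
            resid = Y - xb - a_obs - r_obs
            rw = resid @ Re_inv
            sums = np.stack(
                [np.bincount(dam_idx, weights=rw[:, j], minlength=nc) for j in range(2)],
                axis=1,
            )
            prec = counts_c[:, None, None] * Re_inv[None] + np.linalg.inv(Cc)[None]
            c = mvn_block(prec, sums)
            c_obs = c[dam_idx]
            nuC, PsiC = prior.components["C"]
            Cc = _inv_wishart(rng, nuC + nc, PsiC + c.T @ c)
        if use_r:
            resid = Y - xb - a_obs - c_obs
            rw = resid @ Re_inv
            sums = np.stack(
                [np.bincount(line_idx, weights=rw[:, j], minlength=nr) for j in range(2)],
                axis=1,
            )
            prec = counts_r[:, None, None] * Re_inv[None] + np.linalg.inv(Rr)[None]
            r = mvn_block(prec, sums)
            r_obs = r[line_idx]
            nuR, PsiR = prior.components["R"]
            Rr = _inv_wishart(rng, nuR + nr, PsiR + r.T @ r)
        resid = Y - a_obs - c_obs - r_obs
        Bm = np.linalg.solve(XtX, X.T @ resid)
        cholRe = np.linalg.cholesky(Re)
        B = Bm + np.linalg.solve(cholX.T, rng.standard_normal((p, 2))) @ cholRe.T
        resid = resid - X @ B
        SS = resid.T @ resid
        nuE, PsiE = prior.components["E"]
        Re = _inv_wishart(rng, nuE + m, PsiE + SS)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            if use_a:
                out["A"][k] = Ga
            if use_c:
                out["C"][k] = Cc
            if use_r:
                out["R"][k] = Rr
            out["E"][k] = Re
            fixed_out[k] = B
            Re_inv_new = np.linalg.inv(Re)
            _, logdet = np.linalg.slogdet(Re)
            dev_out[k] = m * (2 * LOG2PI + logdet) + np.trace(Re_inv_new @ SS)
            fitted_sum += Y - resid
            Re_sum += Re
            k += 1

    fitted_mean = fitted_sum / k
    Re_mean = Re_sum / k
    rme = Y - fitted_mean
    _, logdet = np.linalg.slogdet(Re_mean)
    d_at_mean = m * (2 * LOG2PI + logdet) + np.trace(
        np.linalg.inv(Re_mean) @ (rme.T @ rme)
    )
    return PosteriorSample(
        traits=spec.traits,
        components={name: arr[:k] for name, arr in out.items()},
        fixed=fixed_out[:k],
        fixed_names=fixed_names,
        deviance=dev_out[:k],
        d_at_mean=float(d_at_mean),
        n_obs=m,
        spec=spec,
        cfg=cfg,
        label=label,
    )


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def autocorrelation(x: np.ndarray, lag: int = 1) -> float:
    """Lag-``lag`` autocorrelation of a chain (error if too short/constant)."""
    x = np.asarray(x, dtype=float)
    if len(x) < max(lag + 2, 10):
        raise ModelError(f"chain of length {len(x)} too short for lag {lag}")
    a, b = x[:-lag], x[lag:]
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant chain: autocorrelation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def autocorrelation_check(
    ps: PosteriorSample, lag: int = 1, threshold: float = 0.05
) -> pd.DataFrame:
    """Per-component lag autocorrelation of the thinned chain, with a flag
    for values exceeding ``threshold`` (the convergence rule of thumb)."""
    rows = []
    for name, arr in ps.components.items():
        if arr.ndim == 1:
            series = {name: arr}
        else:
            series = {
                f"{name}[{i}{j}]": arr[:, i, j]
                for i in range(arr.shape[1])
                for j in range(i, arr.shape[2])
            }
        for label, x in series.items():
            ac = autocorrelation(x, lag)
            rows.append((label, ac, bool(np.isfinite(ac) and abs(ac) > threshold)))
    return pd.DataFrame(rows, columns=["parameter", "autocorr", "exceeds"])


def dic(ps: PosteriorSample) -> tuple[float, float, float]:
    """(DIC, pD, mean deviance): DIC = Dbar + pD, pD = Dbar - D(theta_bar),
    with the deviance conditional on the latent effects."""
    if ps.deviance is None or ps.d_at_mean is None:
        raise ModelError("posterior sample has no deviance trace")
    dbar = float(np.mean(ps.deviance))
    pd_ = dbar - ps.d_at_mean
    return dbar + pd_, pd_, dbar
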