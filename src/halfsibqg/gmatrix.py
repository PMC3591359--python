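"""G-matrix comparison between environments by jackknife-pseudovalue MANOVA.

The additive (co)variance matrix for each treatment group is estimated by
the moment (expected-mean-squares) method on the nested sire/dam design:
V_A = 4 x sire component, with unbalanced-design coefficients.  Deleting
each sire family in turn gives leave-one-out matrices G_{-i}, and the
delete-one jackknife pseudovalues

    p_i = n vec(G) - (n - 1) vec(G_{-i})

(on the unique lower-triangle vectorization) behave approximately like
independent replicates of vec(G), so two treatments can be compared with a
two-group MANOVA on the pseudovalue vectors: Wilks' lambda = det(E)/
det(E+H) with its exact F transform, df (p, N - p - 1), followed by
univariate one-way ANOVAs per matrix element.

Nuisance fixed effects are removed beforehand by residualizing each trait
on its significant main effects; negative moment components are retained
untruncated, since truncation would bias the MANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .phenotypes import PhenotypeTable, TRAITS


class GMatrixError(ValueError):
    pass


# ----------------------------------------------------------------------
# vectorization helpers (trait order fixed; lower triangle, row-major)
# ----------------------------------------------------------------------
def vech(M: np.ndarray) -> np.ndarray:
    """Unique elements of a symmetric matrix, lower triangle row-major."""
    M = np.asarray(M)
    i, j = np.tril_indices(M.shape[0])
    return M[i, j]


def unvech(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    t = int((np.sqrt(8 * len(v) + 1) - 1) / 2)
    if t * (t + 1) // 2 != len(v):
        raise GMatrixError(f"length {len(v)} is not a triangular number")
    M = np.zeros((t, t))
    i, j = np.tril_indices(t)
    M[i, j] = v
    M[j, i] = v
    return M


def vech_labels(traits) -> list[str]:
    i, j = np.tril_indices(len(traits))
    return [f"({traits[a]},{traits[b]})" for a, b in zip(i, j)]


@dataclass
class GMatrix:
    """Additive (co)variance matrix on the log10 trait scale."""

    values: np.ndarray
    traits: tuple[str, ...]
    n_families: int = 0
    negative_components: bool = False

    def vec(self) -> np.ndarray:
        return vech(self.values)


@dataclass
class PseudovalueSet:
    """Per-family jackknife pseudovalue vectors, one group per treatment."""

    values: pd.DataFrame        # columns: group, family, then vech elements
    traits: tuple[str, ...]

    @property
    def element_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in ("group", "family")]


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df_num: int
    df_den: int
    p: float
    univariate: pd.DataFrame


# ----------------------------------------------------------------------
def residualize(tab: PhenotypeTable, factors: tuple[str, ...] = ()) -> PhenotypeTable:
    """Replace each trait by residuals from a main-effects-only model.

    With no factors this just centres each trait on its grand mean.
    """
    df = tab.df.copy()
    for f in factors:
        if f not in df.columns:
            raise GMatrixError(f"factor {f!r} not in phenotype table")
    for t in TRAITS:
        mask = df[t].notna()
        if not mask.any():
            continue
        y = df.loc[mask, t].to_numpy(dtype=float)
        if factors:
            X = [np.ones((mask.sum(), 1))]
            for f in factors:
                X.append(pd.get_dummies(
                    df.loc[mask, f].astype(str), drop_first=True
                ).to_numpy(dtype=float))
            X = np.hstack(X)
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            df.loc[mask, t] = y - X @ beta
        else:
            df.loc[mask, t] = y - y.mean()
    return PhenotypeTable(df=df, scale=tab.scale)


# ----------------------------------------------------------------------
def _nested_components(Y: np.ndarray, sire: np.ndarray, dam: np.ndarray):
    """Sire/dam/within (co)variance components by unbalanced-design EMS.

    Returns (Sigma_sire, Sigma_dam, Sigma_within) as t x t matrices.  The
    same mean-cross-product algebra as the classical univariate expected
    mean squares is applied element-wise, which is equivalent to the
    sum-variance identity cov = [Var(x+y) - Var(x) - Var(y)]/2 applied at
    the component level.
    """
    N, t = Y.shape
    s_codes, s_uniq = pd.factorize(sire)
    d_codes, d_uniq = pd.factorize(dam)
    s = len(s_uniq)
    d = len(d_uniq)
    if s < 2 or d <= s:
        raise GMatrixError("need >=2 sires and nested dams")

    tot = Y.sum(axis=0)
    dam_sums = np.zeros((d, t))
    np.add.at(dam_sums, d_codes, Y)
    dam_n = np.bincount(d_codes, minlength=d).astype(float)
    sire_sums = np.zeros((s, t))
    np.add.at(sire_sums, s_codes, Y)
    sire_n = np.bincount(s_codes, minlength=s).astype(float)
    dam_sire = np.array([s_codes[d_codes == j][0] for j in range(d)])

    Syy = Y.T @ Y
    Sdam = (dam_sums / dam_n[:, None]).T @ dam_sums
    Ssire = (sire_sums / sire_n[:, None]).T @ sire_sums
    Sg = np.outer(tot, tot) / N

    T_w = Syy - Sdam
    T_d = Sdam - Ssire
    T_s = Ssire - Sg
    df_w = N - d
    df_d = d - s
    df_s = s - 1
    if df_w <= 0 or df_d <= 0:
        raise GMatrixError("not enough offspring per dam / dams per sire")
    MS_w = T_w / df_w
    MS_d = T_d / df_d
    MS_s = T_s / df_s

    # unbalanced EMS coefficients (Satterthwaite-style k's)
    nij2_over_ni = float(np.sum(dam_n**2 / sire_n[dam_sire]))
    nij2_over_N = float(np.sum(dam_n**2) / N)
    ni2_over_N = float(np.sum(sire_n**2) / N)
    k1 = (N - nij2_over_ni) / df_d
    k2 = (nij2_over_ni - nij2_over_N) / df_s
    k3 = (N - ni2_over_N) / df_s

    Sigma_w = MS_w
    Sigma_d = (MS_d - MS_w) / k1
    Sigma_s = (MS_s - MS_w - k2 * Sigma_d) / k3
    return Sigma_s, Sigma_d, Sigma_w


def moment_G(
    tab: PhenotypeTable,
    ped: Pedigree,
    traits: tuple[str, ...] = TRAITS,
    min_offspring: int = 2,
    min_families: int = 3,
) -> GMatrix:
    """Moment estimate of the additive (co)variance matrix, V_A = 4 sigma2_sire.

    Uses complete cases for ``traits``; sire families contributing fewer
    than ``min_offspring`` complete offspring are dropped with a warning.
    Negative component estimates are retained (flagged, not truncated).
    """
    df = tab.df.dropna(subset=list(traits))
    parent = {i: (s, d) for i, s, d in ped.entries}
    sires = np.array([parent[i][0] for i in df["id"]], dtype=object)
    dams = np.array([parent[i][1] for i in df["id"]], dtype=object)
    if any(s is None or d is None for s, d in zip(sires, dams)):
        raise GMatrixError("all phenotyped individuals must have known parents")

    counts = pd.Series(sires).value_counts()
    small = counts[counts < min_offspring].index
    if len(small):
        warnings.warn(
            f"dropping {len(small)} sire families with < {min_offspring} "
            f"complete offspring"
        )
        keep = ~pd.Series(sires).isin(small).to_numpy()
        df, sires, dams = df[keep], sires[keep], dams[keep]
    if pd.Series(sires).nunique() < min_families:
        raise GMatrixError(f"need >= {min_families} sire families")

    Y = df[list(traits)].to_numpy(dtype=float)
    Sigma_s, _, _ = _nested_components(Y, sires, dams)
    G = 4.0 * Sigma_s
    neg = bool(np.any(np.diag(G) < 0))
    return GMatrix(
        values=G,
        traits=tuple(traits),
        n_families=int(pd.Series(sires).nunique()),
        negative_components=neg,
    )


# ----------------------------------------------------------------------
def jackknife_pseudovalues(
    tab: PhenotypeTable,
    ped: Pedigree,
    traits: tuple[str, ...] = TRAITS,
    group_col: str = "ethanol",
) -> PseudovalueSet:
    """Delete-one-sire-family pseudovalues of vec(G), per treatment group.

    Each treatment's jackknife is internal to that treatment's data: the
    deleted sire's dams and offspring are removed only from the group
    being estimated.  One pseudovalue vector per family per group.
    """
    parent = {i: (s, d) for i, s, d in ped.entries}
    labels = vech_labels(traits)
    rows = []
    for group, sub in tab.df.groupby(group_col, sort=True):
        sub_tab = PhenotypeTable(df=sub.reset_index(drop=True), scale=tab.scale)
        g_obs = moment_G(sub_tab, ped, traits)
        fams = sorted(
            {parent[i][0] for i in sub.dropna(subset=list(traits))["id"]}
        )
        n = len(fams)
        if n < 3:
            raise GMatrixError(f"group {group!r} has < 3 families")
        v_obs = g_obs.vec()
        for fam in fams:
            keep = [i for i in sub["id"] if parent[i][0] != fam]
            red = PhenotypeTable(
                df=sub[sub["id"].isin(keep)].reset_index(drop=True),
                scale=tab.scale,
            )
            try:
                # leave-one-out subsets may legitimately drop to 2 families
                g_red = moment_G(red, ped, traits, min_families=2)
            except GMatrixError as exc:
                warnings.warn(
                    f"leave-one-out estimate failed for family {fam!r}: {exc}"
                )
                continue
            pseudo = n * v_obs - (n - 1) * g_red.vec()
            rows.append([group, fam, *pseudo])
    values = pd.DataFrame(rows, columns=["group", "family", *labels])
    return PseudovalueSet(values=values, traits=tuple(traits))


def manova_compare(ps: PseudovalueSet) -> ManovaResult:
    """Two-group MANOVA on pseudovalue vectors.

    Wilks' lambda = det(E)/det(E+H); for two groups the exact F transform
    is F = (1 - lambda)/lambda x (N - p - 1)/p on (p, N - p - 1) df.
    Univariate one-way ANOVAs per element use (1, N - 2) df.
    """
    df = ps.values
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise GMatrixError(f"exactly two groups required, got {groups}")
    cols = ps.element_columns
    p = len(cols)
    Y = df[cols].to_numpy(dtype=float)
    g = df["group"].to_numpy()
    N = len(Y)
    if N <= p + 1:
        raise GMatrixError(f"need N > p + 1 vectors (N={N}, p={p})")

    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for gr in groups:
        sub = Y[g == gr]
        m = sub.mean(axis=0)
        H += len(sub) * np.outer(m - grand, m - grand)
        E += (sub - m).T @ (sub - m)
    sign, logdetE = np.linalg.slogdet(E)
    if sign <= 0:
        raise GMatrixError(
            "singular within-group matrix; analyse a subset of elements"
        )
    sign2, logdetEH = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdetE - logdetEH))
    df_num = p
    df_den = N - p - 1
    F = (1 - lam) / lam * df_den / df_num if lam > 0 else np.inf
    pval = float(stats.f.sf(F, df_num, df_den))

    uni_rows = []
    for j, col in enumerate(cols):
        a = Y[g == groups[0], j]
        b = Y[g == groups[1], j]
        ssb = (
            len(a) * (a.mean() - Y[:, j].mean()) ** 2
            + len(b) * (b.mean() - Y[:, j].mean()) ** 2
        )
        ssw = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        dfw = N - 2
        Fu = (ssb / 1) / (ssw / dfw) if ssw > 0 else np.inf
        uni_rows.append((col, Fu, 1, dfw, float(stats.f.sf(Fu, 1, dfw))))
    uni = pd.DataFrame(uni_rows, columns=["element", "F", "df_num", "df_den", "p"])
    return ManovaResult(
        wilks_lambda=lam, F=float(F), df_num=df_num, df_den=df_den,
        p=pval, univariate=uni,
    )
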