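"""Phenotype-level linear models.

``fit_mixed_anova`` reproduces the classical mixed-model ANOVA used for
trait means: Type-III sums of squares under sum-to-zero contrasts, with
the replicate-line-within-population mean square as the error term for the
population main effect (expected-mean-squares F construction; with two
populations of three lines each this yields the characteristic F with 4
denominator df) and the residual mean square for everything else.

``unequal_n_hsd`` is the Tukey–Kramer post-hoc for unequal group sizes and
``slope_homogeneity`` tests equality of body-mass–RMR slopes across groups
by the ANCOVA interaction F.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .phenotypes import PhenotypeTable


class AnovaError(ValueError):
    pass


@dataclass
class AnovaSpec:
    """Model specification for one trait's mixed ANOVA.

    ``fixed`` are main-effect factor columns; ``interactions`` are tuples of
    factor names; ``covariate`` (log10 body mass) is only sensible for RMR;
    ``random_line`` includes replicate line nested in population.
    """

    response: str
    fixed: tuple[str, ...] = ("population", "ethanol", "sex")
    interactions: tuple[tuple[str, ...], ...] = (
        ("population", "ethanol"),
        ("population", "sex"),
        ("ethanol", "sex"),
    )
    covariate: str | None = None
    random_line: bool = True

    def __post_init__(self):
        if self.covariate is not None and self.response != "rmr":
            raise AnovaError("covariate only allowed for the RMR model")


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise AnovaError(f"factor needs >=2 levels, got {levels}")
    X = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = (values == lev).astype(float) - (values == levels[-1]).astype(float)
    return X, levels


def _interaction(cols: list[np.ndarray]) -> np.ndarray:
    out = cols[0]
    for c in cols[1:]:
        out = np.einsum("ij,ik->ijk", out, c).reshape(len(out), -1)
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2)), int(rank)


def fit_mixed_anova(tab: PhenotypeTable, spec: AnovaSpec) -> pd.DataFrame:
    """Type-III mixed ANOVA table (effect, ss, df_num, df_den, F, p).

    The population main effect is tested against the line-within-population
    mean square (the containing random term); all other fixed terms and the
    line term itself are tested against the residual.
    """
    df = tab.df
    need = [spec.response, *spec.fixed]
    if spec.random_line:
        need += ["population", "line"]
    if spec.covariate:
        need += [spec.covariate]
    df = df.dropna(subset=[c for c in need if c in df.columns])
    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise AnovaError("no complete cases")

    blocks: dict[str, np.ndarray] = {}
    main_cols: dict[str, np.ndarray] = {}
    for f in spec.fixed:
        main_cols[f], _ = _sum_code(df[f])
        blocks[f] = main_cols[f]
    for terms in spec.interactions:
        for t in terms:
            if t not in main_cols:
                raise AnovaError(f"interaction term {t!r} has no main effect")
        blocks[":".join(terms)] = _interaction([main_cols[t] for t in terms])
    if spec.covariate:
        cov = df[spec.covariate].to_numpy(dtype=float)
        blocks[spec.covariate] = (cov - cov.mean())[:, None]
    line_term = None
    if spec.random_line:
        # nested coding: per population, sum-to-zero contrasts among its lines
        cols = []
        for pop in sorted(df["population"].unique()):
            m = (df["population"] == pop).to_numpy()
            sub = df.loc[m, "line"]
            if sub.nunique() < 2:
                continue
            Xp, _ = _sum_code(sub)
            full = np.zeros((n, Xp.shape[1]))
            full[m] = Xp
            cols.append(full)
        if not cols:
            raise AnovaError("random line term requires >=2 lines per population")
        line_term = "line(population)"
        blocks[line_term] = np.hstack(cols)

    X_full = np.hstack([np.ones((n, 1))] + [blocks[k] for k in blocks])
    rss_full, rank_full = _rss(X_full, y)
    p_cols = X_full.shape[1]
    if rank_full < p_cols:
        raise AnovaError(
            f"aliased design: rank {rank_full} < {p_cols} columns "
            f"(terms: {list(blocks)})"
        )
    df_resid = n - rank_full
    ms_resid = rss_full / df_resid

    rows = []
    term_stats = {}
    for name in blocks:
        others = [blocks[k] for k in blocks if k != name]
        X_red = np.hstack([np.ones((n, 1))] + others)
        rss_red, rank_red = _rss(X_red, y)
        ss = max(rss_red - rss_full, 0.0)
        df_num = rank_full - rank_red
        term_stats[name] = (ss, df_num)

    line_ms = None
    if line_term is not None:
        ss_l, df_l = term_stats[line_term]
        line_ms = ss_l / df_l if df_l else np.nan
    for name, (ss, df_num) in term_stats.items():
        if df_num == 0:
            continue
        ms = ss / df_num
        if name == "population" and line_ms is not None:
            denom_ms, df_den = line_ms, term_stats[line_term][1]
        else:
            denom_ms, df_den = ms_resid, df_resid
        F = ms / denom_ms if denom_ms > 0 else 0.0
        p = float(stats.f.sf(F, df_num, df_den)) if denom_ms > 0 else 1.0
        rows.append((name, ss, df_num, df_den, F, p))
    rows.append(("residual", rss_full, df_resid, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["effect", "ss", "df_num", "df_den", "F", "p"]
    )


# ----------------------------------------------------------------------
def unequal_n_hsd(groups: dict) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons for unequal group sizes.

    ``groups`` maps label -> 1-d samples.  q = |mi - mj| /
    sqrt(MSE/2 (1/ni + 1/nj)); p from the studentized-range distribution
    with k groups and the pooled within-group df.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise AnovaError("need >=2 groups")
    data = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, v in data.items():
        if len(v) < 2:
            raise AnovaError(f"group {k!r} has n < 2")
    ns = {k: len(v) for k, v in data.items()}
    means = {k: v.mean() for k, v in data.items()}
    df_w = sum(ns.values()) - len(labels)
    mse = sum(np.sum((v - means[k]) ** 2) for k, v in data.items()) / df_w
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
        q = abs(means[a] - means[b]) / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(q, len(labels), df_w))
        rows.append((a, b, means[a] - means[b], q, p))
    return pd.DataFrame(rows, columns=["group1", "group2", "diff", "q", "p"])


# ----------------------------------------------------------------------
def slope_homogeneity(
    tab: PhenotypeTable, group_factor: str = "sex"
) -> dict:
    """Per-group body-mass–RMR slopes and the ANCOVA interaction test.

    Fits log10 RMR ~ group * log10 Mb; returns per-group slope +/- SE and
    the group x covariate interaction F and p.
    """
    df = tab.df.dropna(subset=["rmr", "mb", group_factor]).copy()
    groups = sorted(df[group_factor].unique())
    if len(groups) < 2:
        raise AnovaError(f"need >=2 groups in {group_factor!r}, got {groups}")
    for g in groups:
        if (df[group_factor] == g).sum() < 3:
            raise AnovaError(f"group {g!r} has < 3 points")
    df = df.rename(columns={group_factor: "grp"})
    full = smf.ols("rmr ~ C(grp) * mb", data=df).fit()
    reduced = smf.ols("rmr ~ C(grp) + mb", data=df).fit()
    if reduced.ssr - full.ssr < 1e-12 * max(1.0, reduced.ssr):
        # reduced model already fits (numerically) perfectly
        comp = (0.0, 1.0, len(groups) - 1)
    else:
        comp = full.compare_f_test(reduced)
    slopes = {}
    for g in groups:
        sub = df[df["grp"] == g]
        fit = smf.ols("rmr ~ mb", data=sub).fit()
        slopes[g] = (float(fit.params["mb"]), float(fit.bse["mb"]))
    return {
        "slopes": slopes,
        "F": float(comp[0]),
        "p": float(comp[1]),
        "df": (int(comp[2]), int(full.df_resid)),
    }
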