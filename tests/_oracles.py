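"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they are used to check:
gene dropping estimates relationship coefficients by simulating allele
transmission; the Hotelling T² and Monte-Carlo studentized-range oracles
recompute reference statistics from first principles.
"""

from __future__ import annotations

import numpy as np


def gene_dropping_A(entries, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo numerator relationship matrix by gene dropping.

    ``entries`` are (id, sire, dam) trios in topological order with None
    for founder parents.  Each founder gets two unique alleles; every drop
    transmits one random allele per parent.  A[i,j] = 2 * kinship(i,j)
    estimated as the probability that random alleles from i and j are
    identical by descent.
    """
    rng = np.random.default_rng(seed)
    ids = [e[0] for e in entries]
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    alleles = np.empty((n_drops, n, 2), dtype=np.int32)
    next_allele = 0
    for k, (i, s, d) in enumerate(entries):
        if s is None and d is None:
            alleles[:, k, 0] = next_allele
            alleles[:, k, 1] = next_allele + 1
            next_allele += 2
            continue
        for slot, parent in enumerate((s, d)):
            if parent is None:
                alleles[:, k, slot] = next_allele
                next_allele += 1
            else:
                p = idx[parent]
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, k, slot] = alleles[np.arange(n_drops), p, pick]
    A = np.empty((n, n))
    for i in range(n):
        same = alleles[:, i, 0] == alleles[:, i, 1]
        A[i, i] = 2 * np.mean((1 + same) / 2)
        for j in range(i):
            m = (
                alleles[:, i, :, None] == alleles[:, j, None, :]
            ).mean(axis=(1, 2))
            A[i, j] = A[j, i] = 2 * m.mean()
    return A


def hotelling_two_sample_F(a: np.ndarray, b: np.ndarray):
    """Two-sample Hotelling T² and its exact F transform, from scratch."""
    n1, p = a.shape
    n2 = b.shape[0]
    d = a.mean(axis=0) - b.mean(axis=0)
    S = (
        (a - a.mean(axis=0)).T @ (a - a.mean(axis=0))
        + (b - b.mean(axis=0)).T @ (b - b.mean(axis=0))
    ) / (n1 + n2 - 2)
    t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
    F = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    return float(t2), float(F)


def mc_studentized_range_sf(q_obs: float, k: int, df: int, n_draws: int, seed: int) -> float:
    """P(Q > q_obs) for the studentized range by direct Monte Carlo."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    rng_range = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    return float(np.mean(rng_range / s > q_obs))
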