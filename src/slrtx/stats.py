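"""Statistical primitives: exact 2xk Fisher test, negative-binomial Wald
differential expression, and Benjamini-Hochberg adjustment."""
from __future__ import annotations

from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1e-9


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_2xk(
    table,
    enumeration_cutoff: int = 200,
    n_monte_carlo: int = 100_000,
    seed: int = 20210427,
) -> float:
    """Two-sided exact p for a 2 x k contingency table.

    Conditional on the margins, the probability of a table with first-row
    cells a_j is prod_j C(c_j, a_j) / C(N, r); the two-sided p sums the
    probability of every table no more probable than the observed one
    (full enumeration when N <= `enumeration_cutoff`, else Monte-Carlo with
    a fixed seed).  Degenerate tables (a single non-zero row or column)
    return p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or (t < 0).any():
        raise ValueError("expected a non-negative 2 x k table")
    col = t.sum(axis=0)
    keep = col > 0
    t, col = t[:, keep], col[keep]
    row = t.sum(axis=1)
    n = int(t.sum())
    if t.shape[1] < 2 or row.min() == 0 or n == 0:
        return 1.0
    r = int(row[0])
    k = t.shape[1]
    logp_obs = sum(_log_comb(int(col[j]), int(t[0, j])) for j in range(k))
    thresh = logp_obs + _REL_TOL * abs(logp_obs) + 1e-12

    if n <= enumeration_cutoff:
        suffix = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])
        log_cnr = _log_comb(n, r)
        total = 0.0

        def recurse(j: int, rem: int, logp: float) -> None:
            nonlocal total
            if j == k:
                if rem == 0 and logp <= thresh:
                    total += np.exp(logp - log_cnr)
                return
            lo = max(0, rem - int(suffix[j]))
            hi = min(int(col[j]), rem)
            for a in range(lo, hi + 1):
                recurse(j + 1, rem - a, logp + _log_comb(int(col[j]), a))

        recurse(0, r, 0.0)
        return min(1.0, total)

    # Monte-Carlo: sample first-row cells by sequential hypergeometric draws
    rng = np.random.default_rng(seed)
    hits = 0
    logC = -_log_comb(n, r)
    thresh_mc = logp_obs + logC + _REL_TOL * abs(logp_obs + logC) + 1e-12
    for _ in range(n_monte_carlo):
        rem_r, rem_n = r, n
        logp = logC
        for j in range(k):
            cj = int(col[j])
            a = rng.hypergeometric(cj, rem_n - cj, rem_r) if rem_r > 0 else 0
            logp += _log_comb(cj, a)
            rem_r -= a
            rem_n -= cj
        if logp <= thresh_mc:
            hits += 1
    return (hits + 1) / (n_monte_carlo + 1)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# negative-binomial Wald differential test
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors per sample (column)."""
    c = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    finite = np.isfinite(logc).all(axis=1)
    if finite.sum() == 0:
        tot = c.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot[tot > 0])))
    else:
        loggeo = logc[finite].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc[finite] - loggeo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    alpha_floor: float = 0.01,
    fdr: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Two-group NB Wald-type test per feature (rows) over samples (columns).

    Median-of-ratios size factors; method-of-moments dispersion per feature,
    floored at `alpha_floor` and at the pooled median across features (the
    per-feature estimate is far too noisy at small n, and a plain Wald with
    it is anticonservative).  The statistic compares the normalised group
    means against the null-variance at the pooled mean (score-type
    denominator), referred to the standard normal.  Features that are
    all-zero get p = 1 and are excluded from the BH denominator.
    Significance requires BH-adjusted p <= `fdr` and fold change > `min_fold`.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    g1 = [s for s in counts.columns if groups[s] == labels[0]]
    g2 = [s for s in counts.columns if groups[s] == labels[1]]
    if not g1 or not g2:
        raise ValueError("each group needs at least one sample")
    sf = size_factors(counts)
    y = counts / sf
    m1 = y[g1].mean(axis=1).to_numpy()
    m2 = y[g2].mean(axis=1).to_numpy()
    mu = y.mean(axis=1).to_numpy()
    # pooled within-group variance (MoM dispersion)
    if len(g1) > 1 or len(g2) > 1:
        ss = ((y[g1].sub(y[g1].mean(axis=1), axis=0) ** 2).sum(axis=1)
              + (y[g2].sub(y[g2].mean(axis=1), axis=0) ** 2).sum(axis=1))
        df_w = max(1, len(g1) + len(g2) - 2)
        s2 = (ss / df_w).to_numpy()
    else:
        s2 = mu  # no replication: Poisson-like fallback
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_i = np.maximum(alpha_floor, (s2 - mu) / np.maximum(mu, 1e-12) ** 2)
    pooled = float(np.median(alpha_i[mu > 0])) if (mu > 0).any() else alpha_floor
    alpha = np.maximum(alpha_i, pooled)

    eps = 0.5
    lfc = np.log2((m2 + eps) / (m1 + eps))
    # null variance of the mean difference at the pooled mean
    var0 = (mu + alpha * mu**2) * (1.0 / len(g1) + 1.0 / len(g2))
    z = (m2 - m1) / np.sqrt(np.maximum(var0, 1e-12))
    pvals = 2.0 * sps.norm.sf(np.abs(z))

    tested = (counts.sum(axis=1) > 0).to_numpy()
    pvals = np.where(tested, pvals, 1.0)
    padj = np.ones_like(pvals)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])
    res = pd.DataFrame(
        {
            "feature": counts.index,
            "baseMean": mu,
            "log2FoldChange": lfc,
            "pvalue": pvals,
            "padj": padj,
            "tested": tested,
        }
    ).set_index("feature")
    res["significant"] = (
        res["tested"] & (res["padj"] <= fdr) & (np.abs(res["log2FoldChange"]) > np.log2(min_fold))
    )
    return res
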