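"""Nonparametric cohort statistics over per-biopsy quantification results.

Group comparison uses the Mann-Whitney U test (exact enumeration with
midranks for small samples, tie-corrected normal approximation otherwise),
rank correlation uses Spearman's rho, and inter-rater agreement over
ordinal fibrosis stages uses the weighted kappa score.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "spearman_rho",
    "weighted_kappa",
    "stage_summary",
    "EXACT_LIMIT",
]

# combined sample size up to which the exact null distribution is used;
# the study's groups are small (n <= 12), where exact enumeration is
# feasible and preferable to the normal approximation
EXACT_LIMIT = 20


@lru_cache(maxsize=128)
def _exact_rank_sum_counts(n: int, m: int) -> tuple[np.ndarray, int]:
    """Counts of rank-sum values for n untied ranks drawn from 1..n+m.

    Returns (counts indexed by rank-sum, offset) with
    ``P(R = s) = counts[s - offset] / C(n+m, n)``.
    """
    total = n + m
    smin = n * (n + 1) // 2
    smax = n * (2 * total - n + 1) // 2
    counts = np.zeros((n + 1, smax + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for value in range(1, total + 1):
        for k in range(min(value, n), 0, -1):
            counts[k, value:] += counts[k - 1, :-value or None]
    return counts[n, smin:], smin


def _two_sided_p(values: np.ndarray, weights: np.ndarray, observed: float) -> float:
    total = weights.sum()
    lo = weights[values <= observed + 1e-9].sum() / total
    hi = weights[values >= observed - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) and two-sided p value.

    U is computed from rank sums with midranks for ties. For combined
    n <= ``EXACT_LIMIT`` the p value comes from exact enumeration of the
    rank assignments (the classical count recurrence without ties, full
    enumeration of midrank subsets with ties); larger samples use the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx = ranks[:n].sum()
    u = rx - n * (n + 1) / 2.0

    total = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if total <= EXACT_LIMIT:
        if not has_ties:
            counts, offset = _exact_rank_sum_counts(n, m)
            u_values = np.arange(counts.size, dtype=np.float64) \
                + offset - n * (n + 1) / 2.0
            p = _two_sided_p(u_values, counts, u)
        else:
            combos = np.fromiter(
                itertools.chain.from_iterable(
                    itertools.combinations(range(total), n)),
                dtype=np.intp).reshape(-1, n)
            rank_sums = ranks[combos].sum(axis=1)
            u_values = rank_sums - n * (n + 1) / 2.0
            p = _two_sided_p(u_values, np.ones_like(u_values), u)
        return float(u), p

    mu = n * m / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (total * (total - 1.0))
    sigma2 = n * m / 12.0 * (total + 1.0 - tie_term)
    if sigma2 <= 0:  # all values tied
        return float(u), 1.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return float(u), p


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks).

    Returns NaN for constant inputs, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


def weighted_kappa(ratings_a, ratings_b, weights: str = "linear",
                   categories=None) -> float:
    """Weighted Cohen's kappa over a declared ordered category set.

    Disagreement weights are ``|i - j| / (k - 1)`` (linear) or its square
    (quadratic); kappa = 1 - sum(w*o) / sum(w*e) with the observed
    contingency matrix o and expected matrix e from the marginals.
    Perfect agreement gives exactly 1; chance-level agreement ~0.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValueError("rating vectors must be nonempty")
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    if categories is None:
        categories = sorted(set(a) | set(b))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    unseen = (set(a) | set(b)) - set(categories)
    if unseen:
        raise ValueError(f"ratings contain labels outside the declared "
                         f"category set: {sorted(unseen)}")
    k = len(categories)
    o = np.zeros((k, k), dtype=np.float64)
    for ra, rb in zip(a, b):
        o[index[ra], index[rb]] += 1
    o /= o.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    if k == 1:
        return 1.0
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) / (k - 1)
    if weights == "quadratic":
        w = w**2
    observed = (w * o).sum()
    expected = (w * e).sum()
    if expected == 0:
        return 1.0 if observed == 0 else math.nan
    return float(1.0 - observed / expected)


def stage_summary(table: pd.DataFrame, value_col: str = "mean_shg",
                  stage_col: str = "fibrosis_stage",
                  holm: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage summary plus adjacent-stage Mann-Whitney tests.

    Returns (summary, tests): the summary holds n, mean, sd and median of
    ``value_col`` per stage; the tests hold U and the two-sided p value
    for each adjacent stage pair present in the data (p is NaN when either
    group has fewer than 2 samples). Pairwise p values are unadjusted by
    default; ``holm=True`` applies a Holm correction.
    """
    if stage_col not in table.columns or value_col not in table.columns:
        raise ValueError(f"table must contain '{stage_col}' and '{value_col}'")
    grouped = table.groupby(stage_col)[value_col]
    summary = pd.DataFrame({
        "n": grouped.size(),
        "mean": grouped.mean(),
        "sd": grouped.std(ddof=1),
        "median": grouped.median(),
    }).reset_index()

    stages = sorted(table[stage_col].unique())
    rows = []
    for s0, s1 in zip(stages[:-1], stages[1:]):
        g0 = table.loc[table[stage_col] == s0, value_col].to_numpy()
        g1 = table.loc[table[stage_col] == s1, value_col].to_numpy()
        if len(g0) < 2 or len(g1) < 2:
            rows.append({"stage_a": s0, "stage_b": s1,
                         "u": math.nan, "p": math.nan})
        else:
            u, p = mann_whitney_u(g0, g1)
            rows.append({"stage_a": s0, "stage_b": s1, "u": u, "p": p})
    tests = pd.DataFrame(rows, columns=["stage_a", "stage_b", "u", "p"])
    if holm and len(tests):
        order = np.argsort(tests["p"].to_numpy())
        k = np.isfinite(tests["p"].to_numpy()).sum()
        adj = tests["p"].to_numpy(copy=True)
        running = 0.0
        for rank, idx in enumerate(order):
            if not np.isfinite(adj[idx]):
                continue
            running = max(running, (k - rank) * adj[idx])
            adj[idx] = min(1.0, running)
        tests["p_holm"] = adj
    return summary, tests
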