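"""Behavioral statistics for the 3-point congruence ratings.

A Friedman omnibus test compares the five prior-congruence conditions
within subjects, followed by all 10 pairwise Wilcoxon signed-rank tests
with Bonferroni correction.  Trial-level ratings are first aggregated to
one value per subject and condition (mean by default, median optionally).

The Friedman statistic uses mid-ranks and the standard tie-correction
factor; the Wilcoxon tests enumerate the exact sign-flip null when at most
12 non-zero differences remain and fall back to the tie-corrected normal
approximation otherwise.  Zero differences are dropped (their count is
logged).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "RatingTable",
    "rating_table",
    "friedman",
    "pairwise_wilcoxon",
]

EXACT_WILCOXON_MAX_N = 12


@dataclass
class RatingTable:
    """Subject x condition matrix of aggregated ratings."""

    values: np.ndarray           # (n_subjects, n_conditions)
    subjects: list[str]
    conditions: list[str]
    aggregation: str = "mean"


def rating_table(ratings: pd.DataFrame, aggregation: str = "mean",
                 conditions: tuple[str, ...] = CONDITIONS) -> RatingTable:
    """Aggregate trial-level ratings to one value per subject and condition."""
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    agg = ratings.groupby(["subject_id", "condition"])["rating"].agg(aggregation)
    wide = agg.unstack("condition").reindex(columns=list(conditions))
    if wide.isna().any().any():
        raise ValueError("missing subject x condition cells")
    return RatingTable(values=wide.to_numpy(dtype=float),
                       subjects=list(wide.index),
                       conditions=list(wide.columns),
                       aggregation=aggregation)


def _friedman_chi2(x: np.ndarray) -> float:
    """Mid-rank Friedman statistic with tie correction."""
    n, k = x.shape
    ranks = np.apply_along_axis(sstats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1.0))
    if correction <= 0:
        return 0.0  # every row constant: no information
    return chi2 / correction


def friedman(table: RatingTable | np.ndarray,
             method: str = "asymptotic",
             n_perm: int = 10_000, seed: int | None = 0) -> dict:
    """Friedman rank test over k within-subject conditions.

    ``method='asymptotic'`` uses the chi-square reference with k-1 degrees
    of freedom; ``method='permutation'`` builds the null by independently
    permuting each subject's row (exhaustive when (k!)^n is small enough,
    Monte Carlo otherwise).
    """
    x = table.values if isinstance(table, RatingTable) else np.asarray(table,
                                                                       float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    chi2 = _friedman_chi2(x)
    df = k - 1
    if method == "asymptotic":
        p = float(sstats.chi2.sf(chi2, df))
    elif method == "permutation":
        n_exhaustive = math.factorial(k) ** n if k <= 6 and n <= 8 else None
        count, total = 0, 0
        if n_exhaustive is not None and n_exhaustive <= n_perm:
            perms = list(itertools.permutations(range(k)))
            for combo in itertools.product(perms, repeat=n):
                xp = np.stack([x[i, list(pi)] for i, pi in enumerate(combo)])
                count += _friedman_chi2(xp) >= chi2 - 1e-12
                total += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_perm):
                xp = np.stack([row[rng.permutation(k)] for row in x])
                count += _friedman_chi2(xp) >= chi2 - 1e-12
            p = (1.0 + count) / (n_perm + 1.0)
        p = float(p)
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return {"chi2": float(chi2), "df": df, "p": p, "n": n, "k": k}


# --------------------------------------------------------------------- #
# Wilcoxon signed-rank
# --------------------------------------------------------------------- #

def _signed_rank_w(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """Positive-rank sum and the mid-ranks of |diff| (zeros already removed)."""
    ranks = sstats.rankdata(np.abs(diff))
    return float(ranks[diff > 0].sum()), ranks


def _wilcoxon_exact_p(diff: np.ndarray) -> float:
    """Two-sided exact p by enumerating all sign patterns (supports ties)."""
    w_obs, ranks = _signed_rank_w(diff)
    m = diff.size
    total = ranks.sum()
    mu = total / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    for pattern in itertools.product((0.0, 1.0), repeat=m):
        w = float(np.dot(pattern, ranks))
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return count / 2 ** m


def _wilcoxon_normal_p(diff: np.ndarray) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    w, ranks = _signed_rank_w(diff)
    m = diff.size
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    return float(2.0 * sstats.norm.sf(max(z, 0.0)))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired two-sided Wilcoxon signed-rank test.

    Exact enumeration of the 2^m sign patterns when m <= 12 non-zero
    differences remain, tie-corrected normal approximation otherwise.
    """
    diff = np.asarray(a, float) - np.asarray(b, float)
    nonzero = diff[diff != 0]
    n_zero = diff.size - nonzero.size
    if n_zero:
        logger.info("wilcoxon: dropped %d zero difference(s)", n_zero)
    if nonzero.size == 0:
        logger.info("wilcoxon: all differences zero, reporting p = 1")
        return {"W": 0.0, "p": 1.0, "n_nonzero": 0, "n_zero": n_zero,
                "method": "degenerate"}
    w, _ = _signed_rank_w(nonzero)
    if nonzero.size <= EXACT_WILCOXON_MAX_N:
        p = _wilcoxon_exact_p(nonzero)
        method = "exact"
    else:
        p = _wilcoxon_normal_p(nonzero)
        method = "normal"
    return {"W": w, "p": float(min(p, 1.0)), "n_nonzero": int(nonzero.size),
            "n_zero": n_zero, "method": method}


def pairwise_wilcoxon(table: RatingTable | np.ndarray,
                      correction: str = "bonferroni") -> pd.DataFrame:
    """All condition-pair Wilcoxon tests with family-wise correction.

    Returns a frame with one row per pair: W, raw p and adjusted p
    (p_adj = min(1, n_pairs * p_raw) under Bonferroni).
    """
    if isinstance(table, RatingTable):
        x, conds = table.values, table.conditions
    else:
        x = np.asarray(table, dtype=float)
        conds = [f"c{i}" for i in range(x.shape[1])]
    pairs = list(itertools.combinations(range(len(conds)), 2))
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    factor = len(pairs) if correction == "bonferroni" else 1
    rows = []
    for i, j in pairs:
        res = wilcoxon_signed_rank(x[:, i], x[:, j])
        rows.append({
            "condition_a": conds[i], "condition_b": conds[j],
            "W": res["W"], "p_raw": res["p"],
            "p_adj": min(1.0, factor * res["p"]),
            "n_nonzero": res["n_nonzero"], "method": res["method"],
        })
    return pd.DataFrame(rows)
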