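"""Rank statistics and Ward clustering used by the group comparisons.

Two-group comparisons use the Mann–Whitney U test computed from mid-ranks:
exact p-values by full enumeration of rank assignments when the pooled
sample is small (n1 + n2 ≤ 12) and tie-free, otherwise a normal
approximation whose variance carries the standard tie-correction term.
Paired comparisons (e.g. central vs peripheral region of the same sample)
use the Wilcoxon signed-rank test with Pratt handling of zero differences:
zeros are ranked together with the non-zero differences and then dropped
from the signed sums, which is conservative relative to simply discarding
them.  Mid-ranks resolve tied magnitudes.

Hierarchical clustering uses Ward's minimum-variance criterion on Euclidean
distances (scipy linkage) with column-median imputation for missing
features.

No multiple-testing adjustment is applied by default; Benjamini–Hochberg
is available as an option on the batch interface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import false_discovery_control, norm, rankdata

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank_pratt",
    "ward_clustering",
    "compare_groups",
    "compare_paired_regions",
]

EXACT_LIMIT = 12  # largest pooled/usable n for exact enumeration


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


# ---------------------------------------------------------------------------
# Mann–Whitney U


def _exact_mw_p(u: float, n1: int, n2: int, ranks1_sum: float, alternative: str) -> float:
    """Exact p by enumerating all C(n1+n2, n1) assignments of ranks to group 1."""
    n = n1 + n2
    all_ranks = range(1, n + 1)
    us = []
    for combo in itertools.combinations(all_ranks, n1):
        r1 = sum(combo)
        us.append(r1 - n1 * (n1 + 1) / 2.0)
    us = np.array(us)
    if alternative == "two-sided":
        lo = np.mean(us <= u)
        hi = np.mean(us >= u)
        return min(1.0, 2.0 * min(lo, hi))
    if alternative == "greater":
        return float(np.mean(us >= u))
    return float(np.mean(us <= u))


def mann_whitney_u(
    group1, group2, alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U from mid-ranks with tie-corrected normal approximation.

    ``alternative`` is ``two-sided`` (default), ``greater`` (group1 tends
    larger) or ``less``.  NaNs are dropped.  Exact enumeration is used for
    tie-free pooled samples of at most 12 observations.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _clean(group1)
    y = _clean(group2)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty after NA removal")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # U for group 1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if len(tie_counts) == 1:
        # all values identical in both groups: no evidence either way
        return TestResult(u1, 1.0, "mann-whitney-u degenerate (all tied)", n1, n2)

    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        p = _exact_mw_p(u1, n1, n2, r1, alternative)
        return TestResult(u1, p, "mann-whitney-u exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u1, 1.0, "mann-whitney-u degenerate (all tied)", n1, n2)
    sd = math.sqrt(sigma2)
    # continuity correction toward the mean
    if alternative == "two-sided":
        z = (abs(u1 - mu) - 0.5) / sd
        p = 2.0 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u1 - mu - 0.5) / sd
        p = norm.sf(z)
    else:
        z = (u1 - mu + 0.5) / sd
        p = norm.cdf(z)
    return TestResult(
        u1, min(1.0, p), "mann-whitney-u normal approx, tie-corrected", n1, n2
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed rank, Pratt zeros


def _exact_wilcoxon_p(w_plus: float, ranks: np.ndarray, alternative: str) -> float:
    """Exact p by enumerating all 2^m sign patterns over the non-zero ranks."""
    m = len(ranks)
    total = ranks.sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=m):
        ws.append(float(np.dot(signs, ranks)))
    ws = np.array(ws)
    if alternative == "two-sided":
        lo = np.mean(ws <= w_plus)
        hi = np.mean(ws >= w_plus)
        return min(1.0, 2.0 * min(lo, hi))
    if alternative == "greater":
        return float(np.mean(ws >= w_plus))
    return float(np.mean(ws <= w_plus))


def wilcoxon_signed_rank_pratt(
    paired_diffs, alternative: str = "two-sided"
) -> TestResult:
    """Signed-rank test on paired differences with Pratt zero handling.

    Zero differences are ranked together with the rest (mid-ranks over
    |d|), then dropped from the signed sums.  Exact enumeration over sign
    patterns when the number of non-zero differences is ≤ 12 and their
    magnitudes are tie-free; otherwise a normal approximation with
    variance Σr²/4 over the non-zero ranks (which absorbs both the zero
    and tie corrections).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = _clean(paired_diffs)
    if len(d) == 0:
        raise ValueError("no usable paired differences after NA removal")

    ranks_all = rankdata(np.abs(d))  # zeros included in the ranking (Pratt)
    nonzero = d != 0
    m = int(nonzero.sum())
    n = len(d)
    if m == 0:
        return TestResult(0.0, 1.0, "wilcoxon-pratt degenerate (all zero)", n, n)

    r = ranks_all[nonzero]
    w_plus = float(r[d[nonzero] > 0].sum())

    mags = np.abs(d[nonzero])
    tie_free = len(np.unique(mags)) == m and not (d == 0).any()
    if tie_free and m <= EXACT_LIMIT:
        p = _exact_wilcoxon_p(w_plus, r, alternative)
        return TestResult(w_plus, p, "wilcoxon-pratt exact", n, n)

    mu = r.sum() / 2.0
    sigma2 = (r**2).sum() / 4.0
    if sigma2 <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon-pratt degenerate", n, n)
    sd = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(w_plus - mu) - 0.5) / sd
        p = 2.0 * norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (w_plus - mu - 0.5) / sd
        p = norm.sf(z)
    else:
        z = (w_plus - mu + 0.5) / sd
        p = norm.cdf(z)
    return TestResult(
        w_plus, min(1.0, p), "wilcoxon-pratt normal approx, tie-corrected", n, n
    )


# ---------------------------------------------------------------------------
# Ward clustering


def ward_clustering(matrix, k: int) -> np.ndarray:
    """Cut a Ward-linkage dendrogram into ``k`` clusters.

    ``matrix`` is samples × features; NaN features are imputed by column
    median (a column that is all-NaN is dropped).  Returns integer labels
    in ``1..k``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples x features)")
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, n_samples={n}]")
    col_ok = ~np.all(np.isnan(X), axis=0)
    X = X[:, col_ok]
    if X.shape[1] == 0:
        raise ValueError("no usable features after dropping all-NaN columns")
    med = np.nanmedian(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X = X.copy()
    X[nan_r, nan_c] = med[nan_c]
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# batch interfaces over density tables


def compare_groups(
    table: pd.DataFrame,
    hgp_labels: pd.Series | dict,
    *,
    value: str = "density_per_mm2",
    by: list[str] | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Mann–Whitney dHGP-vs-ndHGP comparison per stratum of a density table.

    ``table`` is a zone- or region-density table with a ``sample_id``
    column; ``hgp_labels`` maps sample_id -> "dHGP"/"ndHGP".  Strata are
    the non-sample key columns present (``by`` overrides autodetection).
    NA densities are dropped pairwise.  ``adjust="bh"`` adds a
    Benjamini–Hochberg ``q_value`` column (off by default).
    """
    if isinstance(hgp_labels, dict):
        hgp_labels = pd.Series(hgp_labels)
    if by is None:
        candidates = ["measure", "subset", "zone", "region", "compartment"]
        by = [c for c in candidates if c in table.columns]
    return _compare_groups_impl(table, hgp_labels, value, by, adjust)


def _compare_groups_impl(table, hgp_labels, value, by, adjust):
    rows = []
    labeled = table.assign(hgp=table["sample_id"].map(hgp_labels))
    if labeled["hgp"].isna().any():
        missing = labeled.loc[labeled["hgp"].isna(), "sample_id"].unique()
        raise ValueError(f"samples without growth-pattern label: {list(missing)[:5]}")
    for key, grp in labeled.groupby(by, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        g1 = grp.loc[grp["hgp"] == "dHGP", value].dropna()
        g2 = grp.loc[grp["hgp"] == "ndHGP", value].dropna()
        if len(g1) == 0 or len(g2) == 0:
            continue
        res = mann_whitney_u(g1, g2)
        row = dict(zip(by, key))
        row.update(
            {
                "n_dhgp": res.n1,
                "n_ndhgp": res.n2,
                "median_dhgp": float(g1.median()),
                "median_ndhgp": float(g2.median()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        out["q_value"] = false_discovery_control(out["p_value"], method="bh")
    return out


def compare_paired_regions(
    region_table: pd.DataFrame,
    *,
    region_a: str = "CENTRAL",
    region_b: str = "PERIPHERY",
    value: str = "density_per_mm2",
    compartment: str = "TOTAL",
) -> pd.DataFrame:
    """Wilcoxon (Pratt) test of region_a − region_b within samples, per subset."""
    t = region_table[region_table["compartment"] == compartment]
    rows = []
    for subset, grp in t.groupby("subset", sort=True):
        piv = grp.pivot_table(
            index="sample_id", columns="region", values=value, aggfunc="first"
        )
        if region_a not in piv.columns or region_b not in piv.columns:
            continue
        diffs = (piv[region_a] - piv[region_b]).dropna()
        if len(diffs) == 0:
            continue
        res = wilcoxon_signed_rank_pratt(diffs)
        rows.append(
            {
                "subset": subset,
                "n_pairs": len(diffs),
                "median_diff": float(diffs.median()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
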