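"""ddCt relative quantification of validation qPCR with exact Mann-Whitney.

Relative expression follows the classic ddCt convention with an assumed
amplification efficiency of 2: per sample,

    dCt   = Ct(target) - Ct(housekeeping)          (miR-16-5p by convention)
    ddCt  = dCt - mean(dCt over the reference group)
    fold  = 2 ** (-ddCt)

so the reference group's mean ddCt is 0 and its geometric-mean fold change
is 1.  Technical replicates are averaged to one Ct per sample beforehand.

Group comparison uses the exact two-sided Mann-Whitney U test on the
per-sample dCt values (rank-equivalent to testing the fold changes).  With
ties an asymptotic mid-rank fallback is used and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._io import PathLike

log = logging.getLogger(__name__)

HOUSEKEEPING = "miR-16-5p"


@dataclass
class FoldChangeResult:
    """Per-sample folds plus group summaries and the group-comparison p."""

    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, fold_change
    summary: pd.DataFrame     # group, n, mean_fold, sd_fold
    p_value: float
    p_exact: bool
    reference_group: str


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates: mean Ct per (sample_id, group)."""
    return (
        table.groupby(["sample_id", "group"], as_index=False, sort=False)[
            ["ct_target", "ct_housekeeping"]
        ].mean()
    )


def ddct_fold_changes(
    measurements: pd.DataFrame,
    reference_group: str,
    collapse_replicates: bool = True,
) -> FoldChangeResult:
    """ddCt fold changes relative to ``reference_group``.

    ``measurements`` needs columns sample_id, group, ct_target,
    ct_housekeeping (one row per sample, or several when
    ``collapse_replicates``).  A missing housekeeping Ct is a hard error.
    """
    required = {"sample_id", "group", "ct_target", "ct_housekeeping"}
    if not required <= set(measurements.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    df = measurements.copy()
    if df["ct_housekeeping"].isna().any():
        bad = df.loc[df["ct_housekeeping"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing housekeeping Ct for samples: {bad}")
    if df["ct_target"].isna().any():
        bad = df.loc[df["ct_target"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing target Ct for samples: {bad}")
    if collapse_replicates:
        df = average_replicates(df)
    groups = set(df["group"])
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in {sorted(groups)}")
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {sorted(groups)}")

    df["dct"] = df["ct_target"] - df["ct_housekeeping"]
    ref_mean = df.loc[df["group"] == reference_group, "dct"].mean()
    df["ddct"] = df["dct"] - ref_mean
    df["fold_change"] = np.exp2(-df["ddct"])

    summary = (
        df.groupby("group", sort=False)["fold_change"]
        .agg(n="size", mean_fold="mean", sd_fold="std")
        .reset_index()
    )
    (other,) = groups - {reference_group}
    a = df.loc[df["group"] == other, "dct"].to_numpy()
    b = df.loc[df["group"] == reference_group, "dct"].to_numpy()
    p, exact = mann_whitney_exact(a, b)
    return FoldChangeResult(
        per_sample=df[["sample_id", "group", "dct", "ddct", "fold_change"]],
        summary=summary,
        p_value=p,
        p_exact=exact,
        reference_group=reference_group,
    )


def _rank_sum_counts(n_total: int, n_a: int) -> np.ndarray:
    """Number of size-``n_a`` subsets of ranks 1..n_total per rank sum.

    Classic Mann-Whitney counting recursion; equivalent to enumerating all
    C(n_total, n_a) rank assignments.
    """
    max_sum = n_a * n_total
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_a), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n_a]


def mann_whitney_exact(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, bool]:
    """Exact two-sided Mann-Whitney U p-value.

    The exact null distribution of U is computed over all C(n_a + n_b, n_a)
    equally likely rank assignments; the two-sided p is the probability of a
    U at least as far from its null mean n_a*n_b/2 as observed.  With tied
    values exactness is unavailable; a mid-rank normal approximation is used
    and flagged (second return value False).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) != pooled.size:
        log.warning("ties present: falling back to mid-rank normal approximation")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.pvalue), False
    n_a, n_b = a.size, b.size
    ranks = sps.rankdata(pooled)
    rank_sum_a = ranks[: n_a].sum()
    u = rank_sum_a - n_a * (n_a + 1) / 2.0
    dist = _rank_sum_counts(n_a + n_b, n_a)
    total = math.comb(n_a + n_b, n_a)
    # rank sums run from n_a(n_a+1)/2 upward; convert to U = rs - n_a(n_a+1)/2
    min_rs = n_a * (n_a + 1) // 2
    u_support = np.arange(dist.size) - min_rs
    valid = (u_support >= 0) & (u_support <= n_a * n_b)
    u_support = u_support[valid]
    u_counts = dist[valid]
    mean_u = n_a * n_b / 2.0
    extreme = np.abs(u_support - mean_u) >= abs(u - mean_u) - 1e-9
    p = float(u_counts[extreme].sum() / total)
    return min(p, 1.0), True
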