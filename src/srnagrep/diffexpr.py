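"""Differential expression over small-RNA count tables.

This stage mirrors a pooled 5-vs-5 two-group design (each sample a pool of
five animals): median-of-ratios library-size normalization, a ratio-of-means
log2 fold-change estimator, an exact two-group permutation test as a
transparent built-in significance method, Benjamini-Hochberg adjustment, a
consensus hit rule across methods, and presence/absence detection-set
analysis.

The published negative-binomial / linear-model DE packages are not
re-implemented here; their per-feature result tables can be ingested for the
consensus call, while the built-in method is clearly labelled
``method="permutation"``.

The consensus rule: a method *supports* a feature when that method's adjusted
p-value is below the method's alpha AND that method's |log2FC| exceeds the
fold-change threshold (default 3); a feature is a hit when at least
``min_supporting_methods`` methods support it.  Default alphas follow common
package conventions: adjusted p < 0.05 (deseq2, limma, permutation) and
FDR < 0.1 (edger).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._io import PathLike
from .counts import validate_count_table

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

DEFAULT_METHOD_ALPHAS: dict[str, float] = {
    "deseq2": 0.05,
    "limma": 0.05,
    "edger": 0.1,
    "permutation": 0.05,
}


@dataclass
class SampleDesign:
    """Two-group design: every sample labelled case or control."""

    sample_ids: list[str]
    group: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in design")
        missing = [s for s in self.sample_ids if s not in self.group]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        labels = {self.group[s] for s in self.sample_ids}
        if labels != {CASE, CONTROL}:
            raise ValueError(
                f"design must contain exactly the groups "
                f"{{'{CASE}', '{CONTROL}'}}; got {sorted(labels)}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == CONTROL]

    @property
    def n_case(self) -> int:
        return sum(1 for s in self.sample_ids if self.group[s] == CASE)

    @property
    def n_control(self) -> int:
        return sum(1 for s in self.sample_ids if self.group[s] == CONTROL)


def read_design(path: PathLike) -> SampleDesign:
    """Load a design TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design needs 'sample_id' and 'group' columns")
    return SampleDesign(
        sample_ids=list(df["sample_id"]),
        group=dict(zip(df["sample_id"], df["group"])),
    )


def write_design(design: SampleDesign, path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": design.sample_ids,
         "group": [design.group[s] for s in design.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and effect size
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(
    table: pd.DataFrame, pseudocount: float = 0.0
) -> pd.Series:
    """Median-of-ratios size factors.

    Features with strictly positive counts in every sample form the reference
    set; per sample, the factor is the median over those features of
    count / geometric-mean(count across samples).  With no all-positive
    feature, pass ``pseudocount > 0`` (added for factor estimation only).
    """
    validate_count_table(table)
    mat = table.to_numpy(dtype=float) + pseudocount
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has strictly positive counts in all samples; "
            "rerun with a pseudocount (pseudocount mode)"
        )
    ref = mat[allpos]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=table.columns, name="size_factor")


def normalize(table: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if set(factors.index) != set(table.columns):
        raise ValueError("size factors do not match the table's samples")
    if (factors <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return table.astype(float) / factors[table.columns]


def log2_fold_change(
    normed: pd.DataFrame, design: SampleDesign, pseudocount: float = 0.5
) -> pd.Series:
    """Ratio-of-means log2 fold change, case over control.

    ``log2((mean_case + pc) / (mean_control + pc))``; the pseudocount keeps
    the estimate finite at zero counts.
    """
    mean_case = normed[design.case_samples].mean(axis=1)
    mean_control = normed[design.control_samples].mean(axis=1)
    lfc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    lfc.name = "log2fc"
    return lfc


# ---------------------------------------------------------------------------
# permutation test and BH
# ---------------------------------------------------------------------------

def permutation_test(
    normed: pd.DataFrame,
    design: SampleDesign,
    mode: str = "exact",
    n_perm: int = 10_000,
    seed: int | None = None,
    pseudocount: float = 0.5,
    exact_cap: int = 200_000,
) -> pd.Series:
    """Two-sided two-group permutation p-values per feature.

    The statistic is the difference of group means of
    ``log2(normalized count + pseudocount)``.  Exact mode enumerates all
    C(n, n_case) relabelings (252 for 5v5); the p-value is the proportion of
    relabelings whose |statistic| is >= the observed |statistic| (>= makes
    ties conservative, and the observed labeling is one of the relabelings,
    so p >= 1/K).  Sampled mode draws ``n_perm`` random relabelings and adds
    the observed labeling to numerator and denominator.
    """
    samples = design.sample_ids
    M = np.log2(normed[samples].to_numpy(dtype=float) + pseudocount)
    n = len(samples)
    n_case = design.n_case
    case_mask = np.array([design.group[s] == CASE for s in samples])

    def weights(mask: np.ndarray) -> np.ndarray:
        w = np.where(mask, 1.0 / n_case, -1.0 / (n - n_case))
        return w

    obs = M @ weights(case_mask)
    if mode == "exact":
        total = math.comb(n, n_case)
        if total > exact_cap:
            raise ValueError(
                f"exact mode needs {total} relabelings (> cap {exact_cap}); "
                f"use mode='sampled'"
            )
        case_idx = tuple(i for i, is_case in enumerate(case_mask) if is_case)
        W = np.empty((n, total))
        k_obs = 0
        for k, idx in enumerate(combinations(range(n), n_case)):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            W[:, k] = weights(mask)
            if idx == case_idx:
                k_obs = k
        stats = M @ W
        # take the observed statistic from its own enumerated column so the
        # observed labeling always counts itself (identical rounding)
        obs = stats[:, k_obs]
        p = (np.abs(stats) >= np.abs(obs)[:, None]).mean(axis=1)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(M.shape[0], dtype=np.int64)
        chunk = 512
        done = 0
        while done < n_perm:
            k = min(chunk, n_perm - done)
            W = np.empty((n, k))
            for j in range(k):
                idx = rng.choice(n, size=n_case, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                W[:, j] = weights(mask)
            stats = M @ W
            exceed += (np.abs(stats) >= np.abs(obs)[:, None]).sum(axis=1)
            done += k
        p = (exceed + 1.0) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(p, index=normed.index, name="pvalue")


def bh_adjust(pvalues: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    ``padj_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the ascending
    order statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# consensus hit calling
# ---------------------------------------------------------------------------

@dataclass
class HitCriteria:
    method_alphas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_ALPHAS)
    )
    lfc_threshold: float = 3.0
    min_supporting_methods: int = 1

    def __post_init__(self) -> None:
        for method, alpha in self.method_alphas.items():
            if not 0 < alpha < 1:
                raise ValueError(f"alpha for {method!r} must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.min_supporting_methods < 1:
            raise ValueError("min_supporting_methods must be >= 1")


def call_hits(
    results: pd.DataFrame, criteria: HitCriteria | None = None
) -> pd.DataFrame:
    """Consensus hit calling over per-method DE rows.

    ``results`` needs columns ``feature_id``, ``method``, ``log2fc``,
    ``padj`` (``pvalue`` optional).  A method supports a feature iff *that
    method's row* has ``padj < alpha(method)`` and ``|log2fc| >
    lfc_threshold`` (strict inequalities; a missing/NaN padj or log2fc never
    supports).  Returns one row per feature: supporting methods, their count,
    and the hit decision.
    """
    criteria = criteria or HitCriteria()
    required = {"feature_id", "method", "log2fc", "padj"}
    if not required <= set(results.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    unknown = set(results["method"]) - set(criteria.method_alphas)
    if unknown:
        raise ValueError(
            f"methods without an alpha: {sorted(unknown)}; "
            f"known: {sorted(criteria.method_alphas)}"
        )
    rows = []
    for feature_id, sub in results.groupby("feature_id", sort=False):
        supporting = []
        for _, row in sub.iterrows():
            alpha = criteria.method_alphas[row["method"]]
            padj = row["padj"]
            lfc = row["log2fc"]
            if pd.notna(padj) and pd.notna(lfc):
                if padj < alpha and abs(lfc) > criteria.lfc_threshold:
                    supporting.append(row["method"])
        rows.append(
            {
                "feature_id": feature_id,
                "supporting_methods": ",".join(supporting),
                "n_supporting": len(supporting),
                "hit": len(supporting) >= criteria.min_supporting_methods,
            }
        )
    return pd.DataFrame(rows, columns=[
        "feature_id", "supporting_methods", "n_supporting", "hit"
    ])


# ---------------------------------------------------------------------------
# detection sets
# ---------------------------------------------------------------------------

@dataclass
class DetectionRule:
    """Presence rule: nonzero counts in >= min_positive of a group's samples."""

    min_positive_samples: int = 3
    of_samples: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.min_positive_samples <= self.of_samples:
            raise ValueError("need 1 <= min_positive_samples <= of_samples")


@dataclass
class DetectionSets:
    detected_case: frozenset[str]
    detected_control: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.detected_case & self.detected_control

    @property
    def case_only(self) -> frozenset[str]:
        return self.detected_case - self.detected_control

    @property
    def control_only(self) -> frozenset[str]:
        return self.detected_control - self.detected_case


def detection_sets(
    table: pd.DataFrame,
    design: SampleDesign,
    rule: DetectionRule | None = None,
) -> DetectionSets:
    """Per-group detected feature sets under the k-of-n presence rule."""
    rule = rule or DetectionRule()
    detected = {}
    for label, samples in (
        (CASE, design.case_samples),
        (CONTROL, design.control_samples),
    ):
        if len(samples) != rule.of_samples:
            log.warning(
                "group %s has %d samples, rule expects %d; using actual n",
                label, len(samples), rule.of_samples,
            )
        positive = (table[samples] > 0).sum(axis=1)
        detected[label] = frozenset(table.index[positive >= rule.min_positive_samples])
    return DetectionSets(
        detected_case=detected[CASE], detected_control=detected[CONTROL]
    )


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def de_analysis(
    table: pd.DataFrame,
    design: SampleDesign,
    mode: str = "exact",
    n_perm: int = 10_000,
    seed: int | None = None,
    pseudocount: float = 0.5,
    size_factor_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Counts -> normalized -> log2FC + permutation p + BH, as a result table.

    Returns a DataFrame with columns feature_id, method ("permutation"),
    log2fc, pvalue, padj, ready for :func:`call_hits`.
    """
    factors = size_factors_median_of_ratios(table, pseudocount=size_factor_pseudocount)
    normed = normalize(table, factors)
    lfc = log2_fold_change(normed, design, pseudocount=pseudocount)
    p = permutation_test(
        normed, design, mode=mode, n_perm=n_perm, seed=seed, pseudocount=pseudocount
    )
    return pd.DataFrame(
        {
            "feature_id": table.index,
            "method": "permutation",
            "log2fc": lfc.to_numpy(),
            "pvalue": p.to_numpy(),
            "padj": bh_adjust(p.to_numpy()),
        }
    )


def read_results(paths: Iterable[PathLike]) -> pd.DataFrame:
    """Concatenate per-method DE result TSVs (feature_id, method, log2fc,
    pvalue, padj) for consensus calling."""
    frames = [pd.read_csv(p, sep="\t") for p in paths]
    return pd.concat(frames, ignore_index=True)
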