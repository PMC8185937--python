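"""Group comparisons: rank tests, Fisher's exact test, ROC/AUC, genome scan.

The regional statistic compared between clinicopathologic groups is the
per-case covered fraction of a region in one direction (continuous in
[0, 1]; a binary overlap indicator is available).  The genome-wide scan
applies the two-group Wilcoxon rank-sum comparison to every SOR segment;
raw p-values are reported by default with optional Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .cna_io import CaseSet
from .sor import Region, SorProfile, per_case_region_burden

__all__ = [
    "WilcoxonResult",
    "GroupComparison",
    "RocResult",
    "FisherResult",
    "wilcoxon_rank_sum",
    "compare_region",
    "differential_scan",
    "roc_auc",
    "fisher_exact_2x2",
    "bh_adjust",
]

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # 'exact' or 'asymptotic'


@dataclass(frozen=True)
class GroupComparison:
    region: Optional[Region]
    direction: Optional[str]
    groups: tuple
    n_per_group: tuple
    statistic: float
    p_value: float
    alternative: str


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    bootstrap_reps: int
    seed: int


@dataclass(frozen=True)
class FisherResult:
    table: tuple
    p_value: float


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most 10 and the
    data are tie-free; otherwise the normal approximation with mid-rank tie
    correction and continuity correction.  ``alternative='less'`` means the
    first sample tends to smaller values.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # fully tied data carry no ordering information
        return WilcoxonResult(x.size * y.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 10:
        if has_ties:
            # ties make the rank-sum null distribution data-dependent, so
            # enumerate the permutation distribution of the observed data
            method = sps.PermutationMethod(n_resamples=100_000,
                                           rng=np.random.default_rng(0))
            name = "permutation"
        else:
            method = "exact"
            name = "exact"
    else:
        method = "asymptotic"
        name = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), name)


def _two_group_values(values: pd.Series, grouping, group_order=None):
    grouping = pd.Series(grouping)
    grouping = grouping.loc[values.index]
    labels = list(group_order) if group_order is not None else sorted(
        grouping.dropna().unique()
    )
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    x = values[grouping == labels[0]]
    y = values[grouping == labels[1]]
    if x.empty or y.empty:
        raise ValueError("both groups must be non-empty")
    return labels, x.to_numpy(), y.to_numpy()


def compare_region(case_set: CaseSet, region: Region, direction: str,
                   grouping: Union[pd.Series, Mapping], alternative: str = "two-sided",
                   binary: bool = False, group_order=None) -> GroupComparison:
    """Wilcoxon comparison of per-case region burden between two groups.

    The ``alternative`` refers to the first label of ``group_order``
    (sorted labels by default): ``'greater'`` tests whether that group has
    larger burdens.
    """
    burden = per_case_region_burden(case_set, region, direction, binary=binary)
    labels, x, y = _two_group_values(burden, grouping, group_order)
    res = wilcoxon_rank_sum(x, y, alternative=alternative)
    return GroupComparison(
        region=region,
        direction=direction,
        groups=tuple(labels),
        n_per_group=(len(x), len(y)),
        statistic=res.statistic,
        p_value=res.p_value,
        alternative=alternative,
    )


def differential_scan(case_set: CaseSet, profile: SorProfile,
                      grouping: Union[pd.Series, Mapping],
                      alternative: str = "two-sided", binary: bool = False,
                      adjust: bool = False, group_order=None) -> pd.DataFrame:
    """Apply :func:`compare_region` to every SOR segment of a profile.

    Returns one row per segment (chromosome, start, end, direction, group
    sizes, U statistic, p_value and, with ``adjust=True``, a
    Benjamini-Hochberg ``p_adj`` column).
    """
    rows = []
    for seg in profile.segments:
        cmp = compare_region(case_set, seg.region, seg.direction, grouping,
                             alternative=alternative, binary=binary,
                             group_order=group_order)
        rows.append(
            {
                "chromosome": seg.chromosome,
                "start": seg.start,
                "end": seg.end,
                "direction": seg.direction,
                "rf": seg.rf,
                f"n_{cmp.groups[0]}": cmp.n_per_group[0],
                f"n_{cmp.groups[1]}": cmp.n_per_group[1],
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
            }
        )
    table = pd.DataFrame(rows)
    if adjust and not table.empty:
        table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    return table


def roc_auc(scores, labels, bootstrap_reps: int = 2000, seed: int = 1) -> RocResult:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2),
    with a stratified percentile-bootstrap confidence interval.

    Bootstrap resamples positives and negatives independently (with
    replacement) so each replicate keeps both classes, then takes the 2.5th
    and 97.5th percentiles of the replicate AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    reps = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        p = rng.choice(pos, size=n_pos, replace=True)
        q = rng.choice(neg, size=n_neg, replace=True)
        # rank formulation of the Mann-Whitney probability
        ranks = sps.rankdata(np.concatenate([p, q]))
        u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
        reps[b] = u / (n_pos * n_neg)
    ci_low, ci_high = np.percentile(reps, [2.5, 97.5])
    ci_low = min(float(ci_low), auc)
    ci_high = max(float(ci_high), auc)
    return RocResult(auc, ci_low, ci_high, n_pos, n_neg, bootstrap_reps, seed)


def fisher_exact_2x2(counts) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 table (hypergeometric tail)."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(int)
        if np.any(table < 0):
            raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margin: a row or column sums to zero")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return FisherResult(tuple(map(tuple, table.tolist())), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
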