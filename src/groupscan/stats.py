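"""Pairwise statistical comparison of gene groups.

Binary features (e.g. motif presence) are compared with Fisher's exact test
(two-sided by the point-probability convention: the p-value sums every table,
conditional on the margins, whose probability does not exceed the observed
one).  Continuous features (lengths, intron counts, ...) use the
Mann-Whitney U test: exact enumeration when n_x + n_y <= 14 and no ties are
present, otherwise the normal approximation with midranks, tie-corrected
variance and continuity correction.  Within each feature, p-values are
Benjamini-Hochberg adjusted across the group pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import ExclusionLog
from .expression import adjust_bh

__all__ = [
    "PairwiseTestResult",
    "fisher_exact",
    "mannwhitney_u",
    "pairwise_compare",
]

EXACT_MAX_N = 14


@dataclass
class PairwiseTestResult:
    feature: str
    group_a: str
    group_b: str
    test: str  # "fisher" | "mannwhitney"
    statistic: float  # odds ratio or U (of group_a)
    p: float
    p_adj: float
    n_a: int
    n_b: int


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns (odds_ratio, p) with the sample odds ratio (a*d)/(b*c), inf when
    b*c == 0 and a*d > 0, and nan for the degenerate 0/0 case.  An all-zero
    table is an error.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table has no defined test")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def mannwhitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (of x) and two-sided p.

    Exact enumeration when the combined sample size is at most 14 and no
    ties are present (the exact null requires distinct ranks); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_compare(
    feature_table: pd.DataFrame,
    group_members: Mapping[str, Sequence[str]],
    feature_kind: str,
    log: ExclusionLog | None = None,
) -> list[PairwiseTestResult]:
    """Test every feature for every unordered group pair.

    ``feature_table`` is indexed by gene_id with one column per feature;
    ``feature_kind`` is "binary" (Fisher) or "continuous" (Mann-Whitney).
    Missing values are dropped per comparison.  BH adjustment is applied
    within each feature across its pairs.  Pairs where a group has fewer
    than two usable observations for a continuous feature are skipped with
    a log record.
    """
    if feature_kind not in ("binary", "continuous"):
        raise ValueError("feature_kind must be 'binary' or 'continuous'")
    log = log if log is not None else ExclusionLog()
    results: list[PairwiseTestResult] = []
    pairs = list(itertools.combinations(sorted(group_members), 2))
    for feature in feature_table.columns:
        feat_results: list[PairwiseTestResult] = []
        for ga, gb in pairs:
            va = _values(feature_table, feature, group_members[ga])
            vb = _values(feature_table, feature, group_members[gb])
            if feature_kind == "binary":
                if va.size == 0 or vb.size == 0:
                    log.add("stats", f"{ga}~{gb}", f"{feature}:empty_group")
                    continue
                a, b = int(va.sum()), int(va.size - va.sum())
                c, d = int(vb.sum()), int(vb.size - vb.sum())
                if a + b + c + d == 0:
                    log.add("stats", f"{ga}~{gb}", f"{feature}:all_zero_table")
                    continue
                stat, p = fisher_exact(a, b, c, d)
                test = "fisher"
            else:
                if va.size < 2 or vb.size < 2:
                    log.add("stats", f"{ga}~{gb}", f"{feature}:fewer_than_2_observations")
                    continue
                stat, p = mannwhitney_u(va, vb)
                test = "mannwhitney"
            feat_results.append(
                PairwiseTestResult(
                    feature=str(feature), group_a=ga, group_b=gb, test=test,
                    statistic=stat, p=p, p_adj=math.nan,
                    n_a=int(va.size), n_b=int(vb.size),
                )
            )
        if feat_results:
            adj = adjust_bh(np.array([r.p for r in feat_results]))
            for r, pa in zip(feat_results, adj):
                r.p_adj = float(pa)
        results.extend(feat_results)
    return results


def _values(table: pd.DataFrame, feature: str, members: Sequence[str]) -> np.ndarray:
    present = [g for g in members if g in table.index]
    vals = table.loc[present, feature].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def results_frame(results: Sequence[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "group_a": r.group_a, "group_b": r.group_b,
                "test": r.test, "n_a": r.n_a, "n_b": r.n_b,
                "statistic": r.statistic, "p": r.p, "p_adj": r.p_adj,
            }
            for r in results
        ]
    )
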