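"""RPM normalization, signed fold-changes, DEG/stable classification, and
construction of the six ranked top gene groups (U40/D40/S40, U500/D500/S500).

The classification rules follow the single-library-per-condition design:
per cultivar and time point, stress is compared against control.  A gene is

* up      if fc >= +2, BH-adjusted p <= 0.01, and >= 20 raw reads in at least
          one of the two libraries;
* down    symmetrically with fc <= -2;
* stable  if |fc| <= 1.1 (within 1.1-fold either way) and >= 20 raw reads in
          BOTH libraries;
* none    otherwise.

Signed fold-change is the stress/control RPM ratio when >= 1 and the negative
reciprocal otherwise, with +/-inf sentinels when exactly one side is zero.

Statistical significance comes from a documented stand-in for an exact-test
DEG caller: a two-sided conditional Fisher test on the 2x2 table
[gene reads vs remaining reads] x [stress vs control], BH-corrected across
genes within each comparison.  A user-supplied adjusted-p table (e.g. edgeR
output) takes precedence when provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from ._util import ExclusionLog
from .io_formats import CULTIVARS, TIMEPOINTS, CountMatrix, LibraryKey

__all__ = [
    "ComparisonRecord",
    "GeneGroup",
    "compute_rpm",
    "signed_fold_change",
    "test_differential",
    "test_differential_batch",
    "adjust_bh",
    "classify",
    "classify_counts",
    "build_top_groups",
    "GROUP_NAMES",
]

GROUP_NAMES = ("U40", "D40", "S40", "U500", "D500", "S500")

FC_UP = 2.0
FC_DOWN = -2.0
ALPHA = 0.01
STABLE_BAND = 1.1
MIN_READS = 20


@dataclass
class ComparisonRecord:
    """One gene x cultivar x time point stress-vs-control comparison."""

    gene_id: str
    cultivar: str
    timepoint: float
    rpm_control: float
    rpm_stress: float
    raw_control: int
    raw_stress: int
    fc: float  # signed fold-change, |fc| >= 1, +/-inf sentinels, nan if 0/0
    adj_p: float | None = None
    label: str = "none"


@dataclass
class GeneGroup:
    """A named, ranked gene set with per-gene scores and provenance."""

    name: str
    members: list[str] = field(default_factory=list)
    rank_scores: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rank_scores


def compute_rpm(cm: CountMatrix) -> np.ndarray:
    """Reads per mapped million: 1e6 * count / library size, per column."""
    return 1e6 * cm.counts / cm.library_sizes[np.newaxis, :]


def signed_fold_change(rpm_stress: float, rpm_control: float) -> float:
    """Signed expression ratio: r = stress/control reported as r when >= 1
    and -1/r when < 1; +/-inf when exactly one side is zero, nan when both."""
    if rpm_stress < 0 or rpm_control < 0:
        raise ValueError("RPM values must be non-negative")
    if rpm_stress == 0 and rpm_control == 0:
        return math.nan
    if rpm_control == 0:
        return math.inf
    if rpm_stress == 0:
        return -math.inf
    r = rpm_stress / rpm_control
    return r if r >= 1 else -1.0 / r


def _signed_fc_vector(rpm_stress: np.ndarray, rpm_control: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        r = rpm_stress / rpm_control
        fc = np.where(r >= 1, r, -1.0 / r)
    fc = np.where((rpm_control == 0) & (rpm_stress > 0), np.inf, fc)
    fc = np.where((rpm_stress == 0) & (rpm_control > 0), -np.inf, fc)
    fc = np.where((rpm_stress == 0) & (rpm_control == 0), np.nan, fc)
    return fc


def test_differential_batch(
    raw_stress: np.ndarray,
    raw_control: np.ndarray,
    size_stress: int,
    size_control: int,
) -> np.ndarray:
    """Vectorized two-sided conditional exact test for many genes at once.

    For each gene the 2x2 table is [x_s, N_s - x_s; x_c, N_c - x_c];
    conditioning on the gene total t = x_s + x_c, x_s is hypergeometric, and
    the two-sided p sums all outcomes whose point probability does not exceed
    the observed one (point-probability convention, as in R's fisher.test).
    Genes are grouped by t so each null distribution is computed once.
    """
    x_s = np.asarray(raw_stress, dtype=np.int64)
    x_c = np.asarray(raw_control, dtype=np.int64)
    if size_stress <= 0 or size_control <= 0:
        raise ValueError("library sizes must be positive")
    n_s, n_c = int(size_stress), int(size_control)
    t = x_s + x_c
    p = np.ones(len(x_s))
    lg = gammaln
    denom_base = lg(n_s + 1) + lg(n_c + 1)
    for tot in np.unique(t):
        idx = np.nonzero(t == tot)[0]
        if tot == 0:
            p[idx] = 1.0
            continue
        k = np.arange(max(0, tot - n_c), min(tot, n_s) + 1)
        logpmf = (
            denom_base
            - lg(k + 1)
            - lg(n_s - k + 1)
            - lg(tot - k + 1)
            - lg(n_c - tot + k + 1)
            - (lg(n_s + n_c + 1) - lg(tot + 1) - lg(n_s + n_c - tot + 1))
        )
        pmf = np.exp(logpmf)
        obs = logpmf[x_s[idx] - k[0]]
        # 1+1e-7 relative tolerance absorbs floating-point ties
        sel = logpmf[np.newaxis, :] <= obs[:, np.newaxis] + np.log1p(1e-7)
        p[idx] = np.minimum(1.0, (pmf[np.newaxis, :] * sel).sum(axis=1))
    return p


def test_differential(
    raw_stress: int, raw_control: int, size_stress: int, size_control: int
) -> float:
    """Scalar form of :func:`test_differential_batch`."""
    return float(
        test_differential_batch(
            np.array([raw_stress]), np.array([raw_control]), size_stress, size_control
        )[0]
    )


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    record: ComparisonRecord,
    abundance_min_reads: int = MIN_READS,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
    stable_band: float = STABLE_BAND,
) -> str:
    """Label one comparison as up / down / stable / none."""
    fc = record.fc
    if math.isnan(fc):
        return "none"
    any_abundant = max(record.raw_control, record.raw_stress) >= abundance_min_reads
    both_abundant = min(record.raw_control, record.raw_stress) >= abundance_min_reads
    sig = record.adj_p is not None and record.adj_p <= alpha
    if fc >= fc_up and sig and any_abundant:
        return "up"
    if fc <= fc_down and sig and any_abundant:
        return "down"
    if abs(fc) <= stable_band and both_abundant:
        return "stable"
    return "none"


def classify_counts(
    cm: CountMatrix,
    adjp_table: pd.DataFrame | None = None,
    abundance_min_reads: int = MIN_READS,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
    stable_band: float = STABLE_BAND,
) -> pd.DataFrame:
    """Build the full comparison table (gene x cultivar x time point).

    Returns a tidy DataFrame with one row per comparison; columns mirror
    :class:`ComparisonRecord`.  When ``adjp_table`` (columns gene_id,
    cultivar, timepoint, adj_p) is given those values are used verbatim;
    otherwise the stand-in exact test is run and BH-adjusted across genes
    within each comparison.
    """
    genes = np.array(cm.gene_ids)
    user_p = None
    if adjp_table is not None:
        user_p = {
            (str(r.gene_id), str(r.cultivar), float(r.timepoint)): float(r.adj_p)
            for r in adjp_table.itertuples()
        }
    frames = []
    for cultivar in CULTIVARS:
        for tp in TIMEPOINTS:
            ctrl_key = LibraryKey(cultivar, "control", tp)
            strs_key = LibraryKey(cultivar, "stress", tp)
            ic, is_ = cm.library_index(ctrl_key), cm.library_index(strs_key)
            raw_c = cm.counts[:, ic].astype(np.int64)
            raw_s = cm.counts[:, is_].astype(np.int64)
            rpm_c = 1e6 * raw_c / cm.library_sizes[ic]
            rpm_s = 1e6 * raw_s / cm.library_sizes[is_]
            fc = _signed_fc_vector(rpm_s, rpm_c)
            if user_p is not None:
                adj = np.array(
                    [user_p.get((g, cultivar, tp), np.nan) for g in genes]
                )
            else:
                raw_p = test_differential_batch(
                    raw_s, raw_c,
                    int(cm.library_sizes[is_]), int(cm.library_sizes[ic]),
                )
                adj = adjust_bh(raw_p)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "cultivar": cultivar,
                        "timepoint": tp,
                        "rpm_control": rpm_c,
                        "rpm_stress": rpm_s,
                        "raw_control": raw_c,
                        "raw_stress": raw_s,
                        "fc": fc,
                        "adj_p": adj,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    any_ab = np.maximum(df.raw_control, df.raw_stress) >= abundance_min_reads
    both_ab = np.minimum(df.raw_control, df.raw_stress) >= abundance_min_reads
    sig = df.adj_p.to_numpy() <= alpha
    fc = df.fc.to_numpy()
    label = np.full(len(df), "none", dtype=object)
    label[(fc >= fc_up) & sig & any_ab] = "up"
    label[(fc <= fc_down) & sig & any_ab] = "down"
    label[(np.abs(fc) <= stable_band) & both_ab] = "stable"
    df["label"] = label
    return df


def _geometric_mean(values: np.ndarray) -> float:
    if np.any(np.isinf(values)):
        return math.inf
    return float(np.exp(np.mean(np.log(values))))


def build_top_groups(
    records: pd.DataFrame,
    n_top: tuple[int, int] = (40, 500),
    log: ExclusionLog | None = None,
) -> dict[str, GeneGroup]:
    """Construct the six ranked groups from the comparison table.

    Membership: U/D at size n_top[0] require the label at ALL time points in
    BOTH cultivars; at size n_top[1] at >= 1 time point in BOTH cultivars.
    Stable groups require the label at all time points in both cultivars at
    either size.  Ranking: U/D by geometric mean |fc| over qualifying
    comparisons (descending; +/-inf sentinels first, ordered by stress RPM);
    S by max |log2 ratio| over all comparisons (ascending, ties by total RPM
    descending).  Final tie-break is always lexicographic gene id.
    """
    log = log if log is not None else ExclusionLog()
    n_small, n_large = n_top
    n_tp = records.timepoint.nunique()
    by_gene = records.groupby("gene_id", sort=True)

    strict: dict[str, list[tuple]] = {"up": [], "down": [], "stable": []}
    loose: dict[str, list[tuple]] = {"up": [], "down": []}
    loose_sets: dict[str, set[str]] = {"up": set(), "down": set()}

    for gene_id, sub in by_gene:
        labels = sub.label
        for direction in ("up", "down"):
            mask = labels == direction
            if not mask.any():
                continue
            per_cultivar = sub.loc[mask].groupby("cultivar").size()
            in_both = all(per_cultivar.get(c, 0) >= 1 for c in CULTIVARS)
            if not in_both:
                continue
            qual = sub.loc[mask]
            absfc = np.abs(qual.fc.to_numpy())
            score = _geometric_mean(absfc)
            max_stress_rpm = float(qual.rpm_stress.max())
            entry = (gene_id, score, max_stress_rpm, list(map(_comp_tag, qual.itertuples())))
            loose[direction].append(entry)
            loose_sets[direction].add(gene_id)
            if mask.sum() == 2 * n_tp:  # all time points, both cultivars
                strict[direction].append(entry)
        if (labels == "stable").sum() == 2 * n_tp:
            with np.errstate(divide="ignore"):
                log2r = np.log2(sub.rpm_stress.to_numpy() / sub.rpm_control.to_numpy())
            score = float(np.max(np.abs(log2r)))
            total_rpm = float(sub.rpm_stress.sum() + sub.rpm_control.sum())
            strict["stable"].append(
                (gene_id, score, total_rpm, list(map(_comp_tag, sub.itertuples())))
            )

    # genes eligible for both U-large and D-large conflict; drop from both
    conflict = loose_sets["up"] & loose_sets["down"]
    for g in sorted(conflict):
        log.add("groups", g, "conflicting_up_down_eligibility")
    for d in ("up", "down"):
        loose[d] = [e for e in loose[d] if e[0] not in conflict]
        strict[d] = [e for e in strict[d] if e[0] not in conflict]

    def rank_deg(entries: list[tuple]) -> list[tuple]:
        # inf scores first ordered by stress RPM desc, then finite by score desc
        return sorted(
            entries,
            key=lambda e: (
                0 if math.isinf(e[1]) else 1,
                -e[2] if math.isinf(e[1]) else -e[1],
                e[0],
            ),
        )

    def rank_stable(entries: list[tuple]) -> list[tuple]:
        return sorted(entries, key=lambda e: (e[1], -e[2], e[0]))

    groups: dict[str, GeneGroup] = {}
    for name, entries, n in (
        (f"U{n_small}", rank_deg(strict["up"]), n_small),
        (f"D{n_small}", rank_deg(strict["down"]), n_small),
        (f"S{n_small}", rank_stable(strict["stable"]), n_small),
        (f"U{n_large}", rank_deg(loose["up"]), n_large),
        (f"D{n_large}", rank_deg(loose["down"]), n_large),
        (f"S{n_large}", rank_stable(strict["stable"]), n_large),
    ):
        if len(entries) < n:
            log.add("groups", name, f"only_{len(entries)}_eligible_of_{n}")
        top = entries[:n]
        groups[name] = GeneGroup(
            name=name,
            members=[e[0] for e in top],
            rank_scores={e[0]: e[1] for e in top},
            provenance={e[0]: e[3] for e in top},
        )
    return groups


def _comp_tag(row) -> str:
    return f"{row.cultivar}:{row.timepoint:g}h"
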