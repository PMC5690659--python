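"""RPM, fold-change, stand-in exact test, BH, classification, top groups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupscan.expression import (
    ComparisonRecord,
    adjust_bh,
    build_top_groups,
    classify,
    classify_counts,
    compute_rpm,
    signed_fold_change,
)
from groupscan.expression import test_differential as standin_test
from groupscan.expression import test_differential_batch as standin_test_batch
from groupscan.io_formats import CountMatrix, LibraryKey
from groupscan.simulate import GeneratorConfig, generate_dataset


def _lib_keys():
    return [
        LibraryKey(cv, cond, tp)
        for cv in ("tolerant", "sensitive")
        for cond in ("control", "stress")
        for tp in (0.5, 4.0, 28.0)
    ]


class TestRpm:
    def test_direct_formula(self):
        cm = CountMatrix(["g1"], _lib_keys(),
                         np.full((1, 12), 20), np.full(12, 2_000_000))
        assert np.allclose(compute_rpm(cm), 10.0)

    def test_zero_counts(self):
        cm = CountMatrix(["g1"], _lib_keys(), np.zeros((1, 12)), np.full(12, 1e6))
        assert np.all(compute_rpm(cm) == 0)

    def test_column_sum_linearity(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, (30, 12))
        sizes = np.full(12, 5e5)
        cm = CountMatrix([f"g{i}" for i in range(30)], _lib_keys(), counts, sizes)
        rpm = compute_rpm(cm)
        assert np.allclose(rpm.sum(axis=0), 1e6 * counts.sum(axis=0) / sizes)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "s,c,expected",
        [(18, 9, 2.0), (9, 18, -2.0), (10, 10, 1.0), (0, 5, -math.inf), (5, 0, math.inf)],
    )
    def test_examples(self, s, c, expected):
        assert signed_fold_change(s, c) == expected

    def test_both_zero_is_nan(self):
        assert math.isnan(signed_fold_change(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(-1, 2)

    @given(
        a=st.floats(0.01, 1e6), b=st.floats(0.01, 1e6)
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        if abs(a - b) < 1e-12:
            return
        assert signed_fold_change(a, b) == pytest.approx(
            -signed_fold_change(b, a), rel=1e-9
        )


def _hypergeom_two_sided(x_s, x_c, n_s, n_c):
    """Brute-force point-probability oracle over the full conditional support."""
    from math import comb

    t = x_s + x_c
    lo, hi = max(0, t - n_c), min(t, n_s)
    weights = {k: comb(n_s, k) * comb(n_c, t - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[x_s]
    return sum(w for w in weights.values() if w <= obs) / total


class TestStandInDifferentialTest:
    def test_identical_margins_give_p_one(self):
        assert standin_test(10, 10, 10**6, 10**6) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # 40 vs 10 reads in equal-size libraries (scaled down so the oracle
        # enumerates quickly), plus assorted asymmetric tables
        cases = [(40, 10, 10_000, 10_000), (3, 9, 2_000, 4_000), (0, 7, 1_000, 1_000)]
        for xs, xc, ns, nc in cases:
            assert standin_test(xs, xc, ns, nc) == pytest.approx(
                _hypergeom_two_sided(xs, xc, ns, nc), rel=1e-9
            )

    def test_invariant_under_library_swap(self):
        p1 = standin_test(25, 9, 50_000, 80_000)
        p2 = standin_test(9, 25, 80_000, 50_000)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(3)
        xs = rng.integers(0, 50, 20)
        xc = rng.integers(0, 50, 20)
        batch = standin_test_batch(xs, xc, 30_000, 40_000)
        for i in range(20):
            assert batch[i] == pytest.approx(
                standin_test(int(xs[i]), int(xc[i]), 30_000, 40_000), rel=1e-9
            )

    def test_null_calibration_small(self):
        # quick version of the full calibration (acceptance suite runs 10k)
        rng = np.random.default_rng(11)
        xs = rng.poisson(100, 2000)
        xc = rng.poisson(100, 2000)
        frac = (standin_test_batch(xs, xc, 10**6, 10**6) <= 0.05).mean()
        assert frac <= 0.06


class TestAdjustBh:
    def test_step_up_by_hand(self):
        # p_(i) * m/i = [.04, .04, .04, .04]; running min from the top = .04
        out = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_all_equal_unchanged(self):
        out = adjust_bh(np.full(7, 0.2))
        assert np.allclose(out, 0.2)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        out = adjust_bh(p)
        assert np.all(out >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestClassify:
    def _rec(self, fc, adj_p, raw_c, raw_s):
        return ComparisonRecord("g", "tolerant", 4.0, raw_c / 2, raw_s / 2,
                                raw_c, raw_s, fc, adj_p)

    def test_up_at_thresholds(self):
        assert classify(self._rec(2.0, 0.005, 10, 40)) == "up"

    def test_stable_band(self):
        assert classify(self._rec(1.05, None, 30, 30)) == "stable"

    def test_significance_required(self):
        assert classify(self._rec(3.0, 0.02, 30, 90)) == "none"

    def test_stable_needs_both_libraries_abundant(self):
        assert classify(self._rec(1.05, None, 30, 10)) == "none"

    def test_down_mirror(self):
        assert classify(self._rec(-2.5, 0.001, 50, 10)) == "down"

    def test_labels_mutually_exclusive_by_thresholds(self):
        # no fc satisfies both |fc|>=2 and |fc|<=1.1
        for fc in (-5, -2, -1.1, 1, 1.1, 2, 5):
            labels = set()
            for adj_p in (0.001, 1.0):
                labels.add(classify(self._rec(fc, adj_p, 100, 100)))
            assert not ({"up", "stable"} <= labels or {"down", "stable"} <= labels)


def _records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cultivar", "timepoint", "rpm_control", "rpm_stress",
                 "raw_control", "raw_stress", "fc", "adj_p", "label"],
    )


def _full_design_rows(gene, labels_by_comp, fc=4.0):
    rows = []
    for cv in ("tolerant", "sensitive"):
        for tp in (0.5, 4.0, 28.0):
            label = labels_by_comp.get((cv, tp), "none")
            f = fc if label == "up" else (-fc if label == "down" else 1.0)
            rows.append([gene, cv, tp, 100.0, 100.0 * max(f, 0) if f > 0 else 25.0,
                        200, 200, f, 0.001, label])
    return rows


class TestBuildTopGroups:
    def test_all_comparison_gene_in_both_sizes(self):
        all_up = {(cv, tp): "up" for cv in ("tolerant", "sensitive")
                  for tp in (0.5, 4.0, 28.0)}
        df = _records_frame(_full_design_rows("g1", all_up))
        groups = build_top_groups(df)
        assert "g1" in groups["U40"] and "g1" in groups["U500"]

    def test_single_timepoint_both_cultivars_only_large_group(self):
        one_tp = {("tolerant", 4.0): "up", ("sensitive", 4.0): "up"}
        df = _records_frame(_full_design_rows("g1", one_tp))
        groups = build_top_groups(df)
        assert "g1" not in groups["U40"] and "g1" in groups["U500"]

    def test_single_cultivar_in_neither(self):
        one_cv = {("tolerant", tp): "up" for tp in (0.5, 4.0, 28.0)}
        df = _records_frame(_full_design_rows("g1", one_cv))
        groups = build_top_groups(df)
        assert "g1" not in groups["U40"] and "g1" not in groups["U500"]

    def test_groups_disjoint_and_ranked(self):
        rows = []
        for i, fc in enumerate([8.0, 4.0, 16.0]):
            all_up = {(cv, tp): "up" for cv in ("tolerant", "sensitive")
                      for tp in (0.5, 4.0, 28.0)}
            rows += _full_design_rows(f"g{i}", all_up, fc=fc)
        df = _records_frame(rows)
        groups = build_top_groups(df)
        assert groups["U40"].members == ["g2", "g0", "g1"]  # by |fc| descending
        assert not set(groups["U40"].members) & set(groups["D40"].members)


class TestParameterRecoverySmall:
    def test_planted_up_genes_recovered(self):
        # one-seed spot check; the acceptance suite runs the full 50-seed design
        ds = generate_dataset(GeneratorConfig(n_genes=500), 77, with_sequences=False)
        rec = classify_counts(ds.counts)
        truth = ds.truth.set_index("gene_id")
        planted = set(truth.index[truth["class"] == "up"])
        sub = rec[rec.gene_id.isin(planted)]
        rate = (sub.label == "up").mean()
        assert rate >= 0.95
        groups = build_top_groups(rec)
        assert len(planted & set(groups["U500"].members)) / len(planted) >= 0.95
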