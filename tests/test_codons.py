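"""Codon counting, RSCU normalization, group pooling, tRNA annotation."""

import numpy as np
import pandas as pd
import pytest

from groupscan.codons import (
    CODON_TO_AA,
    FAMILIES,
    RSCU_CODONS,
    TWO_FOLD_NNY,
    count_all_windows,
    count_codons,
    group_rscu,
    join_trna_copies,
    rscu,
    rscu_long,
)


def brute_force_tally(cds):
    out = {}
    for i in range(0, len(cds), 3):
        c = cds[i : i + 3]
        if c in CODON_TO_AA and "N" not in c:
            out[c] = out.get(c, 0) + 1
    return out


class TestCountCodons:
    def test_met_tracked_but_rscu_ineligible(self):
        t = count_codons("ATGATGATG")
        assert t.counts["ATG"] == 3
        vals = rscu(t)
        assert "ATG" not in vals

    def test_90_codon_cds_windows_partition(self):
        rng = np.random.default_rng(4)
        cds = "".join(
            rng.choice(["GCT", "GCC", "AAA", "TTC", "GGA", "CAT"], 90)
        )
        tables = count_all_windows(cds)
        assert set(tables) == {"full", "start30", "middle30", "end30"}
        for w in ("start30", "middle30", "end30"):
            assert tables[w].total() == 30
        summed = {
            c: sum(tables[w].counts[c] for w in ("start30", "middle30", "end30"))
            for c in tables["full"].counts
        }
        assert summed == tables["full"].counts

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            cds = "".join(rng.choice(list("ACGT"), 3 * int(rng.integers(5, 120))))
            cds = cds  # may contain stop triplets; they are simply not counted
            t = count_codons(cds)
            brute = brute_force_tally(cds)
            assert {c: n for c, n in t.counts.items() if n} == brute

    def test_codons_with_n_skipped(self):
        t = count_codons("ATNGCTAAA")
        assert t.n_skipped == 1 and t.counts["GCT"] == 1

    def test_short_cds_windowed_absent(self):
        assert count_codons("GCT" * 50, "start30") is None


class TestRscu:
    def test_uniform_usage_gives_one(self):
        counts = {c: 5 for c in RSCU_CODONS}
        vals = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_two_fold_family_skew(self):
        vals = rscu({"TTC": 10, "TTT": 0})
        assert vals["TTC"] == pytest.approx(2.0) and vals["TTT"] == 0.0

    def test_six_fold_family_scaling(self):
        leu = FAMILIES["L"]
        assert len(leu) == 6
        vals = rscu({leu[0]: 6})
        assert vals[leu[0]] == pytest.approx(6.0)
        assert all(vals[c] == 0.0 for c in leu[1:])

    def test_unobserved_family_absent_not_zero(self):
        vals = rscu({"TTC": 3, "TTT": 1})
        assert vals["CAC"] is None

    def test_family_sums_equal_degeneracy(self, rng):
        counts = {c: int(rng.integers(0, 30)) for c in RSCU_CODONS}
        vals = rscu(counts)
        for aa, codons in FAMILIES.items():
            if aa in ("M", "W"):
                continue
            got = [vals[c] for c in codons]
            if any(v is not None for v in got):
                assert sum(got) == pytest.approx(len(codons), abs=1e-9)

    def test_scale_invariance(self, rng):
        counts = {c: int(rng.integers(1, 20)) for c in RSCU_CODONS}
        doubled = {c: 2 * n for c, n in counts.items()}
        v1, v2 = rscu(counts), rscu(doubled)
        assert all(v1[c] == pytest.approx(v2[c]) for c in v1)


class TestGroupRscu:
    def test_pooling_idempotent_for_identical_genes(self):
        cds = "GCTGCCAAATTC" * 30
        matrix = group_rscu({"G": ["a", "b", "c"]}, {x: cds for x in "abc"},
                            genome_column=False)
        single = rscu(count_codons(cds))
        for codon, v in single.items():
            cell = matrix.loc[codon, ("G", "full")]
            if v is None:
                assert np.isnan(cell)
            else:
                assert cell == pytest.approx(v)

    def test_pooling_averages_complementary_usage(self):
        # two genes using exclusively TTC vs exclusively TTT, equal counts
        matrix = group_rscu(
            {"G": ["a", "b"]}, {"a": "TTC" * 40, "b": "TTT" * 40},
            genome_column=False,
        )
        assert matrix.loc["TTC", ("G", "full")] == pytest.approx(1.0)
        assert matrix.loc["TTT", ("G", "full")] == pytest.approx(1.0)

    def test_planted_c_ending_bias_recovered(self, rng):
        # C-ending probability 0.7 vs 0.5 at flat G+C 0.5: pooled RSCU of a
        # two-fold codon estimates 2*P(C) within binomial tolerance
        from groupscan.simulate import sample_cds

        for p_c, name in ((0.7, "biased"), (0.5, "neutral")):
            cds_by_gene = {
                f"g{i}": sample_cds(200, 0.5, 0.5, p_c, rng) for i in range(40)
            }
            matrix = group_rscu({"G": list(cds_by_gene)}, cds_by_gene,
                                genome_column=False)
            pooled_c = np.mean(
                [matrix.loc[c, ("G", "full")] for c in sorted(TWO_FOLD_NNY)
                 if c.endswith("C")]
            )
            assert pooled_c / 2 == pytest.approx(p_c, abs=0.03)

    def test_genome_column_present(self, rng):
        cds_by_gene = {"a": "GCTGCC" * 50, "b": "AAATTC" * 50}
        matrix = group_rscu({"G": ["a"]}, cds_by_gene)
        assert ("genome", "full") in matrix.columns


class TestJoinTrna:
    def test_watson_crick_anticodon_mapping(self):
        matrix = group_rscu({"G": ["a"]}, {"a": "CACCAT" * 60}, genome_column=False)
        long = join_trna_copies(matrix, {"GTG": 7})
        row = long[(long.codon == "CAC") & (long.window == "full")].iloc[0]
        assert row.anticodon == "GTG" and row.trna_copies == 7

    def test_unknown_anticodon_rejected(self):
        matrix = group_rscu({"G": ["a"]}, {"a": "CACCAT" * 60}, genome_column=False)
        with pytest.raises(ValueError, match="ZZZ"):
            join_trna_copies(matrix, {"ZZZ": 1})

    def test_empty_table_no_copy_column(self):
        matrix = group_rscu({"G": ["a"]}, {"a": "CACCAT" * 60}, genome_column=False)
        long = join_trna_copies(matrix, {})
        assert "trna_copies" not in long.columns

    def test_wobble_flag_hand_mapping(self):
        matrix = group_rscu({"G": ["a"]}, {"a": "CACTTTGCAAAG" * 30},
                            genome_column=False)
        long = join_trna_copies(matrix, {}).set_index("codon")
        # His CAC and Phe TTT: two-fold pyrimidine families -> G34-decoded
        assert bool(long.loc["CAC", "wobble_G34"].iloc[0])
        assert bool(long.loc["TTT", "wobble_G34"].iloc[0])
        # Ala GCA: four-fold family -> not G34 two-fold
        assert not bool(long.loc["GCA", "wobble_G34"].iloc[0])

    def test_two_fold_nny_set(self):
        # exactly the Y-ending codons of Phe, Tyr, His, Asn, Asp, Cys (+ Ser AGY)
        assert {"TTC", "TTT", "TAC", "TAT", "CAC", "CAT", "AAC", "AAT",
                "GAC", "GAT", "TGC", "TGT"} <= TWO_FOLD_NNY
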