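"""Synthetic-data generator: determinism, closure with the readers/scanners,
planted-signal integrity."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from groupscan.expression import classify_counts
from groupscan.io_formats import (
    extract_cds,
    read_annotation,
    read_counts,
    read_genome,
    strip_stop,
    validate_cds,
)
from groupscan.motifs import scan_gene
from groupscan.simulate import (
    ClassParams,
    GeneratorConfig,
    assign_truth,
    expected_gc_profile,
    generate_dataset,
    sample_cds,
    write_dataset,
)


def small_config(**kw):
    base = dict(n_genes=80, genes_per_chromosome=40)
    base.update(kw)
    return GeneratorConfig(**base)


class TestConfig:
    def test_fraction_and_fc_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(group_fractions={"up": 0.7, "down": 0.6})
        with pytest.raises(ValueError):
            GeneratorConfig(fc_up=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        again = GeneratorConfig.from_yaml(tmp_path / "c.yaml")
        assert again == cfg


class TestTruth:
    def test_one_record_per_gene_and_fractions(self):
        cfg = GeneratorConfig(n_genes=1000)
        truth = assign_truth(cfg, np.random.default_rng(0))
        assert len(truth) == 1000 and truth.gene_id.is_unique
        counts = truth["class"].value_counts()
        assert counts["up"] == 100 and counts["down"] == 100
        assert counts["stable"] == 250

    def test_multipliers_follow_class(self):
        cfg = GeneratorConfig(n_genes=500)
        truth = assign_truth(cfg, np.random.default_rng(1))
        up = truth[truth["class"] == "up"]
        assert (up.mult_tolerant == cfg.fc_up).all()
        stable = truth[truth["class"] == "stable"]
        assert (stable.mult_tolerant == 1).all()

    def test_divergent_class_opposite_directions(self):
        cfg = GeneratorConfig(
            n_genes=200,
            group_fractions={"up": 0.1, "down": 0.1, "stable": 0.1, "divergent": 0.2},
        )
        truth = assign_truth(cfg, np.random.default_rng(2))
        div = truth[truth["class"] == "divergent"]
        assert len(div) == 40
        assert (div.mult_tolerant > 1).all() and (div.mult_sensitive < 1).all()


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = small_config()
        p1 = write_dataset(cfg, 123, tmp_path / "a")
        p2 = write_dataset(cfg, 123, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        cfg = small_config()
        p1 = write_dataset(cfg, 1, tmp_path / "a")
        p2 = write_dataset(cfg, 2, tmp_path / "b")
        assert not filecmp.cmp(p1["counts"], p2["counts"], shallow=False)


class TestClosure:
    def test_readers_accept_generated_artifacts(self, tmp_path):
        paths = write_dataset(small_config(), 5, tmp_path / "d")
        genome = read_genome(paths["genome"])
        models = read_annotation(paths["annotation"], genome)
        assert len(models) == 80
        cm = read_counts(paths["counts"], paths["library_sizes"])
        assert cm.counts.shape == (80, 12)
        # every CDS is valid and stop-terminated
        for m in models:
            cds = extract_cds(m, genome)
            assert validate_cds(cds) == []
            assert len(strip_stop(cds)) == len(cds) - 3

    def test_annotation_matches_truth_structure(self, small_dataset):
        ds = small_dataset
        truth = ds.truth.set_index("gene_id")
        for m in ds.models[:60]:
            t = truth.loc[m.gene_id]
            assert m.n_variants == t.n_variants
            assert m.strand == t.strand
            cds_nt = sum(e - s for s, e in m.cds_segments)
            assert cds_nt == 3 * (t.cds_codons + 1)

    def test_planted_tata_always_found(self, tmp_path):
        cfg = small_config(
            class_params={
                **GeneratorConfig().class_params,
                "background": ClassParams(1.0, 0.2, 0.2, 3.0, (150, 350), 0.8,
                                          0.55, 0.45, 0.55),
            }
        )
        ds = generate_dataset(cfg, 9)
        truth = ds.truth.set_index("gene_id")
        bg = [m for m in ds.models if truth.loc[m.gene_id, "class"] == "background"]
        assert bg
        for m in bg:
            scans = scan_gene(m, ds.genome)
            assert scans["TATA_consensus"].present

    def test_planted_motifs_equal_scan_results(self, small_dataset):
        ds = small_dataset
        truth = ds.truth.set_index("gene_id")
        found = {"TATA_consensus": 0, "ABRE": 0, "DRE_CRT": 0}
        for m in ds.models:
            scans = scan_gene(m, ds.genome)
            t = truth.loc[m.gene_id]
            # planted => found (scrubbing never removes planted instances)
            if t.tata:
                assert scans["TATA_consensus"].present
            if t.abre:
                assert scans["ABRE"].present
            if t.dre:
                assert scans["DRE_CRT"].present
            for k in found:
                found[k] += scans[k].present
        # false extras are rare (only CDS-protected window bases can harbor them)
        extras = sum(found.values()) - int(
            truth.tata.sum() + truth.abre.sum() + truth.dre.sum()
        )
        assert extras <= 0.05 * len(ds.models)


class TestCounts:
    def test_null_poisson_config_has_no_false_deg_labels(self):
        # under the stand-in test's own (Poisson) noise model, a null config
        # produces essentially no false DEG labels
        cfg = GeneratorConfig(n_genes=1500, fc_up=2.0, fc_down=-2.0,
                              nb_dispersion=0.0,
                              group_fractions={"up": 0.0, "down": 0.0, "stable": 0.3})
        ds = generate_dataset(cfg, 31, with_sequences=False)
        rec = classify_counts(ds.counts)
        assert (rec.label.isin(["up", "down"])).mean() <= 0.005

    def test_null_overdispersed_config_false_label_rate_matches_theory(self):
        # with NB dispersion 0.05 the Poisson-conditional test cannot see the
        # biological overdispersion: the per-comparison false-label rate is
        # ~2*Phi(-ln2/0.332) ~ 3.7%, the known single-replicate caveat
        cfg = GeneratorConfig(n_genes=1500, fc_up=2.0, fc_down=-2.0,
                              group_fractions={"up": 0.0, "down": 0.0, "stable": 0.3})
        ds = generate_dataset(cfg, 31, with_sequences=False)
        rec = classify_counts(ds.counts)
        rate = (rec.label.isin(["up", "down"])).mean()
        assert 0.02 <= rate <= 0.07

    def test_column_sums_scaled_to_library_size(self):
        cfg = GeneratorConfig(
            n_genes=1000, scale_to_library_size=True, fc_up=2.0, fc_down=-2.0,
            group_fractions={"up": 0.0, "down": 0.0, "stable": 0.0},
        )
        ds = generate_dataset(cfg, 8, with_sequences=False)
        sums = ds.counts.counts.sum(axis=0)
        assert np.all(np.abs(sums / cfg.library_size - 1) < 0.05)

    def test_stable_genes_have_equal_means(self):
        cfg = GeneratorConfig(n_genes=4000)
        ds = generate_dataset(cfg, 12, with_sequences=False)
        truth = ds.truth.set_index("gene_id")
        stable = truth["class"] == "stable"
        cm = ds.counts
        ctrl = cm.counts[stable.to_numpy()][:, [0, 1, 2]].mean()
        strs = cm.counts[stable.to_numpy()][:, [3, 4, 5]].mean()
        assert strs / ctrl == pytest.approx(1.0, abs=0.05)


class TestCdsEngine:
    def test_no_stop_codons(self, rng):
        for _ in range(30):
            cds = sample_cds(150, 0.6, 0.4, 0.7, rng)
            assert validate_cds(cds + "TAA") == []

    def test_flat_gc_c_end_probability_exact(self, rng):
        # at g = 0.5 the NNY third-position C probability equals c_end_prob
        n_c = n_t = 0
        for _ in range(40):
            cds = sample_cds(300, 0.5, 0.5, 0.7, rng)
            for i in range(0, len(cds), 3):
                codon = cds[i : i + 3]
                if codon[:2] in ("TT", "TA", "CA", "AA", "GA", "TG") and codon[2] in "CT":
                    if codon[2] == "C":
                        n_c += 1
                    else:
                        n_t += 1
        assert n_c / (n_c + n_t) == pytest.approx(0.7, abs=0.02)

    def test_expected_profile_matches_empirical(self, rng):
        exp = expected_gc_profile(60, 0.6, 0.4, 0.7)
        reps = 400
        sims = np.zeros(180)
        for _ in range(reps):
            cds = sample_cds(60, 0.6, 0.4, 0.7, rng)
            arr = np.frombuffer(cds.encode(), dtype="S1").astype("U1")
            sims += np.isin(arr, ["G", "C"])
        emp = sims / reps
        # per-position binomial se at 400 reps is ~0.025; the mean absolute
        # deviation over 180 positions should sit near its noise floor
        assert np.abs(emp - exp).mean() < 0.03
        # and there is no systematic bias
        assert abs((emp - exp).mean()) < 0.01
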