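"""Shared fixtures: hand-built toy genome/annotation and small simulated
datasets.  Everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from groupscan.io_formats import read_annotation, read_genome
from groupscan.simulate import GeneratorConfig, generate_dataset

TOY_FASTA = """\
>chr1
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC
GTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC
GTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
>chr2
TTTTTTTTTTATGAAACCCGGGTTTTAAGGGTTTTTTTTTTTTTTTTTTT
TTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT
"""

# gA: single-exon plus-strand gene with a 12-nt CDS; gB: minus-strand gene
# with three isoforms (structural only); gC: two-exon plus-strand gene with
# a spliced 15-nt CDS (ATG AAA CCC GGG AGG on chr2)
TOY_GFF = """\
##gff-version 3
chr1\tsrc\tgene\t11\t40\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t11\t40\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tsrc\texon\t11\t40\t.\t+\t.\tParent=gA.1
chr1\tsrc\tCDS\t11\t22\t.\t+\t.\tParent=gA.1
chr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=gB
chr1\tsrc\tmRNA\t101\t200\t.\t-\t.\tID=gB.1;Parent=gB
chr1\tsrc\texon\t101\t140\t.\t-\t.\tParent=gB.1
chr1\tsrc\texon\t161\t200\t.\t-\t.\tParent=gB.1
chr1\tsrc\tmRNA\t101\t200\t.\t-\t.\tID=gB.2;Parent=gB
chr1\tsrc\texon\t101\t200\t.\t-\t.\tParent=gB.2
chr1\tsrc\tmRNA\t101\t190\t.\t-\t.\tID=gB.3;Parent=gB
chr1\tsrc\texon\t101\t190\t.\t-\t.\tParent=gB.3
chr2\tsrc\tgene\t11\t31\t.\t+\t.\tID=gC
chr2\tsrc\tmRNA\t11\t31\t.\t+\t.\tID=gC.1;Parent=gC
chr2\tsrc\texon\t11\t22\t.\t+\t.\tParent=gC.1
chr2\tsrc\texon\t28\t31\t.\t+\t.\tParent=gC.1
chr2\tsrc\tCDS\t11\t22\t.\t+\t.\tParent=gC.1
chr2\tsrc\tCDS\t28\t30\t.\t+\t.\tParent=gC.1
"""


@pytest.fixture()
def toy_paths(tmp_path):
    fa = tmp_path / "toy.fa"
    gff = tmp_path / "toy.gff3"
    fa.write_text(TOY_FASTA)
    gff.write_text(TOY_GFF)
    return fa, gff


@pytest.fixture()
def toy_genome(toy_paths):
    return read_genome(toy_paths[0])


@pytest.fixture()
def toy_models(toy_paths, toy_genome):
    return read_annotation(toy_paths[1], toy_genome)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully materialized synthetic dataset (shared, read-only)."""
    cfg = GeneratorConfig(n_genes=200, genes_per_chromosome=100)
    return generate_dataset(cfg, 20240101)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
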