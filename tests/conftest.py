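from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import m6atlas as m


@pytest.fixture(scope="session")
def default_bundle() -> m.SyntheticBundle:
    """One default-scale synthetic genome shared across tests."""
    return m.generate(m.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_bundle) -> m.SiteTable:
    return m.filter_by_coverage(default_bundle.records, 25)


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory) -> dict[str, Path]:
    """The same bundle written to disk once."""
    outdir = tmp_path_factory.mktemp("bundle")
    return default_bundle.write(outdir)


@pytest.fixture()
def toy_genome() -> m.GenomeSequence:
    # chr length 200; gene fixture spans [11, 100] 1-based
    import numpy as np

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    return m.GenomeSequence({"c1": seq})


TOY_GFF = """##gff-version 3
c1\ttest\tgene\t11\t100\t.\t{strand}\t.\tID=g1;gene_biotype=protein_coding
c1\ttest\tmRNA\t11\t100\t.\t{strand}\t.\tID=g1.t1;Parent=g1
c1\ttest\texon\t11\t40\t.\t{strand}\t.\tID=g1.t1.e1;Parent=g1.t1
c1\ttest\texon\t61\t100\t.\t{strand}\t.\tID=g1.t1.e2;Parent=g1.t1
c1\ttest\tCDS\t21\t40\t.\t{strand}\t0\tID=g1.t1.c1;Parent=g1.t1
c1\ttest\tCDS\t61\t90\t.\t{strand}\t0\tID=g1.t1.c2;Parent=g1.t1
"""


@pytest.fixture()
def toy_gff_path(tmp_path) -> Path:
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF.format(strand="+"))
    return path


@pytest.fixture()
def toy_gff_minus_path(tmp_path) -> Path:
    path = tmp_path / "toy_minus.gff3"
    path.write_text(TOY_GFF.format(strand="-"))
    return path
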