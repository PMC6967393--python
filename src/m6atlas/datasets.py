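"""Small bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def fvesca_site_counts() -> pd.DataFrame:
    """Published per-chromosome adenine and 6mA site counts for the
    woodland strawberry (FraVesHawaii_1.0) assembly.

    Columns: ``group`` (linkage group / chloroplast accession),
    ``n_adenines_minus/plus`` (adenines per strand; minus counts are Ts on
    the forward sequence) and ``n_sites_minus/plus`` (called 6mA sites per
    strand at the 25x coverage cutoff).  Feed to
    :func:`m6atlas.landscape.density_from_counts` to reproduce the
    genome-wide density table.
    """
    with resources.files("m6atlas.data").joinpath("fvesca_v1_site_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
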