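"""Bundled reference catalog of sugarcane miRNA precursors.

The package ships the published catalog of 19 distinct sugarcane miRNA
precursor loci (14 families) recovered from the SoGI EST and NCBI GSS/BAC
collections, together with the reported mature sequence, precursor arm
(5p/3p), trimmed precursor length and minimal-free-energy index (MFEI) of
each locus.  The mature sequences double as the default query set for the
homology scan and the synthetic-data generator; the per-locus MFEI values
feed the report-level summary statistics.

One locus (*SsMIR319*) was annotated on homology grounds only and has no
validated secondary structure; its precursor length and MFEI are missing
(``NaN``) in the catalog.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .homology_scan import MatureQuery

_CATALOG_FILE = "sugarcane_catalog.tsv"


def load_catalog() -> pd.DataFrame:
    """Load the reference catalog as a DataFrame.

    Columns: ``family, source, source_id, gene, mature_sequence,
    mature_sequence_alt, arm, nm, precursor_len, mfei, conserved_in_rice``.
    ``precursor_len`` and ``mfei`` are numeric with ``NaN`` for the
    unvalidated locus.
    """
    ref = resources.files("mircane.data").joinpath(_CATALOG_FILE)
    with ref.open() as handle:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    for col in ("precursor_len", "mfei"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def reference_mature_queries() -> List[MatureQuery]:
    """The 19 catalogued mature miRNAs as scan queries, one per locus.

    For tandem loci carrying two overlapping mature sequences the first
    listed sequence is used.  Query names are the gene symbols, which are
    unique across loci (family names are not).
    """
    df = load_catalog()
    return [
        MatureQuery(family=row.gene, residues=row.mature_sequence,
                    expected_arm=row.arm)
        for row in df.itertuples()
    ]
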