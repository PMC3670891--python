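"""Loaders for the packaged data files.

``table2_mutations.tsv`` transcribes the published cohort mutation table
(9 mutations across 6 cases).  ``cds_synthetic.fa`` and
``gene_status_synthetic.tsv`` are synthetic stand-ins: the mini coding
sequences carry exactly the codons implied by the printed c./p. pairs,
and the status table reproduces the published marginal counts (45 serous
/ 20 clear cell / 42 endometrioid; per-gene and co-occurrence margins)
with synthetic filler case ids for the unmutated cases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort_stats import load_gene_status
from .trace_io import (
    MutationRecord,
    ReferenceSeq,
    SNPCatalog,
    read_fasta,
    read_mutation_table,
    read_snp_catalog,
)


def fixture_path(name: str) -> str:
    return str(resources.files("dipscan") / "data" / name)


def load_table2_mutations() -> list[MutationRecord]:
    """The packaged cohort mutation table (9 records, 6 distinct cases)."""
    return read_mutation_table(fixture_path("table2_mutations.tsv"))


def load_synthetic_cds() -> dict[str, ReferenceSeq]:
    """Synthetic mini-CDS per gene, keyed by gene symbol."""
    return {r.name: r for r in read_fasta(fixture_path("cds_synthetic.fa"), role="CDS")}


def load_gene_status_fixture() -> pd.DataFrame:
    """Per-case mutated flags for ESCO1/CHTF18/MRE11A/ATAD5 (107 cases)."""
    return load_gene_status(fixture_path("gene_status_synthetic.tsv"))


def load_snp_catalog_fixture() -> SNPCatalog:
    """A tiny demonstration SNP catalog."""
    return read_snp_catalog(fixture_path("snp_catalog_synthetic.tsv"))
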