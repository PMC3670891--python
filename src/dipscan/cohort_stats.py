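"""Cohort-level mutation statistics.

Per-gene case frequencies by histological subtype, two-tailed Fisher's
exact co-occurrence tests, discovery-screen power, and oncoprint export.

The two-tailed exact test uses the probability-mass convention: with all
margins fixed, the p-value is the sum of hypergeometric probabilities of
every table no more likely than the observed one.  It is implemented
directly from log-factorials rather than delegated to a statistics
library, since the test itself is a deliverable of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trace_io import MutationRecord

SUBSETS = ("all", "serous", "clear_cell", "endometrioid", "NEEC", "EEC")

_SUBSET_HISTOTYPES = {
    "all": {"serous", "clear cell", "endometrioid"},
    "serous": {"serous"},
    "clear_cell": {"clear cell"},
    "endometrioid": {"endometrioid"},
    "NEEC": {"serous", "clear cell"},
    "EEC": {"endometrioid"},
}


@dataclass(frozen=True)
class CohortSpec:
    """Histotype composition of the screened cohort."""

    n_serous: int = 45
    n_clear_cell: int = 20
    n_endometrioid: int = 42

    def __post_init__(self) -> None:
        if min(self.n_serous, self.n_clear_cell, self.n_endometrioid) < 0:
            raise ValueError("cohort sizes must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_serous + self.n_clear_cell + self.n_endometrioid

    @property
    def n_neec(self) -> int:
        return self.n_serous + self.n_clear_cell

    @property
    def n_eec(self) -> int:
        return self.n_endometrioid

    def subset_size(self, subset: str) -> int:
        sizes = {
            "all": self.n_total,
            "serous": self.n_serous,
            "clear_cell": self.n_clear_cell,
            "endometrioid": self.n_endometrioid,
            "NEEC": self.n_neec,
            "EEC": self.n_eec,
        }
        try:
            return sizes[subset]
        except KeyError:
            raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Mutated/non-mutated cross-counts for two genes.

    a = both mutated, b = gene A only, c = gene B only, d = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def gene_case_frequency(
    records: Sequence[MutationRecord],
    cohort: CohortSpec,
    gene: str,
    subset: str = "all",
) -> tuple[int, int, float]:
    """(k, n, fraction) of distinct mutated cases for one gene in a subset.

    Several mutation rows in one case count once.  ``gene`` may also be a
    collection of gene symbols, in which case a case counts if it carries
    a mutation in any of them.
    """
    histos = _SUBSET_HISTOTYPES.get(subset)
    if histos is None:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    genes = {gene} if isinstance(gene, str) else set(gene)
    cases = {
        r.case_id for r in records if r.gene in genes and r.histotype in histos
    }
    n = cohort.subset_size(subset)
    k = len(cases)
    return k, n, (k / n if n else 0.0)


def build_contingency(
    status: pd.DataFrame, gene_a: str, gene_b: str
) -> ContingencyTable2x2:
    """Cross-tabulate two genes' mutated flags from a per-case status table.

    ``status`` needs one row per case with 0/1 columns named after genes.
    """
    for g in (gene_a, gene_b):
        if g not in status.columns:
            raise ValueError(f"gene {g!r} not in status table")
    fa = status[gene_a].astype(bool)
    fb = status[gene_b].astype(bool)
    return ContingencyTable2x2(
        a=int((fa & fb).sum()),
        b=int((fa & ~fb).sum()),
        c=int((~fa & fb).sum()),
        d=int((~fa & ~fb).sum()),
    )


def contingency_from_margins(
    n_total: int, n_a: int, n_b: int, n_both: int
) -> ContingencyTable2x2:
    """Build the 2x2 table from marginal counts; negative cells are an error."""
    a = n_both
    b = n_a - n_both
    c = n_b - n_both
    d = n_total - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"margins imply a negative cell: total={n_total}, A={n_a}, B={n_b}, both={n_both}"
        )
    return ContingencyTable2x2(a, b, c, d)


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) with row margins r1, r2 and first-column margin c1."""
    n = r1 + r2

    def lchoose(nn: int, kk: int) -> float:
        return (
            math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)
        )

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_two_tailed(table: ContingencyTable2x2, tie_rtol: float = 1e-7) -> float:
    """Two-tailed Fisher's exact test, probability-mass convention.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability is at most that of the observed table (with
    relative tie tolerance ``tie_rtol``).  A table with any zero margin
    returns 1 by convention.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    c2 = table.b + table.d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(table.a, r1, r2, c1)
    cutoff = log_obs + math.log1p(tie_rtol)
    p = 0.0
    for a in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(a, r1, r2, c1)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def fisher_exact_one_tailed(table: ContingencyTable2x2) -> float:
    """One-tailed exact p: the smaller tail of the hypergeometric at the
    observed count (direction of the observed association)."""
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    c2 = table.b + table.d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pmf = {a: math.exp(_log_hypergeom_pmf(a, r1, r2, c1)) for a in range(lo, hi + 1)}
    upper = sum(v for a, v in pmf.items() if a >= table.a)
    lower = sum(v for a, v in pmf.items() if a <= table.a)
    return min(1.0, min(upper, lower))


def discovery_power(x: float, n: int = 24) -> float:
    """Probability of seeing >= 1 mutated tumor among ``n`` screened when a
    fraction ``x`` of tumors carry a mutation: ``1 - (1 - x)**n``."""
    if not 0 <= x <= 1:
        raise ValueError("mutated fraction x must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - x) ** n


def oncoprint_matrix(
    status: pd.DataFrame,
    genes: Sequence[str],
    mutated_only: bool = False,
) -> pd.DataFrame:
    """Binary gene-by-case matrix for oncoprint display.

    Case columns are ordered by number of mutated genes (descending), then
    case id.  With ``mutated_only`` cases without any mutation in
    ``genes`` are dropped.
    """
    for g in genes:
        if g not in status.columns:
            raise ValueError(f"gene {g!r} not in status table")
    sub = status.set_index("case_id")[list(genes)].astype(int)
    if mutated_only:
        sub = sub[sub.sum(axis=1) > 0]
    order = sorted(sub.index, key=lambda c: (-int(sub.loc[c].sum()), c))
    return sub.loc[order].T


def load_gene_status(path) -> pd.DataFrame:
    """Read a per-case gene-status TSV (case_id, histotype, msi_status, genes...)."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    required = {"case_id", "histotype", "msi_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"status table missing columns {sorted(missing)}")
    return df
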