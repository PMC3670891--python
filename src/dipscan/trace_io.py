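"""Readers and writers for every external format the pipeline touches.

Formats
-------
* FASTA for reference amplicons and coding sequences (via Biopython).
* A columnar "poly" TSV dialect for per-position trace peak data: one row
  per read position carrying the primary (largest-area) peak and, when
  present, the secondary peak.  This emulates the per-peak output of a
  Sanger basecaller; the column layout is this package's own and is
  documented below.
* A mutation-table TSV (one annotated somatic mutation per row).
* A SNP-catalog TSV (known polymorphism positions and alleles).
* A variant-report TSV with canonical ordering, so that equal call sets
  produce byte-identical files.

Poly dialect columns (tab-separated, header required)::

    read_id  sample_id  amplicon  strand  ref_start  index
    primary_base  primary_area  secondary_base  secondary_area

``index`` is the 0-based read position; ``ref_start`` is the 1-based
reference coordinate of index 0.  ``secondary_base`` is ``-`` (with area 0)
when only one peak was observed.  Areas are written with 4 fractional
digits.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .variants import VariantCall

BASES = ("A", "C", "G", "T", "N")
HISTOTYPES = ("serous", "clear cell", "endometrioid")
MSI_STATUSES = ("stable", "unstable", "unknown")
MUTATION_TYPES = ("nonsense", "missense", "synonymous", "frameshift", "inframe", "splice")

AREA_DIGITS = 4
AREA_RTOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class ReferenceSeq:
    """A named reference sequence (PCR amplicon or coding sequence)."""

    name: str
    bases: str
    role: str = "amplicon"

    def __post_init__(self) -> None:
        if not self.name or not self.bases:
            raise ValueError("reference name and bases must be non-empty")
        if self.role not in ("amplicon", "CDS"):
            raise ValueError(f"bad role {self.role!r}")
        bad = set(self.bases) - {"A", "C", "G", "T"}
        if bad:
            raise FormatError(f"illegal bases in {self.name}: {sorted(bad)}")
        if self.role == "CDS" and len(self.bases) % 3 != 0:
            raise ValueError(f"CDS {self.name} length {len(self.bases)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PolyRow:
    """Primary and secondary fluorescence peak at one read position."""

    index: int
    primary_base: str
    primary_area: float
    secondary_base: str
    secondary_area: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("row index must be >= 0")
        if self.primary_base not in BASES:
            raise ValueError(f"bad primary base {self.primary_base!r}")
        if self.secondary_base not in BASES + ("-",):
            raise ValueError(f"bad secondary base {self.secondary_base!r}")
        if self.primary_area < 0 or self.secondary_area < 0:
            raise ValueError("peak areas must be non-negative")
        if self.secondary_area > self.primary_area * (1 + AREA_RTOL):
            raise FormatError(
                f"row {self.index}: secondary area {self.secondary_area} exceeds "
                f"primary area {self.primary_area}"
            )
        if self.secondary_base == "-" and self.secondary_area != 0:
            raise FormatError(f"row {self.index}: absent secondary peak must have area 0")


@dataclass(frozen=True)
class TraceRead:
    """All per-position peak data for one sequencing read."""

    read_id: str
    sample_id: str
    amplicon: str
    strand: str
    ref_start: int
    rows: tuple[PolyRow, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.ref_start < 1:
            raise ValueError("ref_start is 1-based and must be >= 1")
        for i, row in enumerate(self.rows):
            if row.index != i:
                raise ValueError(
                    f"read {self.read_id}: rows must be contiguous from 0, "
                    f"got index {row.index} at slot {i}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def primary_string(self) -> str:
        return "".join(r.primary_base for r in self.rows)


@dataclass(frozen=True)
class SNPCatalog:
    """Known-polymorphism positions; stands in for a dbSNP extract."""

    entries: frozenset[tuple[str, int, str]] = frozenset()

    def __contains__(self, item: tuple[str, int, str]) -> bool:
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic mutation (the mutation-table row type).

    ``cdna_change`` / ``protein_change`` use the compact dialect
    ``c.<ref><pos><alt>`` and ``p.<refAA><codon><altAA>`` with ``X`` for a
    stop codon.  The three ``predicted_*`` columns carry external impact
    predictions as free text; this package never computes them.
    """

    case_id: str
    gene: str
    histotype: str
    msi_status: str
    cdna_change: str
    protein_change: str
    mutation_type: str
    predicted_assessor: str = ""
    predicted_sift: str = ""
    predicted_polyphen: str = ""

    def __post_init__(self) -> None:
        if self.histotype not in HISTOTYPES:
            raise ValueError(f"bad histotype {self.histotype!r}")
        if self.msi_status not in MSI_STATUSES:
            raise ValueError(f"bad MSI status {self.msi_status!r}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"bad mutation type {self.mutation_type!r}")
        parse_cdna_change(self.cdna_change)  # raises on malformed strings
        if self.protein_change.endswith("X") != (self.mutation_type == "nonsense"):
            raise ValueError(
                f"{self.case_id}/{self.gene}: protein change {self.protein_change!r} "
                f"inconsistent with type {self.mutation_type!r}"
            )


def parse_cdna_change(text: str) -> tuple[str, int, str] | None:
    """Parse ``c.<ref><pos><alt>`` substitutions; return None for indel strings.

    Indel c. strings (containing ``del``/``ins``) are carried opaquely.
    """
    if not text.startswith("c."):
        raise FormatError(f"cDNA change {text!r} does not start with 'c.'")
    body = text[2:]
    if "del" in body or "ins" in body:
        return None
    if len(body) < 3 or body[0] not in "ACGT" or body[-1] not in "ACGT":
        raise FormatError(f"unparseable cDNA substitution {text!r}")
    digits = body[1:-1]
    if not digits.isdigit():
        raise FormatError(f"unparseable cDNA substitution {text!r}")
    return body[0], int(digits), body[-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, role: str = "amplicon") -> list[ReferenceSeq]:
    """Read references from FASTA; uppercases and rejects ambiguity codes.

    Duplicate record names are an error.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ReferenceSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        if "N" in bases:
            raise FormatError(f"{path}: sequence {rec.id} contains N")
        records.append(ReferenceSeq(name=rec.id, bases=bases, role=role))
    return records


def write_fasta(refs: Iterable[ReferenceSeq], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n")
            for i in range(0, len(ref.bases), width):
                fh.write(ref.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Poly-dialect trace TSV

POLY_COLUMNS = (
    "read_id",
    "sample_id",
    "amplicon",
    "strand",
    "ref_start",
    "index",
    "primary_base",
    "primary_area",
    "secondary_base",
    "secondary_area",
)


def read_poly(path: str | Path) -> list[TraceRead]:
    """Read trace reads from poly-dialect TSV, grouped by read_id.

    Rows for one read must be contiguous in the file and indexed from 0.
    """
    path = Path(path)
    reads: list[TraceRead] = []
    current: list[PolyRow] = []
    meta: tuple[str, str, str, str, int] | None = None

    def flush() -> None:
        if meta is not None:
            reads.append(TraceRead(*meta, rows=tuple(current)))

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != POLY_COLUMNS:
            raise FormatError(f"{path}: bad poly header {reader.fieldnames}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                row = PolyRow(
                    index=int(rec["index"]),
                    primary_base=rec["primary_base"],
                    primary_area=float(rec["primary_area"]),
                    secondary_base=rec["secondary_base"],
                    secondary_area=float(rec["secondary_area"]),
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            this_meta = (
                rec["read_id"],
                rec["sample_id"],
                rec["amplicon"],
                rec["strand"],
                int(rec["ref_start"]),
            )
            if this_meta != meta:
                flush()
                meta, current = this_meta, []
            current.append(row)
        flush()
    return reads


def write_poly(reads: Iterable[TraceRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(POLY_COLUMNS)
        for read in reads:
            for row in read.rows:
                writer.writerow(
                    (
                        read.read_id,
                        read.sample_id,
                        read.amplicon,
                        read.strand,
                        read.ref_start,
                        row.index,
                        row.primary_base,
                        f"{row.primary_area:.{AREA_DIGITS}f}",
                        row.secondary_base,
                        f"{row.secondary_area:.{AREA_DIGITS}f}",
                    )
                )


# ---------------------------------------------------------------------------
# Mutation table TSV

MUTATION_COLUMNS = (
    "case_id",
    "gene",
    "histotype",
    "msi_status",
    "cdna_change",
    "protein_change",
    "mutation_type",
    "predicted_assessor",
    "predicted_sift",
    "predicted_polyphen",
)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    path = Path(path)
    records: list[MutationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != MUTATION_COLUMNS:
            raise FormatError(f"{path}: bad mutation-table header {reader.fieldnames}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                records.append(MutationRecord(**{k: rec[k] for k in MUTATION_COLUMNS}))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MUTATION_COLUMNS)
        for rec in sorted(records, key=lambda r: (r.case_id, r.gene, r.cdna_change)):
            writer.writerow([getattr(rec, col) for col in MUTATION_COLUMNS])


# ---------------------------------------------------------------------------
# SNP catalog TSV

SNP_COLUMNS = ("reference", "position", "alt")


def read_snp_catalog(path: str | Path) -> SNPCatalog:
    entries: set[tuple[str, int, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != SNP_COLUMNS:
            raise FormatError(f"{path}: bad SNP-catalog header {reader.fieldnames}")
        for lineno, rec in enumerate(reader, start=2):
            entry = (rec["reference"], int(rec["position"]), rec["alt"])
            if entry in entries:
                raise FormatError(f"{path}:{lineno}: duplicate catalog entry {entry}")
            entries.add(entry)
    return SNPCatalog(entries=frozenset(entries))


def write_snp_catalog(catalog: SNPCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SNP_COLUMNS)
        for entry in sorted(catalog.entries):
            writer.writerow(entry)


# ---------------------------------------------------------------------------
# Variant report TSV

REPORT_COLUMNS = (
    "sample_id",
    "reference",
    "position",
    "ref",
    "alt",
    "zygosity",
    "kind",
    "score",
    "window",
)


def write_variant_report(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls sorted by (sample, reference, position, ...); deterministic bytes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for call in sorted(calls, key=VariantCall.sort_key):
            writer.writerow(
                (
                    call.sample_id,
                    call.reference,
                    call.position,
                    call.ref,
                    call.alt,
                    call.zygosity,
                    call.kind,
                    f"{call.score:.{AREA_DIGITS}f}",
                    call.window,
                )
            )


def read_variant_report(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != REPORT_COLUMNS:
            raise FormatError(f"{path}: bad variant-report header {reader.fieldnames}")
        for rec in reader:
            calls.append(
                VariantCall(
                    sample_id=rec["sample_id"],
                    reference=rec["reference"],
                    position=int(rec["position"]),
                    ref=rec["ref"],
                    alt=rec["alt"],
                    zygosity=rec["zygosity"],
                    kind=rec["kind"],
                    score=float(rec["score"]),
                    window=int(rec["window"]),
                )
            )
    return calls
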