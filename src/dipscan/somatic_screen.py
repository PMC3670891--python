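"""Somatic/germline classification and mutation annotation.

A variant seen in a tumor is accepted as somatic only when it is
reproduced in an independently amplified tumor replicate and absent from
the matched normal — the re-amplification/verification logic of a
tumor/normal Sanger screen.  Known polymorphisms are removed against a
SNP catalog before classification.  Coding consequences are annotated in
the compact ``c.<ref><pos><alt>`` / ``p.<refAA><codon><altAA>`` dialect
with ``X`` for stop codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .trace_io import MutationRecord, ReferenceSeq, SNPCatalog
from .variants import VariantCall

SOMATIC = "somatic"
GERMLINE = "germline"
KNOWN_SNP = "known_snp"
UNCONFIRMED = "unconfirmed"

STATUSES = (SOMATIC, GERMLINE, KNOWN_SNP, UNCONFIRMED)


def filter_known_snps(
    calls: Sequence[VariantCall], catalog: SNPCatalog
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (retained, removed-as-known-polymorphism).

    A call is removed iff its (reference, position, alt) triple is in the
    catalog.
    """
    retained, removed = [], []
    for call in calls:
        if (call.reference, call.position, call.alt) in catalog:
            removed.append(call)
        else:
            retained.append(call)
    return retained, removed


def classify_somatic(
    tumor_calls_rep1: Sequence[VariantCall],
    tumor_calls_rep2: Sequence[VariantCall],
    normal_calls: Sequence[VariantCall],
    case_id: str | None = None,
    require_both_replicates: bool = True,
) -> list[tuple[VariantCall, str]]:
    """Label every variant seen in any of the three call sets.

    somatic      in both tumor replicates (or any, when
                 ``require_both_replicates=False``) and absent from normal
    germline     present in the normal
    unconfirmed  in exactly one tumor replicate, absent from normal

    A variant present in the normal is never labelled somatic.  When
    ``case_id`` is given, every call's sample id must start with it.
    """
    if case_id is not None:
        for group in (tumor_calls_rep1, tumor_calls_rep2, normal_calls):
            for call in group:
                if not call.sample_id.startswith(case_id):
                    raise ValueError(
                        f"call from sample {call.sample_id!r} does not belong to "
                        f"case {case_id!r}"
                    )
    t1 = {c.key: c for c in tumor_calls_rep1}
    t2 = {c.key: c for c in tumor_calls_rep2}
    nn = {c.key: c for c in normal_calls}

    labelled: list[tuple[VariantCall, str]] = []
    for key in sorted(set(t1) | set(t2) | set(nn), key=lambda k: (k[0], k[1], k[4], k[2], k[3])):
        call = t1.get(key) or t2.get(key) or nn[key]
        if key in nn:
            status = GERMLINE
        elif key in t1 and key in t2:
            status = SOMATIC
        elif not require_both_replicates:
            status = SOMATIC
        else:
            status = UNCONFIRMED
        labelled.append((call, status))
    return labelled


def screen_case(
    tumor_calls_rep1: Sequence[VariantCall],
    tumor_calls_rep2: Sequence[VariantCall],
    normal_calls: Sequence[VariantCall],
    catalog: SNPCatalog = SNPCatalog(),
    case_id: str | None = None,
    require_both_replicates: bool = True,
) -> list[tuple[VariantCall, str]]:
    """SNP filtering followed by somatic classification for one case."""
    t1, removed1 = filter_known_snps(tumor_calls_rep1, catalog)
    t2, removed2 = filter_known_snps(tumor_calls_rep2, catalog)
    nn, _ = filter_known_snps(normal_calls, catalog)
    labelled = classify_somatic(
        t1, t2, nn, case_id=case_id, require_both_replicates=require_both_replicates
    )
    seen = {c.key for c, _ in labelled}
    for call in removed1 + removed2:
        if call.key not in seen:
            seen.add(call.key)
            labelled.append((call, KNOWN_SNP))
    return labelled


# ---------------------------------------------------------------------------
# Annotation


def _aa(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "X" if aa == "*" else aa


def codon_number(cds_position: int) -> int:
    """1-based codon index of a 1-based CDS position: ceil(pos / 3)."""
    if cds_position < 1:
        raise ValueError("CDS positions are 1-based")
    return math.ceil(cds_position / 3)


def annotate_variant(
    call: VariantCall,
    cds: ReferenceSeq,
    case_id: str | None = None,
    gene: str | None = None,
    histotype: str = "serous",
    msi_status: str = "unknown",
) -> MutationRecord:
    """Annotate a coding variant (positions in CDS coordinates).

    Substitutions get codon-arithmetic consequences; indels are typed
    frameshift when the length change is not a multiple of three, inframe
    otherwise.  The call's ref allele must match the CDS.
    """
    seq = cds.bases
    pos = call.position
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside CDS of length {len(seq)}")
    if seq[pos - 1 : pos - 1 + len(call.ref)] != call.ref:
        raise ValueError(
            f"ref allele {call.ref!r} does not match CDS {cds.name} at position {pos}"
        )
    gene = gene or cds.name
    case_id = case_id or call.sample_id

    if call.kind == "SNV":
        codon_idx = codon_number(pos)
        codon_start = 3 * (codon_idx - 1)
        codon = seq[codon_start : codon_start + 3]
        offset = (pos - 1) % 3
        alt_codon = codon[:offset] + call.alt + codon[offset + 1 :]
        ref_aa, alt_aa = _aa(codon), _aa(alt_codon)
        if alt_aa == "X":
            mtype = "nonsense"
        elif alt_aa == ref_aa:
            mtype = "synonymous"
        else:
            mtype = "missense"
        cdna = f"c.{call.ref}{pos}{call.alt}"
        protein = f"p.{ref_aa}{codon_idx}{alt_aa}"
    else:
        # anchored indel: first changed CDS base is position + 1
        net = len(call.alt) - len(call.ref)
        first_changed = pos + 1
        codon_idx = codon_number(first_changed)
        codon_start = 3 * (codon_idx - 1)
        ref_aa = _aa(seq[codon_start : codon_start + 3])
        if call.kind == "DEL":
            k = len(call.ref) - 1
            if k == 1:
                cdna = f"c.{first_changed}del"
            else:
                cdna = f"c.{first_changed}_{first_changed + k - 1}del"
        else:
            cdna = f"c.{pos}_{first_changed}ins{call.alt[1:]}"
        if net % 3 != 0:
            mtype = "frameshift"
            protein = f"p.{ref_aa}{codon_idx}fs"
        else:
            mtype = "inframe"
            protein = f"p.{ref_aa}{codon_idx}{'del' if net < 0 else 'ins'}"
    return MutationRecord(
        case_id=case_id,
        gene=gene,
        histotype=histotype,
        msi_status=msi_status,
        cdna_change=cdna,
        protein_change=protein,
        mutation_type=mtype,
    )


def is_splice_proximal(
    position: int, exon_boundaries: Iterable[int], margin: int = 2
) -> bool:
    """Whether a position lies within ``margin`` bases of any exon boundary."""
    return any(abs(position - b) <= margin for b in exon_boundaries)
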