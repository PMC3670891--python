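"""Shared variant-call container and indel normalization.

Indels are represented VCF-style: anchored on the last unchanged reference
base, so both alleles are non-empty (``ref="AG", alt="A"`` is a 1-bp
deletion after the A).  In repetitive sequence the same edit admits several
placements; :func:`left_align` shifts every call to its leftmost anchored
form so that calls from different code paths (planted truth, alignment gaps,
phase-shift search) compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ZYGOSITIES = ("hom", "het")
KINDS = ("SNV", "INS", "DEL")

_DNA = set("ACGTN")


@dataclass(frozen=True)
class VariantCall:
    """One called substitution or short indel on a reference sequence.

    ``position`` is 1-based.  SNVs carry single differing bases; indels are
    anchored (see module docstring).  ``score`` / ``window`` hold the
    supporting evidence: the phase-shift match fraction and window size for
    heterozygous indels, the alignment score (window 0) for homozygous calls.
    """

    sample_id: str
    reference: str
    position: int
    ref: str
    alt: str
    zygosity: str
    kind: str
    score: float = 0.0
    window: int = 0

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if self.kind not in KINDS:
            raise ValueError(f"bad kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.kind == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError("SNV alleles must be single, differing bases")
        bad = (set(self.ref) | set(self.alt)) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in alleles: {sorted(bad)}")

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        """Identity used for presence matching across samples (no zygosity)."""
        return (self.reference, self.position, self.ref, self.alt, self.kind)

    def sort_key(self) -> tuple:
        return (self.sample_id, self.reference, self.position, self.kind, self.ref, self.alt)


def left_align(seq: str, position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize an anchored variant against its reference sequence.

    ``seq`` is the full reference, ``position`` the 1-based coordinate of
    ``ref[0]``.  Returns the canonical (position, ref, alt).  Substitutions
    pass through unchanged.
    """
    if seq[position - 1 : position - 1 + len(ref)] != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match reference at position {position}"
        )
    if len(ref) == 1 and len(alt) == 1:
        return position, ref, alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and position > 1 and (len(ref) == 1 or len(alt) == 1):
            prev = seq[position - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            position -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def normalize_call(call: VariantCall, seq: str) -> VariantCall:
    """Return ``call`` in left-aligned canonical form against ``seq``."""
    pos, ref, alt = left_align(seq, call.position, call.ref, call.alt)
    if (pos, ref, alt) == (call.position, call.ref, call.alt):
        return call
    return replace(call, position=pos, ref=ref, alt=alt)


def apply_to_sequence(seq: str, position: int, ref: str, alt: str) -> str:
    """Apply one anchored variant to ``seq`` (1-based position of ref[0])."""
    i = position - 1
    if seq[i : i + len(ref)] != ref:
        raise ValueError(f"ref allele mismatch at {position}")
    return seq[:i] + alt + seq[i + len(ref) :]
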