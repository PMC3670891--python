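"""Synthetic diploid Sanger-trace generator with known ground truth.

A diploid template produces, at every chromatogram position, the
superposition of the two haplotype signals.  Downstream of a heterozygous
insertion or deletion the two haplotypes fall out of register, so every
subsequent position carries two comparable-area peaks — the signature the
phase-shift caller looks for.  The generator renders this superposition
directly at the peak-area level (no per-scan-point waveform): haplotype 1
contributes ``allele_fraction * peak_mean`` to its base, haplotype 2 the
complement, identical bases merge, optional cross-talk adds one spurious
peak, and truncated Gaussian noise perturbs each area.  Only the two
largest peaks per position are kept, matching the two-vector formulation of
the caller.

The cohort generator mirrors an amplicon-based tumor/normal screen: per
case one normal sample and two independently re-amplified tumor replicates
(same variants, fresh noise), with exactly one planted variant per amplicon
so reads never carry two heterozygous indels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trace_io import (
    PolyRow,
    ReferenceSeq,
    TraceRead,
    write_fasta,
    write_poly,
)
from .variants import left_align

VARIANT_KINDS = ("SNV_hom", "SNV_het", "INS_het", "DEL_het")
MAX_INDEL = 99  # callers target short (<100 bp) indels only

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

TRUTH_COLUMNS = ("case_id", "status", "amplicon", "kind", "zygosity", "position", "ref", "alt")


@dataclass(frozen=True)
class Variant:
    """A planted variant in reference coordinates (0-based ``pos``).

    ``seq`` is the alternate base for SNVs and the inserted sequence for
    insertions (inserted *before* ``pos``); deletions remove ``length``
    bases starting at ``pos``.
    """

    kind: str
    pos: int
    seq: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"bad variant kind {self.kind!r}")
        if self.kind.startswith("SNV") and len(self.seq) != 1:
            raise ValueError("SNV needs a single alternate base in seq")
        if self.kind == "INS_het" and not (1 <= len(self.seq) < 100):
            raise ValueError("heterozygous insertion length must be in [1, 100)")
        if self.kind == "DEL_het" and not (1 <= self.length < 100):
            raise ValueError("heterozygous deletion length must be in [1, 100)")

    @property
    def span(self) -> tuple[int, int]:
        """Closed interval of reference positions this variant occupies."""
        if self.kind == "DEL_het":
            return (self.pos, self.pos + self.length - 1)
        return (self.pos, self.pos)


@dataclass(frozen=True)
class HaplotypePair:
    """The two haplotype strings of a diploid template."""

    hap1: str
    hap2: str
    variants: tuple[Variant, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable rendering parameters.

    peak_mean
        Total fluorescence area of a full (merged) peak, arbitrary units.
    allele_fraction
        Fraction of signal contributed by haplotype 1; 0.5 models balanced
        diploid amplification, 1.0 a haploid template.
    noise_sd
        SD of additive Gaussian noise on each peak area, truncated at 0.
    cross_talk
        Area fraction of one spurious peak added per position on a random
        channel, modelling dye cross-talk / baseline wobble.
    """

    peak_mean: float = 1000.0
    allele_fraction: float = 0.5
    noise_sd: float = 30.0
    cross_talk: float = 0.05
    seed: int = 0
    read_length: int = 240

    def __post_init__(self) -> None:
        if self.peak_mean <= 0:
            raise ValueError("peak_mean must be positive")
        if not 0 < self.allele_fraction <= 1:
            raise ValueError("allele_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.cross_talk < 0.1:
            raise ValueError("cross_talk must be in [0, 0.1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


def apply_variants(ref: str, variants: Sequence[Variant]) -> HaplotypePair:
    """Apply variants to a reference; heterozygous edits go on haplotype 2.

    Variants must be non-overlapping and inside the reference.
    """
    ordered = sorted(variants, key=lambda v: v.pos)
    for v in ordered:
        lo, hi = v.span
        if lo < 0 or hi >= len(ref):
            raise ValueError(f"variant at {v.pos} outside reference of length {len(ref)}")
    for a, b in zip(ordered, ordered[1:]):
        if a.span[1] >= b.span[0]:
            raise ValueError(f"overlapping variants at {a.pos} and {b.pos}")

    hap1, hap2 = ref, ref
    for v in reversed(ordered):  # right-to-left so positions stay valid
        if v.kind == "SNV_hom":
            hap1 = hap1[: v.pos] + v.seq + hap1[v.pos + 1 :]
            hap2 = hap2[: v.pos] + v.seq + hap2[v.pos + 1 :]
        elif v.kind == "SNV_het":
            hap2 = hap2[: v.pos] + v.seq + hap2[v.pos + 1 :]
        elif v.kind == "INS_het":
            hap2 = hap2[: v.pos] + v.seq + hap2[v.pos :]
        else:  # DEL_het
            hap2 = hap2[: v.pos] + hap2[v.pos + v.length :]
    return HaplotypePair(hap1=hap1, hap2=hap2, variants=tuple(ordered))


def variant_to_anchored(ref: str, v: Variant) -> tuple[int, str, str, str, str]:
    """Truth-table form: left-aligned (position, ref, alt, kind, zygosity)."""
    if v.kind in ("SNV_hom", "SNV_het"):
        kind, zyg = "SNV", ("hom" if v.kind == "SNV_hom" else "het")
        return v.pos + 1, ref[v.pos], v.seq, kind, zyg
    if v.kind == "INS_het":
        anchor = v.pos - 1
        if anchor < 0:
            raise ValueError("insertion at position 0 cannot be anchored")
        pos, r, a = left_align(ref, anchor + 1, ref[anchor], ref[anchor] + v.seq)
        return pos, r, a, "INS", "het"
    anchor = v.pos - 1
    if anchor < 0:
        raise ValueError("deletion at position 0 cannot be anchored")
    pos, r, a = left_align(
        ref, anchor + 1, ref[anchor : v.pos + v.length], ref[anchor]
    )
    return pos, r, a, "DEL", "het"


def render_trace(
    pair: HaplotypePair,
    config: SimulationConfig,
    read_id: str = "read",
    sample_id: str = "sample",
    amplicon: str = "amp",
    ref_start: int = 1,
    rng: np.random.Generator | None = None,
) -> TraceRead:
    """Render the diploid superposition of a haplotype pair into peak rows.

    Position ``j`` receives ``allele_fraction * peak_mean`` on ``hap1[j]``
    and the complement on ``hap2[j]``; equal bases merge into one peak.
    On exactly tied areas the haplotype-1 base is taken as primary (the
    deterministic noiseless convention; under noise ties have measure zero).
    """
    L = config.read_length
    if L > min(len(pair.hap1), len(pair.hap2)):
        raise ValueError(
            f"read_length {L} exceeds shortest haplotype "
            f"({min(len(pair.hap1), len(pair.hap2))})"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    af, mu = config.allele_fraction, config.peak_mean

    rows = []
    for j in range(L):
        b1, b2 = pair.hap1[j], pair.hap2[j]
        areas: dict[str, float] = {b1: af * mu}
        if af < 1.0:
            areas[b2] = areas.get(b2, 0.0) + (1 - af) * mu
        if config.cross_talk > 0:
            spur = _ALPHABET[rng.integers(4)]
            areas[spur] = areas.get(spur, 0.0) + config.cross_talk * mu
        if config.noise_sd > 0:
            for base in list(areas):
                areas[base] = max(0.0, areas[base] + rng.normal(0.0, config.noise_sd))
        # primary = largest area; ties resolved toward hap1's base, then A<C<G<T
        ranked = sorted(areas.items(), key=lambda kv: (-kv[1], kv[0] != b1, kv[0]))
        pb, pa = ranked[0]
        if len(ranked) > 1 and ranked[1][1] > 0:
            sb, sa = ranked[1]
        else:
            sb, sa = "-", 0.0
        rows.append(
            PolyRow(
                index=j,
                primary_base=pb,
                primary_area=round(pa, 4),
                secondary_base=sb,
                secondary_area=round(min(sa, pa), 4),
            )
        )
    return TraceRead(
        read_id=read_id,
        sample_id=sample_id,
        amplicon=amplicon,
        strand="+",
        ref_start=ref_start,
        rows=tuple(rows),
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class SyntheticCohort:
    """References, traces, and the planted-variant truth table."""

    references: tuple[ReferenceSeq, ...]
    reads: tuple[TraceRead, ...]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.references, outdir / "references.fa")
        write_poly(self.reads, outdir / "traces.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_reference(rng: np.random.Generator, name: str, length: int) -> ReferenceSeq:
    bases = "".join(_ALPHABET[rng.integers(4, size=length)])
    return ReferenceSeq(name=name, bases=bases)


def _draw_variant(
    rng: np.random.Generator,
    ref: str,
    kind: str,
    lo: int,
    hi: int,
    max_indel: int,
) -> Variant:
    pos = int(rng.integers(lo, hi))
    if kind in ("SNV_hom", "SNV_het"):
        choices = [b for b in "ACGT" if b != ref[pos]]
        return Variant(kind=kind, pos=pos, seq=choices[int(rng.integers(3))])
    size = int(rng.integers(1, max_indel + 1))
    if kind == "INS_het":
        seq = "".join(_ALPHABET[rng.integers(4, size=size)])
        return Variant(kind=kind, pos=pos, seq=seq)
    return Variant(kind="DEL_het", pos=pos, length=size)


def generate_cohort(
    n_cases: int = 10,
    config: SimulationConfig = SimulationConfig(),
    somatic_spectrum: Sequence[str] = ("SNV_het", "INS_het", "DEL_het"),
    germline_spectrum: Sequence[str] = ("SNV_hom", "DEL_het"),
    amplicon_length: int = 258,
    max_indel_size: int = 10,
) -> SyntheticCohort:
    """Simulate a tumor/normal screen with per-case truth labels.

    Each case gets one amplicon per planted variant (somatic variants on the
    leading amplicons, germline on the rest), a normal sample carrying only
    the germline variants, and two tumor replicates carrying germline plus
    somatic variants with independent noise — so replicate concordance is
    informative exactly as in an independent-PCR verification.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if amplicon_length - max_indel_size < config.read_length:
        raise ValueError("amplicon_length too short for read_length plus indel slack")
    rng = np.random.default_rng(config.seed)
    n_amp = len(somatic_spectrum) + len(germline_spectrum)
    refs = tuple(
        _random_reference(rng, f"AMP{i + 1}", amplicon_length) for i in range(n_amp)
    )
    # interior placement: far enough from the read end that the scoring
    # window after the variant stays comfortably above min_window
    lo, hi = 50, config.read_length - 60

    reads: list[TraceRead] = []
    truth_rows: list[dict] = []
    for c in range(n_cases):
        case = f"C{c + 1:02d}"
        spectrum = [("somatic", k) for k in somatic_spectrum] + [
            ("germline", k) for k in germline_spectrum
        ]
        planted: list[tuple[str, str, Variant]] = []  # (status, amplicon, variant)
        for (status, kind), ref in zip(spectrum, refs):
            v = _draw_variant(rng, ref.bases, kind, lo, hi, max_indel_size)
            planted.append((status, ref.name, v))
            pos, r, a, vkind, zyg = variant_to_anchored(ref.bases, v)
            truth_rows.append(
                dict(
                    case_id=case,
                    status=status,
                    amplicon=ref.name,
                    kind=vkind,
                    zygosity=zyg,
                    position=pos,
                    ref=r,
                    alt=a,
                )
            )
        for ref in refs:
            germ = [v for s, amp, v in planted if amp == ref.name and s == "germline"]
            tumor = [v for s, amp, v in planted if amp == ref.name]
            normal_pair = apply_variants(ref.bases, germ)
            tumor_pair = apply_variants(ref.bases, tumor)
            for sample_suffix, pair in (
                ("N", normal_pair),
                ("T1", tumor_pair),
                ("T2", tumor_pair),
            ):
                sample = f"{case}-{sample_suffix}"
                reads.append(
                    render_trace(
                        pair,
                        config,
                        read_id=f"{sample}-{ref.name}",
                        sample_id=sample,
                        amplicon=ref.name,
                        rng=rng,
                    )
                )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return SyntheticCohort(references=refs, reads=tuple(reads), truth=truth, config=config)
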