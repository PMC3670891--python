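"""Heterozygous-indel detection from superposed Sanger trace signals.

Downstream of a heterozygous insertion or deletion, a diploid trace shows
two comparable-area peaks at every position: the two allele sequences are
out of register.  The caller exploits this directly:

1.  The primary-base string is globally aligned to the reference and
    homozygous variants are read off the alignment.
2.  Two base vectors are formed per read: ``v1`` holds the largest-area
    peak at each position, ``v2`` the second peak — unless the second
    peak's area is less than a fraction ``rho`` (default 10%) of the
    largest, in which case the primary base is copied into both vectors.
3.  Candidate phase shifts of every size ``s`` at every read position
    ``p`` are scored by the fraction of downstream positions where ``v2``
    equals ``v1`` displaced by ``s``.  A positive ``s`` means the minor
    allele's downstream content arrives ``s`` positions early — a
    deletion of size ``s`` on that allele; a negative ``s`` is an
    insertion of size ``|s|``.
4.  The best hypothesis is called as a heterozygous indel if its score
    reaches ``theta``, covers at least ``min_window`` positions, and
    improves on the unshifted match fraction by at least ``delta``.

Isolated positions where the two vectors disagree (with clean flanks) are
reported as heterozygous SNVs.  At most one heterozygous indel is called
per read; reads carrying two are outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .trace_io import ReferenceSeq, TraceRead
from .variants import VariantCall, left_align, normalize_call

MAX_SHIFT_HARD_CAP = 99  # the screen targets short (<100 bp) indels


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the caller; defaults are the package's calibration."""

    rho: float = 0.10
    theta: float = 0.90
    delta: float = 0.20
    min_window: int = 10
    max_shift: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")
        if self.min_window < 1:
            raise ValueError("min_window must be >= 1")
        if not 1 <= self.max_shift <= MAX_SHIFT_HARD_CAP:
            raise ValueError(f"max_shift must be in [1, {MAX_SHIFT_HARD_CAP}]")


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-to-reference alignment with a coordinate map.

    ``read_to_ref`` maps 0-based read positions to 1-based reference
    coordinates for match/mismatch columns.  ``gap_read_positions`` are
    read positions inside or immediately flanking alignment gap runs;
    the phase-shift search does not anchor hypotheses there.
    """

    aligned_read: str
    aligned_ref: str
    score: float
    read_to_ref: Mapping[int, int]
    gap_read_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")
        if self.aligned_read.replace("-", "") == "":
            raise ValueError("empty read alignment")


@dataclass(frozen=True)
class BaseVectors:
    """The two phased candidate base strings derived from one read."""

    v1: str
    v2: str
    rho: float = 0.10

    def __post_init__(self) -> None:
        if len(self.v1) != len(self.v2):
            raise ValueError("v1 and v2 must have equal length")

    def __len__(self) -> int:
        return len(self.v1)


@dataclass(frozen=True)
class ShiftHypothesis:
    """One candidate phase shift: insert offset ``size`` at read position ``position``."""

    position: int
    size: int
    score: float
    window: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # reads cover a sub-interval of the amplicon: reference overhangs are free
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_primary(read: TraceRead, ref: ReferenceSeq) -> AlignmentResult:
    """Globally align the read's primary-base string to its reference window.

    The window runs from the read's ``ref_start`` to the end of the
    reference; overhanging reference bases are not penalized.  Scoring:
    match +1, mismatch -1, gap open -2, gap extend -1.
    """
    query = read.primary_string
    if not query:
        raise ValueError("empty read")
    window = ref.bases[read.ref_start - 1 :]
    if len(query) > len(window):
        raise ValueError(
            f"read {read.read_id} ({len(query)} bp) longer than reference window "
            f"({len(window)} bp)"
        )
    alignment = _ALIGNER.align(window, query)[0]
    a_ref, a_read = str(alignment[0]), str(alignment[1])

    read_to_ref: dict[int, int] = {}
    gap_pos: set[int] = set()
    t = read.ref_start - 1  # 0-based reference cursor
    q = 0
    ncols = len(a_ref)
    for col in range(ncols):
        rc, qc = a_ref[col], a_read[col]
        if rc != "-" and qc != "-":
            read_to_ref[q] = t + 1
            t += 1
            q += 1
        elif rc == "-":  # extra read base (insertion run)
            gap_pos.add(q)
            if q > 0:
                gap_pos.add(q - 1)
            q += 1
        else:  # read gap (deletion run or free end overhang)
            if 0 < q < len(query):
                gap_pos.update((q - 1, q))
            t += 1
    return AlignmentResult(
        aligned_read=a_read,
        aligned_ref=a_ref,
        score=float(alignment.score),
        read_to_ref=read_to_ref,
        gap_read_positions=frozenset(gap_pos),
    )


def _gap_runs(aligned_ref: str, aligned_read: str) -> list[tuple[str, int, int]]:
    """Internal gap runs as (kind, start_col, end_col) with kind ins/del."""
    runs: list[tuple[str, int, int]] = []
    col = 0
    n = len(aligned_ref)
    while col < n:
        if aligned_ref[col] == "-" or aligned_read[col] == "-":
            kind = "ins" if aligned_ref[col] == "-" else "del"
            start = col
            while col < n and (
                (kind == "ins" and aligned_ref[col] == "-")
                or (kind == "del" and aligned_read[col] == "-")
            ):
                col += 1
            if start > 0 and col < n:  # end-touching runs are free overhangs
                runs.append((kind, start, col - 1))
        else:
            col += 1
    return runs


def call_homozygous(
    alignment: AlignmentResult,
    read: TraceRead,
    ref: ReferenceSeq,
    rho: float = 0.10,
) -> list[VariantCall]:
    """Read homozygous variants off the primary-string alignment.

    Mismatch columns whose trace row has a qualifying secondary peak
    (area >= rho * primary) are left to the heterozygous machinery.
    Gap runs become homozygous insertions/deletions, left-normalized.
    """
    calls: list[VariantCall] = []
    a_ref, a_read = alignment.aligned_ref, alignment.aligned_read
    t = read.ref_start - 1
    q = 0
    for col in range(len(a_ref)):
        rc, qc = a_ref[col], a_read[col]
        if rc != "-" and qc != "-":
            if rc != qc and qc != "N":
                row = read.rows[q]
                het_capable = (
                    row.secondary_base != "-"
                    and row.secondary_area >= rho * row.primary_area
                )
                if not het_capable:
                    calls.append(
                        VariantCall(
                            sample_id=read.sample_id,
                            reference=ref.name,
                            position=t + 1,
                            ref=rc,
                            alt=qc,
                            zygosity="hom",
                            kind="SNV",
                            score=alignment.score,
                        )
                    )
            t += 1
            q += 1
        elif rc == "-":
            q += 1
        else:
            t += 1

    # column -> reference coordinate bookkeeping for gap runs
    ref_coord_before: list[int] = []  # 1-based ref coord of last ref base at/before col
    t = read.ref_start - 1
    for col in range(len(a_ref)):
        if a_ref[col] != "-":
            t += 1
        ref_coord_before.append(t)  # t is 1-based count consumed so far

    for kind, start, end in _gap_runs(a_ref, a_read):
        anchor = ref_coord_before[start - 1]  # ref coord of base before the run
        if anchor < 1:
            continue
        if kind == "ins":
            inserted = a_read[start : end + 1]
            if "N" in inserted:
                continue
            pos, r, a = left_align(
                ref.bases, anchor, ref.bases[anchor - 1], ref.bases[anchor - 1] + inserted
            )
            vkind = "INS"
        else:
            deleted = a_ref[start : end + 1]
            pos, r, a = left_align(
                ref.bases, anchor, ref.bases[anchor - 1] + deleted, ref.bases[anchor - 1]
            )
            vkind = "DEL"
        calls.append(
            VariantCall(
                sample_id=read.sample_id,
                reference=ref.name,
                position=pos,
                ref=r,
                alt=a,
                zygosity="hom",
                kind=vkind,
                score=alignment.score,
            )
        )
    return calls


def form_base_vectors(read: TraceRead, rho: float = 0.10) -> BaseVectors:
    """Form the two candidate base vectors under the secondary-peak rule.

    The secondary base enters ``v2`` only when its area is at least
    ``rho`` times the primary area (strict "less than rho" copies the
    primary into both vectors).
    """
    v1 = []
    v2 = []
    for row in read.rows:
        v1.append(row.primary_base)
        if row.secondary_base != "-" and row.secondary_area >= rho * row.primary_area:
            v2.append(row.secondary_base)
        else:
            v2.append(row.primary_base)
    return BaseVectors(v1="".join(v1), v2="".join(v2), rho=rho)


def score_shift(
    vectors: BaseVectors, p: int, s: int, min_window: int = 1
) -> tuple[float, int]:
    """Match fraction between ``v2`` and ``v1`` displaced by ``s``, from ``p`` on.

    The scored window is every ``j`` in ``[p, L-1-max(s,0)]`` with
    ``j+s >= 0``.  Returns ``(0.0, 0)`` when the window is smaller than
    ``min_window``.
    """
    L = len(vectors)
    if not 0 <= p < L:
        raise ValueError(f"shift position {p} out of range [0, {L})")
    if s == 0 or abs(s) > min(MAX_SHIFT_HARD_CAP, L - 1):
        raise ValueError(f"shift size {s} out of range")
    start = max(p, -s)
    stop = L - 1 - max(s, 0)
    window = stop - start + 1
    if window < max(min_window, 1):
        return 0.0, 0
    v1, v2 = vectors.v1, vectors.v2
    matches = sum(1 for j in range(start, stop + 1) if v2[j] == v1[j + s])
    return matches / window, window


def unshifted_match_fraction(vectors: BaseVectors, p: int) -> float:
    """Fraction of positions from ``p`` on where the two vectors agree."""
    L = len(vectors)
    if not 0 <= p < L:
        raise ValueError(f"position {p} out of range")
    tail = range(p, L)
    return sum(1 for j in tail if vectors.v1[j] == vectors.v2[j]) / len(tail)


def enumerate_shifts(
    vectors: BaseVectors,
    max_shift: int = 30,
    min_window: int = 10,
    masked: frozenset[int] | set[int] = frozenset(),
) -> ShiftHypothesis | None:
    """Best-scoring phase-shift hypothesis over all (position, size) pairs.

    Ties break toward higher score, then smaller ``|s|``, then smaller
    position, then deletions (``s > 0``) before insertions.  For ``s < 0``
    only positions ``p >= |s|`` are anchored (smaller ``p`` duplicates the
    ``p = |s|`` window).  Positions in ``masked`` are skipped.
    """
    L = len(vectors)
    if L < 2:
        return None
    v1 = np.frombuffer(vectors.v1.encode(), dtype=np.uint8)
    v2 = np.frombuffer(vectors.v2.encode(), dtype=np.uint8)
    mask_arr = np.zeros(L, dtype=bool)
    for p in masked:
        if 0 <= p < L:
            mask_arr[p] = True

    best: ShiftHypothesis | None = None
    for size in range(1, min(max_shift, L - 1) + 1):
        for s in (size, -size):
            if s > 0:
                m = v2[: L - s] == v1[s:]
                p_lo = 0
            else:
                m = v2[size:] == v1[: L - size]
                p_lo = size
            # suffix match counts over the valid j range
            suffix = np.cumsum(m[::-1])[::-1]
            p_hi = L - 1 - max(s, 0)  # largest anchorable position
            ps = np.arange(p_lo, p_hi + 1)
            windows = (p_hi - ps + 1).astype(np.float64)
            scores = suffix[ps - p_lo].astype(np.float64) / windows
            scores[windows < min_window] = -1.0
            scores[mask_arr[ps]] = -1.0
            i = int(np.argmax(scores))  # first occurrence -> smallest p on ties
            if scores[i] >= 0 and (best is None or scores[i] > best.score):
                best = ShiftHypothesis(
                    position=int(ps[i]),
                    size=s,
                    score=float(scores[i]),
                    window=int(windows[i]),
                )
    return best


def hypothesis_to_call(
    hyp: ShiftHypothesis,
    vectors: BaseVectors,
    alignment: AlignmentResult,
    read: TraceRead,
    ref: ReferenceSeq,
) -> VariantCall | None:
    """Map an accepted shift hypothesis to an anchored, left-normalized call."""
    if hyp.size > 0:  # deletion of `size` bases on the minor allele
        r = alignment.read_to_ref.get(hyp.position)
        if r is None or r < 2 or r - 1 + hyp.size > len(ref.bases):
            return None
        deleted = ref.bases[r - 1 : r - 1 + hyp.size]
        pos, rr, aa = left_align(ref.bases, r - 1, ref.bases[r - 2] + deleted, ref.bases[r - 2])
        kind = "DEL"
    else:  # insertion: the minor allele carries |size| extra bases
        d = -hyp.size
        start = hyp.position - d  # first divergent read row
        if start < 1:
            return None
        inserted = vectors.v2[start : hyp.position]
        if "N" in inserted:
            return None
        r = alignment.read_to_ref.get(start)
        if r is None or r < 2:
            return None
        pos, rr, aa = left_align(ref.bases, r - 1, ref.bases[r - 2], ref.bases[r - 2] + inserted)
        kind = "INS"
    return VariantCall(
        sample_id=read.sample_id,
        reference=ref.name,
        position=pos,
        ref=rr,
        alt=aa,
        zygosity="het",
        kind=kind,
        score=hyp.score,
        window=hyp.window,
    )


def call_het_snvs(
    vectors: BaseVectors,
    alignment: AlignmentResult,
    read: TraceRead,
    ref: ReferenceSeq,
    exclude_from: int | None = None,
    flank: int = 2,
) -> list[VariantCall]:
    """Heterozygous SNVs: isolated vector disagreements with clean flanks.

    A position qualifies when ``v1 != v2`` there, the ``flank`` neighbours
    on each side agree, and one of the two bases matches the reference.
    Positions at or beyond ``exclude_from`` (the divergence start of a
    called heterozygous indel) are skipped.
    """
    L = len(vectors)
    calls: list[VariantCall] = []
    for j in range(L):
        if vectors.v1[j] == vectors.v2[j]:
            continue
        if exclude_from is not None and j >= exclude_from - flank:
            continue
        lo, hi = max(0, j - flank), min(L - 1, j + flank)
        if any(vectors.v1[k] != vectors.v2[k] for k in range(lo, hi + 1) if k != j):
            continue
        r = alignment.read_to_ref.get(j)
        if r is None:
            continue
        ref_base = ref.bases[r - 1]
        pair = {vectors.v1[j], vectors.v2[j]}
        if ref_base not in pair:
            continue
        alt = (pair - {ref_base}).pop()
        if alt == "N":
            continue
        calls.append(
            VariantCall(
                sample_id=read.sample_id,
                reference=ref.name,
                position=r,
                ref=ref_base,
                alt=alt,
                zygosity="het",
                kind="SNV",
            )
        )
    return calls


def enumerate_and_call(
    read: TraceRead,
    ref: ReferenceSeq,
    config: DetectorConfig = DetectorConfig(),
) -> list[VariantCall]:
    """Full per-read calling: homozygous scan, then the phase-shift search.

    At most one heterozygous indel is emitted per read — the best
    hypothesis that clears ``theta``, ``min_window`` and the ``delta``
    improvement over the unshifted match fraction.
    """
    alignment = align_primary(read, ref)
    calls = call_homozygous(alignment, read, ref, rho=config.rho)
    vectors = form_base_vectors(read, rho=config.rho)

    exclude_from: int | None = None
    if vectors.v1 != vectors.v2:
        best = enumerate_shifts(
            vectors,
            max_shift=config.max_shift,
            min_window=config.min_window,
            masked=alignment.gap_read_positions,
        )
        if (
            best is not None
            and best.score >= config.theta
            and best.window >= config.min_window
            and best.score - unshifted_match_fraction(vectors, best.position)
            >= config.delta
        ):
            call = hypothesis_to_call(best, vectors, alignment, read, ref)
            if call is not None:
                calls.append(call)
                exclude_from = (
                    best.position if best.size > 0 else best.position + best.size
                )
    calls.extend(
        call_het_snvs(vectors, alignment, read, ref, exclude_from=exclude_from)
    )
    calls = [normalize_call(c, ref.bases) for c in calls]
    return sorted(calls, key=VariantCall.sort_key)


def cross_validate_amplimers(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
    overlap: tuple[int, int],
) -> list[tuple[VariantCall, str | None]]:
    """Merge two amplimers' call sets with concordance flags in the overlap.

    Calls inside ``overlap`` (1-based inclusive) are flagged
    ``"concordant"`` when present in both sets (by position/allele/kind
    identity) and ``"discordant"`` otherwise; calls outside pass through
    unflagged (``None``).
    """
    start, end = overlap
    if start > end or start < 1:
        raise ValueError(f"malformed overlap interval {overlap}")
    keys_a = {c.key for c in calls_a}
    keys_b = {c.key for c in calls_b}
    seen: set = set()
    merged: list[tuple[VariantCall, str | None]] = []
    for call in sorted(list(calls_a) + list(calls_b), key=VariantCall.sort_key):
        if call.key in seen:
            continue
        seen.add(call.key)
        if start <= call.position <= end:
            flag = "concordant" if (call.key in keys_a and call.key in keys_b) else "discordant"
        else:
            flag = None
        merged.append((call, flag))
    return merged


def detect_reads(
    reads: Iterable[TraceRead],
    references: Mapping[str, ReferenceSeq],
    config: DetectorConfig = DetectorConfig(),
) -> list[VariantCall]:
    """Run the caller over many reads against their named references."""
    calls: list[VariantCall] = []
    for read in reads:
        try:
            ref = references[read.amplicon]
        except KeyError:
            raise KeyError(f"read {read.read_id}: unknown reference {read.amplicon!r}")
        calls.extend(enumerate_and_call(read, ref, config))
    return sorted(calls, key=VariantCall.sort_key)
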