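"""Caller correctness: alignment, base vectors, shift scoring, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dipscan.dipdetector import (
    BaseVectors,
    DetectorConfig,
    ShiftHypothesis,
    align_primary,
    call_het_snvs,
    call_homozygous,
    cross_validate_amplimers,
    enumerate_and_call,
    enumerate_shifts,
    form_base_vectors,
    score_shift,
    unshifted_match_fraction,
)
from dipscan.synthetic_traces import (
    HaplotypePair,
    SimulationConfig,
    Variant,
    apply_variants,
    render_trace,
    variant_to_anchored,
)
from dipscan.trace_io import PolyRow, ReferenceSeq, TraceRead
from dipscan.variants import VariantCall

NOISELESS = SimulationConfig(noise_sd=0.0, cross_talk=0.0, seed=0, read_length=240)


def read_from_bases(bases: str, ref_start: int = 1, sample="S", amp="A") -> TraceRead:
    rows = tuple(PolyRow(i, b, 1000.0, "-", 0.0) for i, b in enumerate(bases))
    return TraceRead("r", sample, amp, "+", ref_start, rows)


def affine_dp_score(target: str, query: str, match=1, mismatch=-1, open_=-2, ext=-1):
    """Quadratic-space affine-gap DP oracle; reference end gaps free."""
    n, m = len(target), len(query)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (consumes reference)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (consumes read)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = 0.0  # free leading reference overhang
    for j in range(1, m + 1):
        I[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if target[i - 1] == query[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            D[i][j] = max(M[i - 1][j] + open_, D[i - 1][j] + ext, I[i - 1][j] + open_)
            I[i][j] = max(M[i][j - 1] + open_, I[i][j - 1] + ext, D[i][j - 1] + open_)
    return max(max(M[i][m], I[i][m]) for i in range(n + 1))


class TestAlignPrimary:
    def test_identity_read_scores_plus_one_per_base(self, random_ref):
        ref = ReferenceSeq("A", random_ref(100))
        read = read_from_bases(ref.bases[10:60], ref_start=11)
        aln = align_primary(read, ref)
        assert aln.score == 50
        # no internal gaps; only the free reference-overhang columns at the ends
        assert "-" not in aln.aligned_read.strip("-") and "-" not in aln.aligned_ref
        assert aln.read_to_ref[0] == 11 and aln.read_to_ref[49] == 60

    def test_single_mismatch_column(self, random_ref):
        ref = ReferenceSeq("A", random_ref(100))
        bases = list(ref.bases[:50])
        bases[25] = "A" if bases[25] != "A" else "C"
        aln = align_primary(read_from_bases("".join(bases)), ref)
        mismatches = [
            c
            for c in range(len(aln.aligned_read))
            if "-" not in (aln.aligned_read[c], aln.aligned_ref[c])
            and aln.aligned_read[c] != aln.aligned_ref[c]
        ]
        assert len(mismatches) == 1
        assert aln.score == 49 - 1

    def test_score_matches_independent_dp_oracle(self, rng, random_ref):
        for _ in range(25):
            target = random_ref(40)
            s, e = sorted(rng.integers(0, 41, size=2))
            if e - s < 8:
                e = min(40, s + 8)
            q = list(target[s:e])
            for k in range(len(q)):
                if rng.random() < 0.1:
                    q[k] = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.3 and len(q) > 10:
                del q[5]
            query = "".join(q)
            ref = ReferenceSeq("A", target)
            aln = align_primary(read_from_bases(query), ref)
            assert aln.score == affine_dp_score(target, query)

    def test_read_longer_than_window_rejected(self, random_ref):
        ref = ReferenceSeq("A", random_ref(30))
        with pytest.raises(ValueError, match="longer than"):
            align_primary(read_from_bases("ACGT" * 10), ref)


class TestCallHomozygous:
    def test_identity_alignment_no_calls(self, random_ref):
        ref = ReferenceSeq("A", random_ref(100))
        read = read_from_bases(ref.bases[:60])
        aln = align_primary(read, ref)
        assert call_homozygous(aln, read, ref) == []

    def test_clean_mismatch_called_hom_snv(self, random_ref):
        ref = ReferenceSeq("A", random_ref(100))
        bases = list(ref.bases[:60])
        alt = "A" if bases[30] != "A" else "C"
        bases[30] = alt
        read = read_from_bases("".join(bases))
        aln = align_primary(read, ref)
        calls = call_homozygous(aln, read, ref)
        assert [(c.position, c.alt, c.zygosity, c.kind) for c in calls] == [
            (31, alt, "hom", "SNV")
        ]

    def test_mismatch_with_qualifying_secondary_left_to_het_machinery(self, random_ref):
        ref = ReferenceSeq("A", random_ref(100))
        bases = list(ref.bases[:60])
        alt = "A" if bases[30] != "A" else "C"
        bases[30] = alt
        rows = list(PolyRow(i, b, 1000.0, "-", 0.0) for i, b in enumerate(bases))
        rows[30] = PolyRow(30, alt, 1000.0, ref.bases[30], 500.0)
        read = TraceRead("r", "S", "A", "+", 1, tuple(rows))
        aln = align_primary(read, ref)
        assert call_homozygous(aln, read, ref) == []
        het = call_het_snvs(form_base_vectors(read), aln, read, ref)
        assert [(c.position, c.alt, c.zygosity) for c in het] == [(31, alt, "het")]

    def test_planted_hom_deletion_recovered(self, random_ref):
        ref_str = random_ref(258)
        ref = ReferenceSeq("A", ref_str)
        deleted = ref_str[:100] + ref_str[103:]
        pair = HaplotypePair(hap1=deleted, hap2=deleted)
        read = render_trace(pair, NOISELESS)
        calls = enumerate_and_call(read, ref, DetectorConfig())
        dels = [c for c in calls if c.kind == "DEL"]
        truth = variant_to_anchored(ref_str, Variant("DEL_het", pos=100, length=3))
        assert [(c.position, c.ref, c.alt, c.zygosity) for c in dels] == [
            (truth[0], truth[1], truth[2], "hom")
        ]


class TestFormBaseVectors:
    def test_below_ten_percent_copies_primary(self):
        read = TraceRead("r", "S", "A", "+", 1, (PolyRow(0, "A", 100.0, "G", 9.0),))
        vec = form_base_vectors(read)
        assert vec.v1 == "A" and vec.v2 == "A"

    def test_exactly_ten_percent_keeps_secondary(self):
        read = TraceRead("r", "S", "A", "+", 1, (PolyRow(0, "A", 100.0, "G", 10.0),))
        vec = form_base_vectors(read)
        assert vec.v1 == "A" and vec.v2 == "G"

    def test_disagreement_count_equals_qualifying_secondary_count(self, rng):
        for _ in range(10):
            rows = []
            expected = 0
            for i in range(80):
                pb = "ACGT"[int(rng.integers(4))]
                if rng.random() < 0.5:
                    sb = [b for b in "ACGT" if b != pb][int(rng.integers(3))]
                    sa = round(float(rng.uniform(0, 100)), 4)
                    if sa >= 0.10 * 100.0:
                        expected += 1
                    rows.append(PolyRow(i, pb, 100.0, sb, sa))
                else:
                    rows.append(PolyRow(i, pb, 100.0, "-", 0.0))
            vec = form_base_vectors(TraceRead("r", "S", "A", "+", 1, tuple(rows)))
            assert sum(a != b for a, b in zip(vec.v1, vec.v2)) == expected


class TestScoreShift:
    def test_single_mismatch_in_window_of_twenty(self):
        v1 = "A" * 30
        v2 = "A" * 15 + "C" + "A" * 14
        # s=1 window [10, 28]: 19 positions, one mismatch at j=15
        score, window = score_shift(BaseVectors(v1, v2), 9, 1)
        assert window == 20
        assert score == pytest.approx(19 / 20)

    def test_identical_vectors_score_below_one_on_nonrepetitive_string(self, random_ref):
        v = random_ref(100)
        vec = BaseVectors(v, v)
        for s in (1, 2, -3):
            score, _ = score_shift(vec, 0, s)
            assert score < 1.0

    def test_noiseless_het_deletion_scores_one(self, random_ref):
        ref = random_ref(258)
        pair = apply_variants(ref, [Variant("DEL_het", pos=100, length=2)])
        vec = form_base_vectors(render_trace(pair, NOISELESS))
        score, window = score_shift(vec, 100, 2)
        assert score == 1.0 and window == 240 - 2 - 100

    def test_window_below_minimum_returns_zero(self):
        vec = BaseVectors("ACGTACGT", "ACGTACGT")
        assert score_shift(vec, 6, 1, min_window=5) == (0.0, 0)

    def test_out_of_range_arguments_rejected(self):
        vec = BaseVectors("ACGTACGT", "ACGTACGT")
        with pytest.raises(ValueError):
            score_shift(vec, 8, 1)
        with pytest.raises(ValueError):
            score_shift(vec, 0, 0)

    @given(st.data())
    def test_invariant_under_alphabet_relabeling(self, data):
        n = data.draw(st.integers(20, 60))
        v1 = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(n))
        v2 = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(n))
        perm = dict(zip("ACGT", data.draw(st.permutations("ACGT"))))
        p = data.draw(st.integers(0, n - 2))
        s = data.draw(st.sampled_from([1, 2, -1, -2]))
        before = score_shift(BaseVectors(v1, v2), p, s)
        after = score_shift(
            BaseVectors("".join(perm[b] for b in v1), "".join(perm[b] for b in v2)), p, s
        )
        assert before == after


def brute_force_best(vec: BaseVectors, max_shift: int, min_window: int):
    """Exhaustive reference implementation of the hypothesis search."""
    best = None
    L = len(vec)
    for size in range(1, min(max_shift, L - 1) + 1):
        for s in (size, -size):
            p_lo = 0 if s > 0 else size
            p_hi = L - 1 - max(s, 0)
            for p in range(p_lo, p_hi + 1):
                score, window = score_shift(vec, p, s, min_window=min_window)
                if window == 0:
                    continue
                if best is None or score > best.score:
                    best = ShiftHypothesis(position=p, size=s, score=score, window=window)
    return best


class TestEnumerate:
    def test_variant_free_read_yields_no_calls(self, random_ref):
        ref = ReferenceSeq("A", random_ref(258))
        read = render_trace(apply_variants(ref.bases, []), NOISELESS)
        assert enumerate_and_call(read, ref, DetectorConfig()) == []

    def test_planted_het_deletion_recovered_exactly(self, random_ref):
        ref_str = random_ref(258)
        ref = ReferenceSeq("A", ref_str)
        v = Variant("DEL_het", pos=120, length=2)
        read = render_trace(apply_variants(ref_str, [v]), NOISELESS)
        calls = enumerate_and_call(read, ref, DetectorConfig())
        truth = variant_to_anchored(ref_str, v)
        assert [(c.position, c.ref, c.alt, c.kind, c.zygosity) for c in calls] == [
            (truth[0], truth[1], truth[2], "DEL", "het")
        ]

    def test_argmax_matches_brute_force_oracle_on_short_reads(self, rng, random_ref):
        checked = 0
        for _ in range(40):
            L = int(rng.integers(15, 31))
            v1 = "".join("ACGT"[i] for i in rng.integers(4, size=L))
            v2 = list(v1)
            for k in range(L):
                if rng.random() < 0.35:
                    v2[k] = "ACGT"[int(rng.integers(4))]
            vec = BaseVectors(v1, "".join(v2))
            got = enumerate_shifts(vec, max_shift=3, min_window=4)
            want = brute_force_best(vec, max_shift=3, min_window=4)
            assert got == want
            checked += want is not None
        assert checked > 20

    def test_recovery_degrades_monotonically_with_noise(self, random_ref):
        ref_str = random_ref(258)
        ref = ReferenceSeq("A", ref_str)
        dc = DetectorConfig()
        rates = []
        for sd in (0, 60, 120, 240):
            cfg = SimulationConfig(
                noise_sd=sd,
                cross_talk=0.0,
                allele_fraction=0.6,
                seed=5,
                read_length=240,
            )
            noise_rng = np.random.default_rng(5)
            hits = 0
            n = 25
            for i in range(n):
                v = Variant("DEL_het", pos=80 + i, length=3)
                read = render_trace(apply_variants(ref_str, [v]), cfg, rng=noise_rng)
                calls = [
                    c
                    for c in enumerate_and_call(read, ref, dc)
                    if c.zygosity == "het" and c.kind == "DEL"
                ]
                truth = variant_to_anchored(ref_str, v)
                hits += [(c.position, c.ref, c.alt) for c in calls] == [truth[:3]]
            rates.append(hits / n)
        assert rates[0] == 1.0
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < rates[0]


class TestCrossValidate:
    def call(self, pos, alt="A", ref="C", sample="S"):
        return VariantCall(sample, "A", pos, ref, alt, "het", "SNV")

    def test_shared_call_in_overlap_is_concordant(self):
        a, b = [self.call(50)], [self.call(50)]
        merged = cross_validate_amplimers(a, b, (40, 60))
        assert merged == [(a[0], "concordant")]

    def test_one_sided_call_in_overlap_is_discordant(self):
        merged = cross_validate_amplimers([self.call(50)], [], (40, 60))
        assert merged[0][1] == "discordant"

    def test_outside_overlap_passes_through_unflagged(self):
        merged = cross_validate_amplimers([self.call(10)], [], (40, 60))
        assert merged[0][1] is None

    def test_flag_counts_match_set_arithmetic(self, rng):
        pool = [self.call(int(p), alt="G", ref="T") for p in range(1, 101)]
        idx_a = set(map(int, rng.choice(100, size=40, replace=False)))
        idx_b = set(map(int, rng.choice(100, size=40, replace=False)))
        a = [pool[i] for i in sorted(idx_a)]
        b = [pool[i] for i in sorted(idx_b)]
        lo, hi = 20, 70
        merged = cross_validate_amplimers(a, b, (lo, hi))
        in_overlap = {i for i in idx_a | idx_b if lo <= i + 1 <= hi}
        both = {i for i in idx_a & idx_b if lo <= i + 1 <= hi}
        flags = [f for _, f in merged]
        assert flags.count("concordant") == len(both)
        assert flags.count("discordant") == len(in_overlap - both)
        assert flags.count(None) == len((idx_a | idx_b) - in_overlap)

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            cross_validate_amplimers([], [], (60, 40))
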