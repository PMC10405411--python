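"""Aligner behaviour against an exhaustive brute-force oracle, plus
trimming, histogram, ppm and profile conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicerscope._util import derive_rng, random_sequence, revcomp
from dicerscope.align import (
    ReferenceIndex,
    SmallReadAlignment,
    align_read,
    align_reads,
    count_unique_sequences,
    coverage_from_alignments,
    five_prime_profile,
    ppm,
    size_distribution,
    trim_adapter,
)
from tests.conftest import brute_force_placements

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdapter:
    def test_insert_retained(self):
        rng = derive_rng(0, 1)
        insert = random_sequence(rng, 21)
        assert trim_adapter(insert + ADAPTER, ADAPTER) == insert

    def test_short_insert_discarded(self):
        assert trim_adapter("ACGTACGTAC" + ADAPTER, ADAPTER, min_len=17) is None

    def test_untrimmed_in_window_kept(self):
        read = random_sequence(derive_rng(0, 2), 22)
        assert trim_adapter(read, ADAPTER) == read

    def test_untrimmable_long_read_discarded(self):
        read = random_sequence(derive_rng(0, 3), 40)
        assume_no_adapter = ADAPTER[:8] not in read
        assert assume_no_adapter and trim_adapter(read, ADAPTER) is None

    def test_partial_adapter_under_8nt_not_matched(self):
        insert = random_sequence(derive_rng(0, 4), 18)
        # only 5 adapter nt at the 3' end: below the match threshold
        assert trim_adapter(insert + ADAPTER[:5], ADAPTER) == insert + ADAPTER[:5]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT" * 6, "")


@pytest.fixture(scope="module")
def reference():
    return {"ref": random_sequence(derive_rng(42, 5), 2000)}


class TestAlignRead:
    def test_unique_substring_plus(self, reference):
        seq = reference["ref"][100:121]
        hits = align_read(seq, reference, 0)
        assert len(hits) == 1
        a = hits[0]
        assert (a.start, a.strand, a.mismatches, a.weight) == (100, "+", 0, 1.0)

    def test_reverse_complement_minus(self, reference):
        seq = revcomp(reference["ref"][300:322])
        hits = align_read(seq, reference, 0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (300, "-")

    def test_one_mismatch_stratum(self, reference):
        seq = list(reference["ref"][500:521])
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        seq = "".join(seq)
        assert align_read(seq, reference, 0) == []
        hits = align_read(seq, reference, 1)
        assert any(a.start == 500 and a.mismatches == 1 for a in hits)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            align_read("A" * 21, {}, 0)

    def test_short_read_rejected(self, reference):
        with pytest.raises(ValueError, match="15"):
            align_read("ACGTACGTACGT", reference, 0)

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_agrees_with_brute_force(self, reference, max_mm):
        rng = derive_rng(7, 6)
        index = ReferenceIndex(reference)
        ref = reference["ref"]
        for i in range(300):
            mode = i % 3
            if mode == 0:  # exact substring
                s = int(rng.integers(0, len(ref) - 21))
                seq = ref[s : s + 21]
            elif mode == 1:  # planted single mismatch
                s = int(rng.integers(0, len(ref) - 21))
                chars = list(ref[s : s + 21])
                j = int(rng.integers(0, 21))
                chars[j] = "ACGT"[(("ACGT".index(chars[j])) + 1) % 4]
                seq = "".join(chars)
            else:  # random read
                seq = random_sequence(rng, 21)
            if int(rng.integers(0, 2)):
                seq = revcomp(seq)
            got = {(a.reference, a.start, a.strand) for a in align_read(seq, index, max_mm)}
            expected, _ = brute_force_placements(seq, reference, max_mm)
            assert got == expected

    def test_weight_conservation_and_order(self, reference):
        # a repeated site: plant the same 21-mer twice
        ref = reference["ref"]
        seq = ref[50:71]
        doubled = {"ref": ref, "ref2": "TTTT" + seq + "GGGG"}
        hits = align_read(seq, doubled, 0)
        assert len(hits) >= 2
        assert abs(sum(a.weight for a in hits) - 1.0) < 1e-9
        keys = [(a.reference, a.start, a.strand) for a in hits]
        assert keys == sorted(keys)

    def test_strand_involution(self, reference):
        rng = derive_rng(9, 7)
        reads = [("r%d" % i, random_sequence(rng, 21)) for i in range(50)]
        ref = reference["ref"]
        reads += [("e%d" % i, ref[i * 30 : i * 30 + 21]) for i in range(20)]
        fwd = align_reads(reads, reference, 1)
        rev = align_reads([(rid, revcomp(s)) for rid, s in reads], reference, 1)
        plus_f = sum(a.weight for a in fwd if a.strand == "+")
        minus_f = sum(a.weight for a in fwd if a.strand == "-")
        plus_r = sum(a.weight for a in rev if a.strand == "+")
        minus_r = sum(a.weight for a in rev if a.strand == "-")
        assert plus_f == pytest.approx(minus_r, abs=1e-9)
        assert minus_f == pytest.approx(plus_r, abs=1e-9)


def _aln(read_id="r", reference="ref", start=0, length=21, strand="+", mm=0, weight=1.0):
    return SmallReadAlignment(read_id, reference, start, length, strand, mm, weight)


class TestHistogramPpm:
    def test_simple_counts(self):
        alns = [_aln("a", length=21), _aln("b", length=21), _aln("c", length=22)]
        hist = size_distribution(alns)
        assert hist.counts[21] == 2 and hist.counts[22] == 1

    def test_empty_histogram(self):
        hist = size_distribution([])
        assert all(v == 0 for v in hist.counts.values())

    def test_conservation_sums_to_mapped(self, hairpin275):
        from dicerscope.synthetic import DicerModel, simulate_dicer_products

        y = simulate_dicer_products(
            hairpin275, DicerModel(background_fraction=0.0), 3000, seed=3
        )
        refs = {"hairpin": hairpin275.transcript_sequence}
        alns = align_reads([(r, s) for r, s, _ in y.reads.reads], refs, 0)
        hist = size_distribution(alns)
        assert sum(hist.counts.values()) == pytest.approx(hist.mapped, abs=1e-6)
        # every read aligns: total weight equals the number of reads
        assert hist.mapped == pytest.approx(3000, abs=1e-6)

    def test_mode_follows_generator_weights(self, hairpin_yield, hairpin275):
        refs = {"hairpin": hairpin275.transcript_sequence}
        alns = align_reads(
            [(r, s) for r, s, _ in hairpin_yield.reads.reads], refs, 0
        )
        hist = size_distribution(alns)
        assert max(hist.counts, key=hist.counts.get) == 21

    @pytest.mark.parametrize(
        "count,library,expected", [(650, 1_000_000, 650.0), (0, 5, 0.0), (13, 20_000, 650.0)]
    )
    def test_ppm_values(self, count, library, expected):
        assert ppm(count, library) == pytest.approx(expected)

    def test_ppm_zero_library_rejected(self):
        with pytest.raises(ValueError):
            ppm(1, 0)

    @given(
        a=st.floats(0, 1e6), b=st.floats(0, 1e6), lib=st.integers(1, 10**9)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ppm_linearity(self, a, b, lib):
        assert ppm(a + b, lib) == pytest.approx(ppm(a, lib) + ppm(b, lib), abs=1e-9 * 1e6)


class TestProfilesUnique:
    def test_plus_five_prime_is_start(self):
        prof = five_prime_profile([_aln(start=5, length=21)], "ref", 100)
        assert prof.plus[5] == 1.0 and prof.plus.sum() == 1.0

    def test_minus_five_prime_is_end(self):
        prof = five_prime_profile([_aln(start=5, length=21, strand="-")], "ref", 100)
        assert prof.minus[25] == 1.0

    def test_unique_sequence_count(self):
        alns = [_aln("a"), _aln("b"), _aln("c")]
        seqs = {"a": "ACGT" * 5, "b": "ACGT" * 5, "c": "TTTT" * 5}
        assert count_unique_sequences(alns, seqs, "ref", "+") == 2
        assert count_unique_sequences([], {}, "ref", "+") == 0

    def test_coverage_accumulates_interval(self):
        cov = coverage_from_alignments([_aln(start=10, length=5)], {"ref": 20})
        plus, minus = cov["ref"]
        assert plus[10:15].sum() == 5.0 and plus.sum() == 5.0 and minus.sum() == 0.0
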