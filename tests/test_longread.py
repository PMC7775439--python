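"""Demultiplexing, length filtering, alignment-based genotyping and diploid
calling of long amplicon reads."""

import numpy as np
import pytest

from nat2loh import (
    SimParams,
    align_and_genotype_read,
    call_diploid,
    classify_read,
    demultiplex,
    filter_by_length,
    run_longread_pipeline,
    sim_long_reads,
)
from nat2loh.defs import UnclassifiedPattern
from nat2loh.errors import ValidationError
from nat2loh.longread import PADDING_LEN, ReadRecord, hamming, revcomp
from nat2loh.sim import haplotype_template


def _make_read(read_id, fwd_bc, rev_bc, insert, pad="TTTTT"):
    return ReadRecord(
        read_id, fwd_bc + pad + insert + revcomp(rev_bc + pad)
    )


@pytest.fixture()
def insert():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), size=2000))


class TestDemultiplex:
    def test_exact_barcode_assigns(self, barcodes, insert):
        read = _make_read("r1", *barcodes["S000"], insert)
        out, acct = demultiplex([read], barcodes)
        assert out[0].sample == "S000"
        assert acct == {"total": 1, "assigned": 1, "unassigned": 0,
                        "sample:S000": 1}

    def test_too_many_mismatches_leaves_unassigned(self, barcodes, insert):
        fwd, rev = barcodes["S000"]
        mutated = "AAA" + fwd[3:] if fwd[:3] != "AAA" else "CCC" + fwd[3:]
        assert hamming(mutated, fwd) == 3
        read = ReadRecord("r1", mutated + "TTTTT" + insert)
        out, _ = demultiplex([read], barcodes, max_mismatch=1)
        assert out[0].sample is None

    def test_reverse_complemented_read_assigned_same_sample(
        self, barcodes, insert
    ):
        read = _make_read("r1", *barcodes["S001"], insert)
        flipped = ReadRecord("r1", revcomp(read.sequence))
        out_f, _ = demultiplex([read], barcodes)
        out_r, _ = demultiplex([flipped], barcodes)
        assert out_f[0].sample == out_r[0].sample == "S001"
        # trimmed payload is identical after orientation correction
        assert out_f[0].sequence == out_r[0].sequence

    def test_matches_brute_force_oracle(self, barcodes, insert):
        # oracle: scan every barcode and its reverse complement against both
        # read ends; assign iff a unique sample attains the minimum distance
        # within the mismatch budget
        rng = np.random.default_rng(17)
        reads = []
        for i in range(30):
            sample = f"S{rng.integers(0, 4):03d}"
            read = _make_read(f"r{i}", *barcodes[sample], insert)
            seq = read.sequence
            if rng.random() < 0.5:
                seq = revcomp(seq)
            # sprinkle up to 2 mutations into the first barcode
            seq = list(seq)
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, 15))
                seq[pos] = "ACGT"[int(rng.integers(4))]
            reads.append((sample, ReadRecord(f"r{i}", "".join(seq))))

        def oracle(seq, mm=1):
            best = {}
            for s, (fb, rb) in barcodes.items():
                dists = []
                for o in (seq, revcomp(seq)):
                    for end in (o[:15], o[-15:]):
                        for bc in (fb, rb, revcomp(fb), revcomp(rb)):
                            dists.append(hamming(end, bc))
                best[s] = min(dists)
            dmin = min(best.values())
            winners = [s for s, d in best.items() if d == dmin]
            if dmin > mm or len(winners) > 1:
                return None
            return winners[0]

        out, _ = demultiplex([r for _, r in reads], barcodes)
        for (_truth, orig), rec in zip(reads, out):
            assert rec.sample == oracle(orig.sequence)

    def test_equal_distance_tie_between_samples_unassigned(self, insert):
        bcs = {"A": ("A" * 15, "G" * 15), "B": ("A" * 14 + "C", "T" * 15)}
        # read barcode equidistant (1 mismatch) from A's and B's fwd barcodes
        seq = ("A" * 14 + "G") + "TTTTT" + insert
        out, _ = demultiplex([ReadRecord("r1", seq)], bcs, max_mismatch=1)
        assert out[0].sample is None

    def test_duplicate_barcodes_rejected(self, insert):
        bcs = {"A": ("A" * 15, "G" * 15), "B": ("A" * 15, "T" * 15)}
        with pytest.raises(ValidationError, match="duplicate"):
            demultiplex([ReadRecord("r1", insert)], bcs)

    def test_conflicting_end_barcodes_unassigned(self, barcodes, insert):
        fwd_a, _ = barcodes["S000"]
        _, rev_b = barcodes["S001"]
        read = ReadRecord(
            "r1", fwd_a + "TTTTT" + insert + revcomp(rev_b + "TTTTT")
        )
        out, _ = demultiplex([read], barcodes)
        assert out[0].sample is None


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length, kept",
        [(1499, False), (1500, True), (1715, True), (2300, True),
         (2301, False)],
    )
    def test_inclusive_window(self, length, kept):
        reads = [ReadRecord("r", "A" * length)]
        out, acct = filter_by_length(reads)
        assert (len(out) == 1) is kept
        assert acct["length_pass"] + acct["length_fail"] == 1

    def test_reported_fraction_matches_enumeration(self):
        rng = np.random.default_rng(2)
        lengths = list(rng.integers(1200, 1500, size=300)) + list(
            rng.integers(1500, 2301, size=700)
        )
        reads = [ReadRecord(f"r{i}", "A" * int(n)) for i, n in enumerate(lengths)]
        out, acct = filter_by_length(reads)
        assert acct["length_pass"] == 700
        assert acct["length_pass_fraction"] == pytest.approx(0.700)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            filter_by_length([], lo=10, hi=5)


class TestAlignAndGenotype:
    def test_exact_reference_substring_gives_reference_bases(
        self, reference, catalog
    ):
        read = ReadRecord("r1", reference[400:1400])
        obs, aligned, orientation = align_and_genotype_read(
            read, reference, catalog
        )
        assert aligned and orientation == "forward"
        by_rsid = {o.rsid: o for o in obs}
        for site in catalog.classifying:
            assert by_rsid[site.rsid].observed_base == site.ref

    def test_planted_substitution_detected_at_its_site(
        self, reference, catalog
    ):
        site = catalog.by_rsid["rs1799930"]
        mutated = list(reference)
        mutated[site.amplicon_offset] = site.alt
        read = ReadRecord("r1", "".join(mutated))
        obs, aligned, _ = align_and_genotype_read(read, reference, catalog)
        assert aligned
        for o in obs:
            expected = site.alt if o.rsid == "rs1799930" else \
                catalog.by_rsid[o.rsid].ref
            assert o.observed_base == expected

    def test_agrees_with_independent_alignment_oracle(
        self, reference, catalog
    ):
        # a short indel-bearing instance around rs1801279 checked against
        # Biopython's optimal unit-cost aligner as an independent oracle
        from Bio import Align

        site = catalog.by_rsid["rs1801279"]
        off = site.amplicon_offset
        window = list(reference[off - 100 : off + 100])
        window[100] = site.alt  # planted substitution at the site
        del window[30:32]  # planted 2 bp deletion upstream
        query = "".join(window)

        read = ReadRecord("r1", query)
        obs, aligned, _ = align_and_genotype_read(read, reference, catalog)
        assert aligned
        by_rsid = {o.rsid: o for o in obs if o.in_alignment}
        assert by_rsid["rs1801279"].observed_base == site.alt

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        alignment = aligner.align(reference, query)[0]
        t2q = {}
        for (tb, te), (qb, _qe) in zip(*alignment.aligned):
            for k in range(te - tb):
                t2q[tb + k] = qb + k
        assert query[t2q[off]] == site.alt

    def test_reverse_orientation_read_is_recovered(self, reference, catalog):
        read = ReadRecord("r1", revcomp(reference[300:1500]))
        obs, aligned, orientation = align_and_genotype_read(
            read, reference, catalog
        )
        assert aligned and orientation == "reverse"
        by_rsid = {o.rsid: o for o in obs}
        assert by_rsid["rs1801280"].observed_base == "T"

    def test_junk_read_marked_unaligned(self, reference, catalog):
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("ACGT"), size=1800))
        obs, aligned, _ = align_and_genotype_read(
            ReadRecord("r1", junk), reference, catalog
        )
        assert not aligned and obs == []

    def test_noisy_5b_read_classifies_as_5b(
        self, reference, catalog, table
    ):
        template = haplotype_template("*5B", reference, catalog, table)
        params = SimParams(sub_rate=0.02, indel_rate=0.005, seed=42)
        rng = np.random.default_rng(42)
        from nat2loh.sim import _mutate

        for _ in range(10):
            noisy = _mutate(template, rng, 0.02, 0.005)
            obs, aligned, _ = align_and_genotype_read(
                ReadRecord("r", noisy), reference, catalog
            )
            assert aligned
            call = classify_read(obs, catalog, table)
            if isinstance(call, str):
                assert call == "*5B"
                break
        else:
            pytest.fail("no classifiable read among 10 noisy draws")


class TestCallDiploid:
    def test_147_reads_all_5b_called_homozygous(self):
        call = call_diploid(["*5B"] * 147)
        assert (call.allele1, call.allele2) == ("*5B", "*5B")
        assert call.support1 == 147 and call.spanning_total == 147
        assert call.notes == ()  # enough coverage: no dropout caveat

    def test_two_class_sample_called_heterozygous(self):
        call = call_diploid(["*5B"] * 120 + ["*6A"] * 118)
        assert {call.allele1, call.allele2} == {"*5B", "*6A"}

    def test_minor_class_thresholds(self):
        calls = (["*4"] * 55 + ["*6A"] * 40
                 + [UnclassifiedPattern(frozenset({("rs1799931", "A")}))] * 5)
        call = call_diploid(calls, min_minor_fraction=0.20, min_minor_reads=10)
        assert (call.allele1, call.allele2) == ("*4", "*6A")
        assert (call.support1, call.support2) == (55, 40)
        assert call.unclassified_count == 5

    def test_below_min_spanning_is_no_call(self):
        call = call_diploid(["*4"] * 8, min_spanning=20)
        assert not call.is_call
        assert call.no_call_reason == "below_min_spanning"

    def test_zero_classified_reads_is_no_call(self):
        calls = [UnclassifiedPattern(frozenset({("rs1799931", "A")}))] * 30
        call = call_diploid(calls)
        assert call.no_call_reason == "no_classifiable_reads"
        assert call.novel_flag  # one modal pattern dominates

    def test_low_coverage_homozygote_flags_possible_dropout(self):
        call = call_diploid(["*5B"] * 40)
        assert call.homozygous
        assert any("second allele" in note for note in call.notes)

    def test_raising_minor_fraction_never_creates_heterozygote(self):
        reads = ["*4"] * 70 + ["*6A"] * 30
        previous_het = True
        for frac in (0.05, 0.2, 0.25, 0.31, 0.5):
            call = call_diploid(reads, min_minor_fraction=frac)
            het = not call.homozygous
            assert not (het and not previous_het)
            previous_het = het


def test_pipeline_accounting_conserves_reads(
    reference, catalog, table, barcodes
):
    params = SimParams(coverage=40, sub_rate=0.01, indel_rate=0.005, seed=3)
    reads, _ = sim_long_reads(
        ("*4", "*6A"), params, barcodes["S000"], sample="S000",
        reference=reference, catalog=catalog, table=table,
    )
    rng = np.random.default_rng(3)
    junk = [ReadRecord("junk%d" % i,
                       "".join(rng.choice(list("ACGT"), size=1800)))
            for i in range(5)]
    calls, acct, _ = run_longread_pipeline(
        reads + junk, {"S000": barcodes["S000"]}, reference, catalog, table
    )
    assert acct["total"] == acct["assigned"] + acct["unassigned"]
    assert acct["assigned"] == acct["length_pass"] + acct["length_fail"]
    assert acct["length_pass"] == acct["aligned"] + acct["unaligned"]
    assert calls["S000"].is_call
    assert {calls["S000"].allele1, calls["S000"].allele2} == {"*4", "*6A"}
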