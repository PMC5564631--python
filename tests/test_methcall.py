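"""Methylation caller: filter semantics, strand resolution, categorization,
overlap clipping, and equivalence with an independent pileup oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpemeth import methcall
from ffpemeth.bsio import GenomicSite, Region
from ffpemeth.methcall import (
    CallError,
    CallParams,
    MethProfile,
    bisulfite_strand,
    call_methylation,
    categorize,
    merge_symmetric,
)

from conftest import CHROM, make_mixed_fixture, make_read, oracle_pileup

# minimal reference: one CpG at 10-11 inside the target
REF = {"chrT": "A" * 10 + "CG" + "A" * 88}
TARGETS = [Region(CHROM, 0, 100)]
SITE_F = GenomicSite(CHROM, 10, "+")
SITE_R = GenomicSite(CHROM, 11, "-")
NOTRIM = CallParams(trim5=0, trim3=0)


class TestCategorize:
    @pytest.mark.parametrize("p,cat", [
        (0.10, "hypo"), (0.85, "hyper"),
        (0.20, "intermediate"), (0.80, "intermediate"),
        (0.0, "hypo"), (1.0, "hyper"), (0.5, "intermediate"),
        (0.19999, "hypo"), (0.80001, "hyper"),
    ])
    def test_thresholds(self, p, cat):
        assert categorize(p) == cat

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(CallError):
            categorize(p)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_is_exhaustive_and_exclusive(self, p):
        assert categorize(p) in ("hypo", "intermediate", "hyper")


class TestBisulfiteStrand:
    def test_inference_rules(self):
        assert bisulfite_strand(make_read("r", 0, "ACGT", mate=1, bs_strand=None)) == "OT"
        assert bisulfite_strand(make_read("r", 0, "ACGT", mate=2, bs_strand=None)) == "OB"
        assert bisulfite_strand(
            make_read("r", 0, "ACGT", mate=2, reverse=True, bs_strand=None)) == "OT"
        assert bisulfite_strand(
            make_read("r", 0, "ACGT", mate=1, reverse=True, bs_strand=None)) == "OB"

    def test_tag_wins_over_flags(self):
        read = make_read("r", 0, "ACGT", mate=1, bs_strand="OB")  # flags say OT
        assert bisulfite_strand(read) == "OB"

    def test_contradictory_pair_flags_skipped(self):
        read = make_read("r", 0, "ACGT", flag=0x1 | 0x40 | 0x80, bs_strand=None)
        assert bisulfite_strand(read) is None


class TestCallBasics:
    def test_single_ot_read_methylated(self):
        reads = [make_read("r1", 5, "AAAAACGAAA", bs_strand="OT")]
        prof = call_methylation(reads, REF, TARGETS, NOTRIM)
        assert prof[SITE_F].n_meth == 1
        assert prof[SITE_F].n_unmeth == 0
        assert prof[SITE_F].proportion == 1.0
        assert SITE_R not in prof  # OT read is uninformative for the '-' cytosine

    def test_ot_read_converted(self):
        reads = [make_read("r1", 5, "AAAAATGAAA", bs_strand="OT")]
        prof = call_methylation(reads, REF, TARGETS, NOTRIM)
        assert (prof[SITE_F].n_meth, prof[SITE_F].n_unmeth) == (0, 1)
        assert prof[SITE_F].category == "hypo"

    def test_ob_read_informs_reverse_cytosine(self):
        reads = [make_read("r1", 5, "AAAAACGAAA", mate=2, bs_strand="OB")]
        prof = call_methylation(reads, REF, TARGETS, NOTRIM)
        assert prof[SITE_R].n_meth == 1
        assert SITE_F not in prof

    def test_mapq_boundary_30(self):
        lo = make_read("r1", 5, "AAAAACGAAA", mapq=29)
        hi = make_read("r2", 5, "AAAAACGAAA", mapq=30)
        prof = call_methylation([lo], REF, TARGETS, NOTRIM)
        assert SITE_F not in prof  # below the minimum: site has no coverage
        prof = call_methylation([hi], REF, TARGETS, NOTRIM)
        assert prof[SITE_F].coverage == 1

    def test_duplicate_and_secondary_excluded(self):
        reads = [make_read("r1", 5, "AAAAACGAAA", duplicate=True),
                 make_read("r2", 5, "AAAAACGAAA", secondary=True)]
        assert len(call_methylation(reads, REF, TARGETS, NOTRIM)) == 0

    def test_mismatching_base_counts_as_other(self):
        reads = [make_read("r1", 5, "AAAAAGGAAA", bs_strand="OT"),
                 make_read("r2", 5, "AAAAACGAAA", bs_strand="OT")]
        prof = call_methylation(reads, REF, TARGETS, NOTRIM)
        call = prof[SITE_F]
        assert (call.n_meth, call.n_unmeth, call.n_other) == (1, 0, 1)
        assert call.coverage == 1  # coverage counts only informative states

    def test_unknown_reference_sequence_rejected(self):
        reads = [make_read("r1", 5, "AAAAACGAAA", chrom="chrMissing")]
        with pytest.raises(CallError):
            call_methylation(reads, REF, TARGETS, NOTRIM)

    def test_trimming_removes_read_start(self):
        # CpG C at cycle 6 of a forward read: trim5=6 discards it
        reads = [make_read("r1", 5, "AAAAACGAAA", bs_strand="OT")]
        prof = call_methylation(reads, REF, TARGETS, CallParams(trim5=6, trim3=0))
        assert SITE_F not in prof

    def test_trim3_counts_from_sequencing_end(self):
        # reverse-stored read: cycle of base at qpos is qlen - qpos
        seq = "AAAAACGAAA"
        read = make_read("r1", 5, seq, mate=2, reverse=True, bs_strand="OT")
        # CpG C at qpos 5 -> cycle 10-5=5; trim5=5 discards it
        assert SITE_F not in call_methylation([read], REF, TARGETS, CallParams(trim5=5, trim3=0))
        # but 3' trim of 4 keeps it (cycle 5 <= 10-4)
        prof = call_methylation([read], REF, TARGETS, CallParams(trim5=0, trim3=4))
        assert prof[SITE_F].coverage == 1

    def test_base_quality_filter(self):
        qual = "!" * 5 + "5" + "!" * 4  # Phred 20 at the CpG C, 0 elsewhere
        read = make_read("r1", 5, "AAAAACGAAA", qual=qual)
        assert call_methylation([read], REF, TARGETS, NOTRIM)[SITE_F].coverage == 1
        qual = "!" * 5 + "4" + "!" * 4  # Phred 19: below the minimum
        read = make_read("r1", 5, "AAAAACGAAA", qual=qual)
        assert SITE_F not in call_methylation([read], REF, TARGETS, NOTRIM)


class TestOverlapClipping:
    def _pair(self, q1: int, q2: int, b1: str = "C", b2: str = "T"):
        s1 = "AAAAA" + b1 + "GAAA"
        s2 = "AAAAA" + b2 + "GAAA"
        r1 = make_read("frag", 5, s1, mate=1, qual=chr(q1 + 33) * 10)
        r2 = make_read("frag", 5, s2, mate=2, reverse=True, qual=chr(q2 + 33) * 10)
        return [r1, r2]

    def test_overlap_counted_once_higher_quality_wins(self):
        prof = call_methylation(self._pair(30, 37), REF, TARGETS, NOTRIM)
        call = prof[SITE_F]
        assert call.coverage == 1
        assert call.n_unmeth == 1  # mate 2 had higher base quality

    def test_tie_goes_to_mate1(self):
        prof = call_methylation(self._pair(37, 37), REF, TARGETS, NOTRIM)
        assert prof[SITE_F].n_meth == 1

    def test_no_clipping_counts_both(self):
        params = CallParams(trim5=0, trim3=0, clip_overlap=False)
        call = call_methylation(self._pair(37, 37), REF, TARGETS, params)[SITE_F]
        assert call.coverage == 2
        assert (call.n_meth, call.n_unmeth) == (1, 1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("params", [
        CallParams(),
        CallParams(min_mapq=0, min_baseq=0, trim5=0, trim3=0),
        CallParams(min_mapq=30, min_baseq=20, trim5=10, trim3=8, clip_overlap=False),
    ])
    def test_mixed_fixture_matches_bruteforce(self, mixed_fixture, params):
        reference, targets, reads = mixed_fixture
        prof = call_methylation(reads, reference, targets, params)
        expected = oracle_pileup(reads, reference, targets, params)
        got = {(s.pos, s.strand): (c.n_meth, c.n_unmeth, c.n_other)
               for s, c in prof.calls.items()}
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == expected[k], f"site {k}"


class TestProperties:
    def test_trim_monotonicity(self, mixed_fixture):
        reference, targets, reads = mixed_fixture
        prev = None
        for t in (0, 5, 15, 30):
            prof = call_methylation(reads, reference, targets, CallParams(trim5=t, trim3=0))
            cov = {s: c.coverage for s, c in prof.calls.items()}
            if prev is not None:
                for s, c in cov.items():
                    assert prev.get(s, 0) >= c  # more trimming never adds coverage
            prev = cov

    def test_category_partition_sums_to_profile_size(self, mixed_fixture):
        reference, targets, reads = mixed_fixture
        prof = call_methylation(reads, reference, targets, CallParams())
        counts = prof.category_counts()
        assert sum(counts.values()) == len(prof)

    def test_parameter_recovery_smoke(self, small_sim):
        # estimated proportion is unbiased against truth on simulated data
        cfg, reference, targets, truth, ffpe, _ = small_sim
        prof = call_methylation(ffpe, reference, targets, CallParams())
        errs = [prof[s].proportion - truth.m[s] for s in prof.calls if s in truth.m]
        assert len(errs) > 500
        assert abs(float(np.mean(errs))) < 0.02


class TestProfileTsv:
    def test_roundtrip(self, tmp_path, small_sim):
        cfg, reference, targets, _, ffpe, _ = small_sim
        prof = call_methylation(ffpe, reference, targets, CallParams(), label="x")
        p = tmp_path / "prof.tsv"
        prof.write_tsv(p)
        back = MethProfile.read_tsv(p)
        assert back.sites() == prof.sites()
        for s in prof.calls:
            a, b = prof[s], back[s]
            assert (a.n_meth, a.n_unmeth, a.n_other) == (b.n_meth, b.n_unmeth, b.n_other)


class TestMergeSymmetric:
    def test_dyad_pooling(self):
        reads = [make_read("r1", 5, "AAAAACGAAA", mate=1, bs_strand="OT"),
                 make_read("r2", 5, "AAAAATGAAA", mate=1, bs_strand="OT"),
                 make_read("r3", 5, "AAAAACGAAA", mate=2, bs_strand="OB")]
        prof = call_methylation(reads, REF, TARGETS, NOTRIM)
        merged = merge_symmetric(prof)
        assert len(merged) == 1
        call = merged[SITE_F]
        assert (call.n_meth, call.n_unmeth) == (2, 1)
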