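import gzip

import numpy as np
import pytest

import rbnskit as rk
from rbnskit.errors import FastqParseError
from rbnskit.qc import extract_inserts_from_file, mean_quality

from .conftest import random_inserts
from .oracles import naive_adapter_cut


def _record(seq, quals=None, rid="r1"):
    if quals is None:
        quals = [35] * len(seq)
    return rk.ReadRecord(id=rid, sequence=seq, qualities=np.array(quals))


def _random_records(rng, n, length=60):
    recs = []
    for i, seq in enumerate(random_inserts(rng, n, length)):
        recs.append(rk.ReadRecord(id=f"r{i}", sequence=seq,
                                  qualities=rng.integers(2, 41, length)))
    return recs


class TestFastqIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        assert list(rk.read_fastq(p)) == []

    def test_two_record_fixture_preserves_ids(self, tmp_path):
        p = tmp_path / "two.fastq"
        p.write_text("@a\nACGT\n+\nIIII\n@b\nTTTT\n+\n!!!!\n")
        recs = list(rk.read_fastq(p))
        assert [r.id for r in recs] == ["a", "b"]
        assert list(recs[1].qualities) == [0, 0, 0, 0]

    @pytest.mark.parametrize("suffix", [".fastq", ".fastq.gz"])
    def test_roundtrip_100_records(self, tmp_path, suffix):
        rng = np.random.default_rng(0)
        recs = _random_records(rng, 100)
        p = tmp_path / f"rt{suffix}"
        assert rk.write_fastq(recs, p) == 100
        assert list(rk.read_fastq(p)) == recs

    def test_truncated_record_names_index(self, tmp_path):
        p = tmp_path / "trunc.fastq"
        p.write_text("@a\nACGT\n+\nIIII\n@b\nTTTT\n+\n")
        with pytest.raises(FastqParseError, match="record 1"):
            list(rk.read_fastq(p))

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "mismatch.fastq"
        p.write_text("@a\nACGTA\n+\nIII\n")
        with pytest.raises(FastqParseError):
            list(rk.read_fastq(p))


ADAPTER = "CTGTCTCTTATACACATCT"


class TestTrimAdapter:
    def test_exact_full_adapter_at_end_removed(self):
        read = _record("ACGTACGTACGT" + ADAPTER)
        out = rk.trim_adapter(read, ADAPTER)
        assert out.sequence == "ACGTACGTACGT"
        assert len(out.qualities) == 12

    def test_read_without_adapter_unchanged(self):
        read = _record("ACGAACGGACGCACGATTTGGATTGA")
        assert rk.trim_adapter(read, ADAPTER).sequence == read.sequence

    def test_error_rate_boundary_two_vs_three_mismatches(self):
        adapter = "AGATCGGAAG"  # length 10 -> floor(0.2*10) = 2 errors allowed
        read2 = _record("GTCCGTAT" + "AGATCGCAAC" + "GGTTGGTTGG")
        assert rk.trim_adapter(read2, adapter, 0.2).sequence == "GTCCGTAT"
        read3 = _record("GTCCGTAT" + "ACATCGCAAC" + "GGTTGGTTGG")
        assert rk.trim_adapter(read3, adapter, 0.2).sequence == read3.sequence

    def test_trimming_never_lengthens(self):
        rng = np.random.default_rng(1)
        for r in _random_records(rng, 50, 40):
            assert len(rk.trim_adapter(r, ADAPTER).sequence) <= len(r.sequence)

    def test_against_exhaustive_edit_distance_oracle(self):
        """Trim decisions match a brute-force search over all occurrences."""
        rng = np.random.default_rng(2)
        adapter = "AGATCGGAAG"
        reads = []
        for seq in random_inserts(rng, 30, 36):
            reads.append(seq)  # mostly adapter-free
            reads.append(seq[:16] + adapter + seq[16:26])  # embedded exact
            mutated = adapter[:3] + "T" + adapter[4:9] + "C"
            reads.append(seq[:12] + mutated + seq[12:24])  # 2 substitutions
            reads.append(seq[:30] + adapter[:6])  # 3'-terminal prefix
        allowed = 2  # floor(0.2 * 10)
        for seq in reads:
            got = rk.trim_adapter(_record(seq), adapter, 0.2, 3)
            expect = naive_adapter_cut(seq, adapter, 0.2, 3)
            if expect is None:
                assert got.sequence == seq
            else:
                # alignment-ambiguous starts may shift by up to the error budget
                assert abs(len(got.sequence) - expect) <= allowed


class TestQualityFilter:
    def test_mean_is_arithmetic(self):
        assert mean_quality(_record("AC", [20, 40])) == 30.0

    def test_boundary_mean_30_is_kept(self):
        kept, rep = rk.filter_by_quality([_record("ACGT", [30] * 4)], 30)
        assert len(kept) == 1 and rep.n_quality_failed == 0

    def test_just_below_30_rejected(self):
        kept, rep = rk.filter_by_quality([_record("ACGT", [30, 30, 30, 29])], 30)
        assert kept == [] and rep.n_quality_failed == 1

    def test_zero_length_read_counted_not_raised(self):
        kept, rep = rk.filter_by_quality([_record("", [])], 30)
        assert kept == [] and rep.n_quality_failed == 1

    def test_against_brute_force_mean(self):
        rng = np.random.default_rng(3)
        reads = _random_records(rng, 1000, 30)
        kept, _ = rk.filter_by_quality(reads, 30)
        expected = [r for r in reads
                    if sum(int(q) for q in r.qualities) / len(r.qualities) >= 30]
        assert kept == expected


class TestExtractRandomRegion:
    design = rk.LibraryDesign()

    def test_clean_construct(self):
        read = _record(self.design.construct("A" * 20))
        assert rk.extract_random_region(read, self.design) == "A" * 20

    def test_read_without_flank_is_null(self):
        assert rk.extract_random_region(_record("TTAA" * 18), self.design) is None

    def test_flank_mismatch_boundary(self):
        insert = "ACGT" * 5
        f5 = self.design.five_prime_flank
        two_mm = "TT" + f5[2:] + insert + self.design.three_prime_flank
        assert rk.extract_random_region(_record(two_mm), self.design) == insert
        three_mm = "TTT" + f5[3:] + insert + self.design.three_prime_flank
        assert rk.extract_random_region(_record(three_mm), self.design) is None

    def test_offset_fallback_up_to_5(self):
        insert = "GTCA" * 5
        base = self.design.construct(insert)
        assert rk.extract_random_region(_record("TTTTT" + base), self.design) == insert
        assert rk.extract_random_region(_record("TTTTTT" + base), self.design) is None

    def test_n_in_insert_rejected(self):
        read = _record(self.design.construct("A" * 9 + "N" + "A" * 10))
        assert rk.extract_random_region(read, self.design) is None

    def test_three_prime_anchor_mismatch_rejected(self):
        insert = "ACGT" * 5
        bad3 = self.design.five_prime_flank + insert + "TTTT" + "A" * 10
        assert rk.extract_random_region(_record(bad3), self.design) is None

    def test_insert_never_overlaps_flanks(self):
        """The 5' flank contains GACGTGAC; extraction must not leak it."""
        rng = np.random.default_rng(4)
        for insert in random_inserts(rng, 50):
            read = _record(self.design.construct(insert))
            assert rk.extract_random_region(read, self.design) == insert


class TestPipelineCounters:
    def test_counter_conservation_and_binomial_bounds(self, tmp_path):
        """QC counters recover the simulated defect fractions.

        With 20k reads at read-through 0.3 / low-quality 0.1 the report's
        counters must sit inside 99% binomial bounds of the planted truth.
        """
        spec = rk.RBNSSimSpec(
            n_pulldown=20_000, n_control=10, affinities={},
            frac_adapter_readthrough=0.3, frac_low_quality=0.1, seed=99,
        )
        manifest = rk.simulate_rbns_reads(spec, out_dir=tmp_path)
        inserts, report = extract_inserts_from_file(
            tmp_path / "pulldown.fastq", rk.LibraryDesign())
        report.check()
        n = spec.n_pulldown
        for counter, frac, truth in [
            (report.n_adapter_trimmed, 0.3, manifest["pulldown"]["n_adapter_readthrough"]),
            (report.n_quality_failed, 0.1, manifest["pulldown"]["n_low_quality"]),
        ]:
            half = 2.576 * np.sqrt(n * frac * (1 - frac))
            assert abs(counter - truth) <= half
            assert abs(truth - n * frac) <= 4 * np.sqrt(n * frac * (1 - frac))
        assert all(len(i) == 20 for i in inserts)
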