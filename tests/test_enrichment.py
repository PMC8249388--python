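import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rbnskit.enrichment import (
    KmerCounts,
    KmerFrequencies,
    count_kmers,
    kmer_universe,
    normalize_counts,
    relative_frequencies,
    split_kmers,
    zscore_select,
)
from rbnskit.errors import InvalidInputError

from .conftest import random_inserts
from .oracles import naive_count_kmers


class TestSplitKmers:
    @pytest.mark.parametrize("k,expected", [(4, 17), (5, 16), (6, 15)])
    def test_twenty_mer_window_counts(self, k, expected):
        assert len(split_kmers("ACGT" * 5, k)) == expected

    def test_longer_than_sequence_gives_empty(self):
        assert split_kmers("A" * 20, 21) == []

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            split_kmers("ACGT", 0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40),
           st.integers(min_value=1, max_value=8))
    def test_window_count_and_order(self, seq, k):
        kmers = split_kmers(seq, k)
        assert len(kmers) == max(len(seq) - k + 1, 0)
        assert all(seq[i:i + k] == m for i, m in enumerate(kmers))


class TestCountKmers:
    def test_single_insert(self):
        c = count_kmers(["GACGTG"], 6)
        assert c.counts == {"GACGTG": 1} and c.total == 1

    def test_empty_stream(self):
        c = count_kmers([], 4)
        assert c.counts == {} and c.total == 0 and c.n_inserts == 0

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_matches_nested_loop_oracle(self, k):
        rng = np.random.default_rng(42)
        inserts = random_inserts(rng, 500)
        c = count_kmers(inserts, k)
        assert c.counts == naive_count_kmers(inserts, k)
        assert c.total == sum(c.counts.values())
        assert c.total == len(inserts) * (20 - k + 1)

    def test_ambiguous_bases_contribute_only_clean_windows(self):
        c = count_kmers(["ACGNACG"], 3)
        assert c.counts == naive_count_kmers(["ACGNACG"], 3)
        assert c.total == 2  # ACG at 0 and at 4 only

    def test_short_inserts_contribute_nothing(self):
        assert count_kmers(["ACG", "ACGTACG"], 6).total == 2


class TestNormalize:
    def test_uniform_counts_pseudocount_zero(self):
        c = KmerCounts(k=6, counts={m: 2 for m in kmer_universe(6)},
                       total=2 * 4096, n_inserts=1)
        f = normalize_counts(c, pseudocount=0.0)
        assert all(abs(v - 1 / 4096) < 1e-15 for v in f.freqs.values())

    def test_single_kmer_pseudocount_zero(self):
        c = KmerCounts(k=4, counts={"AAAA": 3}, total=3, n_inserts=1)
        f = normalize_counts(c, pseudocount=0.0)
        assert f.freqs["AAAA"] == 1.0

    def test_toy_closed_form_with_pseudocount(self):
        # 3 observed dimers + pseudocount 1: freq = (count+1)/(total+16)
        c = KmerCounts(k=2, counts={"AA": 5, "AC": 3, "GT": 2}, total=10,
                       n_inserts=1)
        f = normalize_counts(c, pseudocount=1.0)
        assert f.freqs["AA"] == pytest.approx(6 / 26)
        assert f.freqs["TT"] == pytest.approx(1 / 26)
        assert sum(f.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_conservation_on_random_inserts(self):
        rng = np.random.default_rng(7)
        inserts = random_inserts(rng, 200)
        for k in (4, 5, 6):
            f = normalize_counts(count_kmers(inserts, k), pseudocount=1.0)
            assert sum(f.freqs.values()) == pytest.approx(1.0, abs=1e-9)
            assert min(f.freqs.values()) > 0

    def test_zero_total_zero_pseudocount_rejected(self):
        c = KmerCounts(k=4, counts={}, total=0, n_inserts=0)
        with pytest.raises(InvalidInputError):
            normalize_counts(c, pseudocount=0.0)


def _freqs(k, mapping):
    return KmerFrequencies(k=k, freqs=mapping, pseudocount_used=1.0)


class TestRelativeFrequencies:
    def test_identical_tables_give_unit_ratios(self):
        rng = np.random.default_rng(3)
        f = normalize_counts(count_kmers(random_inserts(rng, 50), 4), 1.0)
        assert all(r == pytest.approx(1.0) for r in
                   relative_frequencies(f, f).values())

    def test_hand_arithmetic(self):
        p = _freqs(1, {"A": 0.375, "C": 0.125, "G": 0.375, "T": 0.125})
        c = _freqs(1, {"A": 0.125, "C": 0.375, "G": 0.125, "T": 0.375})
        r = relative_frequencies(p, c)
        assert r["A"] == pytest.approx(3.0)
        assert r["C"] == pytest.approx(1 / 3)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_frequencies(_freqs(1, {}), _freqs(2, {}))

    def test_zero_denominator_advises_pseudocount(self):
        p = _freqs(1, {m: 0.25 for m in "ACGT"})
        c = _freqs(1, {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})
        with pytest.raises(InvalidInputError, match="pseudocount"):
            relative_frequencies(p, c)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(11)
        fp = normalize_counts(count_kmers(random_inserts(rng, 100), 4), 1.0)
        fc = normalize_counts(count_kmers(random_inserts(rng, 100), 4), 1.0)
        fwd = relative_frequencies(fp, fc)
        rev = relative_frequencies(fc, fp)
        for m in fwd:
            assert fwd[m] == pytest.approx(1.0 / rev[m], rel=1e-12)


class TestZScoreSelect:
    def test_all_equal_ratios(self):
        ratios = {m: 2.0 for m in kmer_universe(2)}
        with pytest.warns(UserWarning):
            table = zscore_select(ratios)
        assert (table.table["zscore"] == 0).all()
        assert table.selected == []

    def test_hand_mean_sd(self):
        ratios = dict(zip(["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT", "ACGTAC"],
                          [1.0, 1.0, 1.0, 1.0, 6.0]))
        table = zscore_select(ratios, threshold=3.0)
        z_top = table.table.set_index("kmer").loc["ACGTAC", "zscore"]
        assert z_top == pytest.approx(4 / math.sqrt(5))
        assert table.selected == []  # 1.789 < 3

    def test_rank_is_dense_with_lexicographic_ties(self):
        ratios = {"AA": 2.0, "AC": 2.0, "AG": 1.0, "AT": 3.0}
        t = zscore_select(ratios).table.set_index("kmer")
        assert list(t.sort_values("rank").index) == ["AT", "AA", "AC", "AG"]
        assert sorted(t["rank"]) == [1, 2, 3, 4]

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            zscore_select({"AAAA": 1.0})

    def test_oracle_equivalence_end_to_end(self):
        """Counts exact, ratios and Z to 1e-12 against a naive recompute."""
        rng = np.random.default_rng(5)
        pd_ins = random_inserts(rng, 400)
        ct_ins = random_inserts(rng, 400)
        k, pseudo = 4, 1.0
        table = zscore_select(relative_frequencies(
            normalize_counts(count_kmers(pd_ins, k), pseudo),
            normalize_counts(count_kmers(ct_ins, k), pseudo)))
        # naive recompute
        cp = naive_count_kmers(pd_ins, k)
        cc = naive_count_kmers(ct_ins, k)
        uni = kmer_universe(k)
        dp = sum(cp.values()) + pseudo * len(uni)
        dc = sum(cc.values()) + pseudo * len(uni)
        ratios = {m: ((cp.get(m, 0) + pseudo) / dp) / ((cc.get(m, 0) + pseudo) / dc)
                  for m in uni}
        vals = list(ratios.values())
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        got = table.table.set_index("kmer")
        for m in uni:
            assert got.loc[m, "rel_freq"] == pytest.approx(ratios[m], abs=1e-12)
            assert got.loc[m, "zscore"] == pytest.approx(
                (ratios[m] - mean) / sd, abs=1e-12)
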