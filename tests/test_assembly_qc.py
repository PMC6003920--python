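"""Contig QC: k-mer mathematics, filtering, clustering, merging, stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locustde.assembly_qc import (
    ContigRecord,
    assembly_stats,
    filter_contigs,
    find_overlap,
    greedy_cluster,
    kmer_collision_probability,
    kmer_sweep,
    min_safe_kmer,
    n50,
    overlap_merge,
    pairwise_identity,
    read_contig_fasta,
    write_contig_fasta,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestKmerMath:
    def test_single_window_probability_at_19(self):
        # the printed 3.638e-12 for a 19-base word among equiprobable bases
        assert kmer_collision_probability(19) == pytest.approx(3.638e-12, rel=1e-3)

    def test_reoccurrence_among_8e9_windows_below_6_percent(self):
        assert kmer_collision_probability(19, 8.2e9) < 0.06

    @pytest.mark.parametrize(
        "k,n_windows,expected",
        [(1, 1, 0.25), (2, None, 1 / 16), (3, 0, 0.0)],
    )
    def test_small_cases(self, k, n_windows, expected):
        with pytest.warns() if k % 2 == 0 else _nullcontext():
            assert kmer_collision_probability(k, n_windows) == pytest.approx(expected)

    def test_even_k_warns_but_computes(self):
        with pytest.warns(UserWarning):
            assert kmer_collision_probability(4) == pytest.approx(4.0**-4)

    def test_monotone_in_k_and_windows(self):
        probs = [kmer_collision_probability(k, 1e9) for k in range(11, 31, 2)]
        assert all(a > b for a, b in zip(probs, probs[1:]))
        grows = [kmer_collision_probability(19, n) for n in (1e6, 1e9, 1e12)]
        assert grows == sorted(grows)

    def test_min_safe_kmer_recovers_19(self):
        # k=17 gives ~0.38 > 6%, k=19 gives ~0.029 <= 6%
        assert kmer_collision_probability(17, 8.2e9) > 0.06
        assert min_safe_kmer(8.2e9, 0.06) == 19

    def test_min_safe_kmer_trivial_thresholds(self):
        assert min_safe_kmer(1e9, 1.0) == 1
        assert min_safe_kmer(0, 0.5) == 1

    def test_min_safe_kmer_unreachable(self):
        with pytest.raises(ValueError):
            min_safe_kmer(1e30, 1e-30, k_max=5)

    def test_sweep_101_base_reads_has_39_kmers(self):
        sweep = kmer_sweep(101, 19)
        assert len(sweep) == 39
        assert sweep[0] == 95 and sweep[-1] == 19
        assert all(k % 2 == 1 for k in sweep)

    @pytest.mark.parametrize(
        "read_length,k_min,expected",
        [(101, 95, [95]), (20, 19, [19])],
    )
    def test_sweep_edges(self, read_length, k_min, expected):
        assert kmer_sweep(read_length, k_min) == expected


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


class TestFilterContigs:
    @pytest.mark.parametrize(
        "length,reads,positive,kept_expected,reason",
        [
            (80, 2, True, True, None),  # rescued by a homology hit
            (74, 100, True, False, "short"),  # length rule is unconditional
            (80, 4, False, True, None),  # meets the support threshold
            (80, 3, False, False, "low_support"),
        ],
    )
    def test_rules(self, rng, length, reads, positive, kept_expected, reason):
        contig = ContigRecord("c", _random_seq(rng, length), reads)
        kept, removed = filter_contigs([contig], {"c"} if positive else set())
        assert bool(kept) is kept_expected
        if reason:
            assert removed[0][1] == reason

    def test_partition_and_idempotence(self, small_transcriptome):
        _, contigs, truth = small_transcriptome
        positive = set(truth.loc[~truth.is_artifact, "transcript_id"][:50])
        kept, removed = filter_contigs(contigs, positive)
        assert len(kept) + len(removed) == len(contigs)
        assert {c.id for c in kept} | {c.id for c, _ in removed} == {
            c.id for c in contigs
        }
        kept2, removed2 = filter_contigs(kept, positive)
        assert kept2 == kept and removed2 == []

    def test_duplicate_ids_error(self, rng):
        c = ContigRecord("dup", _random_seq(rng, 100), 5)
        with pytest.raises(ValueError, match="duplicate"):
            filter_contigs([c, c])


class TestClustering:
    def test_identical_sequences_one_cluster(self, rng):
        s = _random_seq(rng, 120)
        result = greedy_cluster(
            [ContigRecord("a", s, 4), ContigRecord("b", s, 4)]
        )
        assert result == {"a": "a", "b": "a"}

    def test_six_substitutions_in_100_split(self, rng):
        s = _random_seq(rng, 100)
        mut = list(s)
        for i in (3, 20, 35, 50, 70, 90):
            mut[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[i]]
        assert pairwise_identity(s, "".join(mut)) == pytest.approx(0.94)
        result = greedy_cluster(
            [ContigRecord("a", s, 4), ContigRecord("b", "".join(mut), 4)]
        )
        assert len(set(result.values())) == 2

    def test_idempotent_representatives(self, small_transcriptome):
        _, contigs, _ = small_transcriptome
        result = greedy_cluster(contigs[:60])
        for member, rep in result.items():
            assert result[rep] == rep
        assert len(set(result.values())) <= len(result)


class TestOverlapMerge:
    def test_short_overlap_not_merged(self):
        a = "ACGTACGTACGTACGTAAAA"
        b = "ACGTAAAACCCCCCCCCCCC"
        merged = overlap_merge(
            [ContigRecord("a", a, 1), ContigRecord("b", b, 1)], min_overlap=16
        )
        assert len(merged) == 2

    def test_exact_20_base_overlap_merges(self, rng):
        s1 = _random_seq(rng, 40)
        s2 = s1[-20:] + _random_seq(rng, 20)
        merged = overlap_merge(
            [ContigRecord("p", s1, 3), ContigRecord("q", s2, 5)]
        )
        assert len(merged) == 1
        assert merged[0].length == 40 + 40 - 20
        assert merged[0].sequence == s1 + s2[20:]
        assert merged[0].read_support == 8

    def test_long_overlap_found_via_anchor(self, rng):
        s1 = _random_seq(rng, 200)
        s2 = s1[-80:] + _random_seq(rng, 150)
        assert find_overlap(s1, s2, 16, 0.95) == 80

    def test_disjoint_unchanged_and_support_conserved(self, rng):
        contigs = [
            ContigRecord(f"c{i}", _random_seq(rng, 150), i + 1) for i in range(5)
        ]
        merged = overlap_merge(contigs)
        assert sorted(c.id for c in merged) == sorted(c.id for c in contigs)
        assert sum(c.read_support for c in merged) == sum(
            c.read_support for c in contigs
        )


class TestStats:
    def test_n50_by_example(self):
        # total 15; descending cumulative 5, 9 >= 7.5 at length 4
        assert n50([5, 4, 3, 2, 1]) == 4
        assert n50([7]) == 7

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60))
    def test_n50_matches_threshold_oracle(self, lengths):
        # oracle: largest L among contig lengths with sum(x >= L) >= half
        total = sum(lengths)
        candidates = [
            L for L in sorted(set(lengths), reverse=True)
            if sum(x for x in lengths if x >= L) >= total / 2
        ]
        assert n50(lengths) == max(candidates)

    def test_gc_extremes_and_fields(self):
        contigs = [ContigRecord("g", "G" * 100, 4), ContigRecord("a", "A" * 50, 4)]
        stats = assembly_stats(contigs)
        assert stats.gc == pytest.approx(100 / 150)
        assert (stats.min_len, stats.max_len, stats.total_bases) == (50, 100, 150)
        assert assembly_stats([ContigRecord("x", "GCGC", 1)]).gc == 1.0


def test_fasta_roundtrip_preserves_read_support(tmp_path, small_transcriptome):
    _, contigs, _ = small_transcriptome
    path = tmp_path / "contigs.fasta"
    write_contig_fasta(contigs, path)
    back = read_contig_fasta(path)
    assert back == list(contigs)
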