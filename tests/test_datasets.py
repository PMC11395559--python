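"""Task dataset builders: sub-sequence sampling, mask geometry, next-k-mer
leakage freedom, and Prom300 composition preservation."""

from collections import Counter

import numpy as np
import pytest

from dnalm_probe import (
    GenomeSequence,
    SubsequenceSamplingScheme,
    SyntheticGenomeSpec,
    build_masked_dataset,
    build_next_kmer_dataset,
    build_prom300_dataset,
    build_vocabulary,
    extract_promoter_windows,
    generate_genome,
    make_mask_pattern,
    sample_subsequences,
)
from dnalm_probe.datasets import (
    fully_masked_positions,
    read_masked_jsonl,
    read_next_kmer_tsv,
    read_prom300_tsv,
    read_tss_bed,
    reverse_complement,
    write_masked_jsonl,
    write_next_kmer_tsv,
    write_prom300_tsv,
)
from dnalm_probe.tokenization import DataError, ParameterError


# ---------------------------------------------------------------------------
# sub-sequence sampling
# ---------------------------------------------------------------------------


class TestSubsequenceSampling:
    def test_full_length_fraction_matches_scheme(self):
        genome = generate_genome(SyntheticGenomeSpec(mode="iid", length=4_200_000, seed=0))
        scheme = SubsequenceSamplingScheme(seed=42)  # defaults: 0.5 / 510 / 20
        pieces = sample_subsequences([genome], scheme, k=4, count=10_000)
        token_lens = np.array([len(p) - 3 for p in pieces])
        full_frac = (token_lens == 510).mean()
        # 3 sigma binomial band around 0.5 at n=10,000
        assert abs(full_frac - 0.5) < 0.015
        assert token_lens.min() >= 20 and token_lens.max() <= 510

    def test_determinism_under_seed(self):
        genome = generate_genome(SyntheticGenomeSpec(mode="iid", length=500_000, seed=1))
        scheme = SubsequenceSamplingScheme(seed=7)
        a = sample_subsequences([genome], scheme, k=4, count=100)
        b = sample_subsequences([genome], scheme, k=4, count=100)
        assert a == b

    def test_errors(self):
        with pytest.raises(DataError):
            sample_subsequences([], SubsequenceSamplingScheme(), k=4)
        genome = GenomeSequence("tiny", "ACGT" * 10)
        with pytest.raises(DataError):
            sample_subsequences(
                [genome], SubsequenceSamplingScheme(min_len=100, full_len=510), k=4
            )


# ---------------------------------------------------------------------------
# mask geometry
# ---------------------------------------------------------------------------


class TestMaskPattern:
    @pytest.mark.parametrize(
        "k,offsets,central",
        [(4, (-1, 0, 1, 2), 2), (5, (-2, -1, 0, 1, 2), 2), (6, (-2, -1, 0, 1, 2, 3), 3)],
    )
    def test_canonical_patterns(self, k, offsets, central):
        pattern = make_mask_pattern(k)
        assert pattern.offsets == offsets
        assert pattern.span_nt == 2 * k - 1
        fully = fully_masked_positions(pattern)
        assert fully == [central]

    @pytest.mark.parametrize("k", [2, 3, 7, 8])
    def test_generalized_patterns_keep_invariants(self, k):
        pattern = make_mask_pattern(k)
        assert len(pattern.offsets) == k and 0 in pattern.offsets
        assert pattern.offsets == tuple(range(min(pattern.offsets), min(pattern.offsets) + k))
        assert len(fully_masked_positions(pattern)) == 1

    def test_rejects_bad_k(self):
        with pytest.raises(ParameterError):
            make_mask_pattern(0)


class TestMaskedDataset:
    def test_masked_positions_follow_pattern(self, vocab4):
        rng = np.random.default_rng(0)
        subs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 33)]) for _ in range(50)]
        samples = build_masked_dataset(subs, vocab4, seed=1)
        for s in samples:
            t = s.chosen_index
            assert s.masked_positions == (t - 1, t, t + 1, t + 2)
            assert all(s.ids[p] == vocab4.mask_id for p in s.masked_positions)
            # at least one unmasked flank on each side
            assert s.masked_positions[0] >= 1
            assert s.masked_positions[-1] <= len(s.ids) - 2

    def test_unique_fully_masked_nucleotide_per_sample(self, vocab4):
        """Coverage oracle on real samples: exactly one nucleotide is covered
        only by masked tokens."""
        rng = np.random.default_rng(1)
        subs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)]) for _ in range(30)]
        for s in build_masked_dataset(subs, vocab4, seed=2):
            masked = set(s.masked_positions)
            n_nt = len(s.ids) + 3  # source length
            fully = [
                p
                for p in range(n_nt)
                if all(
                    tok in masked
                    for tok in range(max(0, p - 3), min(len(s.ids) - 1, p) + 1)
                )
            ]
            assert len(fully) == 1

    def test_short_subsequences_skipped_and_determinism(self, vocab4):
        subs = ["ACGTACG", "ACGT" * 10]  # 4 tokens (too short), 37 tokens
        samples = build_masked_dataset(subs, vocab4, seed=3)
        assert len(samples) == 1
        a = build_masked_dataset(["ACGT" * 10] * 100, vocab4, seed=9)
        b = build_masked_dataset(["ACGT" * 10] * 100, vocab4, seed=9)
        assert [s.chosen_index for s in a] == [s.chosen_index for s in b]

    def test_jsonl_roundtrip(self, tmp_path, vocab4):
        samples = build_masked_dataset(["ACGTACGTACGTACGTACGT"] * 5, vocab4, seed=0)
        path = tmp_path / "masked.jsonl"
        write_masked_jsonl(path, samples)
        assert read_masked_jsonl(path) == samples


# ---------------------------------------------------------------------------
# next-k-mer
# ---------------------------------------------------------------------------


class TestNextKmerDataset:
    def test_chunking_and_sample_geometry(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1530)])
        ds = build_next_kmer_dataset([GenomeSequence("c", seq)], k=4, seed=0)
        assert len(ds.samples) == 3  # 1530 / 510
        chunks = {seq[i * 510 : i * 510 + 510] for i in range(3)}
        for s in ds.samples:
            assert len(s.context) == 50 and len(s.label) == 4
            src = next(c for c in chunks if c.startswith(s.context))
            assert src[50:54] == s.label  # label follows context with no overlap

    def test_split_ratio_and_disjointness(self, iid_genome):
        ds = build_next_kmer_dataset([iid_genome], k=4, max_samples=1001, seed=3)
        assert len(ds.samples) == 1001
        assert set(ds.train_idx).isdisjoint(ds.test_idx)
        assert abs(len(ds.train_idx) - 0.8 * 1001) <= 1

    def test_label_class_range(self, periodic_genome):
        ds = build_next_kmer_dataset([periodic_genome], k=6, max_samples=500, seed=0)
        assert all(0 <= s.label_class < 4096 for s in ds.samples)

    @pytest.mark.parametrize("bad_k", [1, 7])
    def test_k_out_of_range(self, bad_k, iid_genome):
        with pytest.raises(ParameterError):
            build_next_kmer_dataset([iid_genome], k=bad_k)

    def test_too_short_input(self):
        with pytest.raises(DataError):
            build_next_kmer_dataset([GenomeSequence("s", "ACGT" * 100)], k=4)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5100)])
        ds = build_next_kmer_dataset([GenomeSequence("c", seq)], k=3, seed=1)
        path = tmp_path / "nk.tsv"
        write_next_kmer_tsv(path, ds)
        back = read_next_kmer_tsv(path)
        assert back.k == 3 and back.samples == ds.samples
        assert back.train_idx == ds.train_idx


# ---------------------------------------------------------------------------
# promoter windows + Prom300
# ---------------------------------------------------------------------------


class TestPromoterWindows:
    def test_plus_strand_coordinates(self):
        rng = np.random.default_rng(8)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        genome = [GenomeSequence("chr1", seq)]
        windows = extract_promoter_windows(genome, [("chr1", 1000, "+")])
        assert windows == [seq[751:1051]]
        assert len(windows[0]) == 300

    def test_minus_strand_is_mirrored_revcomp(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        genome = [GenomeSequence("chr1", seq)]
        (w_minus,) = extract_promoter_windows(genome, [("chr1", 1000, "-")])
        assert w_minus == reverse_complement(seq[950:1250])
        # TSS base at transcript offset 0 (position 249 of the window) matches
        assert w_minus[249] == reverse_complement(seq[1000])

    def test_edge_tss_skipped(self):
        genome = [GenomeSequence("chr1", "ACGT" * 75)]  # 300 nt
        assert extract_promoter_windows(genome, [("chr1", 100, "+")]) == []
        assert extract_promoter_windows(genome, [("chrUn", 100, "+")]) == []

    def test_read_tss_bed(self, tmp_path):
        bed = tmp_path / "tss.bed"
        bed.write_text("chr1\t1000\t1001\ttss_0\t0\t-\nchr2\t500\t501\n")
        assert read_tss_bed(bed) == [("chr1", 1000, "-"), ("chr2", 500, "+")]


class TestProm300:
    def test_counts_and_composition_preserved(self):
        rng = np.random.default_rng(11)
        promoters = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]) for _ in range(50)
        ]
        records = build_prom300_dataset(promoters, seed=4)
        assert len(records) == 100
        for real, shuf in zip(records[::2], records[1::2]):
            assert real.label == "real" and shuf.label == "shuffled"
            assert len(shuf.shuffled_parts) == 15
            assert Counter(real.seq) == Counter(shuf.seq)
            for i in range(20):
                part_r = real.seq[i * 15 : (i + 1) * 15]
                part_s = shuf.seq[i * 15 : (i + 1) * 15]
                assert Counter(part_r) == Counter(part_s)
                if i not in shuf.shuffled_parts:
                    assert part_r == part_s

    def test_degenerate_homopolymer_still_labeled_shuffled(self):
        records = build_prom300_dataset(["A" * 300], seed=0)
        assert records[1].seq == "A" * 300 and records[1].label == "shuffled"

    def test_parts_mode_permutes_whole_parts(self):
        rng = np.random.default_rng(12)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        (real, shuf) = build_prom300_dataset([seq], seed=1, shuffle_mode="parts")
        parts_r = {real.seq[i * 15 : (i + 1) * 15] for i in range(20)}
        parts_s = {shuf.seq[i * 15 : (i + 1) * 15] for i in range(20)}
        assert parts_r == parts_s and real.seq != shuf.seq

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            build_prom300_dataset(["A" * 300], n_parts=7)
        with pytest.raises(ParameterError):
            build_prom300_dataset(["A" * 299])
        with pytest.raises(ParameterError):
            build_prom300_dataset(["A" * 300], n_shuffle=25)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        promoters = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]) for _ in range(3)
        ]
        records = build_prom300_dataset(promoters, seed=2)
        path = tmp_path / "prom.tsv"
        write_prom300_tsv(path, records)
        assert read_prom300_tsv(path) == records
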