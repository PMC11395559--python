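"""Evaluation readouts against brute-force oracles."""

import numpy as np
import pytest

from dnalm_probe import (
    UniformStubModel,
    build_masked_dataset,
    build_next_kmer_dataset,
    build_vocabulary,
    classification_metrics,
    masked_accuracy_by_offset,
    next_kmer_accuracy,
    random_baseline,
    rank_probability_profile,
    tokenize,
)
from dnalm_probe.datasets import MaskedSample, NextKmerDataset, NextKmerSample
from dnalm_probe.evaluation import best_f1_threshold
from dnalm_probe.tokenization import DataError, ParameterError, kmer_index


def _metrics_oracle(y_pred, y_true):
    """Independent confusion-matrix computation from first principles."""
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return acc, prec, rec, f1, mcc


def _sample_with_offsets(k=4, n_nt=33, chosen=10, seed=0):
    """A masked sample built from a real random sequence, so token overlaps
    are mutually consistent."""
    rng = np.random.default_rng(seed)
    vocab = build_vocabulary(k)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_nt)])
    toks = list(tokenize(seq, vocab).ids)
    offsets = (-1, 0, 1, 2)
    positions = tuple(chosen + o for o in offsets)
    truth = tuple(int(toks[p]) for p in positions)
    for p in positions:
        toks[p] = vocab.mask_id
    return MaskedSample(k=k, ids=tuple(int(i) for i in toks), chosen_index=chosen,
                        masked_positions=positions, truth=truth), vocab


class TestMaskedAccuracyByOffset:
    def test_perfect_oracle_is_one_everywhere(self, vocab4):
        pairs = []
        for seed in range(5):
            s, _ = _sample_with_offsets(seed=seed)
            probs = np.zeros((4, vocab4.size))
            probs[np.arange(4), list(s.truth)] = 1.0
            pairs.append((probs, s))
        profile = masked_accuracy_by_offset(pairs)
        assert profile.per_offset == {-1: 1.0, 0: 1.0, 1: 1.0, 2: 1.0}
        assert profile.overall == 1.0 and profile.mean_over_samples == 1.0

    def test_uniform_stub_accuracy_near_prior(self, vocab4):
        """A uniform predictor resolves argmax ties to token id 0, so its
        accuracy is the empirical frequency of truth id 0 (~1/256)."""
        rng = np.random.default_rng(1)
        stub = UniformStubModel(k=4)
        pairs = []
        for seed in range(2000):
            s, _ = _sample_with_offsets(seed=seed)
            pairs.append((stub.predict_masked(s), s))
        profile = masked_accuracy_by_offset(pairs)
        p = 1 / 256
        sigma = np.sqrt(p * (1 - p) / 2000)
        for acc in profile.per_offset.values():
            assert abs(acc - p) < 3.5 * sigma

    def test_hand_built_fixture_fractions(self, vocab4):
        """3 samples with hand-placed argmaxes: offset accuracies equal the
        hand-computed fractions."""
        pairs = []
        hits_plan = [(True, False, True, False), (True, True, False, False),
                     (False, False, False, True)]
        for seed, plan in enumerate(hits_plan):
            s, _ = _sample_with_offsets(seed=seed + 10)
            probs = np.zeros((4, vocab4.size))
            for row, hit in enumerate(plan):
                target = s.truth[row] if hit else (s.truth[row] + 1) % 256
                probs[row, target] = 1.0
            pairs.append((probs, s))
        profile = masked_accuracy_by_offset(pairs)
        assert profile.per_offset == {-1: 2 / 3, 0: 1 / 3, 1: 1 / 3, 2: 1 / 3}
        assert profile.overall == pytest.approx(5 / 12)
        # conservation: overall equals count-weighted mean of per-offset values
        weighted = sum(profile.per_offset[o] * profile.counts[o] for o in profile.counts)
        assert profile.overall == pytest.approx(weighted / sum(profile.counts.values()))

    def test_mixed_k_rejected(self, vocab4):
        s4, _ = _sample_with_offsets()
        s5 = MaskedSample(k=5, ids=s4.ids, chosen_index=5,
                          masked_positions=(3, 4, 5, 6, 7), truth=(0, 0, 0, 0, 0))
        with pytest.raises(ParameterError):
            masked_accuracy_by_offset([(np.ones((4, 261)), s4), (np.ones((5, 261)), s5)])


class TestRankProfile:
    def test_uniform_stub_floor_arithmetic(self, vocab4):
        s, _ = _sample_with_offsets()
        probs = UniformStubModel(k=4).predict_masked(s)
        # floor below 1/261: every token counts; floor above: none
        low = rank_probability_profile(probs, s, vocab4, floor=1e-4)
        high = rank_probability_profile(probs, s, vocab4, floor=0.01)
        assert all(p.n_above_floor == vocab4.size for p in low.positions)
        assert all(p.n_above_floor == 0 for p in high.positions)

    def test_flank_consistent_mass_counts_four(self, vocab4):
        """Probability mass placed only on the 4 tokens consistent with the
        unmasked flanks gives exactly 4 tokens above the floor; the
        consistent set is built by brute-force overlap enumeration."""
        s, vocab = _sample_with_offsets(seed=3)
        from dnalm_probe.tokenization import detokenize, kmer_from_index, TokenSequence

        # reconstruct the true source sequence from the truth tokens
        ids = list(s.ids)
        for p, t in zip(s.masked_positions, s.truth):
            ids[p] = t
        seq = detokenize(TokenSequence(k=4, ids=tuple(ids), source_length=len(ids) + 3))
        central_nt = s.chosen_index + 2  # fully-masked nucleotide for the 4-mer pattern
        probs = np.zeros((4, vocab.size))
        for row, pos in enumerate(s.masked_positions):
            consistent = []
            for base in "ACGT":
                variant = seq[:central_nt] + base + seq[central_nt + 1 :]
                consistent.append(kmer_index(variant[pos : pos + 4]))
            consistent = sorted(set(consistent))
            assert len(consistent) == 4  # one candidate per central base
            probs[row, consistent] = 1.0 / len(consistent)
        profile = rank_probability_profile(probs, s, vocab, floor=0.01)
        for p in profile.positions:
            assert p.n_above_floor == 4

    def test_truth_at_rank_one(self, vocab4):
        s, _ = _sample_with_offsets(seed=4)
        probs = np.full((4, vocab4.size), 1e-6)
        probs[np.arange(4), list(s.truth)] = 1.0
        probs /= probs.sum(axis=1, keepdims=True)
        profile = rank_probability_profile(probs, s, vocab4)
        assert all(p.is_top1 and p.truth_rank == 1 for p in profile.positions)
        for p in profile.positions:
            assert (np.diff(p.probabilities) <= 0).all()
            assert p.ranks[0] == 1 and len(set(p.ranks)) == vocab4.size

    def test_shape_mismatch_rejected(self, vocab4):
        s, _ = _sample_with_offsets()
        with pytest.raises(ParameterError):
            rank_probability_profile(np.ones((3, vocab4.size)), s, vocab4)


class _FixedClassifier:
    def __init__(self, outputs, n_classes=256):
        self.outputs = outputs
        self.n_classes = n_classes

    def predict(self, X):
        return np.asarray(self.outputs[: len(X)])


class TestNextKmerAccuracy:
    @staticmethod
    def _dataset(labels, k=4):
        samples = tuple(
            NextKmerSample(context="A" * 50, label=lab, label_class=kmer_index(lab))
            for lab in labels
        )
        n = len(samples)
        return NextKmerDataset(k=k, samples=samples,
                               train_idx=tuple(range(n - n // 5)),
                               test_idx=tuple(range(n - n // 5, n)))

    def test_always_correct_oracle(self):
        ds = self._dataset(["ACGT"] * 10)
        clf = _FixedClassifier([kmer_index("ACGT")] * 10)
        assert next_kmer_accuracy(clf, ds) == 1.0

    def test_majority_class_on_skewed_fixture(self):
        labels = ["AAAA"] * 6 + ["ACGT"] * 3 + ["TTTT"]
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(labels))
        ds = self._dataset(shuffled)
        clf = _FixedClassifier([kmer_index("AAAA")] * len(shuffled))
        test_labels = [ds.samples[i].label for i in ds.test_idx]
        expected = test_labels.count("AAAA") / len(test_labels)
        assert next_kmer_accuracy(clf, ds) == pytest.approx(expected)

    def test_uniform_classifier_converges_to_baseline(self):
        """A uniform random guesser lands inside the 3-sigma binomial
        envelope of 4**-k at growing n."""
        rng = np.random.default_rng(2)
        p = random_baseline(4)
        for n in (1000, 10_000, 100_000):
            guesses = rng.integers(0, 256, n)
            truths = rng.integers(0, 256, n)
            acc = (guesses == truths).mean()
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(acc - p) < 3.5 * sigma

    def test_head_size_mismatch_and_empty_test(self):
        ds = self._dataset(["ACGT"] * 10)
        with pytest.raises(ParameterError):
            next_kmer_accuracy(_FixedClassifier([0], n_classes=16), ds)
        empty = NextKmerDataset(k=4, samples=ds.samples, train_idx=tuple(range(10)),
                                test_idx=())
        with pytest.raises(DataError):
            next_kmer_accuracy(_FixedClassifier([0]), empty)


class TestRandomBaseline:
    @pytest.mark.parametrize("k,expected", [(2, 0.0625), (4, 1 / 256), (6, 1 / 4096)])
    def test_values(self, k, expected):
        assert random_baseline(k) == expected

    def test_k4_prints_as_0004(self):
        assert round(random_baseline(4), 3) == 0.004

    def test_invalid_k(self):
        with pytest.raises(ParameterError):
            random_baseline(0)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = classification_metrics(y, y)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.mcc) == (1, 1, 1, 1, 1)

    def test_known_confusion_matrix(self):
        """TP=40 TN=45 FP=5 FN=10, checked against the hand oracle."""
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array([1] * 40 + [0] * 10 + [1] * 5 + [0] * 45)
        rep = classification_metrics(y_pred, y_true)
        acc, prec, rec, f1, mcc = _metrics_oracle(y_pred, y_true)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.precision == pytest.approx(prec)
        assert rep.recall == pytest.approx(rec)
        assert rep.f1 == pytest.approx(f1)
        assert rep.mcc == pytest.approx(mcc)

    def test_oracle_agreement_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            y_pred = rng.integers(0, 2, n)
            y_true = rng.integers(0, 2, n)
            rep = classification_metrics(y_pred, y_true)
            acc, prec, rec, f1, mcc = _metrics_oracle(y_pred, y_true)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.precision == pytest.approx(prec, abs=1e-12)
            assert rep.recall == pytest.approx(rec, abs=1e-12)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.mcc == pytest.approx(mcc, abs=1e-12)
            if rep.precision and rep.recall:
                harmonic = 2 / (1 / rep.precision + 1 / rep.recall)
                assert rep.f1 == pytest.approx(harmonic)

    def test_permutation_null_mcc_near_zero(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 2, 10_000)
        y_pred = rng.permutation(y_true)
        assert abs(classification_metrics(y_pred, y_true).mcc) < 0.05

    def test_errors(self):
        with pytest.raises(ParameterError):
            classification_metrics([0, 1], [0])
        with pytest.raises(ParameterError):
            classification_metrics([0, 2], [0, 1])

    def test_best_f1_threshold_diagnostic(self):
        y_true = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.4, 0.45, 0.9])
        threshold, rep = best_f1_threshold(p, y_true)
        assert rep.f1 == 1.0 and threshold <= 0.45
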