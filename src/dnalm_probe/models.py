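"""Model contract, desk-scale reference masked LM, and fine-tuning heads.

Any probed language model must satisfy a small contract:

* ``predict_masked(sample)`` returns one probability distribution over the
  full vocabulary per masked position (rows sum to 1);
* ``token_embeddings()`` returns one row per vocabulary entry;
* for fine-tuning, ``encoder_`` exposes a trainable
  :class:`~dnalm_probe.nn.TransformerEncoder` and ``vocab_`` its vocabulary.

:class:`ReferenceMaskedLM` is a tiny CPU transformer (defaults: 64-dim,
2 layers, 2 heads) trained with the same masking scheme as a full-scale
overlapping-k-mer model; :class:`UniformStubModel` is a test double that
predicts the uniform distribution everywhere.  Fine-tuning heads copy the
encoder weights, so the base model is never mutated by a downstream task.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .datasets import (
    MaskedSample,
    NextKmerDataset,
    PromoterRecord,
    build_masked_dataset,
    make_mask_pattern,
)
from .nn import (
    AdamOptimizer,
    EncoderConfig,
    TransformerEncoder,
    binary_cross_entropy,
    cross_entropy,
    mean_pool,
    mean_pool_backward,
    pad_batch,
    softmax,
)
from .tokenization import (
    DataError,
    KmerVocabulary,
    ParameterError,
    build_vocabulary,
    tokenize,
)

logger = logging.getLogger(__name__)


class LengthError(ValueError):
    """Input exceeds the model's maximum input length."""


class ContractViolation(ValueError):
    """A model object does not satisfy the masked-LM contract."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule settings for fine-tuning.

    Defaults follow the published protocol for fine-tuning a full-scale
    model: Adam with learning rate 1e-6, epsilon 1e-8 and beta2 0.99 (the
    single stated beta is read as the second-moment coefficient, beta1 stays
    at 0.9), batch size 64, 150 iterations for next-k-mer and 10 epochs for
    Prom300, classifier dropout 0.5.  :meth:`desk_scale` adapts the learning
    rate for the tiny reference model.
    """

    learning_rate: float = 1e-6
    adam_epsilon: float = 1e-8
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    batch_size: int = 64
    steps: int = 150
    epochs: int = 10
    classifier_dropout: float = 0.5
    max_input_tokens: int | None = None
    freeze_encoder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "adam_epsilon"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("adam_beta1", "adam_beta2"):
            if not 0 <= getattr(self, name) < 1:
                raise ParameterError(f"{name} must be in [0, 1)")
        if not 0 <= self.classifier_dropout < 1:
            raise ParameterError("classifier_dropout must be in [0, 1)")
        if self.batch_size < 1 or self.steps < 1 or self.epochs < 1:
            raise ParameterError("batch_size, steps and epochs must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        """Settings suited to the small reference model on one CPU: the
        published 1e-6 learning rate barely moves a freshly initialized
        64-dim encoder within 150 iterations, so the desk default is 1e-3."""
        base = dict(learning_rate=1e-3)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ReferenceModelSpec:
    """Architecture of the desk-scale reference model (trains on one CPU in
    minutes at the defaults)."""

    k: int = 4
    embedding_dim: int = 64
    layers: int = 2
    heads: int = 2
    ff_dim: int = 128
    context_length: int = 64
    seed: int = 0


def check_contract(model, vocab: KmerVocabulary, sample: MaskedSample) -> None:
    """Raise :class:`ContractViolation` unless ``model`` behaves like a
    masked LM on ``sample``: k probability rows over the full vocabulary and
    a one-row-per-token embedding matrix."""
    probs = model.predict_masked(sample)
    probs = np.asarray(probs)
    if probs.shape != (len(sample.masked_positions), vocab.size):
        raise ContractViolation(
            f"predict_masked shape {probs.shape} != ({len(sample.masked_positions)}, {vocab.size})"
        )
    if (probs < 0).any() or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ContractViolation("predict_masked rows must be distributions summing to 1")
    emb = np.asarray(model.token_embeddings())
    if emb.shape[0] != vocab.size:
        raise ContractViolation(f"embedding rows {emb.shape[0]} != vocabulary size {vocab.size}")
    if not np.isfinite(emb).all():
        raise ContractViolation("embedding matrix contains non-finite entries")


class ReferenceMaskedLM(BaseEstimator):
    """Tiny trainable masked language model over overlapping k-mer tokens.

    ``fit`` takes a corpus of nucleotide sub-sequences, applies the per-k
    mask pattern to each (one randomly chosen token per sub-sequence) and
    trains with cross-entropy at the masked positions.

    Parameters mirror :class:`ReferenceModelSpec` plus the pretraining
    schedule.  Fitted attributes: ``vocab_``, ``pattern_``, ``encoder_``,
    ``loss_history_``, ``max_input_tokens_``.
    """

    def __init__(
        self,
        k: int = 4,
        embedding_dim: int = 64,
        n_layers: int = 2,
        n_heads: int = 2,
        ff_dim: int = 128,
        context_length: int = 64,
        learning_rate: float = 2e-3,
        batch_size: int = 32,
        steps: int = 1200,
        seed: int = 0,
    ):
        self.k = k
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.context_length = context_length
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.steps = steps
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, X: Sequence[str], y=None) -> "ReferenceMaskedLM":
        """Pretrain on a corpus of nucleotide strings (masked-token loss)."""
        if not X:
            raise DataError("empty pretraining corpus")
        self.vocab_ = build_vocabulary(self.k)
        self.pattern_ = make_mask_pattern(self.k)
        truncated = [s[: self.context_length + self.k - 1] for s in X]
        samples = build_masked_dataset(truncated, self.vocab_, seed=self.seed)
        if not samples:
            raise DataError("no sub-sequence is long enough for the mask pattern")
        cfg = EncoderConfig(
            vocab_size=self.vocab_.size,
            dim=self.embedding_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            ff_dim=self.ff_dim,
            seed=self.seed,
        )
        self.encoder_ = TransformerEncoder(cfg)
        rng = np.random.default_rng(self.seed)
        d, V = self.embedding_dim, self.vocab_.size
        self.encoder_.params["mlm.W"] = rng.normal(0, 0.02, (d, V))
        self.encoder_.params["mlm.b"] = np.zeros(V)
        opt = AdamOptimizer(self.encoder_.params, lr=self.learning_rate)
        self.loss_history_ = []
        for _ in range(self.steps):
            idx = rng.integers(0, len(samples), size=min(self.batch_size, len(samples)))
            loss, grads = self._mlm_loss([samples[i] for i in idx])
            opt.step(grads)
            self.loss_history_.append(loss)
        self.max_input_tokens_ = self.context_length
        return self

    def _mlm_loss(self, batch: list[MaskedSample]) -> tuple[float, dict]:
        p = self.encoder_.params
        ids, mask = pad_batch([s.ids for s in batch], self.vocab_.pad_id)
        hidden, cache = self.encoder_.forward(ids, mask)
        rows_b, rows_p, targets = [], [], []
        for b, s in enumerate(batch):
            for pos, t in zip(s.masked_positions, s.truth):
                rows_b.append(b)
                rows_p.append(pos)
                targets.append(t)
        sel = hidden[rows_b, rows_p]
        logits = sel @ p["mlm.W"] + p["mlm.b"]
        loss, dlogits = cross_entropy(logits, np.asarray(targets))
        grads_head = {
            "mlm.W": sel.T @ dlogits,
            "mlm.b": dlogits.sum(axis=0),
        }
        dsel = dlogits @ p["mlm.W"].T
        dhidden = np.zeros_like(hidden)
        dhidden[rows_b, rows_p] = dsel
        grads = self.encoder_.backward(dhidden, cache)
        grads.update(grads_head)
        return loss, grads

    # ------------------------------------------------------------------
    def predict_masked(self, sample: MaskedSample) -> np.ndarray:
        """(n_masked, vocab_size) probability matrix for one sample."""
        return self.predict_masked_many([sample])[0]

    def predict_masked_many(
        self, samples: Sequence[MaskedSample], batch_size: int = 64
    ) -> list[np.ndarray]:
        self._check_fitted()
        p = self.encoder_.params
        out: list[np.ndarray] = []
        for start in range(0, len(samples), batch_size):
            batch = samples[start : start + batch_size]
            for s in batch:
                if len(s.ids) > self.max_input_tokens_:
                    raise LengthError(
                        f"sample of {len(s.ids)} tokens exceeds max input "
                        f"length {self.max_input_tokens_}"
                    )
            ids, mask = pad_batch([s.ids for s in batch], self.vocab_.pad_id)
            hidden, _ = self.encoder_.forward(ids, mask)
            for b, s in enumerate(batch):
                sel = hidden[b, list(s.masked_positions)]
                out.append(softmax(sel @ p["mlm.W"] + p["mlm.b"]))
        return out

    def token_embeddings(self) -> np.ndarray:
        """The word-embedding weight matrix, one row per vocabulary entry."""
        self._check_fitted()
        return self.encoder_.params["tok_emb"].copy()

    def masked_accuracy(self, samples: Sequence[MaskedSample]) -> float:
        """Fraction of masked positions whose argmax token equals the truth."""
        preds = self.predict_masked_many(samples)
        correct = total = 0
        for probs, s in zip(preds, samples):
            correct += int((probs.argmax(axis=1) == np.asarray(s.truth)).sum())
            total += len(s.truth)
        return correct / total

    def _check_fitted(self) -> None:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("model is not fitted; call fit() first")


def train_reference_mlm(
    corpus: Sequence[str],
    spec: ReferenceModelSpec = ReferenceModelSpec(),
    learning_rate: float = 2e-3,
    batch_size: int = 32,
    steps: int = 1200,
) -> ReferenceMaskedLM:
    """Functional wrapper: pretrain a :class:`ReferenceMaskedLM` from a spec."""
    model = ReferenceMaskedLM(
        k=spec.k,
        embedding_dim=spec.embedding_dim,
        n_layers=spec.layers,
        n_heads=spec.heads,
        ff_dim=spec.ff_dim,
        context_length=spec.context_length,
        learning_rate=learning_rate,
        batch_size=batch_size,
        steps=steps,
        seed=spec.seed,
    )
    return model.fit(list(corpus))


class UniformStubModel:
    """Contract-satisfying test double: uniform predictions everywhere and an
    identity-like embedding matrix."""

    def __init__(self, k: int = 4):
        self.k = k
        self.vocab_ = build_vocabulary(k)
        self.pattern_ = make_mask_pattern(k)
        self.max_input_tokens_ = 10**9

    def predict_masked(self, sample: MaskedSample) -> np.ndarray:
        n = len(sample.masked_positions)
        return np.full((n, self.vocab_.size), 1.0 / self.vocab_.size)

    def predict_masked_many(self, samples, batch_size: int = 64):
        return [self.predict_masked(s) for s in samples]

    def token_embeddings(self) -> np.ndarray:
        return np.eye(self.vocab_.size)

    def masked_accuracy(self, samples) -> float:
        preds = self.predict_masked_many(samples)
        correct = total = 0
        for probs, s in zip(preds, samples):
            correct += int((probs.argmax(axis=1) == np.asarray(s.truth)).sum())
            total += len(s.truth)
        return correct / total


# ---------------------------------------------------------------------------
# fine-tuning heads
# ---------------------------------------------------------------------------


class _FinetuneBase(BaseEstimator):
    """Shared machinery: copy the base encoder, tokenize, pool, optimize."""

    def _setup(self, model, config: TrainingConfig | None) -> TrainingConfig:
        if model is None or not hasattr(model, "encoder_"):
            raise ContractViolation(
                "fine-tuning needs a fitted base model exposing a trainable encoder_"
            )
        cfg = config if config is not None else TrainingConfig.desk_scale()
        self.config_ = cfg
        self.vocab_ = model.vocab_
        self.encoder_ = TransformerEncoder(model.encoder_.config)
        self.encoder_.params = {k: v.copy() for k, v in model.encoder_.params.items()}
        return cfg

    def _tokenize_all(self, X: Sequence[str]) -> list[tuple[int, ...]]:
        return [tokenize(x, self.vocab_).ids for x in X]

    def _forward_pooled(self, id_seqs, train_rng=None):
        ids, mask = pad_batch(id_seqs, self.vocab_.pad_id)
        hidden, cache = self.encoder_.forward(ids, mask)
        pooled, _ = mean_pool(hidden, mask)
        drop_mask = None
        p_drop = self.config_.classifier_dropout
        if train_rng is not None and p_drop > 0:
            drop_mask = (train_rng.random(pooled.shape) >= p_drop) / (1 - p_drop)
            pooled = pooled * drop_mask
        return pooled, (cache, mask, drop_mask)

    def _backward_pooled(self, dpooled, ctx) -> dict:
        cache, mask, drop_mask = ctx
        if drop_mask is not None:
            dpooled = dpooled * drop_mask
        dhidden = mean_pool_backward(dpooled, mask)
        if self.config_.freeze_encoder:
            return {}
        return self.encoder_.backward(dhidden, cache)

    def _make_optimizer(self, head_params: dict) -> AdamOptimizer:
        cfg = self.config_
        params = head_params if cfg.freeze_encoder else {**self.encoder_.params, **head_params}
        return AdamOptimizer(
            params,
            lr=cfg.learning_rate,
            beta1=cfg.adam_beta1,
            beta2=cfg.adam_beta2,
            eps=cfg.adam_epsilon,
        )


class NextKmerClassifier(_FinetuneBase, ClassifierMixin):
    """Fine-tuned classifier over the ``4**k`` possible next k-mers.

    ``X`` is a sequence of 50-nt context strings, ``y`` integer classes in
    ``[0, 4**k)`` (the lexicographic rank of the following k-mer).  The
    encoder output is mean-pooled and fed to a linear head trained with
    cross-entropy under :class:`TrainingConfig`.
    """

    def __init__(self, model=None, k: int = 4, config: TrainingConfig | None = None):
        self.model = model
        self.k = k
        self.config = config

    @property
    def n_classes(self) -> int:
        return 4**self.k

    def fit(self, X: Sequence[str], y) -> "NextKmerClassifier":
        if self.k not in (2, 3, 4, 5, 6):
            raise ParameterError(f"next-k-mer k must be in 2..6, got {self.k}")
        cfg = self._setup(self.model, self.config)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y) or len(y) == 0:
            raise DataError("X and y must be equal-length and non-empty")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ParameterError(
                f"labels must lie in [0, {self.n_classes}) for k={self.k}"
            )
        id_seqs = self._tokenize_all(X)
        rng = np.random.default_rng(cfg.seed)
        d = self.encoder_.config.dim
        head = {
            "head.W": np.random.default_rng(cfg.seed + 1).normal(0, 0.02, (d, self.n_classes)),
            "head.b": np.zeros(self.n_classes),
        }
        self.encoder_.params.update(head)
        opt = self._make_optimizer({k: self.encoder_.params[k] for k in head})
        self.loss_history_ = []
        n = len(id_seqs)
        for _ in range(cfg.steps):
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            loss = self._step([id_seqs[i] for i in idx], y[idx], opt, rng)
            self.loss_history_.append(loss)
        self.classes_ = np.arange(self.n_classes)
        return self

    def _step(self, id_seqs, targets, opt, rng) -> float:
        p = self.encoder_.params
        pooled, ctx = self._forward_pooled(id_seqs, train_rng=rng)
        logits = pooled @ p["head.W"] + p["head.b"]
        loss, dlogits = cross_entropy(logits, targets)
        grads = {
            "head.W": pooled.T @ dlogits,
            "head.b": dlogits.sum(axis=0),
        }
        dpooled = dlogits @ p["head.W"].T
        grads.update(self._backward_pooled(dpooled, ctx))
        opt.step(grads)
        return loss

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p = self.encoder_.params
        id_seqs = self._tokenize_all(X)
        out = []
        for start in range(0, len(id_seqs), 256):
            pooled, _ = self._forward_pooled(id_seqs[start : start + 256])
            out.append(softmax(pooled @ p["head.W"] + p["head.b"]))
        return np.vstack(out)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fit_dataset(self, dataset: NextKmerDataset) -> "NextKmerClassifier":
        """Fit on the dataset's training split (checks k agreement)."""
        if dataset.k != self.k:
            raise ParameterError(f"dataset k={dataset.k} != classifier k={self.k}")
        train = dataset.train
        return self.fit([s.context for s in train], [s.label_class for s in train])


def finetune_next_kmer(
    model, dataset: NextKmerDataset, k: int, config: TrainingConfig | None = None
) -> NextKmerClassifier:
    """Functional wrapper over :class:`NextKmerClassifier`."""
    return NextKmerClassifier(model=model, k=k, config=config).fit_dataset(dataset)


class Prom300Classifier(_FinetuneBase, ClassifierMixin):
    """Binary real-vs-shuffled promoter classifier: single sigmoid neuron on
    the mean-pooled encoder output, decision threshold 0.5.

    ``y`` may be 0/1 integers or the strings ``"real"``/``"shuffled"``
    (real = 1).  If the tokenized promoters exceed the base model's maximum
    input length, the limit is raised automatically (and logged) rather than
    silently truncating five sixths of the window.
    """

    THRESHOLD = 0.5

    def __init__(self, model=None, config: TrainingConfig | None = None):
        self.model = model
        self.config = config

    @staticmethod
    def _encode_labels(y) -> np.ndarray:
        mapping = {"real": 1, "shuffled": 0, 1: 1, 0: 0, True: 1, False: 0}
        try:
            return np.asarray([mapping[v] for v in y], dtype=float)
        except KeyError as e:
            raise DataError(f"unrecognized label {e.args[0]!r}") from None

    def fit(self, X: Sequence[str], y) -> "Prom300Classifier":
        cfg = self._setup(self.model, self.config)
        yb = self._encode_labels(y)
        if len(X) != len(yb) or len(yb) == 0:
            raise DataError("X and y must be equal-length and non-empty")
        if len(np.unique(yb)) < 2:
            raise DataError("Prom300 training needs both classes present")
        id_seqs = self._tokenize_all(X)
        needed = max(len(s) for s in id_seqs)
        limit = getattr(self.model, "max_input_tokens_", needed)
        if needed > limit:
            logger.info(
                "Prom300Classifier: raising max input length %d -> %d to fit "
                "tokenized promoters", limit, needed,
            )
        self.max_input_tokens_ = max(limit, needed)
        rng = np.random.default_rng(cfg.seed)
        d = self.encoder_.config.dim
        self.encoder_.params["head.w"] = np.random.default_rng(cfg.seed + 1).normal(0, 0.02, (d,))
        self.encoder_.params["head.b"] = np.zeros(1)
        opt = self._make_optimizer(
            {k: self.encoder_.params[k] for k in ("head.w", "head.b")}
        )
        self.loss_history_ = []
        n = len(id_seqs)
        order = np.arange(n)
        for _ in range(cfg.epochs):
            rng.shuffle(order)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss = self._step([id_seqs[i] for i in idx], yb[idx], opt, rng)
                self.loss_history_.append(loss)
        self.classes_ = np.array([0, 1])
        return self

    def _step(self, id_seqs, targets, opt, rng) -> float:
        p = self.encoder_.params
        pooled, ctx = self._forward_pooled(id_seqs, train_rng=rng)
        logits = pooled @ p["head.w"] + p["head.b"][0]
        loss, dlogits = binary_cross_entropy(logits, targets)
        grads = {
            "head.w": pooled.T @ dlogits,
            "head.b": np.array([dlogits.sum()]),
        }
        dpooled = dlogits[:, None] * p["head.w"][None, :]
        grads.update(self._backward_pooled(dpooled, ctx))
        opt.step(grads)
        return loss

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """(n, 2) array of [P(shuffled), P(real)]."""
        p = self.encoder_.params
        id_seqs = self._tokenize_all(X)
        probs = []
        for start in range(0, len(id_seqs), 64):
            pooled, _ = self._forward_pooled(id_seqs[start : start + 64])
            logits = pooled @ p["head.w"] + p["head.b"][0]
            probs.append(1.0 / (1.0 + np.exp(-logits)))
        p_real = np.concatenate(probs)
        return np.column_stack([1 - p_real, p_real])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """1 = real, 0 = shuffled, at the 0.5 threshold."""
        return (self.predict_proba(X)[:, 1] >= self.THRESHOLD).astype(int)


def finetune_prom300(
    model, records: Sequence[PromoterRecord], config: TrainingConfig | None = None
) -> Prom300Classifier:
    """Functional wrapper over :class:`Prom300Classifier`."""
    clf = Prom300Classifier(model=model, config=config)
    return clf.fit([r.seq for r in records], [r.label for r in records])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def vocab_hash(vocab: KmerVocabulary) -> str:
    return hashlib.sha256("\n".join(vocab.tokens()).encode()).hexdigest()[:16]


def save_model(directory: str | Path, model: ReferenceMaskedLM) -> None:
    """Checkpoint directory: weights.npz + spec.json (k, dims, vocab hash)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.encoder_.params)
    spec = {
        "k": model.k,
        "embedding_dim": model.embedding_dim,
        "n_layers": model.n_layers,
        "n_heads": model.n_heads,
        "ff_dim": model.ff_dim,
        "context_length": model.context_length,
        "learning_rate": model.learning_rate,
        "batch_size": model.batch_size,
        "steps": model.steps,
        "seed": model.seed,
        "max_input_tokens": model.max_input_tokens_,
        "vocab_hash": vocab_hash(model.vocab_),
    }
    (directory / "spec.json").write_text(json.dumps(spec, indent=2) + "\n")


def load_model(directory: str | Path) -> ReferenceMaskedLM:
    directory = Path(directory)
    spec = json.loads((directory / "spec.json").read_text())
    model = ReferenceMaskedLM(
        k=spec["k"],
        embedding_dim=spec["embedding_dim"],
        n_layers=spec["n_layers"],
        n_heads=spec["n_heads"],
        ff_dim=spec["ff_dim"],
        context_length=spec["context_length"],
        learning_rate=spec["learning_rate"],
        batch_size=spec["batch_size"],
        steps=spec["steps"],
        seed=spec["seed"],
    )
    model.vocab_ = build_vocabulary(spec["k"])
    if vocab_hash(model.vocab_) != spec["vocab_hash"]:
        raise DataError(f"vocabulary hash mismatch in checkpoint {directory}")
    model.pattern_ = make_mask_pattern(spec["k"])
    cfg = EncoderConfig(
        vocab_size=model.vocab_.size,
        dim=spec["embedding_dim"],
        n_layers=spec["n_layers"],
        n_heads=spec["n_heads"],
        ff_dim=spec["ff_dim"],
        seed=spec["seed"],
    )
    model.encoder_ = TransformerEncoder(cfg)
    with np.load(directory / "weights.npz") as npz:
        model.encoder_.params = {k: npz[k].copy() for k in npz.files}
    model.loss_history_ = []
    model.max_input_tokens_ = spec["max_input_tokens"]
    return model
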