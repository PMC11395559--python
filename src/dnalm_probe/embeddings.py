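"""Token-embedding analyses: CBOW baseline, MEV, UMAP, purine/pyrimidine maps.

The contextual model's ``word_embeddings`` matrix and a static Word2Vec-CBOW
baseline are pushed through the same analysis path: Maximum Explainable
Variance (MEV, the fraction of variance on the first principal component —
high MEV suggests token-identity-dominated rather than contextual
representations) and a 2-D UMAP with each k-mer annotated by its central
sub-k-mer and that sub-k-mer's purine (R = A/G) / pyrimidine (Y = C/T)
pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .models import ContractViolation
from .tokenization import (
    DataError,
    KmerVocabulary,
    ParameterError,
    build_vocabulary,
    kmer_from_index,
    tokenize,
)

logger = logging.getLogger(__name__)

_RY = str.maketrans("AGCT", "RRYY")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """One vector per k-mer token (special tokens excluded)."""

    k: int
    source: str  # {"model", "word2vec"}
    tokens: tuple[str, ...]
    vectors: np.ndarray  # (len(tokens), dim)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.tokens):
            raise ParameterError("one vector per token required")
        if not np.isfinite(self.vectors).all():
            raise DataError("embedding matrix contains non-finite entries")


class Word2VecCBOW(BaseEstimator):
    """Static CBOW embeddings over tokenized nucleotide sub-sequences.

    The mean of the input vectors of the tokens within ``window`` positions
    of a center token predicts the center token through a full-softmax output
    layer (practical here because the k-mer vocabulary is small).  Tokens
    seen fewer than ``min_count`` times get no vector and are reported in
    ``missing_tokens_``.

    Fitted attributes: ``vectors_`` (input vectors for the full k-mer
    vocabulary, unobserved rows NaN-free but unreliable — use
    :meth:`embedding_matrix`), ``counts_``, ``missing_tokens_``.
    """

    def __init__(
        self,
        k: int = 4,
        window: int = 5,
        vector_size: int = 768,
        min_count: int = 1,
        epochs: int = 3,
        learning_rate: float = 0.05,
        batch_size: int = 512,
        seed: int = 0,
    ):
        self.k = k
        self.window = window
        self.vector_size = vector_size
        self.min_count = min_count
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X: Sequence, y=None) -> "Word2VecCBOW":
        """Train on sentences: nucleotide strings (tokenized with overlapping
        k-mers) or pre-tokenized k-mer id sequences."""
        if not len(X):
            raise DataError("empty corpus")
        vocab = build_vocabulary(self.k)
        self.vocab_ = vocab
        sentences = []
        for s in X:
            if isinstance(s, str):
                if len(s) >= vocab.k:
                    sentences.append(np.asarray(tokenize(s, vocab).ids))
            else:
                ids = np.asarray(s, dtype=np.int64)
                if ids.size and (ids.min() < 0 or ids.max() >= vocab.n_kmers):
                    raise DataError("token ids outside the k-mer vocabulary")
                sentences.append(ids)
        sentences = [s for s in sentences if s.size]
        if not sentences:
            raise DataError(f"no sentence tokenizes with k={self.k}")
        n_kmers = vocab.n_kmers
        self.counts_ = np.zeros(n_kmers, dtype=np.int64)
        for s in sentences:
            self.counts_ += np.bincount(s, minlength=n_kmers)

        centers, ctx_idx, ctx_mask = self._training_pairs(sentences)
        rng = np.random.default_rng(self.seed)
        d = self.vector_size
        w_in = rng.normal(0, 0.01, (n_kmers, d))
        w_out = rng.normal(0, 0.01, (d, n_kmers))
        n = len(centers)
        order = np.arange(n)
        for _ in range(self.epochs):
            rng.shuffle(order)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                self._cbow_step(w_in, w_out, centers[idx], ctx_idx[idx], ctx_mask[idx])
        self.vectors_ = w_in
        self.missing_tokens_ = tuple(
            kmer_from_index(i, self.k) for i in np.nonzero(self.counts_ < self.min_count)[0]
        )
        if self.missing_tokens_:
            logger.info(
                "Word2VecCBOW: %d of %d k-mers below min_count=%d have no embedding",
                len(self.missing_tokens_), n_kmers, self.min_count,
            )
        return self

    def _training_pairs(self, sentences):
        w = self.window
        centers, ctx_rows = [], []
        for s in sentences:
            n = len(s)
            for i in range(n):
                lo, hi = max(0, i - w), min(n, i + w + 1)
                ctx = np.concatenate([s[lo:i], s[i + 1 : hi]])
                if ctx.size == 0:
                    continue
                centers.append(s[i])
                row = np.full(2 * w, -1, dtype=np.int64)
                row[: ctx.size] = ctx
                ctx_rows.append(row)
        centers = np.asarray(centers, dtype=np.int64)
        ctx_idx = np.asarray(ctx_rows, dtype=np.int64)
        ctx_mask = ctx_idx >= 0
        ctx_idx = np.where(ctx_mask, ctx_idx, 0)
        return centers, ctx_idx, ctx_mask

    def _cbow_step(self, w_in, w_out, centers, ctx_idx, ctx_mask) -> None:
        lr = self.learning_rate
        counts = ctx_mask.sum(axis=1, keepdims=True)
        h = (w_in[ctx_idx] * ctx_mask[:, :, None]).sum(axis=1) / counts
        logits = h @ w_out
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        b = len(centers)
        p[np.arange(b), centers] -= 1.0
        dlogits = p / b
        dw_out = h.T @ dlogits
        dh = dlogits @ w_out.T
        dctx = (dh / counts)[:, None, :] * ctx_mask[:, :, None]
        np.add.at(w_in, ctx_idx.ravel(), -lr * dctx.reshape(-1, self.vector_size))
        w_out -= lr * dw_out

    def embedding_matrix(self) -> EmbeddingMatrix:
        """Observed k-mers only (all ``4**k`` when coverage is complete)."""
        keep = np.nonzero(self.counts_ >= self.min_count)[0]
        return EmbeddingMatrix(
            k=self.k,
            source="word2vec",
            tokens=tuple(kmer_from_index(int(i), self.k) for i in keep),
            vectors=self.vectors_[keep].copy(),
        )


def train_word2vec_embeddings(
    subseqs: Sequence[str],
    vocab: KmerVocabulary,
    window: int = 5,
    dim: int = 768,
    min_count: int = 1,
    seed: int = 0,
    epochs: int = 3,
    learning_rate: float = 0.05,
) -> EmbeddingMatrix:
    """Functional wrapper over :class:`Word2VecCBOW` for a given vocabulary."""
    model = Word2VecCBOW(
        k=vocab.k,
        window=window,
        vector_size=dim,
        min_count=min_count,
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
    )
    model.fit(subseqs)
    return model.embedding_matrix()


def extract_model_embeddings(model, vocab: KmerVocabulary) -> EmbeddingMatrix:
    """The model's token-embedding rows in vocabulary-id order, with special
    token rows dropped for analysis."""
    emb = np.asarray(model.token_embeddings())
    if emb.shape[0] != vocab.size:
        raise ContractViolation(
            f"embedding has {emb.shape[0]} rows but vocabulary size is {vocab.size}"
        )
    return EmbeddingMatrix(
        k=vocab.k,
        source="model",
        tokens=tuple(kmer_from_index(i, vocab.k) for i in range(vocab.n_kmers)),
        vectors=emb[: vocab.n_kmers].copy(),
    )


# ---------------------------------------------------------------------------
# MEV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MevResult:
    """First-PC share of total variance plus the full spectrum."""

    mev: float
    eigenvalues: np.ndarray


def compute_mev(embedding: EmbeddingMatrix | np.ndarray) -> MevResult:
    """PCA on column-mean-centred rows (no scaling); MEV = lambda_1 / sum."""
    X = embedding.vectors if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ParameterError("MEV needs a matrix with at least 2 rows and 2 columns")
    if np.allclose(X, X[0], atol=0):
        raise DataError("degenerate input: all embedding rows are identical")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    ev = pca.explained_variance_
    return MevResult(mev=float(ev[0] / ev.sum()), eigenvalues=ev)


# ---------------------------------------------------------------------------
# R/Y annotation and UMAP
# ---------------------------------------------------------------------------


def ry_annotation(kmer: str, central_width: int) -> tuple[str, str]:
    """Central ``central_width``-mer of ``kmer`` and its purine/pyrimidine
    pattern (A,G -> R; C,T -> Y)."""
    k = len(kmer)
    if not 1 <= central_width <= k:
        raise ParameterError(f"central_width must be in [1, {k}]")
    if (k - central_width) % 2 != 0:
        raise ParameterError(
            f"k - central_width must be even for a well-defined centre "
            f"(k={k}, central_width={central_width})"
        )
    lo = (k - central_width) // 2
    central = kmer[lo : lo + central_width]
    return central, central.translate(_RY)


@dataclass(frozen=True)
class ProjectionResult:
    """2-D coordinates per token with central-sub-k-mer annotation."""

    tokens: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    central: tuple[str, ...]
    ry_pattern: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "token": self.tokens,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "central": self.central,
                "ry_pattern": self.ry_pattern,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def umap_project(
    embedding: EmbeddingMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
    central_width: int | None = None,
) -> ProjectionResult:
    """UMAP to 2-D with per-token central-n-mer / R-Y annotation.

    ``central_width`` defaults to ``k - 2`` (central dimer for 4-mers, trimer
    for 5-mers, tetramer for 6-mers).
    """
    X = embedding.vectors
    if X.shape[0] < n_neighbors + 1:
        raise ParameterError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {X.shape[0]}"
        )
    if central_width is None:
        central_width = max(1, embedding.k - 2)
    import umap  # deferred: numba jit compilation is slow to import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=float)
    ann = [ry_annotation(t, central_width) for t in embedding.tokens]
    return ProjectionResult(
        tokens=embedding.tokens,
        coords=coords,
        central=tuple(a[0] for a in ann),
        ry_pattern=tuple(a[1] for a in ann),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_embedding_tsv(path: str | Path, embedding: EmbeddingMatrix) -> None:
    df = pd.DataFrame(embedding.vectors, columns=[f"v{i + 1}" for i in range(embedding.dim)])
    df.insert(0, "token", embedding.tokens)
    df.to_csv(path, sep="\t", index=False)


def read_embedding_tsv(path: str | Path, source: str = "model") -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t")
    tokens = tuple(df["token"])
    vectors = df.drop(columns="token").to_numpy(dtype=float)
    return EmbeddingMatrix(k=len(tokens[0]), source=source, tokens=tokens, vectors=vectors)


def save_embedding(path: str | Path, embedding: EmbeddingMatrix) -> None:
    """Compact .npz with the token list and metadata embedded."""
    np.savez(
        path,
        vectors=embedding.vectors,
        tokens=np.array(embedding.tokens),
        k=embedding.k,
        source=embedding.source,
    )


def load_embedding(path: str | Path) -> EmbeddingMatrix:
    with np.load(path, allow_pickle=False) as npz:
        return EmbeddingMatrix(
            k=int(npz["k"]),
            source=str(npz["source"]),
            tokens=tuple(str(t) for t in npz["tokens"]),
            vectors=npz["vectors"].copy(),
        )
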