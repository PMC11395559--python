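"""Overlapping k-mer vocabularies, tokenization and genome k-mer statistics.

A DNA language model with overlapping tokenization slides a window of width
``k`` along the sequence one nucleotide at a time, so a sequence of length
``L`` yields ``L - k + 1`` tokens and consecutive tokens share ``k - 1``
nucleotides.  The vocabulary contains all ``4**k`` k-mers plus the five
special tokens CLS, PAD, UNK, SEP and MASK.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
SPECIAL_TOKENS = ("CLS", "PAD", "UNK", "SEP", "MASK")

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class DataError(ValueError):
    """Raised when input data violates a contract (bad alphabet, overlap conflict...)."""


class ParameterError(ValueError):
    """Raised when a parameter is outside its documented range."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig whose sequence is strictly over {A, C, G, T}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise DataError(f"sequence {self.name!r} is empty")
        bad = _first_invalid_position(self.seq)
        if bad is not None:
            raise DataError(
                f"sequence {self.name!r} has non-ACGT character "
                f"{self.seq[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _first_invalid_position(seq: str) -> int | None:
    for i, c in enumerate(seq):
        if c not in _BASE_INDEX:
            return i
    return None


@dataclass(frozen=True)
class KmerVocabulary:
    """All ``4**k`` k-mers in lexicographic order (A<C<G<T) plus special tokens.

    K-mer ids occupy ``0 .. 4**k - 1``; the five special ids follow.
    """

    k: int
    kmer_ids: Mapping[str, int] = field(repr=False)
    special_ids: Mapping[str, int] = field(repr=False)

    @property
    def n_kmers(self) -> int:
        return 4**self.k

    @property
    def size(self) -> int:
        return self.n_kmers + len(self.special_ids)

    @property
    def mask_id(self) -> int:
        return self.special_ids["MASK"]

    @property
    def pad_id(self) -> int:
        return self.special_ids["PAD"]

    @property
    def cls_id(self) -> int:
        return self.special_ids["CLS"]

    def id_to_kmer(self, token_id: int) -> str:
        """Inverse lookup; special ids return their symbolic name."""
        if 0 <= token_id < self.n_kmers:
            return kmer_from_index(token_id, self.k)
        for name, sid in self.special_ids.items():
            if sid == token_id:
                return name
        raise ParameterError(f"token id {token_id} outside vocabulary of size {self.size}")

    def tokens(self) -> list[str]:
        """All tokens in id order (k-mers first, then specials)."""
        return [kmer_from_index(i, self.k) for i in range(self.n_kmers)] + list(SPECIAL_TOKENS)


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer under A<C<G<T (base-4 integer encoding)."""
    idx = 0
    for c in kmer:
        try:
            idx = idx * 4 + _BASE_INDEX[c]
        except KeyError:
            raise DataError(f"non-ACGT character {c!r} in k-mer {kmer!r}") from None
    return idx


def kmer_from_index(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def build_vocabulary(k: int) -> KmerVocabulary:
    """Build the overlapping k-mer vocabulary: ``4**k`` k-mers + 5 special tokens.

    ``k`` is limited to 12 to guard against combinatorial blow-up (4**12 is
    already ~17M entries).
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ParameterError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= 12:
        raise ParameterError(f"k must be in [1, 12], got {k}")
    n = 4**k
    kmer_ids = {kmer_from_index(i, k): i for i in range(n)}
    special_ids = {name: n + j for j, name in enumerate(SPECIAL_TOKENS)}
    return KmerVocabulary(k=int(k), kmer_ids=kmer_ids, special_ids=special_ids)


@dataclass(frozen=True)
class TokenSequence:
    """Token ids from overlapping k-mer tokenization of one sequence."""

    k: int
    ids: tuple[int, ...]
    source_length: int

    def __len__(self) -> int:
        return len(self.ids)


def tokenize(seq: str, vocab: KmerVocabulary) -> TokenSequence:
    """Tokenize ``seq`` into overlapping k-mers (token i covers seq[i:i+k])."""
    k = vocab.k
    bad = _first_invalid_position(seq)
    if bad is not None:
        raise DataError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    if len(seq) < k:
        raise DataError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base = np.zeros(len(seq), dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        base[codes == ord(b)] = i
    # rolling base-4 integer over windows of width k
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(base, k)
    ids = windows @ powers
    return TokenSequence(k=k, ids=tuple(int(i) for i in ids), source_length=len(seq))


def detokenize(tokens: TokenSequence) -> str:
    """Invert :func:`tokenize`; consecutive tokens must overlap consistently."""
    k = tokens.k
    if not tokens.ids:
        raise DataError("cannot detokenize an empty token sequence")
    kmers = [kmer_from_index(i, k) for i in tokens.ids]
    seq = list(kmers[0])
    for pos, (prev, cur) in enumerate(zip(kmers, kmers[1:]), start=1):
        if prev[1:] != cur[:-1]:
            raise DataError(
                f"overlap conflict between token {pos - 1} ({prev}) and token {pos} "
                f"({cur}): {prev[1:]!r} != {cur[:-1]!r}"
            )
        seq.append(cur[-1])
    return "".join(seq)


def read_fasta(path: str | Path, split_at_invalid: bool = False) -> list[GenomeSequence]:
    """Read a FASTA file, keeping only strictly-ACGT sequence.

    Records are uppercased (soft-masked references use lowercase).  By default
    a record containing any non-ACGT character is excluded whole; with
    ``split_at_invalid`` it is split into its maximal valid runs instead
    (suffixed ``name.partN``).  Exclusions are logged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    out: list[GenomeSequence] = []
    excluded = 0
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq).upper()
        if _first_invalid_position(seq) is None and seq:
            out.append(GenomeSequence(name=record.id, seq=seq))
        elif split_at_invalid:
            part = 0
            for run in _valid_runs(seq):
                out.append(GenomeSequence(name=f"{record.id}.part{part}", seq=run))
                part += 1
            excluded += 1
        else:
            excluded += 1
    if excluded:
        logger.info("read_fasta(%s): excluded %d record(s) with non-ACGT characters", path, excluded)
    if n_records == 0:
        logger.warning("read_fasta(%s): file contains no records", path)
    return out


def _valid_runs(seq: str) -> Iterable[str]:
    run: list[str] = []
    for c in seq:
        if c in _BASE_INDEX:
            run.append(c)
        elif run:
            yield "".join(run)
            run = []
    if run:
        yield "".join(run)


def write_fasta(path: str | Path, seqs: Sequence[GenomeSequence], width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def genome_kmer_frequencies(
    seqs: Sequence[GenomeSequence], k: int
) -> dict[str, float]:
    """Relative frequency of every k-mer over all sliding windows of ``seqs``.

    Every one of the ``4**k`` k-mers gets an entry (possibly 0); frequencies
    sum to 1.
    """
    vocab = build_vocabulary(k)
    counts = kmer_counts(seqs, vocab)
    total = counts.sum()
    if total == 0:
        raise DataError(f"no sequence of length >= k={k} supplied")
    freqs = counts / total
    return {kmer_from_index(i, k): float(freqs[i]) for i in range(4**k)}


def kmer_counts(seqs: Sequence[GenomeSequence], vocab: KmerVocabulary) -> np.ndarray:
    """Raw sliding-window k-mer counts as a length-``4**k`` array."""
    counts = np.zeros(vocab.n_kmers, dtype=np.int64)
    for s in seqs:
        if len(s.seq) < vocab.k:
            continue
        ids = np.asarray(tokenize(s.seq, vocab).ids)
        counts += np.bincount(ids, minlength=vocab.n_kmers)
    return counts


def write_frequency_table(path: str | Path, seqs: Sequence[GenomeSequence], k: int) -> pd.DataFrame:
    """TSV with columns kmer, count, frequency."""
    vocab = build_vocabulary(k)
    counts = kmer_counts(seqs, vocab)
    total = counts.sum()
    if total == 0:
        raise DataError(f"no sequence of length >= k={k} supplied")
    df = pd.DataFrame(
        {
            "kmer": [kmer_from_index(i, k) for i in range(vocab.n_kmers)],
            "count": counts,
            "frequency": counts / total,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_vocabulary(path: str | Path, vocab: KmerVocabulary) -> None:
    """One token per line, id implicit in line order (vocab.txt layout)."""
    with open(path, "w") as fh:
        for tok in vocab.tokens():
            fh.write(tok + "\n")


def read_vocabulary(path: str | Path) -> KmerVocabulary:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    n_kmers = len(lines) - len(SPECIAL_TOKENS)
    k = int(round(np.log(n_kmers) / np.log(4))) if n_kmers > 0 else 0
    if 4**k != n_kmers or tuple(lines[n_kmers:]) != SPECIAL_TOKENS:
        raise DataError(f"{path} is not a valid k-mer vocabulary file")
    vocab = build_vocabulary(k)
    if lines[:n_kmers] != vocab.tokens()[:n_kmers]:
        raise DataError(f"{path} k-mer ordering is not lexicographic")
    return vocab
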