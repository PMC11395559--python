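"""Builders for the three probing tasks: masked tokens, next-k-mer, Prom300.

The masked-token task masks ``k`` overlapping tokens around a randomly chosen
token so that exactly one nucleotide — the central nucleotide — is covered by
no unmasked token; every other masked base leaks through overlaps.  The
next-k-mer task predicts the ``k`` nucleotides that follow a 50-nt context,
with zero positional overlap, so only genuine context learning can beat the
``4**-k`` random baseline.  Prom300 opposes intact 300-bp promoter windows to
copies in which 15 of 20 equal parts had their nucleotides shuffled, which
preserves composition exactly and destroys only positional structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tokenization import (
    DataError,
    GenomeSequence,
    KmerVocabulary,
    ParameterError,
    kmer_index,
    tokenize,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sub-sequence sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubsequenceSamplingScheme:
    """Lengths of sub-sequences cut from a chromosome, in tokens.

    With probability ``p_full`` a piece is ``full_len`` tokens long; otherwise
    its length is uniform on ``[min_len, full_len]``.
    """

    p_full: float = 0.5
    full_len: int = 510
    min_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_full <= 1:
            raise ParameterError("p_full must be in [0, 1]")
        if not 1 <= self.min_len <= self.full_len:
            raise ParameterError("need 1 <= min_len <= full_len")

    def draw_length(self, rng: np.random.Generator) -> int:
        if rng.random() < self.p_full:
            return self.full_len
        return int(rng.integers(self.min_len, self.full_len + 1))


def sample_subsequences(
    seqs: Sequence[GenomeSequence],
    scheme: SubsequenceSamplingScheme,
    k: int,
    count: int | None = None,
    fraction: float | None = None,
) -> list[str]:
    """Split sequences into sub-sequences and keep a count or fraction of them.

    Each contig is consumed left to right; each piece's *token* length is
    drawn from ``scheme`` and converted to ``length + k - 1`` nucleotides.
    Pieces shorter than ``min_len`` tokens (contig tails) are dropped.  The
    kept subset is drawn without replacement, deterministically under
    ``scheme.seed``.
    """
    if not seqs:
        raise DataError("no input sequences")
    if count is not None and fraction is not None:
        raise ParameterError("give either count or fraction, not both")
    rng = np.random.default_rng(scheme.seed)
    pieces: list[str] = []
    for s in seqs:
        pos = 0
        n = len(s.seq)
        while n - pos >= scheme.min_len + k - 1:
            nt_len = scheme.draw_length(rng) + k - 1
            piece = s.seq[pos : pos + nt_len]
            pos += nt_len
            if len(piece) >= scheme.min_len + k - 1:
                pieces.append(piece)
    if not pieces:
        raise DataError(
            f"no sequence yields a sub-sequence of at least {scheme.min_len} tokens"
        )
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ParameterError("fraction must be in (0, 1]")
        count = max(1, int(round(fraction * len(pieces))))
    if count is None:
        return pieces
    if count > len(pieces):
        raise DataError(
            f"requested {count} sub-sequences but only {len(pieces)} are available"
        )
    keep = rng.choice(len(pieces), size=count, replace=False)
    return [pieces[i] for i in sorted(keep)]


# ---------------------------------------------------------------------------
# masked-token task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskPattern:
    """Token offsets to mask, relative to the chosen token (offset 0)."""

    k: int
    offsets: tuple[int, ...]

    @property
    def span_nt(self) -> int:
        """Nucleotides covered by the union of masked tokens (= 2k - 1)."""
        return (max(self.offsets) - min(self.offsets)) + self.k

    @property
    def central_offset_nt(self) -> int:
        """Offset (from the chosen token's first base) of the unique
        nucleotide covered by no unmasked token."""
        central = fully_masked_positions(self)
        assert len(central) == 1
        return central[0]


def fully_masked_positions(pattern: MaskPattern) -> list[int]:
    """Brute-force coverage enumeration: nucleotide offsets (relative to the
    chosen token's first base) covered *only* by masked tokens.

    A nucleotide at offset ``p`` is covered by tokens starting at offsets
    ``p - k + 1 .. p``; it is fully masked iff all those starts are masked.
    """
    k = pattern.k
    masked = set(pattern.offsets)
    lo = min(pattern.offsets)
    hi = max(pattern.offsets) + k - 1
    out = []
    for p in range(lo, hi + 1):
        covering = range(p - k + 1, p + 1)
        if all(c in masked for c in covering):
            out.append(p)
    return out


_CANONICAL_PATTERNS = {
    4: (-1, 0, 1, 2),
    5: (-2, -1, 0, 1, 2),
    6: (-2, -1, 0, 1, 2, 3),
}


def make_mask_pattern(k: int) -> MaskPattern:
    """The per-k mask pattern: ``k`` contiguous token offsets containing 0.

    Canonical patterns exist for k in {4, 5, 6}; other k get the
    symmetric-as-possible generalization (logged).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k in _CANONICAL_PATTERNS:
        offsets = _CANONICAL_PATTERNS[k]
    else:
        lo = -((k - 1) // 2)
        offsets = tuple(range(lo, lo + k))
        logger.info("make_mask_pattern: non-canonical k=%d, using generalized offsets %s", k, offsets)
    return MaskPattern(k=k, offsets=offsets)


@dataclass(frozen=True)
class MaskedSample:
    """One tokenized sub-sequence with the mask pattern applied."""

    k: int
    ids: tuple[int, ...]  # token ids with MASK substituted
    chosen_index: int
    masked_positions: tuple[int, ...]  # token indices that were masked
    truth: tuple[int, ...]  # original token ids at masked_positions

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(p - self.chosen_index for p in self.masked_positions)


def build_masked_dataset(
    subseqs: Sequence[str],
    vocab: KmerVocabulary,
    seed: int = 0,
    pattern: MaskPattern | None = None,
) -> list[MaskedSample]:
    """One :class:`MaskedSample` per sub-sequence (too-short ones are skipped).

    The chosen token is uniform over positions where the whole pattern fits
    with at least one unmasked flanking token on each side, so the central
    nucleotide never touches an unmasked token.
    """
    if pattern is None:
        pattern = make_mask_pattern(vocab.k)
    if pattern.k != vocab.k:
        raise ParameterError(f"pattern k={pattern.k} != vocabulary k={vocab.k}")
    rng = np.random.default_rng(seed)
    lo, hi = min(pattern.offsets), max(pattern.offsets)
    samples: list[MaskedSample] = []
    skipped = 0
    for sub in subseqs:
        if len(sub) < vocab.k:
            skipped += 1
            continue
        toks = tokenize(sub, vocab)
        n = len(toks)
        # chosen index t must satisfy t+lo >= 1 and t+hi <= n-2
        t_min, t_max = 1 - lo, n - 2 - hi
        if t_max < t_min:
            skipped += 1
            continue
        t = int(rng.integers(t_min, t_max + 1))
        positions = tuple(t + o for o in pattern.offsets)
        ids = list(toks.ids)
        truth = tuple(ids[p] for p in positions)
        for p in positions:
            ids[p] = vocab.mask_id
        samples.append(
            MaskedSample(
                k=vocab.k,
                ids=tuple(ids),
                chosen_index=t,
                masked_positions=positions,
                truth=truth,
            )
        )
    if skipped:
        logger.info("build_masked_dataset: skipped %d sub-sequence(s) too short for the pattern", skipped)
    return samples


def write_masked_jsonl(path: str | Path, samples: Iterable[MaskedSample]) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {
                        "k": s.k,
                        "ids": list(s.ids),
                        "chosen_index": s.chosen_index,
                        "masked_positions": list(s.masked_positions),
                        "truth": list(s.truth),
                    }
                )
                + "\n"
            )


def read_masked_jsonl(path: str | Path) -> list[MaskedSample]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        out.append(
            MaskedSample(
                k=d["k"],
                ids=tuple(d["ids"]),
                chosen_index=d["chosen_index"],
                masked_positions=tuple(d["masked_positions"]),
                truth=tuple(d["truth"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# next-k-mer task
# ---------------------------------------------------------------------------

CONTEXT_NT = 50
CHUNK_NT = 510


@dataclass(frozen=True)
class NextKmerSample:
    context: str  # 50 nt
    label: str  # k nt
    label_class: int  # kmer_index(label)


@dataclass(frozen=True)
class NextKmerDataset:
    k: int
    samples: tuple[NextKmerSample, ...]
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    @property
    def train(self) -> list[NextKmerSample]:
        return [self.samples[i] for i in self.train_idx]

    @property
    def test(self) -> list[NextKmerSample]:
        return [self.samples[i] for i in self.test_idx]


def build_next_kmer_dataset(
    seqs: Sequence[GenomeSequence],
    k: int,
    max_samples: int = 500_000,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> NextKmerDataset:
    """Cut 510-nt chunks, take context = nt 0..49 and label = nt 50..50+k-1.

    Chunks are consecutive and non-overlapping within each contig; the
    trailing partial chunk is dropped.  Samples are shuffled under ``seed``,
    capped at ``max_samples`` and split 80/20.
    """
    if k not in (2, 3, 4, 5, 6):
        raise ParameterError(
            f"next-k-mer k must be in 2..6 (a 4**k-class head beyond 6 is impractical), got {k}"
        )
    total_len = sum(len(s) for s in seqs)
    if total_len < CHUNK_NT:
        raise DataError(f"combined sequence length {total_len} < one chunk of {CHUNK_NT} nt")
    samples: list[NextKmerSample] = []
    for s in seqs:
        for start in range(0, len(s.seq) - CHUNK_NT + 1, CHUNK_NT):
            chunk = s.seq[start : start + CHUNK_NT]
            context = chunk[:CONTEXT_NT]
            label = chunk[CONTEXT_NT : CONTEXT_NT + k]
            samples.append(
                NextKmerSample(context=context, label=label, label_class=kmer_index(label))
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))[:max_samples]
    samples = [samples[i] for i in order]
    n = len(samples)
    n_train = int(round(train_fraction * n))
    return NextKmerDataset(
        k=k,
        samples=tuple(samples),
        train_idx=tuple(range(n_train)),
        test_idx=tuple(range(n_train, n)),
    )


def write_next_kmer_tsv(path: str | Path, dataset: NextKmerDataset) -> None:
    rows = []
    split = {i: "train" for i in dataset.train_idx} | {i: "test" for i in dataset.test_idx}
    for i, s in enumerate(dataset.samples):
        rows.append({"context": s.context, "label": s.label, "split": split[i]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_next_kmer_tsv(path: str | Path) -> NextKmerDataset:
    df = pd.read_csv(path, sep="\t")
    samples = tuple(
        NextKmerSample(context=r.context, label=r.label, label_class=kmer_index(r.label))
        for r in df.itertuples()
    )
    k = len(samples[0].label)
    train_idx = tuple(i for i, sp in enumerate(df["split"]) if sp == "train")
    test_idx = tuple(i for i, sp in enumerate(df["split"]) if sp == "test")
    return NextKmerDataset(k=k, samples=samples, train_idx=train_idx, test_idx=test_idx)


# ---------------------------------------------------------------------------
# Prom300 task
# ---------------------------------------------------------------------------

PROMOTER_NT = 300
UPSTREAM_NT = 249  # -249 .. +50 inclusive around the TSS (TSS at offset 0)
DOWNSTREAM_NT = 50


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """(contig, 0-based TSS position, strand) from BED (strand from column 6,
    '+' when absent)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        contig, start = str(row[0]), int(row[1])
        strand = str(row[5]) if len(row) >= 6 and str(row[5]) in "+-" else "+"
        out.append((contig, start, strand))
    return out


def extract_promoter_windows(
    genome: Sequence[GenomeSequence],
    tss: Sequence[tuple[str, int, str]],
) -> list[str]:
    """300-nt windows covering -249..+50 around each TSS, strand-aware.

    Minus-strand windows are reverse-complemented so the TSS-proximal end is
    consistent across strands.  TSS too close to a contig edge are skipped
    with a log entry.
    """
    by_name = {s.name: s.seq for s in genome}
    out: list[str] = []
    skipped = 0
    for contig, pos, strand in tss:
        seq = by_name.get(contig)
        if seq is None:
            skipped += 1
            continue
        if strand == "+":
            lo, hi = pos - UPSTREAM_NT, pos + DOWNSTREAM_NT + 1
            if lo < 0 or hi > len(seq):
                skipped += 1
                continue
            out.append(seq[lo:hi])
        else:
            lo, hi = pos - DOWNSTREAM_NT, pos + UPSTREAM_NT + 1
            if lo < 0 or hi > len(seq):
                skipped += 1
                continue
            out.append(reverse_complement(seq[lo:hi]))
    if skipped:
        logger.info("extract_promoter_windows: skipped %d TSS near contig edges or on unknown contigs", skipped)
    return out


@dataclass(frozen=True)
class PromoterRecord:
    seq: str
    label: str  # "real" | "shuffled"
    shuffled_parts: tuple[int, ...]  # part indices altered; empty for real


def build_prom300_dataset(
    promoters: Sequence[str],
    n_parts: int = 20,
    n_shuffle: int = 15,
    seed: int = 0,
    shuffle_mode: str = "nucleotides",
) -> list[PromoterRecord]:
    """One real and one composition-preserving shuffled record per promoter.

    The 300-nt sequence is divided into ``n_parts`` contiguous equal parts;
    ``n_shuffle`` parts are chosen uniformly at random per record.  Default
    mode permutes nucleotides *within* each chosen part; ``shuffle_mode=
    'parts'`` instead permutes the chosen parts among themselves, leaving
    their internal order intact.  Either way every record keeps its global
    nucleotide multiset, and the default also keeps every part's multiset.
    """
    if n_parts < 1 or PROMOTER_NT % n_parts != 0:
        raise ParameterError(f"n_parts={n_parts} must divide {PROMOTER_NT}")
    if not 0 <= n_shuffle <= n_parts:
        raise ParameterError(f"n_shuffle={n_shuffle} must be in [0, n_parts]")
    if shuffle_mode not in ("nucleotides", "parts"):
        raise ParameterError(f"unknown shuffle_mode {shuffle_mode!r}")
    part_len = PROMOTER_NT // n_parts
    rng = np.random.default_rng(seed)
    records: list[PromoterRecord] = []
    for seq in promoters:
        if len(seq) != PROMOTER_NT:
            raise ParameterError(f"promoter length {len(seq)} != {PROMOTER_NT}")
        records.append(PromoterRecord(seq=seq, label="real", shuffled_parts=()))
        chosen = np.sort(rng.choice(n_parts, size=n_shuffle, replace=False))
        parts = [seq[i * part_len : (i + 1) * part_len] for i in range(n_parts)]
        if shuffle_mode == "nucleotides":
            for i in chosen:
                letters = np.array(list(parts[i]))
                parts[i] = "".join(letters[rng.permutation(part_len)])
        else:
            perm = rng.permutation(n_shuffle)
            originals = [parts[i] for i in chosen]
            for slot, i in enumerate(chosen):
                parts[i] = originals[perm[slot]]
        records.append(
            PromoterRecord(
                seq="".join(parts),
                label="shuffled",
                shuffled_parts=tuple(int(i) for i in chosen),
            )
        )
    return records


def write_prom300_tsv(path: str | Path, records: Iterable[PromoterRecord]) -> None:
    rows = [
        {
            "sequence": r.seq,
            "label": r.label,
            "shuffled_parts": ",".join(map(str, r.shuffled_parts)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_prom300_tsv(path: str | Path) -> list[PromoterRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        parts = tuple(int(x) for x in str(r.shuffled_parts).split(",") if x != "")
        out.append(PromoterRecord(seq=r.sequence, label=r.label, shuffled_parts=parts))
    return out
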