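"""Synthetic genomes and promoter sets with controlled statistical structure.

These generators stand in for a real assembly and promoter annotation at desk
scale.  Three genome modes cover the probing controls:

* ``iid`` — independent draws from a base distribution; no sequence context
  exists, so context-learning readouts must stay at their random baselines.
* ``markov`` — an order-``m`` Markov chain; the next base is predictable from
  the previous ``m``, a learnable short-range context.
* ``periodic`` — an exact tiling of a repeat unit; every position is fully
  determined by phase, the strongest possible context signal.

Synthetic promoters carry a positional signal (planted motif copies at fixed
offsets) that within-part nucleotide shuffling destroys, while base
composition carries no signal by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .tokenization import ALPHABET, GenomeSequence, ParameterError, write_fasta

MAX_MARKOV_ORDER = 5

# Motif composition: A3 T3 C1 G1.  Background frequencies are matched to it so
# that base composition is identical in signal and background positions.
DEFAULT_MOTIF = "TATAATCG"
DEFAULT_MOTIF_OFFSETS = (40, 121, 230)
MOTIF_MATCHED_FREQS = (0.375, 0.125, 0.125, 0.375)  # A, C, G, T


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic contig."""

    mode: str  # {"iid", "markov", "periodic"}
    length: int
    seed: int = 0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    transition: np.ndarray | None = None  # (4**order, 4), rows sum to 1
    order: int = 1
    repeat_unit: str = "ACGT"
    name: str = "synthetic"

    def validate(self) -> None:
        if self.mode not in ("iid", "markov", "periodic"):
            raise ParameterError(f"unknown genome mode {self.mode!r}")
        if self.length < 1:
            raise ParameterError("length must be >= 1")
        if self.mode == "iid":
            f = np.asarray(self.base_freqs, dtype=float)
            if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
                raise ParameterError("iid base_freqs must be 4 non-negative values summing to 1")
        if self.mode == "markov":
            if not 1 <= self.order <= MAX_MARKOV_ORDER:
                raise ParameterError(f"markov order must be in [1, {MAX_MARKOV_ORDER}]")
            t = np.asarray(self.transition, dtype=float) if self.transition is not None else None
            if t is None or t.shape != (4**self.order, 4):
                raise ParameterError(f"transition matrix must have shape ({4**self.order}, 4)")
            if (t < 0).any() or not np.allclose(t.sum(axis=1), 1, atol=1e-9):
                raise ParameterError("transition rows must be non-negative and sum to 1")
        if self.mode == "periodic":
            if not self.repeat_unit or any(c not in ALPHABET for c in self.repeat_unit):
                raise ParameterError("repeat_unit must be a non-empty ACGT string")


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeSequence:
    """Generate one contig according to ``spec`` (deterministic under seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "periodic":
        reps = -(-spec.length // len(spec.repeat_unit))
        seq = (spec.repeat_unit * reps)[: spec.length]
        return GenomeSequence(name=spec.name, seq=seq)
    if spec.mode == "iid":
        bases = rng.choice(4, size=spec.length, p=np.asarray(spec.base_freqs, dtype=float))
        return GenomeSequence(name=spec.name, seq=_decode(bases))
    # markov
    m = spec.order
    trans = np.asarray(spec.transition, dtype=float)
    bases = np.empty(spec.length, dtype=np.int64)
    n_init = min(m, spec.length)
    bases[:n_init] = rng.integers(0, 4, size=n_init)
    state = 0
    for i in range(n_init):
        state = (state * 4 + bases[i]) % (4**m)
    # cumulative rows let us draw with one uniform per step
    cum = trans.cumsum(axis=1)
    u = rng.random(spec.length)
    mod = 4 ** (m - 1)
    for i in range(n_init, spec.length):
        b = int(np.searchsorted(cum[state], u[i], side="right"))
        b = min(b, 3)
        bases[i] = b
        state = (state % mod) * 4 + b
    return GenomeSequence(name=spec.name, seq=_decode(bases))


def _decode(bases: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[bases].tobytes().decode("ascii")


def biased_transition_matrix(order: int = 1, strength: float = 0.85, seed: int = 0) -> np.ndarray:
    """A strongly non-uniform transition matrix with a learnable structure.

    Each state concentrates mass ``strength`` on one preferred next base
    (rotating with the state index) and spreads the rest uniformly.
    """
    if not 0.25 <= strength < 1:
        raise ParameterError("strength must be in [0.25, 1)")
    n = 4**order
    t = np.full((n, 4), (1 - strength) / 3)
    for s in range(n):
        t[s, (s + 1) % 4] = strength
    return t


@dataclass(frozen=True)
class SyntheticPromoterSpec:
    """Plan for promoter-like 300-nt sequences with planted positional signal.

    ``motif`` copies are written at ``motif_offsets`` into an otherwise iid
    background whose base frequencies match the motif's own composition, so
    the only real/shuffled difference is *where* bases sit, never how many.
    """

    n: int
    length: int = 300
    motif: str = DEFAULT_MOTIF
    motif_offsets: tuple[int, ...] = DEFAULT_MOTIF_OFFSETS
    base_freqs: tuple[float, float, float, float] = MOTIF_MATCHED_FREQS
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.length < 1:
            raise ParameterError("length must be >= 1")
        if not self.motif or any(c not in ALPHABET for c in self.motif):
            raise ParameterError("motif must be a non-empty ACGT string")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ParameterError("base_freqs must be 4 non-negative values summing to 1")
        for off in self.motif_offsets:
            if not 0 <= off <= self.length - len(self.motif):
                raise ParameterError(
                    f"motif offset {off} does not fit a {len(self.motif)}-nt motif "
                    f"in a {self.length}-nt sequence"
                )


def generate_promoters(spec: SyntheticPromoterSpec) -> list[str]:
    """Generate ``spec.n`` promoter-like sequences (deterministic under seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.base_freqs, dtype=float)
    out = []
    for _ in range(spec.n):
        bases = rng.choice(4, size=spec.length, p=freqs)
        seq = list(_decode(bases))
        for off in spec.motif_offsets:
            seq[off : off + len(spec.motif)] = spec.motif
        out.append("".join(seq))
    return out


def write_genome_fasta(path: str | Path, spec: SyntheticGenomeSpec) -> GenomeSequence:
    """Generate a genome, write it as FASTA plus a JSON spec echo beside it."""
    genome = generate_genome(spec)
    write_fasta(path, [genome])
    _write_spec_echo(path, spec.__dict__ | {"transition": _jsonable(spec.transition)})
    return genome


def write_promoter_fasta(path: str | Path, spec: SyntheticPromoterSpec) -> list[str]:
    promoters = generate_promoters(spec)
    write_fasta(
        path,
        [GenomeSequence(name=f"promoter_{i}", seq=p) for i, p in enumerate(promoters)],
    )
    _write_spec_echo(path, spec.__dict__)
    return promoters


def write_tss_bed(path: str | Path, contig: str, positions: Sequence[int], strands: Sequence[str]) -> None:
    """BED6 records for synthetic TSS positions (0-based)."""
    with open(path, "w") as fh:
        for i, (pos, strand) in enumerate(zip(positions, strands)):
            fh.write(f"{contig}\t{pos}\t{pos + 1}\ttss_{i}\t0\t{strand}\n")


def _jsonable(x):
    return np.asarray(x).tolist() if x is not None else None


def _write_spec_echo(data_path: str | Path, payload: dict) -> None:
    echo = Path(str(data_path) + ".spec.json")
    clean = {k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()}
    echo.write_text(json.dumps(clean, indent=2, default=str) + "\n")
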