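"""Seeded synthetic benchmark-instance generator.

Follows the standard planted-motif benchmark protocol: n strings of length m
are drawn i.i.d. uniform over the alphabet; a uniform random motif of length
ℓ is chosen; in a uniform random subset of Q = ⌈q·n/100⌉ strings a copy of
the motif — mutated in exactly d distinct positions, each to a uniformly
chosen *different* character — overwrites a uniformly chosen window. All
randomness flows from a single integer seed, so the same seed always yields
byte-identical output.

Coordinates are 0-based half-open windows [j, j+ℓ) throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .kmer_core import DNA, Alphabet
from .seq_io import SequenceSet, write_fasta

__all__ = ["PlantedInstance", "generate_instance", "write_instance"]


@dataclass
class PlantedInstance:
    """A synthetic benchmark instance with its planted ground truth."""

    sequences: SequenceSet
    motif: str
    planted: list[tuple[int, int]]  # (string index, 0-based window start)
    seed: int

    @property
    def n(self) -> int:
        return len(self.sequences)


def generate_instance(
    n: int,
    m: int,
    l: int,
    d: int,
    q: float = 100.0,
    alphabet: Alphabet = DNA,
    seed: int = 0,
) -> PlantedInstance:
    """Generate a planted (ℓ, d) instance with quorum q%.

    Every planted occurrence is at Hamming distance *exactly* d from the
    motif, so the motif is guaranteed to satisfy the motif definition on the
    generated instance (occurrences within d in Q strings).
    """
    if not (0 < l <= m):
        raise ValueError(f"need 0 < l <= m, got l={l}, m={m}")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    if not 0 < q <= 100:
        raise ValueError(f"need q in (0, 100], got {q}")
    if n <= 0:
        raise ValueError(f"need n >= 1, got {n}")
    rng = np.random.default_rng(seed)
    sigma = alphabet.size

    strings = rng.integers(0, sigma, size=(n, m), dtype=np.uint8)
    motif = rng.integers(0, sigma, size=l, dtype=np.uint8)

    Q = int(np.ceil(round(q * n, 9) / 100))
    chosen = np.sort(rng.choice(n, size=Q, replace=False))

    planted: list[tuple[int, int]] = []
    for i in chosen:
        occurrence = motif.copy()
        if d > 0:
            positions = rng.choice(l, size=d, replace=False)
            # shifting by 1..σ−1 (mod σ) guarantees a different character,
            # uniform over the σ−1 alternatives: distance is exactly d
            shifts = rng.integers(1, sigma, size=d, dtype=np.uint8)
            occurrence[positions] = (occurrence[positions] + shifts) % sigma
        start = int(rng.integers(0, m - l + 1))
        strings[i, start : start + l] = occurrence
        planted.append((int(i), start))

    records = [(f"seq_{i}", alphabet.decode(strings[i])) for i in range(n)]
    return PlantedInstance(
        sequences=SequenceSet(records=records, alphabet=alphabet),
        motif=alphabet.decode(motif),
        planted=planted,
        seed=seed,
    )


def write_instance(
    instance: PlantedInstance,
    fasta_path: os.PathLike | str,
    answers_path: os.PathLike | str | None = None,
) -> None:
    """Write the instance as FASTA plus an optional plain-text answer file.

    The answer file holds the motif on line 1, then one
    ``string_index<TAB>position`` line (0-based) per planted occurrence.
    """
    write_fasta(instance.sequences, fasta_path)
    if answers_path is not None:
        with open(answers_path, "w") as handle:
            handle.write(instance.motif + "\n")
            for i, pos in instance.planted:
                handle.write(f"{i}\t{pos}\n")
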