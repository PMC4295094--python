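"""FASTA input/output and the solver's plain-text motif format."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .kmer_core import DNA, Alphabet

__all__ = ["SequenceSet", "read_fasta", "write_fasta", "write_motifs"]

FASTA_LINE_WIDTH = 70


@dataclass
class SequenceSet:
    """Ordered (id, sequence) records over a validated alphabet."""

    records: list[Tuple[str, str]] = field(default_factory=list)
    alphabet: Alphabet = DNA

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def validate(self) -> None:
        for rid, seq in self.records:
            _check_alphabet(rid, seq, self.alphabet)


def _check_alphabet(rid: str, seq: str, alphabet: Alphabet) -> None:
    for pos, char in enumerate(seq, start=1):
        if char not in alphabet:
            raise ValueError(
                f"record {rid!r}: character {char!r} at position {pos} is not "
                f"in the {alphabet.name} alphabet ({alphabet.letters})"
            )


def read_fasta(path: os.PathLike | str, alphabet: Alphabet = DNA) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased; any character outside the alphabet (including
    ambiguity codes such as ``N``) is a hard error naming the record and the
    1-based offending position. An empty file is an error.
    """
    records: list[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _check_alphabet(rec.id, seq, alphabet)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records=records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path: os.PathLike | str) -> None:
    """Write a :class:`SequenceSet` to FASTA, wrapped at 70 columns."""
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=FASTA_LINE_WIDTH)
        writer.write_file(
            SeqRecord(Seq(seq), id=rid, description="") for rid, seq in seqs
        )


def write_motifs(motifs: Iterable[str], path: os.PathLike | str) -> None:
    """Write motifs one per line, uppercase, lexicographically sorted.

    The output is a total order over the (deduplicated) set, so re-running on
    any permutation of the same motifs yields byte-identical files.
    """
    ordered = sorted({m.upper() for m in motifs})
    with open(path, "w") as handle:
        for m in ordered:
            handle.write(m + "\n")
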