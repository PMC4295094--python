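"""Core ℓ-mer machinery: alphabets, Hamming distance, consensus statistics.

The solver reasons about fixed-length words (ℓ-mers) over a finite alphabet.
A tuple of ℓ-mers carries per-column character counts so that its consensus
and consensus total distance can be updated incrementally as members are
pushed and popped during the branch-and-bound search.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "LMer",
    "LMerTuple",
    "hamming",
    "consensus",
    "consensus_total_distance",
    "additional_distance",
]

#: An ℓ-mer is plain text at the API surface; internally words are encoded
#: as uint8 code arrays for vectorised distance computations.
LMer = str


class Alphabet:
    """A finite, ordered character alphabet with uint8 encoding.

    The character order is significant: consensus ties are broken in favour
    of the earliest character, and motif output is sorted in this order
    (which coincides with lexicographic order for the built-in alphabets).
    """

    __slots__ = ("name", "letters", "_lookup", "_letter_bytes")

    def __init__(self, name: str, letters: str):
        if len(set(letters)) != len(letters):
            raise ValueError("alphabet letters must be unique")
        self.name = name
        self.letters = letters
        lookup = np.full(256, 255, dtype=np.uint8)
        for i, c in enumerate(letters):
            lookup[ord(c)] = i
        self._lookup = lookup
        self._letter_bytes = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)

    @property
    def size(self) -> int:
        return len(self.letters)

    def __contains__(self, char: str) -> bool:
        return char in self.letters

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alphabet({self.name!r}, {self.letters!r})"

    def encode(self, s: str) -> np.ndarray:
        """Encode a string to a uint8 code array, raising on foreign characters."""
        raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        codes = self._lookup[raw]
        if codes.max(initial=0) == 255:
            pos = int(np.argmax(codes == 255))
            raise ValueError(
                f"character {s[pos]!r} at position {pos + 1} is not in the "
                f"{self.name} alphabet ({self.letters})"
            )
        return codes

    def decode(self, codes: np.ndarray) -> str:
        return self._letter_bytes[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


DNA = Alphabet("DNA", "ACGT")
PROTEIN = Alphabet("protein", "ACDEFGHIKLMNPQRSTVWY")


def _as_codes(x: Union[str, np.ndarray], alphabet: Alphabet) -> np.ndarray:
    if isinstance(x, str):
        return alphabet.encode(x)
    return np.asarray(x, dtype=np.uint8)


def hamming(u: Union[str, np.ndarray], v: Union[str, np.ndarray]) -> int:
    """Number of positions where two equal-length words differ."""
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} vs {len(v)}")
    if isinstance(u, str) and isinstance(v, str):
        return sum(a != b for a, b in zip(u, v))
    u = np.asarray(u, dtype=np.uint8)
    v = np.asarray(v, dtype=np.uint8)
    return int((u != v).sum())


class LMerTuple:
    """An ordered tuple of equal-length ℓ-mers with per-column counts.

    Supports O(ℓ·|Σ|) push/pop and O(ℓ·|Σ|) queries for the consensus word,
    the consensus total distance Cd, and the additional distance incurred by
    a prospective new member — the quantities driving tuple pruning and the
    string-reordering heuristic of the search engine.
    """

    def __init__(self, members: Iterable[Union[str, np.ndarray]] = (), alphabet: Alphabet = DNA):
        self.alphabet = alphabet
        self._members: list[np.ndarray] = []
        self._counts: np.ndarray | None = None  # (|Σ|, ℓ)
        self._length: int | None = None
        for m in members:
            self.append(m)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return (self.alphabet.decode(m) for m in self._members)

    def __getitem__(self, i: int) -> str:
        return self.alphabet.decode(self._members[i])

    def __repr__(self) -> str:  # pragma: no cover
        return f"LMerTuple({list(self)!r})"

    @property
    def length(self) -> int:
        if self._length is None:
            raise ValueError("empty tuple has no length")
        return self._length

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self)

    @property
    def column_counts(self) -> np.ndarray:
        """(|Σ|, ℓ) character counts per column; rows follow alphabet order."""
        if self._counts is None:
            raise ValueError("empty tuple has no column counts")
        return self._counts.copy()

    def encoded(self) -> np.ndarray:
        """Members stacked as a (k, ℓ) uint8 code matrix."""
        if not self._members:
            raise ValueError("empty tuple")
        return np.vstack(self._members)

    # -- mutation ------------------------------------------------------------

    def append(self, lmer: Union[str, np.ndarray]) -> None:
        codes = _as_codes(lmer, self.alphabet)
        if self._length is None:
            self._length = len(codes)
            self._counts = np.zeros((self.alphabet.size, self._length), dtype=np.int64)
        elif len(codes) != self._length:
            raise ValueError(f"member length {len(codes)} != tuple length {self._length}")
        self._counts[codes, np.arange(self._length)] += 1
        self._members.append(codes)

    def pop(self) -> str:
        codes = self._members.pop()
        self._counts[codes, np.arange(self._length)] -= 1
        return self.alphabet.decode(codes)

    # -- consensus statistics ------------------------------------------------

    def consensus(self) -> str:
        """Per-column majority word; ties go to the earliest alphabet character."""
        if not self._members:
            raise ValueError("consensus of an empty tuple is undefined")
        # argmax returns the first maximum, i.e. the lowest code on a tie
        return self.alphabet.decode(np.argmax(self._counts, axis=0))

    @property
    def cd(self) -> int:
        """Consensus total distance: Σ over columns of (k − max character count).

        Equals the sum of Hamming distances from the consensus word to every
        member, and lower-bounds Σ_i Hd(x, t_i) for *any* word x.
        """
        if not self._members:
            raise ValueError("consensus total distance of an empty tuple is undefined")
        k = len(self._members)
        return int((k - self._counts.max(axis=0)).sum())

    def additional_distance(self, lmer: Union[str, np.ndarray]) -> int:
        """Cd(T ∪ {u}) − Cd(T), from column counts without rebuilding the tuple."""
        if not self._members:
            raise ValueError("additional distance is relative to a nonempty tuple")
        codes = _as_codes(lmer, self.alphabet)
        if len(codes) != self._length:
            raise ValueError(f"length mismatch: {len(codes)} vs {self._length}")
        k = len(self._members)
        colmax = self._counts.max(axis=0)
        pos = np.arange(self._length)
        newmax = np.maximum(colmax, self._counts[codes, pos] + 1)
        cd_new = int(((k + 1) - newmax).sum())
        return cd_new - self.cd


def _coerce(T, alphabet: Alphabet) -> LMerTuple:
    if isinstance(T, LMerTuple):
        return T
    if isinstance(T, str):
        T = (T,)
    return LMerTuple(T, alphabet=alphabet)


def consensus(T, alphabet: Alphabet = DNA) -> str:
    """Consensus word of a tuple of ℓ-mers (see :meth:`LMerTuple.consensus`)."""
    return _coerce(T, alphabet).consensus()


def consensus_total_distance(T, alphabet: Alphabet = DNA) -> int:
    """Consensus total distance Cd(T) (see :attr:`LMerTuple.cd`)."""
    return _coerce(T, alphabet).cd


def additional_distance(T, u: Union[str, np.ndarray], alphabet: Alphabet = DNA) -> int:
    """Cd(T ∪ {u}) − Cd(T)."""
    return _coerce(T, alphabet).additional_distance(u)
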