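"""Exact quorum planted-motif search.

The solver interleaves a sample-driven stage with a pattern-driven stage:
it assembles tuples of ℓ-mers taken from distinct input strings that could
still share a common d-neighborhood (the sample-driven stage), generates the
common d-neighborhood of each surviving tuple (the pattern-driven stage,
:mod:`plantedmotif.neighborhood`), and verifies every candidate against all
input strings. Verification makes the reported set exact by construction;
the tuple-stage filters are necessary conditions only and can merely cost
time, never motifs.

Tuple-stage filters ("alive" ℓ-mers): a word u in a remaining string stays
alive with respect to the current tuple T iff Hd(u, t) ≤ 2d for every member
t and Cd(T ∪ {u}) ≤ (|T| + 1)·d, both implied by the existence of a common
neighbor. After each extension the remaining strings are re-sorted by
decreasing minimum additional consensus distance (ties: fewer alive words,
then original position) so that the most constraining strings are consumed
first. Quorum support: up to n − Q strings may be skipped along any search
path; a string with no alive words is force-skipped while budget remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .kmer_core import DNA, Alphabet, LMerTuple
from .neighborhood import common_neighbors_encoded
from .seq_io import SequenceSet
from .stats import prob_within

__all__ = [
    "MotifParams",
    "MotifSet",
    "solve",
    "is_alive",
    "reorder_strings",
    "gen_tuples",
    "qgen_tuples",
    "verify_candidate",
    "choose_k",
]


@dataclass(frozen=True)
class MotifParams:
    """Search parameters: motif length ℓ, radius d, quorum percentage q."""

    l: int
    d: int
    q: float = 100.0
    alphabet: Alphabet = DNA

    def __post_init__(self):
        if self.l <= 0:
            raise ValueError(f"motif length must be positive, got {self.l}")
        if not 0 <= self.d <= self.l:
            raise ValueError(f"need 0 <= d <= l, got d={self.d}, l={self.l}")
        if not 0 < self.q <= 100:
            raise ValueError(f"need q in (0, 100], got {self.q}")

    def quorum_count(self, n: int) -> int:
        """Q = ⌈q·n/100⌉: minimum number of strings a motif must occur in."""
        return int(ceil(Fraction(str(self.q)) * n / 100))


@dataclass
class MotifSet:
    """Verified motifs plus, per motif and string, the best occurrence.

    ``occurrences[m][i]`` is the leftmost minimum-distance window
    ``(position, distance)`` of motif m in string i, or ``None`` when string
    i has no window within distance d.
    """

    motifs: set[str] = field(default_factory=set)
    occurrences: dict[str, list[Optional[tuple[int, int]]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, m: str) -> bool:
        return m in self.motifs

    def sorted(self) -> list[str]:
        return sorted(self.motifs)


# ---------------------------------------------------------------------------
# encoded helpers


def _encode_windows(seqs: SequenceSet, l: int) -> list[np.ndarray]:
    """Per string, the (m − ℓ + 1, ℓ) matrix of overlapping window codes."""
    out = []
    for rid, seq in seqs:
        if len(seq) < l:
            raise ValueError(f"record {rid!r} is shorter than the motif length {l}")
        codes = seqs.alphabet.encode(seq)
        out.append(np.lib.stride_tricks.sliding_window_view(codes, l).copy())
    return out


def _min_distance(windows: np.ndarray, word: np.ndarray) -> tuple[int, int]:
    """(leftmost argmin, min) Hamming distance of ``word`` over all windows."""
    dist = (windows != word[None, :]).sum(axis=1)
    pos = int(np.argmin(dist))
    return pos, int(dist[pos])


def verify_candidate(
    M: str,
    seqs: SequenceSet,
    params: MotifParams,
) -> tuple[bool, list[Optional[tuple[int, int]]]]:
    """Check a candidate against the motif definition; report best occurrences.

    Returns ``(is_motif, occ)`` where ``is_motif`` is True iff at least
    Q = ⌈q·n/100⌉ strings contain a window within distance d of M, and
    ``occ[i]`` is the leftmost minimum-distance position in string i (as
    ``(position, distance)``) or ``None`` if no window is within d.
    """
    word = params.alphabet.encode(M)
    if len(word) != params.l:
        raise ValueError(f"candidate length {len(word)} != l={params.l}")
    occ: list[Optional[tuple[int, int]]] = []
    hits = 0
    for windows in _encode_windows(seqs, params.l):
        pos, dist = _min_distance(windows, word)
        if dist <= params.d:
            occ.append((pos, dist))
            hits += 1
        else:
            occ.append(None)
    return hits >= params.quorum_count(len(seqs)), occ


def choose_k(
    params: MotifParams, n: int, m: int, user_k: Optional[int] = None
) -> int:
    """Tuple-size heuristic balancing sample- and pattern-driven work.

    Larger tuples shrink common neighborhoods (expected size σ^ℓ·p^k, with
    p the single-window match probability) but multiply the number of tuples
    generated: the j-th member must stay alive against all previous ones, so
    a string of W = m − ℓ + 1 windows contributes roughly W·r^j candidates,
    where r is the probability of a random pair lying within 2d. The
    heuristic estimates the cost of depth k as the cumulative tuple-tree
    size Σ_{j≤k} T_j (T_j = Π_{i<j} W·r^i) plus the pattern-driven work
    T_k·(1 + σ^ℓ·p^k), and returns the smallest k ∈ [1, Q] within 10% of
    the minimum (deeper recursion on real, motif-correlated data is never
    free, so near-ties resolve shallow). For d = 0 the neighborhood is a
    single point and k = 1 is always optimal; when 2d ≥ ℓ the pairwise
    filter is void (r = 1) and the minimum lands on small k, degrading
    gracefully to pattern-driven enumeration. A user-specified k always
    wins.
    """
    Q = params.quorum_count(n)
    if user_k is not None:
        if not 1 <= user_k <= n:
            raise ValueError(f"k must be in [1, {n}], got {user_k}")
        return user_k
    if params.d == 0:
        return 1
    sigma = params.alphabet.size
    p = prob_within(params.l, params.d, sigma)
    r = prob_within(params.l, min(2 * params.d, params.l), sigma)
    space = float(sigma) ** params.l
    W = max(m - params.l + 1, 1)
    costs = []
    tuples, cumulative = 1.0, 0.0
    for k in range(1, Q + 1):
        tuples *= W * r ** (k - 1)
        cumulative += tuples
        costs.append(cumulative + tuples * (1.0 + space * p**k))
    floor = min(costs)
    for k, cost in enumerate(costs, start=1):
        if cost <= 1.1 * floor:
            return k
    return 1  # pragma: no cover - the loop always returns


# ---------------------------------------------------------------------------
# alive-table primitives (public, string-level contracts)


def is_alive(u: str, T: LMerTuple, d: int, *, alphabet: Alphabet = DNA) -> bool:
    """Can T ∪ {u} still have a common d-neighborhood?

    Returns False only on a proof of impossibility under the enabled
    necessary conditions: some member at Hamming distance > 2d from u, or
    Cd(T ∪ {u}) > (|T| + 1)·d. An empty tuple keeps every word alive.
    """
    if len(T) == 0:
        return True
    alphabet = T.alphabet
    codes = alphabet.encode(u)
    members = T.encoded()
    if ((members != codes[None, :]).sum(axis=1) > 2 * d).any():
        return False
    return T.cd + T.additional_distance(codes) <= (len(T) + 1) * d


def reorder_strings(
    T: LMerTuple, alive: Mapping[int, Sequence[str]]
) -> list[int]:
    """Order remaining strings for the next tuple extension.

    Sorts decreasingly by the minimum additional consensus distance over each
    string's alive words; ties go to the string with fewer alive words, then
    to the original string index. Strings with no alive words must be handled
    by the caller (backtrack, or a skip in quorum mode).
    """
    keys = []
    for sid, words in alive.items():
        if not words:
            raise ValueError(f"string {sid} has no alive words; caller must handle")
        min_add = min(T.additional_distance(u) for u in words) if len(T) else 0
        keys.append((-min_add, len(words), sid))
    return [sid for _, _, sid in sorted(keys)]


# ---------------------------------------------------------------------------
# tuple-generation engine


class _Entry:
    """Alive windows of one remaining string, with reordering keys."""

    __slots__ = ("sid", "win", "min_add")

    def __init__(self, sid: int, win: np.ndarray, min_add: int):
        self.sid = sid
        self.win = win
        self.min_add = min_add


class _Engine:
    """Recursive tuple generator over encoded windows.

    Emits every tuple of k alive ℓ-mers from k distinct strings that
    survives the necessary-condition filters, honouring a skip budget of
    n − Q strings for the quorum variant.
    """

    def __init__(
        self,
        l: int,
        d: int,
        sigma: int,
        k: int,
        sink: Callable[[np.ndarray], None],
        reorder: bool = True,
    ):
        self.l = l
        self.d = d
        self.sigma = sigma
        self.k = k
        self.sink = sink
        self.reorder = reorder
        self._pos = np.arange(l)
        self._members: list[np.ndarray] = []
        self._counts = np.zeros((sigma, l), dtype=np.int64)
        self._colmax = np.zeros(l, dtype=np.int64)
        self._cd = 0
        self._stack: list[tuple[np.ndarray, int]] = []

    # -- tuple state --------------------------------------------------------

    def _push(self, t: np.ndarray) -> None:
        self._stack.append((self._colmax, self._cd))
        self._counts[t, self._pos] += 1
        self._colmax = np.maximum(self._colmax, self._counts[t, self._pos])
        self._cd = int((len(self._members) + 1 - self._colmax).sum())
        self._members.append(t)

    def _pop(self) -> None:
        t = self._members.pop()
        self._counts[t, self._pos] -= 1
        self._colmax, self._cd = self._stack.pop()

    def _filter(self, entry: _Entry, t: np.ndarray) -> _Entry:
        """Alive windows of one string after the tuple gained member t."""
        W = entry.win
        W = W[(W != t[None, :]).sum(axis=1) <= 2 * self.d]
        if W.shape[0] == 0:
            return _Entry(entry.sid, W, 0)
        k1 = len(self._members)  # tuple size including t
        newmax = np.maximum(self._colmax[None, :], self._counts[W, self._pos[None, :]] + 1)
        cd_new = ((k1 + 1) - newmax).sum(axis=1)
        keep = cd_new <= (k1 + 1) * self.d
        W = W[keep]
        if W.shape[0] == 0:
            return _Entry(entry.sid, W, 0)
        min_add = int(cd_new[keep].min()) - self._cd
        return _Entry(entry.sid, W, min_add)

    # -- recursion ----------------------------------------------------------

    def run(self, windows: Sequence[np.ndarray], max_skips: int,
            seed: Optional[np.ndarray] = None) -> None:
        remaining = [_Entry(sid, W, 0) for sid, W in enumerate(windows)]
        if seed is None:
            self._rec(remaining, max_skips)
            return
        self._push(seed)
        remaining, skips = self._refilter(remaining, max_skips, seed)
        if skips >= 0:
            self._rec(remaining, skips)
        self._pop()

    def _refilter(
        self, entries: list[_Entry], skips_left: int, t: np.ndarray
    ) -> tuple[list[_Entry], int]:
        """Filter entries against new member t; dead strings consume skips."""
        out = []
        for e in entries:
            fe = self._filter(e, t)
            if fe.win.shape[0] == 0:
                skips_left -= 1
                if skips_left < 0:
                    return [], -1
            else:
                out.append(fe)
        return out, skips_left

    def _rec(self, remaining: list[_Entry], skips_left: int) -> None:
        if len(self._members) == self.k:
            self.sink(np.vstack(self._members))
            return
        if len(remaining) < self.k - len(self._members):
            return
        if self.reorder and self._members:
            remaining = sorted(
                remaining, key=lambda e: (-e.min_add, e.win.shape[0], e.sid)
            )
        head, rest = remaining[0], remaining[1:]
        for row in head.win:
            self._push(row)
            new_rest, skips = self._refilter(rest, skips_left, row)
            if skips >= 0:
                self._rec(new_rest, skips)
            self._pop()
        # skip branch: give up on the head string entirely
        if skips_left > 0:
            self._rec(rest, skips_left - 1)


def _run_tuples(
    seqs: SequenceSet,
    params: MotifParams,
    k: Optional[int],
    sink: Callable[[np.ndarray], None],
    reorder: bool,
    max_skips: Optional[int] = None,
) -> int:
    n = len(seqs)
    Q = params.quorum_count(n)
    kk = choose_k(params, n, min(len(s) for s in seqs.sequences), k)
    kk = min(kk, Q)
    windows = _encode_windows(seqs, params.l)
    if max_skips is None:
        max_skips = n - Q
    engine = _Engine(params.l, params.d, params.alphabet.size, kk, sink, reorder)
    engine.run(windows, max_skips)
    return kk


def gen_tuples(
    seqs: SequenceSet,
    params: MotifParams,
    sink: Callable[[LMerTuple], None],
    k: Optional[int] = None,
    reorder: bool = True,
) -> None:
    """Emit every surviving k-tuple of alive ℓ-mers (no skips: the PMS case)."""
    alphabet = params.alphabet

    def wrap(members: np.ndarray) -> None:
        sink(LMerTuple(list(members), alphabet=alphabet))

    _run_tuples(seqs, params, k, wrap, reorder, max_skips=0)


def qgen_tuples(
    seqs: SequenceSet,
    params: MotifParams,
    sink: Callable[[LMerTuple], None],
    k: Optional[int] = None,
    reorder: bool = True,
) -> None:
    """Quorum tuple generation: up to n − Q strings may be skipped per path."""
    alphabet = params.alphabet

    def wrap(members: np.ndarray) -> None:
        sink(LMerTuple(list(members), alphabet=alphabet))

    _run_tuples(seqs, params, k, wrap, reorder)


# ---------------------------------------------------------------------------
# the solver


class _CandidateCollector:
    """Verifies neighborhood candidates against all strings, with caching."""

    def __init__(self, windows: Sequence[np.ndarray], d: int, Q: int,
                 cache: Optional[dict[bytes, bool]] = None):
        self.windows = windows
        self.d = d
        self.Q = Q
        self.cache: dict[bytes, bool] = {} if cache is None else cache

    def verify(self, word: np.ndarray) -> bool:
        key = word.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        count = 0
        budget = len(self.windows)
        for W in self.windows:
            if (W != word[None, :]).sum(axis=1).min() <= self.d:
                count += 1
                if count >= self.Q:
                    break
            budget -= 1
            if count + budget < self.Q:
                break
        ok = count >= self.Q
        self.cache[key] = ok
        return ok

    def consume(self, members: np.ndarray, sigma: int) -> None:
        for row in common_neighbors_encoded(members, self.d, sigma, suffix_prune=True):
            self.verify(row)

    def motifs(self) -> list[bytes]:
        return [key for key, ok in self.cache.items() if ok]


def solve(
    seqs: SequenceSet,
    params: MotifParams,
    k: Optional[int] = None,
    reorder: bool = True,
    with_occurrences: bool = True,
) -> MotifSet:
    """Exact quorum planted-motif search.

    Reports every ℓ-mer that occurs within Hamming distance d in at least
    ⌈q·n/100⌉ of the input strings. ``k`` overrides the automatic tuple-size
    heuristic; ``reorder`` toggles the string-reordering heuristic (a pure
    performance knob — the motif set is identical either way).
    """
    n = len(seqs)
    Q = params.quorum_count(n)
    windows = _encode_windows(seqs, params.l)
    collector = _CandidateCollector(windows, params.d, Q)

    def sink(members: np.ndarray) -> None:
        collector.consume(members, params.alphabet.size)

    _run_tuples(seqs, params, k, sink, reorder)

    result = MotifSet()
    for key in collector.motifs():
        motif = params.alphabet.decode(np.frombuffer(key, dtype=np.uint8))
        result.motifs.add(motif)
        if with_occurrences:
            _, occ = verify_candidate(motif, seqs, params)
            result.occurrences[motif] = occ
    return result
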