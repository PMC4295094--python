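"""Subproblem decomposition and process-pool execution.

A quorum search over n strings with quorum count Q splits into independent
subproblems P_{i,j} for i = 1..n−Q+1 and j ranging over the windows of
string s_i: P_{i,j} explores candidates anchored at the j-th ℓ-mer of s_i
and looks for Q − 1 further occurrences among s_{i+1}, …, s_n. Every motif
is covered by the subproblem anchored at its first qualifying string, and
each candidate is verified against *all* n strings, so the union of the
subproblem results equals the sequential motif set for any worker count or
scheduling order. Workers pull subproblem chunks from a process pool
(single-machine equivalent of a master/worker scheme).
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .search import (
    MotifParams,
    MotifSet,
    _CandidateCollector,
    _encode_windows,
    _Engine,
    choose_k,
    verify_candidate,
)
from .seq_io import SequenceSet

__all__ = ["Subproblem", "decompose", "solve_subproblem", "run_parallel"]


@dataclass(frozen=True)
class Subproblem:
    """Anchor indices (0-based): window ``window_index`` of string ``string_index``."""

    string_index: int
    window_index: int


def decompose(seqs: SequenceSet, params: MotifParams) -> list[Subproblem]:
    """All subproblems P_{i,j}: i over the first n − Q + 1 strings, j over windows."""
    n = len(seqs)
    Q = params.quorum_count(n)
    subs = []
    for i in range(n - Q + 1):
        width = len(seqs.records[i][1]) - params.l + 1
        for j in range(width):
            subs.append(Subproblem(i, j))
    return subs


class _SubContext:
    """Shared per-process state: encoded windows and solver parameters."""

    def __init__(self, seqs: SequenceSet, params: MotifParams, k: Optional[int],
                 reorder: bool = True):
        self.seqs = seqs
        self.params = params
        self.n = len(seqs)
        self.Q = params.quorum_count(self.n)
        self.k = min(
            choose_k(params, self.n, min(len(s) for s in seqs.sequences), k), self.Q
        )
        self.windows = _encode_windows(seqs, params.l)
        self.reorder = reorder
        # verification verdicts are a function of (candidate, input, d, Q)
        # only, so they are shared across every subproblem in this context
        self.verify_cache: dict[bytes, bool] = {}

    def solve_one(self, sub: Subproblem) -> set[bytes]:
        params = self.params
        i, j = sub.string_index, sub.window_index
        if not 0 <= i <= self.n - self.Q:
            raise ValueError(f"anchor string {i} outside the first n-Q+1 strings")
        seed = self.windows[i][j]
        remaining = self.windows[i + 1 :]
        max_skips = (self.n - i - 1) - (self.Q - 1)
        collector = _CandidateCollector(
            self.windows, params.d, self.Q, cache=self.verify_cache
        )
        engine = _Engine(
            params.l,
            params.d,
            params.alphabet.size,
            self.k,
            lambda members: collector.consume(members, params.alphabet.size),
            reorder=self.reorder,
        )
        engine.run(remaining, max_skips, seed=seed)
        return set(collector.motifs())


def solve_subproblem(
    seqs: SequenceSet,
    params: MotifParams,
    sub: Subproblem,
    k: Optional[int] = None,
) -> set[str]:
    """Verified motifs found by one subproblem (for tests and debugging)."""
    ctx = _SubContext(seqs, params, k)
    return {params.alphabet.decode(np.frombuffer(b, dtype=np.uint8))
            for b in ctx.solve_one(sub)}


_WORKER_CTX: _SubContext | None = None


def _worker_init(seqs: SequenceSet, params: MotifParams, k: Optional[int]) -> None:
    global _WORKER_CTX
    _WORKER_CTX = _SubContext(seqs, params, k)


def _worker_run(chunk: Sequence[Subproblem]) -> set[bytes]:
    found: set[bytes] = set()
    for sub in chunk:
        found |= _WORKER_CTX.solve_one(sub)
    return found


def run_parallel(
    seqs: SequenceSet,
    params: MotifParams,
    subproblems: Optional[Sequence[Subproblem]] = None,
    workers: int = 1,
    k: Optional[int] = None,
    with_occurrences: bool = True,
) -> MotifSet:
    """Solve by scheduling subproblems over ``workers`` processes.

    The returned motif set is identical to the sequential result for any
    worker count; motifs reachable from several subproblems are reported
    once. A worker failure propagates as an exception.
    """
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    if subproblems is None:
        subproblems = decompose(seqs, params)
    found: set[bytes] = set()
    if workers == 1 or len(subproblems) <= 1:
        if subproblems:
            ctx = _SubContext(seqs, params, k)
            for sub in subproblems:
                found |= ctx.solve_one(sub)
    else:
        chunks = [list(subproblems[i::workers * 4]) for i in range(workers * 4)]
        chunks = [c for c in chunks if c]
        try:
            mp_ctx = mp.get_context("fork")
        except ValueError:  # pragma: no cover - non-POSIX fallback
            mp_ctx = mp.get_context("spawn")
        with mp_ctx.Pool(
            workers, initializer=_worker_init, initargs=(seqs, params, k)
        ) as pool:
            for part in pool.map(_worker_run, chunks):
                found |= part
    result = MotifSet()
    for key in found:
        motif = params.alphabet.decode(np.frombuffer(key, dtype=np.uint8))
        result.motifs.add(motif)
        if with_occurrences:
            _, occ = verify_candidate(motif, seqs, params)
            result.occurrences[motif] = occ
    return result
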