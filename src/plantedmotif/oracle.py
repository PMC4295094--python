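"""Brute-force reference solver.

Enumerates the entire word space Σ^ℓ and applies the motif definition
literally to each candidate: count the strings with some window within
Hamming distance d, report the candidate iff the count reaches the quorum
Q = ⌈q·n/100⌉. No tuples, no neighborhoods, no pruning — deliberately
disjoint from the optimized search path so it can serve as ground truth in
the exactness test suites. Usable only while σ^ℓ is small.
"""

from __future__ import annotations

import numpy as np

from .search import MotifParams, MotifSet, _encode_windows, verify_candidate
from .seq_io import SequenceSet

__all__ = ["brute_solve", "MAX_SPACE"]

MAX_SPACE = 10**7


def _all_words(l: int, sigma: int) -> np.ndarray:
    """Every word of Σ^ℓ as a (σ^ℓ, ℓ) code matrix, in lexicographic order."""
    grids = np.meshgrid(*([np.arange(sigma, dtype=np.uint8)] * l), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def brute_solve(
    seqs: SequenceSet, params: MotifParams, with_occurrences: bool = False
) -> MotifSet:
    """Solve by exhausting Σ^ℓ; refuses spaces larger than ``MAX_SPACE``."""
    sigma = params.alphabet.size
    space = sigma**params.l
    if space > MAX_SPACE:
        raise ValueError(
            f"candidate space sigma^l = {space} exceeds {MAX_SPACE}; "
            "the brute-force oracle is for small instances only — "
            "use plantedmotif.search.solve instead"
        )
    n = len(seqs)
    Q = params.quorum_count(n)
    candidates = _all_words(params.l, sigma)
    hits = np.zeros(candidates.shape[0], dtype=np.int64)
    chunk = 1 << 13  # bound the (chunk, windows, l) broadcast to tens of MB
    for windows in _encode_windows(seqs, params.l):
        for start in range(0, space, chunk):
            block = candidates[start : start + chunk]
            # min over windows of the Hamming distance of every candidate
            dist = (block[:, None, :] != windows[None, :, :]).sum(axis=2).min(axis=1)
            hits[start : start + chunk] += dist <= params.d
    result = MotifSet()
    for row in candidates[hits >= Q]:
        motif = params.alphabet.decode(row)
        result.motifs.add(motif)
        if with_occurrences:
            _, occ = verify_candidate(motif, seqs, params)
            result.occurrences[motif] = occ
    return result
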