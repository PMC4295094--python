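"""Common d-neighborhood generation for tuples of ℓ-mers.

The common d-neighborhood of a tuple T = (t_1, …, t_k) is the intersection of
the Hamming balls of radius d around the members: every word M with
Hd(M, t_i) ≤ d for all i. It is generated by traversing the Σ-ary tree of
word prefixes level by level; a prefix is abandoned as soon as a necessary
condition proves that no completion can be a common neighbor. All pruning
conditions are *necessary* conditions, so the returned set is exact
regardless of which optional prunes are enabled; prunes only change the
number of tree nodes visited.

Pruning conditions:

* (always) per-member prefix distance: Hd(prefix, t_i[:r]) ≤ d for every i;
* (pre-traversal) pairwise Hd(t_i, t_j) ≤ 2d and Cd(T) ≤ k·d, both implied
  by the existence of any common neighbor;
* (optional, ``suffix_prune``) consensus suffix bound:
  Σ_i Hd(prefix, t_i[:r]) + Cd(suffix columns of T) ≤ k·d — the left side
  lower-bounds the total distance of any completion to the tuple.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Union

import numpy as np

from .kmer_core import DNA, Alphabet, LMerTuple

__all__ = [
    "NodeCounter",
    "common_neighborhood",
    "single_neighborhood_size",
    "prefix_prunable",
]


@dataclass
class NodeCounter:
    """Counts tree nodes expanded during a traversal (for prune diagnostics)."""

    nodes: int = 0


def single_neighborhood_size(l: int, d: int, sigma: int) -> int:
    """|Hamming ball of radius d| around one ℓ-mer: Σ_{i=0..d} C(ℓ,i)(σ−1)^i."""
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    return sum(comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


def _tuple_stats(members: np.ndarray, sigma: int):
    """Column counts, per-column max count, and Cd for a (k, ℓ) code matrix."""
    k, l = members.shape
    counts = np.zeros((sigma, l), dtype=np.int64)
    np.add.at(counts, (members, np.arange(l)[None, :].repeat(k, axis=0)), 1)
    colmax = counts.max(axis=0)
    cd = int((k - colmax).sum())
    return counts, colmax, cd


def common_neighbors_encoded(
    members: np.ndarray,
    d: int,
    sigma: int,
    *,
    suffix_prune: bool = False,
    counter: NodeCounter | None = None,
) -> np.ndarray:
    """Exact common d-neighborhood of a (k, ℓ) code matrix as an (N, ℓ) matrix.

    Rows are produced in lexicographic code order. This is the vectorised
    engine behind :func:`common_neighborhood`; the search module calls it
    directly on encoded tuples.
    """
    members = np.asarray(members, dtype=np.uint8)
    k, l = members.shape
    if k == 0:
        raise ValueError("common neighborhood of an empty tuple is the whole space; refusing")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")

    empty = np.empty((0, l), dtype=np.uint8)
    # pre-traversal necessary conditions
    for i in range(k):
        if ((members[i + 1 :] != members[i]).sum(axis=1) > 2 * d).any():
            return empty
    _, colmax, cd = _tuple_stats(members, sigma)
    if cd > k * d:
        return empty
    # Cd restricted to columns r.. (suffix consensus lower bound)
    percol = (k - colmax).astype(np.int64)
    cd_suffix = np.zeros(l + 1, dtype=np.int64)
    cd_suffix[:l] = percol[::-1].cumsum()[::-1]

    sig = np.arange(sigma, dtype=np.int16)
    prefixes = np.zeros((1, 0), dtype=np.uint8)
    dist = np.zeros((1, k), dtype=np.int16)
    for r in range(l):
        chars = members[:, r].astype(np.int16)
        # (F, σ, k): distance of each one-character extension to each member prefix
        cand = dist[:, None, :] + (sig[None, :, None] != chars[None, None, :])
        ok = (cand <= d).all(axis=2)
        if suffix_prune:
            ok &= cand.sum(axis=2) + cd_suffix[r + 1] <= k * d
        fi, ci = np.nonzero(ok)
        if fi.size == 0:
            return empty
        if counter is not None:
            counter.nodes += int(fi.size)
        prefixes = np.concatenate(
            [prefixes[fi], ci[:, None].astype(np.uint8)], axis=1
        )
        dist = cand[fi, ci]
    return prefixes


def _coerce_tuple(T, alphabet: Alphabet) -> LMerTuple:
    if isinstance(T, LMerTuple):
        return T
    if isinstance(T, str):
        T = (T,)
    return LMerTuple(T, alphabet=alphabet)


def common_neighborhood(
    T: Union[LMerTuple, Iterable[str]],
    d: int,
    *,
    alphabet: Alphabet = DNA,
    suffix_prune: bool = False,
    counter: NodeCounter | None = None,
) -> set[str]:
    """All ℓ-mers within Hamming distance d of every member of T.

    ``suffix_prune`` enables the consensus suffix bound (off by default); it
    never changes the result, only the number of nodes explored, which can be
    observed through ``counter``.
    """
    tup = _coerce_tuple(T, alphabet)
    if len(tup) == 0:
        raise ValueError("common neighborhood of an empty tuple is the whole space; refusing")
    alphabet = tup.alphabet
    rows = common_neighbors_encoded(
        tup.encoded(), d, alphabet.size, suffix_prune=suffix_prune, counter=counter
    )
    return {alphabet.decode(row) for row in rows}


def prefix_prunable(
    prefix: str,
    T: Union[LMerTuple, Iterable[str]],
    d: int,
    *,
    alphabet: Alphabet = DNA,
    suffix_prune: bool = False,
) -> bool:
    """True only if no extension of ``prefix`` can be a common d-neighbor of T.

    The minimal test is the per-member prefix distance; with ``suffix_prune``
    the consensus suffix bound is applied as well. Both are necessary
    conditions, so a ``True`` verdict is always safe to prune on.
    """
    tup = _coerce_tuple(T, alphabet)
    alphabet = tup.alphabet
    members = tup.encoded()
    k, l = members.shape
    codes = alphabet.encode(prefix)
    r = len(codes)
    if r > l:
        raise ValueError(f"prefix longer than tuple words ({r} > {l})")
    pd = (members[:, :r] != codes[None, :]).sum(axis=1)
    if (pd > d).any():
        return True
    if suffix_prune:
        _, colmax, _ = _tuple_stats(members, alphabet.size)
        cd_suffix = int((k - colmax)[r:].sum())
        if int(pd.sum()) + cd_suffix > k * d:
            return True
    return False
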