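"""Spurious-motif statistics and challenging-instance tables.

Under the i.i.d. benchmark model, an (ℓ, d) instance with quorum q admits
"spurious" motifs — words that satisfy the motif definition purely by
chance. The expected number of such words is approximated by the standard
independence chain

    p(ℓ, d, σ)      = |B_d(ℓ)| / σ^ℓ          (random word within d of another)
    P(p, m, ℓ)      = 1 − (1 − p)^(m − ℓ + 1) (within d of some window of a string)
    Q(P, n, Q)      = Σ_{j=Q..n} C(n,j) P^j (1 − P)^(n−j)   (quorum tail)
    E[#motifs]      = σ^ℓ · Q

where |B_d(ℓ)| = Σ_{i=0..d} C(ℓ,i)(σ−1)^i is the Hamming ball size. An
instance is *challenging* when d is the largest radius keeping E[#motifs]
below a constant (500 by convention). Ball sizes and σ^ℓ are kept as exact
integers (σ^ℓ overflows 64 bits for protein words); floating point enters
only at the final probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, comb
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binom

__all__ = [
    "InstanceModel",
    "hamming_ball_size",
    "prob_within",
    "prob_string",
    "prob_quorum",
    "expected_motifs",
    "max_challenging_d",
    "challenging_table",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 500.0


@dataclass(frozen=True)
class InstanceModel:
    """Benchmark-instance model: n strings of length m, motif (ℓ, d), quorum q%."""

    n: int
    m: int
    l: int
    d: int
    q: float = 100.0
    sigma: int = 4

    def __post_init__(self):
        if not (0 < self.l <= self.m):
            raise ValueError(f"need 0 < l <= m, got l={self.l}, m={self.m}")
        if not (0 <= self.d <= self.l):
            raise ValueError(f"need 0 <= d <= l, got d={self.d}, l={self.l}")
        if not (0 < self.q <= 100):
            raise ValueError(f"need q in (0, 100], got {self.q}")
        if self.n <= 0 or self.sigma <= 1:
            raise ValueError("need n >= 1 and sigma >= 2")

    @property
    def quorum_count(self) -> int:
        """Q = ⌈q·n/100⌉, the minimum number of strings a motif must occur in."""
        return ceil(round(self.q * self.n, 9) / 100)


def hamming_ball_size(l: int, d: int, sigma: int) -> int:
    """Exact |{v : Hd(u, v) ≤ d}| = Σ_{i=0..d} C(ℓ,i)(σ−1)^i, as a Python int."""
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    return sum(comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


def prob_within(l: int, d: int, sigma: int) -> float:
    """Probability that a uniform random ℓ-mer lies within distance d of a fixed one."""
    return hamming_ball_size(l, d, sigma) / sigma**l


def prob_string(p: float, m: int, l: int) -> float:
    """Probability of a match within d to some window of a random length-m string.

    Treats the m − ℓ + 1 windows as independent (the standard approximation):
    P = 1 − (1 − p)^(m − ℓ + 1); for m = ℓ this reduces to p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    if m < l:
        raise ValueError(f"need m >= l, got m={m}, l={l}")
    return 1.0 - (1.0 - p) ** (m - l + 1)


def prob_quorum(P: float, n: int, Q: int) -> float:
    """Upper binomial tail: probability of matching at least Q of n strings."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must be a probability, got {P}")
    if not 1 <= Q <= n:
        raise ValueError(f"need 1 <= Q <= n, got Q={Q}, n={n}")
    return float(binom.sf(Q - 1, n, P))


def expected_motifs(model: InstanceModel) -> float:
    """Expected number of spurious motifs: σ^ℓ times the quorum tail probability."""
    p = prob_within(model.l, model.d, model.sigma)
    P = prob_string(p, model.m, model.l)
    return model.sigma**model.l * prob_quorum(P, model.n, model.quorum_count)


def max_challenging_d(
    l: int,
    q: float = 100.0,
    n: int = 20,
    m: int = 600,
    sigma: int = 4,
    threshold: float = DEFAULT_THRESHOLD,
) -> int | None:
    """Largest d with expected spurious-motif count ≤ threshold, or None.

    E[#motifs] is nondecreasing in d, so the scan stops at the first
    exceedance. ``None`` signals that even d = 0 yields more than
    ``threshold`` expected motifs (no challenging radius exists).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    best: int | None = None
    for d in range(l + 1):
        if expected_motifs(InstanceModel(n=n, m=m, l=l, d=d, q=q, sigma=sigma)) <= threshold:
            best = d
        else:
            break
    return best


def challenging_table(
    l_range: Iterable[int],
    q_list: Sequence[float] = (50.0, 75.0, 100.0),
    n: int = 20,
    m: int = 600,
    sigma: int = 4,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Challenging radii as a table: one row per ℓ, one column per quorum q."""
    rows = {}
    for l in l_range:
        rows[l] = [max_challenging_d(l, q, n, m, sigma, threshold) for q in q_list]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"q{int(q)}" for q in q_list]
    )
    df.index.name = "L"
    return df
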