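# Methods

## Problem

Given sequences s_1..s_n over an alphabet Σ (DNA `ACGT` or the 20 standard
amino acids) and integers ℓ, d, q, the solver reports every ℓ-mer
M ∈ Σ^ℓ such that at least Q = ⌈q·n/100⌉ sequences contain a window within
Hamming distance d of M. The ceiling implements "at least q%". q = 100
gives the classic planted-motif problem. The output is the exact set: no
heuristics, no false positives, no misses.

## Solver

**Sample-driven stage.** Tuples T = (t_1, …, t_k) of ℓ-mers from k distinct
sequences are grown recursively. An ℓ-mer u of a remaining sequence is
*alive* with respect to T when the necessary conditions for
T ∪ {u} to retain a common d-neighborhood hold:

* Hd(u, t) ≤ 2d for every member t (triangle inequality through any common
  neighbor), and
* Cd(T ∪ {u}) ≤ (|T| + 1)·d, where Cd is the consensus total distance —
  the sum of Hamming distances from the per-column majority word to the
  members, which lower-bounds Σᵢ Hd(x, tᵢ) for every word x.

These are necessary, not sufficient: a false "alive" verdict costs time
only, because of final verification. Conversely no true occurrence of a
motif is ever filtered, which gives completeness. Exact
common-neighborhood-existence conditions for pairs/triples exist in the
literature; this implementation deliberately restricts itself to the
locally provable conditions above and relies on oracle tests for the rest.

Cd is maintained incrementally: a tuple carries per-column character counts,
so appending or removing a member and computing the *additional distance*
Cd(T ∪ {u}) − Cd(T) of a candidate are O(ℓ·|Σ|), and the additional
distances of all windows of a sequence are computed in one vectorised pass.

**Sequence reordering.** After each extension the remaining sequences are
re-sorted decreasingly by the minimum additional distance over their alive
ℓ-mers; ties prefer the sequence with fewer alive ℓ-mers, then the original
position. Diversity in the tuple shrinks common neighborhoods, so consuming
the most constraining sequence first prunes the tuple tree earlier. The
ordering is a pure performance device — the test suite asserts the motif
set is identical with reordering disabled.

**Quorum support.** Along any search path up to n − Q sequences may be
*skipped*: the skip branch is explored after the ℓ-mer branches of the
current sequence, and a sequence left with zero alive ℓ-mers is
force-skipped while budget remains (no word of it can host any motif
compatible with T, so the sequence cannot contribute to the quorum). When
the budget is exhausted the branch dies. k counts selected members only,
never skips.

**Pattern-driven stage.** Each complete k-tuple's common d-neighborhood
∩ᵢ B_d(tᵢ) is generated by traversing the Σ-ary tree of word prefixes
level by level; the whole frontier advances one position per step as a
numpy batch. A prefix survives when every per-member prefix distance is
≤ d, and (in the solver's traversals) when the consensus suffix bound
Σᵢ Hd(prefix, tᵢ[:r]) + Cd(suffix columns) ≤ k·d holds. All prunes are
necessary conditions, so the enumerated set is exact; equivalence with
exhaustive filtering of Σ^ℓ is tested on random tuples. In the public API
the suffix bound is opt-in, and a node counter exposes how much each prune
saves.

**Verification.** Every candidate from every neighborhood is checked
against all n sequences (vectorised min-distance per sequence, with early
exit on reaching Q or on infeasibility), memoised across tuples. This makes
correctness independent of any tuple-stage subtlety. Reported occurrences
are the leftmost minimum-distance window per sequence.

**Tuple size k.** Deeper tuples shrink neighborhoods but multiply the
tuple tree, so the default k balances the two stages explicitly. With
p = |B_d(ℓ)|/σ^ℓ the single-window match probability and
r = |B_{2d}(ℓ)|/σ^ℓ the probability that a random pair survives the
pairwise alive filter, the expected number of depth-j tuples from strings
of W = m − ℓ + 1 windows is T_j ≈ Π_{i<j} W·r^i, and the cost of depth k is
modelled as Σ_{j≤k} T_j + T_k·(1 + σ^ℓ·p^k). The solver uses the smallest
k ∈ [1, Q] within 10% of the model's minimum (near-ties resolve shallow:
deeper recursion is never free on real, motif-correlated data). This gives
k = 3 for the DNA benchmark instances (13,4)–(17,6), k = 1 when d = 0
(point neighborhood) and when 2d ≥ ℓ (the pairwise filter is void, so the
search degrades gracefully to pattern-driven enumeration). A user-supplied
k always wins.

## Spurious-motif statistics

The expected number of chance motifs in the i.i.d. model is approximated by

    p = |B_d(ℓ)| / σ^ℓ,     |B_d(ℓ)| = Σ_{i=0..d} C(ℓ,i)(σ−1)^i
    P = 1 − (1 − p)^(m−ℓ+1)
    E[#motifs] = σ^ℓ · Σ_{j=Q..n} C(n,j) P^j (1−P)^(n−j)

treating windows within a string, and strings, as independent. The window
count is m − ℓ + 1, so P reduces to p at m = ℓ. Ball sizes and σ^ℓ are
exact Python integers (20^30 overflows any machine word); floats enter only
at the final probabilities, and the binomial tail is `scipy.stats.binom.sf`.
The *challenging* radius for ℓ is the largest d with E[#motifs] ≤ 500;
E is nondecreasing in d, so the scan stops at the first exceedance, and a
length with no admissible radius returns an explicit `None`. These
closed-form approximations are exactly the quantities the acceptance script
recomputes.

## Benchmark generator

`generate_instance(n, m, ℓ, d, q, alphabet, seed)` draws n i.i.d.-uniform
strings of length m and a uniform random motif, picks a uniform subset of
Q = ⌈q·n/100⌉ strings, and overwrites a uniformly placed window in each
with a copy of the motif mutated in exactly d distinct positions (each
mutated character uniform over the σ − 1 alternatives, implemented as a
nonzero cyclic shift). Consequences used by the tests: every planted
occurrence is at distance exactly d, so the planted motif always satisfies
the definition and must appear in the solver output; and with the same seed
the instance is byte-identical. A planted window may by chance resemble
background — there is no rejection sampling, matching the plain protocol.
The generator emulates composition-neutral random sequence only: real
promoter regions have skewed composition, repeats and positional bias, so
recovery on these instances demonstrates algorithmic exactness, not
biological sensitivity.

All coordinates are 0-based half-open windows [j, j+ℓ).

## Parallel decomposition

A run splits into subproblems P_{i,j}, i ≤ n − Q + 1: anchor the tuple at
window j of sequence i and search sequences i+1..n for the remaining
members, with skip budget (n − i − 1) − (Q − 1). A motif occurring in
string set O (|O| ≥ Q) is found by the subproblem anchored at its first
occurrence in min(O) ≤ n − Q + 1, so the union over subproblems — each
candidate still verified against all n sequences — equals the sequential
result; duplicates collapse at aggregation. Subproblems are distributed in
interleaved chunks over a `multiprocessing` pool (pull-style scheduling on
one machine); worker failures propagate. Determinism needs no seeds — the
search itself is deterministic.

## Sizes, tolerances, degenerate inputs

* Exactness is tested by cross-validating solver, permuted-input solver,
  and the 1- and 4-worker pool driver against the brute-force oracle on 200
  random instances (n ≤ 5, m ≤ 40, ℓ ≤ 7, d ≤ 3, q ∈ {50, 75, 100});
  the oracle refuses σ^ℓ > 10^7.
* Planted recovery is exercised at (13,4) and (15,5) with n = 20 and
  m = 200 — the standard protocol at a reduced string length, chosen so the
  whole check stays in the minutes range; 5 seeds per setting.
* Probability comparisons in tests use exact integers where the quantity is
  integral (ball sizes, table cells) and tight float tolerances (≈10⁻⁹
  relative) elsewhere; the challenging tables are asserted cell-for-cell as
  integers.
* Degenerate cases pinned by tests: d = 0 (neighborhood is a point), d = ℓ
  (every word qualifies), a single input string, strings shorter than ℓ
  (error), empty motif set (empty output file), empty tuple (error for
  consensus/neighborhood — the neighborhood of nothing would be Σ^ℓ).
* Consensus ties break toward the earliest alphabet character, making
  `consensus()` deterministic; Cd itself is tie-invariant.

## Known limitations

* Runtime is not competitive with tuned C implementations; the aim is an
  exact, testable, vectorised reference. Large protein radii with k = 1
  can allocate neighborhood frontiers in the hundreds of millions of words.
* The independence approximations in the statistics module ignore window
  overlap; they are the field's standard instrument for sizing benchmarks,
  not exact motif-count distributions.
* Single-machine parallelism only; no checkpointing.
* One motif per generated instance; i.i.d. background only (no Markov
  models).
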