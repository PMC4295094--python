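# plantedmotif

Exact quorum planted (ℓ, d) motif search for DNA and protein sequences.

Motif discovery — finding short, imperfectly conserved patterns such as
transcription-factor binding sites across a set of unaligned sequences — is
commonly formalised as the *planted (ℓ, d) motif search* (PMS) problem:
given n sequences over an alphabet Σ and integers ℓ and d, report every
ℓ-mer M ∈ Σ^ℓ that occurs in **each** input sequence with at most d
mismatches per occurrence. The *quorum* variant (qPMS) relaxes "each" to
"at least q% of the sequences" (Q = ⌈q·n/100⌉ sequences); PMS is qPMS at
q = 100%. Both problems are NP-hard, so exact solvers live or die by their
pruning.

This package provides, for people benchmarking or applying exact motif
search:

- **`plantedmotif.search`** — an exact branch-and-bound solver. It
  interleaves a *sample-driven* stage (tuples of ℓ-mers drawn from distinct
  sequences, filtered by necessary conditions for a shared neighborhood:
  pairwise Hd ≤ 2d and the consensus total distance bound Cd(T) ≤ |T|·d)
  with a *pattern-driven* stage (enumeration of the common d-neighborhood
  ∩ᵢ B_d(tᵢ) of each surviving tuple). Remaining sequences are re-sorted
  after each extension by decreasing minimum additional consensus distance,
  which shrinks the tuple tree; up to n − Q sequences may be skipped along a
  search path for the quorum case. Every candidate is verified against the
  definition, so the output is exact.
- **`plantedmotif.stats`** — the spurious-motif probability chain
  p = |B_d(ℓ)|/σ^ℓ, P = 1 − (1 − p)^(m−ℓ+1), quorum tail
  Σ_{j≥Q} C(n,j)P^j(1−P)^(n−j), and E[#motifs] = σ^ℓ·tail, used to tabulate
  *challenging instances*: the largest d per ℓ with at most 500 expected
  chance motifs.
- **`plantedmotif.datagen`** — the standard seeded benchmark generator
  (i.i.d. strings; a random motif mutated in *exactly* d positions planted
  in q% of the strings).
- **`plantedmotif.oracle`** — a brute-force reference solver for small
  word spaces, kept deliberately independent of the optimized code path.
- **`plantedmotif.parallel`** — decomposition into independent subproblems
  P_{i,j} (anchor window j of sequence i) scheduled over a process pool;
  the result set is identical for any worker count.

## Worked example

```
$ python examples/quorum_search.py
planted motif GACTCTCT in strings [2, 4, 6, 8, 9] (5 of 10)
q=100.0%:   0 motif(s); planted motif found: False
q= 50.0%:   1 motif(s); planted motif found: True
```

A motif planted in half of 10 strings is invisible to a full-quorum search
and exactly recovered at q = 50%. At benchmark scale
(`examples/find_planted_motif.py`, 20 strings of length 200, motif length
13 mutated in exactly 4 positions per occurrence):

```
planted motif: GTTTCGGGATTGG
planted in 20 of 20 strings

solver reported 1 motif(s):
  GTTTCGGGATTGG (planted): occurs in 20 strings, e.g. string 0 at position 95 with 4 mismatches
```

One motif is reported — the planted one — because at (13, 4) only ≈ 5
chance motifs are expected in the full m = 600 model (fewer still at
m = 200), so the output is not flooded by noise. That calculation is the
challenging-instance statistic (`examples/challenging_instances.py`):

```
expected chance motifs, DNA n=20 m=600 q=100%:
  (13,3):    8.141e-16
  (13,4):        5.233
  (13,5):     3.24e+07
  -> d=4 is the largest radius below the 500 bound
```

## Command line

```
plantedmotif generate -n 20 -m 600 -l 13 -d 4 -q 100 --seed 1 -o inst.fa --answers inst.answers
plantedmotif solve -l 13 -d 4 -q 100 -t 4 -o motifs.txt inst.fa
plantedmotif oracle -l 5 -d 1 -o motifs_check.txt small.fa
plantedmotif table            # DNA challenging-instance table as TSV
plantedmotif table --protein
```

`solve` writes one motif per line, sorted; run parameters and counts go to
standard error. `oracle` accepts the same flags and must produce
byte-identical output on any instance small enough for it to handle.

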