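"""Quorum search: find motifs present in only a fraction of the strings.

Plants a motif in 50% of 10 strings and compares the q=100% search (which
cannot find it) with the q=50% search (which can). Relaxing the quorum can
only enlarge the motif set.
"""

from plantedmotif import MotifParams, generate_instance, solve

instance = generate_instance(n=10, m=60, l=8, d=1, q=50.0, seed=7)
print(f"planted motif {instance.motif} in strings "
      f"{sorted(i for i, _ in instance.planted)} (5 of 10)")

for q in (100.0, 50.0):
    result = solve(instance.sequences, MotifParams(l=8, d=1, q=q))
    found = instance.motif in result.motifs
    print(f"q={q:5.1f}%: {len(result):3d} motif(s); planted motif found: {found}")
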