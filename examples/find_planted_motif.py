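"""Generate a benchmark-style planted instance and recover the motif.

Builds 20 random DNA strings of length 200, plants a random 13-mer mutated
in exactly 4 positions into every string, then runs the exact solver. The
printed motif list should contain the planted motif (and, rarely, a few
chance motifs); each motif is reported with its best occurrence per string.
"""

from plantedmotif import MotifParams, generate_instance, solve

instance = generate_instance(n=20, m=200, l=13, d=4, q=100.0, seed=42)
print(f"planted motif: {instance.motif}")
print(f"planted in {len(instance.planted)} of {instance.n} strings")

params = MotifParams(l=13, d=4, q=100.0)
result = solve(instance.sequences, params)

print(f"\nsolver reported {len(result)} motif(s):")
for motif in result.sorted():
    occ = result.occurrences[motif]
    hits = [(i, pos, dist) for i, o in enumerate(occ) if o is not None for pos, dist in [o]]
    tag = " (planted)" if motif == instance.motif else ""
    print(f"  {motif}{tag}: occurs in {len(hits)} strings, "
          f"e.g. string {hits[0][0]} at position {hits[0][1]} with {hits[0][2]} mismatches")
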