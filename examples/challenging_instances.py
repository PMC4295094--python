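"""Which (l, d) instances are worth benchmarking?

For each motif length l, the largest radius d keeping the expected number of
chance ("spurious") motifs below 500 defines the *challenging* instance:
any larger d floods the output with meaningless motifs. The probability
chain below reproduces the classic DNA series (13,4), (15,5), (17,6), ...
for the standard benchmark model of 20 strings of length 600.
"""

from plantedmotif import InstanceModel, challenging_table, expected_motifs

print("expected chance motifs, DNA n=20 m=600 q=100%:")
for d in (3, 4, 5):
    model = InstanceModel(n=20, m=600, l=13, d=d, q=100.0, sigma=4)
    print(f"  (13,{d}): {expected_motifs(model):12.4g}")
print("  -> d=4 is the largest radius below the 500 bound\n")

table = challenging_table(range(13, 31), (50.0, 75.0, 100.0), sigma=4)
print("challenging radius per length and quorum (DNA):")
print(table.to_string())
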