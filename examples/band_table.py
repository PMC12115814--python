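"""Predict the EEG frequency bands from sphere tilings.

Each symmetric tiling of the sphere fixes a surface-oscillation mode
whose frequency scales with the tile count and whose amplitude scales
with the tile area, giving the inverse amplitude-frequency law.  The
scale is pinned by the slowest (delta) wave: frequency 1, 200 microvolt.
"""

from surfnet import enumerate_schwarz_triples, platonic_tiling_table

triples = enumerate_schwarz_triples(30)
print("Schwarz triples beyond the dihedral family:",
      [(s.p, s.q, s.r) for s in triples if not s.is_dihedral])

print(f"\n{'tiling':<14}{'tiles':>6}{'freq':>7}{'amp (uV)':>10}  band")
for row in platonic_tiling_table(1.0, 200.0, dihedral_n=20):
    print(f"{row.name:<14}{row.tile_count:>6}{row.frequency:>7.0f}"
          f"{row.amplitude:>10.0f}  {row.band}")

# The frequency column spans 1-40 on the delta-normalized scale, matching
# the five observed EEG bands; amplitude falls as 1/frequency, which is
# why slow waves are large and gamma activity is small.
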