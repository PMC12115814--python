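"""Walk through the proton-spin memory stability ledger.

The numbers: Nc spins per axon circle, N0 charge units per pulse, Ns
pulses.  The ledger answers, in CGS arithmetic, whether a spike train
can write a stable memory and how fast.
"""

import json

from surfnet import (MemoryConstants, MemoryStrand, memory_ledger,
                     spins_per_circle)

consts = MemoryConstants()          # mu=1e-23 erg/G, d=1e-8 cm, 2*pi*ra=1e-3 cm ...
strand = MemoryStrand(Nc=spins_per_circle(consts), N0=10, Ns=1000)
ledger = memory_ledger(strand, consts, W=5)

print(json.dumps({k: v for k, v in ledger.items() if k != "constants"}, indent=2))

# Reading the ledger: the excitation frequency 10 Hz (20 Hz for the
# paired-spin structure) lands in the sleep-spindle range; alignment
# needs Ns*N0 > 1e3, so a single weak pulse cannot write memory; the
# spin-spin binding 1e-12 erg sits two decades above body-heat kT; and a
# W=5 loop structure (4 neurons) forms in ~5 s of pulsing.
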