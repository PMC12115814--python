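"""Synthesize the two stereotyped deep-sleep transients.

The K-complex is a biphasic pair of Gaussian-windowed cosine lobes (a
blocking excitation modulating the slow wave); the sleep spindle is the
memory structure's resonance omega0 riding on the unit-frequency slow
carrier, with the paired-spin structure at double frequency/amplitude.
"""

import numpy as np

from surfnet import (KComplexParams, SpindleParams, kcomplex_waveform,
                     spindle_modulation)

kc = KComplexParams(A=1.0, n=1, T=5.0)
t = np.arange(-kc.T, 3 * kc.T, 0.01)
m = kcomplex_waveform(kc, t)
print(f"K-complex: trough {m.min():.3f} at t={t[np.argmin(m)]:.2f}, "
      f"crest {m.max():.3f} at t={t[np.argmax(m)]:.2f}")

sp = SpindleParams(Ns=1000, omega0=12.0, T=6.0)
ts = np.arange(0.0, sp.T, 0.005)
dv, dv2 = spindle_modulation(sp, ts)
print(f"spindle: peak modulation {np.max(np.abs(dv)):.3e} statvolt, "
      f"paired structure {np.max(np.abs(dv2)):.3e}")

# The K-complex's negative-then-positive lobes straddle t=T with a C1
# glue; the spindle waxes and wanes with the sin(t) envelope while
# oscillating at the 12 rad/s memory frequency, and the predicted second
# structure is twice as fast and twice as large.
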