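"""Theta-function bookkeeping behind the signal code.

The spin topology number W = 4 sum(alpha.beta) of the half-integer
characteristics decides the parity of the theta function (odd parity
makes it vanish at the origin) and, physically, the sign phase carried
by every soliton and the size of the engram the signal can write.
The pinch-expansion coefficients of the one-forms are the deformation
parameters that become the (a, b, c) of the pulses.
"""

import numpy as np

from surfnet import (Characteristics, HyperellipticCurve, PeriodMatrix,
                     ThetaArgs, characteristic_parity, pinch_expansion,
                     spin_topology_number, theta_with_characteristics)

for alpha, beta in [((0.5, 0.5), (0.5, 0.5)), ((0.5, 0.0), (0.5, 0.5))]:
    ch = Characteristics(alpha, beta)
    W = spin_topology_number(ch)
    print(f"alpha={alpha} beta={beta}: W={W} ({characteristic_parity(ch)}), "
          f"engram size Ne={W - 1}")

pm = PeriodMatrix(1j * np.eye(1))
odd = Characteristics([0.5], [0.5])
val = theta_with_characteristics(ThetaArgs([0.0], 10), pm, odd)
print(f"odd theta at z=0: |theta| = {abs(val):.2e} (vanishes by parity)")

curve = HyperellipticCurve([1.0, -1.0, 2.0, -2.0])
coeffs = pinch_expansion(curve, j=1, order=4)
print("pinch coefficients of omega_1 about z=0:", np.round(coeffs.real, 4))

# The leading coefficient 1/sqrt(P(0)) = 0.5 and its corrections are the
# distortion parameters a pinch deformation imprints on the outgoing
# solitons.
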