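"""Force delivered by the autonomous device as a function of target stiffness.

The calibrated default device (97-nt ss connectors, six per side, 23 C)
balances its two antagonistic connector sets against a linear protein
spring.  Soft targets see ~1.6 pN; stiff targets up to ~30 pN.
"""

import numpy as np

from nanowinch import default_autonomous_model, force_vs_kprotein, solve_equilibrium

model = default_autonomous_model()
table = force_vs_kprotein(model, np.logspace(-1, np.log10(20), 8))
print(table.to_string(index=False))

free = solve_equilibrium(default_autonomous_model(k_protein=0.0))
print(f"\nfree equilibrium (no target attached): x_eq = {free.x_eq:.2f} nm")
print("Force grows and the piston retracts (x_eq falls) as the target stiffens;")
print("the two ends of the table are the device's published operating range.")
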