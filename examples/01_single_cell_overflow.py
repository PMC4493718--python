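"""The crowding-constrained single cell: maximum yield and lactate overflow.

Solves the coarse-grained cell's ATP-maximization closed form across glucose
supplies.  Below the crowding onset u_G every glucose is oxidized (38 ATP
per glucose); above it the volume budget for oxidative enzymes is exhausted
and the excess glucose overflows to lactate (the Warburg effect), collapsing
the yield toward 2.
"""

import numpy as np

from crowdflux import MinimalModelParams, single_cell_optimum, thresholds

params = MinimalModelParams()  # empirical coefficients, phi_ATP = 0.4
th = thresholds(params)
print(f"crowding onset   u_G = {th.u_G:.4f} mM/min")
print(f"full fermentation v_G = {th.v_G:.2f} mM/min")
print()
print(f"{'U_G':>8} {'f_ox':>8} {'f_LDH':>9} {'f_ATP':>9} {'ATP/glc':>8}")
for u in [0.25, 0.5, th.u_G, 2.0, 10.0, 50.0, th.v_G]:
    s = single_cell_optimum(params, u)
    print(f"{u:8.3f} {s.f_ox:8.3f} {s.f_LDH:9.3f} {s.f_ATP:9.2f} "
          f"{s.f_ATP / u:8.2f}")

# The yield column drops from 38 (pure oxidation) toward 2 (pure
# fermentation) as the crowding constraint saturates past u_G; f_LDH > 0 is
# the lactate secretion flux that defines overflow metabolism.
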