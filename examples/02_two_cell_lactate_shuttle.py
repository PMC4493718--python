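"""Donor/acceptor coupling: the analytic lactate shuttle and its LP check.

Two crowding-constrained cells share one glucose supply; the donor maximizes
ATP while both must sustain a survival flux f_atp_min.  As the supply grows
the system passes through glucose sharing, lactate subsidy (the donor
overflows lactate which replaces the acceptor's glucose), and full glucose
sequestration.  Every closed form is cross-checked against an independent
six-flux linear program.
"""

import numpy as np

from crowdflux import lp_oracle, thresholds, two_cell_solution, two_cell_test_params

params = two_cell_test_params()  # survival demand 19 u_G: all regimes exist
th = thresholds(params)
print(f"u_G0 = {th.u_G0:.4f}  u_G1 = {th.u_G1:.4f}  u_G2 = {th.u_G2:.4f}")
print()
print(f"{'U_G':>7} {'regime':<20} {'glc_don':>8} {'glc_acc':>8} "
      f"{'LDH_don':>8} {'LDH_acc':>8} {'dU_G':>7} {'LP dev':>9}")
grid = [1.05, 1.3, 1.495, 1.505, 1.6, 5.0, 120.0]
for u in grid:
    a = two_cell_solution(params, u)
    b = lp_oracle(params, u)
    dev = max(
        abs(getattr(a.donor, f) - getattr(b.donor, f))
        for f in ("f_glyc", "f_ox", "f_LDH", "f_ATP")
    )
    print(f"{u:7.3f} {a.regime.value:<20} {a.donor.U_G_in:8.3f} "
          f"{a.acceptor_min.U_G_in:8.3f} {a.donor.f_LDH:8.3f} "
          f"{a.acceptor_min.f_LDH:8.3f} {a.delta_U_G:7.3f} {dev:9.1e}")

# LDH_acc < 0 marks lactate intake: in the subsidized window the acceptor
# progressively trades its glucose share (dU_G) for donor-derived lactate,
# and past u_G2 it lives on lactate alone.  The LP deviation column shows
# the independent linear program agreeing with the closed forms.
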