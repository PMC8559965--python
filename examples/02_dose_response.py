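"""Steady-state dose-response of the intracellular apoptosis switch.

Computes the closed-form (L*, F*, B*, X*) equilibria along a TZB dose grid
for low/high cancer-stem-cell density with and without ATV, and reports the
smallest dose whose equilibrium is apoptotic (Bcl-2 below and BAX above the
threshold 8).
"""

import numpy as np

from crccsim import default_parameters, dose_response_curve

params = default_parameters()
grid = np.linspace(0.0, 1.0, 41)

for S, A, label in [(0.25, 0.0, "low CSC, no ATV"),
                    (0.25, 5.0, "low CSC, ATV A=5"),
                    (1.0, 0.0, "high CSC, no ATV"),
                    (1.0, 5.0, "high CSC, ATV A=5")]:
    c = dose_response_curve(params, grid, S_fixed=S, A_fixed=A)
    cross = ("none" if c.crossing_dose is None
             else f"{c.crossing_dose:.3f}")
    print(f"{label:18s} L*={c.L_star[0]:6.2f}  "
          f"B*(T=0)={c.B_star[0]:5.2f} -> B*(T=1)={c.B_star[-1]:5.2f}  "
          f"apoptotic from T={cross}")

print("\nATV lowers IL-6 (hence NF-kB and Bcl-2), so the switch to "
      "apoptosis\nhappens at a much smaller TZB dose; with a CSC-rich "
      "microenvironment and\nno ATV the equilibrium never becomes "
      "apoptotic on this dose range.")
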