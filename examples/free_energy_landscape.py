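"""Tabulate the brush free-energy landscape F(H) for several tip cohesions.

The free energy per chain of the FG-nup brush is evaluated over the
admissible height range (H_floor, R - delta] for tip-tip cohesions of 0, 2
and 4.7 kT.  At low cohesion the minimum sits mid-pore (open conduit); at
the 4.7 kT Nsp1 reference value the minimum moves to H = R - delta, where
the sticky tips meet at the pore axis and the conduit is closed.
"""

import numpy as np

from dcbg import BrushParameters, equilibrium_height, free_energy_curve

params = BrushParameters()  # R=25 nm pore, d=10 nm grafting, shrubs on

print("eps [kT]   H_eq [nm]  F_eq [kT]  opening [nm]  state")
for eps in (0.0, 2.0, 4.7):
    state = equilibrium_height(params.with_(epsilon=eps))
    print(
        f"{eps:7.1f}   {state.H_eq:8.2f}  {state.F_eq:9.3f}"
        f"  {state.opening_diameter:12.2f}  {state.label}"
    )

curve = free_energy_curve(params.with_(epsilon=2.0), n_grid=2000)
print("\nlandscape at eps = 2 kT, sampled every ~2.7 nm:")
print("H [nm]   stretch   excl.vol  tip-tip  tip-shrub   total [kT]")
for i in range(0, len(curve.H_grid), 250):
    print(
        f"{curve.H_grid[i]:6.2f} {curve.F_stretching[i]:9.3f}"
        f" {curve.F_excluded_volume[i]:9.3f} {curve.F_tip_tip[i]:8.3f}"
        f" {curve.F_tip_shrub[i]:9.3f} {curve.F_total[i]:11.3f}"
    )
print(
    "\nThe height can extend at most to R - delta ="
    f" {params.H_max} nm (tips at the pore axis)."
)
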