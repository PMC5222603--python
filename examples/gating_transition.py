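"""Scan the tip-tip cohesion and locate the first-order gating transition.

As the effective cohesion between the sticky FG-domain tips rises (i.e. as
transport-factor screening is removed), the equilibrium brush height jumps
discontinuously from a mid-pore open state to the fully stretched closed
state at H = R - delta.  The scan detects the jump and refines the critical
cohesion by bisection to 1e-3 kT, with and without the single-block (shrub)
FG nups on the pore wall.
"""

import numpy as np

from dcbg import BrushParameters, scan_epsilon

eps_grid = np.round(np.arange(0.0, 5.01, 0.25), 10)

for shrubs in (False, True):
    scan = scan_epsilon(BrushParameters(shrubs_present=shrubs), eps_grid)
    tag = "with shrubs" if shrubs else "no shrubs  "
    print(
        f"{tag}: critical eps = {scan.transition:.3f} kT,"
        f" height jump = {scan.transition_jump:.1f} nm"
    )

scan = scan_epsilon(BrushParameters(shrubs_present=True), eps_grid)
print("\neps [kT]   H_eq [nm]  opening [nm]")
for eps, h, o in zip(scan.grid[::2], scan.H_eq_series[::2], scan.opening_series[::2]):
    print(f"{eps:7.2f}   {h:8.2f}  {o:11.2f}")
print(
    "\nBelow the critical cohesion the brush sits mid-pore (open conduit);"
    "\nabove it the tips coalesce at the axis and the opening collapses to"
    f"\n2*delta = {2 * BrushParameters().delta:.1f} nm."
)
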