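"""Trajectory analysis on synthetic shrub and tree FG-nup chains.

Generates a collapsed-coil single-block chain (shrub, target Rg 2.0 nm) and
a di-block chain (tree: 200-residue extended stalk + 100-residue collapsed
tip), computes the 1.6 nm contact probability maps and radii of gyration,
and calls each chain's block architecture from its contact map alone.
"""

import numpy as np

from dcbg import (
    GeneratorSpec,
    classify_architecture,
    contact_probability_map,
    generate,
    radius_of_gyration,
)

specs = {
    "shrub": GeneratorSpec(
        architecture="shrub", chain_length=280, n_frames=300, seed=1, target_rg=2.0
    ),
    "tree": GeneratorSpec(
        architecture="tree", chain_length=300, n_frames=300, seed=2,
        tip_length=100, stalk_length=200,
    ),
}

for name, spec in specs.items():
    traj = generate(spec)
    rg = radius_of_gyration(traj)
    cmap = contact_probability_map(traj, cutoff=1.6)
    call = classify_architecture(cmap)
    off_diag = cmap.P[~np.eye(spec.chain_length, dtype=bool)].mean()
    print(f"{name}: {spec.chain_length} residues, {spec.n_frames} frames")
    print(f"  time-averaged Rg            = {rg:.3f} nm")
    print(f"  mean contact probability    = {off_diag:.3f}")
    print(f"  architecture call           = {call.call}")
    print(f"  segments (1-based, incl.)   = {call.segments}")
print(
    "\nThe shrub map is one monolithic contact block; the tree map splits"
    "\ninto a diagonal-band stalk plus a dense terminal FG-tip block, which"
    "\nis what the classifier keys on."
)
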