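# Methods

## The brush free energy

The package models the core of the nuclear pore as an Alexander–de Gennes
polymer brush grafted to the inside of a cylinder of radius `R` (nm), in
the Sevick mean-field form for cylindrically confined brushes.  Each
di-block FG nup is a stalk of `N` effective monomers of Kuhn length `a`
ending in a cohesive tip blob of diameter `δ`; single-block FG nups are
cohesive blobs of diameter `δs` at radial position `Rs`.  Per chain, in
units of kT:

    F(H) = (H/a)^{5/2} N^{-3/2}
         + a^{5/2} N^{3/2} R / (√H d² (2R − H))
         − ε δ² R / (d² (R − H))
         − εs δ² (δs − H) R Θ(δs − H) / (d² δs Rs)

Assumptions inherited from this mean-field picture: the stalks are neutral
excluded-volume chains (counterion effects on the charged stalks are
ignored); the tips mix uniformly in a central cylindrical region, so the
tip–tip energy scales as the square of tip concentration (divergent as the
plug closes, `H → R`); the tip–shrub energy scales as the product of tip
and shrub concentrations and is only nonzero while the tips overlap the
wall shrub layer (`H < δs`, with `Θ(0) = 0` so the term vanishes exactly
at the kink).  Kinetics, the nuclear basket, cytoplasmic filaments and
transport-factor binding dynamics are out of scope; the model is purely
equilibrium.

### Parameters (defaults, units)

| symbol | field        | default | meaning |
|--------|--------------|---------|---------|
| R      | `R`          | 25 nm   | pore radius |
| d      | `d`          | 10 nm   | grafting distance (32 chains on the wall) |
| a      | `a`          | 0.76 nm | Kuhn length, twice the 0.38 nm residue contour length |
| N      | `N`          | 198     | effective polymerisation number (calibrated, see below) |
| δ      | `delta`      | 3.6 nm  | sticky-tip blob diameter (twice the FG-domain Rg) |
| δs     | `delta_s`    | 4 nm    | shrub blob diameter |
| Rs     | `R_s`        | 25 nm   | shrub radial position (wall scenario) |
| ε      | `epsilon`    | 4.7 kT  | tip–tip cohesion (Nsp1 self-interaction reference) |
| εs     | `epsilon_s`  | 6 kT    | tip–shrub cohesion |
|        | `H_floor`    | 0.1 nm  | lower end of the admissible height range |

Admissible heights are `(H_floor, R − δ]`.  The floor exists because the
stretching and excluded-volume terms diverge as `H → 0`; a minimum found
at the floor is flagged (`at_floor`) and warned about, since its location
is floor-dependent rather than physical.

### Calibration of (a, N)

`a` is fixed at twice the residue contour length.  `N` (nominally half the
stalk residue count) is an *effective* number: the Kuhn-segment mapping of
a disordered protein is approximate, so `N` is calibrated once against the
gating transition values of ~1.6 kT (no shrubs) and ~1.9 kT (with shrubs)
quoted for this class of model in the NPC literature.  Under this
functional the two scans share a single critical cohesion (see
*Limitations*), so the least-squares calibration lands the common
transition midway: `N = 198` gives a critical cohesion of 1.753 kT, within
0.16 kT of both quoted values.  The pair `(a, N) = (0.76 nm, 198)` is
frozen in the defaults and used unchanged by every analysis, test and the
acceptance script.

### Numerics

* **Landscape tabulation** — `free_energy_curve` uses a uniform grid
  (default 2000 points) over the admissible range, always containing the
  Heaviside kink `H = δs` and the endpoint `H = R − δ` exactly.
* **Global minimisation** — the landscape is deliberately bistable, so
  `equilibrium_height` brackets every discrete local minimum of the dense
  grid, refines each by bounded golden-section search to 1e-4 nm, and
  compares the refined candidates and both endpoints.  If two candidates
  are degenerate within 1e-6 kT, the smaller height (wider opening) is
  reported and a `degenerate` flag set, making ties deterministic.
* **Transition detection** — `scan_epsilon` flags the first adjacent grid
  pair whose equilibrium heights differ by more than 5 nm (the gating jump
  is ≈ 9.4 nm at the defaults while the smooth drift of the open branch is
  ≈ 2 nm across the whole scan) and refines the critical cohesion by
  bisection to 1e-3 kT.  No jump ⇒ the transition is reported absent.
* **Binding budget** — `max_opening_under_binding` reads the tip–cargo
  binding free energy as an additive budget: the brush may visit any
  height with `F(H) ≤ F(H_eq) + E_bind`.  The smallest such height is
  located on the dense grid and sharpened by bisection on the crossing.
  This is one consistent reading of "binding energy added to the brush";
  a chemical-equilibrium treatment of bound tips would be an alternative.
* **State labels** — `open_wall` if `H_eq < δs`, `closed` if
  `H_eq > R − δ − 1 nm`, else `open_intermediate`.

## Trajectory analysis

Contact probability: `P[i,j]` is the fraction of snapshots in which
side-chain beads `i, j` lie within the cutoff (default 1.6 nm = 16 Å,
inclusive, Euclidean).  Frames are weighted equally; the diagonal is
exactly 1.  Rg is the per-frame root-mean-square bead distance from the
frame centroid (equal masses), time-averaged without interval weighting.
Residue indices are 1-based along the simulated disordered domain; mapping
to full-protein numbering is the caller's concern.

File input accepts multi-frame XYZ and multi-model PDB (parsed by
MDAnalysis, Å → nm by the exact factor 0.1).  For multi-bead PDB models
one bead per residue is chosen as the side-chain proxy (CB, then SC1,
then CA, else the first atom); XYZ is assumed to be one bead per residue.

### Architecture classification

The visual criterion — "a monolithic contact block" (single-block shrub)
versus "a terminal dense block plus a diagonal band" (di-block tree) — is
operationalised as follows: for each residue, average `P[i,j]` over pairs
with sequence separation in `[5, 50]`.  Excluding the near-diagonal band
is essential, because chain connectivity keeps sequence neighbours within
the 1.6 nm cutoff in *every* architecture; the discriminating signal is
medium-range.  Residues above `block_threshold` (default 0.06) are
collapsed; segments shorter than `min_segment` (default 10) merge into
their longer neighbour.  One collapsed segment covering ≥ 80 % of the
chain ⇒ `single_block`; a collapsed segment touching a terminus plus an
extended segment ⇒ `di_block`; otherwise majority coverage decides.  The
default threshold sits between the medium-range contact level of a
collapsed coil at the largest Rg of interest (≈ 0.10 at Rg = 2.4 nm for a
1.6 nm cutoff) and that of an extended stalk (≲ 0.03).  All knobs are
exposed because the underlying criterion is a by-eye call with no
canonical quantitative form.

## The synthetic-trajectory generator

The generator emulates the *statistics the analyses consume*, not the
physics that produced them:

* **shrub** — every frame redraws all beads i.i.d. uniformly in a ball of
  radius `ρ = target_Rg · √(5/3)`, so `E[Rg²] = (3/5)ρ² = target_Rg²`
  exactly (up to the `1 − 1/n` centroid correction).  Defaults target the
  2.0–2.4 nm Rg range measured for the yeast single-block FG nups
  (Nup42/Nup49/Nup57).
* **tree** — a stalk grown as a *persistent* fixed-bond random walk
  (bond 0.38 nm, directions uniform in a 35° half-angle cone about the
  previous bond, persistence length ≈ 4 nm), with the tip drawn as a
  shrub-like ball (default Rg 1.8 nm, half the 3.6 nm tip-blob diameter)
  centred on the stalk's free end.  The persistence is a deliberate
  design choice: at a 0.38 nm bond an *ideal* walk of 200 steps has
  Rg ≈ 2 nm — as compact as the collapsed coil it must contrast with —
  and nearly all medium-range pairs would sit inside the 1.6 nm cutoff.
  The persistent stalk reproduces the extended domain's signature of
  diagonal-band-only contacts.

Frames are statistically independent: the analyses under test are time
averages, so temporal correlation would only slow the tests without
exercising more code.  Consequently passing tests demonstrate correctness
of the estimators and classifier on chains with the right block/coil
*spatial* statistics; they say nothing about force fields, kinetics, or
real contact-map fine structure (specific residue–residue propensities,
transient secondary structure), which require genuine molecular dynamics.
Identical seeds reproduce trajectories bit for bit.

## Limitations

* **The shrub term is too weak to move the gate in this functional.**
  With the default geometry the tip–shrub term is bounded by
  `εs δ² R/(d² Rs) ≈ 0.78 kT` with slope ≤ 0.195 kT/nm, while the
  excluded-volume term climbs by far more than that as `H` approaches the
  wall for any `(a, N)` that keeps the gating transition near 1.6 kT (the
  closed-state stretching scale `P = ((R−δ)/a)^{5/2} N^{−3/2}` and the
  excluded-volume scale `Q = a^{5/2} N^{3/2}` obey `P·Q = (R−δ)^{5/2}`,
  independent of `a` and `N`, so lowering one necessarily raises the
  other).  As a result this functional has no wall-adjacent free-energy
  minimum, the with- and without-shrub ε-scans share one critical value
  (1.753 kT at the defaults), the open conduit just below threshold is
  ≈ 27 nm rather than the ≈ 40 nm quoted in the literature for the
  wall-open state, and a tip–cargo binding budget opens the pore
  essentially equally with and without shrubs (ratio ≈ 1.0, not the
  quoted up-to-4×).  Those literature numbers evidently require either a
  substantially stronger tip–shrub coupling or a different shrub-term
  functional form; the package implements the stated form faithfully and
  reports what it actually yields.  The corresponding checks in
  `tests/test_acceptance.py` document this gap by failing honestly.
* The mean-field tip-mixing assumption degrades for wide-open pores; the
  scaling prefactors are order-unity approximations throughout, so
  absolute free energies are meaningful to no better than ~1 kT.
* The equilibrium picture says nothing about opening/closing kinetics or
  transport rates.
* The classifier is tuned for one-bead-per-residue maps with a 1.6 nm
  cutoff; very short chains (< ~60 residues) leave little medium-range
  signal and may classify unreliably.
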