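# Model and methods

`angiosprout` simulates sprouting angiogenesis as a hybrid of two
continuum fields and a set of discrete agents, closed by a feedback loop
through the grown network's blood flow.  This note records the model, the
numerical choices, the default parameters and why they have the values
they do, and what the synthetic scenarios do and do not represent.

## Fields

Two order parameters live on a uniform node-centred grid (spacing `h`,
no-flux boundaries on every face):

* `phi` — endothelial (vessel) phase, +1 inside vessels, −1 outside;
* `psi` — tissue-cell phase, +1 inside the static spherical tissue cells,
  −1 outside, built once per scenario as a tanh-smoothed indicator of the
  cell spheres (ramp width `eps`).

`phi` evolves by conserved (Cahn–Hilliard type) interface dynamics plus a
proliferation source:

    d(phi)/dt = M lap[ phi^3 − phi − eps^2 lap(phi)
                       + gamma (phi^2 − 1)(psi − 2)(psi + 1)^2 ]
                + alpha_p(T) phi Theta(phi)

with `alpha_p(T) = beta_p min(T, T_p)`.  The bracket is the chemical
potential of a double-well free energy with surface tension (wall width
`eps`) and an energy penalty for vessel/tissue-cell overlap.  The
conservative form makes the interface term exactly mass conserving on the
discrete grid (mirror boundaries; `sum(lap) = 0` to round-off), which the
test suite checks to 1e-8 relative over a thousand steps.

The angiogenic factor `T` (concentration in units of the source value
`T_s`) diffuses, is consumed inside vessels, and is clamped at `T_s` on a
small disc at the centre of every *hypoxic* tissue cell:

    dT/dt = D lap(T) − alpha_T phi T Theta(phi),   T|sources = T_s.

Clamping is a Dirichlet reset applied after each explicit step, so `T`
obeys a maximum principle (0 ≤ T ≤ T_s), also asserted in the tests.

### Stability of the overlap penalty

The penalty derivative makes the vessel phase linearly unstable wherever
`gamma |(psi − 2)(psi + 1)^2| > 1`.  This is the intended mechanism — an
invading vessel is expelled from a cell — but if the unstable band
extends into the smoothed cell boundary where vessel legitimately sits,
vessel mass piles up there without bound (the conserved dynamics feeds
the runaway pocket).  With `gamma = 0.4` the threshold sits at
`psi ≈ 0.2`, strictly inside the cells, and tip imprinting never writes
vessel at `psi ≥ −0.5`, so the configuration space the simulation
actually visits is linearly stable.  A side effect is a slightly elevated
`phi` equilibrium where vessels press against cell rims: `phi` stays in
about [−1.1, 1.2] over a full run rather than the ideal [−1.1, 1.1];
the vessel/tissue-cell overlap (share of cell volume with `phi > 0`)
stays well under 2%.

## Tip-cell agents

Tip cells are point agents of radius `R_c`.  A vessel-wall node
(|phi| < 0.9) nucleates a new tip when `T ≥ T_c`, `|grad T| ≥ G_m`, and
no active tip (nor an earlier acceptance in the same raster-order scan)
lies within `4 R_c` — the lateral-inhibition ("salt and pepper")
exclusion.  Tips move at `v = chi grad T`, speed-capped at `chi G_M`; the
optional `chi_variant="hypoxia_scaled"` uses `chi0 (1 − T)` instead of a
constant `chi`.  Near a tissue cell (surface closer than `2 R_c`) the
inward radial velocity component is removed and the tip slides around the
cell.  A moving tip imprints `phi = min(1, |v|/(chi G_M) +
alpha_p/(2 alpha_p_max))` on the disc of radius `R_c` around it (so a tip
at the saturation speed lays mature vessel), never inside cells.

A tip retires when

* its disc overlaps vessel core (`phi > 0.3`) that is not its own recent
  trail — another sprout, the parent capillary, or its own older sprout
  after closing a loop.  Detection uses an ownership grid recording which
  agent laid each vessel node, plus a short per-tip trail memory
  (subsampled positions covering the last ~4 R_c of path) so that
  self-anastomoses count but a tip does not "merge" with the vessel it
  laid a moment ago; or
* the local gradient stays below `G_m / 2` for 30 consecutive simulated
  minutes (guidance lost).

## Irrigation and the two hypoxia rules

Every 15 simulated minutes the `phi > 0` region is binarised, thinned to
a one-voxel medial line (8-/26-connectivity), traced to a multigraph
(junction clusters merged; terminal spurs shorter than `2 R_c` pruned;
pass-through nodes contracted), and flow-solved: each branch is a
Poiseuille conductance `r^4 / L` (radius from the distance transform,
floored at `h/2`), unit pressure drop between the two ends of the parent
capillary, Kirchhoff solve on the conductance Laplacian.  Loops fused
back onto the capillary then sit on parallel pressure paths and carry
flow.  Edges with `|Q|` above 1e-6 of the network maximum count as
flowing.

Hypoxic cells deactivate irreversibly when their centre comes within the
oxygen diffusion length `d = 25 um` of

* **Rule 1**: a medial-line point of a *flowing* branch (irrigation needs
  anastomoses), or
* **Rule 2**: any vessel node (`phi > 0`), flowing or not.

Distances use the sampled Euclidean distance transform, so Rule 1's
deactivation set is a subset of Rule 2's by construction.  A simulation
ends when every cell is deactivated, or at `t_max` (default 24 h).

## Default parameters

| symbol    | value      | units    | why |
|-----------|-----------|----------|-----|
| h         | 2.5 (2D), 5 (3D) | um | resolves the wall with >= 2 nodes; explicit 4th-order stepping at finer h costs h^-6 |
| eps       | 3.75 (2D), 6 (3D) | um | capillary wall width; >= h |
| M         | 0.05      | um^2/s   | interface relaxes in minutes, far faster than sprouting but slow enough for dt ~ 0.6 s |
| gamma     | 0.4       | –        | expulsion strictly inside cells; see stability note above |
| beta_p    | 3.5e-4    | 1/s per T | with T_p = 0.8, saturated proliferation beta_p*T_p = 2.8e-4 1/s, the quoted operating point |
| T_p       | 0.8       | T_s      | saturation just below the source concentration |
| D         | 0.05      | um^2/s   | matrix-bound factor; halos spread ~130 um over 24 h, so gradients stay local to cells |
| alpha_T   | 0.006     | 1/s      | screening length sqrt(D/alpha_T) ~ 3 um: vessels absorb within a tip radius, yet a tip senses across its own disc |
| T_s       | 1         | –        | concentration unit |
| source_radius | 5     | um       | clamp at the cell centre (half the cell radius) |
| R_c       | 5         | um       | tip-cell radius; 4 R_c = 20 um exclusion |
| T_c       | 0.04      | T_s      | wall concentration reached only where a cell's halo has arrived; confines nucleation to source-adjacent wall |
| G_m       | 2e-3      | T_s/um   | activation gradient gate |
| G_M       | 2e-2      | T_s/um   | halo-edge gradients (~1e-2) approach but rarely exceed it |
| chi       | 0.3125    | um^2/s per T | chi * G_M = 0.375 um/min, the quoted maximum tip speed |
| d_oxygen  | 25        | um       | oxygen diffusion length |
| cell radius | 10      | um       | typical somatic cell |
| dt        | stability-limited (~0.64 s 2D) | s | explicit Euler; see below |
| agent cadence | 10 PDE steps | – | agents move ~0.04 um per update |
| irrigation cadence | 15 | min   | skeleton + flow + hypoxia update |

The box sizes (375 x 375 um^2; 250 x 250 x 125 um^3), the regular
8-rows-of-10 layout, the operating point (2.8e-4 1/s, 0.375 um/min) and
`d = 25 um` are the study conditions and are used verbatim.  Everything
else in the table is a package default chosen once, on the qualitative
grounds stated, because no published value exists for it.  Two of those
choices deserve emphasis:

* **Slow diffusion is essential.**  With fast diffusion the eighty
  clamped sources saturate the box at T ≈ T_s within minutes; the only
  gradient is a thin strip at the vessel front, every wall node passes
  the activation gates, and the vasculature advances as a solid front.
  Slow diffusion keeps per-cell halos distinct, so tips steer toward
  individual cells and branching tracks the hypoxic-cell distribution —
  the central phenomenon the tool exists to study.
* **Intermediate consumption.**  Strong absorption (screening length
  below ~1 um) makes a tip blind: its own freshly-laid sprout consumes
  the factor at its centre and the sampled gradient vanishes.  Weak
  absorption lets the factor flood vessel interiors and drives runaway
  wall proliferation.  The default screening length of ~3 um (about one
  tip radius) sits between the two failure modes.

## Time integration

Explicit Euler at the stability-limited step
`dt = 0.5 * 2 / (M (eps^2 s^2 + (2 + 8.8 gamma) s))`, `s = 4 dims / h^2`
(biharmonic symbol + worst-case bulk and penalty diffusivities), capped
by the diffusion bound `0.9 h^2 / (2 dims D)` for `T`; about 0.64 s in
2D.  Each T step is operator-split: diffusion + consumption, clip
negative round-off at zero, re-clamp sources.

## Morphometrics

* **branch density** — skeleton edge count per domain measure (mm^-2 or
  mm^-3);
* **anastomosis density** — graph cycle rank `E − V + C` per measure
  (the number of independent loops); tip merge events are logged
  separately but loops they close appear in the cycle rank once the
  fused geometry is skeletonised;
* **mean diameter** — twice the mask distance transform averaged over
  all medial points;
* **band densities** (regular layout) — each branch is attributed to a
  horizontal band by the fraction of its medial points inside it
  (a partition of the edge count), with the top hypoxic band at
  250–350 um and the empty middle band at 180–240 um above the bottom
  edge.  Midpoint and presence countings are also implemented; the
  fractional attribution is the default because it is unbiased for
  long branches crossing a sparse band.

## Synthetic scenarios

Scenarios are generated programmatically and are fully deterministic
given (parameters, seed): seeded rejection sampling with non-overlap and
a standoff of at least `d` from the parent capillary (so every cell
starts hypoxic under both rules).  The regular layout places eight rows
of ten cells with a 90 um empty band between rows 4 and 5.  These
scenarios emulate avascular tissue patches with point-like VEGF sources;
they do not represent moving or deformable cells, multiple VEGF isoforms,
matrix mechanics, oxygen transport, or lumen formation — so passing
tests say nothing about those aspects of real angiogenesis.

## Problem sizes

The standard 2D runs use the full 375 um box at h = 2.5 um for up to 24
simulated hours (a few minutes of wall time each).  Parameter-sweep
batteries run in a 300 um box (the morphometrics are densities) to the
same 24-hour horizon, and 3D runs use h = 5 um with an 8-hour cap, past
full irrigation under proximity deactivation.  Sweep endpoints bracket
the operating point: maximum proliferation 0.35–5.6 e-4 1/s (16-fold),
maximum tip speed 0.25–1.0 um/min (4-fold, bounded below so the slowest
networks grow out within the horizon).

## Known limitations

* The phase boundedness is [−1.1, ~1.2], not [−1.1, 1.1], where vessels
  press against cell rims (see the stability note).
* Tip merge *events* are rarer than geometric loop formation: most
  anastomoses close by two sprout walls fusing laterally rather than by
  a tip centre entering a foreign core, so `cycle_rank` (not the merge
  counter) is the anastomosis measure.
* At h = 2.5 um a 10 um vessel is four nodes wide; diameters carry a
  +-h quantisation, and the skeleton can drop one-node-wide necks.
* The flow solve is constant-viscosity Poiseuille with rigid walls and
  a unit pressure drop; only the flowing/non-flowing distinction feeds
  Rule 1, so absolute flow units are arbitrary.
* In the calibrated regime the branch count is set almost entirely by the
  hypoxic-cell geometry and is nearly insensitive to the proliferation
  cap and chemotactic coefficient under *both* irrigation rules: the
  morphology-resilience phenomenon appears globally rather than only for
  flow-gated deactivation.  The vessel-maturity activation gate exists
  precisely to couple proliferation to branching, but at the default
  gates tips migrate near gradient saturation and lay mature vessel, so
  it rarely binds.
* 3D runs at the feasible resolution (h = 5 um; a tip radius spans one
  node) produce single-digit loop counts, so 3D anastomosis statistics
  are qualitative at best.
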