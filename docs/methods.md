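# Methods

`episem` simulates the apical plane of a proliferating epithelial monolayer
(the *Drosophila* wing imaginal disc is the calibration system) with a
subcellular-element model: each cell is an ordered ring of membrane nodes —
plasma membrane plus actomyosin cortex — enclosing a cloud of internal
nodes representing cytoplasm. This note records the model, the package's
own numerical and design choices, and what the synthetic test conditions do
and do not establish.

## Model

### Interactions

Five families couple the nodes (units: µm, nN, s, rad; energies nN·µm;
pressures nN/µm² = kPa):

| family | between | form | role |
|---|---|---|---|
| II | internal–internal, same cell | Morse, node–node | cytoplasmic pressure |
| MI | internal node – own membrane *segment* | Morse (repulsive, W = 0) | keeps cytoplasm inside; pressure on the membrane |
| MMD | membrane node – foreign membrane *segment* | Morse, repulsive branch only | volume exclusion |
| MMS | consecutive/adjacent ring nodes | linear + torsional springs | cortical stiffness |
| Adh | membrane–membrane nodes, different cells | linear spring, one bond per node | cell–cell adhesion (E-cadherin) |

**The wall families act on segments.** The membrane ring stands for a
continuous cortex. Evaluating the wall potentials (MI, MMD) against the
point-to-segment distance — with the reaction split between the segment
endpoints by the lever rule, the exact energy gradient — keeps the wall
impenetrable at any discretization. A node-node wall becomes porous once
the node spacing exceeds the repulsion range (≈ 0.45 µm vs ξ = 0.13 µm at
the desk-scale resolution): internal nodes then leak out of their cells
and packed cells interpenetrate, which is what we observed before adopting
the segment form. At full resolution (spacing 0.06–0.15 µm ≪ cutoffs) the
segment and pairwise forms are numerically close.

The Morse pair energy is `E(r) = U e^(−r/ξ) − W e^(−r/γ)` with a hard
cutoff `L`. The calibrated parameter table (each entry an interphase and a
mitotic value) is built into `mechanics.default_phase_params()`:
II `U 0.49/21.75, W 0.15/6.71, ξ 0.31/0.58, γ 1.25/1.34, L 1.56/3.12`;
MI `U 0.78/4.36, ξ 0.13/0.27, L 1.56/3.12` (no attractive term);
MMD `U = W = 3.9, ξ 0.13, γ 1.6, L 0.78` (phase-constant);
cortex `k_stiff 200/450 nN/µm, L_stiff 0.060/0.13 µm, k_tor 6/7 nN·µm/rad`;
adhesion `k_adh 20/8 nN/µm` engaging on `[0.062, 0.40] µm`.

**Volume exclusion is repulsion-only.** With the printed amplitudes the MMD
Morse force would turn attractive beyond r ≈ 0.355 µm, ending in a 1.4 nN
discontinuity at the 0.78 µm cutoff. A cross-cell attraction of that
strength makes the sheet unstable: membranes of different cells maximize
mutual contact, the outer cells of a starting cluster stream toward the
core and crush the center cell (we observed unbounded force growth at any
time step). Since the family's function is volume exclusion — cohesion is
the adhesion springs' job — `episem` uses only the repulsive branch,
cutting the force at its zero crossing and shifting the energy to stay
continuous. This is exposed per family as `MorseParams(repulsive_only=...)`.

**Cortical springs.** Each ring segment carries `½ k_stiff (ℓ − L_stiff)²`;
each vertex carries a harmonic torsional spring `½ k_tor (ψ − ψ₀)²` in the
signed turning angle, with `ψ₀ = ±2π/n` (the regular-polygon value for the
ring's orientation). Forces are analytic gradients; every cortex term is
internal, so the ring's net force and net torque vanish identically.

**Adhesion pairing.** Each membrane node bonds at most one membrane node of
another cell: candidates are mutual nearest neighbors within the engagement
cutoff, accepted greedily shortest-first (ties by node index), so conflicts
keep the shorter bond. Pairing is recomputed every step. A bonded pair
feels the adhesion spring *plus* the ordinary volume exclusion: the
alternative convention — exclusion only below the adhesion rest length —
makes the pair force jump by the full ~16 nN contact repulsion at `L_min`,
and bonds in crowded regions then chatter across the discontinuity
indefinitely (we measured persistent ~15 nN force spikes in an otherwise
resting cluster). The summed force is continuous in distance.

### Dynamics

Nodes are overdamped: `η dx/dt = F`, integrated by forward Euler with
`η = 36 nN·s/µm` and `dt = 3 ms`. Internal nodes collect II and MI forces;
membrane nodes collect MI, cortical, volume-exclusion and adhesion forces.
A step that would move any node farther than half the adhesion rest length
(0.031 µm) aborts the run rather than sub-stepping — the signal that `dt`
is too large for the current stiffness. There is no thermal noise; the only
randomness in the model is in growth rates and node insertion.

Transient forces of 50–300 nN arise at crowded vertices (and just after
divisions) at *any* node resolution, so the stable `dt` is nearly
resolution-independent. Desk-scale runs use a 7 ms step, chosen from a
displacement census over 100k active growth steps (99.9th percentile
0.0054 µm, maximum 0.0091 µm against the 0.031 µm guard at 3 ms — more
than 2× headroom at 7 ms). The rare larger spike is handled by an explicit
recovery driver (`run_resilient`): the guard *rejects* the oversized step,
leaving the state intact, and the driver integrates a short logged window
at half step before resuming. Trajectories remain deterministic per
(config, seed).

Internal nodes are constitutively confined: a point-in-polygon check each
bookkeeping round pulls any internal node found outside its own ring back
toward the ring centroid. The wall potentials make this rare — it fires
essentially only when a freshly divided, contracting daughter ring
squeezes a node through the capped soft core of the wall (about one node
per division before the rescue existed; zero escapes after).

### Cell cycle

Cycle progress CP ∈ [0, 1] accrues at `g_i(t) = g0_i e^(−k_g t)` with
`g0_i ~ U[2×10⁻³, 4×10⁻³]` per second drawn once at birth and
`k_g = 4×10⁻⁴ s⁻¹`. Internal nodes are added one per `1/(N_max − N_0)` of
CP (20 → 40 at full resolution), each placed uniformly within `0.2 R_c` of
the centroid. Membrane nodes are added at segment midpoints whenever a
segment exceeds twice its rest length (100 → at most 200).

**Time convention.** The printed growth rates (per second) are mutually
inconsistent with the printed clock times (a 30-minute M phase would exceed
the entire early cycle of ≈ 5.5 minutes, and all growth would end hours
before the stated 35–55 h landmarks). `episem` keeps the *rates* literally
per simulation second and reads the *clock times* in biological minutes:
one simulation second of the growth clock corresponds to one biological
minute. Hence `T_mit = 30 s` of simulation (= 30 min biological) and the
35 h steady-state landmark falls at 2100 s. Under this convention every
printed number is reproduced: `g·T_mit ≤ 0.12`, total doublings
`g0_avg/k_g = 7.5`, M phase ≈ 9% of the early cycle.

**Mitosis.** A cell enters the mitotic phase when CP first exceeds the
dynamic entry point `1 − g_i(t)·T_mit`, which makes the realized M-phase
duration ≈ `T_mit` despite heterogeneous growth rates. At entry the
division axis is frozen as the long axis of the membrane ring (principal
second-moment direction; an exactly circular ring falls back to the x axis
deterministically). During M every parameter with distinct phase columns
ramps linearly in CP from its interphase to its mitotic value
(`phase_interpolate`); the phase-constant families are unaffected by the
same ramp applied entrywise.

**Division** (at CP = 1, Hertwig's rule): the cleavage line runs through
the centroid perpendicular to the stored long axis. Membrane nodes are
assigned by side, each daughter ring closed with fresh nodes along the
cleavage line at the cortical rest-length spacing, offset 0.025 µm into its
daughter's side (so the new membranes do not coincide; each daughter sheds
an offset-wide strip, keeping the daughters' summed area within ~3% of the
mother's). Near-coincident nodes at the cut are merged — a crossing point
can land arbitrarily close to an arc node, and the resulting near-zero
segment otherwise produces diverging vertex-spring forces. Internal nodes
go by side (exactly-on-line to daughter A). Daughters restart at CP = 0 in
interphase with fresh `g0` draws from their own RNG streams. A cut that
would produce a degenerate daughter (ring crossing the line more than
twice, < 3 membrane or < 1 internal node) is abandoned and retried on a
later step.

### Initialization and reproducibility

Runs start from circular cells (membrane ring + uniform internal nodes) on
a hexagonal layout, 0.3 µm apart so the initially separate cells fall into
adhesion range and anneal into a sheet. The initial radius default
(1.2 µm at full resolution) is the relaxed single-cell radius, measured
once, so the startup transient is small; the relaxed interphase cell has
apical area ≈ 4.5 µm². One root `SeedSequence` drives a per-cell stream
tree (daughters spawn from their mother's sequence), so identical
(config, seed) reproduce event logs and positions bit-exactly, and adding
a cell never perturbs another's draws.

## Numerics

- **Coincident nodes:** Morse force magnitudes are frozen below `0.01 ξ`
  (random insertion can momentarily superpose nodes).
- **Evaluation floor:** the integrator kernels truncate each Morse family
  at the largest separation where the pair force still reaches 0.01 nN
  (typical nodal forces are 1–10 nN). This shortens only the MI reach
  materially (1.56 → 0.83 µm interphase). The API-level potential functions
  keep the full table cutoffs.
- **Neighbor search:** uniform spatial hash over membrane nodes; cross-cell
  candidate pairs are kept in a Verlet list with a 0.35 µm skin, rebuilt
  when accumulated displacement could span half the skin or after any
  topology change. Candidate supersets are exact within the interaction
  reach.
- **Greedy pairing order** uses a fine counting sort on squared bond length
  (bucket ≈ 10⁻⁴ µm); exact ties resolve by node index, matching the
  reference implementation in `mechanics.pair_membranes`.
- **Cycle bookkeeping cadence:** insertions, mitosis entries and divisions
  are processed every 5 integration steps (15 ms of simulated time, about
  10⁻⁴ of an M phase), with the CP increment scaled accordingly.
- **Resolution scaling** (factor `s ≤ 1`): node counts scale by `s`
  (membrane ⌈100·s⌉ → ⌈200·s⌉, internal ⌈20·s⌉ → ⌈40·s⌉); the segment rest
  length scales as `L_stiff/s` (perimeter preserved); `k_stiff` scales by
  `s` (cortical tension per strain preserved); the adhesion engagement
  reach is extended by half the coarsened segment so every junction node
  keeps a partner in range. Two constants deliberately do *not* follow
  their naive density arguments, in both cases because coarse rings
  otherwise misbehave: `k_tor` is unscaled (scaling preserves the
  continuum bending modulus but lowers the barrier against a sharp
  single-joint fold by `s`, and coarse rings then buckle at crowded
  vertices), and `k_adh` is unscaled (with one bond per node, coarse
  junctions carry few bonds, and weaker bonds fail to zip membranes into
  contact — the packing opens up and the contact graph thins). Morse
  families are unscaled; the equilibrium cell area consequently shrinks
  mildly with `s` (the initial radius follows an `s^(1/8)` fit of the
  relaxed radius). Desk-scale tissue runs use `s = 0.2`; the neighborship
  threshold scales with bond density as `max(1, round(3 s))`, validated
  against a centroid-Voronoi contact oracle (100% of interior cells within
  ±1 at `s = 0.2`).

## Calibration harnesses

- **Stretch (elastic modulus):** a relaxed single cell at full resolution;
  a linearly growing total force (0.05 nN/s) is split over the membrane
  nodes within ±15° of each x pole. Strain is the relative x-extent change;
  stress divides the pole force by the current y-width times a fixed
  out-of-plane depth `depth_h`; the modulus is the least-squares slope over
  the strain window 0.02–0.10. `depth_h` converts the intrinsically 2D
  force-per-length response to a 3D stress; it is not a printed constant,
  so it was fixed once so the calibrated interphase parameter set reports
  E = 19 kPa, then frozen in the configuration default. A bisection wrapper
  on `k_stiff` reaches any target modulus in the epithelial range
  (10–55 kPa).
- **Detachment (adhesion strength):** two cells adhere for 60 s — long
  enough for the junction to zip to its steady contact length, which makes
  the junction-length denominator reproducible — then opposing pole forces
  ramp until the adhesion bond count reaches zero. Strength = force
  at separation / junction length at ramp onset (distance between the
  outermost bonded nodes). The early strain is slightly negative — strong
  adhesion compresses the pair. The reading is loading-rate dependent —
  faster ramps give the peeling junction less time to relax and re-engage
  bonds and read higher (0.227 nN/s → 61, 0.05 → 30, 0.01 → 21,
  0.0035 → 20 nN/µm with the calibrated parameters) — so the default rate
  of 0.01 nN/s sits near, though not at, the quasi-static plateau. Even
  quasi-statically the harness reads about twice the 10 nN/µm the
  adhesion constant was nominally calibrated to reproduce: with ~20 bonds
  of 20 nN/µm each across a 1.2–1.4 µm junction, near-uniform loading
  through the soft cell bodies breaks bonds at ~3 nN apiece; a 10 nN/µm
  failure would require a far sharper peel or far fewer engaged bonds.
- **Growth curve:** cell count over time with a 95% normal band over seeds;
  the closed-form check is `doublings = (g0/k_g)(1 − e^(−k_g t))`.

## Mitotic-rounding readouts and topology

Cell geometry comes from the ring polygon: shoelace area, polyline
perimeter, isoperimetric roundness `4πA/P² ≤ 1`. Pressure is the 2D pair
virial over the cytoplasmic families, `P = (1/2A) Σ r·f` (repulsion
positive). For each completed M phase: `A_inter` (area at entry), `A_mit`
(peak during M), `A_ratio = A_mit/A_inter`, `R_norm` (peak roundness /
entry roundness — the normalization is a package choice, the source
normalization being unprinted), and `ΔP` (peak minus entry virial
pressure).

Two cells are neighbors when they share ≥ `min_bonds` adhesion bonds
(3 at full resolution, scaled with linear node density, floor 2 — at
`s = 0.2` a true junction carries ~4–6 bonds, a corner contact 0–1).
Topology statistics (polygon-class histogram, per-phase means, Lewis and
Aboav–Weaire tables) run over interior cells only: a cell is excluded when
any of its membrane nodes lies within one cell radius of the tissue's
convex hull. T1 events are neighbor exchanges: a lost contact whose two
former common neighbors gained the transverse contact.

## Response-surface analysis

Factors: mitotic adhesion `k_adh_mit`, mitotic cortical stiffness
`k_stiff_mit`, and the pressure multiplier `deltaP_scale` (scales the
mitotic II and MI amplitudes; the realized ΔP is measured post hoc).
Factor ranges default to ±50% of the calibrated mitotic point (the printed
design levels being unavailable). Designs: 3³ full factorial and a
rotatable CCD (α = 8^¼). Responses come from `mr_probe`: the
centermost interior cell of a small *grown* tissue (~30 cells; a relaxed
free-standing cluster would start round and show no rounding signal) is
driven through one M phase at constant growth rate while its neighbors
idle, and its readouts are recorded. All factor combinations are probed
against the same grown packing, so differences are purely mitotic. Full second-order
polynomials in coded units are fit per response (WLS with `1/se²` weights
when replicate standard errors exist), reduced by backward elimination at
p < 0.01 under term hierarchy (a linear term survives while any of its
higher-order descendants remain), and differentiated for coded-unit local
sensitivities. The Pareto front minimizes the two scaled distances to
user-supplied experimental targets; experimental target values are config
inputs, not shipped constants. An optional studentized-residual outlier
flag (|t| > 3, refit once) is off by default.

## What the synthetic conditions do and do not show

All tests run on synthetic tissues generated by the package itself
(single cells, adhered pairs, 7-cell clusters, grown sheets at `s = 0.2`).
They establish internal consistency — force/energy consistency, exact
conservation properties, reproducibility, emergent packing topology
(mean polygon class ≈ 6, Lewis and Aboav–Weaire trends), calibration
landmarks and the qualitative mitotic-rounding regime. They do not
establish agreement with any real imaging data: experimental mitotic area
and roundness distributions are user inputs, boundary conditions are free
(no basement membrane or compartment boundaries), and the apical-plane 2D
abstraction ignores cell height changes during rounding.

## Known limitations

- Coarse resolution shifts absolute readouts (equilibrium areas, ΔP);
  ratios and topology statistics are the quantities meant to be compared
  across resolutions.
- Forward Euler with the displacement guard means pathological parameter
  sets abort rather than integrate slowly; the guard is a config field.
- The mitotic parameter ramp applies entrywise to the whole table; a
  per-parameter ramp schedule is not exposed.
- `A_ratio` at the calibrated coarse settings is larger than typical
  apical-area expansions reported for real epithelia; the response-surface
  analyses therefore read slopes and signs, not absolute areas.
- Because the mitotic cortical rest length (0.13 µm column) exceeds the
  interphase value, the mitotic ring's rest perimeter is larger than its
  actual perimeter: the mitotic cortex sits in compression, and a stiffer
  mitotic cortex *supports* area expansion rather than resisting it (and
  slightly lowers peak roundness). Sensitivity signs around the calibrated
  point inherit this; the magnitude ordering (pressure dominates area,
  stiffness dominates roundness relative to pressure) does not.
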