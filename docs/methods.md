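# Methods

`spherosim` simulates the growth of a multicellular tumor spheroid (MTS) as
a coupled multiscale system: stochastic single-cell metabolic automata,
facilitated membrane transport, diffusion through the extracellular spaces
on a Delaunay network, and center-based overdamped mechanics.  This note
documents the model as implemented, its parameters, the numerical choices,
and what the scaled-down test runs do and do not demonstrate.

## The single-cell automaton

Each cell carries 15 internal variables (intracellular glucose `G`,
glucose-6-phosphate `G6P`, a glycogen store, glutamine `A`, lactate `AL`,
oxygen, an ATP pool, protein mass, nuclear DNA fraction, mitochondrial DNA,
two representative cyclins, the mitochondria count, volume and phase age)
and 4 extracellular variables (the masses of O2, glucose, glutamine and
lactate in its private extracellular free volume) — 19 biochemical degrees
of freedom per cell.  Glutamine stands for the amino-acid class as a whole
and lactate for the metabolite/waste class; no other species are modeled.

Rate laws:

- **Transport.** O2 permeates passively, flux `p A (c_out − c_in)` with
  membrane area `A`.  Glucose, glutamine and lactate use saturable carriers,
  `Vmax_eff(pH) A [c_o/(Km+c_o) − c_i/(Km+c_i)]` — antisymmetric in the two
  concentrations, with the carrier capacity modulated smoothly
  (logistically) by extracellular pH: acidification slows uptake.
- **Glycolysis and storage.** `G → G6P` (hexokinase-like MM step); `G6P`
  branches into glycolytic flux and a glycogen store that refills when
  `G6P` is plentiful and is mobilized when it is scarce.
- **Oxygen sensor and Warburg shift.** A Hill switch
  `h = c_O2^3/(c_O2^3 + K^3)` (half-switch at ~2.4 mmHg) gates the oxidized
  fraction of glycolytic flux, but that fraction is capped at
  `ox_fraction_max = 0.15` even at full oxygenation: tumor cells are
  Warburg-shifted and ferment most of their glucose to lactate at all
  times.  The glycolytic flux itself is set to the literature scale for
  tumor cells (~3×10⁻¹⁸ kg glucose/s per cell).  Both choices are load-
  bearing for the emergent behavior: without aerobic glycolysis the
  spheroid builds no lactate field, hence no core acidification and no
  cytotoxic death.  ATP production is `(e_f(1−route) + e_ox·route·μ)` per
  unit glycolytic flux, with `route = ox_fraction_max·h` and μ the
  mitochondrial *density* relative to a standard newborn (density, not
  count: otherwise large arrested cells inflate their ATP concentration
  and never starve).
- **Glutaminolysis.** An oxygen-dependent MM term oxidizes glutamine,
  contributing to the ATP pool.
- **Biosynthesis.** Protein, nuclear DNA and mitochondrial DNA are built by
  double-substrate Michaelis–Menten kinetics in (glutamine, ATP):
  `v s1 s2/((k1+s1)(k2+s2))`.  Mitochondria self-replicate (rate per
  existing unit); `n_mito = floor(mtDNA)`.
- **ATP pool.** Production as above; consumption as a first-order turnover
  (maintenance, time constant 600 s) plus a cost per unit protein
  synthesized.  The pool concentration is the cell's energy read-out: it
  gates the G1 checkpoint and, below a starvation threshold
  (0.15 kg/m³), kills the cell outright.

### Cell cycle

Phases `G1m → G1p → S → G2 → M`.  `G1m` is nutrient-sensitive: exit
requires (i) ATP concentration above the energetic-checkpoint threshold,
(ii) cyclin E (accumulated at an ATP-dependent rate) above its threshold,
and (iii) a **protein sizer** — protein mass at least 1.3× the newborn
reference.  The sizer is our addition: with all rates proportional to
volume, concentrations are size-invariant and nothing else controls cell
size across generations; the sizer provides the standard size-homeostasis
mechanism and automatically lengthens G1 under starvation.  Once the gate
is open, exit is a memoryless (exponential) event with a 1 h mean delay;
the G2→M checkpoint behaves likewise (45 min).  `G1p` is a fixed 3 h timer
insensitive to nutrients; `S` ends when the DNA fraction reaches 1 (its
duration is set by the DNA synthesis rate, so it stretches under
glutamine/ATP limitation); `M` lasts 1 h and ends in mitosis.

With the default parameters an isolated cell in the standard environment
cycles in 20.4 ± 1.6 h (calibration target ~20 h).  The cycle-time spread —
checkpoint delays, binomial mitochondria partitioning and the random
volume split — is what desynchronizes an initially synchronized
population; with n = 100 cells the phase-fraction oscillations drop below
the binomial sampling floor after ~3 weeks of simulated time.

### Death

Two routes: (i) Poissonian cytotoxicity with hazard
`λ = λ0 · max(c_AL − c_thr, 0)/AL_scale` — zero below a tolerated tissue
lactate of 0.9 kg/m³ (~10 mM; normally cycling Warburg cells sit near
0.5), rising linearly (hence monotone) above it, with λ0 = 10⁻⁴ s⁻¹;
(ii) certain death when the ATP pool concentration falls below the
starvation threshold.  The hazard senses the *tissue* lactate — the
cell's own content plus its extracellular space — matching the view that
metabolite accretion inside the microenvironment, not just the drained
extracellular wash, is what kills.  Dead cells are frozen — no
transport, no synthesis, cyclins and DNA immutable — except that their
radius decays exponentially (half-life ≈ 33 h) to a residual fraction
(0.5) of the radius at death.  Their extracellular compartments persist in
the diffusion network.

### Mitosis

The mother's soluble contents split with a truncated-Gaussian fraction
(mean 0.5, sd 0.05, bounds [0.35, 0.65]); mitochondria partition
binomially with p = 1/2.  Cell volume is the linear map
`V = V_birth (0.7 · protein/protein_ref + 0.3 · n_mito/100)`, so the two
daughter volumes add up to the mother's exactly.  Daughters are placed
inside the region occupied by the mother, centers 0.4 R0 apart along a
uniformly random axis; they start deeply overlapped, the saturated contact
force pushes them apart over the following hours, and the axis reorients
against the neighborhood as they separate.

## Extracellular network and the stiff solve

The Delaunay triangulation of cell centers defines both the mechanical
neighbor lists and the scaffolding of the discretized diffusion problem.
Each cell's extracellular free volume is a fixed fraction (0.15) of its
volume.  A link between neighbors a, b carries flux
`D_s g_ab (c_a − c_b)` where the geometric factor
`g_ab = A_shared / d` uses a shared-boundary-area estimate
`π min(r_a, r_b)² · taper(d)` — constant for closely packed pairs and
tapering linearly to zero at 1.4 (r_a + r_b).  Surface cells (alpha-shape
boundary, α = (2⟨r⟩)² in the squared-radius convention) get an additional
link to the environment with conductance ∝ their area.  The environment is
a finite, well-mixed volume (default 0.1 mL) whose masses evolve during
growth runs and are pinned during initialization.

The effective diffusion coefficients (defaults: O2 2×10⁻⁹, glucose and
glutamine 1.3×10⁻¹⁰, lactate 2×10⁻¹⁰ m²/s) are deliberately prominent in
the configuration: the emergent interior structure — where the necrotic
core forms, whether the split glucose-flow regime appears — depends
strongly on them.

The extracellular compartments are tiny, so their filling times
(sub-millisecond to microseconds) are 10–12 orders of magnitude below the
spheroid's growth timescale.  The coupled system (19 variables per cell +
4 environment slots) is integrated with implicit Euler at a 50 s default
step, solving each step's nonlinear equations with a modified
Newton–Raphson iteration warm-started from the current state (the warm
start is what keeps convergence to 2–3 iterations).  Details:

- The Jacobian is assembled once per step: the within-cell blocks by
  grouped finite differences (each of the 16 dynamic slots perturbed for
  all cells at once; local terms never couple distinct cells), the
  diffusion operator analytically.
- A backtracking line search on the scaled residual guards against
  overshoot at the sharp oxygen-sensor switch; on stalls the system is
  re-linearized at the current iterate.
- Linear solves are direct (sparse LU) below 4000 unknowns and
  ILU-preconditioned GMRES above.  The environment slots sit at the front
  of the global vector and newborn cells are appended at the back, so a
  preconditioner built a few steps earlier stays index-compatible after
  divisions (new rows get a diagonal tail); it is rebuilt on a fixed
  cadence or on GMRES failure.
- Convergence: maximum scaled update ≤ 1% (configurable).  Per-slot scales
  combine the current value, the population-typical value and class floors
  so that zero-valued slots (fresh cyclins, absent lactate) do not inflate
  the metric.
- Positivity: negative masses after a step are clamped; for extracellular
  species the deficit is redistributed proportionally over positive
  compartments of the same species, so closed-system mass is preserved
  exactly.  Non-convergence triggers step halving (4 levels) before an
  error.

## Mechanics

Cells are stretchable spheres with overdamped dynamics.  The pair force
is Hertzian in the overlap, `k √R* δ^{3/2}` with
`R* = r_a r_b/(r_a + r_b)`, capped at a saturation force for deep
compression; zero at contact; a cubic adhesion well
(`27/4 · s(1−s)²` shape, peak 0.2 nN) between contact and a detachment
distance of 1.2 (r_a + r_b); identically zero beyond.  The force is
continuous everywhere.  Drag is Stokes-like, `γ = 6πη_eff r` with
η_eff = 500 Pa·s — an effective tissue viscosity chosen so that a
freshly divided pair separates over a few hours.  Within each 50 s
biochemical step the mechanical subsystem relaxes in explicit sub-steps
bounded by the stiffest unsaturated contact (`dt < 0.3 γ/k_max`, capped at
40 sub-steps); relaxation that does not finish simply continues in the
next step — the dynamics are quasi-static.  Velocities reported in
snapshots are displacements over the macro step, i.e. the macroscopic
velocity field.

## Program loop

Per step: (1) implicit biochemical solve, then volume update from the
protein/mitochondria map and dead-cell shrinkage; (2) mechanical
relaxation; (3) discrete events — deaths sampled first, then mitoses, in
cell order; (4) geometry/topology refresh (Delaunay, alpha shape);
(5) statistics and snapshots.  Initialization grows the seed population in
a fixed environment at constant count (one daughter of each mitosis is
discarded, death disabled) until the population is desynchronized and
metabolically stationary.  Stop conditions: all cells dead, or the step
budget exhausted.  A fixed seed gives bitwise-identical trajectories; all
randomness flows through one `numpy` Generator in a defined order.

## Scaled-down runs: what they show

The reference experiments behind the emergent-behavior tests run at a
deliberately reduced scale: all four effective diffusion coefficients are
divided by 49, which compresses every diffusion length by 7× (penetration
depth ∝ √D), so the viable rim and necrotic core develop at a ~100 µm
spheroid radius reachable with ~2×10³ cells in ~12 simulated days (about
ten minutes of CPU time), instead of the ~250 µm radius and ~3×10⁵ cells
of a full-scale spheroid.  Concentration-like quantities (central pO2 and
pH, ΔpH at a proportionally rescaled depth) are compared directly;
geometric metrics after multiplying by the length factor 7.  What such
runs demonstrate: the emergence and sharpening of the necrotic core, the
sign structure of the radial velocity field (outward in the proliferating
rim, inward in the contracting core), the split glucose-flow regime —
outward from the core, inward in the rim — and its disappearance when the
glucose diffusivity is raised, and sigmoidal growth.  What they do not
demonstrate: quantitative rim/core metric values at the paper-scale
spheroid size.  The rescaling is not exact — death kinetics, lactate
retention in the necrotic debris and core re-oxygenation carry absolute
time- and concentration-scales — so at desk scale the viable rim comes
out relatively thicker, the re-oxygenated core less hypoxic and the
census more arrest-heavy than the full-scale reference values; the
corresponding checks in the acceptance suite report these discrepancies
rather than hide them.

## Limitations

- The metabolic network is minimal; pH is a phenomenological, monotone map
  from the local tissue lactate concentration (cell + extracellular space),
  not a dynamic variable.
- Cells are spheres; there is no active motility, no extracellular-matrix
  mechanics, and no agar confinement.
- The exact constants of the original supplementary parameter tables are
  not reproduced; the shipped parameter file is a self-consistent,
  physiologically plausible instantiation calibrated to the stated cycle
  time and to literature-scale per-cell O2/glucose consumption, not a
  transcription.
- Single-threaded; the decoupled biochemistry/mechanics update would admit
  the paper's shared-memory parallelism but this implementation does not
  use threads.
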