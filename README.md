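# spherosim

A lattice-free, multiscale simulator of multicellular tumor spheroids
(MTS) — the standard *in vitro* model of pre-vascular solid tumors.  Each
cell is a partly stochastic metabolic automaton (glycolysis, oxidative
phosphorylation switched by an oxygen sensor, glutamine metabolism, ATP
pool, protein/DNA/mitochondrial synthesis, a G1 energetic checkpoint and
cyclin-gated cycle progression); cells exchange O2, glucose, glutamine and
lactate with private extracellular compartments that diffuse into one
another over the Delaunay network of cell centers; and cells push and pull
each other through a Hertz-contact force law with adhesion, moving in the
overdamped regime.  Necrotic-core formation, radial nutrient/pH gradients,
and the internal flows of glucose and of cells themselves are emergent —
nothing in the model prescribes them.

## Model sketch

Per cell, 19 biochemical variables evolve under

- facilitated transport `J = Vmax(pH)·A·[c_o/(Km+c_o) − c_i/(Km+c_i)]`
  (O2 passively, `J = pA(c_o − c_i)`),
- an oxygen-sensing Hill switch `h = c_O2³/(c_O2³+K³)` that gates how much
  glycolytic flux is oxidized (high ATP yield, scaled by the mitochondrial
  density) versus fermented to lactate (low yield); the oxidized fraction
  is capped well below 1 — the Warburg shift — so lactate is produced even
  in normoxia,
- double-substrate Michaelis–Menten biosynthesis
  `v·s₁s₂/((k₁+s₁)(k₂+s₂))` in (glutamine, ATP) for protein, DNA, mtDNA,
- a Poissonian cytotoxic death hazard, zero below a tolerated tissue
  lactate level and rising linearly above it, plus certain death below an
  ATP starvation threshold.

The coupled metabolism–transport–diffusion system spans ~12 orders of
magnitude in timescale (extracellular filling in microseconds, growth over
weeks) and is integrated with implicit Euler (50 s steps) + a modified
Newton–Raphson solve; mechanics relaxes quasi-statically between
biochemical steps.  See `docs/methods.md` for the full account.

## Worked example

Divide one cell and inspect the mitotic placement rule:

```python
>>> import numpy as np, spherosim as ss
>>> cfg = ss.SimulationConfig(seed=1)
>>> rng = np.random.default_rng(1)
>>> pop = ss.Population.standard_newborn(1, cfg.metabolic,
...     cfg.environment.concentrations(), 0.15)
>>> cell = pop.get_cell(0)
>>> cell.phase, cell.DNA = ss.Phase.M, 1.0
>>> cell.radius = 6.3e-6
>>> d1, d2 = ss.divide_cell(cell, rng, cfg.metabolic)
>>> float(np.linalg.norm(d1.position - d2.position) / cell.radius)
0.4
>>> d1.n_mito + d2.n_mito == cell.n_mito
True
```

The daughters sit 0.4 mother-radii apart along a random axis, deeply
overlapped, and the saturated contact force pushes them apart over the
following simulated hours; volume, mitochondria and every soluble species
are conserved exactly.

Run a small spheroid from one seed cell and summarize it:

```sh
spherosim simulate --seed 1 --out out --max-steps 1000 --snapshot-every 500
spherosim metrics out/snapshot_000000050000
```

`metrics` prints the histo-metric summary of a snapshot — surface radius,
necrotic-core radius, viable-rim and hypoxic-rim thickness (the distance
from the surface to the shell where only 5 % of cells remain alive, and
from there to the pO2 < 5 mmHg shell), central pO2 (mmHg) and pH, ΔpH at
200 µm depth, and the live-cell cycle census mapped to G0/G1 / S / G2/M.
At this desk scale (a thousand steps from a single cell) the spheroid is
still small, fully viable and fully oxygenated, so the core metrics read
zero; the gradients and the necrotic core develop in longer runs — the
emergence tests in `tests/test_acceptance.py` grow such a spheroid with
reduced diffusion coefficients (see `docs/methods.md`, "Scaled-down
runs").

A population-level example — desynchronization of an initially
synchronized culture under the constant-count initialization protocol —
is exactly what `scripts/acceptance.py` measures (below).

## Layout

| module | contents |
|---|---|
| `spherosim.metabolism` | cell state, rate laws, cycle automaton, division |
| `spherosim.diffusion` | extracellular network, implicit-Euler/Newton solve |
| `spherosim.geometry` | Delaunay adjacency, alpha-shape surface, contacts |
| `spherosim.mechanics` | force law, overdamped motion, dead-cell shrinkage |
| `spherosim.engine` | initialization protocol, program loop, termination |
| `spherosim.analysis_io` | snapshots (CSV/JSON/VTK), profiles, metrics, flows |
| `spherosim.params` | parameter dataclasses + versioned YAML defaults |
| `spherosim.cli` | `spherosim simulate / init-population / resume / profile / metrics / flow / growthcurve` |
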