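# adhesim

Off-lattice, three-dimensional agent-based simulation of collective cell
migration through extracellular matrix (ECM), for researchers in cell
biophysics studying how receptor-mediated adhesion and traction shape the
stability and motility of cell groups — pairs first, then larger
clusters.

## The model

Cells are spheres of radius `R` that may partially overlap (an
abstraction of deformability) and carry two families of coarse-grained
surface receptors, placed uniformly at random on the sphere: **C-C
sites** mediating cell-cell adhesion and **C-M sites** mediating
cell-matrix traction.  Inertia is negligible, so forces balance at every
instant and each cell moves at

```
v_i = (F_adh + F_trac + F_rep) / (6 π η R)
```

through an ECM modeled as a homogeneous viscous medium (Stokes drag,
viscosity η).  C-C sites engage one-to-one across cells — nearest
available partner within a cutoff `r_cut` — and each engaged pair pulls
with a force linear in the site separation; sites trapped in the overlap
region of two cells contribute in bulk through `min(m_i, m_j)`.  Each
matrix-exposed C-M site pushes its cell radially outward with force
`K·F^LR`; the random finite placement leaves a nonzero resultant that
propels the cell.  Overlapping cells repel linearly in the center
distance, with an impenetrable core of diameter `2R(1-α)`.  The center
ODEs are integrated by classical RK4, one timestep per synchronous
movement cycle; each receptor family is either *static* (fixed
directions: persistent motion) or *dynamic* (resampled every cycle),
giving four regimes, cases I–IV.

Key observables: the **time of first break-up** (first moment a pair's
center distance exceeds `2R`), the **companion time** (total bound time),
break-up fractions over independent runs with twice-SEM error bars and
Gompertz fits `exp(-exp(-c(x-b)))`, and for clusters the radius of
gyration and mean overlapping-neighbor count.  A power-law schedule
`σ(t) = σ0 (1-(t/T)^p)` models adhesion depletion.  See
`docs/methods.md` for the full force laws, conventions and parameter
table.

## Worked example

Simulate one touching pair with persistent (static) sites at a traction
inside the break-up transition, and summarize it:

```python
from adhesim import ModelParams, init_pair, run, summarize_pair

params = ModelParams(f_lr=0.0008, seed=4).with_case("I")
traj = run(init_pair(params), params)
print(summarize_pair(traj, params.R))
```

Running `python examples/pair_trajectory.py` (the same computation with
narration) prints:

```
frames: 801, t_total: 8.0
initial distance: 2.000 (touching, 2R)
minimum distance: 1.995 (adhesive settling below contact)
final distance:   3.307
time of first break-up: 0.8400000000000005
companion time:         0.84
the pair detached; with static sites traction points in a fixed direction, so break-ups are effectively irreversible
```

The pair settles slightly below contact (adhesion pulling against the
overlap repulsion), detaches at t = 0.84 when the fixed-direction
traction wins, and never rejoins — hence companion time equals the time
of first break-up, the signature of the persistent regime.  With dynamic
C-M sites (case II) the traction direction is resampled every cycle and
detached pairs rejoin, so the companion time exceeds the first break-up
time; `examples/breakup_sweep.py` shows this contrast across a whole
traction grid, and the other scripts in `examples/` cover adhesion
depletion, cluster dissociation and the zero-traction bound equilibrium.

A thin CLI wraps the same library calls:

```
adhesim run --case I --seed 4 --out out/          # one trajectory -> CSV
adhesim sweep-pairs --case II --runs 100 --out out/
adhesim cluster --cells 50 --f-lr 0 --f-lr 0.001 --f-lr 0.01 --out out/
```

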