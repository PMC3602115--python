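# Methods

## Model

`adhesim` simulates groups of cells migrating through extracellular matrix
(ECM) in three dimensions with an off-lattice, cell-center representation.
Each cell is a sphere of fixed radius `R` that may partially overlap its
neighbors (an abstraction of deformability) and carries two families of
coarse-grained surface receptors, stored as unit directions in the cell's
body frame:

* **C-C sites** mediate cell-cell adhesion,
* **C-M sites** mediate cell-matrix traction.

Cells cannot rotate, so a site's world position is always
`center + R * direction`.  Inertia is negligible at cellular scales: the
forces on each cell balance at every instant,

```
F_adh + F_trac + F_rep + F_drag = 0,      F_drag = -6 pi eta R v,
```

with the ECM modeled as a homogeneous viscous medium of viscosity `eta`
(Stokes drag).  Solving for `v` yields a set of coupled, autonomous,
first-order ODEs for the cell centers.

### Adhesion

C-C sites interact one-to-one: each site engages at most one partner site
on another cell, preferring the nearest available partner within the
cutoff `r_cut`.  An engaged pair at site-site distance `s` pulls the two
cells together (force applied at the centers, along the line of the two
sites) with the linear law

```
|F| = (sigma_pair / r_cut^2) * (r_cut - s),        0 <= s <= r_cut,
```

zero at the cutoff and maximal (`sigma_pair / r_cut`) at contact.  Sites
that fall strictly inside a neighboring sphere ("trapped" in the
lens-shaped overlap region) are handled in bulk: if `m_i` and `m_j` sites
of the two cells are trapped in their mutual overlap, only
`min(m_i, m_j)` of them participate (sites must be paired to pull), with
total magnitude `(sigma_pair / r_cut) * min(m_i, m_j)` along the line of
centers.

`sigma_pair` is the energy scale of a *single* engaged pair.  The model
parameter `sigma0` is the adhesion budget of a whole cell, shared across
its `n_cc` sites: the dynamics resolves `sigma_pair = sigma(t) / n_cc`.
This normalization is what makes the reference parameter set mechanically
consistent: with order `sqrt(n_cc)`-to-`n_cc/4` sites engaged near
contact, the total adhesive pull stays of order `sigma0`, and the linear
repulsion (scale `eps`, below) can balance it at a separation *above* the
incompressible core — a stable bound state exists at the defaults
(`sigma0 = 0.004 < eps = 0.025`).  A linear-stability estimate makes the
threshold explicit: the trapped-count term steepens with `sigma0`, and
once `sigma0` approaches `eps` the bound state disappears and pairs
collapse onto the core, where the wall force flings them apart.  That
collapse-and-rebound regime is reproduced by the model at high adhesion,
and is regarded as unphysical (see Limitations).

### Matching algorithm

The one-to-one negotiation is a *globally shortest-first greedy matching*:
all cross-cell candidate site pairs with `s <= r_cut` (among sites not
trapped in any overlap region) are sorted by ascending distance and
accepted greedily, skipping candidates whose either endpoint is already
engaged.  Exact distance ties — a measure-zero event for random site
placements — are broken by a random per-step priority permutation of the
site indices, so no site index is systematically favored.

Two properties motivated this choice over a per-site scan in random
order:

1. **Determinism of the static regimes.**  The matched set, and hence the
   force at fixed positions, is a deterministic function of the
   configuration.  With static sites the dynamics is then a genuine ODE
   and a relaxing pair converges to a true fixed point (per-cell speed
   below 1e-8 in the packaged check).  A random-scan greedy makes the
   matched set depend on the scan order whenever two sites contest the
   same nearest partner — a common event at ~20-40 engaged sites — which
   injects permanent force chatter of order `sigma0 / n_cc` and destroys
   the fixed point.
2. **Symmetry.**  The matching is invariant under swapping the two cells'
   roles, so no "scanning side" convention is needed, and for multi-cell
   configurations the same global pass enforces that a receptor engages at
   most one partner across *all* neighbors.

A site trapped in the overlap regions of several cells at once is counted
against one of them, drawn uniformly per step from the eligible neighbors
(one frozen uniform per site per step).

### Traction

Each C-M site exposed to the matrix — lying inside no other cell —
contributes a radially outward force `K * f_lr` along the surface normal
at the site (`K` the adhesivity function value, equal for all sites;
`f_lr` the force per ligand-receptor complex).  Sites trapped in overlap
regions are inactive.  A uniformly covered isolated sphere would feel
zero net traction; the finite random placement leaves a resultant of
order `sqrt(n_cm) * K * f_lr` in a random direction, which is the engine
of migration.  With static sites this direction is fixed (persistent
motion, e.g. under a chemotactic cue); resampling the sites each movement
cycle randomizes it (amoeboid probing of the matrix).

### Repulsion

Overlapping spheres repel along the line of centers, linearly in the
center distance `d`:

```
|F| = (eps / (2R)^2) * (2R - d),        2R(1-alpha) < d < 2R,
```

zero at and beyond contact.  Each cell has an incompressible core of
diameter `2R(1-alpha)` (`alpha` is the compressibility — the deformable
fraction of the radius); at or inside the core distance an "infinite
wall" acts, realized numerically as a finite capped magnitude
(`wall_force_cap`, default 1e3 force units) so the ODE remains
integrable.  No event detection is attempted: a trajectory that reaches
the wall takes a large velocity for one step and rebounds, which is the
expected (and biologically meaningless) signature of over-compression.

### Boundary conventions

All measure-zero boundary cases are fixed once: "inside" a sphere is
strict (`<`), so tangent cells (`d = 2R` exactly) do not overlap and
their sites are exposed; a pair at exactly `d = 2R` is classified *bound*
(the bound side of the classification is closed); coincident engaged
sites (`s = 0`) exert zero force (direction undefined); repulsion
vanishes at exact contact.  Thus a tangent pair is bound but force-free.

## Time integration

The center ODEs are advanced by the classical fourth-order Runge-Kutta
scheme with timestep `dt`.  One step is one complete, synchronous
movement cycle (protrusion, attachment, traction, detachment) for every
cell.  Within a step the following are frozen: the site directions, the
matching tie-break priorities, the trapped-site neighbor draws, and the
adhesion scale (evaluated at the step's start time).  The geometric
predicates themselves — overlap, exposure, the matching — are re-evaluated
at each RK4 stage from the stage positions, so the stage field is a
deterministic function of position and the step retains its classical
order on smooth segments (observed order ~3.9 against a dt/100 reference
in the packaged check).  Between steps, site sets are resampled uniformly
on the sphere according to the regime:

| case | C-C sites | C-M sites |
|------|-----------|-----------|
| I    | static    | static    |
| II   | static    | dynamic   |
| III  | dynamic   | static    |
| IV   | dynamic   | dynamic   |

Uniform sphere sampling normalizes standard-normal triples (exactly
uniform by rotational invariance; numerically-zero draws are rejected).
A run's randomness comes from one seeded generator, so a trajectory is a
pure function of (initial state, parameters, seed).

### Adhesion depletion

Weakening intercellular bonds (e.g. an epithelial-to-mesenchymal
program) are modeled by a power-law decay of the adhesion scale,

```
sigma(t) = sigma0 * (1 - (t / t_total)^p),       p > 0,
```

clamped at zero; every exponent reaches zero exactly at the end of the
run.  Small `p` depletes early, large `p` late; `p = None` keeps
adhesion constant.

## Parameters

All quantities are nondimensional (length in cell radii, time in movement
cycles at the reference scale).  Reference values:

| parameter | symbol | default | meaning |
|-----------|--------|---------|---------|
| `R` | R | 1 | cell radius (the length unit) |
| `dt` | Δt | 0.01 | movement-cycle timestep |
| `n_cc` | N_C-C | 100 | adhesion sites per cell |
| `n_cm` | N_C-M | 100 | traction sites per cell |
| `eta` | η | 0.0016 | ECM viscosity (Stokes drag 6πηR) |
| `r_cut` | r_cut | 1 | adhesion bond cutoff (site-site) |
| `sigma0` | σ | 0.004 | per-cell adhesion energy budget |
| `eps` | ε | 0.025 | repulsive (deformation) energy scale |
| `alpha` | α | 0.5 | compressibility (core diameter 2R(1-α)) |
| `K` | K | 1 | adhesivity function value |
| `f_lr` | F^LR | 0.01 | force per ligand-receptor complex |

Dimensionally these correspond to cells of order 10 μm radius, movement
cycles of order 10 minutes, and per-complex forces of order piconewtons;
the package computes in nondimensional units throughout and performs no
unit conversion.

Choices without a printed reference value, fixed once as experiment
defaults:

* `t_total = 8.0` — long enough for a bound pair to settle and for
  transition-window tractions to produce both bound and broken batches;
  run length is an experiment knob, not a model constant.
* `wall_force_cap = 1e3` — about 40× the maximum linear repulsion, large
  enough that the core is effectively impenetrable on the step scale and
  small enough that a wall event stays finite.
* Cluster initialization: random uniform positions in a ball sized for a
  volume packing fraction of 0.3, rejection-sampled so that no two
  centers are closer than the core diameter; a documented attempt budget
  turns an overcrowded request into an error rather than a hang.
* Seed ladder: run `k` of grid point `i` uses
  `base_seed + i * runs_per_point + k`, making batches reproducible,
  independent of iteration order, and disjoint across points.
* Default depletion exponents for the depletion protocol:
  p ∈ {0.5, 1, 2, 4}, spanning early, linear and late depletion.
* Sweep grids: the interesting traction range depends on every other
  scale, so the default grid is found at run time by a bisection
  pre-pass (`find_breakup_window`) that brackets break fractions 0 and 1
  on small probe batches, then spans the bracket geometrically.

## Observables

* **Bound/detached**: a pair is bound iff its center distance is ≤ 2R.
* **Time of first break-up (TFB)**: first sampled time with distance
  > 2R; `None` if never.  Batch means truncate never-broken runs at
  `t_total` (so mean-TFB curves saturate at the maximum time rather than
  dropping runs); this convention is stated in the batch metadata.
* **Companion time (CT)**: total bound time, summed over sample
  intervals by the left-endpoint rule at the trajectory's resolution; no
  sub-step crossing interpolation (the model's time resolution is the
  movement cycle).  CT ≥ TFB whenever a break-up exists.
* **Error bars**: twice the standard error of the mean (ddof = 1).
* **Break-fraction curves** are fitted with the Gompertz sigmoid
  `y = exp(-exp(-c (x - b)))`: `b` is the displacement along the
  abscissa (the inflection, where y = 1/e) and `c > 0` the growth rate
  toward the asymptote 1.  The form's asymmetric approach to the upper
  asymptote fits break-up saturation better than a logistic.  The fit is
  a deterministic least-squares solve initialized at `b` = abscissa of
  the point nearest 1/e, `c = 1`; non-convergence raises.
* **Radius of gyration**: RMS distance of all cell centers from their
  centroid, counting every cell regardless of connectivity.
* **Mean overlapping neighbors**: average over cells of the number of
  other cells with center distance < 2R.

## What the generated configurations do and do not emulate

Initial conditions are generated internally: uniform random site
placements on each sphere and either a touching pair on the x-axis
(separation `d0 = 2R` by default, configurable down to the core limit) or
the random ball packing for clusters.  These reproduce the *model's*
study conditions — independent random receptor configurations over
replicate runs — and nothing more.  Passing checks on them demonstrates
internal consistency of the force laws, integrator and statistics; they
do not capture features of living tissue that the model itself abstracts
away: heterogeneous or fibrous ECM, ligand depletion, receptor transport
along the membrane, cell deformation beyond the overlap abstraction,
rotation, proliferation or death, or asynchronous movement cycles.
Conclusions about real cells therefore rest on the model's biological
fidelity, not on these tests.

## Problem sizes in the packaged checks

The test suite and the acceptance script run reduced-scale versions of
the full protocols, chosen as the smallest batches whose signatures are
statistically unambiguous: sweeps use 4 traction points × 10 runs per
point (the full protocol default is 100 runs/point), the negotiation
oracle uses 1000 random ≤6-site instances, the cluster check uses the
full 50 cells for initialization plus a 100-step evolution, and the
fixed-point check integrates a single pair until its speed falls below
1e-8 (a few hundred time units).  The depletion and viscosity-crossover
protocols are exercised at example scale (`examples/`) and through
configuration rather than asserted in the default suite, because their
signatures need larger batches to clear noise.

## Known limitations

* The wall cap makes core penetration events finite but unphysical
  (single-step rebounds); runs in the high-adhesion / low-`alpha` corner
  are dominated by them and should be read as "over-compressed", not as
  trajectories.
* Matching is greedy, not optimal: a maximum-weight matching could
  differ.  Greedy shortest-first is the field's convention for this kind
  of receptor pairing, is O(candidates log candidates), and is what the
  calibration and statistics were built on.
* The adhesion scale enters traction-free equilibria only through
  `sigma0 / n_cc`; changing `n_cc` at fixed `sigma0` changes the number
  of engaged pairs and hence slightly shifts equilibria — site counts
  are part of the parameter set, not a numerical resolution knob.
* With depletion active the adhesion scale is frozen over each step
  (evaluated at the step's start), an O(dt) splitting consistent with
  the per-cycle interpretation of the forces.
* Trajectories sample at step resolution; TFB and CT are therefore
  quantized at `dt` (and at the thinning interval if thinning is used).
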