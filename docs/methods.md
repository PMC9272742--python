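# Methods

This note documents the models, numerical methods, fixtures and design
choices behind `cajal`, in the order a simulation passes through them.

## Units

All internal quantities use the conventional neurosimulation scheme:
time ms, voltage mV, concentration mM, length μm, specific capacitance
μF/cm², axial resistivity Ω·cm, density conductance S/cm², point current
nA, lumped conductance μS, lumped capacitance nF, diffusion coefficient
μm²/ms. The scheme is chosen so that `μS·mV = nA` and `nF·mV/ms = nA`
hold exactly; the conversions are `C[nF] = cm·area[μm²]·1e-5`,
`g[μS] = gbar[S/cm²]·area·1e-2`, `R_axial[MΩ] = ra·Δx/(πr²)·1e-2`.
`cajal.units.unit_factor` exposes the conversion table (e.g. `hour` →
3.6e6 ms), which is how the circadian fixture states hour-scale rate
constants without a separate engine.

Physical constants are CODATA-2018 exact values (F = 96485.33212331 C/mol,
R = 8.31446261815324 J/(mol·K)).

## Morphology and discretization

Morphologies are trees of sections; each section is a sampled polyline
with per-sample diameters, and consecutive samples bound frusta
(truncated cones). SWC ingestion contracts soma samples (type 1) to one
cylinder preserving the summed frustum lateral surface (a point soma of
radius r becomes an L = d = 2r cylinder, preserving the sphere surface
πd²); unbranched runs of non-soma samples become sections split at
branch points, each section leading with its parent sample's coordinate.

Discretization at `nseg` compartments per section places centers at
fractions (2i−1)/(2·nseg). Membrane area is the exact lateral frustum
surface integrated over the compartment span (slant form, π(r₁+r₂)·s);
volumes use the exact frustum volume; axial conductance between adjacent
centers is the reciprocal of `ra·∫dx/(πr(x)²)` over the two half
compartments, which for linear radius has the closed form `Δl/(π r_a r_b)`
per piece. A child section's first compartment couples to the parent
compartment containing the attachment fraction, with the parent-side
resistance integrated from that compartment's center to the attachment
point. Defaults: cm = 1 μF/cm², ra = 100 Ω·cm (round-number values in
the standard physiological range; every fixture states its own values).

Section ends (fraction 0/1) map to the nearest compartment center for
stimulus, recording and synapse placement — a documented convention; no
extra boundary nodes exist.

## Mechanism DSL and kernel generation

The DSL is a deliberately small NMODL subset: NEURON / UNITS / PARAMETER /
STATE / ASSIGNED / INITIAL / BREAKPOINT / DERIVATIVE / NET_RECEIVE blocks,
`SOLVE … METHOD cnexp|derivimplicit`, arithmetic with `^`, comparisons
evaluating to 0/1 (how the current-step stimulus gates itself without a
conditional statement), and calls to a fixed function table. KINETIC,
LINEAR, FUNCTION_TABLE, VERBATIM, TABLE and variable-step support are
out of scope. Unit strings are retained but not dimension-checked.

Each mechanism is translated twice from the same validated spec: a
*reference* kernel (scalar Python over `math`, one instance record at a
time) and a *compact* kernel (vectorized numpy over contiguous
per-variable arrays). Generation is deterministic (same source → byte
identical kernel text) and the two translations must agree to 1e-12
relative — the property that licenses backend switching.

ODE classification is symbolic (sympy): a state is *linear* when its
rate is affine in the state with coefficients free of all states; such
states get the exact exponential update
`s' = −a/b + (s+a/b)e^{b·dt}` (ε-guard at |b| ≤ 1e-12 switching to
`s + a·dt`). Rather than emitting symbolic a and b, kernels evaluate the
(locals-inlined) rate at s = 0 and s = 1: for an affine rate this yields
a and a+b exactly and sidesteps symbolic simplification in generated
code. Nonlinear states are advanced jointly by damped Newton on the
implicit-Euler residual (tol 1e-10, ≤ 50 iterations, forward-difference
Jacobian, step halving on residual growth).

Membrane conductance loads are numerical: `g = ∂i/∂v` by forward
difference with ε_v = 0.001 mV, evaluated by re-running the BREAKPOINT
current assignments at v+ε_v into shadow locals. This works for arbitrary
current expressions and matches the implicit linearization the voltage
step needs. A global `celsius` (default 6.3 °C) is visible to rate
expressions; the built-in hh mechanism carries the classic q10 = 3^((T−6.3)/10).

Built-ins: squid-axon `hh` (states m, h, n; na/k ions plus leak),
passive `pas`, single-exponential synapse `expsyn` (NET_RECEIVE adds the
event weight to its conductance), and a current-step point process
`stim` (onset/dur/amp, negative current convention = depolarizing
injection).

## Voltage solver

The implicit-Euler voltage system is tree-structured; `hines_solve`
eliminates leaf-to-root and back-substitutes root-to-leaf with exactly
one division per node (the pivot reciprocal — the division count is
recorded and asserted in tests). The sequential kernel is jitted with
numba when available; the pure-Python loop is the authoritative
implementation and produces identical results. On unbranched cables the
method reduces to the Thomas algorithm (tested against scipy's banded
solver).

Two node orderings are provided: `identity` and `cell_interleaved`,
which sorts nodes by (depth level, cell id, original index) so same-depth
nodes across cells are contiguous. These stand in for production cell
permutations whose exact construction lives in prior work on the
optimized engine; the testable contract — renumbering must not change
results beyond floating-point reassociation (≤ 1e-9 relative) — is what
the package enforces.

## Engine and transfer

The reference backend stores one record per compartment (voltage plus
co-located mechanism instance dictionaries) and steps with scalar
kernels; the compact backend stores every variable in a contiguous array
under the node permutation, instances sorted by permuted node index, and
steps with vectorized kernels. A `TransferImage` snapshots V, every
mechanism variable (in reference instance order), the clock, detector
re-arm flags and the pending event queue; transfer in either direction
is bit-exact for stored arrays and preserves the event multiset, so a
run may switch backend at any step boundary and continue seamlessly.

Step phases, in order: (1) deliver events with time in `(t, t+dt/2]`
(boundary inclusive, 1e-9 ms tolerance, FIFO by insertion sequence on
ties); (2) evaluate mechanism currents at V(t); (3) assemble and solve
the voltage system → V(t+dt), with a finite-value check naming the
offending compartment; (4) advance mechanism states using V(t+dt)
(staggered update, consistent with cnexp); (5) threshold-crossing spike
detection (spike time = end of step, no sub-dt interpolation; a detector
re-arms only after falling below threshold), scheduling connection
events at spike time + delay. Wall time per phase accumulates in a
timing table under fixed names ("event delivery", "current calculation",
"matrix solver", "state update", "spike detection/exchange", "data
transfer"); the table is reporting-only — performance is never asserted,
since it is hardware-dependent.

The engine is single-process. Distributed spike exchange is represented
only by the queue abstraction and its timing label.

## Networking and stimulus streams

Connections carry (source gid, threshold detector) → (point process,
weight, delay ≥ 0). Stimulus streams are counter-based (Philox): every
draw is a pure function of (gid, stream id, seed) and the draw index,
never of call order or construction order, so rasters are invariant to
how a model is assembled. Poisson trains use inverse-CDF exponentials
on the keyed uniform stream.

## Reaction–diffusion

**1D.** Finite-volume diffusion on the compartment tree: coupling
`g_ij = D·A_ij/Δx_ij` with the cross-section area at the shared
boundary; backward Euler via the Hines solver. The flux form is
antisymmetric, so sealed-domain total moles are conserved to roundoff
and the uniform state is exactly stationary.

**3D.** Douglas–Gunn ADI with three per-axis tridiagonal stages (a
batched Thomas algorithm over all grid lines of equal length). Voxel
grids carry fractional volumes; the face conductance between voxels is
weighted by the face-adjacent mean fraction `(frac_i+frac_j)/2` and each
row is scaled by `1/(frac_i·dx³)` — the conservative finite-volume
choice (the exact flux law between fractional boundary voxels is not
prescribed by the architecture this follows; this is our choice, and
conservation is exact under it). Sealed boundaries fall out of omitting
couplings to inactive neighbors. The scheme is second-order in time
(Richardson-verified order ≥ 1.8 in the tests, ~2.0 measured).

**Extracellular space.** A single axis-aligned box under macroscopic
volume averaging: free volume fraction α ∈ (0,1], tortuosity λ ≥ 1,
effective diffusion D/λ², sealed faces. Membrane currents add
`dC/dt = 1e6·I/(z·F·α·dx³)` mM/ms (I in nA, dx in μm) to their voxel.
With α = λ = 1 the step is exactly the plain 3D operator.

**Voxelization.** A morphology decomposes into convex bodies: one
frustum per consecutive sample pair, plus spherical joins at sample
points shared by two frusta and at branch attachments (radius = largest
adjacent frustum radius there). Terminal ends carry no join sphere, so a
two-point cylinder voxelizes as a bare frustum. Each body is voxelized
independently on a common lattice and merged by elementwise max. A
boundary voxel's fraction is the inside-count of its k³ subvoxel centers
(default k = 5); `boundary="full"` reproduces the legacy rule (any
intersected voxel counts fully), which systematically overestimates
volume — the package's tests reproduce that contrast (≈ 0.35% vs ≈ 27%
on the 20 μm × 2 μm test cylinder at dx = 0.25 μm). Because subsampling
error is quasi-random in the lattice offset, error-vs-k monotonicity is
asserted on the mean over several offsets, not per-offset.

**Reactions.** Reaction systems compile once (sympy → lambdified numpy
closures for the rate vector and its Jacobian, cached on the canonical
expression text). Because reactions couple only co-located species, the
implicit-Euler update solves an independent (species × species) Newton
system per location, vectorized over locations (tol 1e-10, ≤ 50
iterations, step damping that also rejects negative iterates; tiny
negative roundoff is clipped at −1e-12). Rate expressions may reference
`v`, the membrane potential probe, enabling voltage-driven chemistry
without a DSL mechanism.

**Operator splitting.** `RxdModel.step` applies reactions first, then
diffusion — first-order splitting, fixed order, documented; second-order
(Strang) splitting is a non-goal. 3D grids are driven directly through
`dgadi_step`/`ecs_step`; a species lives in one representation (1D tree
or 3D grid) — hybrid 1D/3D coupling of the same species is out of scope.

**Species overlap rule.** A species name may be declared repeatedly as
long as the geometric domains are disjoint (different cells, different
grids, distinct point regions); overlap is a registration-time error
naming the species and both regions. This is what lets one cell object
carry its complete kinetics and be reused in larger models.

**Nernst.** `E = 1000·R·T/(zF)·ln(c_out/c_in)` mV with T = celsius +
273.15; errors on non-positive concentrations or zero valence.

## State archive

A little-endian binary format: magic `CAJS`, version (0 without
extensions, 1 with), t, voltages, per-mechanism per-variable float64
arrays in reference instance order, the full event queue (time, sequence,
target, weight), the event sequence counter, and detector flags; a
version-1 trailer appends (count, identifier, length, payload) extension
records. Trailer-less archives are byte-reproducible and parse under the
version-0 reader. The reaction-diffusion extension registers itself the
first time a model declares a species — importing the subsystem alone
registers nothing — and serializes concatenated concentration arrays
zlib-compressed. Restore is shape-checked against the constructed model,
unknown extension identifiers are an error naming the identifier, and
resuming after restore is bit-identical to the uninterrupted run. The
spike raster is treated as an output record, not dynamical state, and is
not archived.

## Fixtures (what the synthetic models emulate)

* `ball_and_stick`: 20 μm hh soma plus 200 μm passive dendrite
  (g_pas = 0.0005 S/cm², e = −65 mV), 0.5 nA × 3 ms somatic step — the
  smallest model with realistic spiking; subthreshold runs use 0.05 nA.
* `ring_network`: N such cells, expsyn (τ = 2 ms) at mid-dendrite,
  soma detector (−20 mV) to next cell's synapse at weight 0.05 μS and
  2 ms delay, kicked once at t = 1 ms — deterministic propagation with a
  measurable per-hop latency (≈ 2.85 ms at dt = 0.025 ms).
* `test_cylinder`: the 200 μm × 2 μm cylinder at 1,001 segments used for
  both cable and diffusion benchmarks.
* `circadian`: the Leloup–Goldbeter PER/TIM Drosophila oscillator —
  10 species (per/tim mRNAs, three phosphorylation states each, the
  cytosolic and nuclear complex), 21 elementary rate processes, the
  published parameter set in nM and hours (vdT = 3.0 nM/h, Hill n = 4,
  kdN = 0.01/h as the only first-order loss term), started from a
  generic low-concentration state with a ~100 h transient onto the limit
  cycle. Measured period ≈ 24.9 h.
* `random_tree`: seeded random branching passive morphologies for
  topology property tests.

These fixtures are idealized: noiseless geometry, homogeneous channel
densities, single cells or small rings, and deterministic stimuli.
Passing tests therefore demonstrate numerical correctness of the
methods under controlled conditions, not fidelity to any particular
biological dataset; real morphologies (soma outlines, spines, varying
diameters) and channel diversity are exercised only through the same
code paths, not represented statistically.

## Problem sizes and step sizes used in the checks

Chosen as the package's own accuracy/runtime balance: cable checks run
the 1,001-segment cylinder to steady state at dt = 0.1 ms (40 ms ≫ τ_m =
1 ms); Hodgkin–Huxley fine-step comparisons use dt/100 = 0.25 μs on the
smooth subthreshold trajectory — on the action-potential upstroke
(~500 mV/ms) a first-order method's phase error dominates any pointwise
bound, so spiking runs are compared by spike count and spike time (within
one dt) instead; 3D diffusion uses 41³ sealed boxes (10³ steps for
conservation) and 21³ grids for Richardson order; the circadian model
integrates at dt = 0.005 h for measurement after a dt = 0.02 h transient,
against a BDF oracle at rtol 1e-9 (measured per-species RMSE ≈ 0.15% of
range over one period).

## Known limitations

* Fixed-timestep implicit Euler only; no Crank–Nicolson for voltages and
  no variable-step integration.
* The DSL subset excludes kinetic schemes and verbatim code; mechanisms
  needing them must be rewritten in DERIVATIVE form.
* Single process, single thread of control; the optimized backend
  reproduces layout and transfer semantics, not SIMD/accelerator
  performance.
* The ECS is one sealed axis-aligned box; periodic or absorbing
  boundaries are not implemented.
* SBML support covers export (and re-import of what it exports) of point
  mass-action/rate-law models, Level 3 Version 1 core only.
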