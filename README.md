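# cajal

A desk-scale compartmental neuron and reaction-diffusion simulator built
around the architecture of a modernized multiscale neurosimulation stack:
a mechanism-DSL compiler that translates every membrane mechanism twice
(scalar and vectorized kernels), two interchangeable execution engines —
an array-of-structures *reference* backend and a structure-of-arrays
*compact* backend — with lossless two-way in-memory model transfer,
an O(n) Hines tree solver with pluggable node orderings, event-driven
synaptic networking with counter-based stimulus streams, a
reaction-diffusion subsystem (1D tree diffusion, 3D Douglas–Gunn ADI,
morphology voxelization with fractional boundary volumes, compiled
reaction kernels, SBML export), and a versioned binary state archive with
registered save extensions.

It is aimed at computational neuroscientists and simulator developers who
want a small, fully testable implementation of these mechanisms — every
numerical claim in this package is backed by an oracle test (dense linear
algebra, closed-form PDE solutions, adaptive stiff integrators).

## The models

**Electrophysiology.** Membrane potential on a branched neurite obeys the
cable equation; discretized into compartments it becomes, per timestep
(implicit Euler, fixed dt),

```
(C_i/dt + Σ g_mech,i + Σ_j g_ij) V_i' − Σ_j g_ij V_j' = C_i/dt · V_i + Σ i_rhs,i
```

a tree-structured linear system solved in O(n) with exactly one division
per node (Hines' algorithm). Mechanisms (channels, synapses, stimuli) are
written in an NMODL-subset DSL; DERIVATIVE-block ODEs that are linear in
their state (`ds/dt = a + b·s` with state-independent coefficients)
receive the analytic exponential (cnexp) update
`s' = −a/b + (s + a/b)·e^{b·dt}`, all others a damped-Newton implicit
Euler step.

**Reaction–diffusion.** Chemical species diffuse on the same tree (1D,
via the Hines solver) or on voxelized 3D geometry (Douglas–Gunn
alternating-direction implicit; extracellular space uses macroscopic
volume averaging with free-volume fraction α and tortuosity λ, effective
D/λ²). Reactions couple species only at the same location, so the
implicit reaction solve factorizes into per-location Newton iterations
on small species×species Jacobian blocks. Nernst potentials follow
`E = (RT/zF)·ln(c_out/c_in)`.

## Worked example

```python
import numpy as np
from cajal.engine import SimConfig, Simulation
from cajal.fixtures import build_ball_and_stick

model, info = build_ball_and_stick(stim_amp=0.5)   # hh soma + passive dendrite
sim = Simulation(model, SimConfig(dt=0.025, tstop=10.0))
v_soma = sim.record_v(info["cell"], info["soma"], 0.5)
sim.finitialize(-65.0)
sim.psolve(0.5, "reference")     # array-of-structures engine
sim.psolve(10.0, "compact")      # switch to the structure-of-arrays engine

v = np.array(v_soma.values)
print(f"spikes: {[(round(t, 3), gid) for t, gid in sim.spikes]}")
print(f"peak somatic voltage: {v.max():.2f} mV")

ref = Simulation(model, SimConfig(dt=0.025, tstop=10.0))
rec = ref.record_v(info["cell"], info["soma"], 0.5)
ref.finitialize(-65.0)
ref.psolve(10.0, "reference")    # same model, reference engine only
print(f"max |dV| vs reference-only run: "
      f"{np.max(np.abs(v - np.array(rec.values))):.2e} mV")
```

Output:

```
spikes: [(2.175, 0)]
peak somatic voltage: 36.98 mV
max |dV| vs reference-only run: 2.61e-11 mV
```

The 0.5 nA step depolarizes the soma past threshold at 2.175 ms and the
action potential peaks near +37 mV. Switching engines mid-run at 0.5 ms —
every voltage, mechanism state and pending event is transferred in memory
— reproduces the single-backend trajectory to ~1e-11 mV: layout is an
implementation detail, not a modelling choice.

The same models run from the command line:

```sh
cajal fixtures ball_and_stick --outdir demo
cajal run demo/config.yaml                 # recordings.csv + raster.txt + timings
cajal compile demo/hh.mod                  # per-state ODE classification report
cajal fixtures circadian --outdir demo
cajal export-sbml demo/circadian.yaml --out demo/circadian.sbml
```

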