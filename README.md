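# spikesim

A clock-driven simulator for spiking neural networks with
conductance-based Hodgkin–Huxley neurons, written for computational
neuroscientists who want a small, fully transparent CPU reference for
the simulation machinery that large neural simulators implement behind
code generation: equation-defined models integrated with exponential
Euler, sparse (CSR/Yale) synaptic connectivity, two exactly-equivalent
spike-delivery strategies, and trace-based STDP with all-to-all pairing.

## The model

Neurons follow Hodgkin–Huxley dynamics

```
C_M dV/dt = g_L (V_L − V) + g_Na m³h (V_Na − V) + g_K n⁴ (V_K − V) + I_syn
   dx/dt = α_x(V) (1 − x) − β_x(V) x          x ∈ {m, h, n}
```

with the classic Traub–Miles rate curves α_x, β_x (in kHz, as functions
of V/mV).  Synapses are conductance-based: each presynaptic spike
increments a conductance g by the synaptic weight w, g decays
exponentially with time constant τ, and contributes the current
g·(V_rev − V_post).  Spikes are detected when V strictly exceeds
V_thresh = −20 mV outside a 3 ms refractory window; only detection is
suppressed during refractoriness — the ODEs keep integrating.

Every ODE is *conditionally linear* (its right-hand side is a + b·x with
a, b independent of x), so each variable advances one time step
(dt = 0.1 ms by default) by the exact solution of dx/dt = a + b·x with
a, b frozen at step-start values — the exponential-Euler scheme.  Models
are written in a one-line-per-ODE DSL and compiled (via sympy) into
vectorized update kernels in single or double precision.

Plastic synapses implement spike-timing-dependent plasticity with
all-to-all pairing: every pre/post pair contributes
Δw = ±A·e^{−|Δt|/τ_l}, realized exactly by per-neuron exponential
traces, with w clipped to [0, w_max] after every event.

Two benchmark networks are built in:

* **cobahh** — N recurrent Hodgkin–Huxley neurons (80% excitatory, 20%
  inhibitory), pairwise-Bernoulli connectivity with p = min(1, 1000/N)
  so in-degree stays ~1000 at any scale, and tiny recurrent weights so
  activity is scale-invariant.
* **mbody** — an insect mushroom-body circuit: 100 input projection
  neurons (spike sources driven by a structured random pattern
  generator) → N intrinsic Kenyon cells → 100 extrinsic Kenyon cells
  with all-to-all lateral inhibition and STDP on the middle projection,
  with a k = max(1, 2500/N_inputs) parameter-scaling rule.

Spike delivery supports a source-major ("pre") and a target-major
("post") strategy; with a canonical per-target, ascending-source
summation order the two are bit-identical in double precision, which the
test suite verifies spike-for-spike against an independent scalar-loop
reference implementation.

## Worked example

```
$ spikesim --model cobahh --n 500 --duration 1000 --seed 7 --out demo
run complete: 6531 spikes (neurons: 6531); phases [s]: codegen_s=0.012,
synapse_creation_s=0.051, simulation_s=1.546, overhead_s=0.003
$ head -3 demo/spikes_neurons.txt
0.8000 79
0.8000 204
0.9000 15
```

500 neurons simulated for 1 s of biological time produce 6,531 spikes
(~13 Hz per neuron, sustained by the cells' intrinsic excitability and
the initial synaptic conductances).  The spike file lists one event per
line (`time_ms neuron_index`); `demo/summary.json` records the seed,
per-group spike counts, how many neurons (if any) diverged under the
untruncated initial-conductance draws, and the wall-clock split across
the four runtime phases (code generation, synapse creation, simulation,
overheads).  Re-running with the same seed reproduces the spike file
byte-for-byte, with either `--strategy pre` or `--strategy post`.

The same run in Python:

```python
import spikesim as ss
net = ss.build_cobahh(500, strategy="pre", rng=7)
data = net.run(1000.0)          # ms
print(data.count(), data.min_isi())   # 6531 spikes, min ISI >= 3 ms
```

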