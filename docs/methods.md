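# Methods

## Integration scheme

All neuron and synapse models are systems of *conditionally linear*
ODEs: for each state variable x the right-hand side decomposes as
a + b·x, where a and b may depend on every other state variable and on
parameters, but not on x itself.  The parser enforces this by symbolic
differentiation (b = ∂RHS/∂x must not contain x; a = RHS at x = 0).

One step of length dt advances every variable synchronously from
step-start values by the exact solution of dx/dt = a + b·x with a, b
frozen over the step:

    x ← x + (x + a/b)·(e^{b·dt} − 1)

computed through `expm1` for accuracy near b·dt = 0, with the series
limit x ← x + a·dt taken when |b·dt| < 1e−12 to avoid catastrophic
cancellation in (e^{b·dt} − 1)/b.  Freezing a and b per variable at
step-start is the standard exponential-Euler convention; it makes the
update order-free (no within-step sequencing effects) and exact for
pure-decay equations up to one rounding per step.  For Hodgkin–Huxley
gating variables the update is a convex combination of x and the frozen
fixed point x∞ = a/(a+b)·…, so gates initialized in [0, 1] remain in
[0, 1] for any dt > 0.

The scheme is first-order accurate in dt for the coupled system.  The
test suite verifies convergence toward an independent fixed-step RK4
reference on a strongly driven single-neuron action potential at
dt ∈ {0.008, 0.004, 0.002} ms; at coarser steps the max-|ΔV| metric
saturates at spike amplitude because the dominant error is a spike-phase
shift larger than the ~0.3 ms upstroke.

## Units

Internal state is kept in (mV, ms, nS, pF): conductance over capacitance
then has units of 1/ms, consistent with rate curves in kHz and time in
ms, so no conversion factors appear in any equation.  Membrane
capacitances are therefore stored in pF (0.2 nF → 200 pF) and maximal
conductances in nS (20 μS → 20,000 nS).

## Rate curves

The six Traub–Miles rate curves are total functions of v = V/mV.  Three
have removable 0/0 singularities of the form c·u/(e^{u/s} − 1) (α_m at
v = −50, β_m at v = −23, α_n at v = −48); these are evaluated through
the analytic limit c·s whenever |u| < 1e−9, which keeps the curve
continuous to ~1e−5 relative across the switch.  Gate initialisation
uses the fixed point x∞(V) = α/(α+β).

## Spike detection and refractoriness

A spike is recorded when V strictly exceeds V_thresh = −20 mV and the
neuron is outside its 3 ms refractory window.  Detection is a
state-condition test per step, not an upward-crossing detector; the
refractory window is what prevents one ~1–2 ms action potential from
being counted repeatedly.  Refractoriness is bookkept in integer steps
(30 steps at dt = 0.1 ms), never by comparing accumulated float times,
and suppresses only detection — every ODE keeps integrating.

## Spike delivery and the equivalence contract

Connectivity is compressed sparse row: per-source target lists, strictly
ascending, plus a transpose index (built by a CSR→CSC conversion
carrying synapse ids) that exposes the same weight array target-major.
Delivery supports two strategies mirroring the two ways spike
propagation can be parallelised — per emitted spike ("pre") or per
target neuron ("post").  Both accumulate each target's increments in
ascending source order, so they are bit-identical in double precision,
not merely close; the suite checks this on 1,000 randomized instances
and on full network runs.  Increments from spikes at step t first affect
the state update of step t+1 (a homogeneous one-step effective latency;
heterogeneous delays are out of scope).  Spike-source times are snapped
to the nearest grid point with ties to the earlier step; times in
[0, dt) are processed at the first step.

## STDP

Plastic synapses use all-to-all pairing: each pre/post pair (Δt = t_post
− t_pre) contributes Δw = A·e^{−Δt/τ_l} for Δt > 0 and −A·e^{Δt/τ_l}
otherwise, with w clipped to [0, w_max] after every event.  Because the
kernel is exponential, per-neuron traces that decay by e^{−dt/τ_l} each
step and jump by 1 at each spike implement the all-pairs sum exactly;
clipping is the only nonlinearity and both the trace engine and the
brute-force oracle clip at the same event sequence, so they agree to
~1e−13 relative (the residue is per-step rounding of the decay factor).
Within a step, post events are processed before pre events, so a
coincident pair (Δt = 0) takes the depression branch — the only ordering
consistent with the piecewise kernel.  The conductance increment of a
pre spike uses the weight after that same step's depression update (one
consistent convention applied in engine and oracle alike).  Clipping is
applied per event, the literal reading of "clip after Δw is added".

## Benchmark networks

**COBAHH.**  N neurons (N a multiple of 5), 0.8·N excitatory and 0.2·N
inhibitory, each ordered pair (self-pairs included) connected with
p = 1 for N < 1,000 and p = 1000/N otherwise, giving mean total
in-degree N·p = min(N, 1000).  Weights ω·10⁻⁹ nS (ω ~ U[0,1]) are
deliberately negligible so activity is scale-free while propagation
still runs.  V(0) ~ N(V_L − 5, 5²) mV, g_E(0) ~ N(40, 15²) nS,
g_I(0) ~ N(200, 120²) nS, all kept as drawn (untruncated); gates start
at x∞(V(0)).  Connectivity is generated row-wise (binomial degree, then
distinct uniform targets, sorted), distributionally identical to
pairwise Bernoulli at O(S) memory.

Two consequences of these initial conditions are worth knowing.  First,
the neuron model is tonically active: even with zero synaptic input a
cell fires at ~13 Hz, so network activity neither dies out nor explodes
at any N — which is the design goal of this benchmark.  Second, the
untruncated normals give roughly 2% of neurons a net *negative* total
conductance at t = 0; such a membrane runs away exponentially until the
offending conductance decays, and for the deepest draws the state
overflows.  The engine's default policy quarantines these neurons (their
IEEE inf/nan state is kept, they can never cross threshold, and they are
counted in the run summary) and continues; `on_divergence="abort"`
instead raises a diagnostic naming group and variable.  Typical N=2,000
runs quarantine 0–3 neurons and the spike output of all other neurons is
unaffected.

**Mbody.**  100 projection neurons (spike sources) → N_iKC intrinsic
Kenyon cells → 100 extrinsic Kenyon cells.  PN→iKC: Bernoulli p = 0.15,
weights (6.75 + 0.844ν) nS, ν ~ N(0,1), kept as drawn.  iKC→eKC:
all-to-all for N_iKC ≤ 10,000, else Bernoulli p = 10,000/N_iKC; plastic
with A = k·0.1 nS, τ_l = 10 ms, w_max = k·3.75 nS, where
k = max(1, 2500/N_inputs) rescales these parameters relative to the
original 2,500-iKC model (the floor is implemented exactly as stated,
so k never scales down).  eKC→eKC: all-to-all including self-pairs,
50.6 nS, reversal −92 mV.  HH neurons start at V = V_L = −63.56 mV,
m = 0, h = 0.5; n is started at 0 (the natural companion of m = 0, which
the stated initialisation lists without an n value).  Plastic weights
start at k·ω·0.375 nS (ω ~ U[0,1] per synapse) and are promoted with
probability 0.2 to k·(2.5 + 0.5ν) nS, clipped to [0, w_max]; w_max/10 is
read as the unscaled base 0.375 nS so k enters each weight exactly once.

**Input generator.**  10 basis patterns of exactly 20 active PNs; each
is expanded into N_rep = ⌈duration/500 ms⌉ variants by re-drawing each
active PN with probability 0.1 (replacement drawn uniformly from the
currently inactive PNs, preserving 20 distinct actives).  All variants
are presented once, round-robin over bases, at onsets 50·i + U(0, 2) ms
— the jitter shifts the whole pattern, and every active PN emits exactly
one spike per presentation.  The generator emulates structured,
noise-perturbed sensory input; it does not emulate PN rate codes,
background activity, or trial-to-trial count variability, so passing
tests say nothing about those features of real recordings.

With the stated weights, ~30% of iKCs cross threshold per presentation
(~6 Hz per cell): three coincident ~6.75 nS inputs suffice to reach the
regenerative Na⁺ threshold ~14 mV above rest.  Activity is sparse in
time but not restricted to a handful of cells per pattern.

## Problem sizes and determinism

The shipped verification runs use desk-scale sizes chosen so the full
suite completes in minutes on one core: COBAHH at N = 2,000 for 1 s
(cross-strategy spike identity, refractoriness), a 5-neuron COBAHH
network for 1 s against a straight-line scalar-loop reference
(spike-for-spike), 500 random spike-train instances for the STDP
trace/oracle equivalence, and connectivity statistics at N = 4,000
(COBAHH) and N_iKC = 20,000 (Mbody).  All randomness flows through a
single seeded NumPy generator per build; builders are pure functions of
(arguments, seed), so rebuilt networks and re-runs are bit-identical,
independent of precision mode and delivery strategy.

## Known limitations

Single global clock and homogeneous one-step synaptic latency; no
continuous (gap-junction-like) coupling; no stiff or event-driven
integration; serial/vectorized CPU kernels only (the two delivery
strategies model the *algorithmic* contract of parallel spike delivery,
not its concurrency); single precision is supported for state arithmetic
but cross-strategy bit-identity is only contracted in double precision.
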