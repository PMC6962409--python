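"""Clock-driven simulation engine.

A :class:`Network` holds Hodgkin-Huxley neuron groups, spike-source
arrays and sparse synapse groups on a single global clock.  Each step
(duration dt, default 0.1 ms) executes, in order:

1. state update — every neuron group advances one exponential-Euler step
   from step-start values;
2. spike detection (V > V_thresh, strict, outside the refractory window)
   and spike-source emission for the current step;
3. plasticity — trace decay, then post-synaptic events, then
   pre-synaptic events;
4. spike propagation: conductance increments g_target[j] += w_ij under
   the chosen delivery strategy;
5. monitor recording.

Conductance increments applied at step t first influence the state
update of step t+1 (a homogeneous one-step effective delay).

Under the benchmark initial conditions a small fraction of neurons can
start with net negative total conductance (the stated conductance
distributions are untruncated normals), and their membrane state runs
away to IEEE inf/nan.  By default such neurons are quarantined — they
keep their non-finite state, can never cross threshold again, and are
counted per group in ``NeuronGroup.n_diverged`` — and the run continues;
``Network(on_divergence="abort")`` instead raises
:class:`SimulationError` with a diagnostic naming group and variable.

The two delivery strategies — source-major ("pre", loop over each
emitted spike's targets) and target-major ("post", loop over each
target's incoming spikes via the transpose index) — accumulate increments
per target in ascending source order, so in double precision they are
bit-identical by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ReverseIndex, SparseConnectivity, transpose_index
from .equations import EquationSet, ExponentialEulerKernel
from .plasticity import StdpParameters, StdpState, decay_traces, on_post_spikes, on_pre_spikes

__all__ = [
    "SimulationError",
    "NeuronGroup",
    "SpikeSourceArray",
    "SynapseGroup",
    "SpikeData",
    "Network",
    "detect_spikes",
    "propagate_pre",
    "propagate_post",
    "discretize_times",
]


class SimulationError(RuntimeError):
    """Numeric failure during a run (non-finite state)."""


def discretize_times(times, dt: float) -> np.ndarray:
    """Snap spike times to the step grid (nearest step, ties to the
    earlier step); times in [0, dt) map to step 1, the first step at
    which events can be processed."""
    steps = np.ceil(np.asarray(times, dtype=float) / dt - 0.5).astype(np.int64)
    return np.maximum(steps, 1)


class NeuronGroup:
    """State arrays for one population sharing an equation set.

    ``v_var`` names the membrane-potential variable used for threshold
    detection.  ``last_spike_step`` implements refractoriness in integer
    steps, avoiding floating-point comparison of accumulated times; only
    detection is suppressed during the refractory window — the ODEs keep
    integrating.
    """

    def __init__(
        self,
        name: str,
        n: int,
        equation_set: EquationSet,
        initial_state: dict,
        v_thresh: float = -20.0,
        t_ref: float = 3.0,
        v_var: str = "V",
    ):
        self.name = name
        self.n = int(n)
        self.equation_set = equation_set
        self.v_thresh = float(v_thresh)
        self.t_ref = float(t_ref)
        self.v_var = v_var
        self._initial_state = {
            k: np.broadcast_to(np.asarray(v, dtype=np.float64), (self.n,)).copy()
            for k, v in initial_state.items()
        }
        missing = set(equation_set.state_variables) - set(self._initial_state)
        if missing:
            raise ValueError(f"group {name!r}: missing initial values for {sorted(missing)}")
        self.state: dict = {}
        self.last_spike_step: np.ndarray | None = None
        self.kernel: ExponentialEulerKernel | None = None

    def reset(self, dt: float, precision: str) -> None:
        dtype = np.float32 if precision == "single" else np.float64
        self.state = {k: v.astype(dtype) for k, v in self._initial_state.items()}
        self.last_spike_step = np.full(self.n, -(10**9), dtype=np.int64)
        self.diverged = np.zeros(self.n, dtype=bool)
        self._ref_steps = int(round(self.t_ref / dt))

    @property
    def n_diverged(self) -> int:
        return int(self.diverged.sum())

    @property
    def V(self) -> np.ndarray:
        return self.state[self.v_var]


class SpikeSourceArray:
    """Input neurons that emit spikes at predetermined times.

    ``times`` and ``indices`` are parallel arrays (ms, source index);
    times are snapped to the step grid when the run starts.
    """

    def __init__(self, name: str, n: int, times, indices):
        self.name = name
        self.n = int(n)
        times = np.asarray(times, dtype=float)
        indices = np.asarray(indices, dtype=np.int64)
        if times.shape != indices.shape:
            raise ValueError("times and indices must be parallel arrays")
        if times.size and times.min() < 0:
            raise ValueError("spike times must be non-negative")
        if indices.size and (indices.min() < 0 or indices.max() >= self.n):
            raise ValueError("source index out of range")
        order = np.lexsort((indices, times))
        self.times = times[order]
        self.indices = indices[order]
        self._buckets: dict[int, np.ndarray] = {}

    def reset(self, dt: float, precision: str) -> None:
        steps = discretize_times(self.times, dt)
        self._buckets = {}
        for s in np.unique(steps):
            idx = self.indices[steps == s]
            idx.sort()
            self._buckets[int(s)] = idx

    def spikes_at(self, step: int) -> np.ndarray:
        return self._buckets.get(step, _EMPTY_IDX)


_EMPTY_IDX = np.empty(0, dtype=np.int64)


class SynapseGroup:
    """Sparse projection from a source group (or a contiguous slice of
    it) onto a target conductance variable.

    ``source_offset`` maps source-group indices [offset, offset+n_pre)
    onto CSR rows, so sub-populations of one neuron group can drive
    distinct synapse classes.  ``stdp`` enables trace-based plasticity on
    the shared weight array.
    """

    def __init__(
        self,
        name: str,
        source,
        target: NeuronGroup,
        conn: SparseConnectivity,
        weights: np.ndarray,
        target_var: str,
        source_offset: int = 0,
        stdp: StdpParameters | None = None,
    ):
        if conn.n_post != target.n:
            raise ValueError(f"synapse group {name!r}: target size mismatch")
        if len(weights) != conn.n_synapses:
            raise ValueError(f"synapse group {name!r}: weight array size mismatch")
        self.name = name
        self.source = source
        self.target = target
        self.conn = conn
        self._weights64 = np.asarray(weights, dtype=np.float64)
        self.target_var = target_var
        self.source_offset = int(source_offset)
        self.stdp = stdp
        self._rev: ReverseIndex | None = None
        self.weights: np.ndarray = self._weights64
        self.stdp_state: StdpState | None = None

    @property
    def rev(self) -> ReverseIndex:
        if self._rev is None:
            self._rev = transpose_index(self.conn)
        return self._rev

    def reset(self, dt: float, precision: str) -> None:
        dtype = np.float32 if precision == "single" else np.float64
        self.weights = self._weights64.astype(dtype)
        if self.stdp is not None:
            self.stdp_state = StdpState.zeros(self.conn.n_pre, self.conn.n_post, dtype=np.float64)

    def source_spike_rows(self, spikes: np.ndarray) -> np.ndarray:
        """Map spiking source-group indices to CSR rows of this projection."""
        lo = self.source_offset
        hi = lo + self.conn.n_pre
        sel = spikes[(spikes >= lo) & (spikes < hi)]
        return sel - lo


def detect_spikes(group: NeuronGroup, step: int) -> np.ndarray:
    """Indices with V above threshold (strict) and outside the refractory
    window; updates the spikers' refractory bookkeeping."""
    mask = (group.V > group.v_thresh) & (step - group.last_spike_step >= group._ref_steps)
    mask &= ~group.diverged
    idx = np.flatnonzero(mask)
    group.last_spike_step[idx] = step
    return idx


def propagate_pre(spikes: np.ndarray, syn: SynapseGroup, g: np.ndarray) -> None:
    """Source-major delivery: for each spiking source (ascending), add its
    row of weights onto the targets' conductances."""
    if spikes.size == 0:
        return
    rp, ci = syn.conn.row_ptr, syn.conn.col_idx
    pos = np.concatenate([np.arange(rp[i], rp[i + 1]) for i in spikes])
    np.add.at(g, ci[pos], syn.weights[pos])


def propagate_post(spikes: np.ndarray, syn: SynapseGroup, g: np.ndarray) -> None:
    """Target-major delivery via the transpose index: for each target,
    accumulate its incoming spiking sources in ascending order.

    Per-target addition sequences are identical to :func:`propagate_pre`,
    so double-precision results are bit-identical.
    """
    if spikes.size == 0:
        return
    rev = syn.rev
    mask = np.zeros(syn.conn.n_pre, dtype=bool)
    mask[spikes] = True
    sel = mask[rev.row_idx]
    if not np.any(sel):
        return
    tgt = np.repeat(
        np.arange(syn.conn.n_post, dtype=np.int64), np.diff(rev.col_ptr)
    )[sel]
    np.add.at(g, tgt, syn.weights[rev.perm[sel]])


@dataclass
class SpikeData:
    """(time, neuron, group) event records, sorted by time then index."""

    events: dict = field(default_factory=dict)  # group name -> (times, indices)

    def add_group(self, name: str, times: np.ndarray, indices: np.ndarray) -> None:
        self.events[name] = (np.asarray(times, dtype=float), np.asarray(indices, dtype=np.int64))

    def group(self, name: str):
        return self.events.get(name, (np.empty(0), np.empty(0, dtype=np.int64)))

    def count(self, name: str | None = None) -> int:
        if name is not None:
            return len(self.events.get(name, ((), ()))[0])
        return sum(len(t) for t, _ in self.events.values())

    def spike_trains(self, name: str) -> dict:
        """Per-neuron sorted spike-time arrays for one group."""
        times, idx = self.group(name)
        trains: dict[int, list] = {}
        for t, i in zip(times, idx):
            trains.setdefault(int(i), []).append(float(t))
        return {i: np.asarray(ts) for i, ts in trains.items()}

    def min_isi(self) -> float:
        """Minimum inter-spike interval over all neurons with >= 2 spikes,
        across all groups; inf if none."""
        best = math.inf
        for name in self.events:
            for ts in self.spike_trains(name).values():
                if len(ts) >= 2:
                    best = min(best, float(np.diff(ts).min()))
        return best

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeData):
            return NotImplemented
        if set(self.events) != set(other.events):
            return False
        for name in self.events:
            t1, i1 = self.events[name]
            t2, i2 = other.events[name]
            if len(t1) != len(t2) or not np.array_equal(t1, t2) or not np.array_equal(i1, i2):
                return False
        return True


class Network:
    """A simulatable collection of groups, sources and synapses.

    ``strategy`` selects the spike-delivery kernel ("pre" or "post");
    both satisfy an exact-equivalence contract in double precision.
    """

    def __init__(
        self,
        dt: float = 0.1,
        precision: str = "double",
        strategy: str = "pre",
        on_divergence: str = "mask",
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")
        if strategy not in ("pre", "post"):
            raise ValueError("strategy must be 'pre' or 'post'")
        if on_divergence not in ("mask", "abort"):
            raise ValueError("on_divergence must be 'mask' or 'abort'")
        self.dt = float(dt)
        self.precision = precision
        self.strategy = strategy
        self.on_divergence = on_divergence
        self.groups: dict[str, NeuronGroup] = {}
        self.sources: dict[str, SpikeSourceArray] = {}
        self.synapses: list[SynapseGroup] = []
        self._initialized = False

    # -- construction -------------------------------------------------
    def add_group(self, group: NeuronGroup) -> NeuronGroup:
        if group.name in self.groups or group.name in self.sources:
            raise ValueError(f"duplicate group name {group.name!r}")
        self.groups[group.name] = group
        return group

    def add_source(self, source: SpikeSourceArray) -> SpikeSourceArray:
        if source.name in self.groups or source.name in self.sources:
            raise ValueError(f"duplicate group name {source.name!r}")
        self.sources[source.name] = source
        return source

    def add_synapses(self, syn: SynapseGroup) -> SynapseGroup:
        self.synapses.append(syn)
        return syn

    # -- lifecycle ----------------------------------------------------
    def initialize(self) -> None:
        """(Re)compile kernels and reset all state to initial values."""
        for g in self.groups.values():
            if g.kernel is None or g.kernel.dt != self.dt or g.kernel.precision != self.precision:
                g.kernel = ExponentialEulerKernel(g.equation_set, self.dt, self.precision)
            g.reset(self.dt, self.precision)
        for s in self.sources.values():
            s.reset(self.dt, self.precision)
        for syn in self.synapses:
            syn.reset(self.dt, self.precision)
            if self.strategy == "post" or syn.stdp is not None:
                syn.rev  # build transpose index up front
        self._initialized = True

    def _track_divergence(self, group: NeuronGroup, step: int) -> None:
        bad = np.zeros(group.n, dtype=bool)
        bad_var = None
        for var, arr in group.state.items():
            nf = ~np.isfinite(arr)
            if nf.any():
                bad |= nf
                bad_var = bad_var or var
        new = bad & ~group.diverged
        if not new.any():
            return
        if self.on_divergence == "abort":
            raise SimulationError(
                f"non-finite value in group {group.name!r}, variable {bad_var!r} "
                f"at step {step} (t = {step * self.dt:.4f} ms)"
            )
        group.diverged |= new

    def step(self, step_index: int) -> dict:
        """Execute one step; returns {group/source name: spike indices}."""
        # 1. synchronous state update from step-start values
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for g in self.groups.values():
                g.kernel.step(g.state)
                self._track_divergence(g, step_index)
        # 2. spike detection and source emission
        spikes: dict[str, np.ndarray] = {}
        for g in self.groups.values():
            spikes[g.name] = detect_spikes(g, step_index)
        for s in self.sources.values():
            spikes[s.name] = s.spikes_at(step_index)
        # 3. plasticity: decay, post events, then pre events
        for syn in self.synapses:
            if syn.stdp is None:
                continue
            decay_traces(syn.stdp_state, self.dt, syn.stdp.tau)
        for syn in self.synapses:
            if syn.stdp is None:
                continue
            post = spikes.get(syn.target.name, _EMPTY_IDX)
            if post.size:
                on_post_spikes(syn.weights, syn.stdp_state, syn.stdp, syn.rev, post)
        for syn in self.synapses:
            if syn.stdp is None:
                continue
            pre = syn.source_spike_rows(spikes.get(syn.source.name, _EMPTY_IDX))
            if pre.size:
                on_pre_spikes(syn.weights, syn.stdp_state, syn.stdp, syn.conn, pre)
        # 4. propagation (affects dynamics from the next step)
        deliver = propagate_pre if self.strategy == "pre" else propagate_post
        for syn in self.synapses:
            pre = syn.source_spike_rows(spikes.get(syn.source.name, _EMPTY_IDX))
            deliver(pre, syn, syn.target.state[syn.target_var])
        return spikes

    def run(self, duration: float, record=None, record_sources: bool = False) -> SpikeData:
        """Simulate ``duration`` ms (rounded down to a whole number of
        steps) and return the recorded spikes.

        ``record`` selects group names to monitor (default: all neuron
        groups, plus spike sources if ``record_sources``).  Recording
        never alters simulation state.
        """
        if duration < 0:
            raise ValueError("duration must be non-negative")
        self.initialize()
        n_steps = int(math.floor(duration / self.dt + 1e-9))
        if record is None:
            record = list(self.groups)
            if record_sources:
                record += list(self.sources)
        buffers: dict[str, list] = {name: [] for name in record}
        for s in range(1, n_steps + 1):
            spikes = self.step(s)
            for name in record:
                idx = spikes.get(name, _EMPTY_IDX)
                if idx.size:
                    buffers[name].append((s, idx))
        data = SpikeData()
        for name in record:
            if buffers[name]:
                times = np.concatenate(
                    [np.full(len(idx), s * self.dt) for s, idx in buffers[name]]
                )
                indices = np.concatenate([idx for _, idx in buffers[name]])
            else:
                times = np.empty(0)
                indices = np.empty(0, dtype=np.int64)
            data.add_group(name, times, indices)
        return data
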