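"""Spike-timing-dependent plasticity with all-to-all pairing.

Every pre/post spike pair (i, j) contributes a weight change
``+A*exp(-dt_pair/tau)`` when the post spike follows the pre spike
(dt_pair = t_post - t_pre > 0) and ``-A*exp(-|dt_pair|/tau)`` otherwise
(including coincident spikes), with the weight clipped to [0, w_max]
after every event.  Because the pairing kernel is exponential, the full
all-pairs sum is implemented exactly by two per-neuron traces that decay
by ``exp(-dt/tau)`` each step and jump by 1 at each spike; clipping is the
only nonlinearity, and both the trace engine and the brute-force pairwise
oracle clip at the same event sequence.

Event ordering at coincident spikes: post-synaptic events are processed
before pre-synaptic events within a step, so a dt_pair = 0 pair takes the
depression branch and contributes no potentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ReverseIndex, SparseConnectivity

__all__ = [
    "StdpParameters",
    "StdpState",
    "decay_traces",
    "on_post_spikes",
    "on_pre_spikes",
    "pairwise_oracle",
]


@dataclass(frozen=True)
class StdpParameters:
    """Amplitude A (nS), pairing time constant tau (ms), weight bound
    w_max (nS) and the dimensionless network-scaling constant k."""

    amplitude: float
    tau: float
    w_max: float
    k: float = 1.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")

    @classmethod
    def from_scaling(cls, k: float) -> "StdpParameters":
        """Mushroom-body parameterisation: A = k*0.1 nS, tau = 10 ms,
        w_max = k*3.75 nS."""
        return cls(amplitude=k * 0.1, tau=10.0, w_max=k * 3.75, k=k)


@dataclass
class StdpState:
    """Per-neuron pairing traces for one plastic projection."""

    x_pre: np.ndarray
    x_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int, dtype=np.float64) -> "StdpState":
        return cls(np.zeros(n_pre, dtype=dtype), np.zeros(n_post, dtype=dtype))


def decay_traces(state: StdpState, dt: float, tau: float) -> None:
    """Multiply both traces by exp(-dt/tau), in place (exact per-step decay)."""
    f = np.exp(-dt / tau)
    state.x_pre *= f
    state.x_post *= f


def on_post_spikes(
    weights: np.ndarray,
    state: StdpState,
    params: StdpParameters,
    rev: ReverseIndex,
    post_indices: np.ndarray,
) -> None:
    """Potentiation events: for every synapse (i, j) with j spiking,
    w_ij <- clip(w_ij + A*x_pre[i], 0, w_max); then x_post[j] += 1.

    Traces must already be decayed for the current step.  Processed before
    the step's pre-synaptic events.
    """
    post_indices = np.asarray(post_indices, dtype=np.int64)
    if post_indices.size:
        segs = [np.arange(rev.col_ptr[j], rev.col_ptr[j + 1]) for j in post_indices]
        pos = np.concatenate(segs)
        sid = rev.perm[pos]
        dw = params.amplitude * state.x_pre[rev.row_idx[pos]]
        weights[sid] = np.clip(weights[sid] + dw, 0.0, params.w_max)
        state.x_post[post_indices] += 1.0


def on_pre_spikes(
    weights: np.ndarray,
    state: StdpState,
    params: StdpParameters,
    conn: SparseConnectivity,
    pre_indices: np.ndarray,
) -> None:
    """Depression events: for every synapse (i, j) with i spiking,
    w_ij <- clip(w_ij - A*x_post[j], 0, w_max); then x_pre[i] += 1.

    Must run after the step's post-synaptic events, so coincident pairs
    depress.  The conductance increment of the same pre spike (applied in
    the engine's propagation phase, after this call) therefore uses the
    post-depression weight.
    """
    pre_indices = np.asarray(pre_indices, dtype=np.int64)
    if pre_indices.size:
        segs = [np.arange(conn.row_ptr[i], conn.row_ptr[i + 1]) for i in pre_indices]
        sid = np.concatenate(segs)
        dw = params.amplitude * state.x_post[conn.col_idx[sid]]
        weights[sid] = np.clip(weights[sid] - dw, 0.0, params.w_max)
        state.x_pre[pre_indices] += 1.0


def pairwise_oracle(
    pre_times,
    post_times,
    params: StdpParameters,
    w0: float,
) -> float:
    """Brute-force all-pairs reference for a single synapse.

    Processes spike events chronologically (post before pre at ties); at
    each event it sums the exponential pairing kernel over *all* earlier
    opposite-type spikes by explicit iteration, adds the increment and
    clips to [0, w_max].  Serves as the independent reference for the
    trace engine.
    """
    events = [(float(t), 0) for t in post_times] + [(float(t), 1) for t in pre_times]
    events.sort(key=lambda e: (e[0], e[1]))  # post (0) before pre (1) at ties
    w = float(w0)
    seen_pre: list[float] = []
    seen_post: list[float] = []
    for t, kind in events:
        if kind == 0:  # post spike: potentiate from all earlier pre spikes
            dw = 0.0
            for tp in seen_pre:
                dw += params.amplitude * np.exp(-(t - tp) / params.tau)
            w = min(max(w + dw, 0.0), params.w_max)
            seen_post.append(t)
        else:  # pre spike: depress from all earlier-or-coincident post spikes
            dw = 0.0
            for tq in seen_post:
                dw -= params.amplitude * np.exp(-(t - tq) / params.tau)
            w = min(max(w + dw, 0.0), params.w_max)
            seen_pre.append(t)
    return w
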