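"""Independent straight-line scalar reference implementations.

These re-simulate networks built by the package using plain Python
loops, ``math.exp`` and hand-written per-variable update formulas — no
shared code with the vectorized engine beyond the network description
(connectivity, weights, initial state), which is input data.  Used to
cross-check the engine's spike trains and propagation kernels.
"""

from __future__ import annotations

import math

from spikesim.models import COBAHH_PARAMETERS


def _alpha_m(v):
    u = -50.0 - v
    if abs(u) < 1e-9:
        return 0.32 * 4.0
    return 0.32 * u / math.expm1(u / 4.0)


def _beta_m(v):
    u = 23.0 + v
    if abs(u) < 1e-9:
        return 0.28 * 5.0
    return 0.28 * u / math.expm1(u / 5.0)


def _alpha_h(v):
    return 0.128 * math.exp((-46.0 - v) / 18.0)


def _beta_h(v):
    return 4.0 / (1.0 + math.exp((-23.0 - v) / 5.0))


def _alpha_n(v):
    u = -48.0 - v
    if abs(u) < 1e-9:
        return 0.032 * 5.0
    return 0.032 * u / math.expm1(u / 5.0)


def _beta_n(v):
    return 0.5 * math.exp((-53.0 - v) / 40.0)


def _ee_step(x, a, b, dt):
    """One exponential-Euler step of dx/dt = a + b*x."""
    if abs(b * dt) < 1e-12:
        return x + a * dt
    return x + (x + a / b) * math.expm1(b * dt)


def simulate_cobahh_scalar(net, duration):
    """Re-simulate a COBAHH network built by ``build_cobahh`` with
    explicit scalar loops; returns a sorted list of (step, neuron) spike
    events.

    Implements the same conventions as the engine (synchronous update
    from step-start values, strict threshold, integer-step refractoriness,
    one-step synaptic latency) but with independent control flow and
    scalar arithmetic.
    """
    P = COBAHH_PARAMETERS
    group = net.groups["neurons"]
    n = group.n
    dt = net.dt
    n_steps = int(math.floor(duration / dt + 1e-9))
    ref_steps = int(round(group.t_ref / dt))
    v_th = group.v_thresh

    # initial state (float64 copies of the builder's draws)
    init = group._initial_state
    V = [float(x) for x in init["V"]]
    m = [float(x) for x in init["m"]]
    h = [float(x) for x in init["h"]]
    ng = [float(x) for x in init["n"]]
    gE = [float(x) for x in init["gE"]]
    gI = [float(x) for x in init["gI"]]
    last = [-(10**9)] * n

    # dense weight maps per projection: (source, target) -> weight
    proj = []
    for syn in net.synapses:
        rp, ci, w = syn.conn.row_ptr, syn.conn.col_idx, syn._weights64
        rows = []
        for i in range(syn.conn.n_pre):
            rows.append([(int(ci[s]), float(w[s])) for s in range(rp[i], rp[i + 1])])
        proj.append((syn.source_offset, rows, syn.target_var))

    events = []
    for step in range(1, n_steps + 1):
        # 1. synchronous state update
        newV, newm, newh, newn = [0.0] * n, [0.0] * n, [0.0] * n, [0.0] * n
        newgE, newgI = [0.0] * n, [0.0] * n
        for i in range(n):
            v = V[i]
            gna = P["gNa"] * m[i] ** 3 * h[i]
            gk = P["gK"] * ng[i] ** 4
            b_v = -(P["gL"] + gna + gk + gE[i] + gI[i]) / P["CM"]
            a_v = (
                P["gL"] * P["VL"]
                + gna * P["VNa"]
                + gk * P["VK"]
                + gE[i] * P["VE"]
                + gI[i] * P["VI"]
            ) / P["CM"]
            am, bm = _alpha_m(v), _beta_m(v)
            ah, bh = _alpha_h(v), _beta_h(v)
            an, bn = _alpha_n(v), _beta_n(v)
            newV[i] = _ee_step(v, a_v, b_v, dt)
            newm[i] = _ee_step(m[i], am, -(am + bm), dt)
            newh[i] = _ee_step(h[i], ah, -(ah + bh), dt)
            newn[i] = _ee_step(ng[i], an, -(an + bn), dt)
            newgE[i] = _ee_step(gE[i], 0.0, -1.0 / P["tauE"], dt)
            newgI[i] = _ee_step(gI[i], 0.0, -1.0 / P["tauI"], dt)
        V, m, h, ng, gE, gI = newV, newm, newh, newn, newgE, newgI
        # 2. detection
        spikers = []
        for i in range(n):
            if math.isfinite(V[i]) and V[i] > v_th and step - last[i] >= ref_steps:
                last[i] = step
                spikers.append(i)
                events.append((step, i))
        # 4. propagation (increments take effect next step)
        for offset, rows, tvar, in proj:
            g = gE if tvar == "gE" else gI
            for i in spikers:
                if offset <= i < offset + len(rows):
                    for j, w in rows[i - offset]:
                        g[j] += w
    return events


def propagate_dense(conn, weights, spikes, n_post):
    """Brute-force dense delivery oracle: sum incoming spiking weights per
    target in ascending source order."""
    pre, post = conn.pairs()
    dense = {}
    for s in range(conn.n_synapses):
        dense[(int(pre[s]), int(post[s]))] = float(weights[s])
    out = [0.0] * n_post
    for j in range(n_post):
        for i in sorted(spikes):
            if (i, j) in dense:
                out[j] += dense[(i, j)]
    return out


def cobahh_derivatives(s):
    """Time derivatives of the single-neuron state (V, m, h, n, gE, gI),
    written independently of the package's DSL."""
    P = COBAHH_PARAMETERS
    V, m, h, n, gE, gI = s
    gna = P["gNa"] * m**3 * h
    gk = P["gK"] * n**4
    dV = (
        P["gL"] * (P["VL"] - V)
        + gna * (P["VNa"] - V)
        + gk * (P["VK"] - V)
        + gE * (P["VE"] - V)
        + gI * (P["VI"] - V)
    ) / P["CM"]
    return [
        dV,
        _alpha_m(V) * (1 - m) - _beta_m(V) * m,
        _alpha_h(V) * (1 - h) - _beta_h(V) * h,
        _alpha_n(V) * (1 - n) - _beta_n(V) * n,
        -gE / P["tauE"],
        -gI / P["tauI"],
    ]


def rk4_cobahh(s0, dt, duration):
    """Classic fixed-step RK4 reference trajectory; returns the list of
    states at every step (including the initial one)."""
    s = [float(x) for x in s0]
    out = [list(s)]
    for _ in range(int(round(duration / dt))):
        k1 = cobahh_derivatives(s)
        k2 = cobahh_derivatives([x + dt / 2 * k for x, k in zip(s, k1)])
        k3 = cobahh_derivatives([x + dt / 2 * k for x, k in zip(s, k2)])
        k4 = cobahh_derivatives([x + dt * k for x, k in zip(s, k3)])
        s = [
            x + dt / 6 * (a + 2 * b + 2 * c + d)
            for x, a, b, c, d in zip(s, k1, k2, k3, k4)
        ]
        out.append(list(s))
    return out


def run_single_synapse_traces(pre_steps, post_steps, params, w0, dt=0.1):
    """Drive the package's trace-based plasticity machinery for one
    synapse given spike trains as step indices; returns the final weight.

    This exercises the production code path (decay + post/pre event
    handlers on a 1x1 connectivity); compare against
    ``spikesim.pairwise_oracle`` for the all-pairs reference.
    """
    import numpy as np

    from spikesim.connectivity import SparseConnectivity, transpose_index
    from spikesim.plasticity import (
        StdpState,
        decay_traces,
        on_post_spikes,
        on_pre_spikes,
    )

    conn = SparseConnectivity(1, 1, np.array([0, 1]), np.array([0]))
    rev = transpose_index(conn)
    w = np.array([w0], dtype=float)
    state = StdpState.zeros(1, 1)
    pre_steps, post_steps = set(pre_steps), set(post_steps)
    last = max(pre_steps | post_steps, default=0)
    one = np.array([0])
    for step in range(1, last + 1):
        decay_traces(state, dt, params.tau)
        if step in post_steps:
            on_post_spikes(w, state, params, rev, one)
        if step in pre_steps:
            on_pre_spikes(w, state, params, conn, one)
    return float(w[0])
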