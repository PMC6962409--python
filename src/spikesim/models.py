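"""Builders for the two benchmark networks: COBAHH and Mbody.

COBAHH is a recurrent random network of N Hodgkin-Huxley neurons (80%
excitatory, 20% inhibitory) with conductance-based synapses and a
size-scaled connection probability p = min(1, 1000/N), so each neuron
receives on average 1,000 inputs regardless of N.  The recurrent weights
are vanishingly small (omega * 1e-9 nS), so the network activity — a
transient driven by randomly initialised synaptic conductances — is
insensitive to scale while every propagation computation still runs.

Mbody is a feedforward insect mushroom-body circuit: 100 projection
neurons (PNs, spike sources) -> N_iKC intrinsic Kenyon cells -> 100
extrinsic Kenyon cells (eKCs) with all-to-all lateral eKC inhibition and
STDP on the iKC->eKC synapses.  The iKC->eKC wiring and plastic-synapse
parameters follow the k = max(1, 2500/N_inputs) scaling rule.

All builders are pure functions of (arguments, seed): rebuilding with the
same seed yields bit-identical networks, independent of precision mode
and delivery strategy.

Internal units are (mV, ms, nS, pF): conductance/capacitance then has
units 1/ms, matching kHz rate curves, so membrane capacitances are stored
in pF (0.2 nF -> 200 pF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import (
    all_to_all_connect,
    bernoulli_connect,
    coba_connection_probability,
    mbody_scaling,
)
from .engine import Network, NeuronGroup, SpikeSourceArray, SynapseGroup
from .equations import parse_model
from .plasticity import StdpParameters
from .rates import steady_state_gate

__all__ = [
    "COBAHH_EQUATIONS",
    "COBAHH_PARAMETERS",
    "MBODY_IKC_EQUATIONS",
    "MBODY_EKC_EQUATIONS",
    "MBODY_HH_PARAMETERS",
    "InputPatternSet",
    "build_cobahh",
    "build_mbody",
    "generate_input_patterns",
    "init_plastic_weights",
]

_HH_GATES = """
dm/dt = alpha_m(V)*(1 - m) - beta_m(V)*m
dh/dt = alpha_h(V)*(1 - h) - beta_h(V)*h
dn/dt = alpha_n(V)*(1 - n) - beta_n(V)*n
"""

COBAHH_EQUATIONS = (
    """
dV/dt = (gL*(VL - V) + gNa*m**3*h*(VNa - V) + gK*n**4*(VK - V) + gE*(VE - V) + gI*(VI - V)) / CM
"""
    + _HH_GATES
    + """
dgE/dt = -gE / tauE
dgI/dt = -gI / tauI
"""
)

# (mV, ms, nS, pF); conductances in nS (20 uS -> 20,000 nS), C_M in pF.
COBAHH_PARAMETERS = {
    "CM": 200.0,  # 0.2 nF
    "gL": 10.0,
    "gNa": 20_000.0,
    "gK": 6_000.0,
    "VL": -60.0,
    "VNa": 50.0,
    "VK": -90.0,
    "VE": 0.0,
    "VI": -80.0,
    "tauE": 5.0,
    "tauI": 10.0,
}

MBODY_HH_PARAMETERS = {
    "CM": 300.0,  # 0.3 nF
    "gL": 26.7,
    "gNa": 7_150.0,
    "gK": 1_430.0,
    "VL": -63.56,
    "VNa": 50.0,
    "VK": -95.0,
}

MBODY_IKC_EQUATIONS = (
    """
dV/dt = (gL*(VL - V) + gNa*m**3*h*(VNa - V) + gK*n**4*(VK - V) + gPN*(VPN - V)) / CM
"""
    + _HH_GATES
    + """
dgPN/dt = -gPN / tauPN
"""
)

MBODY_EKC_EQUATIONS = (
    """
dV/dt = (gL*(VL - V) + gNa*m**3*h*(VNa - V) + gK*n**4*(VK - V) + gKC*(VKC - V) + gLat*(VLat - V)) / CM
"""
    + _HH_GATES
    + """
dgKC/dt = -gKC / tauKC
dgLat/dt = -gLat / tauLat
"""
)

V_THRESH = -20.0  # mV, strict
T_REF = 3.0  # ms


def build_cobahh(
    n_total: int,
    precision: str = "double",
    strategy: str = "pre",
    rng=None,
    dt: float = 0.1,
) -> Network:
    """Build the COBAHH benchmark network of ``n_total`` neurons.

    0.8*N excitatory and 0.2*N inhibitory neurons (N a multiple of 5),
    each ordered pair connected with probability min(1, 1000/N) including
    self-pairs; weights omega*1e-9 nS with omega ~ U[0,1].  Membrane
    potentials start at N(V_L - 5 mV, (5 mV)^2), synaptic conductances at
    g_E ~ N(40, 15^2) nS and g_I ~ N(200, 120^2) nS (kept as drawn), and
    gates at their steady state for the initial potential.
    """
    if n_total < 5 or n_total % 5 != 0:
        raise ValueError("COBAHH network size must be a multiple of 5, at least 5")
    rng = np.random.default_rng(rng)
    n_exc = (n_total * 4) // 5
    n_inh = n_total - n_exc
    p = coba_connection_probability(n_total)

    v0 = rng.normal(-65.0, 5.0, size=n_total)  # V_L - 5 mV
    ge0 = rng.normal(40.0, 15.0, size=n_total)
    gi0 = rng.normal(200.0, 120.0, size=n_total)
    eqs = parse_model(COBAHH_EQUATIONS, COBAHH_PARAMETERS)
    group = NeuronGroup(
        "neurons",
        n_total,
        eqs,
        initial_state={
            "V": v0,
            "m": steady_state_gate("m", v0),
            "h": steady_state_gate("h", v0),
            "n": steady_state_gate("n", v0),
            "gE": ge0,
            "gI": gi0,
        },
        v_thresh=V_THRESH,
        t_ref=T_REF,
    )

    conn_e = bernoulli_connect(n_exc, n_total, p, include_self=True, rng=rng)
    w_e = rng.uniform(0.0, 1.0, size=conn_e.n_synapses) * 1e-9
    conn_i = bernoulli_connect(n_inh, n_total, p, include_self=True, rng=rng)
    w_i = rng.uniform(0.0, 1.0, size=conn_i.n_synapses) * 1e-9

    net = Network(dt=dt, precision=precision, strategy=strategy)
    net.add_group(group)
    net.add_synapses(
        SynapseGroup("exc", group, group, conn_e, w_e, target_var="gE", source_offset=0)
    )
    net.add_synapses(
        SynapseGroup("inh", group, group, conn_i, w_i, target_var="gI", source_offset=n_exc)
    )
    return net


@dataclass
class InputPatternSet:
    """Structured random PN input: 10 basis patterns of 20 active PNs,
    each expanded into n_rep variants (active identities re-drawn with
    probability 0.1), every variant presented once on a 50 ms grid with a
    uniform 0-2 ms onset jitter applied to the whole pattern."""

    n_pn: int
    basis: list  # 10 arrays of 20 PN indices
    variants: list  # 10*n_rep arrays of 20 PN indices, presentation order
    onsets: np.ndarray  # ms, one per presentation
    times: np.ndarray  # flattened spike times, ms
    indices: np.ndarray  # flattened PN indices

    @property
    def n_rep(self) -> int:
        return len(self.variants) // len(self.basis)

    def as_source(self, name: str = "PN") -> SpikeSourceArray:
        return SpikeSourceArray(name, self.n_pn, self.times, self.indices)


def generate_input_patterns(
    n_pn: int = 100, duration: float = 500.0, rng=None, n_active: int = 20, n_basis: int = 10
) -> InputPatternSet:
    """Generate the Mbody structured input-pattern set for ``duration`` ms.

    n_rep = ceil(duration / (n_basis * 50 ms)) variants per basis pattern;
    presentation i (round-robin over bases) starts at 50*i + U(0, 2) ms,
    and every active PN of the presented variant emits exactly one spike
    at the onset.
    """
    if duration < 50.0:
        raise ValueError("duration must be at least one 50 ms presentation slot")
    if n_active > n_pn:
        raise ValueError("cannot have more active PNs than PNs")
    rng = np.random.default_rng(rng)
    n_rep = int(math.ceil(duration / (n_basis * 50.0)))

    basis = [np.sort(rng.choice(n_pn, size=n_active, replace=False)) for _ in range(n_basis)]
    # presentation order: round-robin over bases, so every 500 ms block
    # shows one variant of each basis pattern
    variants = []
    for rep in range(n_rep):
        for b in range(n_basis):
            active = set(int(i) for i in basis[b])
            redraw = [i for i in sorted(active) if rng.random() < 0.1]
            for i in redraw:
                inactive = np.setdiff1d(np.arange(n_pn), np.fromiter(active, dtype=np.int64))
                active.remove(i)
                active.add(int(rng.choice(inactive)))
            variants.append(np.sort(np.fromiter(active, dtype=np.int64)))

    n_pres = len(variants)
    onsets = 50.0 * np.arange(n_pres) + rng.uniform(0.0, 2.0, size=n_pres)
    times = np.repeat(onsets, n_active)
    indices = np.concatenate(variants)
    return InputPatternSet(
        n_pn=n_pn, basis=basis, variants=variants, onsets=onsets, times=times, indices=indices
    )


def init_plastic_weights(n_synapses: int, params: StdpParameters, rng=None) -> np.ndarray:
    """Two-step initial weights for the plastic iKC->eKC synapses.

    All synapses start at a low "inactive" weight k*omega*0.375 nS with
    omega ~ U[0,1] drawn per synapse (0.375 nS being a tenth of the
    unscaled 3.75 nS weight bound); each is then independently promoted
    with probability 0.2 to an "active" weight k*(2.5 + 0.5*nu) nS,
    nu ~ N(0,1).  Weights are clipped to [0, w_max].
    """
    rng = np.random.default_rng(rng)
    k = params.k
    w = k * rng.uniform(0.0, 1.0, size=n_synapses) * 0.375
    active = rng.random(n_synapses) < 0.2
    w[active] = k * (2.5 + 0.5 * rng.normal(size=active.sum()))
    return np.clip(w, 0.0, params.w_max)


def build_mbody(
    n_ikc: int,
    precision: str = "double",
    strategy: str = "pre",
    rng=None,
    duration: float = 500.0,
    dt: float = 0.1,
) -> Network:
    """Build the Mbody mushroom-body network with ``n_ikc`` intrinsic
    Kenyon cells (100 PNs and 100 eKCs are fixed).

    PN->iKC: Bernoulli p = 0.15, weights (6.75 + 0.844*nu) nS kept as
    drawn.  iKC->eKC: all-to-all for N_iKC <= 10,000, else Bernoulli
    p = 10,000/N_iKC; plastic (STDP, scaling constant k).  eKC->eKC:
    all-to-all including self-pairs, 50.6 nS inhibitory.  HH neurons start
    at V = V_L, m = 0, h = 0.5, n = 0 with zero conductances.  The input
    pattern set covers ``duration`` ms.
    """
    if n_ikc < 1:
        raise ValueError("N_iKC must be at least 1")
    rng = np.random.default_rng(rng)
    n_pn, n_ekc = 100, 100
    scaling = mbody_scaling(n_ikc)
    stdp = StdpParameters.from_scaling(scaling.k)

    ikc_params = {**MBODY_HH_PARAMETERS, "VPN": 0.0, "tauPN": 2.0}
    ekc_params = {**MBODY_HH_PARAMETERS, "VKC": 0.0, "tauKC": 10.0, "VLat": -92.0, "tauLat": 5.0}
    vl = MBODY_HH_PARAMETERS["VL"]
    hh_init = {"V": vl, "m": 0.0, "h": 0.5, "n": 0.0}

    ikc = NeuronGroup(
        "iKC",
        n_ikc,
        parse_model(MBODY_IKC_EQUATIONS, ikc_params),
        initial_state={**hh_init, "gPN": 0.0},
        v_thresh=V_THRESH,
        t_ref=T_REF,
    )
    ekc = NeuronGroup(
        "eKC",
        n_ekc,
        parse_model(MBODY_EKC_EQUATIONS, ekc_params),
        initial_state={**hh_init, "gKC": 0.0, "gLat": 0.0},
        v_thresh=V_THRESH,
        t_ref=T_REF,
    )

    patterns = generate_input_patterns(n_pn=n_pn, duration=duration, rng=rng)
    pn = patterns.as_source("PN")

    conn_pn = bernoulli_connect(n_pn, n_ikc, 0.15, include_self=True, rng=rng)
    w_pn = 6.75 + 0.844 * rng.normal(size=conn_pn.n_synapses)

    if scaling.all_to_all:
        conn_kc = all_to_all_connect(n_ikc, n_ekc, include_self=True)
    else:
        conn_kc = bernoulli_connect(n_ikc, n_ekc, scaling.p, include_self=True, rng=rng)
    w_kc = init_plastic_weights(conn_kc.n_synapses, stdp, rng=rng)

    conn_lat = all_to_all_connect(n_ekc, n_ekc, include_self=True)
    w_lat = np.full(conn_lat.n_synapses, 50.6)

    net = Network(dt=dt, precision=precision, strategy=strategy)
    net.add_source(pn)
    net.add_group(ikc)
    net.add_group(ekc)
    net.add_synapses(SynapseGroup("PN_iKC", pn, ikc, conn_pn, w_pn, target_var="gPN"))
    net.add_synapses(
        SynapseGroup("iKC_eKC", ikc, ekc, conn_kc, w_kc, target_var="gKC", stdp=stdp)
    )
    net.add_synapses(SynapseGroup("eKC_eKC", ekc, ekc, conn_lat, w_lat, target_var="gLat"))
    net.patterns = patterns
    return net
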