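"""Sparse synaptic connectivity in CSR (Yale) form with a transpose index.

Connectivity is stored as per-presynaptic-neuron synapse lists: a
``row_ptr`` offset array of length n_pre+1 and a ``col_idx`` target array
of length S (the synapse count), with targets strictly ascending within
each row.  A :class:`ReverseIndex` adds the transposed (per-postsynaptic)
view plus a permutation mapping transpose positions back to CSR synapse
ids, enabling target-major iteration (the post-synaptic delivery strategy,
STDP back-access) over the same shared weight array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps

__all__ = [
    "SparseConnectivity",
    "ReverseIndex",
    "bernoulli_connect",
    "all_to_all_connect",
    "coba_connection_probability",
    "mbody_scaling",
    "MbodyScaling",
    "transpose_index",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class SparseConnectivity:
    """CSR synapse structure: row_ptr offsets plus ascending target lists."""

    n_pre: int
    n_post: int
    row_ptr: np.ndarray  # int64, length n_pre + 1
    col_idx: np.ndarray  # int64, length S

    def __post_init__(self):
        object.__setattr__(self, "row_ptr", np.asarray(self.row_ptr, dtype=np.int64))
        object.__setattr__(self, "col_idx", np.asarray(self.col_idx, dtype=np.int64))

    @property
    def n_synapses(self) -> int:
        return int(self.row_ptr[-1])

    def row_degrees(self) -> np.ndarray:
        return np.diff(self.row_ptr)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.col_idx, minlength=self.n_post)

    def pairs(self):
        """Expand to parallel (pre, post) index arrays in synapse-id order."""
        pre = np.repeat(np.arange(self.n_pre, dtype=np.int64), self.row_degrees())
        return pre, self.col_idx.copy()

    def validate(self) -> None:
        rp, ci = self.row_ptr, self.col_idx
        if rp[0] != 0 or np.any(np.diff(rp) < 0) or rp[-1] != len(ci):
            raise ValueError("row_ptr is not a valid offset array")
        if len(ci) and (ci.min() < 0 or ci.max() >= self.n_post):
            raise ValueError("col_idx out of range")
        for i in range(self.n_pre):
            row = ci[rp[i] : rp[i + 1]]
            if np.any(np.diff(row) <= 0):
                raise ValueError(f"targets of row {i} not strictly ascending")


@dataclass(frozen=True)
class ReverseIndex:
    """Transposed (per-target) view of a :class:`SparseConnectivity`.

    ``perm[t]`` is the CSR synapse id stored at transpose position t, so
    weight arrays indexed by synapse id can be traversed target-major
    without duplication.  Sources are ascending within each column.
    """

    col_ptr: np.ndarray  # int64, length n_post + 1
    row_idx: np.ndarray  # int64, length S
    perm: np.ndarray  # int64, length S


def _sorted_sample(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """d distinct values from range(n), sorted ascending."""
    if d == 0:
        return np.empty(0, dtype=np.int64)
    out = rng.choice(n, size=d, replace=False)
    out.sort()
    return out.astype(np.int64)


def bernoulli_connect(
    n_pre: int,
    n_post: int,
    p: float,
    include_self: bool = True,
    rng: np.random.Generator | None = None,
) -> SparseConnectivity:
    """Pairwise-Bernoulli connectivity: each ordered (pre, post) pair exists
    independently with probability p.

    Generated row-wise as a binomial degree draw followed by uniform
    sampling of distinct targets, which is distributionally identical to
    per-pair coin flips but O(S) in memory.  ``include_self=False``
    excludes (i, i) pairs; this is only meaningful when the two
    populations are the same group.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(rng)
    rows = []
    for i in range(n_pre):
        exclude = include_self is False and i < n_post
        n_avail = n_post - 1 if exclude else n_post
        d = int(rng.binomial(n_avail, p)) if n_avail > 0 else 0
        tgt = _sorted_sample(rng, n_avail, d)
        if exclude:
            tgt = tgt + (tgt >= i)
        rows.append(tgt)
    row_ptr = np.zeros(n_pre + 1, dtype=np.int64)
    row_ptr[1:] = np.cumsum([len(r) for r in rows])
    col_idx = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    return SparseConnectivity(n_pre, n_post, row_ptr, col_idx)


def all_to_all_connect(n_pre: int, n_post: int, include_self: bool = True) -> SparseConnectivity:
    """Dense connectivity in sparse form; optionally without (i, i) pairs."""
    if n_pre < 1 or n_post < 1:
        raise ValueError("population sizes must be positive")
    rows = []
    for i in range(n_pre):
        tgt = np.arange(n_post, dtype=np.int64)
        if include_self is False and i < n_post:
            tgt = np.delete(tgt, i)
        rows.append(tgt)
    row_ptr = np.zeros(n_pre + 1, dtype=np.int64)
    row_ptr[1:] = np.cumsum([len(r) for r in rows])
    return SparseConnectivity(n_pre, n_post, row_ptr, np.concatenate(rows))


def coba_connection_probability(n_total: int) -> float:
    """Size-scaled recurrent connection probability of the COBAHH network.

    p = 1000/N so that every neuron receives on average 1,000 inputs; for
    N < 1,000 the network is fully connected (p = 1).
    """
    if n_total < 1:
        raise ValueError("N must be at least 1")
    return 1.0 if n_total < 1000 else 1000.0 / n_total


@dataclass(frozen=True)
class MbodyScaling:
    """iKC->eKC wiring regime and synaptic scaling constant.

    ``p`` is None in the all-to-all regime (N_iKC <= 10,000), else the
    Bernoulli probability 10,000/N_iKC.  ``n_inputs_per_ekc`` is the
    expected number of iKC inputs per eKC and ``k = max(1, 2500/n_inputs)``
    rescales the plastic-synapse parameters (A, w_max, initial weights)
    relative to the original 2,500-iKC mushroom-body model.
    """

    p: float | None
    n_inputs_per_ekc: int
    k: float

    @property
    def all_to_all(self) -> bool:
        return self.p is None


def mbody_scaling(n_ikc: int) -> MbodyScaling:
    if n_ikc < 1:
        raise ValueError("N_iKC must be at least 1")
    if n_ikc <= 10_000:
        p = None
        n_inputs = n_ikc
    else:
        p = 10_000.0 / n_ikc
        n_inputs = 10_000
    k = 2500.0 / n_inputs
    if k < 1.0:
        k = 1.0
    return MbodyScaling(p=p, n_inputs_per_ekc=n_inputs, k=k)


def transpose_index(conn: SparseConnectivity) -> ReverseIndex:
    """Build the per-target view of a CSR connectivity.

    Uses a CSR->CSC conversion carrying synapse ids as data, so
    ``perm`` is a bijection on [0, S) and sources come out ascending
    within each column.
    """
    S = conn.n_synapses
    mat = sps.csr_matrix(
        (np.arange(1, S + 1, dtype=np.int64), conn.col_idx, conn.row_ptr),
        shape=(conn.n_pre, conn.n_post),
    )
    csc = mat.tocsc()
    csc.sort_indices()
    return ReverseIndex(
        col_ptr=csc.indptr.astype(np.int64),
        row_idx=csc.indices.astype(np.int64),
        perm=csc.data.astype(np.int64) - 1,
    )


def save_bundle(path, conn: SparseConnectivity, weights: np.ndarray | None = None, **extra):
    """Write connectivity (and optional per-synapse weights) as an NPZ bundle."""
    arrays = {
        "n_pre": np.int64(conn.n_pre),
        "n_post": np.int64(conn.n_post),
        "row_ptr": conn.row_ptr,
        "col_idx": conn.col_idx,
    }
    if weights is not None:
        arrays["weights"] = np.asarray(weights)
    arrays.update(extra)
    np.savez(path, **arrays)


def load_bundle(path):
    """Read a bundle written by :func:`save_bundle`.

    Returns (connectivity, weights-or-None).
    """
    with np.load(path) as data:
        conn = SparseConnectivity(
            int(data["n_pre"]), int(data["n_post"]), data["row_ptr"], data["col_idx"]
        )
        weights = data["weights"].copy() if "weights" in data else None
    return conn, weights
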