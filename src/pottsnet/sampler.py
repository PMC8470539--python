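"""Potts Hamiltonian evaluation, Metropolis Monte Carlo sampling, and an
exact-enumeration oracle for small systems.

Energy convention (recorded in every parameter file): the Hamiltonian is
evaluated on *densities*,

    H(sigma) = sum_i h_i s_i(sigma) + sum_cls sum_{i<=j} J^cls_ij c^cls_ij(sigma),

and the Boltzmann weight is exp(-H) with no extra scale, so H equals the flat
dot product ``theta . x(sigma)``.  A single-node state change then shifts H by
``(h_new - h_old)/N`` plus ``(J[new, s_nb] - J[old, s_nb])/n_links`` per
incident edge, which is what the O(degree) Metropolis step uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .observables import ObservableLayout, ObservableVector, ensemble_features, layout_for
from .topology import Configuration, Ensemble, NetworkTopology

__all__ = [
    "PottsParameters",
    "SamplerOptions",
    "energy",
    "local_energy_delta",
    "metropolis_sample",
    "enumerate_exact",
    "conditional_marginals",
    "ExactSolution",
]


@dataclass
class PottsParameters:
    """Field vector ``h`` (length Q) and one symmetric Q x Q coupling matrix
    per edge class."""

    h: np.ndarray
    J: list
    class_names: tuple = ("spatial",)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = [np.asarray(Jc, dtype=float) for Jc in self.J]
        Q = self.n_states
        for Jc in self.J:
            if Jc.shape != (Q, Q):
                raise ValueError("each J must be Q x Q")
            if not np.allclose(Jc, Jc.T, atol=1e-12):
                raise ValueError("J must be symmetric")
        if not np.all(np.isfinite(self.h)) or not all(
            np.all(np.isfinite(Jc)) for Jc in self.J
        ):
            raise ValueError("parameters must be finite")

    @property
    def n_states(self) -> int:
        return len(self.h)

    @property
    def n_classes(self) -> int:
        return len(self.J)

    def layout(self) -> ObservableLayout:
        return ObservableLayout(self.n_states, self.n_classes, self.class_names)

    def flatten(self) -> np.ndarray:
        lay = self.layout()
        parts = [self.h] + [lay.matrix_to_tri(Jc) for Jc in self.J]
        return np.concatenate(parts)

    @classmethod
    def from_flat(cls, theta: np.ndarray, layout: ObservableLayout,
                  metadata: dict | None = None) -> "PottsParameters":
        h = np.array(theta[layout.s_slice()])
        J = [layout.tri_to_matrix(theta[layout.c_slice(c)])
             for c in range(layout.n_classes)]
        return cls(h=h, J=J, class_names=layout.class_names,
                   metadata=metadata or {})

    def to_json(self) -> str:
        payload = {
            "n_states": self.n_states,
            "h": self.h.tolist(),
            "J": {name: Jc.tolist() for name, Jc in zip(self.class_names, self.J)},
            "convention": {"pair_counting": "unordered", "energy_scale": "density"},
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PottsParameters":
        payload = json.loads(text)
        names = tuple(payload["J"].keys())
        return cls(
            h=np.array(payload["h"]),
            J=[np.array(payload["J"][n]) for n in names],
            class_names=names,
            metadata=payload.get("metadata", {}),
        )


@dataclass
class SamplerOptions:
    """Metropolis schedule.  A sweep is one single-site proposal per free
    node; ``n_kept`` configurations are stored every ``stride`` sweeps after
    ``burn_in`` discarded sweeps."""

    n_kept: int = 1000
    burn_in: int = 1000
    stride: int = 10
    seed: int = 0
    clamped: dict | None = None          # node -> fixed state
    node_alphabets: dict | None = None   # node -> allowed states (>=1 each)
    initial: np.ndarray | None = None

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_kept < 1:
            raise ValueError("n_kept must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def energy(config, params: PottsParameters, topology: NetworkTopology) -> float:
    """H = theta . x(sigma) under the density convention."""
    states = config.states if isinstance(config, Configuration) else np.asarray(config)
    F = ensemble_features(states[None, :], topology, params.n_states)
    return float(F[0] @ params.flatten())


def ensemble_energies(X: np.ndarray, params: PottsParameters,
                      topology: NetworkTopology) -> np.ndarray:
    return ensemble_features(X, topology, params.n_states) @ params.flatten()


def local_energy_delta(config, node: int, new_state: int,
                       params: PottsParameters, topology: NetworkTopology) -> float:
    """Energy change of setting ``node`` to ``new_state``; equals the global
    energy difference to numerical tolerance."""
    states = config.states if isinstance(config, Configuration) else np.asarray(config)
    old = int(states[node])
    if new_state == old:
        return 0.0
    delta = (params.h[new_state] - params.h[old]) / states.size
    links = topology.links_per_class()
    indptr, idx, cls = topology.neighbor_csr()
    for k in range(indptr[node], indptr[node + 1]):
        nb, c = idx[k], cls[k]
        s_nb = int(states[nb])
        delta += (params.J[c][new_state, s_nb] - params.J[c][old, s_nb]) / links[c]
    return float(delta)


@njit(cache=True)
def _metropolis_kernel(states, h, Jstack, inv_links, inv_n, indptr, nb_idx,
                       nb_cls, alph_indptr, alph_states, free_nodes,
                       burn_in, stride, n_kept, seed, out):  # pragma: no cover
    np.random.seed(seed)
    n_free = free_nodes.size
    total_sweeps = burn_in + (n_kept - 1) * stride + 1
    kept = 0
    for sweep in range(total_sweeps):
        for _ in range(n_free):
            node = free_nodes[np.random.randint(n_free)]
            a0 = alph_indptr[node]
            a1 = alph_indptr[node + 1]
            n_allowed = a1 - a0
            old = states[node]
            # uniform among the other allowed states: draw from the first
            # n_allowed-1 entries and remap a self-pick to the last entry
            pick = np.random.randint(n_allowed - 1)
            new = alph_states[a0 + pick]
            if new == old:
                new = alph_states[a0 + n_allowed - 1]
            delta = (h[new] - h[old]) * inv_n
            for k in range(indptr[node], indptr[node + 1]):
                nb = nb_idx[k]
                c = nb_cls[k]
                s_nb = states[nb]
                delta += (Jstack[c, new, s_nb] - Jstack[c, old, s_nb]) * inv_links[c]
            if delta <= 0.0 or np.random.random() < np.exp(-delta):
                states[node] = new
        if sweep >= burn_in and (sweep - burn_in) % stride == 0:
            out[kept] = states
            kept += 1
    return kept


def _build_alphabets(n_nodes: int, n_states: int, options: SamplerOptions):
    alph = [list(range(n_states)) for _ in range(n_nodes)]
    if options.node_alphabets:
        for node, allowed in options.node_alphabets.items():
            allowed = sorted(set(int(a) for a in allowed))
            if not allowed:
                raise ValueError(f"empty alphabet for node {node}")
            if allowed[0] < 0 or allowed[-1] >= n_states:
                raise ValueError(f"alphabet state out of range for node {node}")
            alph[node] = allowed
    if options.clamped:
        for node, state in options.clamped.items():
            state = int(state)
            if state < 0 or state >= n_states:
                raise ValueError(f"clamped state {state} out of range")
            alph[int(node)] = [state]
    indptr = np.zeros(n_nodes + 1, dtype=np.int64)
    for i, a in enumerate(alph):
        indptr[i + 1] = indptr[i] + len(a)
    flat = np.concatenate([np.asarray(a, dtype=np.int64) for a in alph])
    free = np.array([i for i, a in enumerate(alph) if len(a) > 1], dtype=np.int64)
    return indptr, flat, free, alph


def metropolis_sample(params: PottsParameters, topology: NetworkTopology,
                      options: SamplerOptions) -> Ensemble:
    """Draw an equilibrium ensemble by single-site Metropolis.

    Proposals pick a uniform random free node and a uniform random different
    allowed state; acceptance is min(1, exp(-deltaH)).  Clamped nodes (or
    nodes with singleton alphabets) are never proposed.  Deterministic given
    ``options.seed``.
    """
    Q = params.n_states
    n = topology.n_nodes
    indptr_a, alph_flat, free, alph = _build_alphabets(n, Q, options)
    if free.size == 0:
        raise ValueError("all nodes are clamped; nothing to sample")
    rng = np.random.default_rng(options.seed)
    if options.initial is not None:
        states = np.asarray(options.initial, dtype=np.int64).copy()
        if states.shape != (n,):
            raise ValueError("initial configuration has wrong length")
    else:
        states = np.array([a[rng.integers(len(a))] for a in alph], dtype=np.int64)
    # respect clamps in the initial state
    for i, a in enumerate(alph):
        if states[i] not in a:
            states[i] = a[0]
    Jstack = np.ascontiguousarray(np.stack(params.J))
    links = topology.links_per_class().astype(float)
    inv_links = np.where(links > 0, 1.0 / np.maximum(links, 1), 0.0)
    indptr, nb_idx, nb_cls = topology.neighbor_csr()
    out = np.zeros((options.n_kept, n), dtype=np.int64)
    kernel_seed = int(rng.integers(2**31 - 1))
    _metropolis_kernel(
        states, params.h, Jstack, inv_links, 1.0 / n,
        indptr.astype(np.int64), nb_idx.astype(np.int64), nb_cls.astype(np.int64),
        indptr_a, alph_flat, free,
        int(options.burn_in), int(options.stride), int(options.n_kept),
        kernel_seed, out,
    )
    return Ensemble(out, n_states=Q)


@dataclass
class ExactSolution:
    """Full Boltzmann table of an enumerable system."""

    configs: np.ndarray        # (K, n_nodes)
    probabilities: np.ndarray  # (K,)
    log_z: float
    observables: ObservableVector
    entropy: float             # exact Shannon entropy -sum P ln P

    def probability_of(self, states) -> float:
        states = np.asarray(states, dtype=np.int64)
        match = np.all(self.configs == states[None, :], axis=1)
        return float(self.probabilities[match][0])


def enumerate_exact(params: PottsParameters, topology: NetworkTopology,
                    cap: int = 10**6) -> ExactSolution:
    """Exact probabilities, partition function, observables and entropy by
    direct summation over all Q^N configurations (N small)."""
    Q = params.n_states
    n = topology.n_nodes
    K = Q**n
    if K > cap:
        raise ValueError(
            f"state space Q^N = {K} exceeds cap {cap}; use metropolis_sample"
        )
    grids = np.indices((Q,) * n).reshape(n, -1).T  # (K, n)
    F = ensemble_features(grids, topology, Q)
    E = F @ params.flatten()
    m = E.min()
    w = np.exp(-(E - m))
    Zs = w.sum()
    P = w / Zs
    log_z = float(np.log(Zs) - m)
    x = P @ F
    entropy = float(P @ E + log_z)  # -sum P ln P for P = e^-E / Z
    lay = layout_for(topology, Q)
    return ExactSolution(
        configs=grids, probabilities=P, log_z=log_z,
        observables=ObservableVector(flat=x, layout=lay), entropy=entropy,
    )


def conditional_marginals(params: PottsParameters, topology: NetworkTopology,
                          clamped: dict, options: SamplerOptions,
                          node_alphabets: dict | None = None) -> np.ndarray:
    """Per-node per-state probabilities with some nodes fixed.

    Metropolis runs restricted to the free nodes; the return value is an
    ``(n_nodes, Q)`` matrix of empirical state frequencies over the stored
    ensemble.  Clamped nodes report their fixed state with probability 1.
    """
    opts = SamplerOptions(
        n_kept=options.n_kept, burn_in=options.burn_in, stride=options.stride,
        seed=options.seed, clamped=dict(clamped),
        node_alphabets=node_alphabets, initial=options.initial,
    )
    ens = metropolis_sample(params, topology, opts)
    Q = params.n_states
    probs = np.zeros((topology.n_nodes, Q))
    for i in range(Q):
        probs[:, i] = (ens.X == i).mean(axis=0)
    return probs
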