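"""Constrained observables: state densities, near-neighbor couple densities,
their ensemble statistics, and the gauge-fixing projector.

For a configuration sigma on ``N`` nodes with ``Q`` states the per-state
density is ``s_i = (1/N) sum_k delta(sigma_k, i)`` and, for each edge class,
the couple density ``c_ij`` counts each unordered edge once (state pair folded
into a symmetric matrix, ``c_ij = c_ji`` sharing the count for i != j),
normalized by the class link count so that ``sum_{i<=j} c_ij = 1``.

The flat observable vector ``x`` concatenates the s-block and then, per edge
class, the upper triangle of c (including the diagonal, row-major).  The same
layout indexes the parameter vector (h-block, then per-class J upper
triangles), so the Hamiltonian is the plain dot product ``theta . x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Configuration, Ensemble, NetworkTopology

__all__ = [
    "ObservableLayout",
    "ObservableVector",
    "GaugeProjector",
    "state_density",
    "pair_density",
    "configuration_features",
    "ensemble_features",
    "ensemble_averages",
    "observable_covariance",
    "build_gauge_projector",
]


class ObservableLayout:
    """Index bookkeeping for the flat observable/parameter vector.

    The layout is frozen: s-block (length Q), then one c-block of length
    Q(Q+1)/2 per edge class, upper triangle row-major.
    """

    def __init__(self, n_states: int, n_classes: int = 1, class_names=("spatial",)):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.n_states = int(n_states)
        self.n_classes = int(n_classes)
        self.class_names = tuple(class_names)
        Q = self.n_states
        self.tri = [(i, j) for i in range(Q) for j in range(i, Q)]
        self.n_tri = len(self.tri)
        self.size = Q + self.n_classes * self.n_tri
        # (Q, Q) -> position within a c-block
        self.pair_pos = np.zeros((Q, Q), dtype=np.int64)
        for p, (i, j) in enumerate(self.tri):
            self.pair_pos[i, j] = p
            self.pair_pos[j, i] = p

    def s_slice(self):
        return slice(0, self.n_states)

    def c_slice(self, cls: int):
        start = self.n_states + cls * self.n_tri
        return slice(start, start + self.n_tri)

    def tri_to_matrix(self, block: np.ndarray) -> np.ndarray:
        """Expand an upper-triangle block into a symmetric Q x Q matrix."""
        Q = self.n_states
        M = np.zeros((Q, Q))
        for p, (i, j) in enumerate(self.tri):
            M[i, j] = block[p]
            M[j, i] = block[p]
        return M

    def matrix_to_tri(self, M: np.ndarray) -> np.ndarray:
        return np.array([M[i, j] for (i, j) in self.tri])

    def describe(self) -> dict:
        return {
            "s": [f"s_{i}" for i in range(self.n_states)],
            "c": {
                name: [f"c_{i}{j}" for (i, j) in self.tri]
                for name in self.class_names
            },
        }


@dataclass
class ObservableVector:
    """State densities ``s``, per-class couple densities ``c`` and the flat
    concatenated vector, all on the canonical layout."""

    flat: np.ndarray
    layout: ObservableLayout

    @property
    def s(self) -> np.ndarray:
        return self.flat[self.layout.s_slice()]

    def c(self, cls: int = 0) -> np.ndarray:
        """Symmetric Q x Q couple-density matrix of one edge class."""
        return self.layout.tri_to_matrix(self.flat[self.layout.c_slice(cls)])

    def validate(self, atol: float = 1e-9) -> None:
        if not np.isclose(self.s.sum(), 1.0, atol=atol):
            raise ValueError("state densities must sum to 1")
        for cls in range(self.layout.n_classes):
            block = self.flat[self.layout.c_slice(cls)]
            if block.size and not np.isclose(block.sum(), 1.0, atol=atol):
                raise ValueError("couple densities must sum to 1")


def layout_for(topology: NetworkTopology, n_states: int) -> ObservableLayout:
    return ObservableLayout(n_states, topology.n_classes, topology.class_names)


def state_density(config, n_states: int) -> np.ndarray:
    """Per-state density ``s_i = (1/N) sum_k delta(sigma_k, i)``."""
    states = config.states if isinstance(config, Configuration) else np.asarray(config)
    counts = np.bincount(states.ravel(), minlength=n_states)
    return counts / states.size


def pair_density(config, topology: NetworkTopology, n_states: int,
                 edge_class: int = 0) -> np.ndarray:
    """Symmetric Q x Q near-neighbor couple-density matrix for one edge class.

    Each unordered edge contributes once; normalization is by the class link
    count so the upper triangle (diagonal included) sums to 1.
    """
    states = config.states if isinstance(config, Configuration) else np.asarray(config)
    mask = topology.edge_class == edge_class
    edges = topology.edges[mask]
    if len(edges) == 0:
        raise ValueError("edge class has no links")
    Q = n_states
    C = np.zeros((Q, Q))
    a = states[edges[:, 0]]
    b = states[edges[:, 1]]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    np.add.at(C, (lo, hi), 1.0)
    C = C + np.triu(C, 1).T
    return C / len(edges)


def ensemble_features(X: np.ndarray, topology: NetworkTopology,
                      n_states: int) -> np.ndarray:
    """Flat observable vectors for every configuration: (n_conf, layout.size).

    This matrix is the workhorse of the trainer: energies are ``F @ theta``,
    model observables are weighted column means, and the analytic chi-square
    gradient uses its weighted covariance.
    """
    X = np.asarray(X, dtype=np.int64)
    if X.ndim == 1:
        X = X[None, :]
    lay = layout_for(topology, n_states)
    n_conf, n_nodes = X.shape
    F = np.zeros((n_conf, lay.size))
    # s-block
    for i in range(n_states):
        F[:, i] = (X == i).sum(axis=1) / n_nodes
    # c-blocks
    links = topology.links_per_class()
    rows = np.arange(n_conf)
    for cls in range(topology.n_classes):
        mask = topology.edge_class == cls
        edges = topology.edges[mask]
        if len(edges) == 0:
            continue
        sl = lay.c_slice(cls)
        block = np.zeros((n_conf, lay.n_tri))
        a = X[:, edges[:, 0]]
        b = X[:, edges[:, 1]]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        pos = lay.pair_pos[lo, hi]  # (n_conf, m_cls)
        np.add.at(block, (rows[:, None], pos), 1.0)
        F[:, sl] = block / links[cls]
    return F


def configuration_features(config, topology: NetworkTopology,
                           n_states: int) -> np.ndarray:
    states = config.states if isinstance(config, Configuration) else np.asarray(config)
    return ensemble_features(states[None, :], topology, n_states)[0]


def ensemble_averages(ensemble: Ensemble, topology: NetworkTopology) -> ObservableVector:
    """Weighted ensemble mean of the flat observables (plain mean for unit
    weights)."""
    if ensemble.n_conf == 0:
        raise ValueError("empty ensemble")
    w = ensemble.normalized_weights()
    F = ensemble_features(ensemble.X, topology, ensemble.n_states)
    lay = layout_for(topology, ensemble.n_states)
    return ObservableVector(flat=w @ F, layout=lay)


def observable_covariance(ensemble: Ensemble, topology: NetworkTopology) -> np.ndarray:
    """Weighted sample covariance of the per-configuration flat observables."""
    if ensemble.n_conf < 2:
        raise ValueError("covariance requires at least two configurations")
    w = ensemble.normalized_weights()
    F = ensemble_features(ensemble.X, topology, ensemble.n_states)
    return weighted_covariance(F, w)


def weighted_covariance(F: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = w @ F
    D = F - mu
    return (D * w[:, None]).T @ D


class GaugeProjector:
    """Projector off the kernel of the observable covariance.

    Exact sum rules (densities summing to one, and any deterministic
    observable in the training set) put directions of the flat space in the
    kernel of Sigma; parameters along those directions are pure gauge.  The
    projector restricts residuals, gradients and parameter updates to the
    informative (non-kernel) subspace, and carries the pseudo-inverse of
    Sigma on that subspace for the chi-square quadratic form.

    Two relative eigenvalue cutoffs are used: ``hard_cutoff`` flags exact
    dependencies, ``soft_cutoff`` (user-settable) additionally guards against
    near-singular directions produced by sampling noise.
    """

    def __init__(self, covariance: np.ndarray, hard_cutoff: float = 1e-10,
                 soft_cutoff: float = 1e-8, abs_cutoff: float = 1e-14):
        covariance = np.asarray(covariance, dtype=float)
        if covariance.ndim != 2 or covariance.shape[0] != covariance.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(covariance, covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.covariance = 0.5 * (covariance + covariance.T)
        evals, evecs = np.linalg.eigh(self.covariance)
        self.eigenvalues = evals
        self.eigenvectors = evecs
        vmax = float(evals.max()) if evals.size else 0.0
        cutoff = max(hard_cutoff, soft_cutoff)
        self.cutoff = cutoff
        if vmax <= 0:
            raise ValueError("no informative directions (degenerate training set)")
        # absolute floor: observables live in [0,1], so any genuine direction
        # has variance far above round-off junk
        self.kernel_mask = evals < max(cutoff * vmax, abs_cutoff)
        if self.kernel_mask.all():
            raise ValueError("no informative directions (degenerate training set)")
        keep = ~self.kernel_mask
        V = evecs[:, keep]
        self.projector = V @ V.T
        self.pseudo_inverse = V @ np.diag(1.0 / evals[keep]) @ V.T
        self.dof = int(keep.sum())

    @property
    def kernel_dim(self) -> int:
        return int(self.kernel_mask.sum())

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.projector @ v

    def quadratic_form(self, r: np.ndarray) -> float:
        return float(r @ self.pseudo_inverse @ r)


def build_gauge_projector(covariance: np.ndarray, cutoff: float = 1e-8,
                          hard_cutoff: float = 1e-10) -> GaugeProjector:
    """Diagonalize Sigma and project out its kernel; ``cutoff`` is the soft
    relative eigenvalue threshold."""
    return GaugeProjector(covariance, hard_cutoff=hard_cutoff, soft_cutoff=cutoff)
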