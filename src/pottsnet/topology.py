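"""Network topologies and configuration ensembles.

A system is a symmetric, unweighted graph whose nodes carry one of ``n_states``
integer states (0-based).  Edges are unordered pairs; they may be partitioned
into *classes* (e.g. spatial vs temporal links of a time-extended network), and
each class contributes its own couple-density block and coupling matrix.

Conventions used throughout the package:

* node indexing is 0-based everywhere; lattice nodes are row-major flattened;
* edges are stored as sorted pairs, once each, with no self-loops;
* configurations are integer vectors of length ``n_nodes`` with entries in
  ``[0, n_states)``; ensembles are ``(n_conf, n_nodes)`` integer matrices with
  one nonnegative weight per row.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkTopology",
    "Configuration",
    "Ensemble",
    "build_lattice",
    "load_topology",
    "save_topology",
    "load_ensemble",
    "save_ensemble",
]


class TopologyError(ValueError):
    pass


@dataclass
class NetworkTopology:
    """Symmetric unweighted graph with optionally labeled edge classes.

    Parameters
    ----------
    n_nodes : int
        Number of nodes.
    edges : (m, 2) int array
        Unordered node pairs, each stored once as ``(min, max)``.
    edge_class : (m,) int array, optional
        Class label per edge (default: all 0).
    class_names : sequence of str
        One name per edge class, default ``("spatial",)``.
    metadata : dict
        Free-form provenance (lattice shape, periodicity, ...).
    """

    n_nodes: int
    edges: np.ndarray
    edge_class: np.ndarray | None = None
    class_names: tuple = ("spatial",)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.n_nodes <= 0:
            raise TopologyError("n_nodes must be positive")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise TopologyError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise TopologyError("self-loops are not allowed")
            # canonical sorted-pair form, reject duplicates
            self.edges = np.sort(self.edges, axis=1)
        if self.edge_class is None:
            self.edge_class = np.zeros(len(self.edges), dtype=np.int64)
        else:
            self.edge_class = np.asarray(self.edge_class, dtype=np.int64)
        key = self.edges[:, 0] * self.n_nodes + self.edges[:, 1]
        if len(np.unique(key)) != len(key):
            raise TopologyError("duplicate edges are not allowed")
        self.class_names = tuple(self.class_names)
        if self.edge_class.size and self.edge_class.max() >= len(self.class_names):
            raise TopologyError("edge_class label without a class name")
        self._neighbors = None

    @property
    def n_links(self) -> int:
        return len(self.edges)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def links_per_class(self) -> np.ndarray:
        return np.bincount(self.edge_class, minlength=self.n_classes).astype(np.int64)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_csr(self):
        """CSR adjacency: (indptr, neighbor_index, neighbor_class)."""
        if self._neighbors is None:
            deg = self.degree()
            indptr = np.concatenate([[0], np.cumsum(deg)])
            idx = np.zeros(indptr[-1], dtype=np.int64)
            cls = np.zeros(indptr[-1], dtype=np.int64)
            cursor = indptr[:-1].copy()
            for (a, b), c in zip(self.edges, self.edge_class):
                idx[cursor[a]] = b
                cls[cursor[a]] = c
                cursor[a] += 1
                idx[cursor[b]] = a
                cls[cursor[b]] = c
                cursor[b] += 1
            self._neighbors = (indptr, idx, cls)
        return self._neighbors

    def neighbors(self, node: int) -> np.ndarray:
        indptr, idx, _ = self.neighbor_csr()
        return idx[indptr[node]:indptr[node + 1]]

    def is_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            for nb in self.neighbors(stack.pop()):
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(int(nb))
        return bool(seen.all())


@dataclass
class Configuration:
    """Integer state per node; validated against a state alphabet size."""

    states: np.ndarray
    n_states: int

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64).ravel()
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.n_states
        ):
            raise ValueError("state value out of range [0, n_states)")

    @property
    def n_nodes(self) -> int:
        return self.states.size


class Ensemble:
    """Weighted collection of configurations sharing one topology/alphabet.

    Stored internally as an ``(n_conf, n_nodes)`` int matrix ``X`` plus a
    weight vector (default all ones).
    """

    def __init__(self, X, n_states: int, weights=None):
        self.X = np.asarray(X, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("ensemble matrix must be 2-D (n_conf, n_nodes)")
        if self.X.size and (self.X.min() < 0 or self.X.max() >= n_states):
            bad = np.argwhere((self.X < 0) | (self.X >= n_states))[0]
            raise ValueError(
                f"state out of range at row {bad[0]}, column {bad[1]}"
            )
        self.n_states = int(n_states)
        if weights is None:
            weights = np.ones(len(self.X))
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (len(self.X),):
            raise ValueError("one weight per configuration required")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")

    @property
    def n_conf(self) -> int:
        return len(self.X)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[1]

    def configurations(self):
        return [Configuration(row, self.n_states) for row in self.X]

    def normalized_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def build_lattice(shape: Sequence[int], periodic: bool = True) -> NetworkTopology:
    """Nearest-neighbor hypercubic lattice, row-major node indexing.

    Periodic boundaries wrap each axis; an axis of length 2 cannot be wrapped
    (the wrap edge would duplicate the interior edge) and is rejected.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise TopologyError("lattice dimensions must be positive")
    if periodic and any(s < 3 for s in shape):
        raise TopologyError(
            "periodic lattice requires every axis length >= 3 "
            "(length-2 axes produce duplicate edges)"
        )
    n_nodes = int(np.prod(shape))
    coords = np.indices(shape).reshape(len(shape), -1).T  # (n_nodes, dim)
    flat = np.ravel_multi_index(coords.T, shape)
    edges = []
    for axis, size in enumerate(shape):
        shifted = coords.copy()
        shifted[:, axis] += 1
        if periodic:
            shifted[:, axis] %= size
            mask = np.ones(n_nodes, dtype=bool)
        else:
            mask = shifted[:, axis] < size
        nb = np.ravel_multi_index(shifted[mask].T, shape)
        edges.append(np.column_stack([flat[mask], nb]))
    edges = np.concatenate(edges) if edges else np.empty((0, 2), dtype=np.int64)
    return NetworkTopology(
        n_nodes=n_nodes,
        edges=edges,
        metadata={"lattice_shape": list(shape), "periodic": bool(periodic)},
    )


def load_topology(path) -> NetworkTopology:
    """Read an edge list: two integer columns, '#' comments, duplicates and
    reversed pairs collapsed.  Node count is max index + 1 unless a header
    line ``# n_nodes=K`` declares it."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    declared = None
    pairs = []
    for ln, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "n_nodes=" in stripped:
                declared = int(stripped.split("n_nodes=")[1].split()[0])
            continue
        tokens = stripped.replace(",", " ").split()
        if len(tokens) != 2:
            raise TopologyError(f"line {ln}: expected two columns, got {len(tokens)}")
        try:
            a, b = int(tokens[0]), int(tokens[1])
        except ValueError:
            raise TopologyError(f"line {ln}: non-integer token in {tokens!r}")
        if a == b:
            raise TopologyError(f"line {ln}: self-loop ({a},{b}) not allowed")
        pairs.append((min(a, b), max(a, b)))
    if not pairs:
        raise TopologyError("no edges in file")
    pairs = sorted(set(pairs))
    edges = np.asarray(pairs, dtype=np.int64)
    n_nodes = declared if declared is not None else int(edges.max()) + 1
    topo = NetworkTopology(n_nodes=n_nodes, edges=edges)
    if not topo.is_connected():
        warnings.warn(
            "topology is not connected; proceeding (nothing in the model "
            "requires connectivity)",
            stacklevel=2,
        )
    return topo


def save_topology(topology: NetworkTopology, path) -> None:
    buf = io.StringIO()
    buf.write(f"# n_nodes={topology.n_nodes}\n")
    for a, b in topology.edges:
        buf.write(f"{a}\t{b}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def load_ensemble(path, topology: NetworkTopology, n_states: int) -> Ensemble:
    """Read a configuration matrix: one configuration per line, whitespace- or
    comma-delimited integers, '#' comments."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.replace(",", " ").split()
        try:
            row = [int(t) for t in tokens]
        except ValueError:
            raise ValueError(f"line {ln}: non-integer token")
        if len(row) != topology.n_nodes:
            raise ValueError(
                f"line {ln}: expected {topology.n_nodes} entries, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ValueError("no configurations in file")
    X = np.asarray(rows, dtype=np.int64)
    bad = np.argwhere((X < 0) | (X >= n_states))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"state out of range at data row {r}, column {c}")
    return Ensemble(X, n_states=n_states)


def save_ensemble(ensemble: Ensemble, path) -> None:
    header = f"# n_conf={ensemble.n_conf} n_nodes={ensemble.n_nodes} n_states={ensemble.n_states}\n"
    body = "\n".join(" ".join(str(v) for v in row) for row in ensemble.X)
    text = header + body + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
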