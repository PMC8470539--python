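"""Dynamical MaxEnt: fit a distribution over whole time sequences.

A sequence of ``T`` frames on a base network with ``N`` nodes is mapped onto
one configuration of a *time-extended* network with ``T*N`` nodes: every
frame keeps the base's spatial edges (class "spatial", couplings tied across
timesteps), and each node is linked to itself at the next timestep (class
"temporal").  Self-time correlations are constrained through the full
symmetric Q x Q temporal couple-density matrix, whose off-diagonal mass is
the probability of changing state between consecutive frames.  The static
machinery (trainer, entropy) then applies unchanged; the dynamical entropy is
the thermodynamic-integration entropy of the extended model, naturally
reported per node per timestep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import ensemble_features, layout_for, weighted_covariance
from .topology import NetworkTopology
from .trainer import FitResult, TrainerOptions, fit_from_moments

__all__ = [
    "TimeSeries",
    "TemporalTopology",
    "extend_topology",
    "series_to_configuration",
    "fit_dynamical",
    "dynamical_entropy",
]


@dataclass
class TimeSeries:
    """T x N_nodes integer state matrix."""

    states: np.ndarray
    n_states: int
    metadata: dict | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("time series must be a (T, n_nodes) matrix")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.n_states
        ):
            raise ValueError("state out of range")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


@dataclass
class TemporalTopology:
    """Time-extended network: node (k, t) has flat index t*N + k."""

    base: NetworkTopology
    T: int
    extended: NetworkTopology

    @property
    def spatial_class(self) -> int | None:
        return (self.extended.class_names.index("spatial")
                if "spatial" in self.extended.class_names else None)

    @property
    def temporal_class(self) -> int:
        return self.extended.class_names.index("temporal")

    def slice_edges(self, t: int) -> set:
        """Spatial edge set of the frame at time t, in base indexing."""
        N = self.base.n_nodes
        out = set()
        for (a, b), c in zip(self.extended.edges, self.extended.edge_class):
            if self.extended.class_names[c] != "spatial":
                continue
            if a // N == t and b // N == t:
                out.add((int(a % N), int(b % N)))
        return out


def extend_topology(base: NetworkTopology, T: int) -> TemporalTopology:
    """Replicate the base network T times and add temporal self-links.

    The extended link count is ``T*n_links_base`` spatial plus
    ``(T-1)*n_nodes_base`` temporal edges.
    """
    if T < 2:
        raise ValueError("temporal extension requires T >= 2")
    N = base.n_nodes
    edges = []
    classes = []
    names = []
    if base.n_links > 0:
        names.append("spatial")
        for t in range(T):
            edges.append(base.edges + t * N)
            classes.append(np.zeros(base.n_links, dtype=np.int64))
    temporal_label = len(names)
    names.append("temporal")
    nodes = np.arange(N)
    for t in range(T - 1):
        e = np.column_stack([nodes + t * N, nodes + (t + 1) * N])
        edges.append(e)
        classes.append(np.full(N, temporal_label, dtype=np.int64))
    extended = NetworkTopology(
        n_nodes=T * N,
        edges=np.concatenate(edges),
        edge_class=np.concatenate(classes),
        class_names=tuple(names),
        metadata={"base_n_nodes": N, "T": T, "temporal": True},
    )
    return TemporalTopology(base=base, T=T, extended=extended)


def series_to_configuration(series: TimeSeries) -> np.ndarray:
    """Flatten a (T, N) series into an extended-network configuration, with
    node (k, t) at flat index t*N + k (row-major ravel)."""
    return series.states.ravel()


def _as_series_list(series_ensemble, n_states) -> list:
    if isinstance(series_ensemble, TimeSeries):
        return [series_ensemble]
    if isinstance(series_ensemble, np.ndarray) and series_ensemble.ndim == 2:
        return [TimeSeries(series_ensemble, n_states)]
    out = []
    for s in series_ensemble:
        out.append(s if isinstance(s, TimeSeries) else TimeSeries(np.asarray(s), n_states))
    return out


@dataclass
class DynamicalFitResult:
    fit: FitResult
    temporal: TemporalTopology

    @property
    def params(self):
        return self.fit.params

    @property
    def state(self):
        return self.fit.state

    @property
    def J_spatial(self) -> np.ndarray | None:
        cls = self.temporal.spatial_class
        return None if cls is None else self.fit.params.J[cls]

    @property
    def J_temporal(self) -> np.ndarray:
        return self.fit.params.J[self.temporal.temporal_class]


def fit_dynamical(series_ensemble, base: NetworkTopology, n_states: int,
                  options: TrainerOptions | None = None) -> DynamicalFitResult:
    """Fit the dynamical MaxEnt model to one or more time sequences.

    The training target is the observable vector of the extended-network
    configuration(s).  With several sequences the chi-square metric uses
    their covariance; a single sequence supplies pseudo-replicas instead:
    every consecutive-frame window is treated as a draw of a two-frame
    extended system (stationarity assumption), which fixes both the gauge
    kernel and the scale of the metric.
    """
    options = options or TrainerOptions()
    series = _as_series_list(series_ensemble, n_states)
    if not series:
        raise ValueError("at least one time series required")
    T = series[0].T
    if any(s.T != T for s in series):
        raise ValueError("all series must share the same length T")
    if T < 2:
        raise ValueError("dynamical fitting requires T >= 2")
    temporal = extend_topology(base, T)
    X = np.stack([series_to_configuration(s) for s in series])
    F = ensemble_features(X, temporal.extended, n_states)
    target = F.mean(axis=0)
    if len(series) >= 2:
        w = np.full(len(series), 1.0 / len(series))
        sigma = weighted_covariance(F, w)
        n_train = len(series)
    else:
        windows = np.stack([
            series[0].states[t:t + 2].ravel() for t in range(T - 1)
        ])
        ext2 = extend_topology(base, 2)
        Fw = ensemble_features(windows, ext2.extended, n_states)
        w = np.full(len(Fw), 1.0 / len(Fw))
        sigma = weighted_covariance(Fw, w)
        n_train = T - 1
    result = fit_from_moments(target, sigma, temporal.extended, n_states,
                              options, n_train=n_train)
    return DynamicalFitResult(fit=result, temporal=temporal)


def dynamical_entropy(result: DynamicalFitResult):
    """Thermodynamic-integration entropy of the fitted sequence distribution.

    Returned as an :class:`EntropyReport` over the extended network, so the
    ``per_site`` values are per base-node per timestep and ``normalized``
    divides by ln Q.
    """
    from .entropy import entropy_from_fit

    return entropy_from_fit(result.fit)
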