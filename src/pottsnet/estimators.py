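"""Scikit-learn style estimators wrapping the MaxEnt machinery.

``PottsMaxEnt`` fits the static model to an ``(n_conf, n_nodes)`` matrix of
configurations; ``DynamicalPottsMaxEnt`` fits the time-extended model to one
or more ``(T, n_nodes)`` state sequences.  Both follow the usual estimator
contract: constructor parameters are plain values, ``fit`` returns ``self``,
fitted attributes carry a trailing underscore, and ``get_params`` /
``set_params`` make them composable with model-selection tools.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from .entropy import EntropyReport, entropy_from_fit
from .observables import ensemble_features, weighted_covariance
from .sampler import SamplerOptions, conditional_marginals, metropolis_sample
from .topology import Ensemble, NetworkTopology, build_lattice
from .trainer import TrainerOptions, fit_from_moments
from .dynamical import dynamical_entropy, fit_dynamical

__all__ = ["PottsMaxEnt", "DynamicalPottsMaxEnt"]

MISSING = -1


def _seed_from(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().entropy % (2**31 - 1))
    if isinstance(random_state, numbers.Integral):
        return int(random_state)
    if isinstance(random_state, np.random.Generator):
        return int(random_state.integers(2**31 - 1))
    raise ValueError("random_state must be None, an int, or a Generator")


def _check_configs(X, n_states, n_nodes=None):
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n_conf, n_nodes) integer matrix")
    if not np.issubdtype(X.dtype, np.integer):
        if np.any(X != np.round(X)):
            raise ValueError("states must be integers")
        X = X.astype(np.int64)
    if n_nodes is not None and X.shape[1] != n_nodes:
        raise ValueError(f"X has {X.shape[1]} nodes, topology has {n_nodes}")
    return X.astype(np.int64)


def lattice_block_covariance(states: np.ndarray, topology: NetworkTopology,
                             n_states: int, n_blocks_per_axis: int = 4):
    """Pseudo-replica covariance for a single lattice configuration.

    The grid is tiled into equal open sub-blocks; each block's observable
    vector (densities, and couple densities over the block's internal edges)
    is one replica.  This assumes approximate translation invariance of the
    underlying process, which is what makes a single image a usable training
    set at all.
    """
    shape = topology.metadata.get("lattice_shape")
    if shape is None or len(shape) != 2:
        raise ValueError("block covariance needs a 2-D lattice topology")
    R, C = shape
    br = max(2, R // n_blocks_per_axis)
    bc = max(2, C // n_blocks_per_axis)
    grid = np.asarray(states).reshape(R, C)
    blocks = []
    for r0 in range(0, R - br + 1, br):
        for c0 in range(0, C - bc + 1, bc):
            blocks.append(grid[r0:r0 + br, c0:c0 + bc].ravel())
    if len(blocks) < 2:
        raise ValueError("lattice too small for block pseudo-replicas")
    sub = build_lattice([br, bc], periodic=False)
    F = ensemble_features(np.stack(blocks), sub, n_states)
    w = np.full(len(F), 1.0 / len(F))
    return weighted_covariance(F, w), len(F)


class PottsMaxEnt(BaseEstimator):
    """Maximum-entropy Potts model on a fixed network.

    Fits the fields ``h`` and near-neighbor couplings ``J`` of a Potts
    Hamiltonian so that the model's state and couple densities match the
    training ensemble's, and records the training path for the variational
    entropy estimate.

    Parameters
    ----------
    n_states : alphabet size Q.
    topology : NetworkTopology (required before fit).
    eta : effective-sample-ratio threshold triggering Metropolis refreshes.
    chi2_threshold : convergence level for chi^2 per degree of freedom.
    n_kept, burn_in, stride : Metropolis schedule for each refresh.
    random_state : seed for all sampling during training.

    Attributes (after fit)
    ----------------------
    h_, J_ : fitted fields (Q,) and couplings (Q, Q).
    params_ : full :class:`PottsParameters` (JSON-serializable).
    chi2_, dof_, ess_, n_refresh_, n_iter_, converged_ : diagnostics.
    result_ : the full :class:`FitResult` including the recorded path.
    """

    def __init__(self, n_states=2, topology=None, *, eta=0.5,
                 chi2_threshold=1.0, max_iter=200, n_kept=1000, burn_in=1000,
                 stride=10, soft_cutoff=1e-8, random_state=None):
        self.n_states = n_states
        self.topology = topology
        self.eta = eta
        self.chi2_threshold = chi2_threshold
        self.max_iter = max_iter
        self.n_kept = n_kept
        self.burn_in = burn_in
        self.stride = stride
        self.soft_cutoff = soft_cutoff
        self.random_state = random_state

    def _options(self) -> TrainerOptions:
        return TrainerOptions(
            eta=self.eta, chi2_threshold=self.chi2_threshold,
            max_iter=self.max_iter, n_kept=self.n_kept, burn_in=self.burn_in,
            stride=self.stride, soft_cutoff=self.soft_cutoff,
            seed=_seed_from(self.random_state),
        )

    def fit(self, X, y=None):
        if self.topology is None:
            raise ValueError("a topology must be supplied before fitting")
        X = _check_configs(X, self.n_states, self.topology.n_nodes)
        ens = Ensemble(X, n_states=self.n_states)
        F = ensemble_features(X, self.topology, self.n_states)
        w = ens.normalized_weights()
        target = w @ F
        if len(X) >= 2:
            sigma = weighted_covariance(F, w)
            n_train = len(X)
        else:
            sigma, n_train = lattice_block_covariance(
                X[0], self.topology, self.n_states)
        result = fit_from_moments(target, sigma, self.topology, self.n_states,
                                  self._options(), n_train=n_train)
        self.result_ = result
        self.params_ = result.params
        self.h_ = result.params.h
        self.J_ = result.params.J[0]
        st = result.state
        self.chi2_, self.dof_ = st.chi2, st.dof
        self.ess_, self.n_refresh_ = st.ess, st.n_refresh
        self.n_iter_, self.converged_ = st.n_iter, st.converged
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted yet")

    def sample(self, n_samples: int = 100, random_state=None,
               burn_in: int | None = None, stride: int | None = None) -> np.ndarray:
        """Draw configurations from the fitted model by Metropolis."""
        self._check_fitted()
        opts = SamplerOptions(
            n_kept=n_samples,
            burn_in=self.burn_in if burn_in is None else burn_in,
            stride=self.stride if stride is None else stride,
            seed=_seed_from(random_state if random_state is not None
                            else self.random_state),
        )
        return metropolis_sample(self.params_, self.topology, opts).X

    def predict_proba(self, X, random_state=None,
                      allowed_states=None) -> np.ndarray:
        """Marginal state probabilities for missing nodes.

        ``X`` is ``(n_samples, n_nodes)`` with -1 marking unknown nodes;
        known nodes are clamped and the unknowns are Gibbs-sampled.  Returns
        ``(n_samples, n_nodes, Q)``; clamped nodes carry probability 1 on
        their observed state.
        """
        self._check_fitted()
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        out = np.zeros((len(X), self.topology.n_nodes, self.n_states))
        seed = _seed_from(random_state if random_state is not None
                          else self.random_state)
        for i, row in enumerate(X):
            clamped = {int(k): int(v) for k, v in enumerate(row) if v != MISSING}
            alphabets = (None if allowed_states is None else
                         {int(k): allowed_states for k in range(len(row))
                          if row[k] == MISSING})
            opts = SamplerOptions(n_kept=self.n_kept, burn_in=self.burn_in,
                                  stride=self.stride, seed=seed + i)
            out[i] = conditional_marginals(self.params_, self.topology,
                                           clamped, opts,
                                           node_alphabets=alphabets)
        return out

    def predict(self, X, random_state=None) -> np.ndarray:
        """Fill missing (-1) nodes with their most probable state."""
        X = np.asarray(X)
        single = X.ndim == 1
        proba = self.predict_proba(X, random_state=random_state)
        X2 = X[None, :] if single else X
        filled = X2.copy()
        guess = proba.argmax(axis=2)
        filled = np.where(filled == MISSING, guess, filled)
        return filled[0] if single else filled

    def entropy(self) -> EntropyReport:
        """Variational entropy by thermodynamic integration of the recorded
        training path (no extra sampling)."""
        self._check_fitted()
        return entropy_from_fit(self.result_)

    def score(self, X, y=None) -> float:
        """Negative gauge-projected chi-square of X's observables against the
        fitted model's (higher is better)."""
        self._check_fitted()
        X = _check_configs(X, self.n_states, self.topology.n_nodes)
        st = self.result_.state
        if st.projector is None:
            return 0.0
        F = ensemble_features(X, self.topology, self.n_states)
        x = F.mean(axis=0)
        # compare within the (possibly reduced) space used in training
        model_x = st.path[-1].observables
        idx = _reduction_index(st, self.topology, self.n_states)
        r = st.projector.project(x[idx] - model_x)
        return -float(st.projector.quadratic_form(r))


def _reduction_index(state, topology, n_states):
    from .observables import layout_for

    layout = layout_for(topology, n_states)
    active = state.active_states
    if active is None or len(active) == n_states:
        return np.arange(layout.size)
    red = state.layout
    idx = list(active)
    for cls in range(layout.n_classes):
        base = layout.c_slice(cls).start
        for (i, j) in red.tri:
            idx.append(base + layout.pair_pos[active[i], active[j]])
    return np.asarray(idx)


class DynamicalPottsMaxEnt(BaseEstimator):
    """Dynamical MaxEnt model over time sequences of configurations.

    Fits fields plus two coupling matrices — spatial (tied across timesteps)
    and temporal (consecutive same-node pairs) — on the time-extended
    network, from one or more ``(T, n_nodes)`` sequences.

    Attributes (after fit): ``h_``, ``J_spatial_`` (None if the base network
    has no edges), ``J_temporal_``, plus the same diagnostics as
    :class:`PottsMaxEnt`.
    """

    def __init__(self, n_states=2, base_topology=None, *, eta=0.5,
                 chi2_threshold=1.0, max_iter=200, n_kept=500, burn_in=300,
                 stride=5, soft_cutoff=1e-8, random_state=None):
        self.n_states = n_states
        self.base_topology = base_topology
        self.eta = eta
        self.chi2_threshold = chi2_threshold
        self.max_iter = max_iter
        self.n_kept = n_kept
        self.burn_in = burn_in
        self.stride = stride
        self.soft_cutoff = soft_cutoff
        self.random_state = random_state

    def _options(self) -> TrainerOptions:
        return TrainerOptions(
            eta=self.eta, chi2_threshold=self.chi2_threshold,
            max_iter=self.max_iter, n_kept=self.n_kept, burn_in=self.burn_in,
            stride=self.stride, soft_cutoff=self.soft_cutoff,
            seed=_seed_from(self.random_state),
        )

    def fit(self, X, y=None):
        base = self.base_topology
        if base is None:
            raise ValueError("a base topology must be supplied before fitting")
        X = np.asarray(X) if not isinstance(X, (list, tuple)) else X
        if isinstance(X, np.ndarray) and X.ndim == 3:
            series = list(X)
        else:
            series = X
        result = fit_dynamical(series, base, self.n_states, self._options())
        self.result_ = result
        self.params_ = result.params
        self.h_ = result.params.h
        self.J_spatial_ = result.J_spatial
        self.J_temporal_ = result.J_temporal
        st = result.state
        self.chi2_, self.dof_ = st.chi2, st.dof
        self.ess_, self.n_refresh_ = st.ess, st.n_refresh
        self.n_iter_, self.converged_ = st.n_iter, st.converged
        return self

    def entropy(self) -> EntropyReport:
        """Dynamical entropy; ``per_site`` is per base-node per timestep."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted yet")
        return dynamical_entropy(self.result_)
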