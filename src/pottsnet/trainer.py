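"""Inverse MaxEnt training loop.

Starting from the non-interacting solution, the trainer alternates cheap
conjugate-gradient steps on a chi-square objective (evaluated by importance
reweighting of the last Metropolis ensemble) with full Metropolis refreshes,
triggered whenever the effective-sample-size ratio of the reweighting drops
below a threshold eta.  The full parameter path, together with the model
observables along it, is recorded so that the variational entropy can later
be obtained by thermodynamic integration at no extra sampling cost.

Degenerate targets are handled before optimization starts:

* states that never appear in the training set are removed from the fitting
  alphabet (their fields are pinned to ``pin_value * n_nodes`` on output, a
  numerically-hard exclusion under the density energy convention);
* couple densities that are exactly zero in the target are pinned to
  ``pin_value * n_links`` through a geometric ramp prepended to the recorded
  path, each ramp point carrying its own Metropolis estimate of the model
  observables, so the entropy integral remains valid even for deterministic
  (e.g. periodic) training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observables import (
    GaugeProjector,
    ObservableLayout,
    ObservableVector,
    build_gauge_projector,
    ensemble_averages,
    ensemble_features,
    layout_for,
    observable_covariance,
    weighted_covariance,
)
from .sampler import PottsParameters, SamplerOptions, metropolis_sample
from .topology import Ensemble, NetworkTopology

__all__ = [
    "TrainerOptions",
    "TrainingState",
    "PathSnapshot",
    "FitResult",
    "init_noninteracting",
    "reweight",
    "effective_sample_ratio",
    "chi_square",
    "chi_square_gradient",
    "fit",
    "fit_from_moments",
]

PIN_VALUE = 30.0   # per-unit exponent of a hard exclusion (e^-30 ~ 1e-13)
RAMP_U_MAX = 6.0   # sampled part of the exclusion ramp (exponent units)
RAMP_DU = 0.5
RAMP_TAIL = (7.0, 8.0, 10.0, 13.0, 17.0, 22.0, PIN_VALUE)


@dataclass
class TrainerOptions:
    """Knobs of the training loop.

    eta : minimum effective-sample ratio before a Metropolis refresh (0, 1].
    chi2_threshold : convergence level for chi^2 per degree of freedom.
    """

    eta: float = 0.5
    chi2_threshold: float = 1.0
    max_iter: int = 200
    n_kept: int = 1000
    burn_in: int = 1000
    stride: int = 10
    soft_cutoff: float = 1e-8
    pin_value: float = PIN_VALUE
    cg_restart: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.eta <= 1):
            raise ValueError("eta must be in (0, 1]")
        if self.chi2_threshold <= 0:
            raise ValueError("chi2_threshold must be positive")


@dataclass
class PathSnapshot:
    """One point of the recorded training path."""

    theta: np.ndarray          # flat parameters
    observables: np.ndarray    # flat model observables at theta
    mean_energy: float         # <H_theta> under the model at theta


@dataclass
class TrainingState:
    """Full record of a training run (reduced-alphabet space)."""

    layout: ObservableLayout
    target: np.ndarray
    projector: GaugeProjector | None
    path: list = field(default_factory=list)
    log: list = field(default_factory=list)
    chi2: float = np.nan
    dof: int = 0
    ess: float = 1.0
    n_refresh: int = 0
    converged: bool = False
    n_iter: int = 0
    active_states: np.ndarray | None = None
    n_states_full: int = 0
    target_stderr: np.ndarray | None = None


@dataclass
class FitResult:
    params: PottsParameters
    state: TrainingState
    topology: NetworkTopology


def init_noninteracting(target: ObservableVector | np.ndarray, n_nodes: int,
                        layout: ObservableLayout | None = None) -> np.ndarray:
    """Non-interacting starting point: J = 0 and fields chosen so the
    independent-node model reproduces the target densities exactly.

    Under the density energy convention a node carries weight
    ``exp(-h_i / N)``, so the matching fields are ``h_i = -N ln<s_i>`` (any
    common shift is gauge).  All target densities must be positive; states
    with zero density are excluded from the alphabet before calling this.
    """
    if isinstance(target, ObservableVector):
        layout = target.layout
        s = target.s
    else:
        s = np.asarray(target)[layout.s_slice()]
    if np.any(s <= 0):
        raise ValueError("all target state densities must be positive "
                         "(exclude zero-density states first)")
    theta = np.zeros(layout.size)
    theta[layout.s_slice()] = -n_nodes * np.log(s)
    return theta


def product_model_observables(s: np.ndarray, layout: ObservableLayout) -> np.ndarray:
    """Exact flat observables of the independent-node model with per-node
    state distribution ``s``: couple densities are ``2 s_i s_j`` off-diagonal
    and ``s_i^2`` on the diagonal for every edge class."""
    x = np.zeros(layout.size)
    x[layout.s_slice()] = s
    tri = np.array([(2.0 if i != j else 1.0) * s[i] * s[j] for i, j in layout.tri])
    for cls in range(layout.n_classes):
        x[layout.c_slice(cls)] = tri
    return x


def reweight(F: np.ndarray, theta_new: np.ndarray,
             theta_anchor: np.ndarray) -> np.ndarray:
    """Importance weights rho_i ∝ exp(-H_new + H_anchor), normalized to sum
    to 1; computed in log space with max subtraction."""
    log_w = F @ (theta_anchor - theta_new)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def effective_sample_ratio(weights: np.ndarray) -> float:
    """(sum rho)^2 / (N sum rho^2); 1 iff uniform, 1/N for single support."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    return float(total**2 / (len(w) * (w**2).sum()))


def chi_square(target, model, projector: GaugeProjector):
    """Gauge-projected quadratic form: chi2 = r' Sigma^+ r with the kernel of
    Sigma projected out of the residual; returns (chi2, dof)."""
    t = target.flat if isinstance(target, ObservableVector) else np.asarray(target)
    m = model.flat if isinstance(model, ObservableVector) else np.asarray(model)
    if t.shape != m.shape:
        raise ValueError("target/model layout mismatch")
    r = projector.project(t - m)
    return projector.quadratic_form(r), projector.dof


def chi_square_gradient(r: np.ndarray, model_cov: np.ndarray,
                        projector: GaugeProjector) -> np.ndarray:
    """Analytic gradient of chi2 wrt the flat parameters.

    For a Boltzmann family d<x_a>/dtheta_b = -Cov(x_a, x_b), hence
    grad = 2 C Sigma^+ r, projected onto the informative subspace.
    """
    g = 2.0 * model_cov @ (projector.pseudo_inverse @ r)
    return projector.project(g)


def _detect_pins(target: np.ndarray, layout: ObservableLayout,
                 topology: NetworkTopology, pin_value: float) -> np.ndarray:
    """Pin vector for exactly-zero couple densities (0 elsewhere)."""
    pin = np.zeros(layout.size)
    links = topology.links_per_class()
    for cls in range(layout.n_classes):
        if links[cls] == 0:
            continue
        sl = layout.c_slice(cls)
        block = target[sl]
        mask = block == 0.0
        pin[sl][...] = np.where(mask, pin_value * links[cls], 0.0)
    return pin


class _Anchor:
    """Metropolis anchor ensemble with cached feature matrix."""

    def __init__(self, theta, F):
        self.theta = theta
        self.F = F


def _run_metropolis(theta, layout, topology, options: TrainerOptions, seed,
                    initial=None) -> _Anchor:
    params = PottsParameters.from_flat(theta, layout)
    sopts = SamplerOptions(n_kept=options.n_kept, burn_in=options.burn_in,
                           stride=options.stride, seed=seed, initial=initial)
    ens = metropolis_sample(params, topology, sopts)
    F = ensemble_features(ens.X, topology, layout.n_states)
    return _Anchor(theta.copy(), F)


def fit(ensemble: Ensemble, topology: NetworkTopology,
        options: TrainerOptions | None = None) -> FitResult:
    """Fit a Potts MaxEnt model to a training ensemble (Metropolis + CG +
    reweighting loop); see :func:`fit_from_moments` for the moment-level
    entry point."""
    options = options or TrainerOptions()
    target = ensemble_averages(ensemble, topology)
    if ensemble.n_conf >= 2:
        sigma = observable_covariance(ensemble, topology)
    else:
        raise ValueError(
            "a single configuration carries no covariance; use "
            "fit_from_moments with a pseudo-replica covariance estimate"
        )
    n_train = ensemble.n_conf
    return fit_from_moments(target.flat, sigma, topology, ensemble.n_states,
                            options, n_train=n_train)


def _reduce_problem(target, sigma, layout, n_states):
    """Drop zero-density states from the flat space; return index map."""
    s = target[layout.s_slice()]
    active = np.flatnonzero(s > 0)
    if active.size == n_states:
        return None
    red_layout = ObservableLayout(active.size, layout.n_classes, layout.class_names)
    idx = list(active)
    for cls in range(layout.n_classes):
        base = layout.c_slice(cls).start
        for (i, j) in red_layout.tri:
            gi, gj = active[i], active[j]
            idx.append(base + layout.pair_pos[gi, gj])
    idx = np.asarray(idx)
    return red_layout, active, idx


def fit_from_moments(target: np.ndarray, sigma: np.ndarray,
                     topology: NetworkTopology, n_states: int,
                     options: TrainerOptions | None = None,
                     n_train: int | None = None) -> FitResult:
    """Core fit: match target observable moments under a covariance metric.

    Parameters
    ----------
    target : flat target observable vector (canonical layout).
    sigma : covariance of the per-configuration observables on the training
        set; its kernel defines the gauge directions.  When ``n_train`` is
        given the chi-square metric is ``sigma / n_train`` — the covariance
        of the target *mean* — so that chi^2/dof < 1 means agreement within
        the training set's stochastic accuracy.
    """
    options = options or TrainerOptions()
    layout = layout_for(topology, n_states)
    target = np.asarray(target, dtype=float)
    if target.shape != (layout.size,):
        raise ValueError("target has wrong length for this topology/alphabet")
    rng = np.random.default_rng(options.seed)

    reduction = _reduce_problem(target, sigma, layout, n_states)
    if reduction is not None:
        red_layout, active, idx = reduction
        red_target = target[idx]
        red_sigma = sigma[np.ix_(idx, idx)]
    else:
        red_layout, active = layout, np.arange(n_states)
        red_target, red_sigma = target, sigma

    state = TrainingState(layout=red_layout, target=red_target, projector=None,
                          active_states=active, n_states_full=n_states)
    if n_train:
        state.target_stderr = np.sqrt(np.clip(np.diag(red_sigma), 0, None) / n_train)

    n_nodes = topology.n_nodes

    # --- degenerate single-state alphabet: deterministic system, no fitting
    if red_layout.n_states == 1:
        theta = np.zeros(red_layout.size)
        x = product_model_observables(np.array([1.0]), red_layout)
        state.path.append(PathSnapshot(theta, x, 0.0))
        state.converged = True
        state.chi2 = 0.0
        params = _embed_params(theta, state, layout, topology, options)
        return FitResult(params=params, state=state, topology=topology)

    theta0 = init_noninteracting(red_target, n_nodes, red_layout)
    x0 = product_model_observables(red_target[red_layout.s_slice()], red_layout)
    state.path.append(PathSnapshot(theta0.copy(), x0, float(theta0 @ x0)))

    # --- gauge projector (may fail for fully deterministic targets); the
    # metric is the covariance of the target mean when n_train is known
    metric_sigma = red_sigma / n_train if n_train else red_sigma
    try:
        projector = build_gauge_projector(metric_sigma, cutoff=options.soft_cutoff)
    except ValueError:
        projector = None
    state.projector = projector
    state.dof = projector.dof if projector is not None else 0

    # --- pin ramp for exactly-zero couple densities
    pin = _detect_pins(red_target, red_layout, topology, options.pin_value)
    theta = theta0.copy()
    anchor = None
    if np.any(pin != 0):
        # sampled part of the exclusion ramp: uniform steps in the per-link
        # exponent u up to RAMP_U_MAX ...
        for u in np.arange(RAMP_DU, RAMP_U_MAX + 1e-9, RAMP_DU):
            theta = theta0 + (u / options.pin_value) * pin
            anchor = _run_metropolis(theta, red_layout, topology, options,
                                     int(rng.integers(2**31 - 1)))
            x_hat = anchor.F.mean(axis=0)
            state.path.append(PathSnapshot(theta.copy(), x_hat,
                                           float(theta @ x_hat)))
        # ... then the analytic tail: for a hard exclusion the pinned couple
        # densities decay as e^{-u}, so extrapolated snapshots integrate the
        # remainder without further sampling
        x_base = state.path[-1].observables
        pin_mask = pin != 0
        for u in RAMP_TAIL:
            theta = theta0 + (u / options.pin_value) * pin
            x = x_base.copy()
            x[pin_mask] = x_base[pin_mask] * np.exp(-(u - RAMP_U_MAX))
            state.path.append(PathSnapshot(theta.copy(), x, float(theta @ x)))
        anchor = _run_metropolis(theta, red_layout, topology, options,
                                 int(rng.integers(2**31 - 1)))

    if projector is None:
        # nothing informative left to optimize (deterministic target)
        state.converged = True
        state.chi2 = 0.0
        params = _embed_params(theta, state, layout, topology, options)
        return FitResult(params=params, state=state, topology=topology)

    if anchor is None:
        anchor = _run_metropolis(theta, red_layout, topology, options,
                                 int(rng.integers(2**31 - 1)))

    # --- CG loop with importance-sampling reuse
    M = projector.pseudo_inverse
    restart_every = options.cg_restart or max(projector.dof, 1)
    g_prev = None
    d = None
    alpha_prev = None
    uniform = np.full(len(anchor.F), 1.0 / len(anchor.F))

    min_ess = 0.5 * options.eta  # line-search trust floor for reweighting

    # parameter box: beyond the hard-exclusion scale (pin_value per unit
    # exponent) parameters are physically indistinguishable, so steps are
    # clipped there to keep ill-conditioned directions from running away
    links = topology.links_per_class().astype(float)
    bound = np.empty(red_layout.size)
    bound[red_layout.s_slice()] = options.pin_value * n_nodes
    for cls in range(red_layout.n_classes):
        bound[red_layout.c_slice(cls)] = options.pin_value * max(links[cls], 1.0)

    def model_stats(th, anc):
        rho = reweight(anc.F, th, anc.theta)
        x_hat = rho @ anc.F
        r = projector.project(red_target - x_hat)
        return rho, x_hat, r, float(r @ M @ r), effective_sample_ratio(rho)

    for it in range(options.max_iter):
        rho, x_hat, r, chi2, ess = model_stats(theta, anchor)
        ess_pre = ess
        refreshed = False
        if ess < options.eta:
            anchor = _run_metropolis(theta, red_layout, topology, options,
                                     int(rng.integers(2**31 - 1)))
            refreshed = True
            state.n_refresh += 1
            rho, x_hat, r, chi2, ess = model_stats(theta, anchor)
        state.chi2, state.ess, state.n_iter = chi2, ess, it + 1
        state.log.append({"iter": it, "chi2": chi2, "dof": projector.dof,
                          "chi2_per_dof": chi2 / projector.dof,
                          "ess": ess, "ess_pre": ess_pre,
                          "refreshed": refreshed})
        if chi2 / projector.dof < options.chi2_threshold:
            state.converged = True
            state.path.append(PathSnapshot(theta.copy(), x_hat.copy(),
                                           float(theta @ x_hat)))
            break

        C = weighted_covariance(anchor.F, rho)
        g = chi_square_gradient(r, C, projector)
        gnorm = float(np.linalg.norm(g))
        if gnorm < 1e-14:
            state.converged = chi2 / projector.dof < options.chi2_threshold
            break
        if g_prev is None or it % restart_every == 0:
            d = -g
        else:
            beta = max(0.0, float(g @ (g - g_prev) / (g_prev @ g_prev)))
            d = -g + beta * d
            if g @ d >= 0:  # not a descent direction: restart
                d = -g
        g_prev = g

        # Gauss-Newton initial step, then Armijo backtracking
        u = C @ d
        denom = float(u @ M @ u)
        gd = float(g @ d)
        alpha = -0.5 * gd / denom if denom > 1e-300 else (alpha_prev or 1.0)
        if not np.isfinite(alpha) or alpha <= 0:
            alpha = alpha_prev or 1.0
        accepted = False
        for _ in range(40):
            trial = np.clip(theta + alpha * d, -bound, bound)
            _, x_t, r_t, chi2_t, ess_t = model_stats(trial, anchor)
            # a step is trusted only while the reweighted ensemble still has
            # a usable effective sample size
            if chi2_t <= chi2 + 1e-4 * alpha * gd and ess_t >= min_ess:
                # record intermediate snapshots along the step (reweighted
                # observables are cheap) so the entropy line integral stays
                # accurate even for large steps in steep directions
                for frac in (0.25, 0.5, 0.75):
                    th_mid = np.clip(theta + frac * alpha * d, -bound, bound)
                    _, x_mid, _, _, _ = model_stats(th_mid, anchor)
                    state.path.append(PathSnapshot(th_mid, x_mid,
                                                   float(th_mid @ x_mid)))
                theta = trial
                state.path.append(PathSnapshot(theta.copy(), x_t.copy(),
                                               float(theta @ x_t)))
                alpha_prev = alpha
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # cannot progress on this ensemble: refresh once, else stop
            if ess < 1.0:
                anchor = _run_metropolis(theta, red_layout, topology, options,
                                         int(rng.integers(2**31 - 1)))
                state.n_refresh += 1
                g_prev = None
            else:
                break
    else:
        # max_iter exhausted: flagged (non-exception) result
        rho, x_hat, r, chi2 = model_stats(theta, anchor)
        state.chi2 = chi2
        state.path.append(PathSnapshot(theta.copy(), x_hat.copy(),
                                       float(theta @ x_hat)))

    params = _embed_params(theta, state, layout, topology, options)
    return FitResult(params=params, state=state, topology=topology)


def _embed_params(theta_red: np.ndarray, state: TrainingState,
                  full_layout: ObservableLayout, topology: NetworkTopology,
                  options: TrainerOptions) -> PottsParameters:
    """Map reduced-alphabet parameters back to the full alphabet, pinning the
    fields of excluded states to a numerically-hard exclusion value."""
    red_layout = state.layout
    active = state.active_states
    Q = state.n_states_full
    theta = np.zeros(full_layout.size)
    theta[full_layout.s_slice()][...] = options.pin_value * topology.n_nodes
    h_full = theta[full_layout.s_slice()]
    h_full[active] = theta_red[red_layout.s_slice()]
    for cls in range(full_layout.n_classes):
        full_sl = full_layout.c_slice(cls)
        red_sl = red_layout.c_slice(cls)
        block = theta[full_sl]
        red_block = theta_red[red_sl]
        for p, (i, j) in enumerate(red_layout.tri):
            gi, gj = active[i], active[j]
            block[full_layout.pair_pos[gi, gj]] = red_block[p]
    meta = {
        "energy_scale": "density",
        "excluded_states": sorted(set(range(Q)) - set(int(a) for a in active)),
        "pin_value": options.pin_value,
    }
    return PottsParameters.from_flat(theta, full_layout, metadata=meta)
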