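"""Fixture simulators: Hopfield recurrent networks, a Wa-Tor-class
predator-prey lattice, and exact/Metropolis Potts ensemble generators.

These generate all inputs the package's tests and examples use; nothing is
read from external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamical import TimeSeries
from .sampler import PottsParameters, SamplerOptions, enumerate_exact, metropolis_sample
from .topology import Ensemble, NetworkTopology, build_lattice

__all__ = [
    "HopfieldNetwork",
    "hopfield_connectivity",
    "hopfield_step",
    "hopfield_trajectory",
    "EcoLatParams",
    "EcoLatResult",
    "ecolat_simulate",
    "generate_potts_ensemble",
]


# ---------------------------------------------------------------------------
# Hopfield recurrent network
# ---------------------------------------------------------------------------

@dataclass
class HopfieldNetwork:
    """Synchronous +-1 recurrent network.

    The connectivity is J = (1 - eps/2) S + (eps/2) A with S symmetric and A
    antisymmetric, off-diagonal entries uniform on [-1, 1] and zero diagonal
    (no autapses).  ``epsilon`` in [0, 2] interpolates from fully symmetric
    to fully antisymmetric coupling.

    Dilution ``d`` removes unordered pairs (J_ij and J_ji together) with
    probability d, so d -> 0 is the fully connected limit and the expected
    number of surviving links is (1 - d) N (N - 1) / 2.  (Reading d as the
    fraction of links KEPT would contradict the fully-connected d -> 0
    limit and is deliberately not used; an elementwise-dilution variant is
    available behind ``pairwise=False``.)
    """

    n_neurons: int
    epsilon: float
    dilution: float
    J: np.ndarray
    eta: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if self.eta is None:
            self.eta = np.zeros(self.n_neurons)


def hopfield_connectivity(N: int, epsilon: float, d: float, seed: int = 0,
                          pairwise: bool = True) -> HopfieldNetwork:
    if not (0 <= epsilon <= 2):
        raise ValueError("epsilon must be in [0, 2]")
    if not (0 <= d <= 1):
        raise ValueError("dilution must be in [0, 1]")
    rng = np.random.default_rng(seed)
    upper = np.triu_indices(N, k=1)
    S = np.zeros((N, N))
    A = np.zeros((N, N))
    S[upper] = rng.uniform(-1, 1, size=len(upper[0]))
    S = S + S.T
    A[upper] = rng.uniform(-1, 1, size=len(upper[0]))
    A = A - A.T
    J = (1 - epsilon / 2) * S + (epsilon / 2) * A
    if d > 0:
        if pairwise:
            keep = rng.random(len(upper[0])) >= d
            mask = np.zeros((N, N), dtype=bool)
            mask[upper] = keep
            mask = mask | mask.T
        else:
            mask = rng.random((N, N)) >= d
            np.fill_diagonal(mask, False)
        J = np.where(mask, J, 0.0)
    np.fill_diagonal(J, 0.0)
    return HopfieldNetwork(n_neurons=N, epsilon=epsilon, dilution=d, J=J, seed=seed)


def hopfield_step(sigma: np.ndarray, network: HopfieldNetwork,
                  rng: np.random.Generator) -> np.ndarray:
    """One synchronous update: sigma_i <- sign(sum_j J_ij sigma_j - eta_i),
    with an exact zero input resolved as +-1 uniformly at random."""
    sigma = np.asarray(sigma)
    if not np.all(np.abs(sigma) == 1):
        raise ValueError("sigma entries must be -1 or +1")
    drive = network.J @ sigma - network.eta
    out = np.sign(drive).astype(np.int64)
    ties = out == 0
    if np.any(ties):
        out[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    return out


def hopfield_trajectory(network: HopfieldNetwork, sigma0=None, T: int = 200,
                        seed: int = 0) -> TimeSeries:
    """Record T synchronous steps, mapped to {0, 1} (-1 -> 0, +1 -> 1).

    For deterministic runs (no ties encountered) the metadata reports the
    detected recurrence: 'fixed_point', a cycle length, or None if no state
    repeats within T steps.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    N = network.n_neurons
    if sigma0 is None:
        sigma = rng.choice([-1, 1], size=N)
    else:
        sigma = np.asarray(sigma0, dtype=np.int64)
        if not np.all(np.abs(sigma) == 1):
            raise ValueError("sigma0 entries must be -1 or +1")
    frames = np.zeros((T, N), dtype=np.int64)
    seen = {}
    cycle = None
    for t in range(T):
        frames[t] = (sigma + 1) // 2
        key = sigma.tobytes()
        if key in seen and cycle is None:
            cycle = t - seen[key]
        seen[key] = t
        sigma = hopfield_step(sigma, network, rng)
    meta = {
        "mapping": {-1: 0, 1: 1},
        "cycle_length": cycle,
        "kind": ("fixed_point" if cycle == 1 else
                 "cycle" if cycle else "no_cycle_within_T"),
        "epsilon": network.epsilon,
        "dilution": network.dilution,
    }
    return TimeSeries(frames, n_states=2, metadata=meta)


# ---------------------------------------------------------------------------
# Predator-prey lattice (Wa-Tor-class rules)
# ---------------------------------------------------------------------------

EMPTY, FISH, SHARK = 0, 1, 2


@dataclass
class EcoLatParams:
    """Three-state predator-prey lattice parameters.

    States: 0 environment, 1 fish (prey), 2 shark (predator).  Each step
    visits all agents in random order: a fish moves to a random empty
    neighbor with ``fish_move`` and, when it moves, breeds into its vacated
    site with ``fish_breed``; a shark always eats a random neighboring fish
    if one exists (resetting its starvation clock), otherwise moves to a
    random empty neighbor with probability ``shark_move`` (the predator
    mobility knob), breeds into its vacated site with ``shark_breed`` when it
    moves, and dies after ``shark_starve`` steps without eating.  These rules
    are this package's own design: they reproduce the qualitative regimes
    (coexistence steady state, fish saturation, extinction) of minimal
    lattice ecosystems.
    """

    L: int = 30
    fish_move: float = 0.8
    fish_breed: float = 0.35
    shark_move: float = 0.7
    shark_breed: float = 0.1
    shark_starve: int = 3
    init_fish: float = 0.3
    init_shark: float = 0.05
    n_steps: int = 300
    burn_in: int = 100
    record_stride: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("fish_move", "fish_breed", "shark_move", "shark_breed",
                     "init_fish", "init_shark"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.init_fish + self.init_shark > 1:
            raise ValueError("initial densities must sum to <= 1")


@dataclass
class EcoLatResult:
    snapshots: Ensemble | None
    topology: NetworkTopology
    absorbed: str | None          # None | 'fish_saturation' | 'extinction'
    absorbed_at: int | None
    density_history: np.ndarray   # (n_steps_run, 2): fish, shark densities


def ecolat_simulate(params: EcoLatParams) -> EcoLatResult:
    """Asynchronous agent updates on a periodic L x L lattice; returns
    steady-state snapshots, or a flagged absorbing outcome instead of a fake
    steady state."""
    L = params.L
    rng = np.random.default_rng(params.seed)
    topo = build_lattice([L, L], periodic=True)
    grid = np.zeros(L * L, dtype=np.int64)
    n = L * L
    order0 = rng.permutation(n)
    n_fish = int(round(params.init_fish * n))
    n_shark = int(round(params.init_shark * n))
    grid[order0[:n_fish]] = FISH
    grid[order0[n_fish:n_fish + n_shark]] = SHARK
    hunger = np.zeros(n, dtype=np.int64)

    indptr, nb_idx, _ = topo.neighbor_csr()

    snapshots = []
    history = []
    absorbed = None
    absorbed_at = None
    for step in range(params.n_steps):
        agents = np.flatnonzero(grid != EMPTY)
        rng.shuffle(agents)
        for site in agents:
            kind = grid[site]
            if kind == EMPTY:
                continue  # eaten earlier this step
            nbs = nb_idx[indptr[site]:indptr[site + 1]]
            if kind == FISH:
                if rng.random() < params.fish_move:
                    empty = nbs[grid[nbs] == EMPTY]
                    if empty.size:
                        dest = empty[rng.integers(empty.size)]
                        grid[dest] = FISH
                        grid[site] = (FISH if rng.random() < params.fish_breed
                                      else EMPTY)
            else:  # SHARK
                hunger[site] += 1
                if hunger[site] > params.shark_starve:
                    grid[site] = EMPTY
                    continue
                fish_nb = nbs[grid[nbs] == FISH]
                moved_to = None
                if fish_nb.size:
                    moved_to = fish_nb[rng.integers(fish_nb.size)]
                    hunger_new = 0
                elif rng.random() < params.shark_move:
                    empty = nbs[grid[nbs] == EMPTY]
                    if empty.size:
                        moved_to = empty[rng.integers(empty.size)]
                        hunger_new = hunger[site]
                if moved_to is not None:
                    grid[moved_to] = SHARK
                    hunger[moved_to] = hunger_new
                    if rng.random() < params.shark_breed:
                        grid[site] = SHARK
                        hunger[site] = 0  # offspring starts fed
                    else:
                        grid[site] = EMPTY
        fish_d = float((grid == FISH).mean())
        shark_d = float((grid == SHARK).mean())
        history.append((fish_d, shark_d))
        if shark_d == 0.0:
            absorbed = "fish_saturation" if fish_d > 0 else "extinction"
            absorbed_at = step
            break
        if fish_d == 0.0:
            # sharks cannot eat again: the lattice empties out
            absorbed, absorbed_at = "extinction", step
            break
        if step >= params.burn_in and (step - params.burn_in) % params.record_stride == 0:
            snapshots.append(grid.copy())
    ens = Ensemble(np.stack(snapshots), n_states=3) if snapshots else None
    return EcoLatResult(
        snapshots=ens, topology=topo, absorbed=absorbed,
        absorbed_at=absorbed_at, density_history=np.asarray(history),
    )


# ---------------------------------------------------------------------------
# Ground-truth Potts ensemble generators
# ---------------------------------------------------------------------------

def generate_potts_ensemble(params: PottsParameters, topology: NetworkTopology,
                            n_conf: int, seed: int = 0,
                            method: str = "exact") -> Ensemble:
    """Draw a training ensemble from known parameters.

    ``method='exact'`` draws i.i.d. configurations from the enumerated
    Boltzmann table (small systems only); ``method='metropolis'`` uses
    thinned Metropolis samples.  Deterministic per seed; the generator is
    recorded so parameter-recovery tests know their ground truth.
    """
    rng = np.random.default_rng(seed)
    if method == "exact":
        sol = enumerate_exact(params, topology)
        picks = rng.choice(len(sol.configs), size=n_conf, p=sol.probabilities)
        X = sol.configs[picks]
    elif method == "metropolis":
        opts = SamplerOptions(n_kept=n_conf, seed=int(rng.integers(2**31 - 1)))
        X = metropolis_sample(params, topology, opts).X
    else:
        raise ValueError("method must be 'exact' or 'metropolis'")
    return Ensemble(X, n_states=params.n_states)
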