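import numpy as np
import pytest

import pottsnet as pn
from pottsnet.sampler import SamplerOptions
from pottsnet.topology import NetworkTopology

# a published-style 4-state parameter set (black/green/red/blue ordering)
# used as fixed test data for energy evaluation and reporting
H4 = np.array([0.64, 1.54, 4.30, 2.23])
J4 = np.array([
    [-0.112, 0.320, -0.036, 0.532],
    [0.320, -0.442, 0.318, 0.247],
    [-0.036, 0.318, 0.047, 0.060],
    [0.532, 0.247, 0.060, -0.927],
])


def term_by_term_energy(states, h, J, topology):
    n = states.size
    e = sum(h[s] for s in states) / n
    for a, b in topology.edges:
        e += J[states[a], states[b]] / topology.n_links
    return e


def test_energy_zero_params(rng):
    topo = pn.build_lattice([3, 3], periodic=True)
    p = pn.PottsParameters(h=np.zeros(3), J=[np.zeros((3, 3))])
    for _ in range(5):
        assert pn.energy(rng.integers(0, 3, 9), p, topo) == 0.0


def test_energy_field_only(rng):
    topo = pn.build_lattice([4], periodic=False)
    h = rng.normal(size=3)
    p = pn.PottsParameters(h=h, J=[np.zeros((3, 3))])
    states = rng.integers(0, 3, 4)
    assert np.isclose(pn.energy(states, p, topo),
                      h @ pn.state_density(states, 3))


def test_energy_four_state_grid_term_by_term(rng):
    topo = pn.build_lattice([3, 3], periodic=False)
    p = pn.PottsParameters(h=H4, J=[J4])
    for _ in range(5):
        states = rng.integers(0, 4, 9)
        assert np.isclose(pn.energy(states, p, topo),
                          term_by_term_energy(states, H4, J4, topo))


def test_local_delta_matches_global(rng):
    topo = pn.build_lattice([3, 3], periodic=True)
    M = rng.normal(size=(3, 3))
    p = pn.PottsParameters(h=rng.normal(size=3), J=[(M + M.T) / 2])
    states = rng.integers(0, 3, 9)
    for node in range(9):
        new = (states[node] + 1) % 3
        flipped = states.copy()
        flipped[node] = new
        delta = pn.local_energy_delta(states, node, new, p, topo)
        assert np.isclose(delta, pn.energy(flipped, p, topo) - pn.energy(states, p, topo))
    assert pn.local_energy_delta(states, 0, int(states[0]), p, topo) == 0.0


def test_local_delta_isolated_node():
    topo = NetworkTopology(n_nodes=1, edges=np.empty((0, 2), dtype=np.int64))
    p = pn.PottsParameters(h=np.array([0.3, 1.7]), J=[np.zeros((2, 2))])
    assert np.isclose(pn.local_energy_delta(np.array([0]), 0, 1, p, topo),
                      1.7 - 0.3)


def test_enumerate_uniform():
    topo = pn.build_lattice([2, 2], periodic=False)
    p = pn.PottsParameters(h=np.zeros(2), J=[np.zeros((2, 2))])
    sol = pn.enumerate_exact(p, topo)
    assert np.isclose(sol.probabilities.sum(), 1.0)
    assert np.allclose(sol.probabilities, 1 / 16)
    assert np.isclose(sol.entropy, 4 * np.log(2))


def test_enumerate_cap():
    topo = pn.build_lattice([5, 5], periodic=True)
    p = pn.PottsParameters(h=np.zeros(4), J=[np.zeros((4, 4))])
    with pytest.raises(ValueError, match="metropolis"):
        pn.enumerate_exact(p, topo, cap=1000)


def test_gauge_shift_leaves_probabilities_unchanged(rng):
    topo = pn.build_lattice([2, 3], periodic=False)
    M = rng.normal(size=(3, 3))
    J = (M + M.T) / 2
    h = rng.normal(size=3)
    base = pn.enumerate_exact(pn.PottsParameters(h=h, J=[J]), topo)
    shifted = pn.enumerate_exact(pn.PottsParameters(h=h + 2.5, J=[J]), topo)
    assert np.allclose(base.probabilities, shifted.probabilities)


def test_metropolis_uniform_target():
    topo = pn.build_lattice([2, 2], periodic=False)
    p = pn.PottsParameters(h=np.zeros(2), J=[np.zeros((2, 2))])
    ens = pn.metropolis_sample(p, topo, SamplerOptions(n_kept=4000, burn_in=100,
                                                       stride=2, seed=0))
    freq = (ens.X == 0).mean()
    sigma = 0.5 / np.sqrt(4000 * 4)
    assert abs(freq - 0.5) < 3 * sigma * 3  # conservative (samples correlate)


def test_metropolis_matches_enumeration_two_nodes():
    """Strong antiferromagnetic pair: empirical distribution matches the
    4-configuration exact table within total variation 0.02."""
    topo = pn.build_lattice([2], periodic=False)
    p = pn.PottsParameters(h=np.zeros(2), J=[np.array([[3.0, -3.0], [-3.0, 3.0]])])
    sol = pn.enumerate_exact(p, topo)
    ens = pn.metropolis_sample(p, topo, SamplerOptions(n_kept=20000, burn_in=200,
                                                       stride=3, seed=4))
    keys = ens.X @ np.array([1, 2])
    emp = np.bincount(keys, minlength=4) / len(keys)
    exact = np.zeros(4)
    exact[sol.configs @ np.array([1, 2])] = sol.probabilities
    assert 0.5 * np.abs(emp - exact).sum() < 0.02


def test_metropolis_determinism():
    topo = pn.build_lattice([3, 3], periodic=True)
    p = pn.PottsParameters(h=np.array([0.2, -0.2]), J=[np.zeros((2, 2))])
    opts = SamplerOptions(n_kept=200, burn_in=50, stride=2, seed=99)
    a = pn.metropolis_sample(p, topo, opts)
    b = pn.metropolis_sample(p, topo, opts)
    assert np.array_equal(a.X, b.X)


def test_metropolis_all_clamped_rejected():
    topo = pn.build_lattice([2], periodic=False)
    p = pn.PottsParameters(h=np.zeros(2), J=[np.zeros((2, 2))])
    with pytest.raises(ValueError, match="clamped"):
        pn.metropolis_sample(p, topo, SamplerOptions(clamped={0: 0, 1: 1}))


def test_detailed_balance(rng):
    """pi(a) T(a->b) A(a->b) is symmetric under swapping a and b."""
    topo = pn.build_lattice([2, 2], periodic=False)
    M = rng.normal(size=(2, 2))
    p = pn.PottsParameters(h=rng.normal(size=2), J=[(M + M.T)])
    sol = pn.enumerate_exact(p, topo)
    for _ in range(20):
        a = rng.integers(0, 2, 4)
        node = rng.integers(4)
        b = a.copy()
        b[node] ^= 1
        dH = pn.energy(b, p, topo) - pn.energy(a, p, topo)
        pa = sol.probability_of(a)
        pb = sol.probability_of(b)
        flow_ab = pa * min(1.0, np.exp(-dH))
        flow_ba = pb * min(1.0, np.exp(dH))
        assert np.isclose(flow_ab, flow_ba, rtol=1e-10)


def test_conditional_marginal_single_free_node():
    """All nodes clamped but one, J = 0: the free node's marginal is the
    single-site Boltzmann weight exp(-h_i / N)."""
    topo = pn.build_lattice([3], periodic=False)
    h = np.array([0.0, 3 * np.log(2.0)])  # per-node weights 1 : 1/2
    p = pn.PottsParameters(h=h, J=[np.zeros((2, 2))])
    probs = pn.conditional_marginals(p, topo, clamped={0: 0, 1: 0},
                                     options=SamplerOptions(n_kept=8000, burn_in=100,
                                                            stride=1, seed=2))
    assert np.allclose(probs[0], [1, 0])
    assert abs(probs[2, 0] - 2 / 3) < 0.02


def test_conditional_marginals_match_oracle():
    topo = pn.build_lattice([2, 3], periodic=False)
    p = pn.PottsParameters(h=np.array([0.5, -0.5]),
                           J=[np.array([[-3.0, 1.0], [1.0, -3.0]])])
    clamped = {0: 1, 5: 0}
    opts = SamplerOptions(n_kept=40000, burn_in=300, stride=2, seed=8)
    probs = pn.conditional_marginals(p, topo, clamped, opts)
    # oracle: condition the exact table
    sol = pn.enumerate_exact(p, topo)
    mask = (sol.configs[:, 0] == 1) & (sol.configs[:, 5] == 0)
    Pc = sol.probabilities[mask] / sol.probabilities[mask].sum()
    sub = sol.configs[mask]
    for node in (1, 2, 3, 4):
        exact = np.array([Pc[sub[:, node] == s].sum() for s in (0, 1)])
        assert 0.5 * np.abs(probs[node] - exact).sum() < 0.02


def test_attractive_clamp_decays_with_distance():
    """With an attractive same-state coupling, the probability of matching a
    clamped end-node decreases monotonically with graph distance on a path."""
    topo = pn.build_lattice([6], periodic=False)
    p = pn.PottsParameters(h=np.zeros(2),
                           J=[np.array([[-6.0, 6.0], [6.0, -6.0]])])
    sol = pn.enumerate_exact(p, topo)
    mask = sol.configs[:, 0] == 1
    Pc = sol.probabilities[mask] / sol.probabilities[mask].sum()
    sub = sol.configs[mask]
    p1 = [Pc[sub[:, node] == 1].sum() for node in range(1, 6)]
    assert all(a >= b for a, b in zip(p1[:-1], p1[1:]))
    assert p1[0] > 0.5
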