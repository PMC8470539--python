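import numpy as np
import pytest

import pottsnet as pn
from pottsnet.observables import ObservableLayout, ensemble_features, layout_for, weighted_covariance
from pottsnet.sampler import SamplerOptions
from pottsnet.simulators import generate_potts_ensemble
from pottsnet.topology import NetworkTopology
from pottsnet.trainer import (
    TrainerOptions,
    chi_square,
    chi_square_gradient,
    effective_sample_ratio,
    fit,
    init_noninteracting,
    product_model_observables,
    reweight,
)


def single_node():
    return NetworkTopology(n_nodes=1, edges=np.empty((0, 2), dtype=np.int64))


def test_init_reproduces_marginals_one_node():
    topo = single_node()
    lay = ObservableLayout(3, 0, ())
    s = np.array([0.7, 0.2, 0.1])
    theta = init_noninteracting(np.array(s), 1, ObservableLayout(3, 1))
    p = pn.PottsParameters(h=theta[:3], J=[lay.tri_to_matrix(np.zeros(6))],
                           class_names=("spatial",))
    # enumeration oracle on the single node (no edges -> field-only weights)
    w = np.exp(-p.h)
    assert np.allclose(w / w.sum(), s)


def test_init_reproduces_marginals_many_nodes():
    """On N nodes the independent-node model implied by the init fields has
    node marginals equal to the target densities (density energy scale)."""
    topo = pn.build_lattice([4], periodic=False)
    lay = layout_for(topo, 2)
    s = np.array([0.3, 0.7])
    theta = init_noninteracting(np.concatenate([s, np.zeros(3)]), 4, lay)
    sol = pn.enumerate_exact(pn.PottsParameters.from_flat(theta, lay), topo)
    assert np.allclose(sol.observables.s, s, atol=1e-12)


def test_init_rejects_zero_density():
    lay = ObservableLayout(2, 1)
    with pytest.raises(ValueError):
        init_noninteracting(np.array([1.0, 0.0, 1.0, 0.0, 0.0]), 3, lay)


def test_product_model_observables_exact():
    topo = pn.build_lattice([4], periodic=False)
    lay = layout_for(topo, 2)
    s = np.array([0.25, 0.75])
    x = product_model_observables(s, lay)
    theta = init_noninteracting(np.concatenate([s, np.zeros(3)]), 4, lay)
    sol = pn.enumerate_exact(pn.PottsParameters.from_flat(theta, lay), topo)
    assert np.allclose(x, sol.observables.flat, atol=1e-12)


def test_reweight_identity_and_gauge(lattice_2x3, rng):
    X = rng.integers(0, 2, (40, 6))
    F = ensemble_features(X, lattice_2x3, 2)
    lay = layout_for(lattice_2x3, 2)
    theta = rng.normal(size=lay.size)
    rho = reweight(F, theta, theta)
    assert np.allclose(rho, 1 / 40)
    shifted = theta.copy()
    shifted[lay.s_slice()] += 3.3
    assert np.allclose(reweight(F, shifted, theta), 1 / 40)


def test_reweight_matches_fresh_sampling(lattice_2x3):
    """Reweighted observables after a small parameter change agree with a
    fresh Metropolis run at the new parameters."""
    p0 = pn.PottsParameters(h=np.array([0.5, -0.5]),
                            J=[np.array([[-2.0, 1.0], [1.0, -2.0]])])
    p1 = pn.PottsParameters(h=p0.h, J=[p0.J[0] + np.array([[0.5, -0.2], [-0.2, 0.3]])])
    ens = pn.metropolis_sample(p0, lattice_2x3,
                               SamplerOptions(n_kept=20000, burn_in=300, stride=3, seed=1))
    F = ensemble_features(ens.X, lattice_2x3, 2)
    rho = reweight(F, p1.flatten(), p0.flatten())
    x_rw = rho @ F
    sol = pn.enumerate_exact(p1, lattice_2x3)
    assert np.abs(x_rw - sol.observables.flat).max() < 0.02


@pytest.mark.parametrize("weights,expected", [
    (np.ones(10), 1.0),
    (np.array([1.0] + [0.0] * 9), 0.1),
    (np.array([2.0, 1.0, 1.0]), 16 / 18),
])
def test_effective_sample_ratio(weights, expected):
    assert np.isclose(effective_sample_ratio(weights), expected)


def test_effective_sample_ratio_rejects_zero():
    with pytest.raises(ValueError):
        effective_sample_ratio(np.zeros(3))


def test_chi_square_examples():
    proj = pn.build_gauge_projector(np.eye(3))
    t = np.array([0.3, 0.3, 0.4])
    chi2, dof = chi_square(t, t, proj)
    assert chi2 == 0.0 and dof == 3
    chi2, _ = chi_square(t, t - np.array([0.1, -0.1, 0.0]), proj)
    assert np.isclose(chi2, 0.02)


def test_chi_square_kernel_residual_vanishes(lattice_2x3, rng):
    X = rng.integers(0, 2, (200, 6))
    cov = pn.observable_covariance(pn.Ensemble(X, 2), lattice_2x3)
    proj = pn.build_gauge_projector(cov)
    t = ensemble_features(X, lattice_2x3, 2).mean(axis=0)
    kernel_dir = np.zeros(5)
    kernel_dir[:2] = 0.05  # the density sum-rule direction
    chi2, _ = chi_square(t, t + kernel_dir, proj)
    assert chi2 < 1e-16


def test_gradient_matches_finite_differences(lattice_2x3, rng):
    p0 = pn.PottsParameters(h=np.array([0.4, -0.4]),
                            J=[np.array([[-1.5, 0.5], [0.5, -1.0]])])
    ens = pn.metropolis_sample(p0, lattice_2x3,
                               SamplerOptions(n_kept=4000, burn_in=200, stride=2, seed=3))
    F = ensemble_features(ens.X, lattice_2x3, 2)
    cov_t = pn.observable_covariance(ens, lattice_2x3)
    proj = pn.build_gauge_projector(cov_t)
    target = F.mean(axis=0) + proj.project(rng.normal(scale=0.02, size=5))
    theta0 = p0.flatten()

    def chi2_at(theta):
        rho = reweight(F, theta, theta0)
        r = proj.project(target - rho @ F)
        return float(r @ proj.pseudo_inverse @ r)

    rho = reweight(F, theta0, theta0)
    C = weighted_covariance(F, rho)
    r = proj.project(target - rho @ F)
    g = chi_square_gradient(r, C, proj)
    for k in range(3):
        d = proj.project(np.eye(5)[k + 1])
        if np.linalg.norm(d) < 1e-12:
            continue
        eps = 1e-5
        fd = (chi2_at(theta0 + eps * d) - chi2_at(theta0 - eps * d)) / (2 * eps)
        assert np.isclose(g @ d, fd, rtol=1e-4, atol=1e-10)
    # gradient along a kernel direction vanishes
    kd = np.zeros(5)
    kd[:2] = 1.0
    assert abs(g @ kd) < 1e-10


def test_gradient_zero_at_solution(lattice_2x3, rng):
    X = rng.integers(0, 2, (100, 6))
    F = ensemble_features(X, lattice_2x3, 2)
    cov = pn.observable_covariance(pn.Ensemble(X, 2), lattice_2x3)
    proj = pn.build_gauge_projector(cov)
    rho = np.full(100, 0.01)
    C = weighted_covariance(F, rho)
    r = proj.project(F.mean(axis=0) - rho @ F)  # model == target
    g = chi_square_gradient(r, C, proj)
    assert np.allclose(g, 0, atol=1e-12)


def test_fit_noninteracting_target_trivial(lattice_2x3):
    """A target drawn from a field-only model converges immediately with
    vanishing gauge-projected couplings."""
    p0 = pn.PottsParameters(h=np.array([6 * np.log(2), 0.0]), J=[np.zeros((2, 2))])
    ens = generate_potts_ensemble(p0, lattice_2x3, 400, seed=5, method="exact")
    res = fit(ens, lattice_2x3, TrainerOptions(seed=1, n_kept=2000, burn_in=200, stride=3))
    st = res.state
    assert st.converged and st.chi2 / st.dof < 1
    lay = layout_for(lattice_2x3, 2)
    projected = st.projector.project(res.params.flatten())
    assert np.abs(projected[lay.c_slice(0)]).max() < 1.0


def test_fit_parameter_recovery(recovery_fit, lattice_2x3, true_params_2x3):
    ens, res = recovery_fit
    st = res.state
    assert st.converged
    assert st.chi2 / st.dof < 1
    # model observables reproduce the generator's within 3 stochastic SE
    exact_fit = pn.enumerate_exact(res.params, lattice_2x3)
    exact_true = pn.enumerate_exact(true_params_2x3, lattice_2x3)
    se = np.sqrt(np.diag(pn.observable_covariance(ens, lattice_2x3)) / ens.n_conf)
    diff = np.abs(exact_fit.observables.flat - exact_true.observables.flat)
    assert np.all(diff <= 3 * se + 1e-12)


def test_fit_monotone_chi2_between_refreshes(recovery_fit):
    _, res = recovery_fit
    prev = np.inf
    for entry in res.state.log:
        if entry["refreshed"]:
            prev = np.inf
        assert entry["chi2"] <= prev + 1e-9
        prev = entry["chi2"]


def test_fit_refresh_triggered_exactly_on_low_ess(recovery_fit):
    """Every logged refresh coincides with the effective-sample ratio having
    dropped below eta, and refreshes restore a usable ensemble."""
    _, res = recovery_fit
    # reconstruct: an iteration refreshes iff the pre-refresh ratio < 0.5;
    # the logged ess of a refreshed iteration is the post-refresh value
    n_low = sum(1 for e in res.state.log if e["refreshed"])
    assert n_low == res.state.n_refresh
    for e in res.state.log:
        if e["refreshed"]:
            assert e["ess"] > 0.5


def test_fit_reproducible_bit_for_bit(lattice_2x3, true_params_2x3):
    ens = generate_potts_ensemble(true_params_2x3, lattice_2x3, 200, seed=2,
                                  method="exact")
    opts = dict(seed=11, n_kept=1000, burn_in=100, stride=2, max_iter=50)
    r1 = fit(ens, lattice_2x3, TrainerOptions(**opts))
    r2 = fit(ens, lattice_2x3, TrainerOptions(**opts))
    assert np.array_equal(r1.params.flatten(), r2.params.flatten())


def test_fit_zero_density_state_excluded(lattice_2x3, rng):
    """A state absent from the training set never appears in samples drawn
    from the fitted model."""
    X = rng.integers(0, 2, (200, 6))  # states 0 and 1 only, alphabet of 3
    ens = pn.Ensemble(X, n_states=3)
    res = fit(ens, lattice_2x3, TrainerOptions(seed=4, n_kept=1000, burn_in=100, stride=2))
    assert res.state.active_states.tolist() == [0, 1]
    assert 2 in res.params.metadata["excluded_states"]
    sample = pn.metropolis_sample(res.params, lattice_2x3,
                                  SamplerOptions(n_kept=2000, burn_in=200, stride=2, seed=9))
    assert not np.any(sample.X == 2)
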