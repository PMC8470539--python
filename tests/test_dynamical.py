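import numpy as np
import pytest

import pottsnet as pn
from pottsnet.dynamical import (
    TimeSeries,
    dynamical_entropy,
    extend_topology,
    fit_dynamical,
    series_to_configuration,
)
from pottsnet.observables import ensemble_features, layout_for
from pottsnet.topology import NetworkTopology
from pottsnet.trainer import TrainerOptions


def isolated(n=1):
    return NetworkTopology(n_nodes=n, edges=np.empty((0, 2), dtype=np.int64))


def markov_series(T, p_flip, seed, n_states=2):
    rng = np.random.default_rng(seed)
    s = np.zeros((T, 1), dtype=np.int64)
    s[0, 0] = rng.integers(n_states)
    for t in range(1, T):
        s[t, 0] = s[t - 1, 0] ^ (rng.random() < p_flip)
    return TimeSeries(s, n_states)


def test_extend_isolated_node():
    tt = extend_topology(isolated(1), 3)
    assert tt.extended.n_nodes == 3
    assert tt.extended.n_links == 2
    assert tt.extended.class_names == ("temporal",)


def test_extend_link_count_formula():
    base = pn.build_lattice([3, 3], periodic=True)
    tt = extend_topology(base, 2)
    assert tt.extended.n_links == 2 * base.n_links + 1 * base.n_nodes
    for T in (2, 3, 5):
        tt = extend_topology(base, T)
        assert tt.extended.n_links == T * base.n_links + (T - 1) * base.n_nodes


def test_extend_slice_recovers_base():
    base = pn.build_lattice([2, 3], periodic=False)
    tt = extend_topology(base, 3)
    for t in range(3):
        assert tt.slice_edges(t) == set(map(tuple, base.edges.tolist()))


def test_extend_requires_two_steps():
    with pytest.raises(ValueError):
        extend_topology(isolated(1), 1)


def test_series_flattening_indexing():
    ser = TimeSeries(np.array([[0, 1, 2], [2, 1, 0]]), 3)
    flat = series_to_configuration(ser)
    # node (k, t) at t*N + k
    assert flat.tolist() == [0, 1, 2, 2, 1, 0]


def test_alternating_series_temporal_couples():
    ser = TimeSeries(np.array([[0], [1], [0], [1]]), 2)
    tt = extend_topology(isolated(1), 4)
    F = ensemble_features(series_to_configuration(ser)[None, :], tt.extended, 2)[0]
    lay = layout_for(tt.extended, 2)
    c = lay.tri_to_matrix(F[lay.c_slice(0)])
    assert c[0, 1] == 1.0 and c[0, 0] == 0.0 and c[1, 1] == 0.0


def test_spatial_observables_are_time_averages(rng):
    base = pn.build_lattice([2, 2], periodic=False)
    frames = rng.integers(0, 2, (5, 4))
    tt = extend_topology(base, 5)
    F = ensemble_features(frames.ravel()[None, :], tt.extended, 2)[0]
    lay = layout_for(tt.extended, 2)
    per_frame = np.mean([pn.pair_density(f, base, 2) for f in frames], axis=0)
    c_spatial = lay.tri_to_matrix(F[lay.c_slice(tt.spatial_class)])
    assert np.allclose(c_spatial, per_frame)


def test_iid_frames_give_zero_temporal_coupling(rng):
    series = [TimeSeries(rng.integers(0, 2, (8, 1)), 2) for _ in range(150)]
    res = fit_dynamical(series, isolated(1), 2,
                        TrainerOptions(seed=6, n_kept=2000, burn_in=200, stride=3))
    assert res.state.converged
    lay = res.params.layout()
    projected = res.state.projector.project(res.params.flatten())
    c_block = projected[lay.c_slice(res.temporal.temporal_class)]
    assert np.abs(c_block).max() < 1.0


def test_markov_chain_flip_probability_recovered():
    """Fitted temporal couple densities reproduce the empirical flip rate of
    a two-state Markov chain within 3 standard errors."""
    p_flip = 0.3
    series = [markov_series(10, p_flip, 1000 + i) for i in range(200)]
    res = fit_dynamical(series, isolated(1), 2,
                        TrainerOptions(seed=5, n_kept=3000, burn_in=200, stride=3))
    assert res.state.converged
    sol = pn.enumerate_exact(res.params, res.temporal.extended)
    c_t = sol.observables.c(res.temporal.temporal_class)
    model_flip = c_t[0, 1]
    # empirical flip density of the training set with its standard error
    flips = np.array([(s.states[1:] != s.states[:-1]).mean() for s in series])
    se = flips.std(ddof=1) / np.sqrt(len(flips))
    assert abs(model_flip - flips.mean()) < 3 * se
    # and the empirical flip rate itself brackets the true one
    assert abs(flips.mean() - p_flip) < 4 * se


def test_constant_series_is_deterministic_model():
    ser = TimeSeries(np.ones((12, 1), dtype=np.int64), 2)
    res = fit_dynamical(ser, isolated(1), 2, TrainerOptions(seed=1))
    rep = dynamical_entropy(res)
    assert rep.s_maxent == pytest.approx(0.0, abs=1e-9)
    assert 0 in res.params.metadata["excluded_states"]


def test_periodic_series_entropy_near_zero():
    ser = TimeSeries((np.arange(20) % 2)[:, None].astype(np.int64), 2)
    res = fit_dynamical(ser, isolated(1), 2,
                        TrainerOptions(seed=1, n_kept=1000, burn_in=200, stride=3))
    rep = dynamical_entropy(res)
    assert abs(rep.normalized["s_maxent"]) < 0.1


def test_iid_uniform_entropy_near_lnQ(rng):
    series = [TimeSeries(rng.integers(0, 2, (8, 1)), 2) for _ in range(200)]
    res = fit_dynamical(series, isolated(1), 2,
                        TrainerOptions(seed=2, n_kept=2000, burn_in=200, stride=3))
    rep = dynamical_entropy(res)
    assert abs(rep.normalized["s_maxent"] - 1.0) < 0.05


def test_markov_entropy_matches_extended_oracle():
    """Thermodynamic-integration entropy of the fitted sequence model agrees
    with exact enumeration on the extended chain within 1e-2 per node-step."""
    series = [markov_series(8, 0.25, 500 + i) for i in range(150)]
    res = fit_dynamical(series, isolated(1), 2,
                        TrainerOptions(seed=9, n_kept=3000, burn_in=200, stride=3))
    rep = dynamical_entropy(res)
    exact = pn.enumerate_exact(res.params, res.temporal.extended).entropy
    assert abs(rep.s_maxent - exact) / 8 < 1e-2


def test_dynamical_spatial_limit_matches_static(rng):
    """For i.i.d.-in-time frames from a static pair model, the dynamical
    fit's spatial couple densities agree with a static fit on the frame
    ensemble (the time-independent-observables limit)."""
    base = pn.build_lattice([2], periodic=False)
    gen = pn.PottsParameters(h=np.zeros(2), J=[np.array([[-3.0, 3.0], [3.0, -3.0]])])
    from pottsnet.simulators import generate_potts_ensemble
    frames = generate_potts_ensemble(gen, base, 600, seed=3, method="exact").X
    series = [TimeSeries(frames[4 * i:4 * i + 4], 2) for i in range(150)]
    tight = dict(n_kept=8000, burn_in=300, stride=3, chi2_threshold=0.25)
    res = fit_dynamical(series, base, 2, TrainerOptions(seed=4, **tight))
    from pottsnet.trainer import fit as static_fit
    stat = static_fit(pn.Ensemble(frames, 2), base,
                      TrainerOptions(seed=5, **tight))
    sol_dyn = pn.enumerate_exact(res.params, res.temporal.extended)
    c_dyn = sol_dyn.observables.c(res.temporal.spatial_class)
    sol_stat = pn.enumerate_exact(stat.params, base)
    c_stat = sol_stat.observables.c(0)
    assert np.abs(c_dyn - c_stat).max() < 0.03
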