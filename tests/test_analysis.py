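import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synprop.analysis import (DetectorConfig, PulseTrace, ResponseCurve,
                              build_map, detect_propagation, lock_ratio,
                              noise_level, propagation_frequency,
                              tangent_bifurcation)
from synprop.experiments import make_fixtures
from synprop.sim_engine import SpikeRecord


@pytest.fixture(scope="module")
def fixtures():
    return make_fixtures(0)


@pytest.fixture(scope="module")
def detector():
    return DetectorConfig(window=3.0, max_shift=10.0, chance_const=0.01,
                          snr_min=3.0, control_interval=400.0)


# --------------------------------------------------------------------------- #
# detector
# --------------------------------------------------------------------------- #

def test_silent_layers_after_initiation(fixtures, detector):
    tr = detect_propagation(fixtures["first_layer_only"], fixtures["layers"],
                            fixtures["t0"], detector,
                            fixtures["silent_control"],
                            control_duration=400.0)
    assert tr.max_successful_layer == 1


def test_perfect_chain_all_layers_successful(fixtures, detector):
    tr = detect_propagation(fixtures["perfect_chain"], fixtures["layers"],
                            fixtures["t0"], detector,
                            fixtures["silent_control"],
                            control_duration=400.0)
    assert tr.max_successful_layer == len(fixtures["layers"])
    for d in tr.layers:
        assert d.noise_level == 1       # silent control floor


def test_broken_chain_stops_at_failure(fixtures, detector):
    tr = detect_propagation(fixtures["broken_at_4"], fixtures["layers"],
                            fixtures["t0"], detector,
                            fixtures["silent_control"],
                            control_duration=400.0)
    assert tr.max_successful_layer == 3


def test_exact_spacing_synthetic_record(detector):
    # every layer fires w spikes at t0 + 5 ms * k; silent control
    w, L, t0 = 30, 6, 100.0
    layers = [np.arange(k * w, (k + 1) * w) for k in range(L)]
    ids = np.concatenate(layers)
    times = np.concatenate([np.full(w, t0 + 5.0 * k) for k in range(L)])
    rec = SpikeRecord(ids, times, L * w)
    silent = SpikeRecord(np.empty(0, np.int64), np.empty(0), L * w)
    tr = detect_propagation(rec, layers, t0, detector, silent,
                            control_duration=400.0)
    assert tr.max_successful_layer == L
    assert np.allclose(np.diff(tr.pulse_times()), 5.0)
    assert propagation_frequency(tr) == pytest.approx(200.0)


def test_noise_level_matches_poisson_quantile_oracle():
    # homogeneous Poisson control: empirical noise level vs the exact
    # Poisson tail quantile, brute-force enumerated
    rate, window, c, T = 2.0, 3.0, 0.01, 50000.0   # spikes per ms
    rng = np.random.default_rng(8)
    n = rng.poisson(rate * T)
    times = np.sort(rng.uniform(0, T, n))
    lam = noise_level(times, window, c, T)
    mu = rate * window
    # brute force: smallest k with P(N >= k) <= c
    k, tail = 0, 1.0
    while tail > c:
        k += 1
        tail = 1.0 - stats.poisson.cdf(k - 1, mu)
    assert abs(lam - k) <= 1


def test_noise_level_monotone_in_chance_const():
    rng = np.random.default_rng(9)
    times = np.sort(rng.uniform(0, 5000.0, 2000))
    lams = [noise_level(times, 3.0, c, 5000.0) for c in (0.1, 0.01, 0.001)]
    assert lams[0] <= lams[1] <= lams[2]    # stricter chance level -> larger


def test_adding_spikes_never_decreases_chi(fixtures, detector):
    rec = fixtures["perfect_chain"]
    tr1 = detect_propagation(rec, fixtures["layers"], fixtures["t0"],
                             detector, fixtures["silent_control"],
                             control_duration=400.0)
    # duplicate all spikes of layer 2
    members = fixtures["layers"][1]
    mask = np.isin(rec.neuron, members)
    rec2 = SpikeRecord(np.concatenate([rec.neuron, rec.neuron[mask]]),
                       np.concatenate([rec.time, rec.time[mask]]), rec.N)
    order = np.argsort(rec2.time)
    rec2 = SpikeRecord(rec2.neuron[order], rec2.time[order], rec.N)
    tr2 = detect_propagation(rec2, fixtures["layers"], fixtures["t0"],
                             detector, fixtures["silent_control"],
                             control_duration=400.0)
    assert tr2.layers[0].chi >= tr1.layers[0].chi


def test_detector_requires_control(fixtures, detector):
    with pytest.raises(ValueError):
        detect_propagation(fixtures["perfect_chain"], fixtures["layers"],
                           fixtures["t0"], detector, None)


def test_propagation_frequency_examples():
    def trace(times):
        t = PulseTrace(t0=times[0], layers=[], max_successful_layer=len(times))
        t.pulse_times = lambda: times
        return t
    assert propagation_frequency(trace([0, 5, 10, 15])) == pytest.approx(200.0)
    assert propagation_frequency(trace([0, 4, 10, 14])) == pytest.approx(1000 / (14 / 3))
    with pytest.raises(ValueError):
        propagation_frequency(trace([0, 5]))


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(chance_const=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(window=-1.0)


# --------------------------------------------------------------------------- #
# iterated map
# --------------------------------------------------------------------------- #

def test_zero_response_gives_zero_map():
    curve = ResponseCurve(np.linspace(0, 50, 11), np.zeros(11), 1000)
    m = build_map(curve, 50, 0.2, 1.0)
    assert np.allclose(m.values, 0.0)
    assert m.fixed_points == [(0.0, True)]


def test_toy_step_map_matches_bruteforce_roots():
    grid = np.linspace(0, 60, 601)
    curve = ResponseCurve.from_step(3.0, 1.0, grid)
    m = build_map(curve, 50, 0.2, 1.0)
    # exact map: G(xi) = 50 * P[Binom(xi, 0.2) >= 3] at integers
    xs = np.arange(51)
    exact = 50 * (1 - stats.binom.cdf(2, xs, 0.2))
    assert np.allclose(m.values, exact)
    # brute-force root scan on a 1e-3 grid
    fine = np.arange(0, 50.0001, 1e-3)
    f = m.G(fine) - fine
    sign_changes = np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)
    brute = [0.0] + [fine[i] for i in sign_changes]
    found = [x for x, _ in m.fixed_points]
    assert len(found) == len(brute)
    assert np.allclose(found, brute, atol=2e-3)


def test_map_monte_carlo_oracle():
    # direct stochastic simulation of the layer-to-layer response
    grid = np.linspace(0, 60, 601)
    curve = ResponseCurve.from_step(3.0, 0.9, grid)
    w, p, eps = 50, 0.2, 1.0
    m = build_map(curve, w, p, eps)
    rng = np.random.default_rng(42)
    n_mc = 4000
    for xi in (5, 15, 40):
        k = rng.binomial(xi, p, size=(n_mc, w))
        spike = rng.random((n_mc, w)) < curve.interp(k * eps)
        est = spike.sum(axis=1).mean()
        se = spike.sum(axis=1).std() / math.sqrt(n_mc)
        assert abs(est - float(m.G(xi))) < 3 * max(se, 1e-3)


def test_fixed_point_count_is_one_or_three():
    grid = np.linspace(0, 60, 601)
    for eps in (0.2, 0.35, 0.5, 0.8, 1.2):
        curve = ResponseCurve.from_step(3.0, 1.0, grid)
        m = build_map(curve, 50, 0.2, eps)
        assert m.n_fixed_points in (1, 3)


def test_tangent_bifurcation_bisection_matches_dense_scan():
    grid = np.linspace(0, 60, 601)
    curve = ResponseCurve.from_step(3.0, 1.0, grid)
    w, p = 50, 0.2
    ec = tangent_bifurcation(curve, w, p, 0.2, 1.2, tol=1e-4)
    dense = np.arange(0.2, 1.2, 1e-3)
    counts = np.array([build_map(curve, w, p, e).n_fixed_points for e in dense])
    first3 = dense[np.argmax(counts >= 3)]
    assert abs(ec - first3) < 2e-3
    # below: iteration from w collapses; above: converges to upper point
    below = build_map(curve, w, p, ec - 0.05)
    above = build_map(curve, w, p, ec + 0.05)
    assert below.iterate(50.0, 60)[-1] < 1.0
    ups = [x for x, s in above.fixed_points if s and x > 1]
    mids = [x for x, s in above.fixed_points if not s]
    assert ups and mids
    assert above.iterate(mids[0] + 1.0, 60)[-1] == pytest.approx(ups[0], abs=0.1)


def test_build_map_coverage_error():
    curve = ResponseCurve(np.linspace(0, 3, 4), np.array([0, 0.2, 0.5, 0.7]),
                          1000)
    with pytest.raises(ValueError):
        build_map(curve, 50, 0.2, 1.0)    # unsaturated, under-covered


@given(st.floats(0.05, 0.95))
@settings(max_examples=20, deadline=None)
def test_map_bounds_property(frac):
    grid = np.linspace(0, 60, 121)
    curve = ResponseCurve.from_step(3.0, frac, grid)
    m = build_map(curve, 40, 0.2, 0.8)
    x = np.linspace(0, 40, 101)
    g = m.G(x)
    assert np.all(g >= -1e-9) and np.all(g <= 40 + 1e-9)


# --------------------------------------------------------------------------- #
# locking ratio
# --------------------------------------------------------------------------- #

def test_lock_ratio_identity_and_subharmonics():
    assert lock_ratio(200.0, 200.0) == (1, 1)
    assert lock_ratio(201.0, 100.0) == (2, 1)
    assert lock_ratio(99.0, 297.0) == (1, 3)
    assert lock_ratio(150.0, 100.0) == (3, 2)
    assert lock_ratio(137.0, 100.0) is None


# --------------------------------------------------------------------------- #
# measured response curves
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="module")
def measured_curves(params, balanced_bg):
    from synprop.analysis import estimate_response_curve
    theta = params.dendrite_threshold
    na = estimate_response_curve(
        np.array([0.0, 0.5, 0.8, 0.95, 1.05, 1.3, 2.0]) * theta,
        "non_additive", 200, balanced_bg, 6, params)
    add = estimate_response_curve(
        np.array([0.0, 30.0, 60.0, 90.0, 130.0, 180.0]),
        "additive", 200, balanced_bg, 7, params)
    return na, add


def test_response_curve_baseline_matches_ground_rate(measured_curves):
    na, _ = measured_curves
    assert na.probs[0] < 0.02      # nearly silent balanced ground state


def test_non_additive_response_jumps_at_threshold(measured_curves, params):
    na, _ = measured_curves
    theta = params.dendrite_threshold
    below = na.interp(0.95 * theta)
    above = na.interp(1.05 * theta)
    ci = na.ci_halfwidth().max()
    assert above - below > 5 * ci


def test_additive_response_monotone_within_ci(measured_curves):
    _, add = measured_curves
    ci = add.ci_halfwidth()
    for i in range(len(add.probs) - 1):
        assert add.probs[i + 1] >= add.probs[i] - (ci[i] + ci[i + 1])


def test_estimate_response_curve_requires_trials(params, balanced_bg):
    from synprop.analysis import estimate_response_curve
    with pytest.raises(ValueError):
        estimate_response_curve([0.0], "additive", 10, balanced_bg, 0, params)


# --------------------------------------------------------------------------- #
# inhibition and the dendritic window
# --------------------------------------------------------------------------- #

def test_inhibition_never_enters_dendritic_window(params):
    from synprop.sim_engine import SimulationConfig, run, single_neuron_network
    from synprop.stimuli import ExternalEvents
    theta = params.dendrite_threshold
    net = single_neuron_network(2)
    # neuron 0: subthreshold excitation + massive inhibition (must not trigger)
    # neuron 1: threshold excitation + massive inhibition (must still trigger)
    ev = ExternalEvents(
        neuron=np.array([0, 0, 1, 1]),
        time=np.array([20.0, 20.0, 20.0, 20.0]),
        sign=np.array([1, -1, 1, -1]),
        strength=np.array([0.9 * theta, 10 * theta, 1.05 * theta, 10 * theta]))
    cfg = SimulationConfig(dt=0.1, duration=60.0, mode="non_additive", seed=0)
    rec = run(net, cfg, params, external=ev,
              initial_V=np.full(2, params.E_L), trace_neurons=[0, 1])
    spikers = set(rec.neuron.tolist())
    assert 0 not in spikers
    assert 1 in spikers    # dendritic spike overcomes even strong inhibition


# --------------------------------------------------------------------------- #
# resonance-band width grows with the dendritic integration window
# --------------------------------------------------------------------------- #

def test_resonance_width_increases_with_dendritic_window(params):
    from synprop.analysis import propagation_trial
    from synprop.experiments import default_setup, standard_oscillation
    from synprop.params import StandardParams
    depths = {}
    for win, tref in [(2.0, 5.0), (4.0, 6.0)]:
        p = StandardParams(dendrite_window=win, dendrite_t_ref=tref)
        setup = default_setup(p, w=150, L=10, mode="non_additive")
        osc = standard_oscillation(p, 110, 135.0)   # below the narrow band
        depths[win] = np.median([
            propagation_trial(setup, 0.9, osc, s)[0].max_successful_layer
            for s in (5, 1005)])
    assert depths[2.0] <= 6          # outside the small-window band
    assert depths[4.0] == 10         # still inside the wide-window band
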