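"""MSN/FS rate functions, synapses, DBS waveform and the integrator."""

import numpy as np
import pytest
import scipy.sparse as sp

from striatonet.connectome import SpatialNetwork
from striatonet.dynamics import (
    DBSParams,
    DriveParams,
    ModelParams,
    SynapseParams,
    dbs_current,
    dbs_pulse,
    fs_steady_states,
    msn_rates,
    simulate,
    single_neuron_network,
    synaptic_current,
    synaptic_gate_rhs,
)
from striatonet.geometry import NeuronTable, generate_synthetic_striatum


# ------------------------------------------------------------ rate functions


def test_msn_rate_singularities_match_limits():
    """Removable singularities evaluate to their analytic limits and agree
    with nearby finite-difference evaluations."""
    a_m = msn_rates(-54.0)[0]
    assert a_m == pytest.approx(0.32 * 4)  # L'Hopital limit
    assert a_m == pytest.approx(msn_rates(-54.0 + 1e-6)[0], rel=1e-5)
    assert a_m == pytest.approx(msn_rates(-54.0 - 1e-6)[0], rel=1e-5)

    b_m = msn_rates(-27.0)[1]
    assert b_m == pytest.approx(0.28 * 5)
    assert b_m == pytest.approx(msn_rates(-27.0 + 1e-6)[1], rel=1e-5)

    a_n = msn_rates(-52.0)[4]
    assert a_n == pytest.approx(0.032 * 5)


def test_msn_h_gate_values():
    a_h = msn_rates(-50.0)[2]
    assert a_h == pytest.approx(0.128)  # exponent is 0 at -50
    b_h = msn_rates(-27.0)[3]
    assert b_h == pytest.approx(2.0)


def test_fs_steady_state_midpoints_and_bounds():
    m, h, n, mD, hD = fs_steady_states(-24.0)
    assert m == pytest.approx(0.5)
    assert fs_steady_states(-12.4)[2] == pytest.approx(0.5)
    assert fs_steady_states(-70.0)[4] == pytest.approx(0.5)
    assert fs_steady_states(-50.0)[3] == pytest.approx(0.5)
    V = np.linspace(-120, 60, 500)
    for x in fs_steady_states(V):
        assert ((x > 0) & (x < 1)).all()
        dx = np.diff(x)
        assert (dx > 0).all() or (dx < 0).all()  # monotone in V


# ----------------------------------------------------------------- synapses


def test_gate_fixed_point_and_decay():
    assert synaptic_gate_rhs(0.0, 0.0, 4.0, 1 / 13) == pytest.approx(4.0)  # H(0)=1
    # V_pre >> 0: fixed point s* = 2a/(2a + b)
    s_star = 8 / (8 + 1 / 13)
    assert synaptic_gate_rhs(s_star, 100.0, 4.0, 1 / 13) == pytest.approx(0.0, abs=1e-9)
    assert s_star == pytest.approx(0.9905, abs=1e-4)
    # long integration converges to the same point
    s, dt = 0.5, 0.01
    for _ in range(20000):
        s += dt * synaptic_gate_rhs(s, 100.0, 4.0, 1 / 13)
    assert s == pytest.approx(s_star, rel=1e-3)
    # V_pre << 0: pure exponential decay at rate beta
    s, beta = 0.5, 1 / 13
    for _ in range(1000):
        s += 0.01 * synaptic_gate_rhs(s, -100.0, 4.0, beta)
    assert s == pytest.approx(0.5 * np.exp(-beta * 10.0), rel=1e-3)


def _two_neuron_net(pre_type="MSN", post_type="MSN"):
    table = NeuronTable(
        pos=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
        nucleus=np.array(["caudate"] * 2, object),
        cell_type=np.array([post_type, pre_type], object),
    )
    A = sp.csr_matrix(np.array([[0, 1], [0, 0]]))  # neuron 1 -> neuron 0
    return SpatialNetwork(table=table, A=A)


def test_synaptic_current_direct_substitution():
    syn = SynapseParams(g_MM=0.1, E_GABA=-80.0)
    net = _two_neuron_net()
    # single presynaptic MSN, s=1: g_MM (V - E_GABA) = 0.1 (-70 + 80) = 1.0
    assert synaptic_current(0, -70.0, [0.0, 1.0], net, syn) == pytest.approx(1.0)
    # zero driving force at E_GABA
    assert synaptic_current(0, -80.0, [0.0, 1.0], net, syn) == 0.0
    # empty presynaptic set
    assert synaptic_current(1, -70.0, [1.0, 1.0], net, syn) == 0.0


def test_synaptic_current_uses_presynaptic_class_conductance():
    syn = SynapseParams(g_MM=0.1, g_FM=0.4, g_MF=0.2, g_FF=0.3)
    fs_to_msn = _two_neuron_net(pre_type="FS", post_type="MSN")
    assert synaptic_current(0, -70.0, [0, 1.0], fs_to_msn, syn) == pytest.approx(0.4 * 10)
    msn_to_fs = _two_neuron_net(pre_type="MSN", post_type="FS")
    assert synaptic_current(0, -70.0, [0, 1.0], msn_to_fs, syn) == pytest.approx(0.2 * 10)


# ---------------------------------------------------------------------- DBS


def test_dbs_pulse_window_and_duty_cycle():
    p = DBSParams(amplitude=1.0, frequency=100.0, delta=2.0)  # T = 10 ms
    t = np.linspace(0, 10, 10001, endpoint=False)
    on = dbs_pulse(t, p)
    # on-window is (T/2 - delta, T/2)
    assert on[(t > 3.001) & (t < 4.999)].all()
    assert not on[(t < 2.999) | (t > 5.001)].any()
    assert on.mean() == pytest.approx(p.delta / p.period, abs=1e-3)


def test_dbs_spatial_factor():
    p = DBSParams(x0=1.0, y0=2.0, z0=3.0, amplitude=10.0, frequency=100.0, delta=2.0, sigma=2.0)
    t_on = p.period / 2 - p.delta / 2
    assert dbs_current([1.0, 2.0, 3.0], t_on, p) == pytest.approx(10.0)  # centre, in-pulse
    at_sigma = dbs_current([3.0, 2.0, 3.0], t_on, p)
    assert at_sigma == pytest.approx(10.0 * np.exp(-1.0))
    assert dbs_current([1.0, 2.0, 3.0], 0.1, p) == 0.0  # outside pulse


def test_dbs_invalid_params_rejected():
    with pytest.raises(ValueError):
        DBSParams(amplitude=1.0, frequency=100.0, delta=11.0)  # delta >= T
    with pytest.raises(ValueError):
        DBSParams(amplitude=-1.0)
    with pytest.raises(ValueError):
        DBSParams(frequency=0.0)


# ----------------------------------------------------------------- simulate


def test_isolated_msn_rests_without_drive():
    net = single_neuron_network("MSN")
    res = simulate(net, ModelParams().with_drive(0.0), t_end=400.0, dt=0.05, seed=2)
    assert res.spike_counts().sum() == 0
    assert abs(res.mean_V[-1] - res.mean_V[-100]) < 0.05  # settled near rest


def test_isolated_msn_tonic_firing_stable_isi():
    net = single_neuron_network("MSN")
    res = simulate(net, ModelParams().with_drive(5.0), t_end=500.0, dt=0.05, seed=2)
    st = res.spikes[0]
    assert len(st) > 20
    isi = np.diff(st[st > 300.0])  # after the M-current adaptation transient
    assert isi.std() / isi.mean() < 0.02  # tonic: near-constant period


def test_spike_times_strictly_increasing_and_grid_uniform(small_net):
    res = simulate(small_net, ModelParams(), t_end=150.0, dt=0.05, seed=0)
    assert np.allclose(np.diff(res.t), 0.05)
    for st in res.spikes:
        if len(st) > 1:
            assert (np.diff(st) > 0).all()
            assert (np.diff(st) >= 1.0 - 1e-9).all()  # refractory lockout


def test_determinism_under_seed(small_net):
    a = simulate(small_net, ModelParams(), t_end=120.0, dt=0.05, seed=7)
    b = simulate(small_net, ModelParams(), t_end=120.0, dt=0.05, seed=7)
    assert np.array_equal(a.mean_V, b.mean_V)
    assert all(np.array_equal(x, y) for x, y in zip(a.spikes, b.spikes))


def test_uncoupled_network_equals_single_neurons(small_table):
    """With all synapses and DBS off, the network factorises: each neuron's
    trace matches its isolated single-neuron simulation."""
    import warnings

    from striatonet.connectome import build_network

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(small_table, k_msn=5, k_fs=10, seed=0)
    zero = SynapseParams(g_MM=0, g_FM=0, g_FF=0, g_MF=0)
    params = ModelParams(syn=zero)
    res = simulate(net, params, t_end=200.0, dt=0.05, seed=3, record=[0, 1])
    # rebuild identical initial conditions for the isolated pair
    rng = np.random.default_rng(3)
    V0 = rng.uniform(-80.0, -50.0, size=net.n)
    for j in (0, 1):
        single = single_neuron_network(str(net.table.cell_type[j]))
        iso = simulate(
            single, params, t_end=200.0, dt=0.05, seed=0, record=[0],
            v_init_range=(V0[j], V0[j]),
        )
        assert np.allclose(iso.V[0], res.V[list(res.record).index(j)], atol=1e-6)


def test_translation_invariance(small_table):
    """Shifting all positions and the electrode together changes nothing."""
    import warnings

    from striatonet.connectome import build_network
    from striatonet.geometry import NeuronTable

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(small_table, k_msn=5, k_fs=10, seed=1)
    shift = np.array([7.0, -3.0, 11.0])
    shifted_table = NeuronTable(
        pos=small_table.pos + shift,
        nucleus=small_table.nucleus.copy(),
        cell_type=small_table.cell_type.copy(),
    )
    net2 = SpatialNetwork(table=shifted_table, A=net.A.copy())
    c = small_table.pos.mean(axis=0)
    dbs1 = DBSParams(x0=c[0], y0=c[1], z0=c[2], amplitude=50.0, frequency=120.0)
    dbs2 = DBSParams(
        x0=c[0] + shift[0], y0=c[1] + shift[1], z0=c[2] + shift[2],
        amplitude=50.0, frequency=120.0,
    )
    r1 = simulate(net, ModelParams().with_drive(1.5), dbs=dbs1, t_end=150.0, dt=0.05, seed=5)
    r2 = simulate(net2, ModelParams().with_drive(1.5), dbs=dbs2, t_end=150.0, dt=0.05, seed=5)
    assert np.allclose(r1.mean_V, r2.mean_V)


def test_gating_variables_stay_in_unit_interval(small_net):
    res = simulate(
        small_net, ModelParams(), t_end=150.0, dt=0.05, seed=1, record=[0], record_s=True
    )
    assert res.s.min() >= 0.0 and res.s.max() <= 1.0


def test_healthy_vs_abnormal_rate_drop(small_net):
    healthy = simulate(small_net, ModelParams().with_drive(5.0), t_end=400.0, dt=0.05, seed=2)
    abnormal = simulate(small_net, ModelParams().with_drive(1.5), t_end=400.0, dt=0.05, seed=2)
    assert healthy.mean_rate() >= 4 * abnormal.mean_rate()


def test_noise_breaks_determinism_only_when_enabled(small_net):
    p = ModelParams(drive=DriveParams(I0=5.0, noise_amp=0.5))
    a = simulate(small_net, p, t_end=50.0, dt=0.05, seed=1)
    b = simulate(small_net, p, t_end=50.0, dt=0.05, seed=1)
    c = simulate(small_net, p, t_end=50.0, dt=0.05, seed=2)
    assert np.array_equal(a.mean_V, b.mean_V)
    assert not np.array_equal(a.mean_V, c.mean_V)
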