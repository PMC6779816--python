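"""Network engine: alpha kernels, delays, routing, determinism, sign sanity."""

import numpy as np
import pytest

import olivonet.scaffold as sc
from olivonet.engine import alpha_kernel, run_simulation, REVERSAL_POTENTIALS
from olivonet.neurons import EGLIFParams, LIFParams, EGLIF_DEFAULTS
from olivonet.protocol import StimulusPhase, StimulusProtocol
from olivonet import config as cfgmod


def _two_pop_net(weight=1.0, delay=4.0, tau=2.0, sign="exc", n_pre=1,
                 conv=1):
    """Minimal MF -> GoC network with one connection row."""
    counts = dict(MF=n_pre, GoC=1, GrC=2, MLI=2, PC=2, DCNp=2, DCNi=2, IO=2)
    row = sc.ConnectionSpec("MF-GoC", "MF", "GoC", conv, None, None, None,
                            weight, delay, 0.0, tau, sign)
    return sc.build_network(counts=counts, rows=[row], placement_seed=0,
                            connectivity_seed=0, clip_to_pool=True)


def _passive_goc(**over):
    base = dict(C_m=100.0, tau_m=20.0, E_L=-60.0, V_th=-40.0, V_r=-70.0,
                t_ref=1.0, I_e=0.0, k_adap=0.0, k_2=0.1, k_1=0.1,
                A_1=0.0, A_2=0.0, lambda_0=1.0, delta_V=1.0)
    base.update(over)
    return EGLIFParams(**base)


def _probe_conductance(net, spike_time, T=120.0, dt=1.0, sign="exc"):
    """Run with a forced single MF spike; return the GoC conductance trace
    reconstructed from two passive probe runs (V clamped via huge C)."""
    # Probe via the recorded membrane deflection of an almost-static cell:
    # simpler — rerun the engine internals directly.
    from olivonet.engine import _RowState

    rs = _RowState(net, 0, dt)
    n_steps = int(T / dt)
    g = np.zeros(n_steps)
    V = np.full(1, -60.0)
    for i in range(n_steps):
        G = np.zeros(1)
        I = np.zeros(1)
        rs.collect(i, G, I)
        g[i] = G[0]
        if i == int(spike_time / dt):
            rs.route(i, np.array([0]))
    return g


def test_alpha_kernel_closed_form():
    """Peak value w at t = tau; zero at t = 0; integral w tau e."""
    w, tau = 2.5, 3.0
    t = np.linspace(0, 200, 400001)
    k = alpha_kernel(t, w, tau)
    assert k[0] == 0.0
    assert np.max(k) == pytest.approx(w, rel=1e-6)
    assert t[np.argmax(k)] == pytest.approx(tau, abs=1e-3)
    integral = np.trapezoid(k, t)
    assert integral == pytest.approx(w * tau * np.e, rel=1e-3)


def test_engine_filter_tracks_alpha_kernel_exactly():
    """The per-step receptor filter samples the closed-form kernel at the
    grid points, including for sub-step time constants."""
    for tau, dt in ((2.0, 1.0), (0.23, 1.0), (5.8, 0.5)):
        net = _two_pop_net(weight=1.7, delay=4.0, tau=tau)
        g = _probe_conductance(net, spike_time=10.0, dt=dt)
        t = (np.arange(len(g))) * dt
        # delivery at emission step + delay
        t0 = 10.0 + 4.0
        expected = alpha_kernel(t - t0, 1.7, tau)
        assert np.allclose(g, expected, atol=1e-9), (tau, dt)


def test_superposition_two_identical_spikes():
    """Two simultaneous identical spikes double the conductance exactly."""
    from olivonet.engine import _RowState

    net = _two_pop_net(weight=0.8, delay=2.0, tau=1.5)
    rs1 = _RowState(net, 0, 1.0)
    rs2 = _RowState(net, 0, 1.0)
    g1 = np.zeros(40)
    g2 = np.zeros(40)
    for i in range(40):
        G = np.zeros(1); rs1.collect(i, G, np.zeros(1)); g1[i] = G[0]
        G = np.zeros(1); rs2.collect(i, G, np.zeros(1)); g2[i] = G[0]
        if i == 5:
            rs1.route(i, np.array([0]))
            rs2.route(i, np.array([0]))
            rs2.route(i, np.array([0]))
    assert np.allclose(g2, 2 * g1, atol=1e-12)


def test_kernel_long_horizon_integral():
    """Discrete-time filter integral matches w tau e within 0.1%."""
    net = _two_pop_net(weight=1.0, delay=1.0, tau=5.8)
    dt = 0.1
    g = _probe_conductance(net, spike_time=2.0, T=400.0, dt=dt)
    assert np.sum(g) * dt == pytest.approx(1.0 * 5.8 * np.e, rel=1e-3)


def test_silent_network_stays_silent():
    """No stimulus and zero intrinsic currents -> no spikes anywhere."""
    net = cfgmod.make_toy_network(0.02, seed=1)
    params = {p: _passive_goc() for p in
              ("GoC", "GrC", "MLI", "PC", "DCNp", "DCNi", "IO")}
    rec = run_simulation(net, params, T=200.0, dt=1.0, seed=0)
    assert sum(rec.counts().values()) == 0


def test_excitation_can_only_depolarize_and_inhibition_hyperpolarize():
    """Sign sanity: with V between the reversal potentials, an excitatory
    input raises V and an inhibitory input lowers it."""
    for sign, cmp in (("exc", np.greater), ("inh", np.less)):
        net = _two_pop_net(weight=5.0, delay=1.0, tau=2.0, sign=sign)
        goc = _passive_goc(V_th=10.0 if sign == "exc" else -40.0)
        # drive: one forced MF spike at t = 5 ms
        phases = [StimulusPhase(4.0, 6.0, "MF", np.array([0]), "burst", 500.0)]
        proto = StimulusProtocol(phases, duration=60.0)
        params = {"GoC": goc}
        # record V via probing the population object
        import olivonet.neurons as nr
        Vs = []
        orig = nr.EGLIFPopulation.step
        def patched(self, G, I):
            Vs.append(self.V[0]); return orig(self, G, I)
        nr.EGLIFPopulation.step = patched
        try:
            run_simulation(net, params, protocol=proto, T=60.0, seed=0)
        finally:
            nr.EGLIFPopulation.step = orig
        V = np.array(Vs)
        assert cmp(V[20], V[0]), sign
        if sign == "inh":
            assert V.min() > REVERSAL_POTENTIALS["inh"] - 1e-6


def test_causality_no_conductance_before_delay():
    net = _two_pop_net(weight=1.0, delay=6.0, tau=2.0)
    g = _probe_conductance(net, spike_time=10.0)
    assert np.all(g[: int(10 + 6)] == 0.0)
    assert g[int(10 + 6) + 1] > 0.0


def test_seed_determinism_and_variation(toy_net):
    params = {p: EGLIF_DEFAULTS[p] for p in
              ("GoC", "GrC", "MLI", "PC", "DCNp", "DCNi", "IO")}
    from olivonet.protocol import ebcc_protocol
    proto = ebcc_protocol(toy_net, baseline_end=200.0, cs_end=300.0, tail=100.0)
    a = run_simulation(toy_net, params, proto, dt=1.0, seed=5)
    b = run_simulation(toy_net, params, proto, dt=1.0, seed=5)
    c = run_simulation(toy_net, params, proto, dt=1.0, seed=6)
    for pop in a.spikes:
        assert np.array_equal(a.spikes[pop][0], b.spikes[pop][0])
        assert np.array_equal(a.spikes[pop][1], b.spikes[pop][1])
    assert any(not np.array_equal(a.spikes[p][1], c.spikes[p][1])
               for p in a.spikes)
    # rate summaries robust to the seed (population totals within 25%)
    ta = sum(len(v[1]) for v in a.spikes.values())
    tc = sum(len(v[1]) for v in c.spikes.values())
    assert abs(ta - tc) / max(ta, tc) < 0.25


def test_halving_dt_preserves_population_rates(toy_net):
    """PSTH at dt = 0.5 ms stays within the across-seed spread at dt = 1."""
    from olivonet.protocol import ebcc_protocol
    from olivonet.analysis import psth

    params = {p: EGLIF_DEFAULTS[p] for p in
              ("GoC", "GrC", "MLI", "PC", "DCNp", "DCNi", "IO")}
    proto = ebcc_protocol(toy_net, baseline_end=400.0, cs_end=500.0, tail=100.0)
    n_pc = toy_net.count("PC")

    def pc_psth(rec):
        return psth(rec.population_times("PC"), n_pc, (50.0, 600.0), 25.0)[1]

    base = [pc_psth(run_simulation(toy_net, params, proto, dt=1.0, seed=s))
            for s in (1, 2, 3, 4)]
    fine = pc_psth(run_simulation(toy_net, params, proto, dt=0.5, seed=1))
    spread = np.ptp(np.array(base), axis=0).mean() + 1e-9
    dev = np.abs(fine - np.mean(base, axis=0)).mean()
    assert dev <= spread * 1.5


def test_wiring_to_relay_population_rejected():
    """A connection row targeting a population with no membrane is an error."""
    counts = dict(MF=2, GoC=2, GrC=2, MLI=2, PC=2, DCNp=2, DCNi=2, IO=2)
    row = sc.ConnectionSpec("GoC-GrC", "GoC", "GrC", 1, None, None, None,
                            1.0, 2.0, 0.0, 1.0, "inh")
    net = sc.build_network(counts=counts, rows=[row], placement_seed=0,
                           connectivity_seed=0, clip_to_pool=True)
    with pytest.raises(RuntimeError, match="relay"):
        run_simulation(net, {"GoC": _passive_goc()}, T=10.0, seed=0)


def test_spike_record_round_trip(toy_net, tmp_path):
    params = {p: EGLIF_DEFAULTS[p] for p in
              ("GoC", "GrC", "MLI", "PC", "DCNp", "DCNi", "IO")}
    rec = run_simulation(toy_net, params, T=100.0, dt=1.0, seed=0)
    rec.to_csv(tmp_path / "spikes.csv")
    rec.to_hdf5(str(tmp_path / "spikes.h5"))
    import pandas as pd

    df = pd.read_csv(tmp_path / "spikes.csv")
    assert len(df) == sum(rec.counts().values())
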