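"""Clock-driven network simulator with alpha-conductance synapses.

Synaptic transmission uses alpha-shaped conductance kernels

    g(t) = w * (t / tau_alpha) * exp(1 - t / tau_alpha),   t >= 0,

peaking at the synaptic weight ``w`` (nS) at ``t = tau_alpha`` and with
total area ``w * tau_alpha * e``.  Reversal potentials are 0 mV for every
excitatory receptor and -80 mV for every inhibitory one, so the synaptic
current on a neuron is ``sum_r g_r(t) * (E_rev,r - V_m)``.

Exploiting the linearity of the kernel, one receptor state pair is kept
per (postsynaptic neuron, connection row) rather than per synapse: the
filter ``y1' = -y1/tau, y2' = -y2/tau + y1`` is advanced exactly each step
and every delivered spike adds an impulse ``w * e / tau`` to ``y1``, which
makes the summed conductance of any spike sequence exact at the grid
points, including for sub-step time constants.  Spike delivery is routed
through per-row ring buffers indexed by the (per-synapse, build-frozen)
delay rounded to the nearest step, minimum one step.

Gap-junction-coupled interneuron subnetworks (GoC-GoC, MLI-MLI) are
approximated as fast chemical synapses with 1 ms delay; climbing-fiber to
molecular-layer-interneuron spillover is carried by normally distributed
delays frozen in the synapse table at build time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .neurons import (EGLIFParams, LIFParams, EGLIFPopulation, LIFPopulation)
from .scaffold import NetworkModel

__all__ = ["SpikeRecord", "alpha_kernel", "run_simulation", "REVERSAL_POTENTIALS"]

REVERSAL_POTENTIALS = {"exc": 0.0, "inh": -80.0}   # mV


def alpha_kernel(t: np.ndarray, weight: float, tau_alpha: float) -> np.ndarray:
    """Closed-form alpha conductance (nS) at times ``t`` (ms) after a spike."""
    t = np.asarray(t, dtype=float)
    out = weight * (t / tau_alpha) * np.exp(1.0 - t / tau_alpha)
    return np.where(t >= 0, out, 0.0)


@dataclass
class SpikeRecord:
    """Per-population spike output of one simulation run."""

    spikes: dict[str, tuple[np.ndarray, np.ndarray]]   # pop -> (gids, times ms)
    T: float
    dt: float
    meta: dict = field(default_factory=dict)

    def train(self, pop: str, gid: int) -> np.ndarray:
        ids, times = self.spikes[pop]
        return times[ids == gid]

    def population_times(self, pop: str,
                         subset: Optional[np.ndarray] = None) -> np.ndarray:
        ids, times = self.spikes[pop]
        if subset is None:
            return np.sort(times)
        return np.sort(times[np.isin(ids, subset)])

    def counts(self) -> dict[str, int]:
        return {p: len(t) for p, (_, t) in self.spikes.items()}

    def to_dataframe(self):
        import pandas as pd

        frames = [
            {"neuron_id": ids, "time_ms": times, "population": pop}
            for pop, (ids, times) in self.spikes.items() if len(ids)
        ]
        if not frames:
            return pd.DataFrame(columns=["neuron_id", "time_ms", "population"])
        return pd.concat([pd.DataFrame(f) for f in frames], ignore_index=True)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["T"] = self.T
            f.attrs["dt"] = self.dt
            for pop, (ids, times) in self.spikes.items():
                g = f.create_group(pop)
                g.create_dataset("neuron_id", data=ids)
                g.create_dataset("time_ms", data=times)


class _RowState:
    """Receptor filter + delay ring buffer of one connection row."""

    __slots__ = ("pre_pop", "post_pop", "n_post", "indptr", "targets",
                 "weights", "delays", "D", "buf", "y1", "y2", "decay",
                 "impulse_scale", "E_rev", "dt_")

    def __init__(self, net: NetworkModel, row_idx: int, dt: float):
        row = net.rows[row_idx]
        self.pre_pop = row.pre_population
        self.post_pop = row.post
        a_pre, b_pre = net.pop_slices[self.pre_pop]
        a_post, b_post = net.pop_slices[self.post_pop]
        n_pre = b_pre - a_pre
        self.n_post = b_post - a_post

        m = np.flatnonzero(net.syn_row == row_idx)
        pre = net.syn_pre[m] - a_pre
        post = net.syn_post[m] - a_post
        w = net.syn_weight[m].astype(np.float64)
        delay_steps = np.maximum(np.rint(net.syn_delay[m] / dt), 1).astype(np.int64)

        order = np.argsort(pre, kind="stable")
        pre, post, w, delay_steps = pre[order], post[order], w[order], delay_steps[order]
        self.indptr = np.zeros(n_pre + 1, dtype=np.int64)
        np.add.at(self.indptr, pre + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.targets = post.astype(np.int64)
        self.weights = w
        self.delays = delay_steps
        self.D = int(delay_steps.max()) + 1 if delay_steps.size else 1
        self.buf = np.zeros(self.D * self.n_post)
        self.y1 = np.zeros(self.n_post)
        self.y2 = np.zeros(self.n_post)
        tau = row.tau_alpha
        self.decay = np.exp(-dt / tau)
        self.impulse_scale = np.e / tau
        self.E_rev = REVERSAL_POTENTIALS[row.sign]
        self.dt_ = dt

    def collect(self, step: int, G: np.ndarray, I_drive: np.ndarray) -> None:
        """Deliver due arrivals, add this row's conductance, advance the filter."""
        slot = step % self.D
        arrivals = self.buf[slot * self.n_post:(slot + 1) * self.n_post]
        np.multiply(arrivals, self.impulse_scale, out=arrivals)
        self.y1 += arrivals
        arrivals[:] = 0.0
        if not np.all(np.isfinite(self.y2)):
            raise FloatingPointError("non-finite synaptic conductance")
        G += self.y2
        if self.E_rev != 0.0:
            I_drive += self.y2 * self.E_rev
        # exact propagation of the critically damped (alpha) filter
        self.y2 = (self.y2 + self.y1 * self.dt_) * self.decay
        self.y1 *= self.decay

    def route(self, step: int, spiking_pre: np.ndarray) -> None:
        """Schedule deliveries from presynaptic neurons that spiked now."""
        counts = self.indptr[spiking_pre + 1] - self.indptr[spiking_pre]
        total = int(counts.sum())
        if total == 0:
            return
        offsets = np.repeat(self.indptr[spiking_pre], counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        e = offsets + within
        slots = (step + self.delays[e]) % self.D
        np.add.at(self.buf, slots * self.n_post + self.targets[e], self.weights[e])


def run_simulation(net: NetworkModel,
                   params: Mapping[str, EGLIFParams | LIFParams],
                   protocol=None,
                   T: Optional[float] = None,
                   dt: float = 1.0,
                   seed: int = 0,
                   v_init: Optional[Mapping[str, np.ndarray]] = None,
                   record: Optional[Sequence[str]] = None) -> SpikeRecord:
    """Simulate the network in lockstep ``dt`` and record all spikes.

    Parameters
    ----------
    net : NetworkModel
        Fully connected scaffold.
    params : mapping
        Per-population parameter set (EGLIF or LIF).  Populations absent
        from the mapping (the mossy fibers) are pure spike relays driven
        only by the stimulation protocol.
    protocol : StimulusProtocol, optional
        Timed external sources.  Poisson phases inject spikes into relay
        populations; burst phases force suprathreshold spiking of their
        target neurons (climbing-fiber volleys on IO cells).
    T : float, optional
        Simulated time (ms); defaults to the protocol duration.
    seed : int
        Single seed for all run-time randomness (escape noise, Poisson
        inputs); identical inputs and seed give identical records.
    v_init : mapping, optional
        Initial membrane potentials per population (e.g. from
        ``protocol.init_membrane_potentials``); defaults to ``E_L``.
    """
    if protocol is None and T is None:
        raise ValueError("either a protocol or an explicit duration T is required")
    T = float(T if T is not None else protocol.duration)
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9:
        raise ValueError("T must be a multiple of dt")

    master = np.random.default_rng(seed)
    pops: dict[str, object] = {}
    for pop, (a, b) in net.pop_slices.items():
        if pop not in params:
            continue
        p = params[pop]
        prng = np.random.default_rng(master.integers(2**31))
        if isinstance(p, EGLIFParams):
            pops[pop] = EGLIFPopulation(p, b - a, dt, prng)
        else:
            pops[pop] = LIFPopulation(p, b - a, dt, prng)
        if v_init is not None and pop in v_init:
            pops[pop].V[:] = np.asarray(v_init[pop], dtype=float)

    rows = [_RowState(net, i, dt) for i in range(len(net.rows))]
    rows_by_pre: dict[str, list[_RowState]] = {}
    for r in rows:
        rows_by_pre.setdefault(r.pre_pop, []).append(r)
    rows_by_post: dict[str, list[_RowState]] = {}
    for r in rows:
        rows_by_post.setdefault(r.post_pop, []).append(r)

    # compile external sources into per-step event lists
    forced: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if protocol is not None:
        forced = protocol.compile_events(
            dt, n_steps, np.random.default_rng(master.integers(2**31)))

    record = list(record) if record is not None else list(net.pop_slices)
    out_ids: dict[str, list[np.ndarray]] = {p: [] for p in record}
    out_t: dict[str, list[np.ndarray]] = {p: [] for p in record}
    for pop in (p for p in net.pop_slices if p not in params):
        if rows_by_post.get(pop):
            raise RuntimeError(f"connection row targets relay population {pop}")

    for i in range(n_steps):
        spikes_now: dict[str, np.ndarray] = {}
        # 1) synaptic conductances and neuron updates
        for pop, obj in pops.items():
            G = np.zeros(obj.n)
            I_drive = np.zeros(obj.n)
            for r in rows_by_post.get(pop, ()):
                r.collect(i, G, I_drive)
            spikes_now[pop] = obj.step(G, I_drive)
        # 2) external sources
        for pop, (indptr, ids) in forced.items():
            ev = ids[indptr[i]:indptr[i + 1]]
            if ev.size == 0:
                continue
            if pop in pops:
                pops[pop].force_spikes(np.unique(ev))
                spikes_now[pop] = np.unique(
                    np.concatenate([spikes_now.get(pop, np.empty(0, np.int64)),
                                    ev]))
            else:
                spikes_now[pop] = ev
        # 3) routing and recording
        t_spk = (i + 1) * dt
        for pop, sp in spikes_now.items():
            if sp.size == 0:
                continue
            for r in rows_by_pre.get(pop, ()):
                r.route(i, sp)
            if pop in out_ids:
                a, _ = net.pop_slices[pop]
                out_ids[pop].append(sp.astype(np.int64) + a)
                out_t[pop].append(np.full(sp.size, t_spk))

    spikes = {}
    for pop in record:
        if out_ids[pop]:
            spikes[pop] = (np.concatenate(out_ids[pop]),
                           np.concatenate(out_t[pop]))
        else:
            spikes[pop] = (np.empty(0, np.int64), np.empty(0, float))
    return SpikeRecord(spikes=spikes, T=T, dt=dt,
                       meta={"seed": seed, "dt": dt})
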