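"""Point-neuron models of the olivocerebellar populations.

Two model families share the same passive membrane:

* **EGLIF** (extended generalized leaky integrate-and-fire): the membrane
  potential is coupled to two spike-triggered currents — an adaptation
  current ``I_adap`` (hyperpolarizing, incremented by ``A_2`` per spike and
  driven by the voltage through ``k_adap``) and a fast depolarizing current
  ``I_dep`` (reset to ``A_1`` per spike, decaying at rate ``k_1``).  The
  three-variable subthreshold system is linear and is advanced by its exact
  matrix-exponential propagator, so integration is step-size invariant.
  Spikes are generated stochastically by an escape-noise rule whose rate
  grows exponentially with the distance of ``V_m`` from threshold; this is
  what produces physiological firing irregularity (CV of the inter-spike
  intervals) during pacemaking.

* **LIF**: plain leaky integrate-and-fire with deterministic threshold
  crossing, used as the simplified-dynamics control network.

Subthreshold dynamics (units: mV, pA, pF, ms, nS):

    dV/dt      = -(V - E_L)/tau_m + (I_e + I_syn + I_dep - I_adap)/C_m
    dI_adap/dt = k_adap (V - E_L) - k_2 I_adap
    dI_dep/dt  = -k_1 I_dep

On a spike: V <- V_r, I_dep <- A_1, I_adap <- I_adap + A_2, and the neuron
is refractory (V clamped at V_r) for ``t_ref``.

Escape rate: lambda(V) = lambda_0 * exp((V - V_th) / delta_V)  [1/ms], and
the per-step spike probability is 1 - exp(-lambda * dt).

The interplay of the two spike-triggered currents yields the non-linear
signatures the network study relies on: a strong excitatory volley drives a
burst sustained by ``I_dep``, the accumulated ``I_adap`` then silences the
cell (burst-pause); conversely, hyperpolarization drives ``I_adap``
negative through the ``k_adap`` coupling so that, on release, the cell
rebounds (pause-burst).  A LIF cell can do neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import expm

__all__ = [
    "EGLIFParams",
    "LIFParams",
    "NeuronState",
    "FiringStats",
    "EGLIF_DEFAULTS",
    "LIF_DEFAULTS",
    "subthreshold_propagator",
    "eglif_step",
    "lif_step",
    "EGLIFPopulation",
    "LIFPopulation",
    "simulate_single",
    "lif_rate_closed_form",
    "tune_intrinsic_current",
    "firing_stats",
    "params_to_csv",
    "params_from_csv",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EGLIFParams:
    """Electrophysiological parameter set of one EGLIF population.

    ``k_adap`` couples the adaptation current to the membrane potential
    (pA / (mV * ms)); ``k_2`` and ``k_1`` are the decay rates (1/ms) of the
    adaptation and depolarizing currents; ``A_1``/``A_2`` (pA) are the
    per-spike updates of ``I_dep``/``I_adap``.  ``lambda_0`` (1/ms) and
    ``delta_V`` (mV) parameterize the escape-noise spike generator.
    """

    C_m: float            # membrane capacitance, pF
    tau_m: float          # membrane time constant, ms
    E_L: float            # leak reversal, mV
    V_th: float           # spike threshold, mV
    V_r: float            # reset potential, mV
    t_ref: float          # absolute refractory period, ms
    I_e: float            # endogenous (pacemaker) current, pA
    k_adap: float         # V -> I_adap coupling, pA/(mV*ms)
    k_2: float            # I_adap decay rate, 1/ms
    k_1: float            # I_dep decay rate, 1/ms
    A_1: float            # I_dep reset per spike, pA
    A_2: float            # I_adap increment per spike, pA
    lambda_0: float = 1.0  # escape-rate baseline at threshold, 1/ms
    delta_V: float = 1.0   # escape-rate voltage sensitivity, mV

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.tau_m <= 0 or self.t_ref <= 0:
            raise ValueError("C_m, tau_m and t_ref must be strictly positive")
        if self.V_r > self.V_th:
            raise ValueError("V_r must not exceed V_th")
        if self.delta_V <= 0:
            raise ValueError("escape-noise sensitivity delta_V must be > 0")


@dataclass(frozen=True)
class LIFParams:
    """Passive parameters of a LIF population (matched to EGLIF passives)."""

    C_m: float
    tau_m: float
    E_L: float
    V_th: float
    V_r: float
    t_ref: float
    I_e: float

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.tau_m <= 0 or self.t_ref <= 0:
            raise ValueError("C_m, tau_m and t_ref must be strictly positive")
        if self.V_r > self.V_th:
            raise ValueError("V_r must not exceed V_th")


@dataclass
class NeuronState:
    """State of a single neuron (scalar convenience API)."""

    V_m: float
    I_adap: float = 0.0
    I_dep: float = 0.0
    refractory_remaining: float = 0.0
    last_spike: float = -np.inf


@dataclass(frozen=True)
class FiringStats:
    """Tonic rate and ISI irregularity of a spike train."""

    f_tonic: float               # Hz
    CV_ISI: Optional[float]      # None when fewer than 3 spikes
    n_spikes: int = 0


# ---------------------------------------------------------------------------
# default parameter tables
# ---------------------------------------------------------------------------
#
# Placeholder per-population sets produced by this package's own
# autorhythm-tuning routine (synthetic stand-ins for the original published
# supplementary optimization, which is not redistributed here).  Passive
# values are literature-typical for each cell type; the pacemaker current
# I_e and the escape-noise sensitivity were tuned with
# ``tune_intrinsic_current`` / isolated-cell simulation so that the
# in-vivo tonic-rate and CV_ISI targets are met (PC 85 Hz / 0.2,
# DCNp 65 Hz / 0.2; remaining populations at rates documented in
# docs/methods.md).  Granule cells are not spontaneously active (I_e = 0).

EGLIF_DEFAULTS: dict[str, EGLIFParams] = {
    "GrC": EGLIFParams(C_m=3.0, tau_m=24.0, E_L=-62.0, V_th=-41.0, V_r=-70.0,
                       t_ref=1.5, I_e=0.0, k_adap=0.022, k_2=0.04, k_1=0.3,
                       A_1=5.0, A_2=2.0, lambda_0=1.0, delta_V=0.5),
    "GoC": EGLIFParams(C_m=145.0, tau_m=44.0, E_L=-62.0, V_th=-55.0, V_r=-75.0,
                       t_ref=2.0, I_e=19.53, k_adap=0.05, k_2=0.05, k_1=0.2,
                       A_1=50.0, A_2=20.0, lambda_0=1.0, delta_V=1.0),
    "MLI": EGLIFParams(C_m=14.6, tau_m=9.1, E_L=-68.0, V_th=-53.0, V_r=-78.0,
                       t_ref=1.6, I_e=23.90, k_adap=0.02, k_2=0.1, k_1=0.3,
                       A_1=5.0, A_2=2.0, lambda_0=1.0, delta_V=0.5),
    "PC": EGLIFParams(C_m=334.0, tau_m=47.0, E_L=-59.0, V_th=-43.0, V_r=-69.0,
                      t_ref=1.0, I_e=1523.4, k_adap=1.0, k_2=0.06, k_1=0.5,
                      A_1=300.0, A_2=700.0, lambda_0=2.0, delta_V=3.5),
    "DCNp": EGLIFParams(C_m=142.0, tau_m=33.0, E_L=-45.0, V_th=-36.0, V_r=-55.0,
                        t_ref=1.5, I_e=175.3, k_adap=1.0, k_2=0.03, k_1=0.25,
                        A_1=400.0, A_2=80.0, lambda_0=2.0, delta_V=1.8),
    "DCNi": EGLIFParams(C_m=56.0, tau_m=30.0, E_L=-60.0, V_th=-48.0, V_r=-70.0,
                        t_ref=3.0, I_e=36.99, k_adap=0.05, k_2=0.1, k_1=0.2,
                        A_1=10.0, A_2=10.0, lambda_0=1.0, delta_V=1.0),
    "IO": EGLIFParams(C_m=189.0, tau_m=40.0, E_L=-45.0, V_th=-35.0, V_r=-50.0,
                      t_ref=1.0, I_e=-1.95, k_adap=0.5, k_2=0.1, k_1=0.2,
                      A_1=100.0, A_2=100.0, lambda_0=1.2, delta_V=1.5),
}

#: pacemaker currents of the LIF control sets, matched to the EGLIF tonic
#: rates by inverting the closed-form constant-drive LIF rate (granule
#: cells are not spontaneously active).
_LIF_I_E = {"GrC": 0.0, "GoC": 31.033, "MLI": 24.097, "PC": 831.553,
            "DCNp": 195.022, "DCNi": 39.281, "IO": 47.25}

#: LIF control sets: passive fields equal the EGLIF ones per population;
#: only I_e differs (re-tuned so the deterministic model reaches the same
#: tonic rate as its stochastic EGLIF counterpart).
LIF_DEFAULTS: dict[str, LIFParams] = {
    name: LIFParams(C_m=p.C_m, tau_m=p.tau_m, E_L=p.E_L, V_th=p.V_th,
                    V_r=p.V_r, t_ref=p.t_ref, I_e=_LIF_I_E[name])
    for name, p in EGLIF_DEFAULTS.items()
}


# ---------------------------------------------------------------------------
# exact subthreshold propagator
# ---------------------------------------------------------------------------

def _system_matrix(p: EGLIFParams) -> np.ndarray:
    return np.array([
        [-1.0 / p.tau_m, -1.0 / p.C_m, 1.0 / p.C_m],
        [p.k_adap, -p.k_2, 0.0],
        [0.0, 0.0, -p.k_1],
    ])


def subthreshold_propagator(p: EGLIFParams, dt: float):
    """Exact one-step propagator of the linear (V, I_adap, I_dep) system.

    Returns ``(M, phi)`` with ``M = exp(A dt)`` and
    ``phi = integral_0^dt exp(A s) ds`` so that for a constant forcing
    vector ``b`` over the step, ``x(t+dt) = M x(t) + phi b``.  ``phi`` is
    obtained from the block matrix exponential, which is well defined even
    when ``A`` is singular.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = _system_matrix(p)
    blk = np.zeros((6, 6))
    blk[:3, :3] = A
    blk[:3, 3:] = np.eye(3)
    E = expm(blk * dt)
    return E[:3, :3], E[:3, 3:]


def _forcing(p: EGLIFParams, I_syn: float | np.ndarray) -> tuple:
    """Constant part and synaptic direction of the forcing vector."""
    b0 = np.array([p.E_L / p.tau_m + p.I_e / p.C_m, -p.k_adap * p.E_L, 0.0])
    e_syn = np.array([1.0 / p.C_m, 0.0, 0.0])
    return b0, e_syn


def escape_probability(V: np.ndarray, p: EGLIFParams, dt: float) -> np.ndarray:
    """Per-step spike probability of the escape-noise generator."""
    # clip the exponent to avoid overflow at strongly suprathreshold V
    expo = np.clip((V - p.V_th) / p.delta_V, -60.0, 30.0)
    lam = p.lambda_0 * np.exp(expo)
    return -np.expm1(-lam * dt)


# ---------------------------------------------------------------------------
# scalar step API
# ---------------------------------------------------------------------------

def eglif_step(state: NeuronState, params: EGLIFParams, I_syn: float,
               dt: float, rng: np.random.Generator, *, t_now: float = 0.0,
               allow_spike: bool = True) -> tuple[NeuronState, bool]:
    """Advance one EGLIF neuron by ``dt`` under constant synaptic current.

    Subthreshold propagation is exact; a spike is drawn from the escape
    rate evaluated at the start-of-step membrane potential.  During the
    refractory period the membrane is clamped at ``V_r`` and no spike can
    be emitted, while the spike-triggered currents keep evolving.
    """
    x = np.array([state.V_m, state.I_adap, state.I_dep])
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite neuron state")
    M, phi = subthreshold_propagator(params, dt)
    b0, e_syn = _forcing(params, I_syn)
    x = M @ x + phi @ (b0 + I_syn * e_syn)

    refr = max(state.refractory_remaining - dt, 0.0)
    if state.refractory_remaining > 0:
        x[0] = params.V_r
    spiked = False
    if allow_spike and refr <= 0 and state.refractory_remaining <= 0:
        p_spike = float(escape_probability(np.asarray(x[0]), params, dt))
        if rng.random() < p_spike:
            spiked = True
            x[0] = params.V_r
            x[1] += params.A_2
            x[2] = params.A_1
            refr = params.t_ref
    new = NeuronState(V_m=float(x[0]), I_adap=float(x[1]), I_dep=float(x[2]),
                      refractory_remaining=refr,
                      last_spike=t_now + dt if spiked else state.last_spike)
    return new, spiked


def lif_step(state: NeuronState, params: LIFParams, I_syn: float,
             dt: float, *, t_now: float = 0.0) -> tuple[NeuronState, bool]:
    """Advance one LIF neuron by ``dt`` (exact exponential relaxation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(state.V_m):
        raise FloatingPointError("non-finite membrane potential")
    V_inf = params.E_L + (params.I_e + I_syn) * params.tau_m / params.C_m
    V = V_inf + (state.V_m - V_inf) * np.exp(-dt / params.tau_m)
    refr = max(state.refractory_remaining - dt, 0.0)
    spiked = False
    if state.refractory_remaining > 0:
        V = params.V_r
    elif V >= params.V_th:
        spiked = True
        V = params.V_r
        refr = params.t_ref
    new = NeuronState(V_m=float(V), refractory_remaining=refr,
                      last_spike=t_now + dt if spiked else state.last_spike)
    return new, spiked


# ---------------------------------------------------------------------------
# vectorized populations (used by the network engine)
# ---------------------------------------------------------------------------

class EGLIFPopulation:
    """Array-of-neurons EGLIF integrator with a shared parameter set.

    Synaptic input enters as a total conductance ``G`` (nS) plus the
    conductance-weighted reversal drive ``I_drive = sum_r g_r E_rev,r``
    (pA), both frozen over the step.  The membrane is advanced by the
    exact exponential solution with the conductance folded into the
    effective leak rate (unconditionally stable for arbitrarily large
    conductances on small cells), while the spike-triggered currents use
    their exact decays with the start-of-step membrane potential in the
    adaptation coupling (exponential splitting, O(dt^2) cross terms).
    """

    def __init__(self, params: EGLIFParams, n: int, dt: float,
                 rng: np.random.Generator):
        self.p = params
        self.n = n
        self.dt = dt
        self.rng = rng
        self.V = np.full(n, params.E_L)
        self.I_adap = np.zeros(n)
        self.I_dep = np.zeros(n)
        self.refr = np.zeros(n, dtype=np.int64)          # steps left
        self._refr_steps = max(int(round(params.t_ref / dt)), 1)
        p = params
        self._e2 = np.exp(-p.k_2 * dt)
        # int_0^dt e^{-k2 s} ds, stable also for k_2 -> 0
        self._i2 = -np.expm1(-p.k_2 * dt) / p.k_2 if p.k_2 > 0 else dt
        self._e1 = np.exp(-p.k_1 * dt)

    def step(self, G: np.ndarray, I_drive: np.ndarray) -> np.ndarray:
        """Advance all neurons one step; returns indices that spiked."""
        p, dt = self.p, self.dt
        V, Ia, Id = self.V, self.I_adap, self.I_dep
        a = 1.0 / p.tau_m + G / p.C_m                       # 1/ms
        b = (p.E_L / p.tau_m
             + (p.I_e + I_drive + Id - Ia) / p.C_m)         # mV/ms
        eA = np.exp(-a * dt)
        nV = V * eA + (b / a) * (1.0 - eA)
        nIa = Ia * self._e2 + p.k_adap * (V - p.E_L) * self._i2
        nId = Id * self._e1
        refractory = self.refr > 0
        nV[refractory] = self.p.V_r
        self.V, self.I_adap, self.I_dep = nV, nIa, nId
        if not np.all(np.isfinite(nV)):
            bad = int(np.flatnonzero(~np.isfinite(nV))[0])
            raise FloatingPointError(f"non-finite membrane potential, neuron {bad}")

        p_spike = escape_probability(nV, self.p, self.dt)
        draws = self.rng.random(self.n)
        spikes = np.flatnonzero((draws < p_spike) & ~refractory)
        self._apply_spikes(spikes)
        self.refr[refractory] -= 1
        return spikes

    def _apply_spikes(self, spikes: np.ndarray) -> None:
        self.V[spikes] = self.p.V_r
        self.I_adap[spikes] += self.p.A_2
        self.I_dep[spikes] = self.p.A_1
        self.refr[spikes] = self._refr_steps

    def force_spikes(self, idx: np.ndarray) -> np.ndarray:
        """Force the listed neurons to spike this step (stimulus injection)."""
        idx = np.asarray(idx, dtype=np.int64)
        self._apply_spikes(idx)
        return idx


class LIFPopulation:
    """Array-of-neurons LIF integrator (deterministic threshold).

    Takes the same frozen-conductance input as :class:`EGLIFPopulation`
    and uses the same conductance-aware exact exponential membrane update.
    """

    def __init__(self, params: LIFParams, n: int, dt: float,
                 rng: np.random.Generator | None = None):
        self.p = params
        self.n = n
        self.dt = dt
        self.V = np.full(n, params.E_L)
        self.refr = np.zeros(n, dtype=np.int64)
        self._refr_steps = max(int(round(params.t_ref / dt)), 1)

    def step(self, G: np.ndarray, I_drive: np.ndarray) -> np.ndarray:
        p = self.p
        a = 1.0 / p.tau_m + G / p.C_m
        b = p.E_L / p.tau_m + (p.I_e + I_drive) / p.C_m
        eA = np.exp(-a * self.dt)
        nV = self.V * eA + (b / a) * (1.0 - eA)
        refractory = self.refr > 0
        nV[refractory] = self.p.V_r
        self.V = nV
        if not np.all(np.isfinite(nV)):
            bad = int(np.flatnonzero(~np.isfinite(nV))[0])
            raise FloatingPointError(f"non-finite membrane potential, neuron {bad}")
        spikes = np.flatnonzero((nV >= self.p.V_th) & ~refractory)
        self._apply_spikes(spikes)
        self.refr[refractory] -= 1
        return spikes

    def _apply_spikes(self, spikes: np.ndarray) -> None:
        self.V[spikes] = self.p.V_r
        self.refr[spikes] = self._refr_steps

    def force_spikes(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.int64)
        self._apply_spikes(idx)
        return idx


# ---------------------------------------------------------------------------
# isolated-cell simulation, closed forms, tuning
# ---------------------------------------------------------------------------

def simulate_single(params: EGLIFParams | LIFParams, T: float, dt: float = 1.0,
                    seed: int = 0, I_syn: float = 0.0,
                    V0: float | None = None) -> np.ndarray:
    """Simulate one isolated neuron for ``T`` ms; returns spike times (ms)."""
    rng = np.random.default_rng(seed)
    if isinstance(params, EGLIFParams):
        pop: EGLIFPopulation | LIFPopulation = EGLIFPopulation(params, 1, dt, rng)
    else:
        pop = LIFPopulation(params, 1, dt)
    if V0 is not None:
        pop.V[:] = V0
    n_steps = int(round(T / dt))
    G = np.zeros(1)
    I = np.full(1, I_syn)
    times = []
    for i in range(n_steps):
        if pop.step(G, I).size:
            times.append((i + 1) * dt)
    return np.asarray(times)


def lif_rate_closed_form(params: LIFParams, I_e: float | None = None) -> float:
    """Steady firing rate (Hz) of a LIF neuron under constant drive.

    rate = 1 / (t_ref + tau_m * ln((V_inf - V_r) / (V_inf - V_th)))
    with V_inf = E_L + I_e tau_m / C_m; zero below rheobase.
    """
    I = params.I_e if I_e is None else I_e
    V_inf = params.E_L + I * params.tau_m / params.C_m
    if V_inf <= params.V_th:
        return 0.0
    isi = params.t_ref + params.tau_m * np.log(
        (V_inf - params.V_r) / (V_inf - params.V_th))
    return 1000.0 / isi


def _simulated_rate(params, I_e: float, T: float, dt: float, seed: int) -> float:
    p = replace(params, I_e=I_e)
    spikes = simulate_single(p, T, dt=dt, seed=seed)
    return len(spikes) / (T / 1000.0)


def tune_intrinsic_current(params: EGLIFParams | LIFParams, target_rate: float,
                           tolerance: float = 1.0, *, T: float = 10_000.0,
                           dt: float = 1.0, seed: int = 12345,
                           bounds: tuple[float, float] = (-2000.0, 20000.0),
                           max_iter: int = 60) -> float:
    """Find the pacemaker current giving the requested tonic rate.

    Monotone bisection on ``I_e`` against the simulated isolated-cell rate
    (same fixed seed at every evaluation so the objective is a deterministic
    monotone staircase).  Raises ``RuntimeError`` if the target is not
    bracketed by ``bounds``.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    lo, hi = bounds
    r_lo = _simulated_rate(params, lo, T, dt, seed)
    r_hi = _simulated_rate(params, hi, T, dt, seed)
    if not (r_lo <= target_rate <= r_hi):
        raise RuntimeError(
            f"target rate {target_rate} Hz not bracketed by I_e bounds "
            f"{bounds} (rates {r_lo:.1f}..{r_hi:.1f} Hz)")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = _simulated_rate(params, mid, T, dt, seed)
        if abs(r - target_rate) <= tolerance:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return mid


def params_to_csv(params: dict[str, EGLIFParams | LIFParams], path: str) -> None:
    """Write per-population parameter sets to a tabular CSV.

    One row per population; columns are the dataclass field names (a
    ``population`` column first, then e.g. ``C_m, tau_m, E_L, V_th, V_r,
    t_ref, I_e`` and, for EGLIF rows, the spike-triggered-current and
    escape-noise fields).
    """
    import dataclasses
    import pandas as pd

    rows = []
    for pop, p in params.items():
        d = {"population": pop, "model": type(p).__name__.replace("Params", "")}
        d.update(dataclasses.asdict(p))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def params_from_csv(path: str) -> dict[str, EGLIFParams | LIFParams]:
    """Load per-population parameter sets written by :func:`params_to_csv`."""
    import dataclasses
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, EGLIFParams | LIFParams] = {}
    for _, row in df.iterrows():
        cls = EGLIFParams if row["model"] == "EGLIF" else LIFParams
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: float(v) for k, v in row.items() if k in fields and pd.notna(v)}
        out[str(row["population"])] = cls(**kwargs)
    return out


def firing_stats(spike_times: np.ndarray, window: tuple[float, float]) -> FiringStats:
    """Tonic rate and CV of the inter-spike intervals inside a window."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    st = np.asarray(spike_times, dtype=float)
    if st.size and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    st = st[(st >= t0) & (st < t1)]
    f = st.size / ((t1 - t0) / 1000.0)
    if st.size < 3:
        return FiringStats(f_tonic=f, CV_ISI=None, n_spikes=int(st.size))
    isi = np.diff(st)
    cv = float(np.std(isi) / np.mean(isi))
    return FiringStats(f_tonic=f, CV_ISI=cv, n_spikes=int(st.size))
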