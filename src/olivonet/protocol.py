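"""Eyeblink-conditioning-like stimulation schedule and initial conditions.

The default single-trial protocol reproduces the pre-learning phase of
eyeblink classical conditioning (EBCC):

* 1 s of baseline: a 4 Hz Poisson process on every mossy fiber,
  emulating in-vivo background noise;
* the conditioned stimulus (LED light): a 40 Hz Poisson train, lasting
  260 ms, conveyed through a wide mossy-fiber bundle — a cylinder of
  150 um radius at the center of the transversal x-z plane, 150 um tall,
  spanning the whole granular layer — investing both microcomplexes;
* the unconditioned stimulus (air puff): a 10 ms, 500 Hz regular burst
  on the climbing fibers of microcomplex 1, injected as forced
  suprathreshold spiking of its inferior-olive neurons so that both the
  CF-PC and CF-MLI (and the IO-DCN collateral) pathways carry it; it
  co-terminates with the conditioned stimulus;
* a final 500 ms of silence to assess the return to rest.

Membrane potentials are initialized uniformly at random between each
population's resting and threshold potential to avoid artificial
synchronization, identically for the EGLIF and LIF networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .neurons import EGLIFParams, LIFParams
from .scaffold import NetworkModel

__all__ = [
    "StimulusPhase",
    "StimulusProtocol",
    "BundleSelection",
    "select_mf_bundle",
    "glomerulus_activation_fraction",
    "poisson_train",
    "burst_train",
    "init_membrane_potentials",
    "ebcc_protocol",
]


@dataclass(frozen=True)
class StimulusPhase:
    """One timed external source mapped onto a neuron subset."""

    t_start: float            # ms
    t_end: float              # ms, exclusive
    population: str
    targets: np.ndarray       # local indices within the population
    kind: str                 # "poisson" | "burst"
    rate: float               # Hz
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("phase must satisfy t_end > t_start")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.kind not in ("poisson", "burst"):
            raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass
class StimulusProtocol:
    """Timed set of external spike sources."""

    phases: list[StimulusPhase]
    duration: float           # ms

    def compile_events(self, dt: float, n_steps: int,
                       rng: np.random.Generator
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Realize all phases as per-step event lists.

        Returns, per source population, ``(indptr, ids)``: ``ids`` holds
        local neuron indices of all events sorted by step, and
        ``indptr[i]:indptr[i+1]`` slices the events of step ``i``.
        Poisson phases are independent per target neuron; burst phases are
        a synchronous regular volley shared by all targets.
        """
        per_pop_steps: dict[str, list[np.ndarray]] = {}
        per_pop_ids: dict[str, list[np.ndarray]] = {}
        for ph in self.phases:
            tgt = np.asarray(ph.targets, dtype=np.int64)
            if tgt.size == 0 or ph.rate == 0:
                continue
            if ph.kind == "poisson":
                lam = ph.rate * (ph.t_end - ph.t_start) / 1000.0
                counts = rng.poisson(lam, tgt.size)
                ids = np.repeat(tgt, counts)
                times = rng.uniform(ph.t_start, ph.t_end, ids.size)
            else:
                times_1 = burst_train(ph.rate, ph.t_start, ph.t_end,
                                      resolution=dt)
                times = np.tile(times_1, tgt.size)
                ids = np.repeat(tgt, times_1.size)
            steps = np.minimum((times / dt).astype(np.int64), n_steps - 1)
            keep = steps < n_steps
            per_pop_steps.setdefault(ph.population, []).append(steps[keep])
            per_pop_ids.setdefault(ph.population, []).append(ids[keep])

        out = {}
        for pop in per_pop_steps:
            steps = np.concatenate(per_pop_steps[pop])
            ids = np.concatenate(per_pop_ids[pop])
            order = np.argsort(steps, kind="stable")
            steps, ids = steps[order], ids[order]
            indptr = np.zeros(n_steps + 1, dtype=np.int64)
            np.add.at(indptr, steps + 1, 1)
            np.cumsum(indptr, out=indptr)
            out[pop] = (indptr, ids)
        return out

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "phases": [
                {"t_start": p.t_start, "t_end": p.t_end,
                 "population": p.population, "kind": p.kind, "rate": p.rate,
                 "label": p.label, "targets": np.asarray(p.targets).tolist()}
                for p in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        phases = [StimulusPhase(
            t_start=p["t_start"], t_end=p["t_end"], population=p["population"],
            targets=np.asarray(p["targets"], dtype=np.int64),
            kind=p["kind"], rate=p["rate"], label=p.get("label", ""))
            for p in d["phases"]]
        return cls(phases=phases, duration=d["duration"])


@dataclass(frozen=True)
class BundleSelection:
    """Mossy-fiber bundle inside the stimulation cylinder."""

    center: tuple[float, float]   # (x, z) um
    radius: float                 # um
    height: float                 # um
    ids: np.ndarray               # local MF indices
    fraction: float               # selected / total


def select_mf_bundle(net: NetworkModel,
                     center: tuple[float, float] = (200.0, 200.0),
                     radius: float = 150.0,
                     height: float = 150.0) -> BundleSelection:
    """Mossy fibers whose glomerulus lies inside the stimulus cylinder.

    The cylinder stands on the transversal plane at ``center`` and spans
    ``height`` um of depth from the top of the granular layer (the default
    covers the whole layer thickness).  An empty selection is allowed.
    """
    pos = net.pos("MF")
    y0 = net.volumes["granular"].origin[1]
    in_depth = (pos[:, 1] >= y0) & (pos[:, 1] <= y0 + height)
    r2 = (pos[:, 0] - center[0]) ** 2 + (pos[:, 2] - center[1]) ** 2
    ids = np.flatnonzero((r2 <= radius ** 2) & in_depth)
    frac = ids.size / max(len(pos), 1)
    return BundleSelection(center=center, radius=radius, height=height,
                           ids=ids, fraction=frac)


def glomerulus_activation_fraction(net: NetworkModel, bundle: BundleSelection,
                                   reach: float = 50.0) -> float:
    """Fraction of glomeruli receiving afferent input from the bundle.

    Each mossy-fiber rosette excites glomerular territory within ``reach``
    um of its stem, so a glomerulus is counted as activated when it lies
    within ``radius + reach`` of the bundle axis.  With the default
    geometry this yields roughly 80% of glomeruli.
    """
    pos = net.pos("MF")
    r2 = (pos[:, 0] - bundle.center[0]) ** 2 + (pos[:, 2] - bundle.center[1]) ** 2
    return float(np.mean(r2 <= (bundle.radius + reach) ** 2))


def poisson_train(rate: float, t0: float, t1: float,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) in ``[t0, t1)``."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = rng.poisson(rate * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, n))


def burst_train(rate: float, t0: float, t1: float,
                resolution: Optional[float] = None) -> np.ndarray:
    """Regular burst at ``rate`` Hz starting at ``t0``, last spike < t1."""
    if rate <= 0:
        raise ValueError("burst rate must be positive")
    interval = 1000.0 / rate
    if resolution is not None and interval < resolution:
        raise ValueError(
            f"burst interval {interval:.3f} ms below resolution {resolution} ms")
    return np.arange(t0, t1 - 1e-9, interval)


def init_membrane_potentials(net: NetworkModel,
                             params: Mapping[str, EGLIFParams | LIFParams],
                             seed: int) -> dict[str, np.ndarray]:
    """Uniform random V_m(0) in [E_L, V_th] per neuron, per population."""
    rng = np.random.default_rng(seed)
    out = {}
    for pop, p in params.items():
        if p.V_th < p.E_L:
            raise ValueError(f"{pop}: V_th below E_L")
        a, b = net.pop_slices[pop]
        out[pop] = rng.uniform(p.E_L, p.V_th, b - a)
    return out


def ebcc_protocol(net: NetworkModel, *,
                  baseline_rate: float = 4.0,
                  cs_rate: float = 40.0,
                  us_rate: float = 500.0,
                  baseline_end: float = 1000.0,
                  cs_end: float = 1260.0,
                  us_duration: float = 10.0,
                  tail: float = 500.0,
                  bundle: Optional[BundleSelection] = None,
                  us_microcomplex: int = 1) -> StimulusProtocol:
    """Build the default EBCC-like schedule on a reconstructed network.

    Baseline Poisson on all mossy fibers, conditioned-stimulus Poisson on
    the bundle, and an unconditioned-stimulus burst co-terminating with
    the conditioned stimulus on the inferior-olive cells of one
    microcomplex.
    """
    bundle = bundle if bundle is not None else select_mf_bundle(net)
    n_mf = net.count("MF")
    io_lab = net.labels("IO")
    io_targets = np.flatnonzero(io_lab == us_microcomplex)
    phases = [
        StimulusPhase(0.0, baseline_end, "MF", np.arange(n_mf), "poisson",
                      baseline_rate, label="baseline"),
        StimulusPhase(baseline_end, cs_end, "MF", bundle.ids, "poisson",
                      cs_rate, label="CS"),
        StimulusPhase(cs_end - us_duration, cs_end, "IO", io_targets, "burst",
                      us_rate, label="US"),
    ]
    return StimulusProtocol(phases=phases, duration=cs_end + tail)
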