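"""Run configuration, end-to-end orchestration and reduced test networks.

A :class:`RunConfig` carries everything a seeded end-to-end run needs:
population counts and layer volumes, the full connection table, the
neuron-model switch (EGLIF or LIF — changing it changes neuron dynamics
only, the synapse table is shared), the stimulation-protocol timings, the
analysis settings, and four independent seed streams (placement,
connectivity, simulation, initialization) so structural and dynamical
stochasticity can be varied separately — e.g. repeated simulations on one
fixed network instance.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import scaffold as sc
from . import protocol as proto
from . import analysis as ana
from .engine import run_simulation, SpikeRecord
from .neurons import EGLIF_DEFAULTS, LIF_DEFAULTS, EGLIFParams, LIFParams

__all__ = ["RunConfig", "default_config", "make_toy_network",
           "run_experiment", "paired_speed_experiment"]


@dataclass
class Seeds:
    placement: int = 0
    connectivity: int = 1
    simulation: int = 2
    initialization: int = 3


@dataclass
class ProtocolConfig:
    baseline_rate: float = 4.0
    cs_rate: float = 40.0
    us_rate: float = 500.0
    baseline_end: float = 1000.0
    cs_end: float = 1260.0
    us_duration: float = 10.0
    tail: float = 500.0
    bundle_center: tuple[float, float] = (200.0, 200.0)
    bundle_radius: float = 150.0
    bundle_height: float = 150.0
    us_microcomplex: int = 1

    @property
    def duration(self) -> float:
        return self.cs_end + self.tail

    @property
    def cf_onset(self) -> float:
        return self.cs_end - self.us_duration


@dataclass
class AnalysisConfig:
    psth_bin: float = 5.0
    sigma_pc: float = 5.0        # ms, PC instantaneous-rate kernel
    sigma_dcnp: float = 10.0     # ms, DCNp instantaneous-rate kernel
    speed_window: tuple[float, float] = (5.0, 105.0)
    decoder_update: float = 1.0
    decoder_tau: float = 10.0
    decoder_ma_window: int = 50
    decoder_mode: str = "sum"


@dataclass
class RunConfig:
    counts: dict = field(default_factory=lambda: dict(sc.DEFAULT_COUNTS))
    model: str = "EGLIF"                       # EGLIF | LIF
    dt: float = 1.0                            # ms, simulation resolution
    n_runs: int = 1
    seeds: Seeds = field(default_factory=Seeds)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    toy_scale: Optional[float] = None          # reduced network if set
    rows: list = field(default_factory=sc.default_connection_table)
    volumes: dict = field(default_factory=lambda: dict(sc.DEFAULT_VOLUMES))
    placement: sc.PlacementParams = field(default_factory=sc.PlacementParams)
    param_overrides: dict = field(default_factory=dict)   # pop -> field -> value

    def validate(self) -> None:
        if self.model not in ("EGLIF", "LIF"):
            raise sc.ConfigurationError("model must be EGLIF or LIF")
        if self.dt <= 0:
            raise sc.ConfigurationError("dt must be positive")
        names = [r.name for r in self.rows]
        if len(names) != len(set(names)):
            raise sc.ConfigurationError("duplicate connection rows")
        canonical = {r.name for r in sc.default_connection_table()}
        if set(names) != canonical and self.toy_scale is None:
            missing = canonical - set(names)
            if missing:
                raise sc.ConfigurationError(f"missing connection rows: {missing}")

    # -- neuron parameter sets -------------------------------------------
    def neuron_params(self, model: Optional[str] = None
                      ) -> dict[str, EGLIFParams | LIFParams]:
        model = model or self.model
        base = EGLIF_DEFAULTS if model == "EGLIF" else LIF_DEFAULTS
        out: dict[str, EGLIFParams | LIFParams] = {}
        for pop, p in base.items():
            over = self.param_overrides.get(pop, {})
            over = {k: v for k, v in over.items()
                    if k in {f.name for f in dataclasses.fields(p)}}
            out[pop] = replace(p, **over) if over else p
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "counts": dict(self.counts),
            "model": self.model,
            "dt": self.dt,
            "n_runs": self.n_runs,
            "toy_scale": self.toy_scale,
            "seeds": asdict(self.seeds),
            "protocol": asdict(self.protocol),
            "analysis": asdict(self.analysis),
            "param_overrides": self.param_overrides,
            "volumes": {k: {"origin": list(v.origin), "extent": list(v.extent)}
                        for k, v in self.volumes.items()},
            "placement": asdict(self.placement),
            "rows": [asdict(r) for r in self.rows],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            counts=dict(d.get("counts", sc.DEFAULT_COUNTS)),
            model=d.get("model", "EGLIF"),
            dt=d.get("dt", 1.0),
            n_runs=d.get("n_runs", 1),
            toy_scale=d.get("toy_scale"),
            seeds=Seeds(**d.get("seeds", {})),
            protocol=_protocol_from_dict(d.get("protocol", {})),
            analysis=_analysis_from_dict(d.get("analysis", {})),
            param_overrides=d.get("param_overrides", {}),
        )
        if "volumes" in d:
            cfg.volumes = {k: sc.VolumeSpec(k, tuple(v["origin"]), tuple(v["extent"]))
                           for k, v in d["volumes"].items()}
        if "placement" in d:
            cfg.placement = sc.PlacementParams(**d["placement"])
        if "rows" in d:
            cfg.rows = [_row_from_dict(r) for r in d["rows"]]
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _protocol_from_dict(d: dict) -> ProtocolConfig:
    d = dict(d)
    if "bundle_center" in d:
        d["bundle_center"] = tuple(d["bundle_center"])
    return ProtocolConfig(**d)


def _analysis_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    if "speed_window" in d:
        d["speed_window"] = tuple(d["speed_window"])
    return AnalysisConfig(**d)


def _row_from_dict(d: dict) -> sc.ConnectionSpec:
    d = dict(d)
    if d.get("reach") is not None:
        d["reach"] = tuple(d["reach"])
    if d.get("divergence_bounds") is not None:
        d["divergence_bounds"] = tuple(d["divergence_bounds"])
    if d.get("subtype_convergence") is not None:
        d["subtype_convergence"] = {k: tuple(v)
                                    for k, v in d["subtype_convergence"].items()}
    return sc.ConnectionSpec(**d)


def default_config() -> RunConfig:
    cfg = RunConfig()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# reduced networks and orchestration
# ---------------------------------------------------------------------------

def _scaled_counts(scale: float) -> dict[str, int]:
    if not 0 < scale <= 1:
        raise sc.ConfigurationError("scale must be in (0, 1]")
    counts = {}
    for pop, n in sc.DEFAULT_COUNTS.items():
        k = max(2, int(round(n * scale)))
        if pop in ("DCNp", "DCNi", "IO") and k % 2:
            k += 1                      # clustering needs even DCN/IO counts
        counts[pop] = min(k, n) if scale < 1 else n
    counts["DCNi"] = counts["DCNp"]     # one satellite per DCNp
    return counts


def make_toy_network(scale: float, seed: int = 0) -> sc.NetworkModel:
    """Proportionally reduced scaffold for fast tests.

    Counts are scaled (minimum 2 per population, even deep-nuclei/olive
    counts preserved for the two-cluster split) and exact convergences are
    clipped to the available candidate pools; all structural invariants of
    the full scaffold hold.
    """
    counts = _scaled_counts(scale)
    return sc.build_network(counts=counts, placement_seed=seed,
                            connectivity_seed=seed + 1,
                            clip_to_pool=(scale < 1))


def build_from_config(cfg: RunConfig) -> sc.NetworkModel:
    cfg.validate()
    if cfg.toy_scale is not None:
        counts = _scaled_counts(cfg.toy_scale)
        clip = cfg.toy_scale < 1
    else:
        counts, clip = cfg.counts, False
    return sc.build_network(counts=counts, volumes=cfg.volumes, rows=cfg.rows,
                            placement=cfg.placement,
                            placement_seed=cfg.seeds.placement,
                            connectivity_seed=cfg.seeds.connectivity,
                            clip_to_pool=clip)


def simulate_from_config(cfg: RunConfig, net: sc.NetworkModel,
                         run_index: int = 0,
                         model: Optional[str] = None) -> SpikeRecord:
    """One seeded simulation of the configured protocol on a built network."""
    model = model or cfg.model
    params = cfg.neuron_params(model)
    pc = cfg.protocol
    bundle = proto.select_mf_bundle(net, pc.bundle_center, pc.bundle_radius,
                                    pc.bundle_height)
    protocol = proto.ebcc_protocol(
        net, baseline_rate=pc.baseline_rate, cs_rate=pc.cs_rate,
        us_rate=pc.us_rate, baseline_end=pc.baseline_end, cs_end=pc.cs_end,
        us_duration=pc.us_duration, tail=pc.tail, bundle=bundle,
        us_microcomplex=pc.us_microcomplex)
    v0 = proto.init_membrane_potentials(
        net, params, cfg.seeds.initialization + 1000 * run_index)
    return run_simulation(net, params, protocol, dt=cfg.dt,
                          seed=cfg.seeds.simulation + 1000 * run_index,
                          v_init=v0)


def analyze_run(cfg: RunConfig, net: sc.NetworkModel, rec: SpikeRecord) -> dict:
    """Per-run readouts: PC/DCNp speeds in microcomplex 1 and the decoder."""
    ac, pc = cfg.analysis, cfg.protocol
    grid = (np.arange(int(round(rec.T / cfg.dt))) + 1) * cfg.dt
    out = {}
    for pop, sigma in (("PC", ac.sigma_pc), ("DCNp", ac.sigma_dcnp)):
        ids_mc1 = net.ids(pop)[net.labels(pop) == 1]
        out[f"{pop}_speeds"] = ana.population_speeds(
            rec.spikes[pop], ids_mc1, sigma, pc.cf_onset, grid,
            ac.speed_window)
        mean_tr = ana.instantaneous_rate(
            rec.population_times(pop, ids_mc1), sigma, grid)
        mean_tr.rate /= max(ids_mc1.size, 1)
        out[f"{pop}_popmean_speed"] = ana.response_speed(
            mean_tr, pc.cf_onset, ac.speed_window).speed
    dcnp_ids, dcnp_t = rec.spikes["DCNp"]
    lab = net.microcomplex[dcnp_ids] if dcnp_ids.size else np.empty(0, np.int8)
    spikes_per_mc = {mc: dcnp_t[lab == mc] for mc in (1, 2)}
    out["eyeblink"] = ana.decode_eyeblink(
        spikes_per_mc, cfg.dt, rec.T, update=ac.decoder_update,
        tau_decay=ac.decoder_tau, ma_window=ac.decoder_ma_window,
        mode=ac.decoder_mode,
        baseline_window=(pc.baseline_end - 500.0, pc.baseline_end))
    return out


def run_experiment(cfg: RunConfig, outdir: str | Path) -> dict:
    """Seeded end-to-end pipeline: build -> simulate -> analyze -> save.

    Writes the network container, the connectivity report, one spike CSV
    per population and per run, speed tables and the decoded eyeblink
    trace; returns a manifest with timings and artifact paths.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": asdict(cfg.seeds),
                      "model": cfg.model}
    t0 = time.perf_counter()
    net = build_from_config(cfg)
    manifest["stages"]["build_s"] = round(time.perf_counter() - t0, 3)
    net.to_hdf5(str(outdir / "network.h5"))
    report = sc.connectivity_report(net)
    report.to_csv(outdir / "connectivity_report.csv", index=False)
    manifest["n_neurons"] = net.n_neurons
    manifest["n_synapses"] = net.n_synapses

    speed_rows = []
    for k in range(cfg.n_runs):
        t0 = time.perf_counter()
        rec = simulate_from_config(cfg, net, run_index=k)
        manifest["stages"][f"simulate_run{k}_s"] = round(
            time.perf_counter() - t0, 3)
        rundir = outdir / f"run{k}"
        rundir.mkdir(exist_ok=True)
        for pop, (ids, times) in rec.spikes.items():
            import pandas as pd

            pd.DataFrame({"neuron_id": ids, "time_ms": times}).to_csv(
                rundir / f"{pop}_spikes.csv", index=False)
        res = analyze_run(cfg, net, rec)
        for pop in ("PC", "DCNp"):
            for s in res[f"{pop}_speeds"]:
                speed_rows.append({"run": k, "population": pop,
                                   "model": cfg.model, "speed_hz_per_ms": s})
        eb = res["eyeblink"]
        import pandas as pd

        pd.DataFrame({"time_ms": eb.time, "net": eb.net,
                      **{f"mc{m}": v for m, v in eb.per_microcomplex.items()}
                      }).to_csv(rundir / "eyeblink.csv", index=False)
        ana.plot_overview(net, rec, eb, str(rundir / "overview.png"))
    import pandas as pd

    pd.DataFrame(speed_rows).to_csv(outdir / "speeds.csv", index=False)
    with open(outdir / "provenance.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def paired_speed_experiment(cfg: RunConfig, n_runs: Optional[int] = None
                            ) -> dict:
    """Matched EGLIF vs LIF runs on one network instance.

    Returns per-model per-run PC and DCNp speed arrays (microcomplex 1)
    plus the two-sample t-tests across pooled per-neuron speeds.
    """
    n_runs = n_runs if n_runs is not None else cfg.n_runs
    net = build_from_config(cfg)
    out: dict = {"net": net, "PC": {}, "DCNp": {}}
    for model in ("EGLIF", "LIF"):
        pc_runs, dcnp_runs, popmean = [], [], {"PC": [], "DCNp": []}
        for k in range(n_runs):
            rec = simulate_from_config(cfg, net, run_index=k, model=model)
            res = analyze_run(cfg, net, rec)
            pc_runs.append(res["PC_speeds"])
            dcnp_runs.append(res["DCNp_speeds"])
            popmean["PC"].append(res["PC_popmean_speed"])
            popmean["DCNp"].append(res["DCNp_popmean_speed"])
        out["PC"][model] = np.asarray(pc_runs)
        out["DCNp"][model] = np.asarray(dcnp_runs)
        out[f"popmean_{model}"] = {p: np.asarray(v) for p, v in popmean.items()}
    for pop in ("PC", "DCNp"):
        t, df, p = ana.compare_speeds(out[pop]["EGLIF"].ravel(),
                                      out[pop]["LIF"].ravel())
        out[f"ttest_{pop}"] = {"t": t, "df": df, "p": p}
    return out
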