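"""Geometric scaffold of the two-microcomplex olivocerebellar network.

The reconstructed tissue block stacks, along the depth axis ``y``:

* the cerebellar cortex, 400 x 330 x 400 um^3 (molecular layer, Purkinje
  cell layer, granular layer);
* the underlying cerebellar nuclei, 200 x 600 x 200 um^3;
* an olivary volume of 100 x 200 x 40 um^3, sized to keep the cortical to
  olivary volume ratio at the murine ~66-68 : 1.

The transversal plane is ``x``-``z``; the cortex is split at the
parasagittal plane ``z = 200 um`` into two microzones of 200 um each.
Each microzone, together with the position-based halves of the deep-nuclei
and olivary populations, forms one *microcomplex*; connections tagged as
microcomplex-confined (the PC-DCN, IO-DCN, DCNi-IO and climbing-fiber
pathways) never cross the two labels, while parallel fibers and shared
mossy-fiber collaterals provide the physiological crosstalk.

Connectivity is generated from a connection table carrying, per pathway,
convergence/divergence statistics and the synaptic parameters (peak
conductance, delay, alpha time constant, sign).  Candidate presynaptic
partners are restricted by axis-aligned transversal reaches standing in
for axonal/dendritic spans, then sampled without replacement to the
convergence target (fixed, or Gaussian-drawn and clipped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VolumeSpec",
    "PopulationSpec",
    "PlacementParams",
    "ConnectionSpec",
    "NetworkModel",
    "ConfigurationError",
    "PlacementInfeasibleError",
    "InfeasibleConnectivityError",
    "DEFAULT_COUNTS",
    "DEFAULT_VOLUMES",
    "DEFAULT_SOMA_RADII",
    "IO_DENSITY",
    "Z_SPLIT",
    "default_connection_table",
    "place_population",
    "place_io_cells",
    "place_dcni",
    "assign_microcomplexes",
    "connect_populations",
    "connectivity_report",
    "build_network",
]


class ConfigurationError(ValueError):
    """Invalid or inconsistent scaffold configuration."""


class PlacementInfeasibleError(RuntimeError):
    """Soma placement could not satisfy its geometric constraints."""


class InfeasibleConnectivityError(RuntimeError):
    """A connection row cannot reach its convergence target."""


# ---------------------------------------------------------------------------
# volumes, populations, defaults
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """Axis-aligned layer volume (origin corner and extent, um)."""

    name: str
    origin: tuple[float, float, float]
    extent: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent):
            raise ConfigurationError(f"volume {self.name}: extents must be positive")

    @property
    def volume_um3(self) -> float:
        ex = self.extent
        return ex[0] * ex[1] * ex[2]

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * 1e-9

    def contains(self, pos: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pos = np.atleast_2d(pos)
        lo = np.asarray(self.origin) - tol
        hi = np.asarray(self.origin) + np.asarray(self.extent) + tol
        return np.all((pos >= lo) & (pos <= hi), axis=1)

    def clip(self, pos: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return np.clip(pos, lo, hi)


#: depth (y) layout: molecular | PC layer | granular | nuclei | olive.
#: The cortical thickness of 330 um is split into a 185 um molecular layer,
#: a 15 um Purkinje-cell monolayer and a 130 um granular layer; mossy-fiber
#: glomeruli live in the granular layer.
DEFAULT_VOLUMES: dict[str, VolumeSpec] = {
    "cortex": VolumeSpec("cortex", (0.0, 0.0, 0.0), (400.0, 330.0, 400.0)),
    "molecular": VolumeSpec("molecular", (0.0, 0.0, 0.0), (400.0, 185.0, 400.0)),
    "pc_layer": VolumeSpec("pc_layer", (0.0, 185.0, 0.0), (400.0, 15.0, 400.0)),
    "granular": VolumeSpec("granular", (0.0, 200.0, 0.0), (400.0, 130.0, 400.0)),
    "nuclei": VolumeSpec("nuclei", (100.0, 330.0, 100.0), (200.0, 600.0, 200.0)),
    "olive": VolumeSpec("olive", (150.0, 930.0, 180.0), (100.0, 200.0, 40.0)),
}

DEFAULT_COUNTS: dict[str, int] = {
    "MF": 7073, "GoC": 219, "GrC": 88164, "MLI": 1206,
    "PC": 69, "DCNp": 12, "DCNi": 12, "IO": 12,
}

#: soma radii (um) used for collision constraints; DCN/IO values are
#: working assumptions (not constrained elsewhere by the connectivity).
DEFAULT_SOMA_RADII: dict[str, float] = {"DCNp": 10.0, "DCNi": 5.0, "IO": 7.5}

IO_DENSITY = 15172.0       # cells / mm^3
Z_SPLIT = 200.0            # parasagittal microzone boundary, um

_LAYER_OF_POP = {
    "MF": "granular", "GrC": "granular", "GoC": "granular",
    "PC": "pc_layer", "MLI": "molecular",
    "DCNp": "nuclei", "DCNi": "nuclei", "IO": "olive",
}

POPULATIONS = ("MF", "GoC", "GrC", "MLI", "PC", "DCNp", "DCNi", "IO")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    count: int
    soma_radius: float = 0.0
    layer: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigurationError(f"population {self.name}: count must be >= 0")


@dataclass(frozen=True)
class PlacementParams:
    """Geometric parameters of the deterministic placement steps."""

    io_density: float = IO_DENSITY
    io_step: float = 10.0          # random-walk step length, um
    r_DCNp: float = DEFAULT_SOMA_RADII["DCNp"]
    r_DCNi: float = DEFAULT_SOMA_RADII["DCNi"]
    r_IO: float = DEFAULT_SOMA_RADII["IO"]
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# connection table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectionSpec:
    """One row of the connection table.

    ``pre``/``post`` name the pathway endpoints; fiber systems are mapped
    onto their parent population (``AA``/``PF`` -> GrC axon, ``CF`` -> IO
    axon).  Convergence is either exact (``convergence_sd`` is None) or
    Gaussian ``mean +- sd`` clipped at 1.  ``reach`` is the transversal
    candidate window ``(dx, dz)`` in um; ``None`` on an axis means
    unrestricted (e.g. parallel fibers run the full mediolateral extent).
    """

    name: str
    pre: str                    # pathway label (may be AA / PF / CF)
    post: str
    convergence_mean: float
    convergence_sd: Optional[float]      # None -> exact convergence
    divergence_mean: Optional[float]
    divergence_sd: Optional[float]
    weight: float               # peak conductance, nS
    delay_mean: float           # ms
    delay_sd: float             # ms (CF-MLI spillover only)
    tau_alpha: float            # ms
    sign: str                   # "exc" | "inh"
    microcomplex_confined: bool = False
    reach: tuple[Optional[float], Optional[float]] | None = None
    strategy: str = "per_target"   # per_target | per_target_unique |
                                   # cluster_all | deal_sources
    exclude_self: bool = False
    divergence_bounds: Optional[tuple[int, int]] = None   # CF-PC
    subtype_convergence: Optional[dict[str, tuple[float, float]]] = None
    subtype_delay: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.tau_alpha <= 0:
            raise ConfigurationError(f"{self.name}: weight and tau_alpha must be > 0")
        if self.sign not in ("exc", "inh"):
            raise ConfigurationError(f"{self.name}: sign must be 'exc' or 'inh'")
        if self.delay_mean < 1.0 and self.delay_sd == 0.0:
            raise ConfigurationError(
                f"{self.name}: fixed delay below the 1 ms simulation resolution")

    @property
    def pre_population(self) -> str:
        return {"AA": "GrC", "PF": "GrC", "CF": "IO"}.get(self.pre, self.pre)


_INHIBITORY = {"GoC-GrC", "GoC-GoC", "MLI-MLI", "MLI-PC",
               "PC-DCNp", "PC-DCNi", "DCNi-IO"}
_CONFINED = {"PC-DCNp", "PC-DCNi", "IO-DCNp", "IO-DCNi",
             "DCNi-IO", "CF-PC", "CF-MLI"}


def default_connection_table() -> list[ConnectionSpec]:
    """The 19-row olivocerebellar connection table with default reaches.

    Weights (nS), delays (ms) and alpha time constants (ms) follow the
    reference scaffold values; transversal reaches are this package's
    documented stand-ins for the precursor morphology-intersection rules
    (only the convergence/divergence statistics are enforced).
    """
    R = ConnectionSpec
    rows = [
        R("MF-GrC", "MF", "GrC", 4, None, 50, 22, 0.15, 4.0, 0.0, 5.8, "exc",
          reach=(60.0, 60.0)),
        R("MF-GoC", "MF", "GoC", 65, 27, 2, 1, 1.5, 4.0, 0.0, 0.23, "exc",
          reach=(150.0, 150.0)),
        R("GoC-GrC", "GoC", "GrC", 2, 1, 624, 267, 0.6, 2.0, 0.0, 13.6, "inh",
          reach=(150.0, 150.0)),
        R("GoC-GoC", "GoC", "GoC", 34, 8, 34, 9, 0.3, 1.0, 0.0, 10.0, "inh",
          reach=(150.0, 150.0), exclude_self=True),
        R("AA-GoC", "AA", "GoC", 360, 81, 1, None, 1.2, 2.0, 0.0, 0.5, "exc",
          reach=(50.0, 50.0), strategy="per_target_unique"),
        R("PF-GoC", "PF", "GoC", 1600, None, 4, 2, 0.05, 5.0, 0.0, 0.5, "exc",
          reach=(100.0, None)),
        R("MLI-MLI", "MLI", "MLI", 4, 2, 4, None, 0.2, 1.0, 0.0, 2.0, "inh",
          reach=(80.0, 80.0), exclude_self=True),
        R("PF-MLI", "PF", "MLI", 1012, 221, 12, 4, 0.015, 5.0, 0.0, 0.64, "exc",
          reach=(100.0, None),
          subtype_convergence={"BC": (1004, 221), "SC": (1021, 221)}),
        R("MLI-PC", "MLI", "PC", 20, None, 3, 1, 0.3, 4.0, 0.0, 2.8, "inh",
          reach=(100.0, 100.0), subtype_delay={"BC": 4.0, "SC": 5.0}),
        R("AA-PC", "AA", "PC", 249, 13, 1, None, 0.7, 2.0, 0.0, 1.1, "exc",
          reach=(30.0, 30.0), strategy="per_target_unique"),
        R("PF-PC", "PF", "PC", 28401, 776, 23, 3, 0.007, 5.0, 0.0, 1.1, "exc",
          reach=(150.0, None)),
        R("PC-DCNp", "PC", "DCNp", 26, 2, 5, 1, 0.4, 4.0, 0.0, 0.7, "inh",
          microcomplex_confined=True),
        R("PC-DCNi", "PC", "DCNi", 26, 4, 5, 1, 0.12, 4.0, 0.0, 1.14, "inh",
          microcomplex_confined=True),
        R("MF-DCNp", "MF", "DCNp", 147, None, 1, None, 0.05, 4.0, 0.0, 1.0, "exc",
          strategy="per_target_unique"),
        R("CF-PC", "CF", "PC", 1, None, 6, 1, 350.0, 4.0, 0.0, 0.4, "exc",
          microcomplex_confined=True, strategy="deal_sources",
          divergence_bounds=(4, 8)),
        R("CF-MLI", "CF", "MLI", 3, 1, 115, 23, 1.0, 70.0, 10.0, 1.2, "exc",
          microcomplex_confined=True),
        R("IO-DCNp", "IO", "DCNp", 6, None, 6, None, 0.1, 4.0, 0.0, 1.0, "exc",
          microcomplex_confined=True, strategy="cluster_all"),
        R("IO-DCNi", "IO", "DCNi", 6, None, 6, None, 0.2, 5.0, 0.0, 3.64, "exc",
          microcomplex_confined=True, strategy="cluster_all"),
        R("DCNi-IO", "DCNi", "IO", 6, None, 6, None, 3.0, 20.0, 0.0, 60.0, "inh",
          microcomplex_confined=True, strategy="cluster_all"),
    ]
    # internal consistency with the canonical sign / confinement sets
    for r in rows:
        assert (r.sign == "inh") == (r.name in _INHIBITORY), r.name
        assert r.microcomplex_confined == (r.name in _CONFINED), r.name
    return rows


# ---------------------------------------------------------------------------
# the network container
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Instantiated scaffold: soma positions, labels and the synapse table."""

    positions: np.ndarray                     # (N, 3) um
    pop_slices: dict[str, tuple[int, int]]    # name -> [start, stop)
    microcomplex: np.ndarray                  # (N,) int8, 0 = unassigned
    mli_subtype: np.ndarray                   # (N,) int8: 0 n/a, 1 BC, 2 SC
    dcni_parent: np.ndarray                   # global DCNp id per DCNi, or -1
    rows: list[ConnectionSpec] = field(default_factory=list)
    syn_pre: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    syn_post: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    syn_weight: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    syn_delay: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    syn_row: np.ndarray = field(default_factory=lambda: np.empty(0, np.int16))
    volumes: dict[str, VolumeSpec] = field(default_factory=lambda: dict(DEFAULT_VOLUMES))
    meta: dict = field(default_factory=dict)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_synapses(self) -> int:
        return int(self.syn_pre.size)

    def ids(self, pop: str) -> np.ndarray:
        a, b = self.pop_slices[pop]
        return np.arange(a, b, dtype=np.int64)

    def count(self, pop: str) -> int:
        a, b = self.pop_slices[pop]
        return b - a

    def pop_of(self, gid: int) -> str:
        for name, (a, b) in self.pop_slices.items():
            if a <= gid < b:
                return name
        raise KeyError(gid)

    def pos(self, pop: str) -> np.ndarray:
        a, b = self.pop_slices[pop]
        return self.positions[a:b]

    def labels(self, pop: str) -> np.ndarray:
        a, b = self.pop_slices[pop]
        return self.microcomplex[a:b]

    def row_synapses(self, row_name: str) -> np.ndarray:
        idx = next(i for i, r in enumerate(self.rows) if r.name == row_name)
        return np.flatnonzero(self.syn_row == idx)

    # -- serialization -----------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("populations")
            g.create_dataset("positions", data=self.positions)
            g.create_dataset("microcomplex", data=self.microcomplex)
            g.create_dataset("mli_subtype", data=self.mli_subtype)
            g.create_dataset("dcni_parent", data=self.dcni_parent)
            for name, (a, b) in self.pop_slices.items():
                g.attrs[f"slice_{name}"] = (a, b)
            s = f.create_group("synapses")
            s.create_dataset("pre", data=self.syn_pre)
            s.create_dataset("post", data=self.syn_post)
            s.create_dataset("weight", data=self.syn_weight)
            s.create_dataset("delay", data=self.syn_delay)
            s.create_dataset("row", data=self.syn_row)
            s.attrs["row_names"] = [r.name for r in self.rows]

    @classmethod
    def from_hdf5(cls, path: str, rows: Optional[list[ConnectionSpec]] = None
                  ) -> "NetworkModel":
        import h5py

        rows = rows if rows is not None else default_connection_table()
        with h5py.File(path, "r") as f:
            g = f["populations"]
            slices = {k[len("slice_"):]: tuple(int(x) for x in v)
                      for k, v in g.attrs.items() if k.startswith("slice_")}
            net = cls(
                positions=g["positions"][...],
                pop_slices=slices,
                microcomplex=g["microcomplex"][...],
                mli_subtype=g["mli_subtype"][...],
                dcni_parent=g["dcni_parent"][...],
                rows=rows,
                syn_pre=f["synapses/pre"][...],
                syn_post=f["synapses/post"][...],
                syn_weight=f["synapses/weight"][...],
                syn_delay=f["synapses/delay"][...],
                syn_row=f["synapses/row"][...],
            )
        return net


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_population(spec: PopulationSpec, volume: VolumeSpec,
                     seed: int) -> np.ndarray:
    """Uniform random soma positions of one population inside its layer."""
    if spec.count < 0:
        raise ConfigurationError("count must be >= 0")
    rng = np.random.default_rng(seed)
    lo = np.asarray(volume.origin)
    ex = np.asarray(volume.extent)
    return lo + rng.random((spec.count, 3)) * ex


def place_io_cells(volume: VolumeSpec, density: float, step: float,
                   seed: int, r_io: float = DEFAULT_SOMA_RADII["IO"],
                   max_attempts: int = 1000) -> np.ndarray:
    """Place inferior-olive somata by a self-avoiding bounded random walk.

    The walker starts at a uniform random point, takes fixed-length steps
    in isotropic random directions, reflecting at the volume boundaries,
    and deposits a soma whenever the current point keeps a distance of at
    least ``2 r_io`` from all deposited somata.  The number of cells is
    ``floor(density x volume)``.
    """
    if density <= 0:
        raise ConfigurationError("IO density must be positive")
    n = int(np.floor(density * volume.volume_mm3))
    rng = np.random.default_rng(seed)
    lo = np.asarray(volume.origin)
    hi = lo + np.asarray(volume.extent)
    pos = lo + rng.random(3) * (hi - lo)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if not placed or all(np.linalg.norm(pos - q) >= 2 * r_io for q in placed):
            placed.append(pos.copy())
            attempts = 0
            if len(placed) == n:
                break
        attempts += 1
        if attempts > max_attempts:
            raise PlacementInfeasibleError(
                f"could not place {n} IO somata with radius {r_io} um in "
                f"{volume.name} after {max_attempts} walk steps")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + step * direction
        # reflect at the boundaries (bounded walk)
        for ax in range(3):
            if pos[ax] < lo[ax]:
                pos[ax] = lo[ax] + (lo[ax] - pos[ax])
            if pos[ax] > hi[ax]:
                pos[ax] = hi[ax] - (pos[ax] - hi[ax])
        pos = np.clip(pos, lo, hi)
    return np.asarray(placed).reshape(n, 3)


def dcni_distance_bounds(dcnp_positions: np.ndarray, r_dcnp: float,
                         r_dcni: float) -> tuple[float, float]:
    """Satellite distance range: d1 = r_p + r_i, d2 = mean_dist/4 - r_p - r_i."""
    dcnp_positions = np.asarray(dcnp_positions, dtype=float)
    if dcnp_positions.shape[0] < 2:
        raise ConfigurationError("need >= 2 DCNp positions to define mean_dist")
    diff = dcnp_positions[:, None, :] - dcnp_positions[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(len(dcnp_positions), k=1)
    mean_dist = float(d[iu].mean())
    d1 = r_dcnp + r_dcni
    d2 = mean_dist / 4.0 - r_dcnp - r_dcni
    return d1, d2


def place_dcni(dcnp_positions: np.ndarray, r_dcnp: float, r_dcni: float,
               seed: int, volume: VolumeSpec | None = None,
               max_tries: int = 500) -> np.ndarray:
    """Place one satellite DCNi per DCNp at distance d in [d1, d2].

    Each DCNi sits at a uniform distance within the satellite range, in a
    uniform random direction, inside the nuclear volume, and is required
    to be closer to its parent DCNp than to any other DCNp (resampled
    until the satellite property holds).
    """
    dcnp_positions = np.asarray(dcnp_positions, dtype=float)
    d1, d2 = dcni_distance_bounds(dcnp_positions, r_dcnp, r_dcni)
    if d2 <= d1:
        raise ConfigurationError(
            f"satellite range violated: d1 = {d1:.2f} um must be < "
            f"d2 = {d2:.2f} um (= mean_dist/4 - r_DCNp - r_DCNi)")
    volume = volume or DEFAULT_VOLUMES["nuclei"]
    rng = np.random.default_rng(seed)
    out = np.empty_like(dcnp_positions)
    for i, parent in enumerate(dcnp_positions):
        others = np.delete(dcnp_positions, i, axis=0)
        for _ in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            d = rng.uniform(d1, d2)
            cand = volume.clip(parent + d * direction)
            dist_parent = np.linalg.norm(cand - parent)
            if dist_parent < np.linalg.norm(others - cand, axis=1).min():
                out[i] = cand
                break
        else:
            raise PlacementInfeasibleError(
                f"could not place a satellite DCNi for DCNp #{i}")
    return out


def assign_microcomplexes(net: NetworkModel, z_split: float = Z_SPLIT
                          ) -> NetworkModel:
    """Label every neuron with its microcomplex (1 or 2).

    Cortical neurons are labeled by the parasagittal slab their soma falls
    in (z < z_split -> 1).  DCNp and IO are split into two equal-size
    position-based clusters by z rank (ties broken by neuron index); each
    DCNi inherits the label of its parent DCNp.
    """
    lab = net.microcomplex
    for pop in ("MF", "GrC", "GoC", "MLI", "PC"):
        if pop not in net.pop_slices:
            continue
        a, b = net.pop_slices[pop]
        lab[a:b] = np.where(net.positions[a:b, 2] < z_split, 1, 2)
    for pop in ("DCNp", "IO"):
        if pop not in net.pop_slices:
            continue
        a, b = net.pop_slices[pop]
        n = b - a
        if n % 2:
            raise ConfigurationError(
                f"{pop}: count {n} is odd, cannot split into two equal clusters")
        order = np.argsort(net.positions[a:b, 2], kind="stable")
        lab[a:b][order[: n // 2]] = 1
        lab[a:b][order[n // 2:]] = 2
    if "DCNi" in net.pop_slices:
        a, b = net.pop_slices["DCNi"]
        for i in range(a, b):
            parent = net.dcni_parent[i - a]
            lab[i] = lab[parent] if parent >= 0 else 1
    return net


# ---------------------------------------------------------------------------
# connectivity sampling
# ---------------------------------------------------------------------------

def _candidate_pools(pre_pos: np.ndarray, post_pos: np.ndarray,
                     reach: tuple[Optional[float], Optional[float]] | None
                     ) -> list[np.ndarray] | None:
    """Per-target candidate index lists under the transversal reach window.

    Returns ``None`` when the reach is unrestricted (all pre are candidates).
    """
    if reach is None or (reach[0] is None and reach[1] is None):
        return None
    rx, rz = reach
    # scale axes so the window becomes a Chebyshev ball of radius 1;
    # an unrestricted axis is collapsed to zero.
    sx = 1.0 / rx if rx is not None else 0.0
    sz = 1.0 / rz if rz is not None else 0.0
    pre_t = np.column_stack([pre_pos[:, 0] * sx, pre_pos[:, 2] * sz])
    post_t = np.column_stack([post_pos[:, 0] * sx, post_pos[:, 2] * sz])
    tree = cKDTree(pre_t)
    pools = tree.query_ball_point(post_t, r=1.0, p=np.inf)
    return [np.asarray(p, dtype=np.int64) for p in pools]


def _draw_convergences(spec: ConnectionSpec, n_post: int, subtype: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Target in-degrees: exact, or Gaussian rounded and clipped at 1."""
    if spec.subtype_convergence is not None:
        k = np.empty(n_post, dtype=np.int64)
        for code, tag in ((1, "BC"), (2, "SC")):
            mean, sd = spec.subtype_convergence[tag]
            m = subtype == code
            k[m] = np.maximum(np.rint(rng.normal(mean, sd, m.sum())), 1).astype(np.int64)
        return k
    if spec.convergence_sd is None:
        return np.full(n_post, int(spec.convergence_mean), dtype=np.int64)
    draws = rng.normal(spec.convergence_mean, spec.convergence_sd, n_post)
    return np.maximum(np.rint(draws), 1).astype(np.int64)


def _sample_per_target(pools, n_pre: int, k: np.ndarray, order: np.ndarray,
                       rng: np.random.Generator, spec: ConnectionSpec,
                       post_mask_by_target, self_idx, unique: bool,
                       clip_to_pool: bool):
    """Sample k[t] presynaptic partners per target, without replacement."""
    pre_out: list[np.ndarray] = []
    post_out: list[np.ndarray] = []
    used = np.zeros(n_pre, dtype=bool) if unique else None
    for t in order:
        pool = pools[t] if pools is not None else None
        if pool is None:
            pool_idx = post_mask_by_target(t)
        else:
            pool_idx = post_mask_by_target(t, pool)
        if self_idx is not None:
            pool_idx = pool_idx[pool_idx != self_idx(t)]
        if unique:
            pool_idx = pool_idx[~used[pool_idx]]
        kt = int(k[t])
        if kt > pool_idx.size:
            if spec.convergence_sd is not None or spec.subtype_convergence or clip_to_pool:
                kt = pool_idx.size      # Gaussian draw clipped to feasibility
            else:
                raise InfeasibleConnectivityError(
                    f"row {spec.name}: target {t} has {pool_idx.size} candidates "
                    f"but needs {kt}")
        if kt == 0:
            continue
        chosen = rng.choice(pool_idx, size=kt, replace=False)
        if unique:
            used[chosen] = True
        pre_out.append(chosen)
        post_out.append(np.full(kt, t, dtype=np.int64))
    if not pre_out:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    return np.concatenate(pre_out), np.concatenate(post_out)


def connect_populations(net: NetworkModel, spec: ConnectionSpec,
                        seed: int, *, clip_to_pool: bool = False
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Instantiate one connection row.

    Returns ``(pre_gid, post_gid, weight, delay)`` arrays.  Candidate
    presynaptic neurons are restricted by the row's transversal reach and,
    for confined rows, to the target's microcomplex; sampling is without
    replacement to the convergence target.  ``clip_to_pool`` relaxes exact
    convergences to pool size (used by reduced toy networks).
    """
    rng = np.random.default_rng(seed)
    pre_pop, post_pop = spec.pre_population, spec.post
    a_pre, _ = net.pop_slices[pre_pop]
    a_post, _ = net.pop_slices[post_pop]
    pre_pos, post_pos = net.pos(pre_pop), net.pos(post_pop)
    n_pre, n_post = len(pre_pos), len(post_pos)
    pre_lab, post_lab = net.labels(pre_pop), net.labels(post_pop)
    if n_pre == 0 or n_post == 0:
        z = np.empty(0, np.int64)
        return z, z, np.empty(0, np.float64), np.empty(0, np.float64)

    if spec.strategy == "cluster_all":
        pre_l, post_l = [], []
        for mc in (1, 2):
            src = np.flatnonzero(pre_lab == mc)
            dst = np.flatnonzero(post_lab == mc)
            if spec.exclude_self and pre_pop == post_pop:
                pass
            pp, qq = np.meshgrid(src, dst, indexing="ij")
            pre_l.append(pp.ravel())
            post_l.append(qq.ravel())
        pre_i = np.concatenate(pre_l)
        post_i = np.concatenate(post_l)
    elif spec.strategy == "deal_sources":
        # each target gets exactly one source; source divergence balanced
        pre_l, post_l = [], []
        lo_b, hi_b = spec.divergence_bounds or (1, n_post)
        for mc in (1, 2):
            src = np.flatnonzero(pre_lab == mc)
            dst = rng.permutation(np.flatnonzero(post_lab == mc))
            if dst.size and not src.size:
                raise InfeasibleConnectivityError(
                    f"row {spec.name}: no sources in microcomplex {mc}")
            if not dst.size:
                continue
            assign = src[np.arange(dst.size) % src.size]
            counts = np.bincount(assign, minlength=n_pre)[src]
            if counts.max() > hi_b or (counts.min() < lo_b and dst.size >= lo_b * src.size):
                raise InfeasibleConnectivityError(
                    f"row {spec.name}: divergence bounds {spec.divergence_bounds} "
                    f"infeasible in microcomplex {mc}")
            pre_l.append(assign)
            post_l.append(dst)
        pre_i = np.concatenate(pre_l) if pre_l else np.empty(0, np.int64)
        post_i = np.concatenate(post_l) if post_l else np.empty(0, np.int64)
    else:
        pools = _candidate_pools(pre_pos, post_pos, spec.reach)
        all_pre = np.arange(n_pre, dtype=np.int64)

        if spec.microcomplex_confined:
            def pool_for(t, pool=None):
                base = pool if pool is not None else all_pre
                return base[pre_lab[base] == post_lab[t]]
        else:
            def pool_for(t, pool=None):
                return pool if pool is not None else all_pre

        subtype = net.mli_subtype[net.ids(post_pop)] if post_pop == "MLI" else \
            np.zeros(n_post, np.int8)
        k = _draw_convergences(spec, n_post, subtype, rng)
        self_idx = (lambda t: t) if (spec.exclude_self and pre_pop == post_pop) else None
        order = rng.permutation(n_post) if spec.strategy == "per_target_unique" \
            else np.arange(n_post)
        pre_i, post_i = _sample_per_target(
            pools, n_pre, k, order, rng, spec, pool_for, self_idx,
            unique=(spec.strategy == "per_target_unique"),
            clip_to_pool=clip_to_pool)

    weight = np.full(pre_i.size, spec.weight, dtype=np.float64)
    if spec.delay_sd > 0:
        delay = np.maximum(rng.normal(spec.delay_mean, spec.delay_sd, pre_i.size), 1.0)
    elif spec.subtype_delay is not None and spec.pre_population == "MLI":
        sub = net.mli_subtype[net.ids("MLI")][pre_i]
        delay = np.where(sub == 2, spec.subtype_delay["SC"], spec.subtype_delay["BC"])
        delay = delay.astype(np.float64)
    else:
        delay = np.full(pre_i.size, spec.delay_mean, dtype=np.float64)
    return pre_i + a_pre, post_i + a_post, weight, delay


# ---------------------------------------------------------------------------
# report and build
# ---------------------------------------------------------------------------

def connectivity_report(net: NetworkModel) -> pd.DataFrame:
    """Realized convergence/divergence statistics per connection row.

    Convergence statistics are computed over all neurons of the target
    population; divergence over sources that make at least one contact.
    The last record carries the grand synapse total.
    """
    records = []
    for i, row in enumerate(net.rows):
        m = net.syn_row == i
        pre = net.syn_pre[m]
        post = net.syn_post[m]
        a_pre, b_pre = net.pop_slices[row.pre_population]
        a_post, b_post = net.pop_slices[row.post]
        conv = np.bincount(post - a_post, minlength=b_post - a_post)
        div_all = np.bincount(pre - a_pre, minlength=b_pre - a_pre)
        div = div_all[div_all > 0]
        cross = 0
        if row.microcomplex_confined and pre.size:
            cross = int(np.sum(net.microcomplex[pre] != net.microcomplex[post]))
        records.append({
            "row": row.name,
            "n_synapses": int(m.sum()),
            "convergence_mean": float(conv.mean()) if conv.size else 0.0,
            "convergence_sd": float(conv.std()) if conv.size else 0.0,
            "divergence_mean": float(div.mean()) if div.size else 0.0,
            "divergence_sd": float(div.std()) if div.size else 0.0,
            "cross_microcomplex": cross,
        })
    records.append({
        "row": "TOTAL", "n_synapses": int(net.n_synapses),
        "convergence_mean": np.nan, "convergence_sd": np.nan,
        "divergence_mean": np.nan, "divergence_sd": np.nan,
        "cross_microcomplex": int(sum(r["cross_microcomplex"] for r in records)),
    })
    return pd.DataFrame.from_records(records)


def build_network(counts: dict[str, int] | None = None,
                  volumes: dict[str, VolumeSpec] | None = None,
                  rows: list[ConnectionSpec] | None = None,
                  placement: PlacementParams | None = None,
                  placement_seed: int = 0, connectivity_seed: int = 1,
                  *, clip_to_pool: bool = False) -> NetworkModel:
    """Place, label and connect the full two-microcomplex scaffold."""
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    volumes = dict(DEFAULT_VOLUMES if volumes is None else volumes)
    rows = list(default_connection_table() if rows is None else rows)
    pp = placement or PlacementParams(rng_seed=placement_seed)
    rng = np.random.default_rng(placement_seed)

    pos_parts: list[np.ndarray] = []
    slices: dict[str, tuple[int, int]] = {}
    offset = 0
    parent_of_dcni = None
    order = [p for p in POPULATIONS if p in counts]
    for pop in order:
        n = counts[pop]
        if pop == "IO":
            # count follows from density x volume; scaled builds place n directly
            vol = volumes["olive"]
            n_density = int(np.floor(pp.io_density * vol.volume_mm3))
            if n == n_density:
                p = place_io_cells(vol, pp.io_density, pp.io_step,
                                   int(rng.integers(2**31)), r_io=pp.r_IO)
            else:
                p = place_io_cells(vol, n / vol.volume_mm3, pp.io_step,
                                   int(rng.integers(2**31)), r_io=pp.r_IO)
        elif pop == "DCNi":
            a, b = slices["DCNp"]
            dcnp_pos = np.concatenate(pos_parts)[a:b]
            if n != b - a:
                raise ConfigurationError("DCNi count must equal DCNp count "
                                         "(one satellite per DCNp)")
            p = place_dcni(dcnp_pos, pp.r_DCNp, pp.r_DCNi,
                           int(rng.integers(2**31)), volume=volumes["nuclei"])
            parent_of_dcni = np.arange(a, b, dtype=np.int64)
        else:
            vol = volumes[_LAYER_OF_POP[pop]]
            p = place_population(PopulationSpec(pop, n), vol,
                                 int(rng.integers(2**31)))
        slices[pop] = (offset, offset + len(p))
        offset += len(p)
        pos_parts.append(p)

    positions = np.concatenate(pos_parts) if pos_parts else np.empty((0, 3))
    N = positions.shape[0]
    net = NetworkModel(
        positions=positions, pop_slices=slices,
        microcomplex=np.zeros(N, np.int8),
        mli_subtype=np.zeros(N, np.int8),
        dcni_parent=(parent_of_dcni if parent_of_dcni is not None
                     else np.full(counts.get("DCNi", 0), -1, np.int64)),
        rows=rows, volumes=volumes,
        meta={"placement_seed": placement_seed,
              "connectivity_seed": connectivity_seed},
    )
    if "MLI" in slices:
        a, b = slices["MLI"]
        sub = np.where(rng.random(b - a) < 0.5, 1, 2).astype(np.int8)  # BC / SC
        net.mli_subtype[a:b] = sub
    assign_microcomplexes(net)

    crng = np.random.default_rng(connectivity_seed)
    pre_l, post_l, w_l, d_l, rid_l = [], [], [], [], []
    for i, row in enumerate(rows):
        p, q, w, d = connect_populations(net, row, int(crng.integers(2**31)),
                                         clip_to_pool=clip_to_pool)
        pre_l.append(p)
        post_l.append(q)
        w_l.append(w)
        d_l.append(d)
        rid_l.append(np.full(p.size, i, dtype=np.int16))
    if rows:
        net.syn_pre = np.concatenate(pre_l).astype(np.int32)
        net.syn_post = np.concatenate(post_l).astype(np.int32)
        net.syn_weight = np.concatenate(w_l).astype(np.float32)
        net.syn_delay = np.concatenate(d_l).astype(np.float32)
        net.syn_row = np.concatenate(rid_l)
    return net
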