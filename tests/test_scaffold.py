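"""Scaffold construction: placement, clustering, connectivity statistics."""

import numpy as np
import pytest

import olivonet.scaffold as sc
from olivonet.scaffold import (
    VolumeSpec, PopulationSpec, ConnectionSpec, ConfigurationError,
    PlacementInfeasibleError, DEFAULT_COUNTS, DEFAULT_VOLUMES, IO_DENSITY,
    default_connection_table, place_population, place_io_cells, place_dcni,
    dcni_distance_bounds, assign_microcomplexes, connect_populations,
    connectivity_report, build_network,
)


# ---------------------------------------------------------------------------
# volumes and counts
# ---------------------------------------------------------------------------

def test_default_volume_ratio_and_counts():
    """Cortical/olivary volume ratio is in the murine 66-68:1 range and the
    default counts sum to the full reconstructed volume."""
    ratio = (DEFAULT_VOLUMES["cortex"].volume_um3
             / DEFAULT_VOLUMES["olive"].volume_um3)
    assert 66 <= ratio <= 68
    assert sum(DEFAULT_COUNTS.values()) == 96_767
    assert int(np.floor(IO_DENSITY * DEFAULT_VOLUMES["olive"].volume_mm3)) == 12


def test_volume_validation():
    with pytest.raises(ConfigurationError):
        VolumeSpec("bad", (0, 0, 0), (10, -5, 10))


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def test_place_population_bounds_and_determinism():
    vol = DEFAULT_VOLUMES["granular"]
    a = place_population(PopulationSpec("GrC", 5000), vol, seed=42)
    b = place_population(PopulationSpec("GrC", 5000), vol, seed=42)
    assert np.array_equal(a, b)
    assert np.all(vol.contains(a))
    assert place_population(PopulationSpec("X", 0), vol, seed=0).shape == (0, 3)
    with pytest.raises(ConfigurationError):
        PopulationSpec("X", -1)


def test_place_population_microzone_split_fraction():
    """Uniform placement puts ~half the somata in each 200 um z-slab."""
    vol = DEFAULT_VOLUMES["granular"]
    pos = place_population(PopulationSpec("GrC", 1000), vol, seed=3)
    frac = np.mean(pos[:, 2] < 200.0)
    # binomial 95% interval around 0.5 for n = 1000
    assert 0.45 < frac < 0.55


def test_place_io_cells_count_and_self_avoidance():
    """Density x volume gives 12 cells; all 66 pairwise distances >= 2 r."""
    vol = DEFAULT_VOLUMES["olive"]
    r_io = 5.0
    pos = place_io_cells(vol, IO_DENSITY, step=10.0, seed=0, r_io=r_io)
    assert pos.shape == (12, 3)
    assert np.all(vol.contains(pos))
    # exhaustive pair scan
    for i in range(12):
        for j in range(i + 1, 12):
            assert np.linalg.norm(pos[i] - pos[j]) >= 2 * r_io


def test_place_io_single_cell():
    vol = DEFAULT_VOLUMES["olive"]
    one = place_io_cells(vol, 1.0 / vol.volume_mm3 + 1e-9, step=10.0, seed=1)
    assert one.shape == (1, 3)
    assert vol.contains(one).all()


def test_place_io_infeasible_raises():
    tiny = VolumeSpec("tiny", (0, 0, 0), (10.0, 10.0, 10.0))
    with pytest.raises(PlacementInfeasibleError):
        place_io_cells(tiny, 50 / tiny.volume_mm3, step=2.0, seed=0, r_io=7.5)


def test_dcni_distance_bounds_arithmetic():
    """d1/d2 from the printed formulas on a hand-checkable configuration."""
    # two DCNp 200 um apart -> mean_dist = 200
    pts = np.array([[0.0, 0, 0], [200.0, 0, 0]])
    d1, d2 = dcni_distance_bounds(pts, r_dcnp=10.0, r_dcni=4.0)
    assert d1 == pytest.approx(14.0)
    assert d2 == pytest.approx(200.0 / 4 - 14.0)   # 36 um
    # vanishing radii: d in [0, mean_dist / 4]
    d1z, d2z = dcni_distance_bounds(pts, 0.0, 0.0)
    assert d1z == 0.0 and d2z == pytest.approx(50.0)


def test_place_dcni_satellite_property():
    """Each DCNi is nearest to its own parent DCNp (exhaustive search)."""
    rng = np.random.default_rng(5)
    vol = DEFAULT_VOLUMES["nuclei"]
    lo = np.asarray(vol.origin) + 50
    ex = np.asarray(vol.extent) - 100
    dcnp = lo + rng.random((12, 3)) * ex
    dcni = place_dcni(dcnp, r_dcnp=10.0, r_dcni=5.0, seed=0, volume=vol)
    assert dcni.shape == (12, 3)
    d1, d2 = dcni_distance_bounds(dcnp, 10.0, 5.0)
    for i in range(12):
        dists = np.linalg.norm(dcnp - dcni[i], axis=1)
        assert np.argmin(dists) == i              # satellite of its parent
        assert dists[i] <= d2 + 1e-9


def test_place_dcni_rejects_inverted_range():
    pts = np.array([[0.0, 0, 0], [30.0, 0, 0]])   # mean_dist/4 = 7.5 < radii
    with pytest.raises(ConfigurationError, match="d1"):
        place_dcni(pts, r_dcnp=10.0, r_dcni=4.0, seed=0)


# ---------------------------------------------------------------------------
# microcomplex labeling
# ---------------------------------------------------------------------------

def test_microcomplex_labels_full(full_net):
    """Cortical labels follow the z slab; DCN/IO split 6/6; DCNi follow parents."""
    for pop in ("MF", "GrC", "GoC", "MLI", "PC"):
        z = full_net.pos(pop)[:, 2]
        lab = full_net.labels(pop)
        assert np.array_equal(lab, np.where(z < 200.0, 1, 2))
    for pop in ("DCNp", "IO", "DCNi"):
        lab = full_net.labels(pop)
        assert np.sum(lab == 1) == 6 and np.sum(lab == 2) == 6
    a, _ = full_net.pop_slices["DCNi"]
    for k, parent in enumerate(full_net.dcni_parent):
        assert full_net.microcomplex[a + k] == full_net.microcomplex[parent]


def test_dcnp_clustering_matches_exhaustive_two_means():
    """On z-separated coordinates, the equal-size z-rank split recovers the
    optimal balanced 2-clustering found by exhausting all 462 bipartitions."""
    import itertools

    rng = np.random.default_rng(11)
    pos = np.vstack([
        np.column_stack([rng.uniform(100, 300, 6), rng.uniform(330, 930, 6),
                         rng.uniform(110, 190, 6)]),     # microcomplex-1 side
        np.column_stack([rng.uniform(100, 300, 6), rng.uniform(330, 930, 6),
                         rng.uniform(210, 290, 6)]),     # microcomplex-2 side
    ])
    perm = rng.permutation(12)
    pos = pos[perm]
    best, best_cost = None, np.inf
    for combo in itertools.combinations(range(12), 6):
        g1 = np.array(combo)
        g2 = np.setdiff1d(np.arange(12), g1)
        cost = (np.sum((pos[g1][:, 2] - pos[g1][:, 2].mean()) ** 2)
                + np.sum((pos[g2][:, 2] - pos[g2][:, 2].mean()) ** 2))
        if cost < best_cost:
            best, best_cost = frozenset(combo), cost
    order = np.argsort(pos[:, 2], kind="stable")
    rank_split = frozenset(order[:6].tolist())
    assert rank_split in (best, frozenset(range(12)) - best)


def test_odd_cluster_size_raises():
    net = build_network(counts={"DCNp": 3, "DCNi": 3, "IO": 2, "PC": 4,
                                "MF": 50, "GrC": 100, "GoC": 4, "MLI": 8},
                        rows=[], placement_seed=0) if False else None
    # direct check on the labeling step
    counts = dict(MF=10, GoC=2, GrC=20, MLI=4, PC=4, DCNp=3, DCNi=3, IO=2)
    with pytest.raises(ConfigurationError, match="odd"):
        build_network(counts=counts, rows=[], placement_seed=0,
                      connectivity_seed=1, clip_to_pool=True)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def test_toy_connectivity_exact_row():
    """Enumerated edge check: 4 sources, 2 targets, exact convergence 2."""
    counts = dict(MF=4, GoC=2, GrC=2, MLI=2, PC=2, DCNp=2, DCNi=2, IO=2)
    row = ConnectionSpec("MF-GoC", "MF", "GoC", 2, None, None, None,
                         1.0, 4.0, 0.0, 1.0, "exc")
    net = build_network(counts=counts, rows=[row], placement_seed=0,
                        connectivity_seed=3, clip_to_pool=False)
    assert net.n_synapses == 4
    a, b = net.pop_slices["GoC"]
    indeg = np.bincount(net.syn_post - a, minlength=2)
    assert np.array_equal(indeg, [2, 2])
    # sampled without replacement: no duplicate (pre, post) pairs
    pairs = set(zip(net.syn_pre.tolist(), net.syn_post.tolist()))
    assert len(pairs) == 4


def test_empty_pre_population_gives_empty_row(toy_net):
    row = ConnectionSpec("MF-GoC", "MF", "GoC", 2, None, None, None,
                         1.0, 4.0, 0.0, 1.0, "exc")
    net = build_network(counts=dict(MF=0, GoC=2, GrC=2, MLI=2, PC=2,
                                    DCNp=2, DCNi=2, IO=2),
                        rows=[row], placement_seed=0, connectivity_seed=0,
                        clip_to_pool=True)
    assert net.n_synapses == 0


def test_exact_convergence_rows(full_net):
    """Fixed-convergence rows realize their in-degree exactly."""
    for row_name, pop, k in (("MF-GrC", "GrC", 4), ("PF-GoC", "GoC", 1600),
                             ("MLI-PC", "PC", 20), ("CF-PC", "PC", 1),
                             ("MF-DCNp", "DCNp", 147)):
        idx = full_net.row_synapses(row_name)
        a, b = full_net.pop_slices[pop]
        indeg = np.bincount(full_net.syn_post[idx] - a, minlength=b - a)
        assert np.all(indeg == k), row_name


def test_distinct_afferents_per_granule_cell(full_net):
    """Each granule cell has 4 distinct mossy-fiber afferents."""
    idx = full_net.row_synapses("MF-GrC")
    pre = full_net.syn_pre[idx]
    post = full_net.syn_post[idx]
    pairs = pre.astype(np.int64) * full_net.n_neurons + post
    assert np.unique(pairs).size == pairs.size


def test_statistical_convergences_within_one_sd(full_net, full_report):
    """Gaussian-sampled rows realize convergence means within 1 SD."""
    rep = full_report.set_index("row")
    for row in full_net.rows:
        if row.convergence_sd is None and row.subtype_convergence is None:
            continue
        if row.strategy in ("cluster_all", "deal_sources"):
            continue
        mean = rep.loc[row.name, "convergence_mean"]
        sd = (row.convergence_sd if row.convergence_sd is not None
              else list(row.subtype_convergence.values())[0][1])
        assert abs(mean - row.convergence_mean) <= sd, row.name


def test_confined_rows_never_cross_microcomplexes(full_report):
    assert (full_report["cross_microcomplex"] == 0).all()


def test_cf_pc_divergence_bounds(full_net):
    idx = full_net.row_synapses("CF-PC")
    pre = full_net.syn_pre[idx]
    a, b = full_net.pop_slices["IO"]
    div = np.bincount(pre - a, minlength=b - a)
    assert div.min() >= 4 and div.max() <= 8


def test_no_self_synapses_in_gap_junction_rows(full_net):
    for name in ("GoC-GoC", "MLI-MLI"):
        idx = full_net.row_synapses(name)
        assert np.all(full_net.syn_pre[idx] != full_net.syn_post[idx])


def test_cluster_rows_all_to_all(full_net):
    """IO-DCN and DCNi-IO are 6x6 all-to-all within each microcomplex."""
    for name in ("IO-DCNp", "IO-DCNi", "DCNi-IO"):
        idx = full_net.row_synapses(name)
        assert idx.size == 72, name


def test_seeded_rebuild_is_identical_and_reseeded_differs():
    counts = {k: v for k, v in DEFAULT_COUNTS.items()}
    counts["GrC"] = 2000  # reduced for speed; same code path
    counts["MF"] = 500
    a = build_network(counts=counts, placement_seed=3, connectivity_seed=4,
                      clip_to_pool=True)
    b = build_network(counts=counts, placement_seed=3, connectivity_seed=4,
                      clip_to_pool=True)
    c = build_network(counts=counts, placement_seed=3, connectivity_seed=5,
                      clip_to_pool=True)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.syn_pre, b.syn_pre)
    assert np.array_equal(a.syn_post, b.syn_post)
    assert np.array_equal(a.syn_delay, b.syn_delay)
    assert not (np.array_equal(a.syn_pre, c.syn_pre)
                and np.array_equal(a.syn_post, c.syn_post))


def test_cf_mli_spillover_delays(full_net):
    """CF-MLI delays are ~N(70, 10) ms, frozen in the synapse table."""
    idx = full_net.row_synapses("CF-MLI")
    d = full_net.syn_delay[idx]
    assert abs(d.mean() - 70.0) < 2.0
    assert abs(d.std() - 10.0) < 2.0
    assert d.min() >= 1.0


def test_connection_spec_validation():
    with pytest.raises(ConfigurationError):
        ConnectionSpec("x", "MF", "GrC", 4, None, None, None,
                       -1.0, 4.0, 0.0, 1.0, "exc")
    with pytest.raises(ConfigurationError):   # sub-resolution fixed delay
        ConnectionSpec("x", "MF", "GrC", 4, None, None, None,
                       1.0, 0.5, 0.0, 1.0, "exc")


def test_connectivity_report_is_pure(toy_net):
    before = toy_net.syn_pre.copy()
    connectivity_report(toy_net)
    assert np.array_equal(before, toy_net.syn_pre)


def test_empty_network_report():
    counts = dict(MF=2, GoC=2, GrC=2, MLI=2, PC=2, DCNp=2, DCNi=2, IO=2)
    net = build_network(counts=counts, rows=[], placement_seed=0,
                        connectivity_seed=0, clip_to_pool=True)
    rep = connectivity_report(net)
    assert rep["n_synapses"].iloc[-1] == 0


def test_hdf5_round_trip(toy_net, tmp_path):
    path = tmp_path / "net.h5"
    toy_net.to_hdf5(str(path))
    back = sc.NetworkModel.from_hdf5(str(path), rows=toy_net.rows)
    assert np.array_equal(back.positions, toy_net.positions)
    assert np.array_equal(back.syn_pre, toy_net.syn_pre)
    assert np.array_equal(back.microcomplex, toy_net.microcomplex)
    assert back.pop_slices == toy_net.pop_slices
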