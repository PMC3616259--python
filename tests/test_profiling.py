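"""Sphere-window intensity measurement, path selection, normalization, writers."""

import numpy as np
import pytest

import arbormap as am
from arbormap.profiling import SphereWindow
from arbormap.synthetic import fine_geometry


@pytest.fixture(scope="module")
def tube_graph(reconstructions):
    fx, mask, graph = reconstructions["straight_tube"]
    return fx, graph


def brute_force_sphere(data, geom, center_zyx, radius_um):
    """Exhaustive scan over all voxels within physical distance of center."""
    zz, yy, xx = np.mgrid[0:geom.nz, 0:geom.ny, 0:geom.nx]
    d2 = (((zz - center_zyx[0]) * geom.dz) ** 2
          + ((yy - center_zyx[1]) * geom.dy) ** 2
          + ((xx - center_zyx[2]) * geom.dx) ** 2)
    sel = data[d2 <= radius_um ** 2]
    return sel.mean(), sel.max()


class TestProfileGraph:
    def test_uniform_signal_constant_everywhere(self, tube_graph):
        fx, graph = tube_graph
        geom = fx.morphology.geometry
        sig = am.ImageStack(np.full(geom.shape_zyx, 42, np.uint8), geom, 8,
                            "signal")
        recs = am.profile_graph(graph, sig)
        for r in (r for v in recs.values() for r in v):
            assert r.point_value == r.mean_value == r.max_value == 42.0

    def test_single_bright_voxel_window_arithmetic(self, tube_graph):
        fx, graph = tube_graph
        geom = fx.morphology.geometry
        comp = graph.edges[0].compartments[len(graph.edges[0].compartments) // 2]
        x, y, z = comp.voxel_index
        vol = np.zeros(geom.shape_zyx, np.uint8)
        vol[z, y, x] = 255
        sig = am.ImageStack(vol, geom, 8, "signal")
        window = SphereWindow(6.0)
        # the window is clipped at the stack border: count in-bounds voxels
        offs = window.offsets(geom)
        vox_all = np.array([z, y, x]) + offs
        shape = np.array(vol.shape)
        n_window = int(((vox_all >= 0) & (vox_all < shape)).all(axis=1).sum())
        recs = am.profile_graph(graph, sig, window)
        flat = {tuple(c.voxel_index): r
                for e in graph.edges
                for c, r in zip(e.compartments, recs[e.name])}
        hit = flat[(x, y, z)]
        assert hit.point_value == 255 and hit.max_value == 255
        assert hit.mean_value == pytest.approx(255.0 / n_window)
        # neighbors within the radius see the voxel in max but not in point
        for c in graph.edges[0].compartments:
            d = np.linalg.norm(c.position - comp.position)
            r = flat[tuple(c.voxel_index)]
            if 0 < d < 2.9:
                assert r.point_value == 0 and r.max_value == 255

    def test_interior_window_voxel_count_regression(self):
        # frozen from one-time enumeration at the fine voxel spacing
        geom = fine_geometry((10, 10, 10))
        assert len(SphereWindow(6.0).offsets(geom)) == 210323

    def test_brute_force_oracle_random_compartments(self, tube_graph):
        fx, graph = tube_graph
        geom = fx.morphology.geometry
        rng = np.random.default_rng(42)
        vol = rng.integers(0, 256, geom.shape_zyx).astype(np.uint8)
        sig = am.ImageStack(vol, geom, 8, "signal")
        recs = am.profile_graph(graph, sig, SphereWindow(6.0))
        comps = graph.edges[0].compartments
        rows = recs[graph.edges[0].name]
        idx = rng.choice(len(comps), size=20, replace=False)
        for i in idx:
            x, y, z = comps[i].voxel_index
            mean, mx = brute_force_sphere(vol, geom, (z, y, x), 3.0)
            assert rows[i].max_value == mx  # exact integer equality
            assert rows[i].mean_value == pytest.approx(mean, rel=1e-9)

    def test_max_nondecreasing_in_diameter(self, tube_graph):
        fx, graph = tube_graph
        geom = fx.morphology.geometry
        rng = np.random.default_rng(1)
        sig = am.ImageStack(rng.integers(0, 256, geom.shape_zyx).astype(np.uint8),
                            geom, 8, "signal")
        small = am.profile_graph(graph, sig, SphereWindow(2.0))
        large = am.profile_graph(graph, sig, SphereWindow(4.0))
        for name in small:
            for a, b in zip(small[name], large[name]):
                assert b.max_value >= a.max_value

    def test_geometry_mismatch_is_hard_error(self, tube_graph):
        _, graph = tube_graph
        other = fine_geometry((5.0, 5.0, 5.0))
        sig = am.ImageStack(np.zeros(other.shape_zyx, np.uint8), other, 8,
                            "signal")
        with pytest.raises(ValueError, match="same imaging session"):
            am.profile_graph(graph, sig)


class TestSelectPath:
    def test_single_edge_identity(self, reconstructions):
        fx, _, graph = reconstructions["y_tree"]
        sig = am.ImageStack(np.full(fx.morphology.geometry.shape_zyx, 9,
                                    np.uint8), fx.morphology.geometry, 8,
                            "signal")
        recs = am.profile_graph(graph, sig)
        path = am.select_path(graph, ["dend[0]"], recs)
        assert len(path.records) == len(graph.edges[0].compartments)
        assert path.records[0].arc_length == 0.0

    def test_two_edges_concatenate_continuously(self, reconstructions):
        _, _, graph = reconstructions["y_tree"]
        stem, child = graph.edges[0], graph.edges[1]
        assert child.proximal == stem.distal
        path = am.select_path(graph, [stem.name, child.name])
        arcs = [r.arc_length for r in path.records]
        assert all(b > a for a, b in zip(arcs, arcs[1:]))
        assert arcs[-1] == pytest.approx(stem.length + child.length, rel=1e-6)

    def test_soma_exclusion_drops_proximal_records(self, reconstructions):
        # the first few um of a soma-seeded dendrite sample the cell body
        # and are excluded from analysis
        _, _, graph = reconstructions["y_tree"]
        path = am.select_path(graph, ["dend[0]"], soma_exclusion_radius=6.0)
        assert all(r.arc_length >= 6.0 for r in path.records)
        full = am.select_path(graph, ["dend[0]"])
        assert len(path.records) < len(full.records)

    def test_unknown_edge_name_rejected(self, reconstructions):
        _, _, graph = reconstructions["y_tree"]
        with pytest.raises(KeyError, match="unknown edge"):
            am.select_path(graph, ["dend[0]", "dend[99]"])

    @staticmethod
    def _three_chain():
        # hand-built chain soma -(d0)- n1 -(d1)- n2 -(d2)- n3
        def comp(x):
            return am.Compartment((0, 0, 0), np.array([x, 0.0, 0.0]), 0.3, x)
        nodes = {i: am.skeletonize.SkeletonNode(
            i, "soma" if i == 0 else "endpoint", np.array([float(i), 0, 0]))
            for i in range(4)}
        edges = [am.SkeletonEdge(f"dend[{i}]", i, i + 1,
                                 [comp(float(i)), comp(i + 0.5),
                                  comp(float(i + 1))])
                 for i in range(3)]
        return am.SkeletonGraph(nodes, edges, 0, None)

    def test_non_adjacent_consecutive_edges_rejected(self):
        graph = self._three_chain()
        with pytest.raises(ValueError, match="not adjacent"):
            am.select_path(graph, ["dend[0]", "dend[2]"])
        # while the full chain is accepted
        path = am.select_path(graph, ["dend[0]", "dend[1]", "dend[2]"])
        assert path.records[-1].arc_length == pytest.approx(3.0)


class TestNormalization:
    def _records(self, values, arcs=None):
        arcs = arcs if arcs is not None else np.arange(len(values), dtype=float)
        return [am.ProfileRecord(a, v, v, v, 0.3)
                for a, v in zip(arcs, values)]

    def test_self_normalization_is_one(self):
        recs = self._records([10, 50, 200])
        out = am.normalize_profile(recs, recs, epsilon=1.0)
        assert all(r.normalized_point == 1.0 and r.normalized_mean == 1.0
                   for r in out)

    def test_linearity(self):
        morph = self._records([10, 50, 100])
        sig = self._records([20, 100, 200])
        out = am.normalize_profile(sig, morph)
        assert all(r.normalized_point == pytest.approx(2.0) for r in out)

    def test_zero_morphology_clamped_and_flagged(self):
        morph = self._records([0, 100])
        sig = self._records([37, 100])
        out = am.normalize_profile(sig, morph, epsilon=1.0)
        assert out[0].normalized_point == 37.0  # divided by epsilon
        assert out[0].flagged and not out[1].flagged

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            am.normalize_profile(self._records([1]), self._records([1, 2]))


class TestWriters:
    def _path(self, n=3, normalized=False):
        recs = [am.ProfileRecord(i * 0.5, 10.0 + i, 11.0 + i, 20.0 + i, 0.4)
                for i in range(n)]
        if normalized:
            recs = am.normalize_profile(recs, recs)
        return am.DendritePath(["dend[0]"], [], recs)

    def test_txt_line_and_column_counts(self, tmp_path):
        p = tmp_path / "d.txt"
        am.write_profile_txt(self._path(3), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4  # header + 3 rows
        assert len(lines[0].split("\t")) == 5
        am.write_profile_txt(self._path(3, normalized=True), p)
        assert len(p.read_text().splitlines()[0].split("\t")) == 7

    def test_txt_round_trip(self, tmp_path):
        p = tmp_path / "d.txt"
        path = self._path(5, normalized=True)
        am.write_profile_txt(path, p)
        back = am.read_profile_txt(p)
        for a, b in zip(path.records, back.records):
            assert b.arc_length == pytest.approx(a.arc_length)
            assert b.point_value == pytest.approx(a.point_value)
            assert b.mean_value == pytest.approx(a.mean_value, rel=1e-8)
            assert b.normalized_mean == pytest.approx(a.normalized_mean,
                                                      rel=1e-8)

    def test_spatial_graph_y_tree_bookkeeping(self, tmp_path, reconstructions):
        fx, _, graph = reconstructions["y_tree"]
        geom = fx.morphology.geometry
        sig = am.ImageStack(np.full(geom.shape_zyx, 10, np.uint8), geom, 8,
                            "signal")
        recs = am.profile_graph(graph, sig)
        p = tmp_path / "y.am"
        am.write_spatial_graph(graph, recs, p, mode="filament")
        data = am.read_spatial_graph(p)
        assert len(data["vertices"]) == 4  # soma + fork + 2 tips
        assert len(data["edges"]) == 3
        assert (data["intensity"] == 10.0).all()
        assert data["n_edge_points"].sum() == len(data["points"])
        # filament mode: constant half-voxel thickness
        assert np.allclose(data["thickness"], 0.5 * min(geom.spacing_xyz))

    def test_spatial_graph_morphology_mode_thickness(self, tmp_path,
                                                     reconstructions):
        fx, _, graph = reconstructions["y_tree"]
        geom = fx.morphology.geometry
        sig = am.ImageStack(np.zeros(geom.shape_zyx, np.uint8), geom, 8,
                            "signal")
        recs = am.profile_graph(graph, sig)
        p = tmp_path / "y.am"
        am.write_spatial_graph(graph, recs, p, mode="morphology")
        data = am.read_spatial_graph(p)
        radii = np.array([c.radius for e in graph.edges
                          for c in e.compartments])
        np.testing.assert_allclose(data["thickness"], radii, atol=1e-4)

    def test_records_mismatch_rejected(self, tmp_path, reconstructions):
        _, _, graph = reconstructions["y_tree"]
        with pytest.raises(ValueError, match="records"):
            am.write_spatial_graph(graph, {}, tmp_path / "x.am")


class TestPunctaRecovery:
    def test_puncta_localized_on_noisy_tube(self, reconstructions):
        fx, _, graph = reconstructions["straight_tube"]
        geom = fx.morphology.geometry
        arcs_true = np.linspace(2.0, 18.0, 10)
        puncta = [am.PunctumSpec("trunk", a, amplitude=180.0, sigma=0.3)
                  for a in arcs_true]
        sig = am.render_signal(puncta, fx.truth, geom, baseline=20.0,
                               noise=am.NoiseModel(gaussian_sigma=4.0,
                                                   poisson=True), seed=99)
        recs = am.profile_graph(graph, sig, SphereWindow(6.0))
        rows = recs[graph.edges[0].name]
        arcs = np.array([r.arc_length for r in rows])
        vals = np.array([r.point_value for r in rows])
        # local maxima of the point profile above the baseline band
        from scipy.signal import argrelextrema
        import scipy.ndimage as ndi
        smooth = ndi.uniform_filter1d(vals, 3)
        peaks = [i for i in range(1, len(vals) - 1)
                 if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
                 and vals[i] > 80]
        # the seed end offsets arc 0 from the tube start at x=1: shift truth
        start_x = graph.edges[0].compartments[0].position[0]
        expect = arcs_true - (start_x - 1.0)
        found = 0
        for a in expect:
            if np.min(np.abs(arcs[peaks] - a)) <= 0.3:
                found += 1
        assert found >= 9
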