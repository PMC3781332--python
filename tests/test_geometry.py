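"""Network geometry: grids, layouts, wall maps, serialization."""

import numpy as np
import pytest

from capatp import (GridSpec, LayoutSpec, NetworkGeometry, TissueGrid,
                    Vessel, build_arteriole_variant, build_capillary_array,
                    GeometryError, TransportParams)
from capatp.geometry import ArterioleSpec, build_wall_map
from capatp.io import load_geometry, save_geometry, vessel_table
from capatp.params import CM_PER_UM


class TestTissueGrid:
    def test_published_node_count(self):
        grid = TissueGrid(216.0, 532.0, 500.0, 2.0)
        assert grid.shape == (109, 267, 251)
        assert grid.n_nodes == 7_304_853

    def test_vertex_centered_convention(self):
        # one capillary-sized box: 40 x 100 x 40 um at h = 2 um
        grid = TissueGrid(40.0, 100.0, 40.0, 2.0)
        assert grid.shape == (21, 51, 21)

    def test_invalid_spacing(self):
        with pytest.raises(GeometryError):
            TissueGrid(10.0, 10.0, 10.0, 0.0)

    def test_control_volumes_sum_to_box(self):
        grid = TissueGrid(40.0, 60.0, 20.0, 4.0)
        v = grid.node_volumes_cm3().sum()
        box = 40 * 60 * 20 * CM_PER_UM ** 3
        assert v == pytest.approx(box, rel=1e-12)


class TestStandardArray:
    def test_vessel_count_and_labels(self):
        g = build_capillary_array()
        assert g.n_vessels == 72
        assert g.vessel(17).depth_um == 16.0
        assert g.vessel(21).depth_um == 16.0
        assert g.vessel(18).depth_um == 33.0
        assert g.vessel(54).depth_um == 133.0

    def test_no_overlaps(self):
        g = build_capillary_array()
        pos = np.array([[v.x_um, v.z_um] for v in g.vessels])
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 2 * g.vessels[0].radius_um

    def test_overlap_rejected(self):
        grid = TissueGrid(40.0, 60.0, 40.0, 4.0)
        v1 = Vessel(1, "capillary", 2.0, 20.0, 20.0, 1e-2, 0.65)
        v2 = Vessel(2, "capillary", 2.0, 22.0, 20.0, 1e-2, 0.65)
        with pytest.raises(GeometryError, match="overlap"):
            NetworkGeometry(grid, [v1, v2])

    def test_out_of_box_rejected(self):
        grid = TissueGrid(40.0, 60.0, 40.0, 4.0)
        v = Vessel(1, "capillary", 2.0, 39.5, 20.0, 1e-2, 0.65)
        with pytest.raises(GeometryError, match="outside"):
            NetworkGeometry(grid, [v])


class TestArterioleVariant:
    def test_counts_and_labels(self):
        g = build_arteriole_variant()
        assert g.n_vessels == 69
        art = g.vessel(69)
        assert art.kind == "arteriole"
        assert art.radius_um == 4.5
        assert art.depth_um == 30.0
        # renumbered capillary labels keep their published depths
        assert g.vessel(14).depth_um == 33.0
        assert g.vessel(17).depth_um == 16.0
        assert g.vessel(50).depth_um == 133.0

    @pytest.mark.parametrize("s_in", [0.65, 0.80])
    def test_entrance_saturation(self, s_in):
        g = build_arteriole_variant(
            arteriole_spec=ArterioleSpec(S_in=s_in))
        assert g.vessel(69).S_in == s_in

    def test_non_adjacent_replacement_rejected(self):
        with pytest.raises(GeometryError, match="adjacent"):
            build_arteriole_variant(
                arteriole_spec=ArterioleSpec(replaced_ids=(1, 2, 3, 4)))


class TestWallMaps:
    def test_segment_area_normalization(self, tiny_geom):
        dy = tiny_geom.dy_cm
        for v in tiny_geom.vessels:
            area = 2 * np.pi * v.radius_cm * dy
            for seg in (0, 25, 49):
                _, w = tiny_geom.segment_wall_nodes(v.id, seg)
                assert w.sum() == pytest.approx(area, rel=1e-12)

    def test_total_wall_area(self, tiny_geom):
        Ly_cm = tiny_geom.grid.Ly_um * CM_PER_UM
        for pos, v in enumerate(tiny_geom.vessels):
            total = tiny_geom.wall_maps[pos].area_cm2.sum()
            assert total == pytest.approx(2 * np.pi * v.radius_cm * Ly_cm,
                                          rel=1e-12)

    def test_documented_segment_area(self):
        # R = 2 um, dy = 532/50 um
        g = build_capillary_array(
            GridSpec(h_um=4.0), params=TransportParams(R_cap_um=2.0))
        _, w = g.segment_wall_nodes(1, 10)
        expect = 2 * np.pi * 2.0 * (532.0 / 50) * CM_PER_UM ** 2
        assert w.sum() == pytest.approx(expect, rel=1e-12)

    def test_translation_invariance(self):
        grid = TissueGrid(80.0, 60.0, 80.0, 4.0)
        a = build_wall_map(Vessel(1, "capillary", 2.0, 22.5, 30.0, 1e-2, 0.65),
                           grid)
        b = build_wall_map(Vessel(1, "capillary", 2.0, 42.5, 46.0, 1e-2, 0.65),
                           grid)
        # grid-aligned translation: identical weight multisets
        np.testing.assert_allclose(np.sort(a.area_cm2), np.sort(b.area_cm2),
                                   rtol=1e-12)

    def test_determinism(self):
        g1 = build_capillary_array(GridSpec(h_um=4.0))
        g2 = build_capillary_array(GridSpec(h_um=4.0))
        assert g1.fingerprint() == g2.fingerprint()
        for m1, m2 in zip(g1.wall_maps, g2.wall_maps):
            assert np.array_equal(m1.node_index, m2.node_index)
            assert np.array_equal(m1.area_cm2, m2.area_cm2)

    def test_segment_out_of_range(self, tiny_geom):
        with pytest.raises(GeometryError):
            tiny_geom.segment_wall_nodes(1, 50)
        with pytest.raises(GeometryError):
            tiny_geom.segment_wall_nodes(99, 0)


class TestQueriesAndIO:
    def test_depth_queries(self):
        g = build_capillary_array()
        assert set(g.vessels_at_depth(16.0)) == {2 * k + 1 for k in range(12)}
        assert g.vessel_nearest(108.0, 16.0) in g.vessels_at_depth(16.0)

    def test_vessel_table_columns(self, tiny_geom):
        tab = vessel_table(tiny_geom)
        assert list(tab.columns) == ["id", "kind", "x_um", "z_um",
                                     "radius_um", "depth_um",
                                     "velocity_cm_s", "entrance_so2"]
        assert len(tab) == tiny_geom.n_vessels

    def test_geometry_roundtrip(self, tiny_geom, tmp_path):
        h5 = tmp_path / "geom.h5"
        js = tmp_path / "geom.json"
        save_geometry(tiny_geom, h5, js)
        g2 = load_geometry(h5)
        assert g2.fingerprint() == tiny_geom.fingerprint()
        assert js.exists()

    def test_lumen_mask_excludes_centerline(self):
        grid = TissueGrid(40.0, 40.0, 40.0, 2.0)
        v = Vessel(1, "capillary", 3.0, 20.0, 20.0, 1e-2, 0.65)
        g = NetworkGeometry(grid, [v])
        mask = g.lumen_mask()
        assert mask[10, :, 10].all()      # node on the centerline
        assert not mask[0, :, 0].any()    # far corner is tissue
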