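"""Skeletonization and morphometrics on constructed vessel masks."""

import numpy as np
import pytest
from scipy.ndimage import label

from angiosprout.grid_fields import Grid, ScalarField
from angiosprout.vessel_network import (
    anastomosis_density,
    branch_density,
    edges_in_band,
    mean_diameter,
    skeletonize,
)


def field_from_mask(mask, h=1.0):
    g = Grid(mask.shape, h)
    return ScalarField(g, np.where(mask, 1.0, -1.0), "phi")


@pytest.fixture
def bar():
    m = np.zeros((120, 120), bool)
    m[55:65, 10:110] = True  # 100 x 10 um bar
    return field_from_mask(m)


@pytest.fixture
def y_shape():
    m = np.zeros((140, 140), bool)
    m[65:75, 10:75] = True
    for i in range(50):
        m[70 - i - 5 : 70 - i + 5, 70 + i - 5 : 70 + i + 5] = True
        m[70 + i - 5 : 70 + i + 5, 70 + i - 5 : 70 + i + 5] = True
    return field_from_mask(m)


@pytest.fixture
def ring():
    yy, xx = np.mgrid[0:120, 0:120]
    r = np.hypot(yy - 60, xx - 60)
    return field_from_mask((r > 30) & (r < 42))


@pytest.fixture
def theta(ring):
    yy, xx = np.mgrid[0:120, 0:120]
    m = (ring.values > 0) | ((np.abs(yy - 60) < 5) & (np.abs(xx - 60) < 38))
    return field_from_mask(m)


class TestSkeletonTopology:
    def test_bar_single_edge_two_endpoints(self, bar):
        g = skeletonize(bar, spur_min=10)
        assert (g.n_edges, g.n_endpoints, g.cycle_rank) == (1, 2, 0)
        d = next(iter(g.g.edges(data=True)))[2]
        assert d["length"] == pytest.approx(100.0, rel=0.1)

    def test_y_three_edges_one_junction(self, y_shape):
        g = skeletonize(y_shape, spur_min=10)
        assert g.n_edges == 3
        assert g.n_endpoints == 3
        assert sum(1 for n in g.g.nodes if g.g.degree(n) >= 3) == 1
        assert g.cycle_rank == 0

    def test_ring_one_loop_no_endpoints(self, ring):
        g = skeletonize(ring, spur_min=10)
        assert g.cycle_rank == 1
        assert g.n_endpoints == 0

    def test_theta_two_loops(self, theta):
        g = skeletonize(theta, spur_min=10)
        assert g.cycle_rank == 2
        assert g.n_edges == 3
        assert sum(1 for n in g.g.nodes if g.g.degree(n) >= 3) == 2

    def test_two_disjoint_rings(self):
        yy, xx = np.mgrid[0:200, 0:100]
        m = ((np.hypot(yy - 50, xx - 50) > 20) & (np.hypot(yy - 50, xx - 50) < 32)) | (
            (np.hypot(yy - 150, xx - 50) > 20) & (np.hypot(yy - 150, xx - 50) < 32)
        )
        g = skeletonize(field_from_mask(m), spur_min=10)
        assert g.n_components == 2
        assert g.cycle_rank == 2

    def test_empty_mask_empty_graph(self):
        g = skeletonize(field_from_mask(np.zeros((32, 32), bool)))
        assert g.n_edges == 0 and g.n_nodes == 0

    def test_euler_identity_holds(self, theta, y_shape, ring):
        for f in (theta, y_shape, ring):
            g = skeletonize(f, spur_min=10)
            assert g.cycle_rank == g.n_edges - g.n_nodes + g.n_components

    def test_topology_preserved_vs_mask(self, theta, ring, bar):
        # component count of the skeleton graph matches the pixel mask's
        for f in (theta, ring, bar):
            g = skeletonize(f, spur_min=10)
            _, n_mask = label(f.values > 0, structure=np.ones((3, 3)))
            assert g.n_components == n_mask

    def test_skeletonize_idempotent_on_rasterized_output(self, theta):
        g1 = skeletonize(theta, spur_min=10)
        raster = np.zeros(theta.grid.shape, bool)
        for *_, d in g1.g.edges(data=True):
            raster[tuple(d["path"].T)] = True
        g2 = skeletonize(ScalarField(theta.grid, np.where(raster, 1.0, -1.0)),
                         spur_min=10)
        assert g2.n_edges == g1.n_edges
        assert g2.n_nodes == g1.n_nodes
        assert g2.cycle_rank == g1.cycle_rank

    def test_short_spur_pruned(self, bar):
        m = bar.values > 0
        m[45:56, 60] = True  # 11-pixel twig off the bar
        g = skeletonize(field_from_mask(m), spur_min=15)
        assert g.n_edges == 1
        assert g.cycle_rank == 0


class TestDescriptors:
    def test_branch_density_unit_conversion(self, bar):
        g = skeletonize(bar, spur_min=10)
        box = 0.375**2  # mm^2 of the standard 2D box
        assert branch_density(g, box) == pytest.approx(1 / 0.140625, rel=1e-6)

    def test_branch_density_scales_linearly_with_edges(self, theta):
        g = skeletonize(theta, spur_min=10)
        assert branch_density(g, 2.0) == pytest.approx(g.n_edges / 2.0)

    def test_empty_graph_zero_density(self):
        g = skeletonize(field_from_mask(np.zeros((32, 32), bool)))
        assert branch_density(g, 1.0) == 0.0
        assert anastomosis_density(g, 1.0) == 0.0

    def test_tree_has_zero_anastomoses(self, y_shape):
        g = skeletonize(y_shape, spur_min=10)
        assert anastomosis_density(g, 1.0) == 0.0

    def test_theta_two_loops_per_measure(self, theta):
        g = skeletonize(theta, spur_min=10)
        assert anastomosis_density(g, 0.5) == pytest.approx(4.0)

    def test_mean_diameter_of_bar(self, bar):
        g = skeletonize(bar, spur_min=10)
        assert mean_diameter(bar, g) == pytest.approx(10.0, abs=bar.grid.h)

    def test_mean_diameter_averages_two_widths(self):
        m = np.zeros((80, 140), bool)
        m[20:30, 10:130] = True  # half-width 5
        m[50:70, 10:130] = True  # half-width 10
        f = field_from_mask(m)
        g = skeletonize(f, spur_min=12)
        assert g.n_edges == 2
        assert mean_diameter(f, g) == pytest.approx(15.0, abs=1.5 * f.grid.h)

    def test_mean_diameter_empty_graph_rejected(self):
        f = field_from_mask(np.zeros((32, 32), bool))
        with pytest.raises(ValueError):
            mean_diameter(f, skeletonize(f))

    def test_edges_in_band_partitions_bar(self, bar):
        g = skeletonize(bar, spur_min=10)
        assert edges_in_band(g, 0, 40.0, 80.0) == 1
        assert edges_in_band(g, 0, 0.0, 30.0) == 0


def test_3d_cylinder_skeletonizes_to_single_edge():
    # axis placed off the voxel lattice, as any simulated field is
    g3 = Grid((24, 60, 24), 1.0)
    zz, yy, xx = np.meshgrid(*[g3.node_coords(a) for a in range(3)], indexing="ij")
    rho = np.hypot(zz - 12.3, xx - 11.8)
    f = ScalarField(g3, np.where(rho < 5.0, 1.0, -1.0))
    g = skeletonize(f, spur_min=8)
    assert g.n_components == 1
    assert g.cycle_rank == 0
    assert g.n_edges >= 1
    assert g.total_length() == pytest.approx(60.0, rel=0.25)
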