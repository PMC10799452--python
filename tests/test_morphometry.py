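"""Morphometrics: closed-form shape oracles, Euler topology, statistics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import digitized_ball
from pomecell.morphometry import (anisotropy_mil,
                                  anisotropy_object, assemble_parameter_vector,
                                  distribution_stats, euler_number,
                                  object_level, sample_level,
                                  specific_surface_area, surface_area)
from pomecell.phantom import TissueMasks


class TestEulerNumber:
    def test_solid_ball_is_contractible(self):
        assert euler_number(digitized_ball(8)) == 1

    def test_torus_has_one_tunnel(self):
        n = 41
        z, y, x = np.mgrid[:n, :n, :n]
        c = n // 2
        rho = np.sqrt((y - c) ** 2 + (x - c) ** 2)
        torus = (rho - 12) ** 2 + (z - c) ** 2 <= 16
        assert euler_number(torus) == 0

    def test_hollow_shell_has_one_cavity(self):
        shell = digitized_ball(12) & ~digitized_ball(8, pad=8)
        assert euler_number(shell) == 2

    def test_empty_mask_is_zero(self):
        assert euler_number(np.zeros((8, 8, 8), bool)) == 0


class TestSurfaceArea:
    def test_ball_ssa_matches_closed_form(self):
        # SSA of a sphere is 3/r; mesh estimate within 5% at r = 20
        r = 20
        ssa = specific_surface_area(digitized_ball(r))
        assert ssa == pytest.approx(3.0 / r, rel=0.05)

    def test_ssa_halves_at_doubled_voxel_size(self):
        ball = digitized_ball(10)
        assert specific_surface_area(ball, voxel_size=2.0) == pytest.approx(
            specific_surface_area(ball, voxel_size=1.0) / 2.0, rel=1e-6)

    def test_splitting_a_ball_increases_ssa(self):
        # two balls of half the volume have 2^(1/3) more total area
        one = digitized_ball(16)
        r_half = int(round(16 / 2 ** (1 / 3)))
        two = np.concatenate([digitized_ball(r_half), digitized_ball(r_half)])
        ssa_one = surface_area(one) / one.sum()
        ssa_two = surface_area(two) / two.sum()
        assert ssa_two > ssa_one

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            surface_area(np.zeros((5, 5, 5), bool))


class TestAnisotropy:
    def test_ball_is_isotropic(self):
        assert anisotropy_mil(digitized_ball(14)) < 0.05

    def test_ellipsoid_object_covariance(self):
        # 4:1 axis ratio -> eigenvalue ratio 16 -> 1 - 1/16 = 0.9375
        z, y, x = np.mgrid[-40:41, -12:13, -12:13]
        ell = (z / 40.0) ** 2 + (y / 10.0) ** 2 + (x / 10.0) ** 2 <= 1.0
        aniso = anisotropy_object(np.argwhere(ell))
        assert aniso == pytest.approx(1.0 - 1.0 / 16.0, rel=0.05)

    def test_mil_invariant_under_axis_rotations(self):
        z, y, x = np.mgrid[-20:21, -14:15, -14:15]
        ell = (z / 18.0) ** 2 + (y / 11.0) ** 2 + (x / 11.0) ** 2 <= 1.0
        base = anisotropy_mil(ell)
        for axes in ((1, 0, 2), (0, 2, 1)):
            assert anisotropy_mil(np.transpose(ell, axes)) == pytest.approx(
                base, abs=0.02)

    def test_coplanar_object_raises(self):
        coords = np.argwhere(np.ones((1, 10, 10), bool))
        with pytest.raises(ValueError):
            anisotropy_object(coords)


class TestObjectLevel:
    def test_ball_sphericity_near_one(self):
        labels = digitized_ball(10).astype(np.int32)
        row = object_level(labels).iloc[0]
        assert row["sphericity"] == pytest.approx(1.0, rel=0.05)

    def test_cube_sphericity_closed_form(self):
        labels = np.zeros((28, 28, 28), np.int32)
        labels[4:24, 4:24, 4:24] = 1
        row = object_level(labels).iloc[0]
        assert row["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=0.05)

    def test_esd_doubles_with_upsampling(self):
        small = digitized_ball(8).astype(np.int32)
        big = np.kron(small, np.ones((2, 2, 2), np.int32))
        esd_small = object_level(small).iloc[0]["esd"]
        esd_big = object_level(big).iloc[0]["esd"]
        assert esd_big == pytest.approx(2 * esd_small, rel=0.02)

    def test_length_at_least_width_and_border_flag(self):
        labels = np.zeros((16, 16, 16), np.int32)
        labels[0:5, 2:12, 2:6] = 1  # touches z border
        labels[8:13, 8:13, 8:13] = 2
        table = object_level(labels).set_index("label")
        assert (table["length"] >= table["width"]).all()
        assert bool(table.loc[1, "touches_border"])
        assert not bool(table.loc[2, "touches_border"])


class TestDistributionStats:
    def test_symmetric_sample_has_zero_skew(self):
        s = distribution_stats([1, 2, 3, 4, 5])
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.iqr == pytest.approx(2.0)

    def test_near_constant_sample_has_tiny_iqr(self):
        rng = np.random.default_rng(0)
        s = distribution_stats(5.0 + 1e-9 * rng.standard_normal(100))
        assert s.iqr < 1e-8

    def test_standard_normal_moments(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        s = distribution_stats(x)
        assert abs(s.skewness) < 0.05
        assert abs(s.kurtosis) < 0.05
        assert s.mode == pytest.approx(0.0, abs=0.2)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            distribution_stats([1.0, 2.0, 3.0])


class TestSampleLevel:
    def test_half_pore_volume_gives_fifty_percent_porosity(self):
        shape = (32, 32, 32)
        pore = np.zeros(shape, bool)
        pore[:16] = True
        masks = TissueMasks(cell_matrix=~pore, pore=pore,
                            stone=np.zeros(shape, bool),
                            vascular=np.zeros(shape, bool))
        cells = np.zeros(shape, np.int32)
        cells[20:28, 4:12, 4:12] = 1
        cells[20:28, 16:24, 16:24] = 2
        pores = (pore).astype(np.int32)
        sm = sample_level(masks, pores, cells, voxel_size=10.0)
        assert sm.porosity == pytest.approx(50.0)

    def test_cell_density_is_count_over_volume(self, apple_phantom):
        ph = apple_phantom
        sm = sample_level(ph.masks, ph.masks.pore.astype(np.int32),
                          ph.cell_labels, ph.config.voxel_size)
        expected = ph.cell_labels.max() / ph.config.volume_mm3
        assert sm.cell_density == pytest.approx(expected, rel=1e-6)

    def test_phantom_targets_recovered_within_ten_percent(self, apple_phantom):
        ph = apple_phantom
        sm = sample_level(ph.masks, ph.masks.pore.astype(np.int32),
                          ph.cell_labels, ph.config.voxel_size)
        assert sm.porosity == pytest.approx(
            100 * ph.config.target_porosity, rel=0.10)
        assert sm.cell_density == pytest.approx(
            ph.config.target_cell_density, rel=0.10)

    def test_volume_fractions_are_additive(self, pear_phantom):
        m = pear_phantom.masks
        total = (m.cell_matrix.sum() + m.pore.sum() + m.stone.sum()
                 + m.vascular.sum())
        assert total == m.cell_matrix.size


def test_pore_euler_number_decreases_with_channel_connectivity():
    """Opening the cell-edge channel network as one connected complex
    creates loops (tunnels), so the pore Euler number falls monotonically
    as the generator's connectivity parameter rises."""
    from pomecell.phantom import generate_phantom, pear_config

    chis = []
    for pc in (0.2, 0.6, 1.0):
        ph = generate_phantom(pear_config(seed=3, shape=(48, 48, 48),
                                          pore_connectivity=pc,
                                          stone_cell_density=0.0))
        chis.append(euler_number(ph.masks.pore))
    assert chis[0] > chis[1] > chis[2]


class TestParameterVector:
    def test_stable_schema_across_samples(self, apple_phantom, pear_phantom):
        vecs = []
        for ph in (apple_phantom, pear_phantom):
            sm = sample_level(ph.masks, ph.masks.pore.astype(np.int32),
                              ph.cell_labels, ph.config.voxel_size)
            cells = object_level(ph.cell_labels, ph.config.voxel_size)
            plab, _ = ndi.label(ph.masks.pore, np.ones((3, 3, 3)))
            pores = object_level(plab, ph.config.voxel_size)
            vecs.append(assemble_parameter_vector(sm, cells, pores))
        assert list(vecs[0].index) == list(vecs[1].index)
        assert vecs[0].index.is_unique

    def test_styles_separate_on_porosity_and_pore_ssa(self, apple_phantom,
                                                      pear_phantom):
        rows = {}
        for name, ph in (("apple", apple_phantom), ("pear", pear_phantom)):
            rows[name] = sample_level(ph.masks, ph.masks.pore.astype(np.int32),
                                      ph.cell_labels, ph.config.voxel_size)
        assert rows["apple"].porosity > rows["pear"].porosity
        assert rows["pear"].pore_ssa > rows["apple"].pore_ssa

    def test_missing_table_raises(self, apple_phantom):
        ph = apple_phantom
        sm = sample_level(ph.masks, ph.masks.pore.astype(np.int32),
                          ph.cell_labels, ph.config.voxel_size)
        with pytest.raises(ValueError, match="missing"):
            assemble_parameter_vector(sm, None, None)
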