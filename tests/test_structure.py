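"""Static observables: Voronoi densities, MIPS detection, hexatic order,
RDF, clusters, profiles, and the central/peripheral decomposition."""

import math

import numpy as np
import pytest

from activedisks import (
    Box,
    FixtureSpec,
    RadialProfile,
    classify_phases,
    cluster_center,
    cluster_components,
    cluster_shape,
    detect_mips,
    first_peak_location,
    hexatic_order,
    lattice_constant,
    local_area_fraction,
    make_box,
    make_fixture,
    minimum_image,
    radial_profile,
    rdf,
    region_boundaries,
    voronoi_areas,
    wrap_positions,
)

HEX_PHI = math.pi / (2 * math.sqrt(3))  # close-packing fraction ~ 0.9069


@pytest.fixture(scope="module")
def lattice_400():
    n = 400
    box = make_box(n, 0.65, 2 / math.sqrt(3))
    return triangular(n, box), box, lattice_constant(n, box)


def triangular(n, box):
    from activedisks import triangular_lattice_init
    return triangular_lattice_init(n, box)


class TestLocalAreaFraction:
    def test_unit_spacing_lattice_gives_close_packing_phi(self):
        # hexagonal cell of a spacing-a lattice has area (sqrt3/2) a^2
        n = 400
        box = Box(20.0, 20.0 * math.sqrt(3) / 2)
        pos = triangular(n, box)  # spacing exactly 1
        phi = local_area_fraction(pos, box)
        np.testing.assert_allclose(phi, HEX_PHI, rtol=1e-9)

    def test_voronoi_areas_tile_the_box(self, rng):
        box = Box(17.0, 13.0)
        pos = rng.uniform(0, 1, (300, 2)) * box.lengths
        areas = voronoi_areas(pos, box)
        assert areas.sum() == pytest.approx(box.area, rel=1e-6)
        assert areas.mean() == pytest.approx(box.area / 300, rel=1e-9)

    def test_overlapping_packing_exceeds_one(self):
        # soft disks may overlap: spacing < 1 means phi_i > 1
        n = 400
        box = Box(16.0, 16.0 * math.sqrt(3) / 2)  # spacing 0.8
        pos = triangular(n, box)
        phi = local_area_fraction(pos, box)
        assert np.all(phi > 1.0)
        np.testing.assert_allclose(phi, HEX_PHI / 0.8**2, rtol=1e-9)

    def test_translation_invariance_mod_box(self, rng):
        box = Box(15.0, 11.0)
        pos = rng.uniform(0, 1, (200, 2)) * box.lengths
        shifted = wrap_positions(pos + [3.7, -2.9], box)
        np.testing.assert_allclose(
            np.sort(local_area_fraction(pos, box)),
            np.sort(local_area_fraction(shifted, box)),
            rtol=1e-8,
        )

    def test_needs_at_least_four(self):
        with pytest.raises(ValueError):
            local_area_fraction(np.zeros((3, 2)), Box(5.0, 5.0))

    def test_reflection_invariance(self, rng):
        # a discrete symmetry of the box: x -> Lx - x
        box = Box(14.0, 10.0)
        pos = rng.uniform(0, 1, (150, 2)) * box.lengths
        mirrored = np.column_stack((box.Lx - pos[:, 0], pos[:, 1]))
        mirrored = wrap_positions(mirrored, box)
        np.testing.assert_allclose(
            local_area_fraction(pos, box),
            local_area_fraction(mirrored, box), rtol=1e-8)
        np.testing.assert_allclose(
            hexatic_order(pos, box), hexatic_order(mirrored, box),
            atol=1e-8)


class TestClassifyPhases:
    def test_strict_threshold(self):
        labels = classify_phases(np.array([0.66, 0.65, 0.64]), 0.65)
        np.testing.assert_array_equal(labels, [True, False, False])

    def test_uniform_field_single_label(self):
        assert not classify_phases(np.full(10, 0.5), 0.65).any()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_phases(np.array([0.5, np.nan]), 0.65)


class TestDetectMips:
    def test_single_gaussian_is_homogeneous(self, rng):
        assert not detect_mips(rng.normal(0.65, 0.05, 10**4)).is_mips

    def test_well_separated_mixture_is_mips(self, rng):
        phi = np.concatenate([rng.normal(0.3, 0.05, 5000),
                              rng.normal(1.1, 0.05, 5000)])
        res = detect_mips(phi)
        assert res.is_mips
        assert np.any(np.abs(res.peaks - 0.3) < 0.06)
        assert np.any(np.abs(res.peaks - 1.1) < 0.06)

    def test_false_positive_rate_on_unimodal_samples(self):
        # <= 5% over 100 unimodal draws of N = 1e4
        rng = np.random.default_rng(42)
        fp = sum(
            detect_mips(rng.normal(0.65, 0.08, 10**4)).is_mips
            for _ in range(100)
        )
        assert fp <= 5

    def test_power_on_separated_mixtures(self):
        # >= 95% on mixtures separated by >= 6 pooled standard deviations
        rng = np.random.default_rng(43)
        hits = 0
        for _ in range(100):
            sd = 0.05
            mu1 = rng.uniform(0.2, 0.5)
            mu2 = mu1 + 6 * sd * math.sqrt(2)
            phi = np.concatenate([rng.normal(mu1, sd, 5000),
                                  rng.normal(mu2, sd, 5000)])
            hits += detect_mips(phi).is_mips
        assert hits >= 95

    def test_two_phase_slab_fixture_detected(self, rng):
        box = make_box(3000, 0.5, 1.0)
        st = make_fixture(FixtureSpec(kind="two_phase_slab"), box, rng)
        assert detect_mips(local_area_fraction(st.pos, box)).is_mips


class TestHexaticOrder:
    def test_perfect_triangular_lattice_is_one(self):
        n = 400
        box = make_box(n, 0.65, 2 / math.sqrt(3))
        q6 = hexatic_order(triangular(n, box), box)
        np.testing.assert_allclose(q6, 1.0, atol=1e-9)

    def test_square_lattice_below_one(self):
        # 4 side neighbors + 2 tie-broken diagonals cannot align 6-fold
        n = 256
        box = Box(16.0, 16.0)
        ix, iy = np.meshgrid(np.arange(16), np.arange(16))
        pos = np.column_stack((ix.ravel() + 0.5, iy.ravel() + 0.5))
        q6 = hexatic_order(pos, box)
        assert np.all(q6 < 1.0)

    def test_random_gas_mean_below_three_quarters(self, rng):
        box = Box(110.0, 95.0)
        pos = rng.uniform(0, 1, (10**4, 2)) * box.lengths
        assert hexatic_order(pos, box).mean() < 0.75

    def test_too_few_particles_raises(self):
        with pytest.raises(ValueError):
            hexatic_order(np.zeros((5, 2)), Box(5.0, 5.0))


class TestRdf:
    def test_ideal_gas_flat_beyond_contact(self, rng):
        box = Box(60.0, 60.0)
        n = 4000
        pos = rng.uniform(0, 1, (n, 2)) * box.lengths
        g = rdf(pos, box, r_max=25.0, dr=0.25)
        sel = g.bin_centers > 2.0
        # 3-sigma Poisson bands on the per-bin pair counts
        expect = g.counts[sel] / np.maximum(g.values[sel], 1e-12)
        sigma = 3.0 / np.sqrt(np.maximum(expect, 1.0))
        assert np.all(np.abs(g.values[sel] - 1.0) <= sigma + 0.02)

    def test_lattice_peaks_at_shell_distances(self):
        n = 1024
        box = make_box(n, 0.65, 2 / math.sqrt(3))
        pos = triangular(n, box)
        a = lattice_constant(n, box)
        g = rdf(pos, box, r_max=2.5 * a, dr=0.02)
        for shell in (a, math.sqrt(3) * a, 2 * a):
            near = np.abs(g.bin_centers - shell) <= 0.03
            assert g.values[near].max() > 5.0

    def test_first_peak_of_lattice(self):
        n = 400
        box = Box(18.0, 18.0 * math.sqrt(3) / 2)  # spacing 0.9
        pos = triangular(n, box)
        g = rdf(pos, box, r_max=4.0, dr=0.05)
        assert first_peak_location(g) == pytest.approx(0.9, abs=0.05)

    def test_monotone_curve_has_no_peak(self):
        g = RadialProfile(
            bin_centers=np.linspace(0.1, 5, 50),
            values=np.linspace(2.0, 0.0, 50),
            counts=np.ones(50, dtype=int),
            dr=0.1,
        )
        with pytest.raises(ValueError):
            first_peak_location(g)

    def test_r_max_beyond_half_box_rejected(self, rng):
        box = Box(20.0, 20.0)
        pos = rng.uniform(0, 1, (200, 2)) * box.lengths
        with pytest.raises(ValueError):
            rdf(pos, box, r_max=11.0)


class TestClusters:
    def test_two_phase_disk_one_big_cluster(self, rng):
        box = make_box(3000, 0.5, 1.0)
        st = make_fixture(FixtureSpec(kind="two_phase_disk"), box, rng)
        phi_i = local_area_fraction(st.pos, box)
        labels = classify_phases(phi_i, 0.5)
        clusters = cluster_components(st.pos, box, labels)
        r = (FixtureSpec(kind="two_phase_disk").region_size
             or 0.3 * min(box.Lx, box.Ly))
        inside = np.hypot(*(st.pos - 0.5 * box.lengths).T) <= r - 1.5
        covered = np.isin(np.flatnonzero(inside), clusters[0])
        assert covered.mean() >= 0.95

    def test_no_dense_particles_empty_list(self, rng):
        box = Box(20.0, 20.0)
        pos = rng.uniform(0, 1, (100, 2)) * box.lengths
        assert cluster_components(pos, box, np.zeros(100, bool)) == []

    def test_lattice_is_single_cluster(self):
        n = 100
        box = make_box(n, 0.65, 2 / math.sqrt(3))
        pos = triangular(n, box)
        clusters = cluster_components(pos, box, np.ones(n, bool),
                                      r_link=1.2 * lattice_constant(n, box))
        assert len(clusters) == 1
        assert len(clusters[0]) == n

    def test_center_of_wrapping_blob(self, rng):
        # compact blob across a box corner: center must sit in the blob
        box = Box(30.0, 30.0)
        blob = rng.normal(0.0, 1.5, (200, 2))  # centered at the corner
        pos = wrap_positions(blob, box)
        c = cluster_center(np.arange(200), pos, box)
        d = minimum_image(c - np.zeros(2), box)
        assert np.hypot(*d) < 1.0

    def test_center_single_particle(self):
        box = Box(10.0, 10.0)
        pos = np.array([[3.3, 7.7]])
        np.testing.assert_allclose(
            cluster_center(np.array([0]), pos, box), [3.3, 7.7], atol=1e-9)

    def test_center_translation_equivariance(self, rng):
        box = Box(25.0, 19.0)
        pos = wrap_positions(rng.normal([5.0, 5.0], 2.0, (150, 2)), box)
        c0 = cluster_center(np.arange(150), pos, box)
        shift = np.array([11.3, 7.9])
        c1 = cluster_center(np.arange(150),
                            wrap_positions(pos + shift, box), box)
        d = minimum_image(c1 - (c0 + shift), box)
        assert np.hypot(*d) < 1e-6

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            cluster_center(np.array([], dtype=int), np.zeros((5, 2)),
                           Box(5.0, 5.0))


class TestClusterShape:
    def test_disk_blob_is_circular(self, rng):
        box = Box(60.0, 60.0)
        ang = rng.uniform(0, 2 * math.pi, 400)
        rad = 8.0 * np.sqrt(rng.uniform(0, 1, 400))
        pos = 30.0 + np.column_stack((rad * np.cos(ang), rad * np.sin(ang)))
        cls, aspect = cluster_shape(np.arange(400), pos, box)
        assert cls == "circular"
        assert aspect == pytest.approx(1.0, abs=0.2)

    def test_band_spanning_x_is_slab(self, rng):
        box = Box(40.0, 40.0)
        x = rng.uniform(0, 40.0, 600)
        y = rng.uniform(17.0, 23.0, 600)
        cls, _ = cluster_shape(np.arange(600), np.column_stack((x, y)), box)
        assert cls == "slab"

    def test_ellipse_aspect_recovered(self, rng):
        box = Box(80.0, 80.0)
        ang = rng.uniform(0, 2 * math.pi, 2000)
        rad = np.sqrt(rng.uniform(0, 1, 2000))
        pos = 40.0 + np.column_stack((12.0 * rad * np.cos(ang),
                                      4.0 * rad * np.sin(ang)))
        _, aspect = cluster_shape(np.arange(2000), pos, box)
        assert aspect == pytest.approx(3.0, rel=0.1)


class TestProfilesAndRegions:
    def test_constant_field_flat_profile(self, rng):
        box = Box(30.0, 30.0)
        pos = rng.uniform(0, 1, (2000, 2)) * box.lengths
        prof = radial_profile(np.full(2000, 1.3), pos,
                              np.array([15.0, 15.0]), box, dr=1.0)
        occ = prof.counts > 0
        np.testing.assert_allclose(prof.values[occ], 1.3, rtol=1e-12)

    def test_distance_field_reproduces_bin_centers(self, rng):
        box = Box(30.0, 30.0)
        pos = rng.uniform(0, 1, (20000, 2)) * box.lengths
        center = np.array([15.0, 15.0])
        d = minimum_image(pos - center, box)
        r = np.hypot(d[:, 0], d[:, 1])
        prof = radial_profile(r, pos, center, box, dr=1.0)
        occ = (prof.counts > 20) & (prof.bin_centers < 14)
        np.testing.assert_allclose(prof.values[occ],
                                   prof.bin_centers[occ], atol=0.35)

    def test_step_profile_boundaries_recovered(self):
        # plateau 1.2 for r < 40, ramp to 0.2 over [40, 60]
        r = np.arange(1.0, 100.0, 2.0)
        v = np.where(r < 40, 1.2,
                     np.where(r > 60, 0.2, 1.2 - (r - 40) * 0.05))
        prof = RadialProfile(r, v, np.full(len(r), 50), 2.0)
        b = region_boundaries(prof, dilute_value=0.2)
        assert b.determinate
        assert b.r1 == pytest.approx(40.0, abs=2.0)
        assert b.r2 == pytest.approx(60.0, abs=2.0)
        assert b.r_p == pytest.approx(20.0, abs=3.0)

    def test_flat_profile_indeterminate(self):
        r = np.arange(1.0, 50.0, 1.0)
        prof = RadialProfile(r, np.full(len(r), 0.8),
                             np.full(len(r), 30), 1.0)
        assert not region_boundaries(prof, dilute_value=0.8).determinate
        # flat at plateau != dilute: never decays -> also indeterminate
        assert not region_boundaries(prof, dilute_value=0.2).determinate

    def test_two_phase_disk_profile_plateau_then_decay(self, rng):
        box = make_box(3000, 0.5, 1.0)
        st = make_fixture(
            FixtureSpec(kind="two_phase_disk", phi_dense=1.0,
                        phi_dilute=0.1), box, rng)
        phi_i = local_area_fraction(st.pos, box)
        labels = classify_phases(phi_i, 0.5)
        clusters = cluster_components(st.pos, box, labels)
        c = cluster_center(clusters[0], st.pos, box)
        prof = radial_profile(phi_i, st.pos, c, box, dr=2.0)
        b = region_boundaries(prof, float(np.mean(phi_i[~labels])))
        assert b.determinate
        assert b.plateau == pytest.approx(1.0, rel=0.05)
        r_disk = 0.3 * min(box.Lx, box.Ly)
        assert b.r1 <= r_disk <= b.r2
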