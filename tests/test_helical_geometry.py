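"""Lattice geometry, reference synthesis, and projections."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mtpipe import helical_geometry as hg


class TestHelicalTable:
    @pytest.mark.parametrize("pf,start,rise,twist", [
        (11, 3, 11.1, -32.5),
        (12, 3, 10.2, -29.9),
        (13, 3, 9.4, -27.7),
        (14, 3, 8.7, -25.8),
        (15, 4, 10.8, -23.8),
        (16, 4, 10.2, -22.4),
    ])
    def test_tabulated_constants(self, pf, start, rise, twist):
        p = hg.helical_table(pf, start)
        assert p.rise == rise
        assert p.twist == twist
        assert p.dimer_repeat == 2 * p.monomer_repeat

    def test_refinement_values(self):
        p13 = hg.helical_table(13, 3)
        assert (p13.refine_twist, p13.refine_rise) == (-27.67, 9.46)
        p14 = hg.helical_table(14, 3)
        assert (p14.refine_twist, p14.refine_rise) == (-25.71, 8.81)

    def test_unsupported_architecture(self):
        with pytest.raises(ValueError, match="supported"):
            hg.helical_table(10, 3)


class TestBuildLattice:
    def test_monomer_count_13pf_246A(self, params13):
        lat = hg.build_lattice(params13, 246.0)
        assert lat.n_monomers == 13 * 6 == 78

    def test_seam_count_by_start_parity(self, params13, params16):
        lat13 = hg.build_lattice(params13, 246.0)
        lat16 = hg.build_lattice(params16, 246.0)
        assert hg.count_heterotypic_interfaces(lat13) == 1
        assert hg.count_heterotypic_interfaces(lat16) == 0

    def test_seam_for_even_start_is_error(self, params16):
        with pytest.raises(ValueError, match="no seam"):
            hg.build_lattice(params16, 246.0, seam_pf=0)

    def test_too_short_lattice(self, params13):
        with pytest.raises(ValueError, match="dimer repeat"):
            hg.build_lattice(params13, 50.0)

    def test_helical_operation_maps_monomers_onto_lattice(self, params13):
        """(twist, rise) maps monomer positions onto themselves away from
        the seam/edges, to within a voxel."""
        lat = hg.build_lattice(params13, 500.0)
        moved = hg.transform_lattice(lat, params13.twist, params13.rise)
        zmax = lat.positions[:, 2].max()
        # the wrap protofilament maps S monomer layers up: exclude that edge
        margin = params13.start_number * params13.monomer_repeat + 10.0
        interior = moved.positions[moved.positions[:, 2] < zmax - margin]
        d, _ = cKDTree(lat.positions).query(interior)
        assert d.max() < 5.56

    def test_even_start_symmetry_includes_identity_pattern(self, params16):
        """For even S the helical operation is a symmetry of the decorated,
        identity-labelled lattice, not just of the positions."""
        lat = hg.build_lattice(params16, 500.0)
        moved = hg.transform_lattice(lat, params16.twist, params16.rise)
        zmax = lat.positions[:, 2].max()
        margin = params16.start_number * params16.monomer_repeat + 10.0
        keep = moved.positions[:, 2] < zmax - margin
        d, idx = cKDTree(lat.positions).query(moved.positions[keep])
        assert d.max() < 5.56
        assert np.array_equal(lat.identity[idx], moved.identity[keep])

    def test_odd_start_identity_pattern_broken_at_seam(self, params13):
        lat = hg.build_lattice(params13, 500.0)
        moved = hg.transform_lattice(lat, params13.twist, params13.rise)
        zmax = lat.positions[:, 2].max()
        keep = moved.positions[:, 2] < zmax - 52.0
        d, idx = cKDTree(lat.positions).query(moved.positions[keep])
        mismatch = lat.identity[idx] != moved.identity[keep]
        # wrap of the last PF onto the first flips alpha/beta (odd start)
        assert mismatch.any()


class TestSynthesizeVolume:
    def test_decorator_only_of_undecorated_is_zero(self, params13):
        lat = hg.build_lattice(params13, 246.0, decorated=False, seam_pf=0)
        vol = hg.synthesize_volume(lat, 7.0, mode="decorator_only", box_px=48)
        assert np.allclose(vol.data, 0.0)

    def test_mass_proportional_to_monomer_count(self, params13):
        a = hg.build_lattice(params13, 246.0, decorated=False, seam_pf=0)
        b = hg.build_lattice(params13, 492.0, decorated=False, seam_pf=0)
        assert 2 * a.n_monomers == b.n_monomers
        va = hg.synthesize_volume(a, 7.0, box_px=96)
        vb = hg.synthesize_volume(b, 7.0, box_px=96)
        ratio = vb.data.sum() / va.data.sum()
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_lowpass_kills_high_frequencies(self, params13):
        lat = hg.build_lattice(params13, 246.0, seam_pf=0)
        vol = hg.synthesize_volume(lat, 7.0, lowpass=15.0, box_px=48)
        ft = np.abs(np.fft.rfftn(vol.data))
        fz = np.fft.fftfreq(48, d=7.0)
        fy = np.fft.fftfreq(48, d=7.0)
        fx = np.fft.rfftfreq(48, d=7.0)
        f2 = (fz[:, None, None] ** 2 + fy[None, :, None] ** 2
              + fx[None, None, :] ** 2)
        beyond = ft[f2 > (1 / 15.0) ** 2]
        assert beyond.max() <= 1e-6 * ft.max()

    def test_nyquist_violation(self, params13):
        lat = hg.build_lattice(params13, 246.0, seam_pf=0)
        with pytest.raises(ValueError, match="Nyquist"):
            hg.synthesize_volume(lat, 10.0, lowpass=15.0)


class TestEnumerateSeamReferences:
    def test_13pf_has_26_references(self, params13, lattice13):
        refs = hg.enumerate_seam_references(lattice13, params13)
        assert len(refs) == 26
        ks = sorted({k for k, _, _ in refs})
        assert ks == list(range(-6, 7))
        assert sorted({r for _, r, _ in refs}) == [0, 1]

    def test_14pf_has_28_references(self):
        p = hg.helical_table(14, 3)
        base = hg.build_lattice(p, 500.0, seam_pf=0)
        assert len(hg.enumerate_seam_references(base, p)) == 28

    def test_identity_reference_equals_base(self, params13, lattice13):
        refs = hg.enumerate_seam_references(lattice13, params13)
        k0 = next(lat for k, reg, lat in refs if k == 0 and reg == 0)
        np.testing.assert_allclose(k0.positions, lattice13.positions)
        np.testing.assert_allclose(k0.decorators, lattice13.decorators)

    def test_even_start_rejected(self, params16):
        base = hg.build_lattice(params16, 500.0)
        with pytest.raises(ValueError, match="even start"):
            hg.enumerate_seam_references(base, params16)

    def test_references_pairwise_distinct(self, params13, lattice13):
        """Distinct decorator-only references never correlate perfectly."""
        refs = hg.enumerate_seam_references(lattice13, params13)
        imgs = []
        for k, reg, lat in refs[:6] + refs[13:16]:
            im = hg.project_lattice(lat, 0, 90, 0, pixel_size=5.56,
                                    box_px=108, mode="decorator_only").data
            imgs.append(im - im.mean())
        for i in range(len(imgs)):
            for j in range(i + 1, len(imgs)):
                ncc = (imgs[i] * imgs[j]).sum() / (
                    np.linalg.norm(imgs[i]) * np.linalg.norm(imgs[j]))
                assert ncc < 1.0 - 1e-6


class TestProjection:
    def test_shift_theorem(self, lattice13_bare):
        vol = hg.synthesize_volume(
            hg.build_lattice(hg.helical_table(13, 3), 246.0, decorated=False,
                             seam_pf=0), 7.0, box_px=48)
        base = hg.project(vol, 20.0, 90.0, 0.0, 0.0, 0.0)
        shifted = hg.project(vol, 20.0, 90.0, 0.0, 14.0, 0.0)
        # shifting by +14 Å = +2 px along x
        np.testing.assert_allclose(shifted.data[:, 2:], base.data[:, :-2],
                                   atol=1e-8 * np.abs(base.data).max() + 1e-12)

    def test_rot_periodicity(self, params13):
        vol = hg.synthesize_volume(
            hg.build_lattice(params13, 246.0, seam_pf=0), 7.0, box_px=48)
        a = hg.project(vol, 33.0, 90.0, 10.0)
        b = hg.project(vol, 33.0 + 360.0, 90.0, 10.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_projection_linear_in_volume(self, params13):
        vol = hg.synthesize_volume(
            hg.build_lattice(params13, 246.0, seam_pf=0), 7.0, box_px=48)
        doubled = hg.ReferenceVolume(2.0 * vol.data, vol.voxel_size)
        a = hg.project(vol, 15.0, 90.0, 5.0)
        b = hg.project(doubled, 15.0, 90.0, 5.0)
        np.testing.assert_allclose(b.data, 2.0 * a.data, rtol=1e-10)

    def test_grid_and_analytic_projectors_agree(self, params13):
        """The voxel-grid projector and the analytic Gaussian projector
        image the same lattice the same way (interpolation-limited)."""
        lat = hg.build_lattice(params13, 492.0, seam_pf=0)
        vol = hg.synthesize_volume(lat, 5.56, box_px=108)
        for angles in [(0, 90, 0, 0, 0), (33, 90, 20, 5, -3)]:
            pg = hg.project(vol, *angles).data
            pa = hg.project_lattice(lat, *angles, pixel_size=5.56,
                                    box_px=108).data
            a, b = pg - pg.mean(), pa - pa.mean()
            ncc = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            assert ncc > 0.98

    def test_nonfinite_angle_rejected(self, params13):
        vol = hg.synthesize_volume(
            hg.build_lattice(params13, 246.0, seam_pf=0), 7.0, box_px=48)
        with pytest.raises(ValueError, match="finite"):
            hg.project(vol, np.nan, 90.0, 0.0)


def test_mrc_round_trip(tmp_path, params13):
    vol = hg.synthesize_volume(
        hg.build_lattice(params13, 246.0, seam_pf=0), 7.0, box_px=32)
    path = tmp_path / "v.mrc"
    hg.write_mrc(path, vol.data, 7.0)
    back, voxel = hg.read_mrc(path)
    assert voxel == pytest.approx(7.0)
    np.testing.assert_allclose(back, vol.data, atol=1e-6 * np.abs(vol.data).max())
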