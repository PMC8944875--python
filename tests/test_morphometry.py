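"""Trabecular morphometry indices validated on analytic phantoms."""
import numpy as np
import pytest
from scipy import ndimage

from carposim import microct_morphometry as mm
from carposim.errors import InputError
from carposim.synthetic_data import phantom

VX = 17.5  # um


class TestBVTV:
    def test_full_and_empty_volumes(self):
        full = mm.VoxelVolume(np.ones((10, 10, 10), bool), VX)
        empty = mm.VoxelVolume(np.zeros((10, 10, 10), bool), VX)
        assert mm.bvtv(full) == 100.0
        assert mm.bvtv(empty) == 0.0

    def test_sphere_matches_analytic_volume(self):
        ph = phantom("sphere", {"size": 32, "radius": 12})
        assert mm.bvtv(ph) == pytest.approx(ph.metadata["BVTV_ref_percent"], abs=1.0)
        assert ph.metadata["BVTV_ref_percent"] == pytest.approx(22.1, abs=0.1)

    def test_empty_voi_mask_rejected(self):
        vol = mm.VoxelVolume(np.ones((4, 4, 4), bool), VX)
        with pytest.raises(InputError):
            mm.bvtv(vol, mask=np.zeros((4, 4, 4), bool))


class TestLocalThickness:
    def test_periodic_plate_thickness_and_separation(self):
        # 8-voxel plates with 24-voxel gaps, tiling the volume periodically
        ph = phantom("plate", {"size": 64, "thickness": 8, "gap": 24})
        tbth, tbsp = mm.tbth_tbsp(ph, periodic=True)
        assert tbth == pytest.approx(ph.metadata["TbTh_ref_um"], abs=VX)  # 140 um
        assert tbsp == pytest.approx(ph.metadata["TbSp_ref_um"], abs=VX)  # 420 um

    def test_rod_diameter_recovered(self):
        ph = phantom("rod", {"size": 33, "diameter": 12})
        tbth, _ = mm.tbth_tbsp(ph)
        assert tbth == pytest.approx(12 * VX, abs=VX)

    @pytest.mark.parametrize("shape,params", [("rod", {"size": 24, "diameter": 10}), ("sphere", {"size": 24, "radius": 9})])
    def test_matches_brute_force_sphere_marking(self, shape, params):
        """Naive largest-inscribed-sphere painting agrees exactly on <= 32^3."""
        ph = phantom(shape, params)
        fast = mm.local_thickness(ph)
        data = ph.data
        dist = ndimage.distance_transform_edt(data)
        brute = np.zeros(data.shape)
        idx = np.argwhere(data)
        grid = np.indices(data.shape).reshape(3, -1).T
        for c in idx:
            r = dist[tuple(c)]
            covered = ((grid - c) ** 2).sum(axis=1) <= r * r + 1e-9
            sel = tuple(grid[covered].T)
            brute[sel] = np.maximum(brute[sel], 2 * r)
        brute = np.where(data, brute, 0.0) * ph.voxel_size
        assert np.allclose(fast, brute, atol=1e-6)


class TestTbN:
    @pytest.mark.parametrize(
        "bvtv_pct,tbth_um,expect",
        [
            (35.4, 199.89, 1.77),  # printed VOI Area 1 triplet
            (40.76, 309.44, 1.32),  # printed Total-VOI triplet
            (51.52, 334.81, 1.54),
        ],
    )
    def test_plate_model_relation_reproduces_printed_triplets(self, bvtv_pct, tbth_um, expect):
        assert round(mm.tbn(bvtv_pct, tbth_um), 2) == expect

    def test_empty_bone_gives_zero(self):
        assert mm.tbn(0.0, 100.0) == 0.0


class TestTbPf:
    def test_convex_structure_is_positive(self):
        assert mm.tbpf(phantom("sphere", {"size": 40, "radius": 12})) > 0.0

    def test_concave_structure_is_negative(self):
        ph = phantom("sphere", {"size": 40, "radius": 12})
        void = mm.VoxelVolume(~ph.data, ph.voxel_size)
        assert mm.tbpf(void) < 0.0


class TestSMI:
    def test_plate_rod_sphere_limits(self):
        assert mm.smi(phantom("plate", {"size": 48, "thickness": 8, "gap": 40})) == pytest.approx(0.0, abs=0.2)
        assert mm.smi(phantom("rod", {"size": 49, "diameter": 14})) == pytest.approx(3.0, abs=0.3)
        assert mm.smi(phantom("sphere", {"size": 48, "radius": 16})) == pytest.approx(4.0, abs=0.3)

    @pytest.mark.parametrize("angle", [15.0, 30.0, 45.0, 60.0, 75.0])
    def test_sphere_limit_is_orientation_independent(self, angle):
        ph = phantom("sphere", {"size": 48, "radius": 16})
        rot = ndimage.rotate(ph.data.astype(float), angle, axes=(0, 2), order=1, reshape=False) > 0.5
        assert mm.smi(mm.VoxelVolume(rot, VX)) == pytest.approx(4.0, abs=0.3)

    def test_plate_limit_under_rotation(self):
        ph = phantom("plate", {"size": 48, "thickness": 8, "gap": 40})
        rot = ndimage.rotate(ph.data.astype(float), 30.0, axes=(0, 2), order=1, reshape=False) > 0.5
        assert mm.smi(mm.VoxelVolume(rot, VX)) == pytest.approx(0.0, abs=0.2)

    def test_empty_phase_rejected(self):
        with pytest.raises(InputError):
            mm.smi(mm.VoxelVolume(np.zeros((8, 8, 8), bool), VX))


class TestDegreeOfAnisotropy:
    def test_isotropic_sphere_packing_is_near_zero(self):
        vals = [mm.degree_of_anisotropy(phantom("isotropic_spheres", {"size": 64}, seed=s)) for s in range(10)]
        assert max(vals) < 0.15

    def test_parallel_plates_are_strongly_anisotropic(self):
        assert mm.degree_of_anisotropy(phantom("plate", {"size": 64})) > 0.6

    def test_rotation_by_90_degrees_preserves_da(self):
        ph = phantom("isotropic_spheres", {"size": 64}, seed=3)
        da0 = mm.degree_of_anisotropy(ph)
        rot = mm.VoxelVolume(np.rot90(ph.data, axes=(0, 2)).copy(), VX)
        assert mm.degree_of_anisotropy(rot) == pytest.approx(da0, abs=0.02)
        pl = phantom("plate", {"size": 64})
        da_pl = mm.degree_of_anisotropy(pl)
        rot_pl = mm.VoxelVolume(np.rot90(pl.data, axes=(1, 2)).copy(), VX)
        assert mm.degree_of_anisotropy(rot_pl) == pytest.approx(da_pl, abs=0.02)

    def test_da_always_in_unit_interval(self):
        for s in range(3):
            da = mm.degree_of_anisotropy(phantom("isotropic_spheres", {"size": 48, "n_spheres": 20}, seed=s))
            assert 0.0 <= da <= 1.0


class TestCartilageThickness:
    def test_uniform_layer(self):
        ph = phantom("cartilage_layer", {"size": 48, "thickness": 17})
        mean, lo, hi = mm.cartilage_thickness(ph)
        ref = ph.metadata["CTh_ref_um"]
        assert mean == pytest.approx(ref, abs=VX)
        assert lo == pytest.approx(ref, abs=VX)
        assert hi == pytest.approx(ref, abs=VX)

    def test_wedge_extremes(self):
        # gentle slope: the inscribed-sphere thickness at the thin end is not
        # contaminated by the thicker neighbourhood
        ph = phantom("wedge_layer", {"size": 80, "t0": 6, "t1": 18})
        _, lo, hi = mm.cartilage_thickness(ph)
        assert lo == pytest.approx(6 * VX, abs=VX)
        assert hi == pytest.approx(18 * VX, abs=VX)

    def test_wedge_thickness_map_drives_contact_onset(self):
        """A spatially varying C.Th map shifts which faces make contact."""
        from carposim.contact import ContactPair, detect_penetration
        from carposim.geometry import make_radiocarpal_geometry
        from carposim.rigid import Pose

        rad, carp = make_radiocarpal_geometry(cartilage_gap=1.0e-3, resolution=8)
        n_faces = len(rad[2].mesh.faces)
        # wedge-derived map: thin on the palmar half, thick on the dorsal half
        ph = phantom("wedge_layer", {"size": 64, "t0": 20, "t1": 44, "voxel_size_um": 25.0})
        th = mm.local_thickness(ph)
        lo, hi = float(th[ph.data].min()) * 1e-6, float(th[ph.data].max()) * 1e-6
        centroids = rad[2].mesh.triangles_center
        cth_map = np.where(centroids[:, 0] > 0, hi, lo)
        pair = ContactPair(id="Ra_Cu", surfA=rad[2], surfB=carp[2], stiffness=1e7, cth=cth_map)
        hits = detect_penetration(pair, Pose.identity(), Pose.identity())
        assert hits  # thick-cartilage side engages at the rest separation
        assert all(centroids[f, 0] > 0 for f, _, _, _ in hits)


def test_resolution_consistency_on_phantoms():
    """Halving the voxel size changes BV/TV, Tb.Th, Tb.Sp by < 2 %."""
    coarse = phantom("plate", {"size": 64, "thickness": 8, "gap": 24, "voxel_size_um": 17.5})
    fine = phantom("plate", {"size": 128, "thickness": 16, "gap": 48, "voxel_size_um": 8.75})
    b0, b1 = mm.bvtv(coarse), mm.bvtv(fine)
    assert b1 == pytest.approx(b0, rel=0.02)
    th0, sp0 = mm.tbth_tbsp(coarse, periodic=True)
    th1, sp1 = mm.tbth_tbsp(fine, periodic=True)
    assert th1 == pytest.approx(th0, rel=0.02)
    assert sp1 == pytest.approx(sp0, rel=0.02)


def test_analyze_bundles_all_indices():
    ph = phantom("plate", {"size": 48, "thickness": 8, "gap": 24})
    cart = phantom("cartilage_layer", {"size": 32, "thickness": 12})
    res = mm.analyze(ph, cartilage=cart)
    assert 0 <= res.BVTV <= 100
    assert res.TbN == pytest.approx(10.0 * res.BVTV / res.TbTh, rel=1e-9)
    assert res.CTh_min <= res.CTh_mean <= res.CTh_max


def test_volume_io_roundtrip(tmp_path):
    ph = phantom("sphere", {"size": 24, "radius": 8})
    raw = tmp_path / "vol.bin"
    mm.write_volume(ph, raw)
    back = mm.read_volume(raw)
    assert np.array_equal(back.data, ph.data)
    assert back.voxel_size == ph.voxel_size
    nii = tmp_path / "vol.nii"
    mm.write_volume(ph, nii)
    back2 = mm.read_volume(nii)
    assert np.array_equal(back2.data, ph.data)
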