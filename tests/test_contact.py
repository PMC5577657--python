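import math

import numpy as np
import pytest

import oracles
from seedcontact import compute_contact, dilate_mask, surface_area, surface_faces
from seedcontact.contact import count_surface_faces
from conftest import make_sphere


class TestDilate:
    def test_single_voxel_neighbourhoods(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[3, 3, 3] = True
        assert dilate_mask(m, 1, connectivity=26).sum() == 27
        assert dilate_mask(m, 1, connectivity=6).sum() == 7
        assert dilate_mask(m, 1, connectivity=18).sum() == 19

    def test_matches_brute_force_expansion(self, rng):
        for _ in range(10):
            seed, _ = oracles.random_scene(rng)
            for conn in (6, 18, 26):
                got = dilate_mask(seed, 2, connectivity=conn)
                np.testing.assert_array_equal(got, oracles.brute_dilate(seed, 2, conn))

    def test_input_unmodified_and_clipped(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = True
        before = m.copy()
        out = dilate_mask(m, 5, connectivity=26)
        np.testing.assert_array_equal(m, before)
        assert out.shape == m.shape and out.all()

    def test_bad_steps(self):
        m = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="steps"):
            dilate_mask(m, 0)

    def test_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            dilate_mask(np.zeros((2, 2, 2), dtype=bool), 1)


class TestSurfaceFaces:
    def test_single_voxel_cube(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert len(surface_faces(m)) == 6

    def test_2x2x2_block(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        assert len(surface_faces(m)) == 24

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            mask = rng.random((9, 9, 9)) < 0.3
            mask[4, 4, 4] = True
            got = {tuple(int(v) for v in row) for row in surface_faces(mask)}
            assert got == oracles.brute_surface_faces(mask)

    def test_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            surface_faces(np.zeros((2, 2, 2), dtype=bool))


class TestSurfaceArea:
    def test_single_voxel_closed_form(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert surface_area(m, 20.0) == pytest.approx(6 * 0.02**2)

    def test_block_closed_form(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        assert surface_area(m, 20.0) == pytest.approx(24 * 0.0004)

    def test_sphere_estimators(self, sphere25):
        """Mesh area tracks the analytic sphere area within 3%; the face
        count carries the known ~1.5x voxelisation bias."""
        true_area = 4 * math.pi * (25 * 0.02) ** 2
        mesh = surface_area(sphere25, 20.0, method="mesh")
        face = surface_area(sphere25, 20.0, method="face_count")
        assert mesh == pytest.approx(true_area, rel=0.03)
        assert face / true_area == pytest.approx(1.5, rel=0.05)

    def test_unknown_method(self, sphere25):
        with pytest.raises(ValueError, match="unknown"):
            surface_area(sphere25, 20.0, method="nope")


class TestComputeContact:
    def test_fully_embedded_sphere(self):
        sphere = make_sphere(8)
        res = compute_contact(sphere, ~sphere, 20.0)
        assert res.contact_pct == 100.0
        assert res.contact_face_count == res.surface_face_count

    def test_sphere_in_vacuum(self):
        sphere = make_sphere(8)
        res = compute_contact(sphere, np.zeros_like(sphere), 20.0)
        assert res.contact_pct == 0.0
        assert res.contact_area_mm2 == 0.0

    def test_half_space_soil_is_half_contact(self):
        sphere = make_sphere(25, margin=4)
        c = sphere.shape[0] // 2
        zz = np.arange(sphere.shape[0])[:, None, None]
        soil = (zz >= c) & ~sphere
        res = compute_contact(sphere, np.broadcast_to(soil, sphere.shape), 20.0)
        assert res.contact_pct == pytest.approx(50.0, abs=3.0)

    def test_overlap_rejected(self):
        sphere = make_sphere(5)
        with pytest.raises(ValueError, match="overlap"):
            compute_contact(sphere, sphere, 20.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            compute_contact(
                np.ones((3, 3, 3), dtype=bool), np.zeros((4, 4, 4), dtype=bool), 20.0
            )

    def test_matches_brute_force_classification(self, rng):
        for _ in range(15):
            seed, soil = oracles.random_scene(rng, max_side=14)
            for conn in (6, 26):
                res = compute_contact(seed, soil, 20.0, connectivity=conn)
                assert res.contact_face_count == oracles.brute_contact_faces(seed, soil, conn)
                assert res.surface_face_count == len(oracles.brute_surface_faces(seed))


class TestContactProperties:
    def test_soil_monotonicity(self, rng):
        """Adding soil voxels never decreases the contact percentage."""
        seed, soil = oracles.random_scene(rng, max_side=16)
        base = compute_contact(seed, soil, 20.0).contact_pct
        more = soil | ((rng.random(soil.shape) < 0.2) & ~seed)
        assert compute_contact(seed, more, 20.0).contact_pct >= base
        fewer = soil & (rng.random(soil.shape) < 0.5)
        assert compute_contact(seed, fewer, 20.0).contact_pct <= base

    def test_translation_invariance(self, rng):
        seed, soil = oracles.random_scene(rng, max_side=12)
        pad = 6
        big_seed = np.pad(seed, pad)
        big_soil = np.pad(soil, pad)
        ref = compute_contact(big_seed, big_soil, 20.0)
        shifted = compute_contact(
            np.roll(big_seed, (2, -1, 3), axis=(0, 1, 2)),
            np.roll(big_soil, (2, -1, 3), axis=(0, 1, 2)),
            20.0,
        )
        assert shifted.contact_face_count == ref.contact_face_count
        assert shifted.surface_face_count == ref.surface_face_count

    def test_connectivity_ordering(self, rng):
        """contact_pct(6) <= contact_pct(18) <= contact_pct(26)."""
        for _ in range(5):
            seed, soil = oracles.random_scene(rng, max_side=14)
            pcts = [
                compute_contact(seed, soil, 20.0, connectivity=c).contact_pct
                for c in (6, 18, 26)
            ]
            assert pcts[0] <= pcts[1] <= pcts[2]
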