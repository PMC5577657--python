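import numpy as np
import pytest

import oracles
from seedcontact import (
    GrainPackingSoil,
    GreyLevels,
    PhantomSpec,
    PhaseLabelMap,
    compute_contact,
    compute_iceberg,
    generate_phantom,
    ring_composition,
    ring_shell,
    ring_surface_effect,
)
from seedcontact.contact import ContactResult
from seedcontact.volume_io import PHASE_AIR, PHASE_SOIL
from conftest import make_sphere


def labels_from_soil(soil: np.ndarray, seed: np.ndarray, voxel_size_um: float = 20.0):
    lab = np.zeros(soil.shape, dtype=np.uint8)
    lab[soil] = PHASE_SOIL
    lab[seed] = 2
    return PhaseLabelMap(lab, voxel_size_um)


class TestRingShell:
    def test_single_voxel_chebyshev_widths(self):
        m = np.zeros((11, 11, 11), dtype=bool)
        m[5, 5, 5] = True
        assert ring_shell(m, 1).mask.sum() == 26
        assert ring_shell(m, 2).mask.sum() == 5**3 - 1

    def test_matches_brute_force_distance(self, rng):
        seed = make_sphere(8, margin=7)
        for metric, brute in (
            ("chebyshev", oracles.brute_chebyshev_shell),
            ("euclidean", oracles.brute_euclidean_shell),
        ):
            shell = ring_shell(seed, 5, metric=metric)
            np.testing.assert_array_equal(shell.mask, brute(seed, 5))

    def test_chebyshev_equals_iterated_dilation(self, rng):
        """Chebyshev shells are exactly the iterated 26-dilation minus seed."""
        for _ in range(5):
            seed, _ = oracles.random_scene(rng, max_side=14)
            for w in (1, 3):
                shell = ring_shell(seed, w).mask
                np.testing.assert_array_equal(
                    shell, oracles.brute_dilate(seed, w, 26) & ~seed
                )

    def test_nesting_and_monotone_counts(self):
        seed = make_sphere(6, margin=16)
        sizes = [ring_shell(seed, w).mask.sum() for w in (1, 3, 5, 8)]
        assert sizes == sorted(sizes)
        short, long_ = ring_shell(seed, 5).mask, ring_shell(seed, 15).mask
        assert (short & ~long_).sum() == 0  # short subset of long

    def test_clipped_fraction(self):
        seed = np.zeros((9, 31, 31), dtype=bool)
        seed[4, 15, 15] = True  # near z boundaries: width-5 shell is clipped
        with pytest.warns(UserWarning, match="clipped"):
            shell = ring_shell(seed, 5)
        assert 0 < shell.clipped_fraction < 1
        unclipped = ring_shell(np.pad(seed, 10), 5)
        assert unclipped.clipped_fraction == 0

    def test_annulus_variant(self):
        seed = make_sphere(5, margin=16)
        full = ring_shell(seed, 10).mask
        inner = ring_shell(seed, 5).mask
        annulus = ring_shell(seed, 10, inner_voxels=5).mask
        np.testing.assert_array_equal(annulus, full & ~inner)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ring_shell(np.zeros((3, 3, 3), dtype=bool), 1)
        with pytest.raises(ValueError, match="width"):
            ring_shell(np.ones((3, 3, 3), dtype=bool), 0)


class TestRingComposition:
    def test_saturation_and_emptiness(self):
        seed = make_sphere(4, margin=8)
        shell = ring_shell(seed, 3)
        all_soil = labels_from_soil(~seed, seed)
        assert ring_composition(shell, all_soil).volume_effect_pct == 100.0
        no_soil = labels_from_soil(np.zeros_like(seed), seed)
        assert ring_composition(shell, no_soil).volume_effect_pct == 0.0

    def test_half_space_soil(self):
        seed = make_sphere(20, margin=17)
        c = seed.shape[0] // 2
        zz = np.arange(seed.shape[0])[:, None, None]
        soil = np.broadcast_to(zz >= c, seed.shape) & ~seed
        shell = ring_shell(seed, 5)
        comp = ring_composition(shell, labels_from_soil(soil, seed))
        assert comp.volume_effect_pct == pytest.approx(50.0, abs=2.0)

    def test_conservation_exact(self, rng):
        """soil + air + stray seed voxel counts equal the shell size."""
        seed, soil = oracles.random_scene(rng, max_side=16)
        stray = (rng.random(seed.shape) < 0.05) & ~seed & ~soil
        lab = labels_from_soil(soil, seed)
        lab.labels[stray] = 2
        shell = ring_shell(seed, 3)
        comp = ring_composition(shell, lab)
        assert (
            comp.soil_voxels + comp.air_voxels + comp.stray_seed_voxels
            == int(shell.mask.sum())
        )


def one_face_contact(voxel_size_um: float = 20.0) -> ContactResult:
    face = (voxel_size_um / 1000.0) ** 2
    return ContactResult(
        surface_area_mm2=6 * face,
        contact_area_mm2=face,
        contact_pct=100 / 6,
        surface_face_count=6,
        contact_face_count=1,
        method="face_count",
    )


class TestRingSurfaceEffect:
    def test_no_soil_flagged_undefined(self):
        seed = make_sphere(4, margin=8)
        shell = ring_shell(seed, 3)
        eff = ring_surface_effect(shell, labels_from_soil(np.zeros_like(seed), seed),
                                  one_face_contact())
        assert eff.undefined and eff.surface_effect_pct is None

    def test_single_soil_voxel(self):
        """One soil voxel (6 faces) against a one-face contact area gives
        a 100/6 percent surface effect."""
        seed = make_sphere(4, margin=8)
        shell = ring_shell(seed, 3)
        soil = np.zeros_like(seed)
        zc = np.argwhere(shell.mask)[0]
        soil[tuple(zc)] = True
        eff = ring_surface_effect(shell, labels_from_soil(soil, seed), one_face_contact())
        assert eff.surface_effect_pct == pytest.approx(100 / 6)

    def test_matches_brute_force_face_count(self, rng):
        seed, soil = oracles.random_scene(rng, max_side=14)
        shell = ring_shell(seed, 3)
        contact = compute_contact(seed, soil, 20.0)
        eff = ring_surface_effect(shell, labels_from_soil(soil, seed), contact)
        soil_in_shell = soil & shell.mask
        if soil_in_shell.any():
            n_faces = len(oracles.brute_surface_faces(soil_in_shell))
            assert eff.soil_surface_mm2 == pytest.approx(n_faces * 0.02**2)


class TestComputeIceberg:
    def test_homogeneous_medium_change_ratio(self, rng):
        """Uniform random soil at all distances: identical composition in
        both rings, so the change in soil mass is ~100%."""
        seed = make_sphere(20, margin=17)
        soil = (rng.random(seed.shape) < 0.5) & ~seed
        contact = compute_contact(seed, soil, 20.0)
        ice = compute_iceberg(seed, labels_from_soil(soil, seed), contact)
        assert ice.change_volume_pct == pytest.approx(100.0, abs=1.0)

    def test_soil_only_near_seed(self):
        """Soil within 5 voxels of the seed, air beyond: short-range effect
        saturates and the change ratio exceeds 100."""
        seed = make_sphere(10, margin=17)
        soil = ring_shell(seed, 5).mask
        contact = compute_contact(seed, soil, 20.0)
        ice = compute_iceberg(seed, labels_from_soil(soil, seed), contact)
        assert ice.short.composition.volume_effect_pct == 100.0
        assert ice.long.composition.volume_effect_pct < 100.0
        assert ice.change_volume_pct > 100.0

    def test_grain_phantom_matches_generator_bookkeeping(self):
        """Volume effects agree with the per-distance soil/air tallies the
        generator recorded, within 2 percentage points."""
        spec = PhantomSpec(
            grid_shape=(100, 100, 100),
            seed_radius_um=400,
            soil_model=GrainPackingSoil(radii_um=(100, 400), target_solid_fraction=0.35),
            grey_levels=GreyLevels(noise_sd=0),
            rng_seed=11,
        )
        _, truth = generate_phantom(spec)
        contact = compute_contact(
            truth.closed_seed_mask, truth.labels.phase_mask(PHASE_SOIL), 20.0
        )
        ice = compute_iceberg(truth.closed_seed_mask, truth.labels, contact)
        for name, width in (("short", 5), ("long", 15)):
            soil = sum(truth.shell_soil_counts[d][0] for d in range(1, width + 1))
            air = sum(truth.shell_soil_counts[d][1] for d in range(1, width + 1))
            expected = 100.0 * soil / (soil + air)
            got = getattr(ice, name).composition.volume_effect_pct
            assert got == pytest.approx(expected, abs=2.0)

    def test_physical_widths_at_20um(self):
        seed = make_sphere(6, margin=16)
        soil = ring_shell(seed, 8).mask
        contact = compute_contact(seed, soil, 20.0)
        ice = compute_iceberg(seed, labels_from_soil(soil, seed), contact, widths=(5, 15))
        assert ice.short.width_um == 100.0
        assert ice.long.width_um == 300.0

    def test_widths_must_increase(self):
        seed = make_sphere(4, margin=16)
        contact = compute_contact(seed, ~seed, 20.0)
        with pytest.raises(ValueError, match="increasing"):
            compute_iceberg(seed, labels_from_soil(~seed, seed), contact, widths=(15, 5))
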