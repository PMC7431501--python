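"""Phantom geometry, sphere placement process and renderers."""

import numpy as np
import pytest
from scipy.ndimage import maximum_filter

from spheredose.grid import make_grid
from spheredose.phantom import (LABELS, MICROCT_BACKGROUND, PhantomSpec,
                                GroundTruth, make_phantom, render_microct,
                                render_pet_activity, sample_sphere_positions,
                                single_sphere_integral)
from spheredose.spheres import SphereTable

SMALL = dict(shape=(80, 80, 80), spacing_mm=0.5,
             hemisphere_center=(20.0, 20.0, 20.0),
             hemisphere_semi_axes=(17.0, 15.0, 13.0),
             tumor_center=(26.0, 20.0, 20.0), tumor_radius=8.0,
             deep_gray_center=(13.0, 20.0, 20.0), deep_gray_semi_axes=(4.0, 3.5, 3.0))


@pytest.fixture(scope="module")
def small_labels():
    return make_phantom(PhantomSpec(**SMALL))


class TestMakePhantom:
    def test_zero_tumor_radius_gives_no_tumor(self):
        spec = PhantomSpec(**{**SMALL, "tumor_radius": 0.0})
        lab = make_phantom(spec).data
        assert (lab == LABELS["tumor"]).sum() == 0

    def test_tumor_volume_matches_analytic(self, small_labels):
        vox = (small_labels.data == LABELS["tumor"]).sum()
        analytic = 4.0 / 3.0 * np.pi * 8.0 ** 3
        assert vox * small_labels.grid.voxel_volume_mm3 == pytest.approx(analytic, rel=0.05)

    def test_labels_partition_hemisphere(self, small_labels):
        lab = small_labels.data
        hemi = lab > 0
        parts = sum(int((lab == LABELS[k]).sum())
                    for k in ("cortex", "deep_gray", "tumor", "necrotic_core"))
        assert parts == int(hemi.sum())

    def test_necrotic_core_inside_tumor(self):
        spec = PhantomSpec(**{**SMALL, "necrotic_core_radius": 3.0})
        lab = make_phantom(spec).data
        assert (lab == LABELS["necrotic_core"]).sum() > 0
        core_vox = lab == LABELS["necrotic_core"]
        # core voxels sit within the analytic tumor sphere
        g = spec.grid
        ijk = np.argwhere(core_vox)
        d = np.linalg.norm(g.index_to_world(ijk) - np.asarray(spec.tumor_center), axis=1)
        assert d.max() <= spec.tumor_radius + g.spacing[0]

    def test_containment_violation_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            PhantomSpec(**{**SMALL, "tumor_center": (36.0, 20.0, 20.0)})
        with pytest.raises(ValueError, match="necrotic"):
            PhantomSpec(**{**SMALL, "necrotic_core_radius": 9.0})


class TestPlacement:
    def test_zero_spheres(self, small_labels):
        truth = sample_sphere_positions(small_labels, 0)
        assert len(truth.spheres) == 0

    def test_density_ratio_recovered(self, small_labels):
        truth = sample_sphere_positions(small_labels, 40_000, 3.0, seed=0)
        assert truth.achieved_tumor_to_normal == pytest.approx(3.0, rel=0.05)

    def test_extreme_ratio_fills_tumor(self, small_labels):
        truth = sample_sphere_positions(small_labels, 500, 1e9, seed=1)
        v = small_labels.grid.voxel_of(truth.spheres.positions_mm)
        lab = small_labels.data[v[:, 0], v[:, 1], v[:, 2]]
        assert np.all(lab == LABELS["tumor"])

    def test_positions_inside_tissue(self, small_labels):
        truth = sample_sphere_positions(small_labels, 2000, 2.0, seed=2)
        v = small_labels.grid.voxel_of(truth.spheres.positions_mm)
        lab = small_labels.data[v[:, 0], v[:, 1], v[:, 2]]
        assert np.all(lab > 0)

    def test_necrotic_core_excluded(self):
        spec = PhantomSpec(**{**SMALL, "necrotic_core_radius": 4.0})
        labels = make_phantom(spec)
        truth = sample_sphere_positions(labels, 5000, 5.0, seed=3)
        v = labels.grid.voxel_of(truth.spheres.positions_mm)
        lab = labels.data[v[:, 0], v[:, 1], v[:, 2]]
        assert not np.any(lab == LABELS["necrotic_core"])

    def test_seeded_determinism(self, small_labels):
        a = sample_sphere_positions(small_labels, 1000, 3.0, seed=7)
        b = sample_sphere_positions(small_labels, 1000, 3.0, seed=7)
        assert np.array_equal(a.spheres.positions_mm, b.spheres.positions_mm)

    def test_clustering_count_and_masks(self, small_labels):
        truth = sample_sphere_positions(small_labels, 3000, 3.0, clustering=4.0, seed=4)
        assert len(truth.spheres) == 3000
        v = small_labels.grid.voxel_of(truth.spheres.positions_mm)
        assert np.all(small_labels.data[v[:, 0], v[:, 1], v[:, 2]] > 0)

    def test_activity_bookkeeping(self, small_labels):
        truth = sample_sphere_positions(small_labels, 777, 3.0, seed=5,
                                        total_activity_gbq=0.019)
        acts = truth.spheres.activities_bq
        assert acts.sum() == pytest.approx(0.019e9, abs=1e-6)
        assert np.allclose(acts[:-1], acts[0])

    def test_empty_region_rejected(self):
        spec = PhantomSpec(**{**SMALL, "shape": (4, 4, 4)})  # hemisphere off-grid
        labels = make_phantom(spec)
        with pytest.raises(ValueError, match="placeable"):
            sample_sphere_positions(labels, 10)


class TestMicroCT:
    GRID = make_grid((96, 96, 96), 0.00874)

    def test_no_spheres_is_background_plus_noise(self):
        vol = render_microct(SphereTable(np.empty((0, 3)), np.empty(0)),
                             self.GRID, noise_sd=10.0, seed=0)
        assert vol.data.mean() == pytest.approx(MICROCT_BACKGROUND, abs=0.5)
        assert vol.data.std() == pytest.approx(10.0, rel=0.05)

    def test_single_sphere_integral_constant(self):
        center = np.array([[0.42, 0.42, 0.42]])
        vol = render_microct(SphereTable(center, [0.0]), self.GRID, noise_sd=0.0)
        measured = (vol.data - MICROCT_BACKGROUND).sum()
        assert measured == pytest.approx(single_sphere_integral(0.00874), rel=0.01)

    def test_two_separated_spheres_two_maxima(self):
        pos = np.array([[0.25, 0.25, 0.25], [0.6, 0.6, 0.6]])
        vol = render_microct(SphereTable(pos, [0, 0]), self.GRID, noise_sd=0.0)
        peaks = (maximum_filter(vol.data, size=5) == vol.data) & \
            (vol.data > MICROCT_BACKGROUND + 100)
        assert peaks.sum() == 2

    def test_coarse_spacing_records_warning(self):
        coarse = make_grid((16, 16, 16), 0.05)
        vol = render_microct(SphereTable(np.array([[0.4, 0.4, 0.4]]), [0.0]),
                             coarse, noise_sd=0.0)
        assert "warning" in vol.provenance

    def test_seeded_determinism(self):
        pos = np.array([[0.3, 0.3, 0.3]])
        a = render_microct(SphereTable(pos, [0.0]), self.GRID, seed=9)
        b = render_microct(SphereTable(pos, [0.0]), self.GRID, seed=9)
        assert np.array_equal(a.data, b.data)


class TestPET:
    GRID = make_grid((21, 21, 21), 2.0)

    def test_total_activity_conserved(self):
        rng = np.random.default_rng(3)
        t = SphereTable(rng.uniform(6, 36, (400, 3)), np.full(400, 5e4))
        pet = render_pet_activity(t, self.GRID, psf_fwhm_mm=5.0)
        assert pet.data.sum() == pytest.approx(400 * 5e4 * 1e-9, rel=1e-6)

    def test_central_sphere_profile_is_gaussian(self):
        t = SphereTable(np.array([[20.0, 20.0, 20.0]]), [1e6])
        pet = render_pet_activity(t, self.GRID, psf_fwhm_mm=5.0)
        sigma = 5.0 / 2.354820045
        c = pet.data[10, 10, 10]
        for off, dist in (((12, 10, 10), 4.0), ((10, 12, 10), 4.0), ((12, 12, 10), np.sqrt(32))):
            expected = np.exp(-dist ** 2 / (2 * sigma ** 2))
            assert pet.data[off] / c == pytest.approx(expected, rel=0.15)

    def test_zero_fwhm_is_pure_binning(self):
        t = SphereTable(np.array([[20.0, 20.0, 20.0], [6.0, 6.0, 6.0]]), [1e6, 2e6])
        pet = render_pet_activity(t, self.GRID, psf_fwhm_mm=0.0)
        assert pet.data[10, 10, 10] == pytest.approx(1e-3)
        assert pet.data[3, 3, 3] == pytest.approx(2e-3)
        assert (pet.data > 0).sum() == 2
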