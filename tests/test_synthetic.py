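"""The synthetic generator: determinism, ground truth, presets, manifests."""

import numpy as np
import pytest

from tismorph.acquisition import RI_BACKGROUND
from tismorph.synthetic import (
    PhenotypeParams,
    PlacementError,
    generate_nlo_fov,
    generate_qpi_tomogram,
    generate_timecourse,
    nlo_preset,
    paint_droplet_mask,
    qpi_preset,
)


class TestParams:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(tpef_area_frac_target=1.4)

    def test_lipid_ri_outside_band_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(lipid_ri=(1.2, 1.46))

    def test_scalar_noise_broadcasts(self):
        p = PhenotypeParams(noise_sd=0.0)
        assert set(p.noise_sd) >= {"TPEF", "SRS", "transmission", "ri"}
        assert all(v == 0.0 for v in p.noise_sd.values())

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeParams(condition="treated")


class TestNloFov:
    def test_bit_identical_under_fixed_seed(self):
        params = nlo_preset("TIS", "72h")
        img1, t1 = generate_nlo_fov(params, 42)
        img2, t2 = generate_nlo_fov(params, 42)
        for name in img1.channels:
            assert np.array_equal(img1[name], img2[name])
        assert t1.as_dict() == t2.as_dict()

    def test_empty_fov_is_pure_background(self):
        params = PhenotypeParams(n_cells_per_fov=0, noise_sd=0.0, outlier_rate=0.0,
                                 serpentine_shift_px=0)
        img, truth = generate_nlo_fov(params, 0)
        assert np.ptp(img["transmission"]) == 0.0
        assert truth.cells == [] and truth.outlier_pixels == []

    def test_srs_identically_zero_without_droplets(self):
        params = PhenotypeParams(droplet_density_per_cell=0.0, noise_sd=0.0,
                                 outlier_rate=0.0, serpentine_shift_px=0)
        img, _ = generate_nlo_fov(params, 1)
        assert np.all(img["SRS"] == 0.0)

    def test_impossible_packing_raises_placement_error(self):
        params = PhenotypeParams(n_cells_per_fov=40, cell_radius_um=16.0, fov_px=150)
        with pytest.raises(PlacementError):
            generate_nlo_fov(params, 0)

    def test_droplet_pixels_match_ground_truth_geometry(self, clean_nlo_params):
        params = clean_nlo_params.replace(droplet_density_per_cell=4.0)
        img, truth = generate_nlo_fov(params, 12)
        painted = paint_droplet_mask(truth, img.shape)
        assert painted.any()
        assert np.array_equal(img["SRS"] > 2.2e-4, painted)

    def test_outlier_coordinates_recorded(self):
        params = PhenotypeParams(outlier_rate=5e-4, serpentine_shift_px=0, noise_sd=0.0)
        img, truth = generate_nlo_fov(params, 3)
        assert truth.outlier_pixels
        by_channel = {}
        for name, r, c in truth.outlier_pixels:
            by_channel.setdefault(name, []).append((r, c))
        tpef = img["TPEF"]
        for r, c in by_channel.get("TPEF", []):
            med = np.median(tpef[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2])
            assert abs(tpef[r, c] - med) > 1.0

    def test_recorded_tpef_fraction_matches_raster(self, clean_nlo_params):
        img, truth = generate_nlo_fov(clean_nlo_params, 5)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
        for cell in truth.cells:
            cy, cx = cell.centroid_px
            ry, rx = cell.radii_px
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            frac = (img["TPEF"][inside] > 0.25).sum() / inside.sum()
            assert frac == pytest.approx(cell.tpef_area_frac, abs=1e-9)


class TestQpiTomogram:
    def test_deterministic_grid(self, qpi_sphere_params):
        t1, _ = generate_qpi_tomogram(qpi_sphere_params, 9)
        t2, _ = generate_qpi_tomogram(qpi_sphere_params, 9)
        assert np.array_equal(t1.ri, t2.ri)

    def test_spherical_cell_analytic_volume(self, qpi_sphere_params):
        _, truth = generate_qpi_tomogram(qpi_sphere_params, 0)
        assert truth.cells[0].volume_um3 == pytest.approx(523.5988, abs=0.01)

    def test_zero_cells_gives_uniform_background(self):
        params = PhenotypeParams(n_cells_per_fov=0, n_cells_per_tomogram=0, noise_sd=0.0)
        tomo, truth = generate_qpi_tomogram(params, 0)
        assert np.all(tomo.ri == RI_BACKGROUND)
        assert truth.cells == []

    def test_lipid_spheres_confined_to_cell(self, qpi_sphere_params):
        params = qpi_sphere_params.replace(droplet_density_per_cell=4.0,
                                           droplet_radius_um=(1.0, 0.1))
        tomo, truth = generate_qpi_tomogram(params, 2)
        cell = truth.cells[0]
        a, b, c = cell.semiaxes_um
        for s in cell.lipid_spheres:
            x, y, z = s["center_um"]
            # sphere center plus radius stays inside the ellipsoid axes
            ccx = cell.center_vox[2] * tomo.voxel_size_um[0]
            ccy = cell.center_vox[1] * tomo.voxel_size_um[1]
            ccz = cell.center_vox[0] * tomo.voxel_size_um[2]
            norm = ((x - ccx) / (a - s["radius_um"])) ** 2 + \
                   ((y - ccy) / (b - s["radius_um"])) ** 2 + \
                   ((z - ccz) / (c - s["radius_um"])) ** 2
            assert norm <= 1.0 + 1e-9

    def test_tis_presets_are_larger_flatter_lipid_richer(self):
        ctrl = qpi_preset("control", "7d")
        tis = qpi_preset("TIS", "7d")
        assert tis.cell_radius_um > ctrl.cell_radius_um
        assert tis.cell_thickness_um < ctrl.cell_thickness_um
        assert tis.droplet_density_per_cell > ctrl.droplet_density_per_cell


class TestTimecourse:
    def _design(self, n_plates=5, n_fovs=2, fast=True):
        kw = dict(fov_px=96, n_cells_per_fov=1, cell_radius_um=4.0,
                  droplet_density_per_cell=0.0, serpentine_shift_px=0,
                  outlier_rate=0.0) if fast else {}
        design = []
        for cond in ("control", "TIS"):
            for _ in range(n_plates):
                design.append((PhenotypeParams(condition=cond, time_point="0h", **kw), n_fovs))
        return design

    def test_five_plus_five_plates_two_fovs_gives_twenty(self, tmp_path):
        manifest = generate_timecourse(self._design(), 0, tmp_path)
        assert len(manifest) == 20
        assert (manifest.groupby("condition").size() == 10).all()
        assert (tmp_path / "manifest.csv").exists()

    def test_empty_design_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_timecourse([], 0, tmp_path)

    def test_duplicate_keys_rejected(self, tmp_path):
        p = PhenotypeParams(fov_px=96, n_cells_per_fov=0)
        with pytest.raises(ValueError, match="duplicate"):
            generate_timecourse([(p, 1, "plate1"), (p, 1, "plate1")], 0, tmp_path)

    def test_manifest_deterministic_under_seed(self, tmp_path):
        m1 = generate_timecourse(self._design(2, 1), 7, tmp_path / "a")
        m2 = generate_timecourse(self._design(2, 1), 7, tmp_path / "b")
        assert list(m1.seed) == list(m2.seed)
        from tismorph import io

        img1 = io.read_multimodal_tiff(m1.path.iloc[0])
        img2 = io.read_multimodal_tiff(m2.path.iloc[0])
        assert np.array_equal(img1["TPEF"], img2["TPEF"])

    def test_roundtrip_through_tiff_and_h5(self, tmp_path, qpi_sphere_params):
        from tismorph import io

        img, _ = generate_nlo_fov(PhenotypeParams(fov_px=64, n_cells_per_fov=1,
                                                  cell_radius_um=3.0), 0)
        path = io.write_multimodal_tiff(img, tmp_path / "fov.tif")
        back = io.read_multimodal_tiff(path)
        for name in img.channels:
            assert np.allclose(back[name], img[name], atol=1e-6)

        tomo, _ = generate_qpi_tomogram(
            qpi_sphere_params.replace(qpi_shape=(16, 32, 32),
                                      qpi_voxel_um=(0.6, 0.6, 0.8)), 0)
        h5 = io.write_tomogram_h5(tomo, tmp_path / "tomo.h5")
        back_t = io.read_tomogram_h5(h5)
        assert np.allclose(back_t.ri, tomo.ri, atol=1e-6)
        assert back_t.voxel_size_um == pytest.approx(tomo.voxel_size_um)
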