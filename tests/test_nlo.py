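"""Cell segmentation, TPEF indices and lipid-droplet particle analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tismorph.nlo import (
    CellMask,
    aggregation_index,
    area_fraction_pct,
    crack_perimeter,
    detect_droplets,
    droplet_summaries,
    mean_intensity,
    segment_cells,
    top_decile_max,
)
from tismorph.synthetic import generate_nlo_fov
from tests.conftest import make_mask


def oracle_perimeter(component):
    """Count exposed unit edges pixel by pixel (independent of the
    adjacency-difference formula used by the implementation)."""
    m = np.asarray(component, bool)
    padded = np.pad(m, 1)
    total = 0
    for i in range(1, padded.shape[0] - 1):
        for j in range(1, padded.shape[1] - 1):
            if padded[i, j]:
                total += sum(
                    not padded[i + di, j + dj]
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                )
    return float(total)


class TestSegmentCells:
    def test_dark_square_on_bright_field(self):
        trans = np.ones((100, 100))
        trans[30:70, 30:70] = 0.5
        mask = segment_cells(trans)
        assert mask.cell_area_px == 1600
        assert mask.mask[30:70, 30:70].all()

    def test_constant_raster_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = segment_cells(np.ones((50, 50)))
        assert mask.cell_area_px == 0 and mask.empty_warning

    def test_generator_footprints_recovered(self, clean_nlo_params):
        img, truth = generate_nlo_fov(clean_nlo_params, 3)
        mask = segment_cells(img["transmission"])
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
        gt = np.zeros(img.shape, bool)
        for cell in truth.cells:
            cy, cx = cell.centroid_px
            ry, rx = cell.radii_px
            gt |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        jaccard = (mask.mask & gt).sum() / (mask.mask | gt).sum()
        assert jaccard >= 0.9


class TestAreaFraction:
    def test_counts_strictly_above_threshold(self):
        ch = np.zeros((10, 10))
        ch.ravel()[:25] = 1.0
        assert area_fraction_pct(ch, make_mask(), 0.5) == 25.0

    def test_values_equal_to_threshold_excluded(self):
        ch = np.full((10, 10), 0.25)
        assert area_fraction_pct(ch, make_mask(), 0.25) == 0.0

    def test_threshold_below_minimum_gives_100(self):
        ch = np.ones((10, 10))
        assert area_fraction_pct(ch, make_mask(), -1.0) == 100.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            area_fraction_pct(np.ones((10, 10)), make_mask(full=False), 0.5)

    @given(t1=st.floats(0, 1), t2=st.floats(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, t1, t2):
        rng = np.random.default_rng(0)
        ch = rng.uniform(0, 1, (10, 10))
        lo, hi = min(t1, t2), max(t1, t2)
        assert area_fraction_pct(ch, make_mask(), lo) >= area_fraction_pct(ch, make_mask(), hi)


class TestTopDecileMax:
    @pytest.mark.parametrize(
        "values,expected",
        [(np.arange(1, 11), 10.0), (np.arange(1, 21), 19.5), (np.full(30, 4.2), 4.2)],
    )
    def test_against_direct_sort(self, values, expected):
        mask = CellMask(np.ones(values.shape[0], bool).reshape(-1, 1))
        assert top_decile_max(values.reshape(-1, 1).astype(float), mask) == pytest.approx(expected)

    def test_aggregation_index_is_product(self):
        ch = np.zeros((10, 10))
        ch.ravel()[:25] = 2.0  # top decile = 10 px, all at 2.0 -> max 2.0
        mask = make_mask()
        assert aggregation_index(ch, mask, threshold=0.5) == pytest.approx(2.0 * 25.0)
        assert aggregation_index(np.zeros((10, 10)), mask, 0.25) == 0.0

    def test_mean_intensity(self):
        ch = np.zeros((10, 10))
        ch[:5] = 2.0
        assert mean_intensity(ch, make_mask()) == pytest.approx(1.0)

    def test_punctate_pattern_outscores_diffuse_at_same_total_signal(self):
        """Condensing fluorescence into bright cores at the same total
        signal and positive area raises the aggregation index: the
        top-decile maximum picks up the cores while the area term is
        unchanged."""
        rng = np.random.default_rng(0)
        mask = make_mask((60, 60))
        n_px = 3600
        idx = rng.choice(n_px, int(0.15 * n_px), replace=False)
        diffuse = np.full((60, 60), 0.1)
        diffuse.ravel()[idx] = 0.5  # uniform plateau
        punctate = np.full((60, 60), 0.1)
        third = idx.size // 3
        punctate.ravel()[idx[:third]] = 0.75  # bright condensed cores
        punctate.ravel()[idx[third:]] = (idx.size * 0.5 - third * 0.75) / (idx.size - third)
        assert punctate.sum() == pytest.approx(diffuse.sum())
        assert area_fraction_pct(punctate, mask, 0.25) == area_fraction_pct(diffuse, mask, 0.25)
        assert aggregation_index(punctate, mask, 0.25) > aggregation_index(diffuse, mask, 0.25)


def paint_disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestDetectDroplets:
    def test_rasterized_disk_is_quasi_single(self):
        disk = paint_disk((30, 30), (15, 15), 4.0)
        assert disk.sum() == 49
        srs = np.where(disk, 1e-3, 0.0)
        found = detect_droplets(srs, make_mask((30, 30)))
        assert len(found) == 1
        d = found.droplets[0]
        assert d.area_px == 49
        assert d.perimeter_px == oracle_perimeter(disk)
        assert d.circularity == pytest.approx(4 * math.pi * 49 / d.perimeter_px**2)
        assert d.quasi_single

    def test_small_square_filtered_out(self):
        srs = np.zeros((20, 20))
        srs[5:7, 5:7] = 1e-3  # 4 px < 5 px minimum
        assert len(detect_droplets(srs, make_mask((20, 20)))) == 0

    def test_line_is_cluster_but_not_quasi_single(self):
        srs = np.zeros((10, 30))
        srs[4, 5:25] = 1e-3  # 1 x 20 line
        found = detect_droplets(srs, make_mask((10, 30)))
        assert len(found) == 1
        d = found.droplets[0]
        assert d.perimeter_px == oracle_perimeter(srs > 0) == 42.0
        assert d.circularity == pytest.approx(4 * math.pi * 20 / 42.0**2)  # ~0.14
        assert not d.quasi_single

    def test_quasi_single_never_exceeds_cluster_count(self, clean_nlo_params):
        params = clean_nlo_params.replace(droplet_density_per_cell=8.0)
        img, _ = generate_nlo_fov(params, 4)
        mask = segment_cells(img["transmission"])
        found = detect_droplets(img["SRS"], mask)
        assert 0 < len(found.quasi_single) <= len(found)

    def test_translation_invariance_of_metrics(self):
        srs = np.zeros((40, 40))
        srs[np.where(paint_disk((40, 40), (10, 10), 3.0))] = 1e-3
        tpef = np.zeros((40, 40))
        tpef[8:14, 8:14] = 1.0
        mask_arr = paint_disk((40, 40), (10, 10), 8.0)

        def metrics(shift):
            m = CellMask(np.roll(mask_arr, shift, (0, 1)))
            s = np.roll(srs, shift, (0, 1))
            t = np.roll(tpef, shift, (0, 1))
            found = detect_droplets(s, m)
            return (
                area_fraction_pct(t, m, 0.25),
                top_decile_max(t, m),
                droplet_summaries(found, m)["srs_area_pct"],
                len(found),
            )

        assert metrics(0) == metrics(17)


class TestDropletSummaries:
    def test_empty_droplets_give_zero_counts_and_missing_mean(self):
        found = detect_droplets(np.zeros((10, 10)), make_mask())
        summ = droplet_summaries(found, make_mask())
        assert summ["srs_area_pct"] == 0.0
        assert summ["cluster_count"] == 0
        assert math.isnan(summ["mean_quasi_single_area_um2"])

    def test_pixel_to_area_conversion(self):
        srs = np.zeros((20, 20))
        srs[5:7, 5:10] = 1e-3  # 10 px component
        mask = make_mask((20, 20), pixel_size_um=0.35)
        found = detect_droplets(srs, mask)
        summ = droplet_summaries(found, mask)
        assert summ["mean_quasi_single_area_um2"] == pytest.approx(10 * 0.35**2)  # 1.225

    def test_cluster_count_matches_ground_truth_components(self, clean_nlo_params):
        from scipy import ndimage

        from tismorph.synthetic import paint_droplet_mask

        params = clean_nlo_params.replace(droplet_density_per_cell=2.0)
        img, truth = generate_nlo_fov(params, 9)
        mask = segment_cells(img["transmission"])
        found = detect_droplets(img["SRS"], mask)
        painted = paint_droplet_mask(truth, img.shape)
        _, n_components = ndimage.label(painted, structure=np.ones((3, 3), bool))
        assert len(found) == n_components > 0
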