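import numpy as np
import pytest
import scipy.ndimage as ndi

import hcscreen as h
from hcscreen.errors import LabelingError, ParameterError, SegmentationError
from hcscreen.imaging import cell_records_to_frame, roi_overlap

from oracles import (
    brute_force_peri_ring,
    brute_force_pm_ring,
    nearest_seed_distances,
    random_blob_pair,
)


def _field(nuclear, target=None):
    nuclear = np.asarray(nuclear, dtype=float)
    return h.FieldImage(nuclear, nuclear.copy() if target is None else target)


class TestSegmentNuclei:
    def test_two_bright_squares_give_two_labels(self):
        img = np.zeros((20, 20))
        img[2:7, 2:7] = 100
        img[12:17, 12:17] = 100
        labels = h.segment_nuclei(_field(img), threshold=50)
        assert labels.max() == 2
        assert sorted(np.bincount(labels.ravel())[1:]) == [25, 25]

    def test_uniform_image_above_threshold_is_empty(self):
        labels = h.segment_nuclei(_field(np.full((10, 10), 5.0)), threshold=6)
        assert labels.max() == 0

    def test_threshold_below_minimum_is_all_foreground_error(self):
        with pytest.raises(SegmentationError, match="all-foreground"):
            h.segment_nuclei(_field(np.full((10, 10), 5.0)), threshold=5)

    def test_small_specks_discarded(self):
        img = np.zeros((20, 20))
        img[5, 5] = 100  # 1-px speck
        img[10:14, 10:14] = 100  # 16-px nucleus
        labels = h.segment_nuclei(_field(img), threshold=50, min_area=10)
        assert labels.max() == 1
        assert (labels[10:14, 10:14] == 1).all()

    def test_recovers_planted_nuclei_from_simulated_field(self):
        spec = h.ImageSimSpec(
            field_shape=(200, 200), n_cells=10, nucleus_radius=4, cell_radius=12,
            noise_sd=0.0, seed=21,
        )
        image, truth = h.simulate_field(spec)
        labels = h.segment_nuclei(image, threshold="auto")
        assert labels.max() == 10
        centroids = np.array(ndi.center_of_mass(labels > 0, labels, range(1, 11)))
        # each planted center is within 1 px of some recovered centroid
        d = np.abs(centroids[:, None, :] - truth.centers[None, :, :]).max(-1).min(0)
        assert (d <= 1.0).all()


class TestSegmentCells:
    def test_single_nucleus_claims_whole_disk(self):
        img = np.zeros((40, 40))
        rr, cc = np.ogrid[:40, :40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 144
        img[disk] = 50
        img[(rr - 20) ** 2 + (cc - 20) ** 2 <= 9] = 500
        nuclei = h.segment_nuclei(_field(img), threshold=400, min_area=1)
        cells = h.segment_cells(_field(img), nuclei, cyto_threshold=20)
        assert np.array_equal(cells > 0, disk)
        assert (cells[disk] == 1).all()

    def test_no_cytoplasm_foreground_floors_to_nucleus(self):
        img = np.zeros((20, 20))
        img[8:12, 8:12] = 500
        nuclei = h.segment_nuclei(_field(img), threshold=400, min_area=1)
        cells = h.segment_cells(_field(img), nuclei, cyto_threshold=600)
        assert np.array_equal(cells, nuclei)

    def test_shared_region_split_by_nearest_seed(self):
        """Two nuclei in one connected bright region: exhaustive nearest-seed split."""
        img = np.zeros((30, 60))
        img[5:25, 5:55] = 50
        img[12:18, 12:18] = 500
        img[12:18, 40:46] = 500
        field = _field(img)
        nuclei = h.segment_nuclei(field, threshold=400, min_area=1)
        cells = h.segment_cells(field, nuclei, cyto_threshold=20)
        fg = img >= 20
        assert np.array_equal(cells > 0, fg)  # partition is exhaustive
        for lab in (1, 2):
            assert (cells[nuclei == lab] == lab).all()
        dists = nearest_seed_distances(fg, nuclei)
        best = np.minimum(dists[1], dists[2])
        for lab in (1, 2):
            own = dists[lab][cells == lab]
            assert (own == best[cells == lab]).all()  # every pixel went to a nearest seed

    def test_orphan_foreground_left_background(self):
        img = np.zeros((30, 30))
        img[2:6, 2:6] = 50  # bright blob with no nucleus
        img[15:19, 15:19] = 500
        field = _field(img)
        nuclei = h.segment_nuclei(field, threshold=400, min_area=1)
        cells = h.segment_cells(field, nuclei, cyto_threshold=20)
        assert (cells[2:6, 2:6] == 0).all()
        assert (cells[15:19, 15:19] == 1).all()


class TestRings:
    def test_square_cell_pm_ring_chebyshev_count(self):
        labels = np.zeros((14, 14), dtype=int)
        labels[2:12, 2:12] = 1  # 10x10 cell
        ring = h.derive_pm_roi(labels, width=2)
        assert (ring == 1).sum() == 100 - 6 * 6
        assert np.array_equal(ring > 0, (labels > 0) & ~((np.arange(14)[:, None] >= 4)
                              & (np.arange(14)[:, None] < 10)
                              & (np.arange(14)[None, :] >= 4)
                              & (np.arange(14)[None, :] < 10)))

    def test_thin_cell_entirely_ring(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4:7, 1:9] = 1  # 3 px thick < 2*width
        ring = h.derive_pm_roi(labels, width=2)
        assert np.array_equal(ring, labels)

    def test_nonpositive_width_rejected(self):
        labels = np.ones((5, 5), dtype=int)
        with pytest.raises(ParameterError):
            h.derive_pm_roi(labels, width=0)
        with pytest.raises(ParameterError):
            h.derive_perinuclear_roi(labels, labels, width=-1)

    def test_perinuclear_ring_square_count(self):
        nuclei = np.zeros((34, 34), dtype=int)
        cells = np.zeros((34, 34), dtype=int)
        cells[2:32, 2:32] = 1  # 30x30 cell
        nuclei[15:19, 15:19] = 1  # 4x4 nucleus
        ring = h.derive_perinuclear_roi(nuclei, cells, width=5)
        assert (ring == 1).sum() == 14 * 14 - 4 * 4

    def test_ring_clipped_by_cell_mask(self):
        nuclei = np.zeros((30, 30), dtype=int)
        cells = np.zeros((30, 30), dtype=int)
        cells[5:20, 5:20] = 1
        nuclei[5:9, 5:9] = 1  # nucleus in the cell corner
        ring = h.derive_perinuclear_roi(nuclei, cells, width=5)
        assert (ring == 1).sum() < 14 * 14 - 4 * 4
        assert ((cells == 0) & (ring > 0)).sum() == 0

    def test_label_mismatch_rejected(self):
        nuclei = np.zeros((10, 10), dtype=int)
        cells = np.zeros((10, 10), dtype=int)
        nuclei[2:4, 2:4] = 1
        cells[1:6, 1:6] = 2
        with pytest.raises(LabelingError):
            h.derive_perinuclear_roi(nuclei, cells, width=2)

    def test_overlap_is_computed_and_reported(self):
        # small cell: the 5-px perinuclear halo reaches the 2-px margin band
        nuclei = np.zeros((14, 14), dtype=int)
        cells = np.zeros((14, 14), dtype=int)
        cells[2:12, 2:12] = 1
        nuclei[6:8, 6:8] = 1
        pm = h.derive_pm_roi(cells, width=2)
        peri = h.derive_perinuclear_roi(nuclei, cells, width=5)
        overlap = roi_overlap(pm, peri)
        assert overlap.loc[1] == (((pm == 1) & (peri == 1)).sum())
        assert overlap.loc[1] > 0

    @pytest.mark.parametrize("metric", ["chebyshev", "manhattan"])
    def test_rings_match_brute_force_on_random_blobs(self, metric, rng):
        for _ in range(25):
            cell, nucleus = random_blob_pair(rng, shape=(48, 48))
            cells = cell.astype(int)
            nuclei = nucleus.astype(int)
            width = int(rng.integers(1, 5))
            pm = h.derive_pm_roi(cells, width=width, metric=metric)
            assert np.array_equal(pm > 0, brute_force_pm_ring(cell, width, metric))
            peri = h.derive_perinuclear_roi(nuclei, cells, width=width, metric=metric)
            assert np.array_equal(peri > 0, brute_force_peri_ring(nucleus, cell, width, metric))

    def test_ring_area_monotone_in_width(self, rng):
        cell, nucleus = random_blob_pair(rng, shape=(48, 48))
        cells, nuclei = cell.astype(int), nucleus.astype(int)
        pm_areas = [(h.derive_pm_roi(cells, w) > 0).sum() for w in range(1, 8)]
        peri_areas = [
            (h.derive_perinuclear_roi(nuclei, cells, w) > 0).sum() for w in range(1, 8)
        ]
        assert all(a <= b for a, b in zip(pm_areas, pm_areas[1:]))
        assert all(a <= b for a, b in zip(peri_areas, peri_areas[1:]))


class TestMeasureCells:
    def test_uniform_target_gives_constant_means(self):
        spec = h.ImageSimSpec(field_shape=(80, 80), n_cells=3, nucleus_radius=4,
                              cell_radius=12, noise_sd=0.0, seed=4)
        image, truth = h.simulate_field(spec)
        image.target_channel[:] = 77.0
        masks = h.SegmentationMasks(truth.nucleus_labels, truth.cell_labels)
        for rec in h.measure_cells(image, masks):
            assert rec.mean_pm == rec.mean_perinuclear == rec.mean_total == 77.0

    def test_zero_cells_gives_empty_list(self):
        image = _field(np.zeros((20, 20)))
        masks = h.SegmentationMasks(np.zeros((20, 20), int), np.zeros((20, 20), int))
        assert h.measure_cells(image, masks) == []

    def test_border_cells_excluded(self):
        nuclei = np.zeros((20, 20), dtype=int)
        cells = np.zeros((20, 20), dtype=int)
        cells[0:6, 0:6] = 1  # touches border
        nuclei[1:3, 1:3] = 1
        cells[10:16, 10:16] = 2
        nuclei[12:14, 12:14] = 2
        image = _field(np.full((20, 20), 9.0))
        recs = h.measure_cells(image, h.SegmentationMasks(nuclei, cells))
        assert [r.cell_id for r in recs] == [2]

    def test_noiseless_recovery_matches_ground_truth(self):
        spec = h.ImageSimSpec(field_shape=(128, 128), n_cells=5, nucleus_radius=4,
                              cell_radius=14, noise_sd=0.0, seed=8)
        image, truth = h.simulate_field(spec)
        recs = h.quantify_field(image, nuclear_threshold="auto", cyto_threshold="auto")
        assert len(recs) == len(truth.records)
        got = cell_records_to_frame(recs).sort_values("mean_total").reset_index(drop=True)
        want = cell_records_to_frame(truth.records).sort_values("mean_total").reset_index(drop=True)
        for col in ("mean_pm", "mean_perinuclear", "mean_total",
                    "area_pm", "area_perinuclear", "area_total"):
            assert np.allclose(got[col], want[col], atol=1e-9), col

    def test_masks_from_wrong_field_rejected(self):
        image = _field(np.zeros((10, 10)))
        masks = h.SegmentationMasks(np.zeros((12, 12), int), np.zeros((12, 12), int))
        with pytest.raises(LabelingError):
            h.measure_cells(image, masks)


class TestSummarizeWell:
    def test_pooled_mean_weights_cells_not_fields(self):
        def rec(m, idx):
            return h.CellRecord(1, m, m, m, 4, 4, 4, field_index=idx, well_id="A01")

        summary = h.summarize_well([[rec(100, 0)], [rec(200, 1), rec(200, 1)]])
        assert summary.mean_total == pytest.approx(500 / 3)
        assert summary.n_cells == 3 and summary.n_fields == 2

    def test_single_field_equals_its_mean(self):
        recs = [h.CellRecord(1, 10, 20, 30, 4, 4, 4), h.CellRecord(2, 30, 40, 50, 4, 4, 4)]
        summary = h.summarize_well([recs], well_id="C05")
        assert summary.mean_pm == 20 and summary.mean_total == 40

    def test_duplicated_fields_same_mean_double_count(self):
        recs = [h.CellRecord(1, 10, 10, 10, 4, 4, 4)]
        one = h.summarize_well([recs], well_id="A01")
        two = h.summarize_well([recs, list(recs)], well_id="A01")
        assert one.mean_total == two.mean_total
        assert two.n_cells == 2 * one.n_cells

    def test_zero_cells_summary_has_missing_means(self):
        summary = h.summarize_well([[]], well_id="A01")
        assert summary.n_cells == 0
        assert np.isnan(summary.mean_total)

    def test_missing_compartment_means_excluded_from_pool(self):
        nan = float("nan")
        recs = [h.CellRecord(1, nan, 20, 30, 0, 4, 4), h.CellRecord(2, 50, 40, 50, 4, 4, 4)]
        summary = h.summarize_well([recs])
        assert summary.mean_pm == 50  # NaN PM mean of cell 1 dropped, not zero-filled
        assert summary.mean_perinuclear == 30

    def test_no_fields_rejected(self):
        with pytest.raises(ParameterError):
            h.summarize_well([])
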