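"""Downstream analyses: stratified nuclei scoring, morphometry, artifact-
excluded intensity quantification, Hill regression, and removal comparison."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from artseg import downstream, synthgen
from artseg.downstream import (WellIntensityRecord, compare_removal, fit_hill,
                               fit_wells, image_specific_intensity, morphometry,
                               stratified_nuclei_eval, well_specific_intensity)
from artseg.synthgen import AssaySpec, hill_response


class TestStratifiedEval:
    def test_empty_artifact_mask_outside_equals_all(self):
        rng = np.random.default_rng(0)
        pred = rng.random((16, 16)) > 0.6
        gt = rng.random((16, 16)) > 0.6
        rep = stratified_nuclei_eval(pred, gt, np.zeros((16, 16), dtype=bool))
        assert rep["inside_artifacts"].empty
        out_c, all_c = rep["outside_artifacts"].pixel_report.counts, \
            rep["all"].pixel_report.counts
        assert (out_c.tp, out_c.fp, out_c.fn) == (all_c.tp, all_c.fp, all_c.fn)

    def test_hand_constructed_inside_outside_case(self):
        """One correct nucleus outside the artifact, one missed inside:
        inside recall 0, outside F1 1."""
        pred = np.zeros((16, 16), dtype=bool)
        gt = np.zeros((16, 16), dtype=bool)
        art = np.zeros((16, 16), dtype=bool)
        art[:, 8:] = True
        gt[2:5, 2:5] = True          # outside, predicted correctly
        pred[2:5, 2:5] = True
        gt[2:5, 10:13] = True        # inside, missed entirely
        rep = stratified_nuclei_eval(pred, gt, art)
        assert rep["inside_artifacts"].pixel_report.recall == 0.0
        assert rep["outside_artifacts"].pixel_report.f1 == 1.0
        assert rep["outside_artifacts"].object_report.f1 == 1.0

    def test_pixel_count_additivity_over_regions(self, rng):
        for _ in range(30):
            pred = rng.random((12, 12)) > 0.5
            gt = rng.random((12, 12)) > 0.5
            art = rng.random((12, 12)) > 0.5
            rep = stratified_nuclei_eval(pred, gt, art)
            if rep["inside_artifacts"].empty or rep["outside_artifacts"].empty:
                continue
            for fieldname in ("tp", "fp", "fn", "tn"):
                total = getattr(rep["all"].pixel_report.counts, fieldname)
                inside = getattr(rep["inside_artifacts"].pixel_report.counts, fieldname)
                outside = getattr(rep["outside_artifacts"].pixel_report.counts, fieldname)
                assert inside + outside == total


class TestMorphometry:
    def test_filled_square_is_fully_convex(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        recs = morphometry(labels)
        assert len(recs) == 1
        assert recs[0].area == 100
        assert recs[0].solidity == pytest.approx(1.0)

    def test_plus_shape_solidity_matches_hull_oracle(self):
        """Discrete convex-hull oracle: hull of pixel coordinates,
        rasterised by point-in-polygon on pixel centres."""
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[10:20, 13:16] = 1      # vertical bar
        labels[13:16, 8:24] = 1       # horizontal bar
        recs = morphometry(labels)
        area = int((labels == 1).sum())
        assert recs[0].area == area

        pts = np.argwhere(labels == 1).astype(float)
        hull = ConvexHull(pts)
        from matplotlib.path import Path as MplPath
        poly = MplPath(pts[hull.vertices])
        all_px = np.argwhere(np.ones_like(labels, dtype=bool)).astype(float)
        inside = poly.contains_points(all_px, radius=1e-9) \
            | poly.contains_points(all_px, radius=-1e-9)
        hull_area = int(inside.sum())
        assert recs[0].solidity == pytest.approx(area / hull_area, abs=0.02)
        assert recs[0].solidity < 1.0

    def test_two_objects_keep_their_label_ids(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[1:4, 1:4] = 3
        labels[10:14, 10:15] = 7
        recs = morphometry(labels)
        assert sorted(r.object_id for r in recs) == [3, 7]

    def test_no_objects_gives_empty_list(self):
        assert morphometry(np.zeros((8, 8), dtype=np.int32)) == []

    def test_naive_nuclei_segmenter_finds_synthetic_nuclei(self):
        f = synthgen.generate_field(synthgen.FieldSpec(seed=33, nucleus_count=10))
        pred = downstream.threshold_nuclei_segmenter(f.image)
        gt = f.nuclei_label_mask > 0
        overlap = (pred & gt).sum() / gt.sum()
        assert overlap > 0.5


class TestWellIntensity:
    def test_uniform_cells_minus_background(self):
        fluor = np.full((20, 20), 10.0)
        cells = np.zeros((20, 20), dtype=bool)
        cells[5:12, 5:12] = True
        fluor[cells] = 100.0
        cm, bm, spec = image_specific_intensity(fluor, cells)
        assert (cm, bm, spec) == (100.0, 10.0, 90.0)

    def test_artifact_pixels_excluded_from_both_means(self):
        """Artifact at aberrant intensity covering half the cells: result
        must equal the hand computation over remaining pixels only."""
        fluor = np.full((10, 10), 5.0)
        cells = np.zeros((10, 10), dtype=bool)
        cells[2:6, 2:6] = True              # 16 cell px
        fluor[cells] = 50.0
        art = np.zeros((10, 10), dtype=bool)
        art[2:6, 2:4] = True                # half the cells
        art[8:10, 8:10] = True              # some background too
        fluor[art] = 9999.0
        cm, bm, spec = image_specific_intensity(fluor, cells, art)
        keep_cells = cells & ~art
        keep_bg = ~cells & ~art
        assert cm == pytest.approx(fluor[keep_cells].mean())
        assert bm == pytest.approx(fluor[keep_bg].mean())
        assert spec == pytest.approx(cm - bm)

    def test_per_well_average_over_images(self):
        assay = AssaySpec(noise_sd=50.0, fields_per_well=4,
                          replicates_per_concentration=1,
                          concentrations=(1e-9, 1e-8, 1e-7, 1e-6), seed=2)
        plate = synthgen.generate_plate(assay)
        records = well_specific_intensity(plate)
        assert all(r.n_images_averaged == 4 for r in records)
        rec0 = records[0]
        per_image = [image_specific_intensity(im.field.fluorescence, im.field.cell_mask)[2]
                     for im in plate.images if im.well_id == rec0.well_id]
        assert rec0.specific_intensity == pytest.approx(np.mean(per_image))

    def test_unusable_well_flagged_not_fabricated(self):
        fluor = np.full((8, 8), 5.0)
        no_cells = np.zeros((8, 8), dtype=bool)
        assert image_specific_intensity(fluor, no_cells) is None


class TestHillFit:
    CONCS = tuple(10.0 ** e for e in np.linspace(-10, -4, 8))

    def test_noise_free_recovery_within_1e4_log_units(self):
        resp = hill_response(np.array(self.CONCS), -7.0, 1000.0, 100.0)
        fit = fit_hill(self.CONCS, resp)
        assert fit.logIC50 == pytest.approx(-7.0, abs=1e-4)
        assert fit.top == pytest.approx(1000.0, rel=1e-3)
        assert fit.bottom == pytest.approx(100.0, rel=1e-3)
        assert fit.r2 >= 0.999999

    def test_fitted_curve_passes_through_midpoint_at_logic50(self):
        resp = hill_response(np.array(self.CONCS), -6.2, 800.0, 50.0)
        fit = fit_hill(self.CONCS, resp)
        mid = fit.predict(np.array([10.0 ** fit.logIC50]))[0]
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-9)

    def test_r2_equals_independent_recomputation(self, rng):
        resp = hill_response(np.array(self.CONCS), -7.0, 1000.0, 100.0) \
            + rng.normal(0, 30, len(self.CONCS))
        fit = fit_hill(self.CONCS, resp)
        ss_res = float((fit.residuals ** 2).sum())
        ss_tot = float(((resp - resp.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            fit_hill([1e-9, 1e-8, 1e-7], [1, 2, 3])          # < 4 distinct
        with pytest.raises(ValueError):
            fit_hill([1e-9, -1e-8, 1e-7, 1e-6], [1, 2, 3, 4])

    def test_noisy_recovery_and_sd_calibration_over_50_plates(self):
        """Median |error| < 0.05 log units with response noise at 5% of
        Top; the asymptotic SD brackets the empirical spread within x2."""
        rng = np.random.default_rng(77)
        top, bottom, true_log = 1000.0, 100.0, -7.0
        concs = np.repeat(np.array(self.CONCS), 2)     # duplicates
        signed_errors, sds = [], []
        for _ in range(50):
            resp = hill_response(concs, true_log, top, bottom) \
                + rng.normal(0, 0.05 * top, concs.size)
            fit = fit_hill(concs, resp)
            signed_errors.append(fit.logIC50 - true_log)
            sds.append(fit.sd_logIC50)
        assert np.median(np.abs(signed_errors)) < 0.05
        empirical = float(np.std(signed_errors))
        mean_sd = float(np.mean(sds))
        assert mean_sd / 2 <= empirical <= mean_sd * 2


class TestCompareRemoval:
    @staticmethod
    def _records(intensities, concs):
        return [WellIntensityRecord(well_id=f"W{i}", ligand="L",
                                    concentration=c, mean_cell_intensity=v,
                                    mean_background_intensity=0.0,
                                    specific_intensity=v, n_images_averaged=1)
                for i, (c, v) in enumerate(zip(concs, intensities))]

    def test_identical_inputs_give_zero_delta_unit_correlation(self):
        concs = [10.0 ** e for e in np.linspace(-10, -4, 8)]
        vals = hill_response(np.array(concs), -7.0, 1000.0, 100.0)
        recs = self._records(vals, concs)
        fit = fit_wells(recs)
        out = compare_removal({"c1": (recs, fit)}, {"c1": (recs, fit)})
        assert out["mean_abs_delta_logIC50"] == 0.0
        assert out["pearson_r_well_intensities"] == pytest.approx(1.0)

    def test_pearson_matches_closed_form_on_six_wells(self):
        concs = [1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4]
        a = np.array([900.0, 850.0, 600.0, 300.0, 150.0, 110.0])
        b = a + np.array([30.0, -20.0, 45.0, -10.0, 25.0, -35.0])
        ra, rb = self._records(a, concs), self._records(b, concs)
        out = compare_removal({"c": (ra, fit_wells(ra))}, {"c": (rb, fit_wells(rb))})
        am, bm = a.mean(), b.mean()
        oracle = ((a - am) * (b - bm)).sum() / np.sqrt(
            ((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
        assert out["pearson_r_well_intensities"] == pytest.approx(oracle, rel=1e-12)

    def test_mismatched_wells_rejected(self):
        concs = [1e-9, 1e-8, 1e-7, 1e-6]
        vals = hill_response(np.array(concs), -7.0, 1000.0, 100.0)
        ra = self._records(vals, concs)
        rb = self._records(vals[:3], concs[:3])
        with pytest.raises(ValueError):
            compare_removal({"c": (ra, fit_wells(ra))}, {"c": (rb, fit_wells(rb))})


def test_true_mask_removal_beats_no_removal_on_artifact_plates():
    """With intensity-biasing artifacts, excluding true artifact pixels must
    bring the fitted LogIC50 closer to the artifact-free truth than doing
    nothing, in >= 90% of seeded replicates."""
    wins = 0
    n = 10
    template = synthgen.FieldSpec(height=64, width=64, nucleus_count=10)
    for seed in range(n):
        assay = AssaySpec(artifact_rate=0.5, noise_sd=50.0, fields_per_well=1,
                          logIC50_true=-7.0, seed=seed)
        plate = synthgen.generate_plate(assay, template)
        true_masks = {i: im.field.artifact_mask
                      for i, im in enumerate(plate.images)}
        fit_removed = fit_wells(well_specific_intensity(plate, true_masks))
        fit_raw = fit_wells(well_specific_intensity(plate, None))
        if abs(fit_removed.logIC50 - (-7.0)) < abs(fit_raw.logIC50 - (-7.0)):
            wins += 1
    assert wins >= 0.9 * n
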