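"""Ensemble metrics: weighted shifts, major peaks, KDE clusters, regions, D2O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluorens as fl
from fluorens.metrics import DEFAULT_REGIONS, RegionPartition


def peakset(*specs):
    return fl.PeakSet([fl.LorentzianPeak(c, w, a, is_contaminant=flag)
                       for c, w, a, flag in specs])


class TestMeanWeightedShift:
    def test_single_peak_identity(self):
        ps = peakset((-83.6, 0.1, 1.0, False))
        assert fl.mean_weighted_shift(ps) == pytest.approx(-83.6)

    def test_weighted_average(self):
        ps = peakset((-83.0, 0.1, 1.0, False), (-84.0, 0.1, 3.0, False))
        assert fl.mean_weighted_shift(ps) == pytest.approx(-83.75)

    def test_area_scale_invariance(self):
        ps1 = peakset((-83.0, 0.1, 1.0, False), (-84.0, 0.1, 3.0, False))
        ps2 = peakset((-83.0, 0.1, 7.0, False), (-84.0, 0.1, 21.0, False))
        assert fl.mean_weighted_shift(ps1) == pytest.approx(fl.mean_weighted_shift(ps2))

    def test_contaminant_excluded_by_default(self):
        ps = peakset((-84.0, 0.1, 1.0, False), (-83.3, 0.015, 5.0, True))
        assert fl.mean_weighted_shift(ps) == pytest.approx(-84.0)
        with_contam = fl.mean_weighted_shift(ps, exclude_contaminant=False)
        assert with_contam != pytest.approx(-84.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fl.mean_weighted_shift(fl.PeakSet())

    def test_zero_area_peak_changes_nothing(self):
        base = peakset((-83.5, 0.1, 1.0, False), (-84.1, 0.2, 2.0, False))
        padded = peakset((-83.5, 0.1, 1.0, False), (-84.1, 0.2, 2.0, False),
                         (-83.9, 0.3, 0.0, False))
        assert fl.mean_weighted_shift(padded) == pytest.approx(
            fl.mean_weighted_shift(base))
        np.testing.assert_allclose(fl.region_fractions(padded),
                                   fl.region_fractions(base))


class TestMajorPeaks:
    def test_five_percent_threshold(self):
        ps = peakset((-83.5, 0.1, 0.90, False), (-84.0, 0.1, 0.06, False),
                     (-84.5, 0.1, 0.04, False))
        kept = fl.major_peaks(ps)
        assert len(kept) == 2

    def test_strict_inequality_at_boundary(self):
        ps = peakset(*[(-83.0 - 0.1 * i, 0.1, 0.05, False) for i in range(20)])
        assert len(fl.major_peaks(ps)) == 0

    def test_single_peak_retained(self):
        ps = peakset((-84.0, 0.1, 0.4, False))
        assert len(fl.major_peaks(ps)) == 1


class TestClusterMap:
    def _blobs(self, centers, n_per, sd, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            np.column_stack([rng.normal(cx, sd[0], n_per), rng.normal(cy, sd[1], n_per)])
            for cx, cy in centers
        ])
        truth = np.repeat(np.arange(len(centers)), n_per)
        return pts, truth

    def test_three_separated_blobs_recovered(self):
        """Blob centers > 6x the within-blob sd apart: all three modes found
        and points co-labeled with their generative blob (20 seeds)."""
        centers = [(-84.3, 0.07), (-83.7, 0.30), (-83.05, 0.10)]
        hits = 0
        for seed in range(20):
            pts, truth = self._blobs(centers, 30, (0.04, 0.02), seed)
            cm = fl.cluster_peak_map(pts)
            if cm.n_clusters != 3:
                continue
            # co-labeling accuracy: majority label per true blob
            correct = 0
            for b in range(3):
                labels = cm.cluster_labels[truth == b]
                correct += np.max(np.bincount(labels)) if labels.size else 0
            if correct / pts.shape[0] >= 0.95:
                hits += 1
        assert hits >= 19

    def test_one_blob_one_cluster(self):
        pts, _ = self._blobs([(-84.0, 0.15)], 40, (0.05, 0.03), 1)
        cm = fl.cluster_peak_map(pts)
        assert cm.n_clusters == 1

    def test_duplicating_points_preserves_mode_structure(self):
        pts, _ = self._blobs([(-84.3, 0.07), (-83.6, 0.3)], 25, (0.04, 0.02), 2)
        bw = (0.05, 0.03)
        a = fl.cluster_peak_map(pts, bandwidth=bw)
        b = fl.cluster_peak_map(np.vstack([pts, pts]), bandwidth=bw)
        assert a.n_clusters == b.n_clusters
        np.testing.assert_array_equal(b.cluster_labels[: len(pts)],
                                      b.cluster_labels[len(pts):])

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fl.cluster_peak_map(np.array([[-84.0, 0.1]]))


class TestRegionFractions:
    def test_all_in_one_region(self):
        # both peaks fall in the third region (-83.75, -83.35] of the default
        # four-region partition (regions ordered upfield first)
        ps = peakset((-83.6, 0.1, 0.5, False), (-83.5, 0.1, 0.5, False))
        fr = fl.region_fractions(ps, DEFAULT_REGIONS)
        np.testing.assert_allclose(fr, [0.0, 0.0, 1.0, 0.0])

    def test_fractions_sum_to_one(self):
        ps = peakset((-85.0, 0.1, 1.0, False), (-84.0, 0.1, 2.0, False),
                     (-83.5, 0.1, 0.5, False), (-82.5, 0.1, 0.25, False))
        fr = fl.region_fractions(ps, DEFAULT_REGIONS)
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_boundary_peak_assigned_upfield(self):
        part = RegionPartition((-86.0, -84.0, -82.0))
        ps = peakset((-84.0, 0.1, 1.0, False))  # exactly on the cut
        fr = fl.region_fractions(ps, part)
        np.testing.assert_allclose(fr, [1.0, 0.0])  # region 0 is more negative

    def test_peak_outside_window_rejected(self):
        ps = peakset((-90.0, 0.1, 1.0, False))
        with pytest.raises(ValueError, match="outside partition window"):
            fl.region_fractions(ps, DEFAULT_REGIONS)


class TestD2OExposure:
    def test_large_upfield_change_is_solvent_exposed(self):
        # free BTFA moved 0.115 ppm upfield over 0->90% D2O
        pairs = [(10, 0.0), (50, -0.115 * 40 / 90), (100, -0.115)]
        slope, label = fl.d2o_exposure_analysis(np.array(pairs))
        assert label == "solvent-exposed"
        assert slope < -0.08

    def test_agonist_bound_probe_exposed(self):
        pairs = [(10, 0.0), (100, -0.116)]
        _, label = fl.d2o_exposure_analysis(np.array(pairs))
        assert label == "solvent-exposed"

    def test_downfield_drift_classified_protected_interacting(self):
        pairs = [(10, 0.0), (50, 0.05), (100, 0.12)]
        slope, label = fl.d2o_exposure_analysis(np.array(pairs))
        assert slope > 0
        assert label == "protected/interacting"

    def test_no_change_is_protected(self):
        pairs = [(10, 0.0), (50, 0.0), (100, 0.0)]
        slope, label = fl.d2o_exposure_analysis(np.array(pairs))
        assert slope == pytest.approx(0.0)
        assert label == "protected"

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="distinct D2O"):
            fl.d2o_exposure_analysis(np.array([(10, 0.0), (10, 0.01)]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.floats(-85.0, -83.0), st.floats(0.01, 1.0),
                          st.floats(0.01, 10.0)), min_size=1, max_size=6))
def test_mean_shift_bounded_by_extreme_centers(peaks):
    """The area-weighted mean always lies within [min, max] of the centers."""
    ps = fl.PeakSet([fl.LorentzianPeak(c, w, a) for c, w, a in peaks])
    mws = fl.mean_weighted_shift(ps)
    centers = [c for c, _, _ in peaks]
    assert min(centers) - 1e-9 <= mws <= max(centers) + 1e-9
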