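"""Tile fusion, segmentation scoring, occurrence sampling/thinning, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import enmkit as ek
from enmkit.datasets import wuyishan_area_tables, wuyishan_confusion_counts
from enmkit.errors import (AlignmentError, DomainError, InsufficientDataError,
                           OutOfBoundsError)


class TestFuseAndBinarize:
    def test_overlap_keeps_maximum(self):
        layout = ek.GridSpec(2, 3, 1.0)
        tiles = [(np.full((2, 2), 0.3), (0, 0)), (np.full((2, 2), 0.7), (0, 1))]
        out = ek.fuse_and_binarize(tiles, layout, threshold=0.5)
        assert out.probability[0, 1] == 0.7
        assert out.labels[0, 1] == 1
        assert out.labels[0, 0] == 0  # only covered at 0.3

    def test_fusion_order_invariant(self):
        layout = ek.GridSpec(4, 4, 1.0)
        rng = np.random.default_rng(0)
        tiles = [(rng.random((2, 2)), (i, j)) for i in (0, 1, 2) for j in (0, 1, 2)]
        a = ek.fuse_and_binarize(tiles, layout, 0.5)
        b = ek.fuse_and_binarize(tiles[::-1], layout, 0.5)
        np.testing.assert_array_equal(a.probability, b.probability)

    def test_non_overlapping_tiles_concatenate(self):
        # stride equal to the tile size: fusion must equal plain concatenation
        layout = ek.GridSpec(4, 8, 1.0)
        rng = np.random.default_rng(1)
        left, right = rng.random((4, 4)), rng.random((4, 4))
        out = ek.fuse_and_binarize([(left, (0, 0)), (right, (0, 4))], layout, 0.5)
        np.testing.assert_array_equal(out.probability, np.hstack([left, right]))

    def test_bad_inputs_rejected(self):
        layout = ek.GridSpec(2, 2, 1.0)
        with pytest.raises(OutOfBoundsError):
            ek.fuse_and_binarize([(np.zeros((3, 3)), (0, 0))], layout, 0.5)
        with pytest.raises(DomainError):
            ek.fuse_and_binarize([(np.full((2, 2), 1.5), (0, 0))], layout, 0.5)


class TestSegmentationMetrics:
    def test_perfect_prediction(self):
        g = ek.GridSpec(4, 4, 1.0)
        labels = np.zeros((4, 4), dtype=int)
        labels[:2] = 1
        r = ek.ClassificationRaster(g, labels)
        m = ek.segmentation_metrics(r, r)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_matches_bruteforce_confusion_counts(self):
        rng = np.random.default_rng(2)
        g = ek.GridSpec(15, 15, 1.0)
        p = ek.ClassificationRaster(g, rng.integers(0, 2, g.shape))
        t = ek.ClassificationRaster(g, rng.integers(0, 2, g.shape))
        m = ek.segmentation_metrics(p, t)
        tp = sum(int(pi == ti == 1) for pi, ti in
                 zip(p.labels.ravel(), t.labels.ravel()))
        fp = sum(int(pi == 1 and ti == 0) for pi, ti in
                 zip(p.labels.ravel(), t.labels.ravel()))
        fn = sum(int(pi == 0 and ti == 1) for pi, ti in
                 zip(p.labels.ravel(), t.labels.ravel()))
        assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
        assert m.tp + m.tn + m.fp + m.fn == 225

    def test_published_map_quality_reproduced(self):
        # counts consistent with the published Wuyishan tea map evaluation
        m = wuyishan_confusion_counts()
        assert round(m.precision, 3) == 0.972
        assert round(m.recall, 3) == 0.935
        assert round(m.f1, 3) == 0.953
        assert round(m.accuracy, 3) == 0.993

    def test_grid_mismatch_rejected(self):
        a = ek.ClassificationRaster(ek.GridSpec(2, 2, 1.0), np.zeros((2, 2)))
        b = ek.ClassificationRaster(ek.GridSpec(2, 2, 2.0), np.zeros((2, 2)))
        with pytest.raises(AlignmentError):
            ek.segmentation_metrics(a, b)


class TestSampleOccurrences:
    def test_samples_distinct_positive_centers(self):
        g = ek.GridSpec(3, 3, 1.0)
        labels = np.zeros((3, 3), dtype=int)
        labels[0, 0] = labels[1, 1] = labels[2, 2] = labels[0, 2] = labels[2, 0] = 1
        r = ek.ClassificationRaster(g, labels)
        pts = ek.sample_occurrences(r, 3, seed=0)
        assert len(pts.drop_duplicates()) == 3
        rows, cols = g.rowcol(pts["x"].to_numpy(), pts["y"].to_numpy())
        assert all(labels[ri, ci] == 1 for ri, ci in zip(rows, cols))

    def test_exhaustive_and_overdraw(self):
        g = ek.GridSpec(2, 2, 1.0)
        r = ek.ClassificationRaster(g, np.array([[1, 0], [1, 1]]))
        assert len(ek.sample_occurrences(r, 3, seed=1)) == 3
        with pytest.raises(InsufficientDataError):
            ek.sample_occurrences(r, 4, seed=1)


class TestThinByGrid:
    def test_keeps_first_per_cell(self):
        env = ek.GridSpec(2, 2, 10.0)
        pts = pd.DataFrame({"x": [1.0, 2.0, 3.0, 15.0], "y": [1.0, 2.0, 3.0, 1.0]})
        out = ek.thin_by_grid(pts, env)
        assert len(out) == 2
        assert out.iloc[0]["x"] == 1.0  # first point of the crowded cell kept

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 39.99), st.floats(0, 39.99)),
                    min_size=0, max_size=60))
    def test_idempotent_and_bounded_by_occupied_cells(self, coords):
        env = ek.GridSpec(4, 4, 10.0)
        pts = pd.DataFrame(coords, columns=["x", "y"])
        once = ek.thin_by_grid(pts, env)
        twice = ek.thin_by_grid(once, env)
        pd.testing.assert_frame_equal(once, twice)
        if len(pts):
            rows, cols = env.rowcol(pts["x"].to_numpy(), pts["y"].to_numpy())
            occupied = len(set(zip(rows.tolist(), cols.tolist())))
            assert len(once) == occupied


class TestAreaConcordance:
    def test_published_township_table_statistics(self):
        est, ref = wuyishan_area_tables()
        stats = ek.area_concordance(est, ref)
        assert round(stats.mae, 2) == 1.51
        assert round(stats.rmse, 2) == 2.45
        xingcun = stats.table.set_index("unit").loc["Xingcun town", "abs_error"]
        assert round(xingcun, 2) == 2.83

    def test_identical_tables_have_zero_error(self):
        est, _ = wuyishan_area_tables()
        stats = ek.area_concordance(est, est.copy())
        assert stats.mae == 0.0 and stats.rmse == 0.0

    def test_unit_mismatch_lists_names(self):
        est, ref = wuyishan_area_tables()
        with pytest.raises(AlignmentError, match="Xingcun"):
            ek.area_concordance(est.replace("Xingcun town", "Elsewhere"), ref)
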