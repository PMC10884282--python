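"""YOLO label I/O, dataset splitting, mosaic augmentation, k-means anchors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polypdet.boxes import iou_xywh
from polypdet.data import (
    AnchorSet,
    kmeans_anchors,
    mosaic,
    read_yolo_labels,
    split_dataset,
    write_yolo_labels,
)


class TestYoloLabels:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n")
        items = read_yolo_labels(p)
        assert len(items) == 1
        cls, box = items[0]
        assert cls == 0
        np.testing.assert_allclose(box, [0.5, 0.5, 0.2, 0.1])

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    def test_out_of_range_center_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n0 1.5 0.5 0.2 0.1\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(p)

    @pytest.mark.parametrize("line", ["0 0.5 0.5 0.2", "x 0.5 0.5 0.2 0.1",
                                      "0 0.5 0.5 0 0.1"])
    def test_malformed_lines_rejected(self, tmp_path, line):
        p = tmp_path / "bad.txt"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=":1"):
            read_yolo_labels(p)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        items = [(int(c), np.array([cx, cy, w, h]))
                 for c, cx, cy, w, h in zip(
                     rng.integers(0, 3, 20),
                     rng.uniform(0.2, 0.8, 20), rng.uniform(0.2, 0.8, 20),
                     rng.uniform(0.01, 0.3, 20), rng.uniform(0.01, 0.3, 20))]
        p = tmp_path / "rt.txt"
        write_yolo_labels(p, items)
        back = read_yolo_labels(p)
        assert len(back) == len(items)
        for (c0, b0), (c1, b1) in zip(items, back):
            assert c0 == c1
            np.testing.assert_allclose(b0, b1, atol=5e-7)  # 6-decimal format


class TestSplit:
    def test_study_scale_split(self):
        train, val, test = split_dataset(list(range(1200)), (8, 1, 1), seed=0)
        assert (len(train), len(val), len(test)) == (960, 120, 120)

    def test_ten_items(self):
        sizes = tuple(len(s) for s in split_dataset(list(range(10)), (8, 1, 1), seed=1))
        assert sizes == (8, 1, 1)

    def test_nine_items_remainder_rule(self):
        sizes = tuple(len(s) for s in split_dataset(list(range(9)), (8, 1, 1), seed=2))
        assert sizes == (7, 1, 1)

    def test_too_few_items(self):
        with pytest.raises(ValueError, match="partitions"):
            split_dataset([1, 2], (8, 1, 1), seed=0)

    @settings(max_examples=30, derandomize=True)
    @given(n=st.integers(3, 400), seed=st.integers(0, 10))
    def test_partitions_disjoint_exhaustive_reproducible(self, n, seed):
        items = list(range(n))
        parts = split_dataset(items, (8, 1, 1), seed=seed)
        flat = [x for p in parts for x in p]
        assert sorted(flat) == items              # exhaustive, disjoint
        again = split_dataset(items, (8, 1, 1), seed=seed)
        assert all(a == b for a, b in zip(parts, again))  # reproducible


class TestMosaic:
    @staticmethod
    def solid(color, size=64):
        img = np.full((size, size, 3), color, dtype=np.uint8)
        return img

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="4"):
            mosaic([(self.solid(0), [])] * 3, out_size=64)

    def test_centered_boxes_survive(self):
        four = [(self.solid(c), [(0, np.array([0.5, 0.5, 0.1, 0.1]))])
                for c in (10, 60, 120, 200)]
        canvas, boxes = mosaic(four, out_size=128, seed=3)
        assert canvas.shape == (128, 128, 3)
        assert 1 <= len(boxes) <= 4
        for _, b in boxes:
            assert np.all(b[:2] - b[2:] / 2 >= -1e-9)
            assert np.all(b[:2] + b[2:] / 2 <= 1 + 1e-9)
            assert np.all(b[2:] > 0)

    def test_quadrant_pixel_provenance(self):
        colors = (10, 60, 120, 200)
        four = [(self.solid(c), []) for c in colors]
        canvas, _ = mosaic(four, out_size=64, seed=5)
        # locate the junction: each quadrant is one solid source colour
        xs = np.unique(canvas[:, :, 0])
        assert set(xs).issubset(set(colors))
        assert canvas[0, 0, 0] == colors[0]
        assert canvas[0, -1, 0] == colors[1]
        assert canvas[-1, 0, 0] == colors[2]
        assert canvas[-1, -1, 0] == colors[3]

    def test_box_outside_crop_dropped(self):
        # object hugging the far corner of a source mostly cropped away
        img = self.solid(50, size=64)
        objs = [(0, np.array([0.99, 0.99, 0.01, 0.01]))]
        dropped = 0
        for seed in range(30):
            _, boxes = mosaic([(img, objs)] * 4, out_size=64, seed=seed)
            dropped += 4 - len(boxes)
        assert dropped > 0

    def test_boxes_always_valid_over_many_seeds(self):
        rng = np.random.default_rng(0)
        img = self.solid(90, size=48)
        for seed in range(100):
            objs = [(0, np.array([rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                                  rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4)]))]
            _, boxes = mosaic([(img, objs)] * 4, out_size=96, seed=seed)
            for _, b in boxes:
                assert np.all(b[2:] > 0)
                assert np.all(b[:2] - b[2:] / 2 >= -1e-9)
                assert np.all(b[:2] + b[2:] / 2 <= 1 + 1e-9)


class TestMixup:
    def test_blend_is_convex_and_labels_union(self):
        a = np.full((32, 32, 3), 200, dtype=np.uint8)
        b = np.full((32, 32, 3), 40, dtype=np.uint8)
        objs_a = [(0, np.array([0.3, 0.3, 0.1, 0.1]))]
        objs_b = [(0, np.array([0.7, 0.7, 0.1, 0.1]))]
        from polypdet.data import mixup
        blended, objs = mixup(a, objs_a, b, objs_b, seed=4)
        assert 40 <= blended.mean() <= 200
        assert len(objs) == 2


def brute_force_two_means(wh):
    """Enumerate every 2-partition; minimize total 1−IoU to partition means."""
    n = len(wh)
    best, best_cost = None, np.inf
    for mask_bits in range(1, 2**n - 1):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        cents = []
        for m in (mask, ~mask):
            c = wh[m].mean(axis=0)
            cents.append(c)
            a = np.concatenate([np.zeros((m.sum(), 2)), wh[m]], axis=1)
            b = np.concatenate([np.zeros(2), c])
            cost += (1 - iou_xywh(a, b)).sum()
        if cost < best_cost:
            best_cost, best = cost, np.array(sorted(map(tuple, cents)))
    return best


class TestKmeansAnchors:
    def test_identical_boxes_k1(self):
        aset = kmeans_anchors([(0.2, 0.3)] * 6, k=1)
        np.testing.assert_allclose(aset.wh, [[0.2, 0.3]])

    def test_two_separated_clusters(self):
        wh = np.array([[0.1, 0.1]] * 5 + [[0.4, 0.4]] * 5)
        aset = kmeans_anchors(wh, k=2, seed=0)
        np.testing.assert_allclose(aset.wh, [[0.1, 0.1], [0.4, 0.4]], atol=1e-12)

    def test_matches_brute_force_oracle_on_ten_boxes(self):
        rng = np.random.default_rng(7)
        wh = np.vstack([rng.uniform(0.05, 0.12, (5, 2)), rng.uniform(0.3, 0.45, (5, 2))])
        aset = kmeans_anchors(wh, k=2, seed=0)
        expected = brute_force_two_means(wh)
        np.testing.assert_allclose(np.array(sorted(map(tuple, aset.wh))), expected, atol=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k=11"):
            kmeans_anchors(np.full((10, 2), 0.1) + np.arange(10)[:, None] * 0.01, k=11)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        wh = rng.uniform(0.02, 0.5, (40, 2))
        a1 = kmeans_anchors(wh, k=4, seed=0)
        a2 = kmeans_anchors(wh[rng.permutation(40)], k=4, seed=0)
        np.testing.assert_allclose(a1.wh, a2.wh, atol=1e-12)

    def test_euclidean_metric_also_available(self):
        wh = np.array([[0.1, 0.1]] * 5 + [[0.4, 0.4]] * 5)
        aset = kmeans_anchors(wh, k=2, metric="euclidean")
        np.testing.assert_allclose(aset.wh, [[0.1, 0.1], [0.4, 0.4]], atol=1e-12)

    def test_anchorset_sorted_by_area_and_partition(self):
        aset = AnchorSet(np.array([[0.5, 0.5], [0.1, 0.1], [0.3, 0.3], [0.2, 0.2],
                                   [0.05, 0.05], [0.4, 0.4]]))
        areas = aset.wh[:, 0] * aset.wh[:, 1]
        assert np.all(np.diff(areas) >= 0)
        per = aset.per_scale(3)
        assert per.shape == (3, 2, 2)
        with pytest.raises(ValueError, match="divide"):
            aset.per_scale(4)
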