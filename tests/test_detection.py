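"""Tile detection merging: globalize, deduplicate, midpoints, checkpoints."""

import numpy as np
import pytest

import hepazone as hz
from hepazone.detection import Detection, DetectionSet, run_backend_on_grid
from hepazone.tiling import TileGrid


def det(cls, box, tile_index, score=1.0):
    return Detection(hz.StructureClass(cls), score, *box, tile_index)


class TestGlobalize:
    def test_origin_zero_unchanged(self):
        grid = hz.make_tile_grid((512, 512), 512)
        d = DetectionSet([det("PF", (10, 10, 20, 20), 0)])
        out = hz.globalize(d, grid)
        assert (out.detections[0].x_min, out.detections[0].y_min) == (10, 10)
        assert out.frame == "wsi_global"

    def test_offset_added(self):
        grid = hz.make_tile_grid((1024, 1024), 512)
        t = next(t for t in grid if (t.x0, t.y0) == (256, 256))
        d = DetectionSet([det("CV", (10, 10, 20, 20), t.index)])
        g = hz.globalize(d, grid).detections[0]
        assert (g.x_min, g.y_min, g.x_max, g.y_max) == (266, 266, 276, 276)

    def test_elementwise_oracle_random(self):
        rng = np.random.default_rng(9)
        grid = hz.make_tile_grid((2048, 2048), 512)
        dets = []
        for _ in range(80):
            ti = int(rng.integers(0, len(grid)))
            x0, y0 = rng.uniform(0, 400, 2)
            dets.append(det("PF", (x0, y0, x0 + 30, y0 + 30), ti))
        out = hz.globalize(DetectionSet(dets), grid)
        for a, b in zip(dets, out.detections):
            t = grid[a.tile_index]
            assert (b.x_min, b.y_min) == (a.x_min + t.x0, a.y_min + t.y0)
            assert (b.x_max, b.y_max) == (a.x_max + t.x0, a.y_max + t.y0)

    def test_unknown_tile_raises(self):
        grid = hz.make_tile_grid((512, 512), 512)
        d = DetectionSet([det("PF", (0, 0, 5, 5), 99)])
        with pytest.raises(KeyError):
            hz.globalize(d, grid)


def brute_force_dedup(ds, grid, thr=0.5):
    """Independent reference: BFS transitive IoU grouping + max interior rule."""

    def iou(a, b):
        ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
        iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
        if ix <= 0 or iy <= 0:
            return 0.0
        i = ix * iy
        return i / (a.area + b.area - i)

    def interior_int(d):
        x0, y0, x1, y1 = grid[d.tile_index].interior
        return max(0.0, min(d.x_max, x1) - max(d.x_min, x0)) * \
            max(0.0, min(d.y_max, y1) - max(d.y_min, y0))

    items = list(ds)
    unvisited = set(range(len(items)))
    survivors = []
    while unvisited:
        seed = min(unvisited)
        group = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for j in list(unvisited - group):
                if items[j].cls == items[cur].cls and iou(items[cur], items[j]) >= thr:
                    group.add(j)
                    frontier.append(j)
        unvisited -= group
        best = min(group, key=lambda i: (-interior_int(items[i]),
                                         grid[items[i].tile_index].y0,
                                         grid[items[i].tile_index].x0, i))
        survivors.append(items[best])
    return sorted(survivors, key=lambda d: (d.y_min, d.x_min, d.cls.value))


class TestDeduplicate:
    def test_box_inside_interior_kept_once(self):
        grid = hz.make_tile_grid((1024, 1024), 512)
        d = DetectionSet([det("PF", (200, 200, 230, 230), 0)], frame="wsi_global")
        out = hz.deduplicate(d, grid)
        assert len(out) == 1

    def test_straddling_duplicate_max_interior_wins(self):
        # tiles (0,0) and (256,0), s=512: interiors split at x=384.
        # box (354,200)-(394,230): 30x30=900 px^2 inside tile0's interior,
        # 10x30=300 px^2 inside tile1's -> tile0 copy survives.
        grid = hz.make_tile_grid((1024, 512), 512)
        t0 = next(t for t in grid if (t.x0, t.y0) == (0, 0))
        t1 = next(t for t in grid if (t.x0, t.y0) == (256, 0))
        box = (354, 200, 394, 230)
        d = DetectionSet([det("CV", box, t1.index), det("CV", box, t0.index)],
                         frame="wsi_global")
        out = hz.deduplicate(d, grid)
        assert len(out) == 1
        assert out.detections[0].tile_index == t0.index

    def test_four_tile_corner_single_survivor_tiebreak(self):
        # box centered exactly on an interior corner: equal intersection in
        # all four tiles -> lexicographically smallest (y0, x0) tile wins
        grid = hz.make_tile_grid((1024, 1024), 512)
        corner = (384.0, 384.0)
        box = (corner[0] - 10, corner[1] - 10, corner[0] + 10, corner[1] + 10)
        quad = [t for t in grid if (t.x0, t.y0) in
                {(0, 0), (256, 0), (0, 256), (256, 256)}]
        d = DetectionSet([det("PF", box, t.index) for t in quad], frame="wsi_global")
        out = hz.deduplicate(d, grid)
        assert len(out) == 1
        t = grid[out.detections[0].tile_index]
        assert (t.y0, t.x0) == (0, 0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        grid = hz.make_tile_grid((1024, 1024), 512)
        for _ in range(100):
            dets = []
            n_struct = rng.integers(1, 8)
            for _ in range(n_struct):
                cx, cy = rng.uniform(60, 960, 2)
                w, h = rng.uniform(20, 60, 2)
                box = (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
                # up to 4 tiles repeating the same structure, small jitter
                tiles = [t for t in grid
                         if t.x0 <= box[0] and box[2] <= t.x0 + 512
                         and t.y0 <= box[1] and box[3] <= t.y0 + 512]
                for t in tiles:
                    jit = rng.normal(0, 1.0, 4) * rng.choice([0, 1])
                    b = (box[0] + jit[0], box[1] + jit[1], box[2] + jit[2], box[3] + jit[3])
                    if b[0] < b[2] and b[1] < b[3]:
                        dets.append(det(rng.choice(["PF", "CV"]), b, t.index))
            if not dets:
                continue
            ds = DetectionSet(dets, frame="wsi_global")
            got = hz.deduplicate(ds, grid).detections
            expect = brute_force_dedup(ds, grid)
            assert [(d.x_min, d.y_min, d.tile_index) for d in got] == \
                   [(d.x_min, d.y_min, d.tile_index) for d in expect]

    def test_no_high_iou_pair_after_dedup(self):
        rng = np.random.default_rng(4)
        grid = hz.make_tile_grid((1024, 1024), 512)
        dets = []
        for _ in range(40):
            cx, cy = rng.uniform(100, 900, 2)
            dets.append(det("PF", (cx - 15, cy - 15, cx + 15, cy + 15),
                            int(rng.integers(0, len(grid)))))
        out = hz.deduplicate(DetectionSet(dets, frame="wsi_global"), grid)
        from hepazone.detection import _iou
        survivors = out.detections
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                if survivors[i].cls == survivors[j].cls:
                    assert _iou(survivors[i], survivors[j]) < 0.5


class TestOracleAndEndToEnd:
    def test_perfect_oracle_reproduces_truth_centers(self, small_phantom):
        grid = hz.make_tile_grid(small_phantom.layout.extent, 200)
        backend = hz.oracle_detector(small_phantom.boxes, 0, 0, 0, seed=1)
        pts = hz.run_wsi_detection(None, grid, backend)
        got = {(round(p.x, 6), round(p.y, 6), p.cls) for p in pts.points}
        want = {(round((b.x_min + b.x_max) / 2, 6), round((b.y_min + b.y_max) / 2, 6), b.cls)
                for b in small_phantom.boxes.boxes}
        assert got == want

    def test_miss_rate_one_empty_output(self, small_phantom):
        grid = hz.make_tile_grid(small_phantom.layout.extent, 200)
        backend = hz.oracle_detector(small_phantom.boxes, 0, 1.0, 0, seed=1)
        pts = hz.run_wsi_detection(None, grid, backend)
        assert len(pts) == 0

    def test_merging_invariant_to_tile_order(self, small_phantom):
        extent = small_phantom.layout.extent
        grid = hz.make_tile_grid(extent, 200)
        shuffled = TileGrid(200, extent, list(reversed(grid.tiles)))
        backend = hz.oracle_detector(small_phantom.boxes, 1.0, 0.1, 0.3, seed=6)

        def points_of(g):
            local = run_backend_on_grid(None, g, backend)
            merged = hz.deduplicate(hz.globalize(local, g), g)
            return sorted((round(d.x_min, 9), round(d.y_min, 9), d.cls.value)
                          for d in merged)

        assert points_of(grid) == points_of(shuffled)

    def test_noisy_backend_reproducible_given_seed(self, small_phantom):
        grid = hz.make_tile_grid(small_phantom.layout.extent, 200)
        runs = []
        for _ in range(2):
            backend = hz.oracle_detector(small_phantom.boxes, 2.0, 0.2, 0.2, seed=13)
            pts = hz.run_wsi_detection(None, grid, backend)
            runs.append(sorted((p.x, p.y, p.cls.value) for p in pts.points))
        assert runs[0] == runs[1]


class TestCheckpointSelection:
    def _truth(self):
        items = [hz.BoxAnnotation(hz.StructureClass.PF, 10 * i, 10, 10 * i + 8, 18)
                 for i in range(1, 20)]
        items += [hz.BoxAnnotation(hz.StructureClass.CV, 10 * i, 40, 10 * i + 8, 48)
                  for i in range(1, 20)]
        return hz.AnnotationSet(items, 227.0, (400, 100))

    def _points_with_recall(self, truth, frac, cls_count=19):
        items = []
        for b in truth.boxes[:int(frac * len(truth.boxes))]:
            cx, cy = b.center
            items.append(hz.PointAnnotation(b.cls, cx, cy))
        return hz.AnnotationSet(items, 227.0, (400, 100))

    def test_single_epoch(self):
        truth = self._truth()
        pts = self._points_with_recall(truth, 1.0)
        assert hz.select_best_checkpoint([pts], truth) == 0

    def test_tie_goes_to_earliest(self):
        truth = self._truth()
        weak = self._points_with_recall(truth, 0.3)
        strong = self._points_with_recall(truth, 1.0)
        assert hz.select_best_checkpoint([weak, strong, strong], truth) == 1

    def test_argmax_matches_independent_f1_table(self):
        truth = self._truth()
        epochs = [self._points_with_recall(truth, f) for f in (0.2, 0.5, 0.9, 0.7)]
        f1s = []
        for pts in epochs:
            counts = hz.match_points_to_boxes(pts, truth)
            rows = {c: hz.metrics_from_counts(counts[c]) for c in counts}
            f1s.append(hz.mean_class_metrics(rows).f1)
        assert hz.select_best_checkpoint(epochs, truth) == int(np.argmax(f1s))

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            hz.select_best_checkpoint([], self._truth())
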