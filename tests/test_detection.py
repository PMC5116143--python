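import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icount import (
    DetectedObject,
    DetectionParams,
    GrayImage,
    ParameterError,
    Rect,
    binarize,
    classify_objects,
    count_eggs,
    count_rafts,
    estimate_by_histogram,
    estimate_cluster,
    label_components,
    reference_egg_area,
)
from icount.detection import (
    Component,
    read_objects_csv,
    round_half_up,
    write_objects_csv,
    write_summary_csv,
)
from icount.synthstrip import StripSpec, generate_strip

from conftest import components_from_labels, flood_fill_components, make_blob_image


def _obj(box_h, box_w, pixel_area=None, status="uncertain"):
    bbox = Rect(0, 0, box_h, box_w)
    return DetectedObject(
        object_id=1, bbox=bbox,
        pixel_area=pixel_area if pixel_area is not None else bbox.area,
        status=status, estimated_count=1,
    )


class TestParams:
    def test_defaults(self):
        p = DetectionParams()
        assert (p.bw_threshold, p.min_box_area, p.max_box_area) == (80, 800, 1400)
        assert p.connectivity == 8 and p.mode == "micro"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bw_threshold": -1},
            {"bw_threshold": 256},
            {"min_box_area": 0},
            {"min_box_area": 1400, "max_box_area": 800},
            {"connectivity": 6},
            {"mode": "telephoto"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            DetectionParams(**kwargs)


class TestBinarize:
    def test_all_white_empty(self, blank_image):
        assert not binarize(blank_image, 80).any()

    def test_all_black_full(self):
        img = GrayImage(np.zeros((5, 5), dtype=np.uint8))
        assert binarize(img, 80).all()

    def test_threshold_zero_always_empty(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.integers(0, 256, (20, 20), dtype=np.uint8))
        assert not binarize(img, 0).any()

    def test_strictly_below_threshold(self):
        img = GrayImage(np.array([[79, 80, 81]], dtype=np.uint8))
        assert binarize(img, 80).tolist() == [[True, False, False]]

    def test_invalid_threshold(self, blank_image):
        with pytest.raises(ParameterError):
            binarize(blank_image, 300)

    @given(st.integers(0, 255), st.integers(0, 255))
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(42)
        img = GrayImage(rng.integers(0, 256, (12, 12), dtype=np.uint8))
        assert not (binarize(img, lo) & ~binarize(img, hi)).any()


class TestLabelComponents:
    def test_solid_block(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        comps, labels = label_components(mask, 8)
        assert len(comps) == 1
        assert comps[0].pixel_area == 9
        assert comps[0].bbox == Rect(1, 1, 4, 4)
        assert (labels == 1).sum() == 9

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, 8)[0]) == 1
        assert len(label_components(mask, 4)[0]) == 2

    def test_empty_mask(self):
        comps, labels = label_components(np.zeros((3, 3), dtype=bool), 8)
        assert comps == [] and not labels.any()

    def test_scan_order_reproducible(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[6, 1] = True   # lower-left
        mask[1, 7] = True   # upper-right
        mask[1, 2] = True   # upper-left
        comps, _ = label_components(mask, 8)
        tops = [(c.bbox.top, c.bbox.left) for c in comps]
        assert tops == sorted(tops) == [(1, 2), (1, 7), (6, 1)]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            mask = rng.random((12, 12)) < 0.4
            comps, labels = label_components(mask, connectivity)
            assert components_from_labels(labels) == flood_fill_components(
                mask, connectivity
            )
            # conservation: every foreground pixel is accounted for once
            assert sum(c.pixel_area for c in comps) == int(mask.sum())


class TestClassify:
    @pytest.mark.parametrize(
        "h, w, status",
        [
            (30, 30, "confident"),   # 900 within [800, 1400]
            (20, 20, "rejected"),    # 400 < 800
            (60, 40, "uncertain"),   # 2400 > 1400
            (20, 40, "confident"),   # 800 boundary inclusive
            (35, 40, "confident"),   # 1400 boundary inclusive
        ],
    )
    def test_box_area_bands(self, h, w, status, default_params):
        comp = Component(bbox=Rect(0, 0, h, w), pixel_area=h * w // 2)
        obj = classify_objects([comp], default_params)[0]
        assert obj.status == status
        assert obj.estimated_count == (0 if status == "rejected" else 1)

    def test_monotone_in_band_edges(self, default_params):
        comp = Component(bbox=Rect(0, 0, 30, 30), pixel_area=500)
        base = classify_objects([comp], default_params)[0].status
        wider = DetectionParams(min_box_area=700, max_box_area=1500)
        assert base == "confident"
        assert classify_objects([comp], wider)[0].status == "confident"


class TestReferenceArea:
    def test_median_of_confident(self, default_params):
        objs = [
            _obj(30, 30, pixel_area=a, status="confident")
            for a in (900, 1000, 1100)
        ]
        assert reference_egg_area(objs, default_params) == 1000

    def test_single_confident(self, default_params):
        objs = [_obj(30, 30, pixel_area=950, status="confident")]
        assert reference_egg_area(objs, default_params) == 950

    def test_fallback_without_confident(self, default_params):
        # 0.7 x midpoint of [800, 1400] = 0.7 x 1100 = 770
        assert reference_egg_area([], default_params) == 770
        objs = [_obj(10, 10, status="rejected")]
        assert reference_egg_area(objs, default_params) == 770

    def test_uncertain_objects_excluded(self, default_params):
        objs = [
            _obj(30, 30, pixel_area=900, status="confident"),
            _obj(60, 60, pixel_area=3000, status="uncertain"),
        ]
        assert reference_egg_area(objs, default_params) == 900


class TestEstimateCluster:
    @pytest.mark.parametrize(
        "pixel_area, reference, expected",
        [(2000, 1000, 2), (2600, 1000, 3), (700, 1000, 1), (2499, 1000, 2),
         (2500, 1000, 3)],
    )
    def test_ratio_rounded_half_up_floored(self, pixel_area, reference, expected):
        obj = _obj(60, 60, pixel_area=pixel_area)
        assert estimate_cluster(obj, reference) == expected

    def test_invalid_reference(self):
        with pytest.raises(ParameterError):
            estimate_cluster(_obj(60, 60), 0)

    @given(st.integers(1, 10_000), st.integers(1, 3_000))
    def test_at_least_one(self, pixel_area, reference):
        assert estimate_cluster(_obj(60, 60, pixel_area=pixel_area), reference) >= 1


class TestRoundHalfUp:
    @pytest.mark.parametrize("x, expected", [(0.5, 1), (1.5, 2), (2.4, 2),
                                             (2.5, 3), (76.245, 76)])
    def test_values(self, x, expected):
        assert round_half_up(x) == expected


class TestCountEggs:
    def test_blank_image(self, blank_image, default_params):
        res = count_eggs(blank_image, default_params)
        assert res.objects == [] and res.total_estimate == 0

    def test_isolated_synthetic_eggs_counted_exactly(self):
        spec = StripSpec(n_eggs=10, cluster_fraction=0.0, seed=5)
        image, truth = generate_strip(spec)
        res = count_eggs(image)
        assert res.total_estimate == truth.total_eggs == 10
        assert res.n_confident == 10

    def test_merged_pair_estimated_as_two(self, default_params):
        # many isolated 30x30 eggs fix the reference near 900; one blob of
        # twice that pixel area must be flagged and estimated as 2
        blobs = [(10 + 40 * i, 10, 30, 30) for i in range(5)]
        blobs.append((10, 100, 36, 50))  # 1800 px, box 1800 > 1400
        img = make_blob_image((300, 200), blobs)
        res = count_eggs(img, default_params)
        assert res.n_uncertain == 1
        uncertain = [o for o in res.objects if o.status == "uncertain"][0]
        assert uncertain.estimated_count == 2
        assert res.total_estimate == 7

    def test_total_is_sum_of_counts(self):
        spec = StripSpec(n_eggs=40, cluster_fraction=0.2, seed=9)
        image, _ = generate_strip(spec)
        res = count_eggs(image)
        assert res.total_estimate == sum(o.estimated_count for o in res.objects)
        assert res.total_estimate >= res.n_confident

    def test_conservation_of_foreground(self, default_params):
        spec = StripSpec(n_eggs=30, cluster_fraction=0.1, seed=2)
        image, _ = generate_strip(spec)
        res = count_eggs(image, default_params)
        mask = binarize(image, default_params.bw_threshold)
        assert sum(o.pixel_area for o in res.objects) == int(mask.sum())

    def test_deterministic(self):
        spec = StripSpec(n_eggs=25, cluster_fraction=0.1, seed=3)
        image, _ = generate_strip(spec)
        a = count_eggs(image)
        b = count_eggs(image)
        assert a.total_estimate == b.total_estimate
        assert [o.bbox for o in a.objects] == [o.bbox for o in b.objects]


class TestHistogramEstimate:
    def test_blank(self, blank_image, default_params):
        assert estimate_by_histogram(blank_image, default_params, 1000) == 0

    def test_exact_division(self, default_params):
        # 10 disjoint blobs of exactly 1000 foreground px, reference 1000
        blobs = [(5 + 45 * i, 5, 25, 40) for i in range(10)]
        img = make_blob_image((500, 60), blobs)
        assert estimate_by_histogram(img, default_params, 1000) == 10

    def test_matches_pixel_count_oracle(self, default_params):
        spec = StripSpec(n_eggs=40, cluster_fraction=0.05, seed=21)
        image, _ = generate_strip(spec)
        ref = count_eggs(image).reference_area
        est = estimate_by_histogram(image, default_params, ref)
        foreground = int((image.pixels < 80).sum())  # independent recount
        assert est == round_half_up(foreground / ref)

    def test_invalid_reference(self, blank_image, default_params):
        with pytest.raises(ParameterError):
            estimate_by_histogram(blank_image, default_params, 0)


class TestCountRafts:
    def _raft_params(self):
        return DetectionParams(mode="raft")

    def test_blank(self, blank_image):
        assert count_rafts(blank_image, self._raft_params()).total_estimate == 0

    def test_large_blobs_count_once_each(self):
        # three blobs far above max_box_area still count 1 each
        img = make_blob_image((400, 400), [(10, 10, 60, 60), (150, 150, 80, 50),
                                           (300, 100, 50, 70)])
        res = count_rafts(img, self._raft_params())
        assert res.total_estimate == 3
        assert all(o.status == "confident" for o in res.objects)

    def test_requires_raft_mode(self, blank_image):
        with pytest.raises(ParameterError):
            count_rafts(blank_image, DetectionParams(mode="micro"))

    def test_raft_total_never_exceeds_micro_total(self):
        for seed in range(5):
            spec = StripSpec(n_eggs=40, cluster_fraction=0.25, seed=seed)
            image, _ = generate_strip(spec)
            micro = count_eggs(image, DetectionParams())
            raft = count_rafts(image, DetectionParams(mode="raft"))
            assert raft.total_estimate <= micro.total_estimate


class TestCsvRoundTrip:
    def test_objects_csv(self, tmp_path):
        spec = StripSpec(n_eggs=20, cluster_fraction=0.2, seed=6)
        image, _ = generate_strip(spec)
        res = count_eggs(image)
        path = tmp_path / "objects.csv"
        write_objects_csv([res], path)
        back = read_objects_csv(path)
        assert len(back) == 1
        assert back[0].total_estimate == res.total_estimate
        assert [o.bbox for o in back[0].objects] == [o.bbox for o in res.objects]
        assert [o.status for o in back[0].objects] == [
            o.status for o in res.objects
        ]

    def test_summary_csv_columns(self, tmp_path):
        spec = StripSpec(n_eggs=10, seed=1)
        image, _ = generate_strip(spec)
        res = count_eggs(image)
        path = tmp_path / "summary.csv"
        write_summary_csv([res], path)
        header = path.read_text().splitlines()[0]
        assert header == ("image_id,n_confident,n_uncertain,n_rejected,"
                          "reference_area,total_estimate")
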