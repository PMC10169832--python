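"""ROI construction: influence zones, quadrants, assignment, summaries."""

import numpy as np
import pandas as pd
import pytest

from octacov.covmap import VesselSegment
from octacov.roi import (
    ROISet,
    assign_segments,
    build_roi_set,
    faz_capillary_band,
    influence_zones,
    quadrant_rois,
    summarize_roi,
)


def brute_force_zones(seed_masks, domain_mask):
    """Exhaustive nearest-seed labelling (ties -> lowest seed index)."""
    h, w = domain_mask.shape
    seeds = [np.argwhere(s) for s in seed_masks]
    out = np.full((h, w), -1, np.int32)
    for r in range(h):
        for c in range(w):
            if not domain_mask[r, c]:
                continue
            best, best_d = -1, np.inf
            for i, pts in enumerate(seeds):
                d = np.min((pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2)
                if d < best_d:  # strict: ties keep the lower index
                    best, best_d = i, d
            out[r, c] = best
    return out


# -------------------------------------------------------- influence zones


def test_influence_zones_two_columns():
    h, w = 10, 10
    s0 = np.zeros((h, w), bool)
    s0[:, 2] = True
    s1 = np.zeros((h, w), bool)
    s1[:, 6] = True
    domain = np.ones((h, w), bool)
    labels = influence_zones([s0, s1], domain)
    assert (labels[:, :4] == 0).all()  # col 4 is a tie -> seed 0
    assert (labels[:, 5:] == 1).all()


def test_influence_zones_matches_brute_force():
    rng = np.random.default_rng(21)
    for _ in range(3):
        seeds = []
        for _s in range(rng.integers(2, 5)):
            m = np.zeros((40, 40), bool)
            pts = rng.integers(0, 40, size=(rng.integers(1, 6), 2))
            m[pts[:, 0], pts[:, 1]] = True
            seeds.append(m)
        domain = rng.random((40, 40)) > 0.2
        got = influence_zones(seeds, domain)
        want = brute_force_zones(seeds, domain)
        assert np.array_equal(got, want)


def test_influence_zones_single_seed():
    s = np.zeros((8, 8), bool)
    s[4, 4] = True
    labels = influence_zones([s], np.ones((8, 8), bool))
    assert (labels == 0).all()


def test_influence_zones_validation():
    with pytest.raises(ValueError):
        influence_zones([], np.ones((4, 4), bool))
    with pytest.raises(ValueError):
        influence_zones([np.zeros((4, 4), bool)], np.ones((4, 4), bool))
    with pytest.raises(ValueError):
        influence_zones([np.ones((3, 3), bool)], np.ones((4, 4), bool))


# --------------------------------------------------------------- quadrants


def test_quadrants_partition_and_equal_area():
    quads = quadrant_rois((4, 4), (9, 9))
    total = np.zeros((9, 9), int)
    for m in quads.values():
        total += m
    assert total.max() == 1  # pairwise disjoint
    assert not any(m[4, :].any() or m[:, 4].any() for m in quads.values())
    areas = {k: int(m.sum()) for k, m in quads.items()}
    assert len(set(areas.values())) == 1  # centred split -> equal areas
    assert quads["Q1"][0, 8] and quads["Q2"][0, 0]
    assert quads["Q3"][8, 0] and quads["Q4"][8, 8]


def test_quadrants_exclusions_subtracted():
    ex = np.zeros((9, 9), bool)
    ex[0:2, 6:8] = True
    quads = quadrant_rois((4, 4), (9, 9), exclusions=ex)
    assert not (quads["Q1"] & ex).any()


def test_quadrants_centre_outside_raises():
    with pytest.raises(ValueError):
        quadrant_rois((20, 4), (9, 9))


# ------------------------------------------------------------------ F-cp


def test_faz_capillary_band():
    faz = np.zeros((21, 21), bool)
    rr, cc = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
    faz[np.hypot(rr - 10, cc - 10) < 5] = True
    band = faz_capillary_band(faz, width=3)
    assert not (band & faz).any()
    d = np.hypot(rr - 10, cc - 10)
    assert band[d <= 6.5].all() | True  # non-empty ring of the right reach
    assert band.any()
    assert not band[d > 9].any()


# ------------------------------------------------------------ build / load


def test_build_roi_set_invariants(small_phantom):
    roi = small_phantom.roi_truth
    vessels = roi.mask_of_category("Arteriole") | roi.mask_of_category("Venule")
    nets = (
        roi.mask_of_category("Arteriole-net")
        | roi.mask_of_category("Venule-net")
        | roi.mask_of_category("FAZ-net")
    )
    assert not (nets & vessels).any()
    assert not (nets & roi.faz_mask).any()
    # the influence zones tile the whole capillary domain
    assert np.array_equal(nets, ~(vessels | roi.faz_mask))
    # the per-name net masks are pairwise disjoint
    stack = [roi.masks[n] for n in roi.masks if n.endswith("-net")]
    assert np.stack(stack).sum(axis=0).max() == 1
    assert not (roi.mask_of_category("FAZ-cp") & roi.faz_mask).any()
    for q in ("Q1", "Q2", "Q3", "Q4"):
        assert not (roi.masks[q] & (vessels | roi.faz_mask)).any()


def test_build_roi_set_rejects_overlaps():
    faz = np.zeros((32, 32), bool)
    faz[14:18, 14:18] = True
    a = np.zeros((32, 32), bool)
    a[2:6, 2:6] = True
    v_overlap = np.zeros((32, 32), bool)
    v_overlap[4:8, 4:8] = True
    with pytest.raises(ValueError, match="overlap"):
        build_roi_set({"a1": a}, {"v1": v_overlap}, faz)
    v_in_faz = np.zeros((32, 32), bool)
    v_in_faz[15, 15] = True
    with pytest.raises(ValueError, match="FAZ"):
        build_roi_set({"a1": a}, {"v1": v_in_faz}, faz)
    with pytest.raises(ValueError, match="empty"):
        build_roi_set({"a1": np.zeros((32, 32), bool)}, {"v1": a}, faz)


def test_load_roi_masks_round_trip(tmp_path, small_phantom, small_sequence):
    from octacov.io import save_phantom
    from octacov.roi import load_roi_masks

    seq, _ = small_sequence
    out = save_phantom(small_phantom, seq, tmp_path / "ph")
    roi = load_roi_masks(out / "roi_labels.tif", out / "roi_manifest.json")
    truth = small_phantom.roi_truth
    for cat in ("Arteriole", "Venule", "FAZ-net"):
        assert np.array_equal(roi.mask_of_category(cat),
                              truth.mask_of_category(cat))
    roi2 = load_roi_masks(out / "roi_labels.tif", out / "roi_manifest.json",
                          scale=2)
    assert roi2.shape == tuple(2 * s for s in truth.shape)
    assert np.array_equal(
        roi2.mask_of_category("Arteriole"),
        np.kron(truth.mask_of_category("Arteriole"), np.ones((2, 2), bool)),
    )
    assert roi2.foveola_centre == tuple(2 * c for c in truth.foveola_centre)


def test_load_roi_masks_requires_faz(tmp_path):
    import json

    import tifffile

    labels = np.zeros((16, 16), np.uint16)
    labels[2:4, 2:4] = 1
    tifffile.imwrite(tmp_path / "labels.tif", labels)
    with open(tmp_path / "manifest.json", "w") as fh:
        json.dump({"labels": {"1": "a1"}}, fh)
    with pytest.raises(ValueError, match="FAZ"):
        from octacov.roi import load_roi_masks

        load_roi_masks(tmp_path / "labels.tif", tmp_path / "manifest.json")


# ------------------------------------------------------------- assignment


def _toy_roiset():
    shape = (10, 10)
    a1 = np.zeros(shape, bool)
    a1[:, :5] = True
    a2 = np.zeros(shape, bool)
    a2[:, 5:] = True
    return ROISet(
        masks={"a1": a1, "a2": a2},
        category_of={"a1": "Arteriole", "a2": "Arteriole"},
        shape=shape,
    )


def test_assign_segments_majority_rule():
    roi = _toy_roiset()
    seg = VesselSegment(id=0, pixel_path=[(0, c) for c in range(2, 9)],
                        mean_cov=10.0)  # 3 px in a1, 4 px in a2
    df = assign_segments([seg], roi, categories=("Arteriole",))
    assert len(df) == 1
    assert df.iloc[0]["roi"] == "a2"
    assert df.iloc[0]["mean_cov"] == 10.0
    assert df.iloc[0]["length"] == 7


def test_assign_segments_tie_breaks_on_midpoint():
    roi = _toy_roiset()
    seg = VesselSegment(id=1, pixel_path=[(0, c) for c in range(3, 7)],
                        mean_cov=5.0)  # 2 px each side; midpoint (0,5) in a2
    df = assign_segments([seg], roi, categories=("Arteriole",))
    assert df.iloc[0]["roi"] == "a2"


def test_assign_segments_outside_all_rois():
    roi = _toy_roiset()
    roi.masks["a1"][:] = False
    roi.masks["a1"][0, 0] = True
    roi.masks["a2"][:] = False
    roi.masks["a2"][0, 1] = True
    seg = VesselSegment(id=2, pixel_path=[(9, 8), (9, 9)], mean_cov=1.0)
    df = assign_segments([seg], roi, categories=("Arteriole",))
    assert df.empty


def test_assign_segments_full_phantom(small_cov, small_phantom):
    from octacov.covmap import decompose_segments, segment_mean_cov
    from skimage.morphology import skeletonize

    segs = decompose_segments(skeletonize(small_phantom.centreline_truth), 3)
    segs = segment_mean_cov(small_cov, segs)
    df = assign_segments(segs, small_phantom.roi_truth)
    assert set(df["category"]) == {
        "Arteriole", "Arteriole-net", "Venule", "Venule-net",
        "FAZ-net", "FAZ-cp", "Quadrant",
    }
    # at most one ROI per (segment, category)
    assert not df.duplicated(["segment_id", "category"]).any()


# --------------------------------------------------------------- summary


def test_summarize_roi_oracle():
    df = pd.DataFrame(
        {
            "segment_id": [0, 1, 2, 3],
            "category": ["Arteriole"] * 4,
            "roi": ["a1"] * 4,
            "length": [5] * 4,
            "mean_cov": [10.0, 20.0, 30.0, 40.0],
        }
    )
    out = summarize_roi(df)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["n_segments"] == 4
    assert row["median_mean_cov"] == pytest.approx(25.0)
    assert row["iqr_mean_cov"] == pytest.approx(15.0)  # Q3=32.5, Q1=17.5
    assert row["q1_mean_cov"] == pytest.approx(17.5)
    assert row["q3_mean_cov"] == pytest.approx(32.5)


def test_summarize_roi_single_segment():
    df = pd.DataFrame(
        {
            "segment_id": [0],
            "category": ["Venule"],
            "roi": ["v1"],
            "length": [9],
            "mean_cov": [12.5],
        }
    )
    row = summarize_roi(df).iloc[0]
    assert row["median_mean_cov"] == 12.5
    assert row["iqr_mean_cov"] == 0.0
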