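"""Clustering-ratio pipeline: projection, thresholding, ROI geometry, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lysoquant as lq

from conftest import brute_force_ratio, small_field_params


# ---------------------------------------------------------------------------
# projection


def test_projection_trivial_cases():
    plane = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.array_equal(lq.project_stack(plane), plane)
    stack = np.array([[[1.0, 0.0], [0.0, 0.0]], [[0.0, 2.0], [0.0, 0.0]]])
    assert np.array_equal(lq.project_stack(stack, "max"), [[1.0, 2.0], [0.0, 0.0]])
    with pytest.raises(ValueError, match="projection|method"):
        lq.project_stack(stack, "median")


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(1, 4), st.integers(1, 5), st.integers(0, 1000))
def test_sum_projection_dominates_max_projection(nz, n, seed):
    stack = np.random.default_rng(seed).uniform(0, 10, size=(nz, n, n))
    assert np.all(lq.project_stack(stack, "sum") >= lq.project_stack(stack, "max"))


# ---------------------------------------------------------------------------
# thresholding


def test_fixed_threshold_zeroes_subthreshold_pixels():
    out, mask, value = lq.apply_threshold(np.array([[1.0, 10.0], [6.0, 2.0]]), ("fixed", 5))
    assert np.array_equal(out, [[0.0, 10.0], [6.0, 0.0]])
    assert value == 5


def test_otsu_splits_two_level_image_between_levels():
    rng = np.random.default_rng(0)
    img = np.where(rng.random((64, 64)) < 0.9, 10.0, 100.0)
    thr = lq.otsu_threshold(img)
    assert 10.0 < thr <= 100.0
    # exhaustive-scan oracle: recompute the best 256-bin split directly
    vals = img[img > 0]
    counts, edges = np.histogram(vals, bins=256)
    best, best_t = -1.0, None
    for k in range(1, 256):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        centers = 0.5 * (edges[:-1] + edges[1:])
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        bc = w0 * w1 * (m0 - m1) ** 2
        if bc > best:
            best, best_t = bc, edges[k]
    assert thr == pytest.approx(best_t)


def test_otsu_close_to_skimage_on_dense_bimodal_image():
    """For an image with no zeros the nonzero-histogram variant should land
    within a few bin widths of the reference full-histogram implementation."""
    from skimage.filters import threshold_otsu as sk_otsu
    rng = np.random.default_rng(3)
    img = np.concatenate([rng.normal(20, 2, 6000), rng.normal(80, 5, 3000)])
    img = np.clip(img, 1.0, None).reshape(90, 100)
    bin_width = (img.max() - img.min()) / 256
    assert lq.otsu_threshold(img) == pytest.approx(sk_otsu(img, nbins=256), abs=3 * bin_width)


def test_all_zero_image_yields_empty_mask():
    out, mask, _ = lq.apply_threshold(np.zeros((4, 4)))
    assert not mask.any()
    assert not out.any()


def test_constant_image_keeps_all_foreground():
    out, mask, value = lq.apply_threshold(np.full((4, 4), 7.0), "otsu")
    assert mask.all()
    assert value == 0.0


# ---------------------------------------------------------------------------
# MTOC detection


def test_single_bright_pixel_detected():
    img = np.zeros((64, 64))
    img[12, 40] = 5.0
    mask = np.ones_like(img, dtype=bool)
    assert lq.detect_mtoc(img, mask, smooth_sigma_px=0) == (12, 40)


def test_mtoc_tie_broken_lexicographically():
    img = np.zeros((10, 10))
    img[3, 7] = img[5, 2] = 1.0
    assert lq.detect_mtoc(img, np.ones_like(img, dtype=bool), smooth_sigma_px=0) == (3, 7)


def test_no_mtoc_signal_raises():
    img = np.zeros((8, 8))
    with pytest.raises(ValueError, match="no MTOC signal"):
        lq.detect_mtoc(img, np.ones_like(img, dtype=bool))


@pytest.mark.parametrize("seed", range(6))
def test_detected_mtoc_within_two_pixels_of_truth(seed):
    p = small_field_params(seed=seed, psf_sigma_um=0.3, noise_model="gaussian",
                           noise_sd=1.0, background_level=1.0)
    field = lq.generate_field(p)
    fi = lq.FieldImage(channels=field.channels, pixel_size_um=p.pixel_size_um)
    shape = field.channels["mtoc"].shape
    for t in field.truth:
        q = lq.quantify_cell(fi, t.cell_mask(shape), lq.QuantConfig(), cell_id=t.cell_id)
        dist = np.hypot(q.mtoc_position[0] - t.mtoc_position[0],
                        q.mtoc_position[1] - t.mtoc_position[1])
        assert dist <= 2.0


# ---------------------------------------------------------------------------
# circular ROI


def test_roi_mask_matches_brute_force_enumeration():
    shape = (80, 80)
    mask = lq.circular_roi_mask((40, 40), 2.0, 0.1, shape)
    expect = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            expect[r, c] = ((r - 40) ** 2 + (c - 40) ** 2) * 0.1**2 <= 2.0**2
    assert np.array_equal(mask, expect)


def test_tiny_radius_keeps_only_centre_pixel():
    mask = lq.circular_roi_mask((5, 5), 0.04, 0.1, (11, 11))
    assert mask.sum() == 1 and mask[5, 5]


def test_corner_roi_is_quarter_disc():
    full = lq.circular_roi_mask((40, 40), 2.0, 0.1, (81, 81)).sum()
    corner = lq.circular_roi_mask((0, 0), 2.0, 0.1, (81, 81)).sum()
    assert corner / full == pytest.approx(0.25, abs=0.02)


def test_roi_centre_outside_image_raises():
    with pytest.raises(ValueError, match="outside"):
        lq.circular_roi_mask((100, 5), 2.0, 0.1, (50, 50))


# ---------------------------------------------------------------------------
# per-cell / per-field quantification


def test_ratio_extremes():
    channels = {"lysosome": np.zeros((60, 60)), "mtoc": np.zeros((60, 60))}
    channels["mtoc"][30, 30] = 100.0
    channels["lysosome"][30, 32] = 50.0  # 0.2 um from MTOC: inside the ROI
    fi = lq.FieldImage(channels=channels, pixel_size_um=0.1)
    mask = np.ones((60, 60), dtype=bool)
    cfg = lq.QuantConfig(threshold_method=("fixed", 0.0), min_cells_per_field=1)
    assert lq.quantify_cell(fi, mask, cfg).ratio == 1.0
    channels["lysosome"][:] = 0.0
    channels["lysosome"][2, 2] = 50.0  # far corner: outside the 2 um ROI
    assert lq.quantify_cell(fi, mask, cfg).ratio == 0.0


def test_noiseless_cell_ratio_matches_planted_fraction():
    p = small_field_params(seed=21, n_cells=1, cell_radius_um=6.0, field_shape=(200, 200),
                           n_lysosomes_per_cell=200, perinuclear_fraction=0.3)
    field = lq.generate_field(p)
    fi = lq.FieldImage(channels=field.channels, pixel_size_um=p.pixel_size_um)
    t = field.truth[0]
    cfg = lq.QuantConfig(threshold_method=("fixed", 1e-12), min_cells_per_field=1)
    q = lq.quantify_cell(fi, t.cell_mask(field.channels["lysosome"].shape), cfg)
    assert q.ratio == pytest.approx(t.planted_fraction_of_intensity_in_roi, abs=0.01)


def test_pipeline_matches_brute_force_oracle(field_image):
    fi, masks, truth = field_image
    cfg = lq.QuantConfig(threshold_method=("fixed", 1e-9), min_cells_per_field=3)
    fq = lq.quantify_field(fi, masks, cfg)
    for c in fq.cells:
        oracle = brute_force_ratio(fi.channels["lysosome"], masks[c.cell_id],
                                   c.mtoc_position, 2.0, fi.pixel_size_um, 1e-9)
        assert c.ratio == pytest.approx(oracle, abs=1e-9)


def test_field_flagging_by_cell_count(field_image):
    fi, masks, _ = field_image
    fq = lq.quantify_field(fi, masks, lq.QuantConfig(min_cells_per_field=3))
    assert len(fq.cells) == 3 and not fq.low_cell_count
    fq2 = lq.quantify_field(fi, masks, lq.QuantConfig(min_cells_per_field=10))
    assert fq2.low_cell_count and len(fq2.cells) == 3  # cells still returned


def test_per_field_aggregate_is_intensity_weighted_mean(field_image):
    fi, masks, _ = field_image
    fq = lq.quantify_field(fi, masks, lq.QuantConfig(min_cells_per_field=3))
    agg = lq.per_field_ratio(fq.cells)
    weights = np.array([c.cell_intensity for c in fq.cells])
    ratios = np.array([c.ratio for c in fq.cells])
    assert agg == pytest.approx(np.average(ratios, weights=weights), rel=1e-12)


def test_enlarging_roi_never_decreases_ratio(field_image):
    fi, masks, _ = field_image
    prev = None
    for radius in (1.0, 2.0, 3.0, 5.0):
        cfg = lq.QuantConfig(roi_radius_um=radius, min_cells_per_field=3)
        ratios = np.array([c.ratio for c in lq.quantify_field(fi, masks, cfg).cells])
        assert np.all(ratios >= 0) and np.all(ratios <= 1)
        if prev is not None:
            assert np.all(ratios >= prev - 1e-12)
        prev = ratios


def test_intensity_scale_invariance(field_image):
    fi, masks, _ = field_image
    cfg = lq.QuantConfig(min_cells_per_field=3)
    base = [c.ratio for c in lq.quantify_field(fi, masks, cfg).cells]
    scaled = lq.FieldImage(channels={**fi.channels, "lysosome": fi.channels["lysosome"] * 7.0},
                           pixel_size_um=fi.pixel_size_um)
    after = [c.ratio for c in lq.quantify_field(scaled, masks, cfg).cells]
    assert after == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# clustering values


def test_clustering_value_arithmetic():
    values = lq.clustering_values({"control": [0.2, 0.4], "treated": [0.6]}, "control")
    assert values["control"] == pytest.approx([2 / 3, 4 / 3])
    assert values["treated"] == pytest.approx([2.0])
    assert values["control"].mean() == pytest.approx(1.0, abs=1e-12)


def test_control_mean_is_one_for_arbitrary_input():
    rng = np.random.default_rng(0)
    for _ in range(5):
        groups = {"ctrl": rng.uniform(0.05, 1.0, rng.integers(2, 40)),
                  "t": rng.uniform(0.05, 1.0, 10)}
        values = lq.clustering_values(groups, "ctrl")
        assert abs(values["ctrl"].mean() - 1.0) < 1e-12


def test_clustering_value_errors():
    with pytest.raises(ValueError, match="control"):
        lq.clustering_values({"a": [1.0]}, "missing")
    with pytest.raises(ValueError, match="zero"):
        lq.clustering_values({"a": [0.0, 0.0], "b": [1.0]}, "a")
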