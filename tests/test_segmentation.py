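import numpy as np
import pytest
from scipy import ndimage as ndi

from cardioseg.errors import ContourError, SeedOffObjectError
from cardioseg.segmentation import (
    binarize,
    detect_edges,
    extract_contour,
    fill_holes,
    isodata_threshold,
    kernel_window,
    overlap_backgrounds,
    region_grow,
    segment_frame,
    segment_study,
)
from cardioseg.types import KernelSpec, SeedPoint

from conftest import dice, small_config, truth_centroid_seed


def rhu(x):
    return int(np.floor(x + 0.5))


def isodata_fixpoints(pixels):
    """Exhaustive scan: thresholds t with t == rhu((mean_below + mean_above)/2)."""
    px = np.asarray(pixels, dtype=float).ravel()
    out = set()
    for t in range(256):
        below = px[px < t]
        above = px[px >= t]
        if below.size == 0 or above.size == 0:
            continue
        if rhu((below.mean() + above.mean()) / 2.0) == t:
            out.add(t)
    return out


def bfs_grow(bin3, seed_row, seed_col, kernel_size=9):
    """Breadth-first flood-fill oracle over 8-connectivity from the kernel seeds."""
    b = np.asarray(bin3, dtype=np.uint8)
    h = kernel_size // 2
    n_rows, n_cols = b.shape
    r0, r1 = max(0, seed_row - h), min(n_rows, seed_row + h + 1)
    c0, c1 = max(0, seed_col - h), min(n_cols, seed_col + h + 1)
    frontier = [(r, c) for r in range(r0, r1) for c in range(c0, c1) if b[r, c]]
    grown = np.zeros_like(b)
    for r, c in frontier:
        grown[r, c] = 1
    while frontier:
        r, c = frontier.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and b[rr, cc] and not grown[rr, cc]:
                    grown[rr, cc] = 1
                    frontier.append((rr, cc))
    return grown


# ---------------------------------------------------------------- kernel_window


def test_kernel_window_interior_and_clipped():
    img = np.arange(400).reshape(20, 20) % 256
    spec = KernelSpec(size=9)
    assert kernel_window(img, SeedPoint(10, 10), spec).shape == (9, 9)
    assert kernel_window(img, SeedPoint(0, 0), spec).shape == (5, 5)
    assert kernel_window(img, SeedPoint(19, 10), spec).shape == (5, 9)


def test_kernel_window_rejects_out_of_bounds_seed():
    img = np.zeros((10, 10), dtype=np.uint8)
    with pytest.raises(ValueError):
        kernel_window(img, SeedPoint(10, 0), KernelSpec())


# ---------------------------------------------------------------- isodata


def test_isodata_two_level_example():
    # kernel {10, 10, 200, 200}: means 10 and 200 -> 105, a fixpoint
    img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
    assert isodata_threshold(img, SeedPoint(0, 0)) == 105


def test_isodata_uniform_kernel_converges_to_its_value():
    img = np.full((5, 5), 50, dtype=np.uint8)
    assert isodata_threshold(img, SeedPoint(2, 2)) == 50
    assert isodata_threshold(img, SeedPoint(2, 2), KernelSpec(k0=0)) == 50
    assert isodata_threshold(img, SeedPoint(2, 2), KernelSpec(k0=255)) == 50


def test_isodata_hold_policy_keeps_k0_on_single_class_kernel():
    img = np.full((5, 5), 50, dtype=np.uint8)
    t = isodata_threshold(img, SeedPoint(2, 2), KernelSpec(k0=128), degenerate_policy="hold")
    assert t == 128


def test_isodata_hold_policy_matches_mean_when_kernel_is_bimodal():
    img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
    t_mean = isodata_threshold(img, SeedPoint(0, 0), degenerate_policy="mean")
    t_hold = isodata_threshold(img, SeedPoint(0, 0), degenerate_policy="hold")
    assert t_mean == t_hold == 105


def test_isodata_uses_only_kernel_pixels():
    img = np.zeros((30, 30), dtype=np.uint8)
    img[10:15, 10:15] = 200  # bright block away from the seed kernel
    img[0:9, 0:9] = 40
    assert isodata_threshold(img, SeedPoint(4, 4)) == 40


def test_isodata_result_is_a_scan_fixpoint_on_random_kernels():
    rng = np.random.default_rng(7)
    for _ in range(100):
        kernel = rng.integers(0, 256, size=(9, 9)).astype(np.uint8)
        t = isodata_threshold(kernel, SeedPoint(4, 4))
        assert t in isodata_fixpoints(kernel)


def test_isodata_rejects_unknown_policy():
    img = np.full((3, 3), 9, dtype=np.uint8)
    with pytest.raises(ValueError):
        isodata_threshold(img, SeedPoint(1, 1), degenerate_policy="bogus")


def test_isodata_k0_insensitive_on_bimodal_kernels():
    rng = np.random.default_rng(11)
    for _ in range(50):
        levels = np.where(rng.integers(0, 2, size=(9, 9)) == 0, 10.0, 200.0)
        kernel = np.clip(np.rint(levels + rng.normal(0, 5, size=(9, 9))), 0, 255)
        results = {
            isodata_threshold(kernel, SeedPoint(4, 4), KernelSpec(k0=k0))
            for k0 in (0, 64, 128, 192, 255)
        }
        assert len(results) == 1


# ---------------------------------------------------------------- detect_edges


def test_detect_edges_constant_image_is_zero():
    img = np.full((16, 16), 77, dtype=np.uint8)
    assert detect_edges(img).max() == 0


def test_detect_edges_vertical_step_peaks_at_step():
    img = np.zeros((16, 16), dtype=np.uint8)
    img[:, 8:] = 200
    edge = detect_edges(img)
    assert np.array_equal(edge[0], edge[8])  # rows identical for a vertical step
    peak_cols = np.nonzero(edge[4] == edge[4].max())[0]
    assert set(peak_cols) <= {7, 8}


def sobel_oracle(img):
    """Independent Sobel magnitude with symmetric padding and min-max rescale."""
    f = np.asarray(img, dtype=float)
    pad = np.pad(f, 1, mode="symmetric")
    deriv, smooth = np.array([-1.0, 0.0, 1.0]), np.array([1.0, 2.0, 1.0])
    gr = np.zeros_like(f)
    gc = np.zeros_like(f)
    for dr in range(3):
        for dc in range(3):
            block = pad[dr:dr + f.shape[0], dc:dc + f.shape[1]]
            gr += deriv[dr] * smooth[dc] * block
            gc += smooth[dr] * deriv[dc] * block
    mag = np.hypot(gr, gc)
    lo, hi = mag.min(), mag.max()
    if hi == lo:
        return np.zeros(f.shape, dtype=np.uint8)
    return np.floor((mag - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def test_detect_edges_matches_explicit_convolution_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        assert np.array_equal(detect_edges(img, "sobel"), sobel_oracle(img))


def test_detect_edges_prewitt_supported_and_bounded():
    rng = np.random.default_rng(4)
    img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
    edge = detect_edges(img, "prewitt")
    assert edge.dtype == np.uint8 and edge.min() == 0 and edge.max() == 255


def test_detect_edges_rejects_unknown_operator():
    with pytest.raises(ValueError):
        detect_edges(np.zeros((4, 4), dtype=np.uint8), "roberts")


# ---------------------------------------------------------------- binarize / overlap


def test_binarize_polarities():
    img = np.array([[0, 100, 200]], dtype=np.uint8)
    assert np.array_equal(binarize(img, 100, "object_above"), [[0, 1, 1]])
    assert np.array_equal(binarize(img, 100, "object_below"), [[1, 0, 0]])
    with pytest.raises(ValueError):
        binarize(img, 300)
    with pytest.raises(ValueError):
        binarize(img, 100, "sideways")


def test_overlap_backgrounds_is_object_and():
    b1 = np.array([[1, 1, 0, 0]], dtype=np.uint8)
    b2 = np.array([[1, 0, 1, 0]], dtype=np.uint8)
    assert np.array_equal(overlap_backgrounds(b1, b2), [[1, 0, 0, 0]])


def test_overlap_backgrounds_shape_mismatch():
    from cardioseg.errors import DimensionMismatchError

    with pytest.raises(DimensionMismatchError):
        overlap_backgrounds(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))


# ---------------------------------------------------------------- region_grow


def test_region_grow_matches_bfs_oracle_on_random_images():
    rng = np.random.default_rng(5)
    spec = KernelSpec(size=9)
    for _ in range(50):
        b3 = (rng.random((32, 32)) < 0.5).astype(np.uint8)
        r, c = int(rng.integers(0, 32)), int(rng.integers(0, 32))
        seed = SeedPoint(r, c)
        if kernel_window(b3, seed, spec).sum() == 0:
            with pytest.raises(SeedOffObjectError):
                region_grow(b3, seed, spec)
            continue
        assert np.array_equal(region_grow(b3, seed, spec), bfs_grow(b3, r, c))


def test_region_grow_never_escapes_closed_ring():
    b3 = np.ones((21, 21), dtype=np.uint8)
    ring = 7  # Chebyshev ring of background at radius 7 around the centre
    for r in range(21):
        for c in range(21):
            if max(abs(r - 10), abs(c - 10)) == ring:
                b3[r, c] = 0
    grown = region_grow(b3, SeedPoint(10, 10), KernelSpec(size=9))
    inside = np.array([[max(abs(r - 10), abs(c - 10)) < ring for c in range(21)]
                       for r in range(21)])
    assert np.array_equal(grown.astype(bool), inside)


def test_region_grow_unions_all_kernel_components():
    b3 = np.zeros((15, 15), dtype=np.uint8)
    b3[3:6, 3:6] = 1   # touches the 9x9 kernel window around (7, 7)
    b3[9:12, 9:12] = 1
    b3[0, 14] = 1      # outside: must not be grown
    grown = region_grow(b3, SeedPoint(7, 7), KernelSpec(size=9))
    assert grown[4, 4] == 1 and grown[10, 10] == 1 and grown[0, 14] == 0


def test_region_grow_empty_kernel_raises_with_seed_location():
    b3 = np.zeros((15, 15), dtype=np.uint8)
    b3[0, 0] = 1
    with pytest.raises(SeedOffObjectError) as excinfo:
        region_grow(b3, SeedPoint(8, 9), KernelSpec(size=9))
    assert "8" in str(excinfo.value) and "9" in str(excinfo.value)


# ---------------------------------------------------------------- fill_holes


def test_fill_holes_fills_enclosed_background_only():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[2:8, 2:8] = 1
    mask[4:6, 4:6] = 0  # enclosed hole
    filled = fill_holes(mask)
    assert filled[4, 4] == 1
    assert filled[0, 0] == 0  # border-connected background untouched
    assert filled.sum() == 36


def test_fill_holes_identity_without_holes():
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[1:4, 1:4] = 1
    assert np.array_equal(fill_holes(mask), mask)


def border_flood_oracle(mask):
    """Object plus any background not reachable (4-connected) from the border."""
    bg = mask == 0
    reach = np.zeros_like(bg)
    stack = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1])
             if bg[r, c] and (r in (0, mask.shape[0] - 1) or c in (0, mask.shape[1] - 1))]
    for r, c in stack:
        reach[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and bg[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                stack.append((rr, cc))
    return (~reach).astype(np.uint8)


def test_fill_holes_matches_border_flood_oracle_on_random_masks():
    rng = np.random.default_rng(6)
    for _ in range(30):
        mask = (rng.random((14, 14)) < 0.45).astype(np.uint8)
        assert np.array_equal(fill_holes(mask), border_flood_oracle(mask))


# ---------------------------------------------------------------- extract_contour


def test_contour_single_pixel_has_area_one():
    mask = np.zeros((5, 5), dtype=np.uint8)
    mask[2, 2] = 1
    contour = extract_contour(mask)
    assert contour.shoelace_area() == pytest.approx(1.0)
    assert len(contour.vertices) == 4


def test_contour_square_area_equals_pixel_count():
    mask = np.zeros((12, 12), dtype=np.uint8)
    mask[1:11, 1:11] = 1
    contour = extract_contour(mask, slice_index=3, phase_index=7)
    assert contour.shoelace_area() == pytest.approx(100.0)
    assert contour.slice_index == 3 and contour.phase_index == 7


def test_contour_vertices_lie_on_half_integer_grid():
    mask = np.zeros((6, 6), dtype=np.uint8)
    mask[2:4, 1:5] = 1
    v = extract_contour(mask).vertices
    assert np.all(np.abs(v - np.floor(v) - 0.5) < 1e-12)


def test_contour_diagonal_pinch_traces_one_loop():
    mask = np.array([[1, 0], [0, 1]], dtype=np.uint8)
    contour = extract_contour(mask)
    assert contour.shoelace_area() == pytest.approx(2.0)


def test_contour_area_equals_count_on_random_blobs():
    rng = np.random.default_rng(8)
    for _ in range(30):
        raw = (rng.random((12, 12)) < 0.6).astype(np.uint8)
        labels, n = ndi.label(raw, structure=np.ones((3, 3), dtype=bool))
        if n == 0:
            continue
        largest = np.argmax(ndi.sum_labels(raw, labels, index=range(1, n + 1))) + 1
        mask = fill_holes((labels == largest).astype(np.uint8))
        contour = extract_contour(mask)
        assert contour.shoelace_area() == pytest.approx(float(mask.sum()))


def test_contour_errors_on_empty_or_multi_component_mask():
    with pytest.raises(ContourError):
        extract_contour(np.zeros((4, 4), dtype=np.uint8))
    two = np.zeros((6, 6), dtype=np.uint8)
    two[0, 0] = 1
    two[4, 4] = 1  # not 8-connected
    with pytest.raises(ContourError):
        extract_contour(two)


# ---------------------------------------------------------------- segment_frame


def test_segment_frame_recovers_phantom_cavity(small_phantom):
    study, truth = small_phantom
    seed = truth_centroid_seed(truth, 1)
    result = segment_frame(study.frame(1, 0), SeedPoint(*seed, 1, 0))
    assert dice(result.mask, truth.mask(1, 0)) >= 0.98
    assert result.contour.shoelace_area() == pytest.approx(float(result.mask.sum()))
    assert 0 <= result.threshold_edge <= 255 and 0 <= result.threshold_gray <= 255


def test_segment_frame_is_deterministic(small_phantom):
    study, truth = small_phantom
    seed = SeedPoint(*truth_centroid_seed(truth, 1), 1, 0)
    a = segment_frame(study.frame(1, 0), seed)
    b = segment_frame(study.frame(1, 0), seed)
    assert np.array_equal(a.mask, b.mask)
    assert np.array_equal(a.contour.vertices, b.contour.vertices)
    assert (a.threshold_edge, a.threshold_gray) == (b.threshold_edge, b.threshold_gray)


def test_segment_frame_background_click_raises(small_phantom):
    study, _ = small_phantom
    with pytest.raises(SeedOffObjectError):
        segment_frame(study.frame(1, 0), SeedPoint(5, 5, 1, 0))


def test_segment_frame_myocardium_click_raises(default_phantom):
    study, _ = default_phantom
    # mid-wall point: kernel entirely inside the myocardial ring
    with pytest.raises(SeedOffObjectError):
        segment_frame(study.frame(4, 0), SeedPoint(112, 81, 4, 0))


def test_segment_frame_fills_papillary_inclusions(default_phantom):
    study, truth = default_phantom
    seed = truth_centroid_seed(truth, 4)
    result = segment_frame(study.frame(4, 0), SeedPoint(*seed, 4, 0))
    cfg = truth.config
    r = int(np.floor(cfg.lv_center[0] + 0.6 * 36.3 * np.sin(cfg.papillary_angles[0]) + 0.5))
    c = int(np.floor(cfg.lv_center[1] + 0.6 * 36.3 * np.cos(cfg.papillary_angles[0]) + 0.5))
    assert result.mask[r, c] == 1  # dark inclusion counted as cavity


# ---------------------------------------------------------------- segment_study


def test_segment_study_covers_all_slices_at_ed_and_es(small_phantom):
    study, truth = small_phantom
    seed = SeedPoint(*truth_centroid_seed(truth, 1), 1, 0)
    outcome = segment_study(study, seed)
    es = study.n_phases // 2
    assert set(outcome["results"]) == {(s, p) for s in range(3) for p in (0, es)}
    assert outcome["failures"] == {}
    for (s, p), result in outcome["results"].items():
        assert dice(result.mask, truth.mask(s, p)) >= 0.95


def test_segment_study_respects_slice_range(small_phantom):
    study, truth = small_phantom
    seed = SeedPoint(*truth_centroid_seed(truth, 1), 1, 0)
    outcome = segment_study(study, seed, slice_range=(1, 1))
    es = study.n_phases // 2
    assert set(outcome["results"]) == {(1, 0), (1, es)}


def test_segment_study_validates_phases_and_range(small_phantom):
    study, truth = small_phantom
    seed = SeedPoint(*truth_centroid_seed(truth, 1), 1, 0)
    with pytest.raises(ValueError):
        segment_study(study, seed, ed_phase=2, es_phase=2)
    with pytest.raises(ValueError):
        segment_study(study, seed, slice_range=(0, 5))
    with pytest.raises(ValueError):
        segment_study(study, SeedPoint(seed.row, seed.col, 0, 0), slice_range=(1, 2))


def test_segment_study_records_nonfatal_apical_failures():
    from cardioseg.phantom import generate_phantom

    # apex so tapered that slice 2 has no cavity at all: both its frames must
    # fail gracefully while the rest of the study completes
    study, truth = generate_phantom(small_config(apical_taper=(1.0, 1.0, 0.01)))
    seed = SeedPoint(*truth_centroid_seed(truth, 1), 1, 0)
    outcome = segment_study(study, seed)
    es = study.n_phases // 2
    assert set(outcome["failures"]) == {(2, 0), (2, es)}
    assert set(outcome["results"]) == {(s, p) for s in (0, 1) for p in (0, es)}


def test_segment_study_fatal_on_bad_initial_click(small_phantom):
    study, _ = small_phantom
    with pytest.raises(SeedOffObjectError):
        segment_study(study, SeedPoint(5, 5, 1, 0))
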