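"""Semiautomatic ventricular cavity segmentation.

The pipeline turns a single mouse-click in a midventricular end-diastolic
frame into one binary cavity mask per frame, with no manual contour editing:

1. *Edge detection* — Sobel (or Prewitt) gradient magnitude, renormalized to
   0-255.
2. *Iterative thresholding on the edge image* — a square kernel around the
   click supplies the pixel sample; the threshold iterates to the midpoint of
   the below/above class means (isodata). Pixels at or above the converged
   value are treated as edges and become background in binary image 1, so
   strong boundaries act as barriers.
3. *Iterative thresholding on the grayscale image* — the same kernel drives a
   second threshold; the bright blood pool (at or above it) is the object in
   binary image 2.
4. *Background overlapping* — a pixelwise OR of the two backgrounds
   (equivalently AND of the objects) seals boundary discontinuities
   (binary image 3).
5. *Region growing* — every object pixel inside the kernel window seeds an
   8-connected flood fill over binary image 3; interior dark structures
   (papillary muscles, trabeculae) are then filled into the cavity, and the
   boundary contour is extracted.

Everything is integer-deterministic: identical inputs give bit-identical
masks, thresholds and contours.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    ContourError,
    DimensionMismatchError,
    NonConvergenceError,
    SeedOffObjectError,
)
from .types import (
    ContourPolygon,
    KernelSpec,
    SegmentationResult,
    SeedPoint,
    validate_binary_mask,
    validate_gray_image,
)

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _renormalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to 0..255 uint8 with round-half-up; constant -> zeros."""
    lo = float(values.min())
    hi = float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.floor((values - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def detect_edges(img: np.ndarray, operator: str = "sobel") -> np.ndarray:
    """Gradient-magnitude edge image, min-max renormalized to 0-255.

    Uses reflective border handling; a constant image maps to all zeros.
    """
    img = validate_gray_image(img)
    if operator == "sobel":
        grad = ndi.sobel
    elif operator == "prewitt":
        grad = ndi.prewitt
    else:
        raise ValueError(f"unknown edge operator {operator!r}")
    f = img.astype(np.float64)
    gr = grad(f, axis=0, mode="reflect")
    gc = grad(f, axis=1, mode="reflect")
    return _renormalize(np.hypot(gr, gc))


def kernel_window(img: np.ndarray, seed: SeedPoint, spec: KernelSpec) -> np.ndarray:
    """The size x size window centred on the seed, clipped to image bounds."""
    n_rows, n_cols = img.shape
    if not (0 <= seed.row < n_rows and 0 <= seed.col < n_cols):
        raise ValueError(f"seed ({seed.row}, {seed.col}) outside image {img.shape}")
    h = spec.size // 2
    r0, r1 = max(0, seed.row - h), min(n_rows, seed.row + h + 1)
    c0, c1 = max(0, seed.col - h), min(n_cols, seed.col + h + 1)
    return img[r0:r1, c0:c1]


def isodata_threshold(
    img: np.ndarray,
    seed: SeedPoint,
    spec: KernelSpec | None = None,
    degenerate_policy: str = "mean",
) -> int:
    """Converged kernel-seeded isodata threshold.

    Starting from ``spec.k0``, the threshold iterates to
    ``round((mean of kernel pixels below k + mean of kernel pixels at or
    above k) / 2)`` until it reaches a fixpoint. Only the kernel window's
    pixels enter the statistics; the result does not depend on pixel order.

    When one class is empty the two-class midpoint is undefined; the
    ``degenerate_policy`` decides what happens:

    ``"mean"`` (default)
        Restart at the rounded mean of all kernel pixels and continue
        iterating. A uniform kernel therefore converges to its own value, and
        the converged result is insensitive to ``k0`` even when ``k0`` lies
        outside the data range.
    ``"hold"``
        Keep the current threshold. A single-class neighbourhood carries no
        information about the class boundary, so the prior ``k0`` stands.
        This is what the full pipeline uses for the grayscale cut (see
        :func:`segment_frame`).
    """
    spec = spec or KernelSpec()
    if degenerate_policy not in ("mean", "hold"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
    px = kernel_window(np.asarray(img), seed, spec).astype(np.float64).ravel()
    if px.size == 0:
        raise ValueError("kernel window contains no pixels")
    k = int(spec.k0)
    prev = k
    for _ in range(spec.max_iter):
        below = px[px < k]
        above = px[px >= k]
        if below.size == 0 or above.size == 0:
            if degenerate_policy == "hold":
                return k
            k1 = _round_half_up(px.mean())
        else:
            k1 = _round_half_up((below.mean() + above.mean()) / 2.0)
        if k1 == k:
            return k
        prev, k = k, k1
    raise NonConvergenceError(k, prev, spec.max_iter)


def binarize(img: np.ndarray, threshold: int, polarity: str = "object_above") -> np.ndarray:
    """Threshold an image into a {0,1} mask.

    ``object_above``: pixels >= threshold are object; ``object_below``:
    pixels < threshold are object.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    a = np.asarray(img)
    if polarity == "object_above":
        return (a >= threshold).astype(np.uint8)
    if polarity == "object_below":
        return (a < threshold).astype(np.uint8)
    raise ValueError(f"unknown polarity {polarity!r}")


def overlap_backgrounds(bin1: np.ndarray, bin2: np.ndarray) -> np.ndarray:
    """OR the backgrounds of two binary images (AND of the objects)."""
    b1 = validate_binary_mask(bin1)
    b2 = validate_binary_mask(bin2)
    if b1.shape != b2.shape:
        raise DimensionMismatchError(f"mask shapes differ: {b1.shape} vs {b2.shape}")
    return (b1 & b2).astype(np.uint8)


def region_grow(bin3: np.ndarray, seed: SeedPoint, spec: KernelSpec | None = None) -> np.ndarray:
    """Grow the object from every object pixel inside the seed kernel window.

    Returns the union of 8-connected object components that intersect the
    kernel window (the breadth-first flood-fill closure of those seeds).
    Raises :class:`SeedOffObjectError` when the window holds no object pixel.
    """
    spec = spec or KernelSpec()
    b3 = validate_binary_mask(bin3)
    window = kernel_window(b3, seed, spec)
    if window.sum() == 0:
        raise SeedOffObjectError(seed.row, seed.col)
    labels, _ = ndi.label(b3, structure=EIGHT_CONNECTED)
    seed_labels = np.unique(kernel_window(labels, seed, spec))
    seed_labels = seed_labels[seed_labels > 0]
    return np.isin(labels, seed_labels).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Convert enclosed background to object.

    Background components not 4-connected to the image border (the standard
    dual of 8-connected objects) become object; border-connected background
    is unchanged. Dark papillary/trabecular structures enclosed by the blood
    pool are thereby counted as cavity.
    """
    m = validate_binary_mask(mask)
    return ndi.binary_fill_holes(m).astype(np.uint8)


def _trace_boundary_loops(mask: np.ndarray):
    """All closed crack-edge loops of a mask, vertices at half-integer (row, col).

    Each object pixel (r, c) owns the unit square [r-.5, r+.5] x [c-.5, c+.5];
    loops follow the exposed square edges with a consistent orientation. At a
    diagonal pinch the traversal crosses toward the 8-connected neighbour.
    """
    obj = mask.astype(bool)
    padded = np.zeros((obj.shape[0] + 2, obj.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = obj
    edges = {}  # start vertex -> list of (end vertex, direction)
    rs, cs = np.nonzero(padded)
    for r, c in zip(rs, cs):
        rr, cc = r - 1, c - 1  # back to unpadded coordinates
        if not padded[r - 1, c]:  # background above: top edge, travel +col
            edges.setdefault((rr - 0.5, cc - 0.5), []).append(((rr - 0.5, cc + 0.5), (0, 1)))
        if not padded[r, c + 1]:  # right edge, travel +row
            edges.setdefault((rr - 0.5, cc + 0.5), []).append(((rr + 0.5, cc + 0.5), (1, 0)))
        if not padded[r + 1, c]:  # bottom edge, travel -col
            edges.setdefault((rr + 0.5, cc + 0.5), []).append(((rr + 0.5, cc - 0.5), (0, -1)))
        if not padded[r, c - 1]:  # left edge, travel -row
            edges.setdefault((rr + 0.5, cc - 0.5), []).append(((rr - 0.5, cc - 0.5), (-1, 0)))
    loops = []
    while edges:
        start = next(iter(edges))
        end, direction = edges[start][0]
        _pop_edge(edges, start, 0)
        loop = [start]
        vertex = end
        while vertex != start:
            loop.append(vertex)
            candidates = edges.get(vertex)
            if not candidates:
                raise ContourError("boundary tracing failed: open chain")
            if len(candidates) == 1:
                idx = 0
            else:
                # diagonal pinch: prefer the left turn (positive cross product)
                # so traversal continues around the 8-connected object
                idx = max(
                    range(len(candidates)),
                    key=lambda i: direction[0] * candidates[i][1][1]
                    - direction[1] * candidates[i][1][0],
                )
            end, direction = candidates[idx]
            _pop_edge(edges, vertex, idx)
            vertex = end
        loops.append(np.array(loop, dtype=float))
    return loops


def _pop_edge(edges, vertex, idx):
    lst = edges[vertex]
    lst.pop(idx)
    if not lst:
        del edges[vertex]


def _simplify_collinear(vertices: np.ndarray) -> np.ndarray:
    """Drop vertices interior to straight runs (closed polygon)."""
    n = len(vertices)
    keep = []
    for i in range(n):
        prev_v = vertices[i - 1]
        cur = vertices[i]
        nxt = vertices[(i + 1) % n]
        if not np.array_equal(np.sign(cur - prev_v), np.sign(nxt - cur)):
            keep.append(i)
    return vertices[keep] if keep else vertices


def extract_contour(mask: np.ndarray, slice_index: int = 0, phase_index: int = 0) -> ContourPolygon:
    """Ordered outer boundary polygon of a single-component mask.

    Vertices lie on the 0.5-level between object and background (pixel edge
    midlines at half-integer coordinates); for a hole-free mask the shoelace
    area equals the object pixel count exactly.
    """
    m = validate_binary_mask(mask)
    if m.sum() == 0:
        raise ContourError("cannot extract a contour from an empty mask")
    _, n_comp = ndi.label(m, structure=EIGHT_CONNECTED)
    if n_comp > 1:
        raise ContourError(f"mask has {n_comp} components; expected exactly one")
    loops = _trace_boundary_loops(m)

    def loop_area(loop):
        r, c = loop[:, 0], loop[:, 1]
        return abs(float(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))) / 2.0

    outer = max(loops, key=loop_area)
    return ContourPolygon(_simplify_collinear(outer), slice_index, phase_index)


def segment_frame(
    img: np.ndarray,
    seed: SeedPoint,
    spec: KernelSpec | None = None,
    edge_operator: str = "sobel",
    edge_kernel_source: str = "gray",
    gray_polarity: str = "object_above",
) -> SegmentationResult:
    """Segment one frame from one seed point.

    Composes the five pipeline steps. Two kernel-seeded thresholds are
    produced: ``threshold_edge`` cuts the edge-magnitude image (pixels at or
    above it are barriers) and ``threshold_gray`` cuts the grayscale image
    (bright blood is object). The edge threshold's kernel statistics come by
    default from the grayscale window (``edge_kernel_source="gray"``): in a
    featureless bright pool this leaves effectively no barrier, while a
    background click yields threshold 0 and an immediate seed-off-object
    error. The grayscale cut uses the "hold" degeneracy policy, so a
    single-class kernel keeps the study-wide prior ``k0`` instead of
    thresholding at the pool's own mean (which would bisect it under noise).
    """
    spec = spec or KernelSpec()
    img = validate_gray_image(img)
    edge = detect_edges(img, edge_operator)
    source = img if edge_kernel_source == "gray" else edge
    threshold_edge = isodata_threshold(source, seed, spec, degenerate_policy="mean")
    bin1 = binarize(edge, threshold_edge, "object_below")  # non-edge pixels are object
    threshold_gray = isodata_threshold(img, seed, spec, degenerate_policy="hold")
    bin2 = binarize(img, threshold_gray, gray_polarity)
    bin3 = overlap_backgrounds(bin1, bin2)
    grown = region_grow(bin3, seed, spec)
    mask = fill_holes(grown)
    contour = extract_contour(mask, seed.slice_index, seed.phase_index)
    return SegmentationResult(mask, contour, threshold_edge, threshold_gray, seed)


def _mask_centroid(mask: np.ndarray) -> tuple:
    r, c = ndi.center_of_mass(mask)
    return _round_half_up(r), _round_half_up(c)


def auto_select_phases(
    study,
    seed: SeedPoint,
    spec: KernelSpec | None = None,
    edge_operator: str = "sobel",
    **frame_kwargs,
) -> tuple:
    """Pick (ed_phase, es_phase) as argmax/argmin of segmented area.

    Segments the seed slice across all phases, chaining each phase's seed
    from the previous phase's mask centroid, and returns the phases of
    maximal and minimal cavity cross-sectional area.
    """
    spec = spec or KernelSpec()
    s = seed.slice_index
    areas = {}
    current = seed
    for p in range(study.n_phases):
        current = SeedPoint(current.row, current.col, s, p)
        result = segment_frame(study.frame(s, p), current, spec, edge_operator, **frame_kwargs)
        areas[p] = int(result.mask.sum())
        r, c = _mask_centroid(result.mask)
        current = SeedPoint(r, c, s, p)
    ed = max(areas, key=lambda p: (areas[p], -p))
    es = min(areas, key=lambda p: (areas[p], p))
    return ed, es


def segment_study(
    study,
    seed: SeedPoint,
    spec: KernelSpec | None = None,
    edge_operator: str = "sobel",
    slice_range: tuple | None = None,
    ed_phase: int = 0,
    es_phase: int | None = None,
    **frame_kwargs,
) -> dict:
    """Segment every (slice, ED/ES phase) frame of a study from one click.

    The seed frame (the click's slice at ED) is segmented first. Seeds then
    propagate by centroid chaining: each neighbouring slice (outward toward
    base and apex) is seeded at the rounded centroid of the nearest
    already-segmented ED mask, and each slice's ES frame at the centroid of
    that slice's ED mask (falling back to the nearest available ED mask).
    Frames whose segmentation fails are recorded under ``"failures"`` rather
    than aborting the run; only failure on the initial seed frame is fatal.

    Returns ``{"results": {(slice, phase): SegmentationResult},
    "failures": {(slice, phase): str}}``.
    """
    spec = spec or KernelSpec()
    if es_phase is None:
        es_phase = study.n_phases // 2
    if ed_phase == es_phase:
        raise ValueError("ed_phase and es_phase must differ")
    lo, hi = slice_range if slice_range is not None else (0, study.n_slices - 1)
    if not (0 <= lo <= hi < study.n_slices):
        raise ValueError(f"slice_range {slice_range} outside study grid")
    s0 = seed.slice_index
    if not lo <= s0 <= hi:
        raise ValueError(f"seed slice {s0} outside slice_range ({lo}, {hi})")

    results: dict = {}
    failures: dict = {}
    first = SeedPoint(seed.row, seed.col, s0, ed_phase)
    results[(s0, ed_phase)] = segment_frame(
        study.frame(s0, ed_phase), first, spec, edge_operator, **frame_kwargs
    )  # fatal on failure: the click itself is bad

    def try_frame(s, p, seed_rc):
        sp = SeedPoint(seed_rc[0], seed_rc[1], s, p)
        try:
            results[(s, p)] = segment_frame(study.frame(s, p), sp, spec, edge_operator, **frame_kwargs)
        except (SeedOffObjectError, NonConvergenceError, ContourError) as exc:
            failures[(s, p)] = f"slice {s}, phase {p}: {exc}"

    # outward over slices at the ED phase, chaining from the nearest ED mask
    order = [s for s in range(s0 + 1, hi + 1)] + [s for s in range(s0 - 1, lo - 1, -1)]
    for s in order:
        neighbor = s - 1 if s > s0 else s + 1
        ref = results.get((neighbor, ed_phase))
        if ref is None:  # neighbour failed; chain from the closest successful slice
            done = [k for k in results if k[1] == ed_phase]
            if not done:
                failures[(s, ed_phase)] = f"slice {s}: no reference mask available"
                continue
            ref = results[min(done, key=lambda k: abs(k[0] - s))]
        try_frame(s, ed_phase, _mask_centroid(ref.mask))

    # ES of each slice, seeded from that slice's (or the nearest) ED centroid
    for s in range(lo, hi + 1):
        ref = results.get((s, ed_phase))
        if ref is None:
            done = [k for k in results if k[1] == ed_phase]
            ref = results[min(done, key=lambda k: abs(k[0] - s))]
        try_frame(s, es_phase, _mask_centroid(ref.mask))

    return {"results": results, "failures": failures}
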