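"""Core data containers.

Grayscale frames and binary masks are plain ``numpy.ndarray`` objects
(``uint8``, 2-D); the dataclasses here carry the geometric and grid metadata
around them. Coordinates are 0-based ``(row, col)`` with row increasing
downward, so a seed click is reproducible across runs and readers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError, IncompleteGridError


def validate_gray_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid 2-D grayscale frame with values in 0..255."""
    a = np.asarray(img)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError(f"grayscale frame must be 2-D and at least 3x3, got shape {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("grayscale frame values must lie in [0, 255]")
    return a


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Check an array is a 2-D {0,1} mask; returns it as uint8."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask values must be 0 or 1")
    return m.astype(np.uint8)


@dataclass(frozen=True)
class SeedPoint:
    """A single mouse-click: pixel (row, col) on a given (slice, phase) frame."""

    row: int
    col: int
    slice_index: int = 0
    phase_index: int = 0


@dataclass
class KernelSpec:
    """Square kernel for seeded threshold selection.

    size
        Odd kernel side length in pixels (9 throughout the reference study).
    k0
        Initial threshold, an integer gray level in [0, 255], set once and
        shared by every frame and patient.
    max_iter
        Iteration cap before threshold selection reports a cycle.
    """

    size: int = 9
    k0: int = 128
    max_iter: int = 100

    def __post_init__(self):
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("kernel size must be an odd integer >= 3")
        if not 0 <= self.k0 <= 255:
            raise ValueError("k0 must lie in [0, 255]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ContourPolygon:
    """Ordered boundary polygon of a cavity mask (closure implicit).

    Vertices are sub-pixel ``(row, col)`` positions on the 0.5-level between
    object and background, i.e. along pixel edges at half-integer offsets.
    """

    vertices: np.ndarray  # (n, 2) float array of (row, col)
    slice_index: int = 0
    phase_index: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 (row, col) vertices")
        self.vertices = v

    def shoelace_area(self) -> float:
        """Enclosed area in pixel units (positive regardless of orientation)."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return abs(float(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))) / 2.0


@dataclass
class SegmentationResult:
    """Output of segmenting one frame from one seed."""

    mask: np.ndarray
    contour: ContourPolygon
    threshold_edge: int  # converged threshold applied to the edge-magnitude image
    threshold_gray: int  # converged threshold applied to the grayscale image
    seed_used: SeedPoint


@dataclass
class CineStudy:
    """A short-axis cine stack: frames on a complete slice x phase grid.

    ``frames[s][p]`` is the 2-D uint8 frame for slice ``s`` (base to apex)
    and cardiac phase ``p``. The inter-slice gap is metadata only: the
    acquisition gap is not recorded in DICOM headers, so it must be supplied
    by the user (``gap_fraction``, as a fraction of slice thickness).
    """

    frames: list  # list over slices of lists over phases of 2-D uint8 arrays
    pixel_spacing_mm: tuple  # (row, col)
    slice_thickness_mm: float
    gap_fraction: float = 0.0
    slice_order: str = "base-to-apex"

    def __post_init__(self):
        if not self.frames or not self.frames[0]:
            raise IncompleteGridError("study has no frames")
        n_phases = len(self.frames[0])
        shape = None
        for s, row in enumerate(self.frames):
            if len(row) != n_phases:
                raise IncompleteGridError(
                    f"slice {s} has {len(row)} phases, expected {n_phases}"
                )
            for p, f in enumerate(row):
                if f is None:
                    raise IncompleteGridError(f"missing frame at slice {s}, phase {p}")
                f = validate_gray_image(f)
                if shape is None:
                    shape = f.shape
                elif f.shape != shape:
                    raise DimensionMismatchError(
                        f"frame (slice {s}, phase {p}) has shape {f.shape}, expected {shape}"
                    )
        rs, cs = self.pixel_spacing_mm
        if rs <= 0 or cs <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must lie in [0, 1)")

    @property
    def n_slices(self) -> int:
        return len(self.frames)

    @property
    def n_phases(self) -> int:
        return len(self.frames[0])

    @property
    def frame_shape(self) -> tuple:
        return self.frames[0][0].shape

    @property
    def slice_spacing_mm(self) -> float:
        """Centre-to-centre inter-slice spacing: thickness x (1 + gap_fraction)."""
        return self.slice_thickness_mm * (1.0 + self.gap_fraction)

    def frame(self, slice_index: int, phase_index: int) -> np.ndarray:
        return self.frames[slice_index][phase_index]


@dataclass
class VentricleFunction:
    """Per-ventricle global function parameters from Simpson's method."""

    areas_ed_mm2: list
    areas_es_mm2: list
    edv_ml: float
    esv_ml: float
    ef_percent: float
    slice_spacing_mm: float
    edv_index_ml_m2: float | None = None
    esv_index_ml_m2: float | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "areas_ed_mm2": [float(a) for a in self.areas_ed_mm2],
            "areas_es_mm2": [float(a) for a in self.areas_es_mm2],
            "edv_ml": float(self.edv_ml),
            "esv_ml": float(self.esv_ml),
            "ef_percent": float(self.ef_percent),
            "slice_spacing_mm": float(self.slice_spacing_mm),
            "edv_index_ml_m2": None if self.edv_index_ml_m2 is None else float(self.edv_index_ml_m2),
            "esv_index_ml_m2": None if self.esv_index_ml_m2 is None else float(self.esv_index_ml_m2),
            "flags": list(self.flags),
        }


@dataclass
class PairedSeries:
    """Two paired measurement series of the same parameter (same units)."""

    values_a: np.ndarray
    values_b: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
            raise ValueError("paired series must be equal-length 1-D sequences")
        if a.size < 3:
            raise ValueError("paired series need n >= 3")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("paired series must not contain missing values")
        self.values_a, self.values_b = a, b

    @property
    def n(self) -> int:
        return int(self.values_a.size)

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class AgreementReport:
    """Method-agreement summary for one paired parameter series."""

    label: str
    units: str
    n: int
    r: float
    t_stat: float
    p_two_tailed: float
    df: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    coverage_fraction: float
    ks_p_a: float
    ks_p_b: float
    clinically_relevant: bool

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "label", "units", "n", "r", "t_stat", "p_two_tailed", "df", "bias",
            "sd_diff", "loa_low", "loa_high", "coverage_fraction",
            "ks_p_a", "ks_p_b", "clinically_relevant")}
        for k, v in d.items():
            if isinstance(v, (np.floating, np.integer)):
                d[k] = v.item()
        return d
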