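"""Reading and writing cine studies, masks, contours and reports.

Two study dialects are supported: a classic single-frame DICOM series, and a
plain-image directory (8/16-bit PNG or TIFF) with a YAML sidecar carrying
the geometry the image files cannot (pixel spacing, slice thickness, gap
fraction, grid shape, filename pattern). Intensities are min-max normalized
to 0-255 *per study*, not per frame, so one threshold is comparable across
slices.

DICOM ordering: slices sort by the projection of the image position onto the
slice normal (base to apex), phases by trigger time with instance number as
fallback. The inter-slice gap does not appear in DICOM headers and is never
inferred; it is caller-supplied metadata.
"""
from __future__ import annotations

import csv
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import CardiosegError, DimensionMismatchError, IncompleteGridError
from .phantom import normalize_frames
from .types import CineStudy, validate_binary_mask

SIDECAR_NAME = "sidecar.yaml"
DEFAULT_PATTERN = "slice{slice:02d}_phase{phase:02d}.png"


def load_cine_series(path, dialect: str = "image_dir", gap_fraction: float | None = None) -> CineStudy:
    """Load a short-axis cine study from a directory.

    ``dialect="image_dir"`` expects a YAML sidecar (``sidecar.yaml``) next to
    the frames; ``dialect="dicom"`` reads every DICOM file in the directory
    as one single-frame series. ``gap_fraction`` overrides (dicom: supplies)
    the inter-slice gap metadata.
    """
    path = Path(path)
    if not path.is_dir():
        raise CardiosegError(f"study directory not found: {path}")
    if dialect == "image_dir":
        return _load_image_dir(path, gap_fraction)
    if dialect == "dicom":
        return _load_dicom_dir(path, 0.0 if gap_fraction is None else gap_fraction)
    raise CardiosegError(f"unknown study dialect {dialect!r}")


def _read_image(file_path: Path) -> np.ndarray:
    try:
        with Image.open(file_path) as im:
            arr = np.asarray(im)
    except OSError as exc:
        raise CardiosegError(f"cannot read image file {file_path}: {exc}") from exc
    if arr.ndim == 3:  # collapse accidental RGB to luminance-free gray
        arr = arr[..., 0]
    return arr.astype(float)


def _load_image_dir(path: Path, gap_override) -> CineStudy:
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise CardiosegError(f"missing sidecar file {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    pattern = meta.get("filename_pattern", DEFAULT_PATTERN)
    n_slices, n_phases = int(meta["n_slices"]), int(meta["n_phases"])
    raw, shape = [], None
    for s in range(n_slices):
        for p in range(n_phases):
            f = path / pattern.format(slice=s, phase=p)
            if not f.exists():
                raise IncompleteGridError(f"missing frame for slice {s}, phase {p}: {f.name}")
            arr = _read_image(f)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise DimensionMismatchError(
                    f"{f.name} has shape {arr.shape}, expected {shape}")
            raw.append(arr)
    frames = normalize_frames(raw)
    grid = [[frames[s * n_phases + p] for p in range(n_phases)] for s in range(n_slices)]
    gap = float(meta.get("gap_fraction", 0.0)) if gap_override is None else float(gap_override)
    return CineStudy(
        frames=grid,
        pixel_spacing_mm=tuple(float(v) for v in meta["pixel_spacing_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        gap_fraction=gap,
    )


def _load_dicom_dir(path: Path, gap_fraction: float) -> CineStudy:
    import pydicom

    records = []
    for f in sorted(path.iterdir()):
        if f.name == SIDECAR_NAME or f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
            pixels = ds.pixel_array
        except Exception as exc:
            raise CardiosegError(f"cannot read DICOM file {f}: {exc}") from exc
        orient = np.array(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(orient[:3], orient[3:])
        location = float(np.dot(np.array(ds.ImagePositionPatient, dtype=float), normal))
        trigger = float(getattr(ds, "TriggerTime", getattr(ds, "InstanceNumber", 0)))
        records.append((round(location, 3), trigger, int(getattr(ds, "InstanceNumber", 0)),
                        pixels.astype(float), ds))
    if not records:
        raise CardiosegError(f"no DICOM frames found in {path}")

    locations = sorted({r[0] for r in records}, reverse=True)  # base first
    by_slice = {loc: sorted((r for r in records if r[0] == loc), key=lambda r: (r[1], r[2]))
                for loc in locations}
    n_phases = len(by_slice[locations[0]])
    for loc in locations:
        if len(by_slice[loc]) != n_phases:
            raise IncompleteGridError(
                f"slice at location {loc} has {len(by_slice[loc])} phases, expected {n_phases}")

    raw = [r[3] for loc in locations for r in by_slice[loc]]
    shapes = {f.shape for f in raw}
    if len(shapes) > 1:
        raise DimensionMismatchError(f"frames have mixed dimensions: {sorted(shapes)}")
    frames = normalize_frames(raw)
    grid = [[frames[s * n_phases + p] for p in range(n_phases)] for s in range(len(locations))]
    ref = records[0][4]
    spacing = tuple(float(v) for v in ref.PixelSpacing)
    return CineStudy(
        frames=grid,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=float(ref.SliceThickness),
        gap_fraction=gap_fraction,
    )


def save_study(study: CineStudy, path, pattern: str = DEFAULT_PATTERN) -> Path:
    """Write a study as an image_dir dialect directory (PNG frames + sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in range(study.n_slices):
        for p in range(study.n_phases):
            Image.fromarray(study.frame(s, p).astype(np.uint8), mode="L").save(
                path / pattern.format(slice=s, phase=p))
    sidecar = {
        "pixel_spacing_mm": [float(v) for v in study.pixel_spacing_mm],
        "slice_thickness_mm": float(study.slice_thickness_mm),
        "gap_fraction": float(study.gap_fraction),
        "n_slices": study.n_slices,
        "n_phases": study.n_phases,
        "filename_pattern": pattern,
    }
    _atomic_write_text(path / SIDECAR_NAME, yaml.safe_dump(sidecar, sort_keys=True))
    return path


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary mask as an 8-bit PNG (0 background, 255 object)."""
    m = validate_binary_mask(mask)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path)
    except OSError as exc:
        raise CardiosegError(f"cannot write mask to {path}: {exc}") from exc
    return path


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back to a {0,1} uint8 array (lossless round trip)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except OSError as exc:
        raise CardiosegError(f"cannot read mask from {path}: {exc}") from exc
    return (arr > 0).astype(np.uint8)


def write_contour_csv(contours, path) -> Path:
    """Write contour polygons to CSV, grouped by ascending (slice, phase).

    Columns: ``slice_index,phase_index,vertex_index,row,col``; an empty
    contour list produces a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = sorted(contours, key=lambda c: (c.slice_index, c.phase_index))
    tmp_fd, tmp_name = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(tmp_fd, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "phase_index", "vertex_index", "row", "col"])
        for contour in ordered:
            for i, (r, c) in enumerate(contour.vertices):
                writer.writerow([contour.slice_index, contour.phase_index, i, r, c])
    os.replace(tmp_name, path)
    return path


def write_json_report(payload: dict, path) -> Path:
    """Serialize a report atomically (temp file + rename), keys sorted."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _atomic_write_text(path: Path, text: str):
    tmp_fd, tmp_name = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(tmp_fd, "w") as fh:
        fh.write(text)
    os.replace(tmp_name, path)
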