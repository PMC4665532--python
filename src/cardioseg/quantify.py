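"""Ventricular volumetry: per-slice areas, Simpson volumes, ejection fraction.

End-diastolic and end-systolic volumes sum the cavity area of every slice
multiplied by the inter-slice spacing (Simpson's method); spacing is the
slice thickness times ``(1 + gap_fraction)`` so an unrecorded acquisition gap
(typically 20% of the thickness) can be included explicitly. Ejection
fraction is ``(EDV - ESV) * 100 / EDV``.
"""
from __future__ import annotations

import numpy as np

from .errors import BasalOffsetError, CardiosegError
from .types import VentricleFunction, validate_binary_mask


def mask_area(mask: np.ndarray, pixel_spacing_mm: tuple) -> float:
    """Cavity area in mm^2: object-pixel count x row spacing x column spacing."""
    m = validate_binary_mask(mask)
    rs, cs = pixel_spacing_mm
    return float(m.sum()) * float(rs) * float(cs)


def simpson_volume(areas_mm2, slice_thickness_mm: float, gap_fraction: float = 0.0) -> float:
    """Stack volume in mL: sum of slice areas times inter-slice spacing.

    ``spacing = thickness * (1 + gap_fraction)``; an empty area list gives 0.
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size and areas.min() < 0:
        raise CardiosegError("slice areas must be non-negative")
    if slice_thickness_mm <= 0:
        raise CardiosegError("slice thickness must be positive")
    if not 0 <= gap_fraction < 1:
        raise CardiosegError("gap_fraction must lie in [0, 1)")
    spacing = slice_thickness_mm * (1.0 + gap_fraction)
    return float(areas.sum() * spacing / 1000.0)  # mm^3 -> mL


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """(EDV - ESV) * 100 / EDV, in percent."""
    if edv_ml <= 0:
        raise CardiosegError("EDV must be positive to compute an ejection fraction")
    if esv_ml < 0:
        raise CardiosegError("ESV must be non-negative")
    return (edv_ml - esv_ml) * 100.0 / edv_ml


def index_to_bsa(volume_ml: float, bsa_m2: float) -> float:
    """Body-surface-area indexed volume, mL/m^2."""
    if bsa_m2 <= 0:
        raise CardiosegError("body surface area must be positive")
    return volume_ml / bsa_m2


def quantify_study(
    results: dict,
    study,
    ed_phase: int = 0,
    es_phase: int | None = None,
    bsa_m2: float | None = None,
    allow_basal_offset: bool = True,
) -> VentricleFunction:
    """Assemble global function parameters from per-frame segmentation results.

    ``results`` maps ``(slice_index, phase_index)`` to objects with a
    ``mask`` attribute (or bare masks). Frames missing from ``results``
    contribute no term — the stack is integrated over the slices that show
    blood pool. The most basal covered slice may differ by one position
    between ED and ES (through-plane motion); a larger basal mismatch is an
    error unless both phases are simply absent there.
    """
    if es_phase is None:
        es_phase = study.n_phases // 2
    ed_slices = sorted(s for (s, p) in results if p == ed_phase)
    es_slices = sorted(s for (s, p) in results if p == es_phase)
    if not ed_slices or not es_slices:
        raise CardiosegError("need at least one ED frame and one ES frame")
    basal_offset = abs(ed_slices[0] - es_slices[0])
    if basal_offset > (1 if allow_basal_offset else 0):
        raise BasalOffsetError(
            f"most basal ED slice {ed_slices[0]} and ES slice {es_slices[0]} "
            f"differ by {basal_offset} positions"
        )

    def area_of(key):
        obj = results[key]
        mask = getattr(obj, "mask", obj)
        return mask_area(mask, study.pixel_spacing_mm)

    areas_ed = [area_of((s, ed_phase)) for s in ed_slices]
    areas_es = [area_of((s, es_phase)) for s in es_slices]
    spacing = study.slice_spacing_mm
    edv = simpson_volume(areas_ed, study.slice_thickness_mm, study.gap_fraction)
    esv = simpson_volume(areas_es, study.slice_thickness_mm, study.gap_fraction)
    ef = ejection_fraction(edv, esv)
    flags = []
    if esv > edv:
        flags.append("esv_exceeds_edv")
    return VentricleFunction(
        areas_ed_mm2=areas_ed,
        areas_es_mm2=areas_es,
        edv_ml=edv,
        esv_ml=esv,
        ef_percent=ef,
        slice_spacing_mm=spacing,
        edv_index_ml_m2=None if bsa_m2 is None else index_to_bsa(edv, bsa_m2),
        esv_index_ml_m2=None if bsa_m2 is None else index_to_bsa(esv, bsa_m2),
        flags=flags,
    )
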