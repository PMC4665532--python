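import numpy as np
import pytest
from scipy import ndimage as ndi

from cardioseg.phantom import PhantomConfig, generate_phantom


def dice(a, b) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def truth_centroid_seed(truth, slice_index, phase_index=None, ventricle="lv"):
    """Rounded centroid of a truth mask — where an operator would click."""
    p = truth.ed_phase if phase_index is None else phase_index
    r, c = ndi.center_of_mass(truth.mask(slice_index, p, ventricle))
    return int(np.floor(r + 0.5)), int(np.floor(c + 0.5))


def small_config(**overrides) -> PhantomConfig:
    """A fast 3-slice, 5-phase phantom for unit tests."""
    defaults = dict(
        n_slices=3,
        n_phases=5,
        image_size=(96, 96),
        lv_center=(48.4, 47.6),
        lv_radius_ed_px=20.2,
        lv_radius_es_px=14.1,
        myo_thickness_px=8.0,
        rv_enabled=False,
        apical_taper=(1.0, 1.0, 0.9),
        papillary_slices=(),
        pixel_spacing_mm=(1.4, 1.4),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """(study, truth) for the fast noiseless unit-test phantom."""
    return generate_phantom(small_config())


@pytest.fixture(scope="session")
def default_phantom():
    """(study, truth) for the full-size noiseless phantom (10 x 25 frames)."""
    return generate_phantom(PhantomConfig())
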