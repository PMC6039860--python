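import numpy as np
import pytest

from pvatquant.core import ThresholdSet
from pvatquant.phantom import (
    AORTIC_DOUBLE_PEAK,
    CohortSpec,
    PhantomSpec,
    PvatProfile,
    generate_cohort,
    generate_slice,
)


@pytest.fixture(scope="session")
def constant_carotid():
    """Noiseless carotid slice: wall 2.0 mm, PVAT 3.0 mm everywhere."""
    spec = PhantomSpec(
        noise_sd=0.0, wall_base_mm=2.0,
        pvat_profile=PvatProfile("constant", base_mm=3.0),
    )
    pair, truth = generate_slice(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def constant_aorta():
    """Noiseless aortic slice at the reported mean thicknesses (2.38 / 3.34 mm)."""
    spec = PhantomSpec(
        image_size_px=(176, 176), vessel_class="aorta", lumen_radius_mm=8.0,
        wall_base_mm=2.38, noise_sd=0.0,
        pvat_profile=PvatProfile("constant", base_mm=3.34),
    )
    pair, truth = generate_slice(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def double_peak_aorta():
    """Noiseless aorta with the 120/220 deg double-peak PVAT pattern."""
    spec = PhantomSpec(
        image_size_px=(176, 176), vessel_class="aorta", lumen_radius_mm=8.0,
        wall_base_mm=2.38, noise_sd=0.0, pvat_profile=AORTIC_DOUBLE_PEAK,
    )
    pair, truth = generate_slice(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort table (no rendering), fixed seed."""
    spec = CohortSpec(n_patients=8, slices_per_patient=4, seed=42)
    _, _, cohort = generate_cohort(spec)
    return spec, cohort


@pytest.fixture
def thresholds():
    return ThresholdSet()
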