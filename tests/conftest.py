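import numpy as np
import pytest

from qusliver.synth import (Acquisition, CohortSpec, HistologySpec,
                            make_cohort, make_ground_truth,
                            make_histology_image, simulate_rf,
                            simulate_spectra)


@pytest.fixture(scope="session")
def piecewise_truth():
    """Two-level attenuation/backscatter phantom (TV-friendly layout)."""
    return make_ground_truth((16, 16), "piecewise",
                             delta_b=(1.0, 100.0), delta_alpha=(0.1, 0.5))


@pytest.fixture(scope="session")
def noiseless_volume(piecewise_truth):
    return simulate_spectra(piecewise_truth)


@pytest.fixture(scope="session")
def homogeneous_rf():
    """Fully developed speckle from identity tissue (one frame)."""
    truth = make_ground_truth((10, 8), axial_spacing_mm=2.8,
                              lateral_spacing_mm=2.8)
    return simulate_rf(truth, Acquisition(), n_frames=1, seed=4)


@pytest.fixture(scope="session")
def histology_20pct():
    spec = HistologySpec(target_fat_fraction_pct=20.0, n_distractors=0, seed=5)
    return make_histology_image(spec)


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(CohortSpec(seed=11))
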