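import numpy as np
import pytest

from dyno17 import PhantomSpec, build_label_volume, render_timeseries


@pytest.fixture(scope="session")
def clean_spec():
    """Phantom with no PSF, no coil bias and no noise: the identity pipeline."""
    return PhantomSpec(psf_fwhm_mm=0.0, bias_amplitude=0.0, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    labels, masks = build_label_volume(clean_spec)
    series, truth = render_timeseries(labels, masks, clean_spec)
    return clean_spec, labels, masks, series, truth


@pytest.fixture(scope="session")
def blurred_spec():
    """Noiseless phantom with the default PSF and no bias: pure PV effect."""
    return PhantomSpec(bias_amplitude=0.0, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def blurred_phantom(blurred_spec):
    labels, masks = build_label_volume(blurred_spec)
    series, truth = render_timeseries(labels, masks, blurred_spec)
    return blurred_spec, labels, masks, series, truth


@pytest.fixture(scope="session")
def noisy_spec():
    """Phantom with 10% noise only (no PSF, no bias), for noise statistics."""
    return PhantomSpec(psf_fwhm_mm=0.0, bias_amplitude=0.0, noise_cv=0.10, seed=7)


@pytest.fixture(scope="session")
def noisy_phantom(noisy_spec):
    labels, masks = build_label_volume(noisy_spec)
    series, truth = render_timeseries(labels, masks, noisy_spec)
    return noisy_spec, labels, masks, series, truth
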