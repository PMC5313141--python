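"""Shared fixtures: parameter sets and a noise-free reference phantom."""

import numpy as np
import pytest

import strokebbb as sb


@pytest.fixture(scope="session")
def acq():
    return sb.AcquisitionParams()


@pytest.fixture(scope="session")
def conv():
    return sb.ConversionParams()


@pytest.fixture(scope="session")
def vif_params():
    return sb.VifParams()


@pytest.fixture(scope="session")
def vif(vif_params, acq):
    return sb.generate_vif(vif_params, acq)


@pytest.fixture(scope="session")
def phantom_nf():
    """Noise-free default phantom (treat as read-only)."""
    truth = sb.default_phantom_truth(noise_sigma=0.0, seed=1)
    return sb.generate_phantom(truth)


@pytest.fixture(scope="session")
def adc_map_nf(phantom_nf):
    return sb.compute_adc(phantom_nf.dwi, phantom_nf.truth.brain_mask)


@pytest.fixture(scope="session")
def vif_nf(phantom_nf, conv):
    return sb.extract_vif(phantom_nf.dce, phantom_nf.truth.sinus_mask, conv)


@pytest.fixture(scope="session")
def kps_map_nf(phantom_nf, vif_nf, conv):
    return sb.compute_kps_map(phantom_nf.dce, vif_nf,
                              phantom_nf.truth.brain_mask, conv)
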