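"""Shared fixtures: phantom cases are expensive, so they are generated once
per session and reused read-only across test modules."""

import numpy as np
import pytest

from adaptcheck.phantom import PhantomParams, generate_case


@pytest.fixture(scope="session")
def clean_case():
    """Deformation-bearing case without rigid offset or CBCT degradation:
    the paired-CT/CT setting used for registration-quality checks."""
    params = PhantomParams(
        with_dose=False, rigid_mm=0, rigid_deg=0,
        noise_hu=0, cupping_hu=0, hu_shift=0,
    )
    return generate_case(params, seed=0)


@pytest.fixture(scope="session")
def degraded_case():
    """Full study conditions (rigid offset + deformation + CBCT degradation),
    without the reference dose."""
    return generate_case(PhantomParams(with_dose=False), seed=1)


@pytest.fixture(scope="session")
def dosed_case():
    """Full study conditions including the normalized reference dose."""
    return generate_case(PhantomParams(), seed=2)


@pytest.fixture(scope="session")
def identity_case():
    """No motion, no degradation: every stage must reduce to a no-op."""
    params = PhantomParams(
        with_dose=False, deformation_mm=0, bladder_scale=1.0, ctv_shift_mm=0,
        rigid_mm=0, rigid_deg=0, noise_hu=0, cupping_hu=0, hu_shift=0,
    )
    return generate_case(params, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
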