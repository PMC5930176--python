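import numpy as np
import pytest

from helogit.ckks import HEParams, keygen


@pytest.fixture(scope="session")
def small_params():
    """A fast parameter set for scheme-level unit tests (32 slots)."""
    return HEParams(ring_degree=64, log_q=150, log_q0=38, log_p=28)


@pytest.fixture(scope="session")
def small_keys(small_params):
    return keygen(small_params, seed=1234)


@pytest.fixture(scope="session")
def medium_params():
    """Enough modulus depth for encrypted polynomial evaluation tests."""
    return HEParams(ring_degree=256, log_q=220, log_q0=38, log_p=28)


@pytest.fixture(scope="session")
def medium_keys(medium_params):
    return keygen(medium_params, seed=99)


def decrypt_slots(ct, keys):
    """Decrypt to the logical slot vector (averaging embedded replicas)."""
    from helogit.ckks import decode, decrypt
    full = decode(decrypt(ct, keys), ct.scale_bits)
    return full.reshape(-1, ct.slot_count).mean(axis=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
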