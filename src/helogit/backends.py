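"""Two interchangeable execution backends for the encrypted trainer.

EncryptedBackend runs the real scheme; MockBackend runs the identical circuit
on plaintext slot vectors while enforcing exactly the same scale and modulus
bookkeeping (including budget exhaustion).  The mock isolates the surrogate /
quantization error of the training circuit from encryption noise, and makes
the pipeline testable in milliseconds; every pipeline test runs against both
and their outputs must agree to the scheme's noise tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import ckks
from .ckks import (
    AlignmentError,
    BudgetExhaustedError,
    Ciphertext,
    HEParams,
    KeySet,
)
from .ring import RingPoly

__all__ = ["EncryptedBackend", "MockBackend", "MockCiphertext"]


class EncryptedBackend:
    """Backend running on real ciphertexts.

    Holds the public key material only, unless constructed with a full KeySet
    (the client side, which can also decrypt).
    """

    name = "real-HE"

    def __init__(self, params: HEParams, keys: KeySet):
        self.params = params
        self.keys = keys

    # -- creation -----------------------------------------------------------
    def encrypt_vector(self, values, slot_count: int, scale_bits: int) -> Ciphertext:
        pt = ckks.encode(np.asarray(values, dtype=float), scale_bits, self.params)
        ct = ckks.encrypt(pt, self.keys, slot_count=slot_count, scale_bits=scale_bits)
        return ct

    def zero_ct(self, slot_count: int, scale_bits: int) -> Ciphertext:
        n, lq = self.params.ring_degree, self.params.log_q
        z = RingPoly.zero(lq, n)
        return Ciphertext(z, z, lq, scale_bits, slot_count)

    # -- arithmetic ---------------------------------------------------------
    def add(self, a, b):
        return ckks.he_add(a, b)

    def sub(self, a, b):
        return ckks.he_sub(a, b)

    def mult(self, a, b):
        return ckks.he_mult(a, b, self.keys)

    def dot(self, cts_a, cts_b):
        return ckks.he_dot(cts_a, cts_b, self.keys)

    def plain_scalar(self, ct, value: float, scale_bits: int):
        return ckks.plain_scalar_mult(ct, round(value * 2 ** scale_bits), scale_bits)

    def add_const(self, ct, value: float):
        n = ct.ring_degree
        pt = RingPoly.constant(round(value * 2 ** ct.scale_bits), ct.log_q, n)
        return ckks.add_plain(ct, pt)

    def rescale(self, ct, r_bits: int):
        return ckks.rescale(ct, r_bits, self.params)

    def relabel(self, ct, new_scale_bits: int):
        return ckks.relabel_scale(ct, new_scale_bits)

    def mod_to(self, ct, log_q: int):
        return ckks.mod_reduce_ct(ct, log_q)

    def rotate(self, ct, shift: int):
        return ckks.rotate_slots(ct, shift, self.keys)

    # -- observation --------------------------------------------------------
    def decrypt_vector(self, ct) -> np.ndarray:
        full = ckks.decode(ckks.decrypt(ct, self.keys), ct.scale_bits)
        k = ct.slot_count
        return full.reshape(-1, k).mean(axis=0)

    @staticmethod
    def log_q_of(ct) -> int:
        return ct.log_q

    @staticmethod
    def scale_of(ct) -> int:
        return ct.scale_bits


@dataclass
class MockCiphertext:
    """Plaintext stand-in: logical slot values plus the real bookkeeping."""

    values: np.ndarray
    log_q: int
    scale_bits: int
    slot_count: int


class MockBackend:
    """No-crypto backend with identical interface and bookkeeping."""

    name = "mock"

    def __init__(self, params: HEParams):
        self.params = params

    def encrypt_vector(self, values, slot_count: int, scale_bits: int) -> MockCiphertext:
        v = np.zeros(slot_count)
        arr = np.asarray(values, dtype=float).ravel()
        v[: arr.size] = arr
        # model the encoding quantization to the scaled integer grid
        v = np.rint(v * 2 ** scale_bits) / 2 ** scale_bits
        return MockCiphertext(v, self.params.log_q, scale_bits, slot_count)

    def zero_ct(self, slot_count: int, scale_bits: int) -> MockCiphertext:
        return MockCiphertext(np.zeros(slot_count), self.params.log_q,
                              scale_bits, slot_count)

    @staticmethod
    def _aligned(a, b):
        if a.log_q != b.log_q:
            raise AlignmentError(f"modulus mismatch 2^{a.log_q} vs 2^{b.log_q}")

    def add(self, a, b):
        self._aligned(a, b)
        if a.scale_bits != b.scale_bits:
            raise AlignmentError("scale mismatch in add")
        return MockCiphertext(a.values + b.values, a.log_q, a.scale_bits, a.slot_count)

    def sub(self, a, b):
        self._aligned(a, b)
        if a.scale_bits != b.scale_bits:
            raise AlignmentError("scale mismatch in sub")
        return MockCiphertext(a.values - b.values, a.log_q, a.scale_bits, a.slot_count)

    def mult(self, a, b):
        self._aligned(a, b)
        return MockCiphertext(a.values * b.values, a.log_q,
                              a.scale_bits + b.scale_bits,
                              min(a.slot_count, b.slot_count))

    def dot(self, cts_a, cts_b):
        acc = None
        for x, y in zip(cts_a, cts_b):
            t = self.mult(x, y)
            acc = t if acc is None else self.add(acc, t)
        return acc

    def plain_scalar(self, ct, value: float, scale_bits: int):
        quant = round(value * 2 ** scale_bits) / 2 ** scale_bits
        return MockCiphertext(ct.values * quant, ct.log_q,
                              ct.scale_bits + scale_bits, ct.slot_count)

    def add_const(self, ct, value: float):
        quant = round(value * 2 ** ct.scale_bits) / 2 ** ct.scale_bits
        return MockCiphertext(ct.values + quant, ct.log_q, ct.scale_bits, ct.slot_count)

    def rescale(self, ct, r_bits: int):
        new_bits = ct.log_q - r_bits
        if new_bits < self.params.log_q0:
            raise BudgetExhaustedError(
                f"rescaling by {r_bits} bits would drop the modulus to "
                f"{new_bits} < log q0 = {self.params.log_q0}")
        return MockCiphertext(ct.values, new_bits, ct.scale_bits - r_bits, ct.slot_count)

    def relabel(self, ct, new_scale_bits: int):
        factor = 2.0 ** (ct.scale_bits - new_scale_bits)
        return MockCiphertext(ct.values * factor, ct.log_q, new_scale_bits, ct.slot_count)

    def mod_to(self, ct, log_q: int):
        if log_q > ct.log_q:
            raise AlignmentError("modulus can only decrease")
        return replace(ct, log_q=log_q)

    def rotate(self, ct, shift: int):
        return MockCiphertext(np.roll(ct.values, -shift), ct.log_q,
                              ct.scale_bits, ct.slot_count)

    def decrypt_vector(self, ct) -> np.ndarray:
        return ct.values.copy()

    @staticmethod
    def log_q_of(ct) -> int:
        return ct.log_q

    @staticmethod
    def scale_of(ct) -> int:
        return ct.scale_bits
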