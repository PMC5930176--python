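"""Exact arithmetic in the negacyclic residue ring R_q = Z_q[X]/(X^N + 1).

All ciphertext and plaintext material of the encryption scheme lives in this
ring.  The modulus is always a power of two, q = 2**log_q, as in the original
implementation of the approximate-arithmetic scheme this package follows: the
rescaling operation then divides by powers of two exactly, and reduction mod q
is a bit mask.  Coefficients are arbitrary-precision Python integers kept in
the centered residue set (-q/2, q/2].

Multiplication is exact.  It is performed by Kronecker substitution: the two
polynomials are packed into single big integers (one coefficient per fixed-width
digit), multiplied with CPython's big-integer multiply, and unpacked; the
negacyclic wrap X^N = -1 is applied afterwards.  This is an exact algorithm --
no floating point is involved -- and is far faster in pure Python than a
schoolbook convolution for the ring degrees used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RingPoly",
    "SamplerSpec",
    "ParameterError",
    "poly_add",
    "poly_sub",
    "poly_neg",
    "poly_mult",
    "poly_scalar_mult",
    "apply_automorphism",
    "mod_reduce",
    "divide_round",
    "sample_ring",
]


class ParameterError(ValueError):
    """Raised for mismatched or invalid ring/sampler parameters."""


def _center(v: int, q: int) -> int:
    """Reduce v into the centered residue set (-q/2, q/2]."""
    v &= q - 1
    if v > q >> 1:
        v -= q
    return v


@dataclass(frozen=True)
class RingPoly:
    """An element of Z_q[X]/(X^N + 1), q = 2**modulus_bits.

    coeffs are centered representatives in (-q/2, q/2], length exactly N.
    """

    coeffs: tuple
    modulus_bits: int
    ring_degree: int

    def __post_init__(self):
        n = self.ring_degree
        if n <= 0 or n & (n - 1):
            raise ParameterError(f"ring degree {n} is not a power of two")
        if len(self.coeffs) != n:
            raise ParameterError(
                f"coefficient vector length {len(self.coeffs)} != ring degree {n}"
            )

    @property
    def modulus(self) -> int:
        return 1 << self.modulus_bits

    @classmethod
    def from_ints(cls, coeffs: Sequence[int], modulus_bits: int, ring_degree: int | None = None):
        n = ring_degree if ring_degree is not None else len(coeffs)
        q = 1 << modulus_bits
        cs = list(int(c) for c in coeffs)
        if len(cs) < n:
            cs += [0] * (n - len(cs))
        return cls(tuple(_center(c, q) for c in cs), modulus_bits, n)

    @classmethod
    def zero(cls, modulus_bits: int, ring_degree: int):
        return cls((0,) * ring_degree, modulus_bits, ring_degree)

    @classmethod
    def constant(cls, c: int, modulus_bits: int, ring_degree: int):
        q = 1 << modulus_bits
        return cls((_center(int(c), q),) + (0,) * (ring_degree - 1), modulus_bits, ring_degree)

    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coeffs)


def _check_match(a: RingPoly, b: RingPoly) -> None:
    if a.ring_degree != b.ring_degree:
        raise ParameterError(
            f"ring degree mismatch: {a.ring_degree} vs {b.ring_degree}")
    if a.modulus_bits != b.modulus_bits:
        raise ParameterError(
            f"modulus mismatch: 2^{a.modulus_bits} vs 2^{b.modulus_bits}")


def poly_add(a: RingPoly, b: RingPoly) -> RingPoly:
    """Coefficient-wise sum mod q."""
    _check_match(a, b)
    q = a.modulus
    return RingPoly(tuple(_center(x + y, q) for x, y in zip(a.coeffs, b.coeffs)),
                    a.modulus_bits, a.ring_degree)


def poly_sub(a: RingPoly, b: RingPoly) -> RingPoly:
    _check_match(a, b)
    q = a.modulus
    return RingPoly(tuple(_center(x - y, q) for x, y in zip(a.coeffs, b.coeffs)),
                    a.modulus_bits, a.ring_degree)


def poly_neg(a: RingPoly) -> RingPoly:
    q = a.modulus
    return RingPoly(tuple(_center(-x, q) for x in a.coeffs), a.modulus_bits, a.ring_degree)


def poly_scalar_mult(a: RingPoly, m: int) -> RingPoly:
    """Multiply every coefficient by the integer m, mod q."""
    q = a.modulus
    m = int(m)
    return RingPoly(tuple(_center(x * m, q) for x in a.coeffs), a.modulus_bits, a.ring_degree)


def _kronecker_mult(ca, cb, n: int, width_bits: int):
    """Exact acyclic convolution of two nonneg coefficient lists via big ints.

    width_bits must exceed the bit length of any convolution coefficient so
    that digits do not overlap.  Returns the 2n convolution coefficients.
    """
    wb = (width_bits + 7) // 8 * 8          # byte-align the digit width
    w = wb // 8
    pa = int.from_bytes(b"".join(c.to_bytes(w, "little") for c in ca), "little")
    pb = int.from_bytes(b"".join(c.to_bytes(w, "little") for c in cb), "little")
    pc = pa * pb
    raw = pc.to_bytes(2 * n * w, "little")
    return [int.from_bytes(raw[i * w:(i + 1) * w], "little") for i in range(2 * n)]


def poly_mult(a: RingPoly, b: RingPoly) -> RingPoly:
    """Exact negacyclic product: multiply in Z[X], reduce by X^N = -1, then mod q."""
    _check_match(a, b)
    n = a.ring_degree
    q = a.modulus
    qb = a.modulus_bits
    # nonnegative representatives keep the packing digits carry-free
    ca = [c & (q - 1) for c in a.coeffs]
    cb = [c & (q - 1) for c in b.coeffs]
    width = 2 * qb + n.bit_length() + 1
    s = _kronecker_mult(ca, cb, n, width)
    out = tuple(_center(s[i] - s[i + n], q) for i in range(n))
    return RingPoly(out, qb, n)


def apply_automorphism(a: RingPoly, k: int) -> RingPoly:
    """The Galois map X -> X^k (k odd), reduced by X^N = -1."""
    n = a.ring_degree
    if k % 2 == 0:
        raise ParameterError(f"automorphism exponent {k} must be odd")
    k %= 2 * n
    q = a.modulus
    out = [0] * n
    for i, c in enumerate(a.coeffs):
        j = (i * k) % (2 * n)
        if j >= n:
            out[j - n] = _center(-c, q)
        else:
            out[j] = c
    return RingPoly(tuple(out), a.modulus_bits, n)


def mod_reduce(a: RingPoly, new_bits: int) -> RingPoly:
    """Reduce to the smaller modulus 2**new_bits (centered representatives)."""
    if new_bits > a.modulus_bits:
        raise ParameterError("cannot mod-reduce to a larger modulus")
    if new_bits == a.modulus_bits:
        return a
    q = 1 << new_bits
    return RingPoly(tuple(_center(c, q) for c in a.coeffs), new_bits, a.ring_degree)


def divide_round(a: RingPoly, r_bits: int, new_bits: int) -> RingPoly:
    """Divide every coefficient by 2**r_bits with rounding to nearest,
    landing in the ring mod 2**new_bits.  This is the coefficient-level core
    of the rescaling procedure."""
    half = 1 << (r_bits - 1) if r_bits > 0 else 0
    q = 1 << new_bits
    return RingPoly(tuple(_center((c + half) >> r_bits, q) for c in a.coeffs),
                    new_bits, a.ring_degree)


# ---------------------------------------------------------------------------
# samplers

_KINDS = ("uniform", "sparse-ternary", "discrete-gaussian", "zero-one")


@dataclass
class SamplerSpec:
    """Which distribution to draw a ring element from.

    kind:
      uniform           -- coefficients uniform mod q (public randomness a).
      sparse-ternary    -- secret keys: exactly `hamming_weight` nonzero
                           coefficients, each +-1.
      discrete-gaussian -- errors: rounded centered normal, sd `stddev`.
      zero-one          -- encryption randomness v: 0 with prob 1/2,
                           +-1 with prob 1/4 each.
    """

    kind: str
    hamming_weight: int = 64
    stddev: float = 3.2
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown sampler kind {self.kind!r}")


def sample_ring(spec: SamplerSpec, N: int, q_bits: int,
                rng: np.random.Generator | None = None) -> RingPoly:
    """Draw a ring element from the named distribution, reproducibly under seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.kind == "uniform":
        # q may exceed 64 bits: assemble from 32-bit words
        words = (q_bits + 31) // 32
        w = rng.integers(0, 1 << 32, size=(N, words), dtype=np.uint64)
        q = 1 << q_bits
        coeffs = []
        for row in w:
            v = 0
            for j, x in enumerate(row):
                v |= int(x) << (32 * j)
            coeffs.append(_center(v, q))
        return RingPoly(tuple(coeffs), q_bits, N)
    if spec.kind == "sparse-ternary":
        h = spec.hamming_weight
        if h > N:
            raise ParameterError(f"hamming weight {h} exceeds ring degree {N}")
        idx = rng.choice(N, size=h, replace=False)
        signs = rng.choice((-1, 1), size=h)
        coeffs = [0] * N
        for i, s in zip(idx, signs):
            coeffs[int(i)] = int(s)
        return RingPoly.from_ints(coeffs, q_bits, N)
    if spec.kind == "discrete-gaussian":
        if spec.stddev <= 0:
            raise ParameterError("gaussian sampler needs stddev > 0")
        vals = np.rint(rng.normal(0.0, spec.stddev, size=N)).astype(np.int64)
        return RingPoly.from_ints(vals.tolist(), q_bits, N)
    # zero-one
    vals = rng.choice((-1, 0, 0, 1), size=N)
    return RingPoly.from_ints(vals.tolist(), q_bits, N)
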