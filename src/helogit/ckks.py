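"""Approximate-arithmetic homomorphic encryption with SIMD slot packing.

The scheme encodes a vector of up to N/2 reals into the "slots" of a ring
element (the canonical embedding: evaluations at odd primitive 2N-th roots of
unity), scales by 2**scale_bits and rounds.  Ciphertexts are RLWE pairs; the
supported homomorphic operations are addition, multiplication (with
relinearization), slot rotation (a Galois automorphism followed by a key
switch) and rescaling, which divides the encrypted message and the ciphertext
modulus by the same power of two -- the fixed-point rounding step that keeps
the message magnitude under control.

Key switching (relinearization and rotations) uses a single special modulus
P = 2**log_special: switching keys are published at modulus P*q and the noisy
product is divided by P, so the switching noise is ~q/P of a unit.

The ciphertext modulus only ever decreases (rescaling / explicit modulus
reduction); running out of modulus before log_q0 raises BudgetExhaustedError,
which is the error that caps the number of training iterations downstream.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .ring import (
    ParameterError,
    RingPoly,
    SamplerSpec,
    apply_automorphism,
    divide_round,
    mod_reduce,
    poly_add,
    poly_mult,
    poly_neg,
    poly_scalar_mult,
    poly_sub,
    sample_ring,
)

__all__ = [
    "HEParams",
    "KeySet",
    "Ciphertext",
    "AlignmentError",
    "KeyMissingError",
    "BudgetExhaustedError",
    "CapacityError",
    "encode",
    "decode",
    "keygen",
    "encrypt",
    "decrypt",
    "he_add",
    "he_sub",
    "he_mult",
    "rescale",
    "mod_reduce_ct",
    "plain_scalar_mult",
    "add_plain",
    "relabel_scale",
    "rotate_slots",
    "poly_eval_encrypted",
    "PRESETS",
]


class AlignmentError(ValueError):
    """Operands disagree in modulus or scale; no silent coercion is done."""


class KeyMissingError(KeyError):
    """A required evaluation/rotation key is not present."""


class BudgetExhaustedError(RuntimeError):
    """The ciphertext modulus cannot absorb the requested rescaling."""


class CapacityError(ValueError):
    """More values than the ring has plaintext slots."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class HEParams:
    """Scheme parameters.

    ring_degree N (power of two, N/2 plaintext slots), log_q fresh ciphertext
    modulus bits, log_q0 the floor the modulus may not drop below (the "paper"
    preset ties it to the scale: log_q0 = log_p + 10), log_p the encoding
    scale.  secret_hamming and error_stddev follow the conventions of the
    cited scheme (the source text defers them to its appendices).
    """

    ring_degree: int
    log_q: int
    log_q0: int
    log_p: int
    security: str = "custom"
    secret_hamming: int = 64
    error_stddev: float = 3.2
    log_special: int | None = None

    def __post_init__(self):
        n = self.ring_degree
        if n <= 0 or n & (n - 1):
            raise ParameterError("ring degree must be a power of two")
        if self.log_q < self.log_q0:
            raise ParameterError("fresh modulus below base modulus")

    @property
    def slot_capacity(self) -> int:
        return self.ring_degree // 2

    @property
    def special_bits(self) -> int:
        return self.log_special if self.log_special is not None else self.log_q + 16

    def fingerprint(self) -> str:
        key = (self.ring_degree, self.log_q, self.log_q0, self.log_p,
               self.secret_hamming, self.error_stddev, self.special_bits)
        return hashlib.sha256(repr(key).encode()).hexdigest()[:16]


def _desk() -> HEParams:
    return HEParams(ring_degree=1 << 13, log_q=220, log_q0=38, log_p=28,
                    security="desk")


def _paper() -> HEParams:
    # fresh modulus from the optimized budget formula at the largest clinical
    # cohort targeted (g3, 25 iterations, n padded to 1024, alpha = 1):
    # 38 + 25*92 = 2338 bits.
    return HEParams(ring_degree=1 << 15, log_q=2338, log_q0=38, log_p=28,
                    security="paper")


PRESETS = {"desk": _desk, "paper": _paper}


# ---------------------------------------------------------------------------
# canonical-embedding encoding


@functools.lru_cache(maxsize=8)
def _embedding_tables(n: int):
    """Precompute the twist and slot-index maps for ring degree n."""
    i = np.arange(n)
    zeta = np.exp(1j * np.pi * i / n)          # zeta^i, zeta = exp(i*pi/N)
    # slot j evaluates at root exponent 5^j mod 2N; odd exponent r sits at
    # twisted-FFT row t = (r-1)/2, its conjugate at row N - (r+1)/2.
    r = 1
    rows = np.empty(n // 2, dtype=np.int64)
    conj_rows = np.empty(n // 2, dtype=np.int64)
    for j in range(n // 2):
        rows[j] = (r - 1) // 2
        conj_rows[j] = n - (r + 1) // 2
        r = (r * 5) % (2 * n)
    return zeta, rows, conj_rows


def _slots_from_coeffs(coeffs_float: np.ndarray) -> np.ndarray:
    """Evaluate a real coefficient vector at the slot roots (complex, N/2)."""
    n = coeffs_float.shape[0]
    zeta, rows, _ = _embedding_tables(n)
    vals = np.fft.ifft(coeffs_float * zeta) * n
    return vals[rows]


def _coeffs_from_slots(slots: np.ndarray) -> np.ndarray:
    """Inverse embedding: real coefficient vector hitting the given slots."""
    k = slots.shape[0]
    n = 2 * k
    zeta, rows, conj_rows = _embedding_tables(n)
    full = np.zeros(n, dtype=complex)
    full[rows] = slots
    full[conj_rows] = np.conj(slots)
    d = np.fft.fft(full) / n
    return np.real(d * np.conj(zeta))


def encode(values, scale_bits: int, params: HEParams) -> RingPoly:
    """Encode a real vector into a plaintext ring element at scale 2**scale_bits.

    The vector is zero-padded to the next power of two k and replicated
    N/(2k) times so that it fills all N/2 slots; rotations then act cyclically
    on the logical k slots.
    """
    v = np.asarray(values, dtype=float).ravel()
    cap = params.slot_capacity
    if v.size > cap:
        raise CapacityError(f"{v.size} values exceed slot capacity {cap}")
    if not np.all(np.isfinite(v)):
        raise ParameterError("values must be finite")
    k = 1
    while k < v.size:
        k *= 2
    padded = np.zeros(k)
    padded[: v.size] = v
    full = np.tile(padded, cap // k)
    coeffs = _coeffs_from_slots(full.astype(complex)) * float(2 ** scale_bits)
    ints = np.rint(coeffs).astype(object)
    return RingPoly.from_ints([int(c) for c in ints], params.log_q, params.ring_degree)


def decode(pt: RingPoly, scale_bits: int) -> np.ndarray:
    """Decode a plaintext ring element to its N/2 slot values (real)."""
    coeffs = np.array([float(c) for c in pt.coeffs])
    return np.real(_slots_from_coeffs(coeffs)) / float(2 ** scale_bits)


# ---------------------------------------------------------------------------
# keys


@dataclass
class KeySet:
    """Secret key, public encryption key, relinearization key and rotation keys.

    Rotation keys cover every power-of-two shift below the slot capacity, the
    exact set AllSum consumes.  Switching keys live at modulus P*q.
    """

    params: HEParams
    secret: RingPoly                      # ternary, stored at modulus P*q
    pk: tuple                             # (b, a) at log_q
    evk: tuple                            # (b, a) at log_q + special
    rot: dict                             # shift -> (b, a, galois exponent)
    _rng: np.random.Generator = None

    def public_part(self) -> "KeySet":
        """A copy without the secret key (what the training server holds)."""
        return KeySet(self.params, None, self.pk, self.evk, dict(self.rot),
                      np.random.default_rng(0))


def keygen(params: HEParams, seed: int) -> KeySet:
    """Deterministic key generation from a root seed."""
    n = params.ring_degree
    lq = params.log_q
    lpq = lq + params.special_bits
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_s, rng_pk, rng_evk, rng_rot, rng_enc, _ = [np.random.default_rng(s) for s in streams]

    s = sample_ring(SamplerSpec("sparse-ternary", hamming_weight=params.secret_hamming),
                    n, lpq, rng=rng_s)
    gauss = SamplerSpec("discrete-gaussian", stddev=params.error_stddev)

    def rlwe_pair(target_bits, rng, extra=None):
        a = sample_ring(SamplerSpec("uniform"), n, target_bits, rng=rng)
        e = sample_ring(gauss, n, target_bits, rng=rng)
        s_red = mod_reduce(s, target_bits)
        b = poly_add(poly_neg(poly_mult(a, s_red)), e)
        if extra is not None:
            b = poly_add(b, extra)
        return b, a

    pk = rlwe_pair(lq, rng_pk)

    p_factor = 1 << params.special_bits
    s_big = mod_reduce(s, lpq)
    s2 = poly_mult(s_big, s_big)
    evk = rlwe_pair(lpq, rng_evk, extra=poly_scalar_mult(s2, p_factor))

    rot = {}
    shift = 1
    while shift < params.slot_capacity:
        k = pow(5, shift, 2 * n)
        s_rot = apply_automorphism(s_big, k)
        b, a = rlwe_pair(lpq, rng_rot, extra=poly_scalar_mult(s_rot, p_factor))
        rot[shift] = (b, a, k)
        shift *= 2
    return KeySet(params, s, pk, evk, rot, rng_enc)


# ---------------------------------------------------------------------------
# ciphertexts and operations


@dataclass
class Ciphertext:
    """(c0, c1) under the secret key, with its bookkeeping.

    current modulus is 2**log_q (non-increasing along any op sequence);
    scale_bits tracks the power of two by which the encoded reals are scaled;
    slot_count is the logical vector length k (<= N/2, power of two).
    """

    c0: RingPoly
    c1: RingPoly
    log_q: int
    scale_bits: int
    slot_count: int

    @property
    def ring_degree(self) -> int:
        return self.c0.ring_degree


def encrypt(pt: RingPoly, keys: KeySet, slot_count: int | None = None,
            scale_bits: int | None = None) -> Ciphertext:
    p = keys.params
    if pt.modulus_bits > p.log_q:
        raise AlignmentError("plaintext modulus exceeds scheme modulus")
    rng = keys._rng
    gauss = SamplerSpec("discrete-gaussian", stddev=p.error_stddev)
    n = p.ring_degree
    bits = pt.modulus_bits
    v = sample_ring(SamplerSpec("zero-one"), n, bits, rng=rng)
    e0 = sample_ring(gauss, n, bits, rng=rng)
    e1 = sample_ring(gauss, n, bits, rng=rng)
    b, a = (mod_reduce(x, bits) for x in keys.pk)
    c0 = poly_add(poly_add(poly_mult(v, b), e0), pt)
    c1 = poly_add(poly_mult(v, a), e1)
    return Ciphertext(c0, c1, bits,
                      scale_bits if scale_bits is not None else keys.params.log_p,
                      slot_count if slot_count is not None else p.slot_capacity)


def decrypt(ct: Ciphertext, keys: KeySet) -> RingPoly:
    if keys.secret is None:
        raise KeyMissingError("secret key not available")
    s = mod_reduce(keys.secret, ct.log_q)
    return poly_add(ct.c0, poly_mult(ct.c1, s))


def _check_aligned(c1: Ciphertext, c2: Ciphertext) -> None:
    if c1.log_q != c2.log_q:
        raise AlignmentError(f"modulus mismatch 2^{c1.log_q} vs 2^{c2.log_q}")
    if c1.scale_bits != c2.scale_bits:
        raise AlignmentError(f"scale mismatch 2^{c1.scale_bits} vs 2^{c2.scale_bits}")


def he_add(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    _check_aligned(c1, c2)
    return Ciphertext(poly_add(c1.c0, c2.c0), poly_add(c1.c1, c2.c1),
                      c1.log_q, c1.scale_bits, c1.slot_count)


def he_sub(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    _check_aligned(c1, c2)
    return Ciphertext(poly_sub(c1.c0, c2.c0), poly_sub(c1.c1, c2.c1),
                      c1.log_q, c1.scale_bits, c1.slot_count)


_KS_MARGIN = 16


def _keyswitch(d: RingPoly, key_pair, params: HEParams) -> tuple:
    """Switch the component d (mod q_t) using a key published at modulus P*q.

    The master key carries the gadget factor P = 2**(log_q + margin).  For a
    ciphertext living at q_t < q the key is first *rescaled* down to the
    effective factor P_t = 2**(q_t + margin) (dividing its message P*s^k by a
    power of two, which only adds sub-unit rounding noise) and reduced to
    modulus P_t * q_t, so the exact convolution shrinks with the working
    modulus instead of staying at fresh-modulus cost.

    Returns the (delta_c0, delta_c1) contribution mod q_t.
    """
    b, a = key_pair
    bits = d.modulus_bits
    st = min(bits + _KS_MARGIN, params.special_bits)
    target = bits + st
    r = params.special_bits - st
    if r > 0:
        b = divide_round(b, r, b.modulus_bits - r)
        a = divide_round(a, r, a.modulus_bits - r)
    b = mod_reduce(b, target)
    a = mod_reduce(a, target)
    lifted = RingPoly(d.coeffs, target, d.ring_degree)
    d0 = divide_round(poly_mult(lifted, b), st, bits)
    d1 = divide_round(poly_mult(lifted, a), st, bits)
    return d0, d1


def _tensor(c1: Ciphertext, c2: Ciphertext) -> tuple:
    """Degree-2 ciphertext product (d0, d1, d2) via Karatsuba (3 ring mults)."""
    t0 = poly_mult(c1.c0, c2.c0)
    t2 = poly_mult(c1.c1, c2.c1)
    t1 = poly_sub(poly_sub(poly_mult(poly_add(c1.c0, c1.c1),
                                     poly_add(c2.c0, c2.c1)), t0), t2)
    return t0, t1, t2


def _relinearize(d0: RingPoly, d1: RingPoly, d2: RingPoly, keys: KeySet) -> tuple:
    if keys.evk is None:
        raise KeyMissingError("relinearization key missing")
    k0, k1 = _keyswitch(d2, keys.evk, keys.params)
    return poly_add(d0, k0), poly_add(d1, k1)


def he_mult(c1: Ciphertext, c2: Ciphertext, keys: KeySet) -> Ciphertext:
    """Slot-wise product at scale p^2 (caller rescales); relinearized."""
    if c1.log_q != c2.log_q:
        raise AlignmentError(f"modulus mismatch 2^{c1.log_q} vs 2^{c2.log_q}")
    d0, d1, d2 = _tensor(c1, c2)
    r0, r1 = _relinearize(d0, d1, d2, keys)
    return Ciphertext(r0, r1, c1.log_q, c1.scale_bits + c2.scale_bits,
                      min(c1.slot_count, c2.slot_count))


def he_dot(cts_a, cts_b, keys: KeySet) -> Ciphertext:
    """Sum of slot-wise products, relinearizing once at the end."""
    acc = None
    for x, y in zip(cts_a, cts_b):
        if x.log_q != y.log_q:
            raise AlignmentError("modulus mismatch in dot")
        t = _tensor(x, y)
        acc = t if acc is None else tuple(poly_add(u, v) for u, v in zip(acc, t))
    r0, r1 = _relinearize(*acc, keys)
    c = cts_a[0]
    return Ciphertext(r0, r1, c.log_q, c.scale_bits + cts_b[0].scale_bits,
                      min(c.slot_count, cts_b[0].slot_count))


def rescale(ct: Ciphertext, r_bits: int, params: HEParams) -> Ciphertext:
    """RS(ct; 2**r_bits): message divided by 2**r_bits, modulus reduced by
    exactly r_bits.  Refuses to drop below the base modulus."""
    new_bits = ct.log_q - r_bits
    if new_bits < params.log_q0:
        raise BudgetExhaustedError(
            f"rescaling by {r_bits} bits would drop the modulus to "
            f"{new_bits} < log q0 = {params.log_q0}")
    return Ciphertext(divide_round(ct.c0, r_bits, new_bits),
                      divide_round(ct.c1, r_bits, new_bits),
                      new_bits, ct.scale_bits - r_bits, ct.slot_count)


def mod_reduce_ct(ct: Ciphertext, new_log_q: int) -> Ciphertext:
    if new_log_q > ct.log_q:
        raise AlignmentError("modulus can only decrease")
    if new_log_q == ct.log_q:
        return ct
    return Ciphertext(mod_reduce(ct.c0, new_log_q), mod_reduce(ct.c1, new_log_q),
                      new_log_q, ct.scale_bits, ct.slot_count)


def plain_scalar_mult(ct: Ciphertext, m: int, added_scale_bits: int) -> Ciphertext:
    """Multiply by the integer constant m, declared to encode a real at
    scale 2**added_scale_bits (scale bookkeeping adds those bits)."""
    return Ciphertext(poly_scalar_mult(ct.c0, m), poly_scalar_mult(ct.c1, m),
                      ct.log_q, ct.scale_bits + added_scale_bits, ct.slot_count)


def add_plain(ct: Ciphertext, pt: RingPoly) -> Ciphertext:
    if pt.modulus_bits != ct.log_q:
        pt = mod_reduce(pt, ct.log_q)
    return Ciphertext(poly_add(ct.c0, pt), ct.c1, ct.log_q, ct.scale_bits, ct.slot_count)


def relabel_scale(ct: Ciphertext, new_scale_bits: int) -> Ciphertext:
    """Pure bookkeeping: reinterpret the scale (value scales by 2**(old-new))."""
    return replace(ct, scale_bits=new_scale_bits)


def rotate_slots(ct: Ciphertext, shift: int, keys: KeySet) -> Ciphertext:
    """Cyclic rotation of the logical slots: slot j takes the value of
    slot j+shift.  Composed from the power-of-two rotation keys."""
    k = ct.slot_count
    shift %= k
    if shift == 0:
        return ct
    out = ct
    bit = 1
    while shift:
        if shift & 1:
            if bit not in keys.rot:
                raise KeyMissingError(f"rotation key for shift {bit} missing")
            b, a, gal = keys.rot[bit]
            r0 = apply_automorphism(out.c0, gal)
            r1 = apply_automorphism(out.c1, gal)
            k0, k1 = _keyswitch(r1, (b, a), keys.params)
            out = Ciphertext(poly_add(r0, k0), k1, out.log_q, out.scale_bits,
                             out.slot_count)
        shift >>= 1
        bit <<= 1
    return out


# ---------------------------------------------------------------------------
# encrypted polynomial evaluation


def poly_eval_encrypted(ct: Ciphertext, int_coeffs, scale_bits: int,
                        keys: KeySet) -> Ciphertext:
    """Evaluate g(x) slot-wise on an encryption of x, where g has real
    coefficients int_coeffs[k] / 2**scale_bits (index = power of x).

    Powers of x are built by repeated squaring/products, each rescaled back to
    the input scale; the quantized coefficients multiply in as integer
    constants and one final rescale by 2**scale_bits returns the result at the
    input scale.  Needs modulus headroom for ceil(log2 deg)+1 rescalings.
    """
    params = keys.params
    coeffs = [int(c) for c in int_coeffs]
    deg = len(coeffs) - 1
    while deg > 0 and coeffs[deg] == 0:
        deg -= 1
    lp = ct.scale_bits
    powers = {1: ct}

    def get_power(k: int) -> Ciphertext:
        if k in powers:
            return powers[k]
        half = k // 2
        a = get_power(half)
        b = get_power(k - half)
        lo = min(a.log_q, b.log_q)
        prod = he_mult(mod_reduce_ct(a, lo), mod_reduce_ct(b, lo), keys)
        powers[k] = rescale(prod, lp, params)
        return powers[k]

    for k in range(2, deg + 1):
        if coeffs[k]:
            get_power(k)
    level = min((p.log_q for p in powers.values()), default=ct.log_q)
    acc = None
    for k in range(1, deg + 1):
        if not coeffs[k]:
            continue
        term = plain_scalar_mult(mod_reduce_ct(powers[k], level), coeffs[k], scale_bits)
        acc = term if acc is None else he_add(acc, term)
    if acc is None:                       # constant polynomial
        acc = plain_scalar_mult(mod_reduce_ct(ct, level), 0, scale_bits)
    if coeffs[0]:
        const = RingPoly.constant(coeffs[0] << lp, acc.log_q, ct.ring_degree)
        acc = add_plain(acc, const)
    return rescale(acc, scale_bits, params)
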