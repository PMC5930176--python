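"""Gradient-descent logistic regression on packed ciphertexts.

Client side: each sample is folded into z_i = y_i * (1, x_i); the j-th
attribute column p*(z_1j, ..., z_nj) is scaled, rounded and packed into one
ciphertext, giving d+1 ciphertexts regardless of n (n is zero-padded to the
next power of two k).

Server side: starting from beta = 0, each full-batch iteration computes

    beta_j  <-  beta_j + (alpha/n) * sum_i g(-z_i^T beta) * z_ij

with the polynomial surrogate g in place of the sigmoid.  Per-slot inner
products use the SIMD packing; the sum over samples is AllSum (log2 k
rotate-and-add steps leaving the slot total replicated in every slot).

Circuit layout.  A literal transcription of the update (inner product,
rescale, generic polynomial evaluation, gradient product, AllSum, rescale by
n/alpha) costs log p * (ceil(log deg g) + 3) + ceil(log n/alpha) modulus bits
per iteration.  This module instead evaluates the surrogate in factored form:
with u^ = (z^T beta)/8 (the fits live on [-8, 8], so u^ is in [-1, 1]),

    g(-u) = 1/2 - (c1 u^ + c3 u^3 [+ c5 u^5 + c7 u^7])
          = 1/2 + (-lead) * u^ (u^2 - y1) [ (u^4 + U u^2 + V) ]

where y1 (and U, V) come from factoring the odd part over the reals.  The
additive constants y1, U, V enter as scale-matched plaintext additions, which
cost no modulus, and the single multiplicative constant lead*(alpha/n) is
folded once into the *fresh* data ciphertexts (which sit far above the
working modulus from iteration 2 on), absorbing Box-style final division by
n/alpha.  The measured cost is then 3*log p + 3 bits per iteration for g3 and
4*log p + 3 for g7 -- within the optimized budget 3 (resp 4) * log p +
ceil(log(n/4 alpha)) whenever n >= 32 alpha, which holds for every dataset
scale this tool targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ckks import BudgetExhaustedError, CapacityError
from .ring import ParameterError
from .sigmoid import ApproxPoly

__all__ = [
    "EncodedDataset",
    "TrainConfig",
    "EncryptedModel",
    "prepare_client_payload",
    "allsum",
    "secure_train",
    "secure_train_iteration",
    "modulus_budget",
    "decrypt_model",
    "factor_odd_part",
]


@dataclass
class EncodedDataset:
    """The d+1 packed data ciphertexts ct.z_0 .. ct.z_d plus shape metadata."""

    ciphertexts: list
    sample_count: int
    padded_slot_count: int
    feature_count: int
    scale_bits: int


@dataclass
class TrainConfig:
    learning_rate: float = 1.0
    iterations: int = 20
    surrogate: ApproxPoly = None
    log_p: int = 28

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.iterations < 0:
            raise ParameterError("iteration count must be >= 0")


@dataclass
class EncryptedModel:
    betas: list
    iterations_done: int
    remaining_log_q: int
    bits_per_iteration: list = field(default_factory=list)


def _pow2_at_least(n: int) -> int:
    k = 1
    while k < n:
        k *= 2
    return k


def prepare_client_payload(X, y=None, backend=None, log_p: int | None = None) -> EncodedDataset:
    """Scale, pack and encrypt the z-columns of a dataset.

    X: (n, d) covariates (or a Dataset, in which case y is omitted and the
    backend may be passed second); y: labels in {-1,+1} (or {0,1}, mapped).
    Produces d+1 ciphertexts, the j-th encrypting p*(z_1j, ..., z_nj)
    zero-padded to a power-of-two slot count.
    """
    if hasattr(X, "covariates"):           # a Dataset
        if backend is None:
            backend = y
        X, y = X.covariates, X.labels
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if set(np.unique(y)) <= {0.0, 1.0}:
        y = 2 * y - 1
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ParameterError("labels must be in {-1,+1} or {0,1}")
    lp = log_p if log_p is not None else backend.params.log_p
    k = _pow2_at_least(n)
    if k > backend.params.slot_capacity:
        raise CapacityError(
            f"{n} samples need {k} slots; ring offers {backend.params.slot_capacity}")
    Z = np.column_stack([y, X * y[:, None]])          # z_i = y_i * (1, x_i)
    cts = [backend.encrypt_vector(Z[:, j], k, lp) for j in range(d + 1)]
    return EncodedDataset(cts, n, k, d, lp)


def allsum(ct, k: int, backend):
    """Replicate the sum of the k logical slots into every slot.

    Exactly log2(k) rotation+add steps; k must be a power of two."""
    if k <= 0 or k & (k - 1):
        raise ParameterError(f"slot count {k} is not a power of two")
    step = 1
    while step < k:
        ct = backend.add(ct, backend.rotate(ct, step))
        step *= 2
    return ct


def modulus_budget(surrogate_degree: int, log_p: int, n: int, alpha: float,
                   iter_num: int, optimized: bool = True) -> tuple:
    """Per-iteration and total ciphertext-modulus requirement (bits).

    Naive circuit: log p * (ceil(log2 deg) + 3) + ceil(log2(n/alpha)) per
    iteration.  Optimized circuit: 3*log p + ceil(log2(n/4 alpha)) for g3,
    4*log p + ceil(log2(n/4 alpha)) for g7.  Total adds the base modulus
    log q0 = log p + 10 on top of iter_num iterations.
    """
    if surrogate_degree not in (3, 7):
        raise ParameterError(f"unsupported surrogate degree {surrogate_degree}")
    if n < 1 or iter_num < 1:
        raise ParameterError("n and iter_num must be >= 1")
    if optimized:
        levels = 3 if surrogate_degree == 3 else 4
        per = levels * log_p + math.ceil(math.log2(n / (4 * alpha)))
    else:
        per = log_p * (math.ceil(math.log2(surrogate_degree)) + 3) \
            + math.ceil(math.log2(n / alpha))
    return per, iter_num * per + (log_p + 10)


def factor_odd_part(surrogate: ApproxPoly) -> tuple:
    """Factor the odd part of a degree-3/7 surrogate over the reals.

    Writes c1 u + c3 u^3 (+ c5 u^5 + c7 u^7) = lead * u (u^2 - y1)
    [* (u^4 + U u^2 + V)] in the surrogate's scaled variable u, and returns
    (lead, y1, quartic) with quartic = (U, V) or None for degree 3.
    """
    odd = surrogate.odd_coefficients
    if surrogate.degree == 3:
        c1, c3 = odd
        return c3, -c1 / c3, None
    if surrogate.degree == 7:
        c1, c3, c5, c7 = odd
        roots = np.roots([c7, c5, c3, c1])
        real = [r for r in roots if abs(r.imag) < 1e-9]
        if not real:
            raise ParameterError("odd part has no real quadratic factor")
        y1 = float(real[0].real)
        # remove the chosen root once, keep the remaining pair
        rest = list(roots)
        rest.remove(real[0])
        U = float(-(rest[0] + rest[1]).real)
        V = float((rest[0] * rest[1]).real)
        return c7, y1, (U, V)
    raise ParameterError(f"unsupported surrogate degree {surrogate.degree}")


def _shift_bits(surrogate: ApproxPoly) -> int:
    a = surrogate.divisor if surrogate.basis == "scaled" else 1.0
    s = round(math.log2(a))
    if 2 ** s != a:
        raise ParameterError("surrogate interval half-width must be a power of two")
    return s


def _fold_constant_lane(enc: EncodedDataset, cfg: TrainConfig, backend):
    """One-time: fresh-ciphertext copies of z scaled by lead*(alpha/n).

    These carry the single multiplicative constant of the factored surrogate;
    they live one rescale below the fresh modulus, still far above the working
    level of any iteration."""
    lead, _, _ = factor_odd_part(cfg.surrogate)
    c_mult = -lead * cfg.learning_rate / enc.sample_count
    lp = cfg.log_p
    out = []
    for ct in enc.ciphertexts:
        out.append(backend.rescale(backend.plain_scalar(ct, c_mult, lp), lp))
    return out


def secure_train_iteration(model: EncryptedModel, enc: EncodedDataset,
                           cfg: TrainConfig, backend, zc=None) -> EncryptedModel:
    """One Box-2 iteration in factored form (see module docstring).

    Decrypting the updated betas matches one plaintext update step with
    activation g to within the scheme's noise tolerance."""
    lp = cfg.log_p
    s3 = _shift_bits(cfg.surrogate)
    lead, y1, quartic = factor_odd_part(cfg.surrogate)
    if zc is None:
        zc = _fold_constant_lane(enc, cfg, backend)
    betas = model.betas
    z = enc.ciphertexts
    m_top = backend.log_q_of(betas[0])
    half_c = 0.5 * cfg.learning_rate / enc.sample_count

    def step(label, fn):
        try:
            return fn()
        except BudgetExhaustedError as err:
            raise BudgetExhaustedError(f"{label}: {err}") from err

    # inner products u_i = z_i^T beta, then u^ = u/8 at scale p
    ipraw = step("inner-product", lambda: backend.dot(
        [backend.mod_to(ct, m_top) for ct in z], betas))
    t = step("inner-product rescale", lambda: backend.rescale(ipraw, lp + s3))
    t = backend.relabel(t, lp)
    m1 = backend.log_q_of(t)

    x2 = step("square", lambda: backend.rescale(backend.mult(t, t), lp))
    m2 = backend.log_q_of(x2)
    x2s = backend.add_const(x2, -y1)

    if quartic is not None:
        U, V = quartic
        braw = backend.add_const(backend.mult(x2, backend.add_const(x2, U)), V)
        B = step("quartic rescale", lambda: backend.rescale(braw, lp))
        m_last = backend.log_q_of(B)
    else:
        B = None
        m_last = m2

    new_betas = []
    for j in range(enc.feature_count + 1):
        zxc = step(f"grad[{j}] data-lane", lambda: backend.rescale(
            backend.mult(backend.mod_to(zc[j], m1), t), lp))
        A = backend.mult(zxc, x2s)
        if B is not None:
            A = step(f"grad[{j}] cubic rescale", lambda: backend.rescale(A, lp))
            A = backend.mult(A, B)
        t0 = backend.plain_scalar(backend.mod_to(z[j], m_last), half_c, lp)
        G = allsum(backend.add(A, t0), enc.padded_slot_count, backend)
        grad = step(f"grad[{j}] final rescale", lambda: backend.rescale(G, lp))
        new_betas.append(backend.add(
            backend.mod_to(betas[j], backend.log_q_of(grad)), grad))

    remaining = backend.log_q_of(new_betas[0])
    bits = model.bits_per_iteration + [m_top - remaining]
    return EncryptedModel(new_betas, model.iterations_done + 1, remaining, bits)


def secure_train(enc: EncodedDataset, cfg: TrainConfig, backend) -> EncryptedModel:
    """Run IterNum encrypted gradient-descent iterations from beta = 0.

    Refuses up front if the modulus cannot support the requested iterations
    (checked against both the published optimized budget and the actual
    per-iteration depth of this circuit)."""
    lp = cfg.log_p
    deg = cfg.surrogate.degree
    per_formula, _ = modulus_budget(deg, lp, enc.sample_count,
                                    cfg.learning_rate, max(cfg.iterations, 1))
    per_actual = (3 if deg == 3 else 4) * lp + _shift_bits(cfg.surrogate)
    need = backend.params.log_q0 + cfg.iterations * max(per_formula, per_actual)
    if backend.params.log_q < need:
        raise BudgetExhaustedError(
            f"fresh modulus {backend.params.log_q} bits cannot support "
            f"{cfg.iterations} iterations (needs {need} bits); "
            f"no work was started")
    k = enc.padded_slot_count
    model = EncryptedModel(
        [backend.zero_ct(k, lp) for _ in range(enc.feature_count + 1)],
        0, backend.params.log_q)
    if cfg.iterations == 0:
        return model
    zc = _fold_constant_lane(enc, cfg, backend)
    for _ in range(cfg.iterations):
        model = secure_train_iteration(model, enc, cfg, backend, zc=zc)
    return model


def decrypt_model(model: EncryptedModel, backend) -> np.ndarray:
    """Recover beta (length d+1): AllSum left every slot holding beta_j."""
    return np.array([float(np.mean(backend.decrypt_vector(ct)))
                     for ct in model.betas])
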