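"""Polynomial surrogates of the sigmoid for evaluation under encryption.

The logistic link sigma(x) = 1/(1+exp(-x)) cannot be evaluated
homomorphically, so training replaces it by a polynomial.  Two surrogates are
provided:

* Taylor (Maclaurin) truncations T_d -- a *local* approximation around 0 whose
  error explodes as |x| grows, kept here mainly as the negative control;
* least-squares fits over a symmetric interval [-a, a] -- the *global*
  approximation minimizing the mean squared error
  (1/2a) * integral_{-a}^{a} (sigma - g)^2 dx,
  which is what the encrypted trainer actually uses (degrees 3 and 7 over
  [-8, 8], the interval that contains every inner product the training
  iterations produce).

Because sigma(x) - 1/2 is odd, the fit is restricted to a constant 1/2 plus
odd powers, and coefficients are reported in the scaled-monomial basis
{1, x/a, (x/a)^3, ...} so their magnitudes stay O(1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import integrate

__all__ = [
    "ApproxPoly",
    "sigmoid",
    "taylor_sigmoid",
    "lsq_sigmoid_fit",
    "mse_on_interval",
    "max_abs_error",
]


def sigmoid(x):
    """1/(1+exp(-x)), overflow-safe for any finite float (vectorized)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ApproxPoly:
    """A polynomial surrogate of the sigmoid.

    coefficients holds (constant, then the odd-term coefficients in ascending
    degree).  basis is "scaled" (monomials in x/divisor) or "raw".  For
    Taylor polynomials every stored odd coefficient corresponds to degrees
    1, 3, 5, ... and even degrees >= 2 vanish identically.
    """

    degree: int
    interval: tuple
    basis: str
    divisor: float
    coefficients: tuple

    def __post_init__(self):
        if self.basis not in ("scaled", "raw"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def constant(self) -> float:
        return self.coefficients[0]

    @property
    def odd_coefficients(self) -> tuple:
        return self.coefficients[1:]

    def raw_odd_coefficients(self) -> tuple:
        """Odd-term coefficients in the raw monomial basis (degrees 1,3,5,...)."""
        if self.basis == "raw":
            return self.odd_coefficients
        a = self.divisor
        return tuple(c / a ** k for c, k in zip(self.odd_coefficients,
                                                range(1, self.degree + 1, 2)))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        u = x / self.divisor if self.basis == "scaled" else x
        out = np.full_like(u, self.constant, dtype=float)
        for c, k in zip(self.odd_coefficients, range(1, self.degree + 1, 2)):
            out = out + c * u ** k
        return float(out) if out.ndim == 0 else out

    def dense_int_coefficients(self, scale_bits: int) -> list:
        """Raw-basis coefficients quantized to integers at 2**scale_bits,
        indexed by power (for the encrypted polynomial evaluator)."""
        dense = [0] * (self.degree + 1)
        dense[0] = round(self.constant * 2 ** scale_bits)
        for c, k in zip(self.raw_odd_coefficients(), range(1, self.degree + 1, 2)):
            dense[k] = round(c * 2 ** scale_bits)
        return dense

    def to_json(self) -> str:
        return json.dumps({
            "degree": self.degree,
            "interval": list(self.interval),
            "basis": self.basis,
            "divisor": self.divisor,
            "coefficients": list(self.coefficients),
        })

    @classmethod
    def from_json(cls, s: str) -> "ApproxPoly":
        d = json.loads(s)
        return cls(d["degree"], tuple(d["interval"]), d["basis"], d["divisor"],
                   tuple(d["coefficients"]))


def _maclaurin_fractions(degree: int) -> list:
    """Exact Maclaurin coefficients of the sigmoid up to `degree`.

    Uses the recurrence for the derivatives of sigma via the Euler zigzag-free
    route: sigma(x) = 1/2 + (1/2) tanh(x/2); tanh's series from Bernoulli
    numbers would do, but a direct Taylor recurrence on the ODE
    sigma' = sigma (1 - sigma) is simpler and exact in rationals.
    """
    # c[k] = sigma^(k)(0)/k! ; from c' relation: (k+1) c[k+1] = sum_{i} c[i]*(delta - c) ...
    # Work with the series product: s' = s - s^2, in coefficient form.
    c = [Fraction(1, 2)]
    for k in range(degree):
        sq = sum(c[i] * c[k - i] for i in range(k + 1))
        c.append((c[k] - sq) / (k + 1))
    return c


def taylor_sigmoid(degree: int) -> ApproxPoly:
    """Maclaurin truncation T_d of the sigmoid (exact rational coefficients)."""
    if degree < 0:
        raise ValueError("degree must be >= 0")
    c = _maclaurin_fractions(degree)
    odd = tuple(float(c[k]) for k in range(1, degree + 1, 2))
    return ApproxPoly(degree=degree, interval=(-math.inf, math.inf),
                      basis="raw", divisor=1.0,
                      coefficients=(float(c[0]),) + odd)


def _gl_nodes(nodes: int):
    return np.polynomial.legendre.leggauss(nodes)


def lsq_sigmoid_fit(degree: int, half_width: float, nodes: int = 256) -> ApproxPoly:
    """MSE-minimizing polynomial of odd degree d over [-a, a].

    Solves the normal equations of the orthogonal projection of sigma onto
    span{1, u, u^3, ...}, u = x/a, with Gauss-Legendre quadrature (256 nodes
    integrate these degree <= 2d+smooth integrands far beyond the 5-decimal
    reproducibility this fit is held to).
    """
    if degree < 1 or degree % 2 == 0:
        raise ValueError("degree must be odd and >= 1")
    if half_width <= 0:
        raise ValueError("half-width must be positive")
    x, w = _gl_nodes(nodes)
    powers = [0] + list(range(1, degree + 1, 2))
    gram = np.array([[np.sum(w * x ** i * x ** j) for j in powers] for i in powers])
    rhs = np.array([np.sum(w * x ** i * sigmoid(half_width * x)) for i in powers])
    cond = np.linalg.cond(gram)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"normal equations ill-conditioned (cond ~ {cond:.2e}) at degree {degree}")
    coef = np.linalg.solve(gram, rhs)
    return ApproxPoly(degree=degree, interval=(-half_width, half_width),
                      basis="scaled", divisor=float(half_width),
                      coefficients=tuple(float(v) for v in coef))


def mse_on_interval(g, half_width: float) -> float:
    """(1/2a) * integral_{-a}^{a} (sigma - g)^2 dx by adaptive quadrature.

    g may be an ApproxPoly or any callable (so an oracle can be injected)."""
    if half_width <= 0:
        raise ValueError("half-width must be positive")
    f = g if callable(g) else (lambda x: float(g))
    val, _ = integrate.quad(lambda x: (sigmoid(x) - f(x)) ** 2,
                            -half_width, half_width, limit=200)
    return val / (2 * half_width)


def max_abs_error(g, half_width: float, grid: int = 20001) -> float:
    """max |sigma(x) - g(x)| over a dense grid on [-a, a]."""
    if half_width <= 0:
        raise ValueError("half-width must be positive")
    x = np.linspace(-half_width, half_width, grid)
    return float(np.max(np.abs(sigmoid(x) - g(x))))
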