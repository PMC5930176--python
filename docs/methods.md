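# Methods

## Problem and model

`helogit` trains a binary logistic regression model without ever decrypting
the training data.  Samples are pairs (x_i, y_i), x_i in R^d, y_i in
{-1, +1}; with z_i = y_i (1, x_i) the negative log-likelihood has gradient
-(1/n) sum_i sigma(-z_i^T beta) z_i, and full-batch gradient descent updates

    beta <- beta + (alpha/n) sum_i sigma(-z_i^T beta) z_i

from beta = 0.  Newton-type methods need matrix inversion, which homomorphic
encryption does not support naturally, so plain gradient descent with a fixed
learning rate alpha (default 1.0) and a fixed iteration count is used; there
is no convergence detection (a known limitation, see below).

## The encryption scheme

The carrier is the ring R_q = Z_q[X]/(X^N+1), N a power of two, with
q = 2^(log q).  A vector of up to N/2 reals is encoded in the ring's
canonical-embedding "slots" (evaluations at odd 2N-th roots of unity, orbit
of 5), scaled by p = 2^(log p) and rounded.  Addition and multiplication act
slot-wise; a Galois automorphism X -> X^(5^r) plus key switch rotates the
slot vector cyclically by r.  Rescaling RS(ct; 2^r) divides the message and
the modulus by 2^r -- fixed-point rounding -- and is the only way the modulus
moves, so the modulus is a strictly decreasing resource ("budget") that caps
the multiplicative depth and hence the iteration count.

Conventions (the source text defers these to appendices, so they are fixed
here as the field's defaults, configurable in `HEParams`):

* secret key: sparse ternary, Hamming weight 64;
* errors: discrete Gaussian, sd 3.2;
* encryption randomness: {0,+-1} with probabilities (1/2, 1/4, 1/4);
* centered coefficient representatives in (-q/2, q/2];
* power-of-two moduli throughout, so every rescale divisor is a power of two
  and reductions are bit masks;
* key switching uses a special modulus P = 2^(log q + 16); for a ciphertext
  at modulus q_t the switching key is rescaled on the fly to the effective
  factor 2^(q_t + 16), shrinking the exact big-integer convolutions with the
  working level.

Ring products are computed exactly by Kronecker substitution (coefficients
packed into one big integer per operand, multiplied with CPython's
arbitrary-precision multiply, unpacked, negacyclically folded).  No floating
point enters the ring.

Two presets are shipped: `desk` (N = 2^13, log q = 220, log p = 28; enough
for a couple of multiplicative levels, used for fast experimentation) and
`paper` (N = 2^15, log p = 28, log q0 = 38, log q = 2338 from the budget
formula at the clinical-study scale).  The parameter presets are not
security-audited artifacts; no lattice-attack estimator is included.

## Sigmoid surrogates

Encrypted evaluation admits only polynomials.  Maclaurin truncations T_d are
provided as the negative control: they are local approximations and their
error explodes on [-8, 8] (T9(4) ~ 4.44 already; the package asserts this
value from exact rational coefficients).  The trainer instead uses the
MSE-minimizing fit over I = [-8, 8]: minimize (1/|I|) int_I (sigma - g)^2 in
span{1, u, u^3, ...}, u = x/8, solved by orthogonal projection with 256-node
Gauss-Legendre quadrature (exact to machine precision for these integrands;
doubling the nodes moves coefficients < 1e-7).  Restricting to a constant
1/2 plus odd terms is exact, because sigma - 1/2 is odd.  The degree-3 and
degree-7 fits are

    g3: (a1, a3)        = ( 1.200963, -0.815625)
    g7: (b1, b3, b5, b7) = ( 1.735165, -4.195716,  5.437381, -2.509360)

in the scaled basis {1, x/8, (x/8)^3, ...}.  An independent cross-check
recomputes both via truncated Legendre series; the two routes agree to 1e-9.
The interval [-8, 8] must contain every inner product z_i^T beta during
training; the synthetic-data generator enforces this by construction and the
tests verify it on the trained iterates.

## The encrypted training circuit

Clients scale z-columns by p, round, zero-pad n to a power of two k, and pack
each attribute column into one ciphertext: d+1 ciphertexts total.  AllSum
(log2 k rotate-and-add steps) replicates a slot total into every slot, so a
batched inner product plus AllSum computes sum_i g(-z_i^T beta) z_ij for all
i in parallel.

A literal iteration (inner product, rescale by p, generic polynomial
evaluation, gradient product, AllSum, rescale by round(n/alpha)) consumes
log p * (ceil(log2 deg g) + 3) + ceil(log2 (n/alpha)) modulus bits.  The
shipped circuit reduces this by evaluating the surrogate in factored form.
Writing u^ = (z^T beta)/8 in [-1, 1],

    g(-u) = 1/2 + (-lead) * u^ (u^2 - y1) [ * (u^4 + U u^2 + V) ]

where y1 (and, for degree 7, U, V) come from factoring the odd part of g
over the reals (one real root of the cubic in u^2 plus a real quadratic from
the conjugate pair).  Three observations make this cheap:

1. additive constants (y1, U, V) enter as scale-matched plaintext additions,
   which cost no modulus;
2. the single multiplicative constant lead * (alpha/n) is folded once into a
   rescaled copy of the *fresh* data ciphertexts.  Fresh ciphertexts sit at
   the full modulus, far above the working level from iteration 2 onward, so
   this multiplication never touches the per-iteration budget -- and it
   absorbs the round(n/alpha) division entirely;
3. the /8 basis change rides the first rescale (divide by 8p instead of p).

Per-iteration consumption is then measured at 3 log p + 3 bits (g3) and
4 log p + 3 bits (g7) -- within the optimized budgets 3 log p +
ceil(log2(n/4 alpha)) and 4 log p + ceil(log2(n/4 alpha)) whenever
n >= 32 alpha, which holds at every target scale.  `modulus_budget` exposes
both the naive and optimized published formulas; `secure_train` refuses up
front if the fresh modulus cannot fund the requested iterations, and logs the
per-iteration consumption so budget exhaustion is diagnosable.  The generic
encrypted `PolyEval` (powers by repeated squaring, quantized coefficients,
one final rescale) is also provided and tested, but the trainer uses the
fused circuit above.

The rescale divisor round(n/alpha) of the literal algorithm is realized
inside the folded constant, so every physical rescale stays a power of two
and the scale ledger is bit-exact.  n here is the true sample count, not the
padded slot count: padded slots carry z = 0 and every gradient term has a
factor z, so padding is exactly neutral.

## Backends, noise, and tolerances

Two backends implement one interface: the real scheme, and a mock backend
that executes the identical circuit on plaintext slot vectors with the same
scale/modulus bookkeeping (including budget-exhaustion errors) and the same
quantized constants.  The mock isolates surrogate/quantization error from
encryption noise; pipeline tests run both and compare.

Empirical noise constants (the source gives none) are pinned as regression
bounds: fresh-encryption slot error is ~sigma*N of a grid unit (the
embedding sums N coefficient errors), i.e. ~2^-11.9 relative at N = 2^13 and
log p = 28, and ~2^-16 at the N = 64 test ring; encode/decode rounding is
sqrt(N) grid units.  The end-to-end gate is the one the method's authors
report: decrypted and plaintext-trained coefficients agree to better than
2^-11 per coordinate.  On the benchmark runs here the mock backend agrees to
~1e-6 (pure quantization) and the real backend to ~2^-16 at N = 512, so the
gate passes with margin; noise does not accumulate destructively because
gradient descent damps perturbations (asserted by injecting a one-off 2^-12
perturbation mid-training and checking the final model moves by less than
the gate).

## Synthetic data

The generator stands in for the clinical tables (187-16k samples, 9-16
features, binary outcome) that this package deliberately does not download.
Covariates are uniform on [-1, 1]^d; the reference coefficient vector
satisfies |beta_0| + ||beta_(1:)||_1 = 4, so every inner product is bounded
by 4 at the truth and stays inside [-8, 8] along the training trajectory
(verified on the benchmarks); labels are +1 with probability
sigma((1, x)^T beta_true).  What passing tests show: the encrypted circuit
reproduces plaintext training on data whose inner products respect the
surrogate interval.  What they do not show: behavior under covariates that
push inner products outside [-8, 8] (real data needs scaling, as in the
original protocol), collinearity, missingness, or class imbalance beyond
what the logistic draw induces.

## Benchmark sizes

Scheme unit tests run at N = 64..256.  The encrypted-vs-plaintext gate runs
the mock backend at n = 1024, d = 9, g7, 20 iterations, and the real backend
at n = 256, d = 9, g7, 10 iterations on N = 512 with log q = 1218 (the
optimized budget for that configuration) -- a reduced-ring surrogate for the
full clinical experiment, whose 80-bit-secure parameter set (N = 2^15,
log q ~ 2300) is constructible with `PRESETS["paper"]` but not exercised in
the test suite.  Five-fold cross-validation utilities mirror the published
evaluation protocol; accuracy uses score threshold 0 and AUC uses the
Mann-Whitney statistic with half-credit ties (the source names the metrics
but not these conventions).

## Known limitations

* No bootstrapping: iteration counts are capped by the fresh modulus.
* Fixed hyperparameters; no early stopping or convergence detection.
* Only power-of-two slot counts; labels must be binary.
* Parameter presets are conventional, not security-audited; no attack-cost
  estimator is included.
* Wall-clock performance is pure-Python big-integer arithmetic: minutes per
  reduced-scale training run, not competitive with native implementations.
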