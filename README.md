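# helogit

Logistic regression training on homomorphically encrypted data.

Medical institutions often cannot ship patient-level data to a cloud, yet
want cloud-scale model fitting.  `helogit` implements the secure-outsourcing
answer for the workhorse of clinical risk modelling: the data owner encrypts
the training samples once, an untrusted server runs full-batch gradient
descent for logistic regression *entirely on ciphertexts*, and the owner
decrypts only the fitted coefficients.  The server never holds a secret key
and never sees a plaintext sample, label, or intermediate statistic.

## What is inside

* **An approximate-arithmetic (CKKS-style) leveled HE scheme** over
  R_q = Z_q[X]/(X^N+1): canonical-embedding slot packing (N/2 reals per
  ciphertext), homomorphic add/multiply with relinearization, slot rotation
  via Galois automorphisms, and the rescaling operation
  RS(ct; r): m -> m/r, q -> q/r that emulates fixed-point rounding.  Exact
  big-integer coefficient arithmetic (Kronecker-substitution multiplication);
  no floating point in the ring.
* **Polynomial sigmoid surrogates.**  Taylor truncations T_d (exact rational
  coefficients) and the least-squares fits over [-8, 8] that make encrypted
  evaluation accurate where it matters:

      g3(x) = 1/2 + 1.20096 (x/8) - 0.81562 (x/8)^3
      g7(x) = 1/2 + 1.73517 (x/8) - 4.19572 (x/8)^3 + 5.43738 (x/8)^5 - 2.50936 (x/8)^7

* **The encrypted trainer.**  Samples fold into z_i = y_i (1, x_i); each
  attribute column is scaled by p = 2^28, packed into one ciphertext (d+1
  ciphertexts regardless of n), and the server iterates

      beta <- beta + (alpha/n) * sum_i g(-z_i^T beta) * z_i

  using SIMD slots for the batch, AllSum (log2 k rotate-and-adds) for the
  sample sum, and a depth-optimized factored evaluation of g that consumes
  3 log p + 3 (g3) or 4 log p + 3 (g7) modulus bits per iteration -- within
  the published optimized budget 3 (resp 4) log p + ceil(log(n/4 alpha)).
* **A plaintext reference trainer and metrics** (accuracy at threshold 0,
  Mann-Whitney AUC, MSE/NMSE between encrypted- and plaintext-trained
  coefficients, five-fold CV) plus a synthetic clinical-style data generator
  whose inner products provably stay inside the surrogate interval.
* **A mock backend** executing the identical circuit on plaintext slots with
  identical scale/modulus bookkeeping, for fast tests and for separating
  surrogate error from encryption noise.
* **A CLI** covering the whole pipeline with strict role separation.

## Worked example

```python
import numpy as np
from helogit import *
from helogit.backends import MockBackend

ds = generate_synthetic(1024, 9, seed=7)          # clinical-style, |z^T beta| <= 8
g7 = lsq_sigmoid_fit(7, 8.0)                      # degree-7 surrogate on [-8, 8]

per, total = modulus_budget(7, 28, 1024, 1.0, 20) # -> 120 bits/iter, 2438 total
params  = HEParams(ring_degree=2048, log_q=total, log_q0=38, log_p=28)
backend = MockBackend(params)                     # swap in EncryptedBackend(params, keygen(params, seed))

enc   = prepare_client_payload(ds.covariates, ds.labels, backend)
model = secure_train(enc, TrainConfig(1.0, 20, g7, 28), backend)
beta  = decrypt_model(model, backend)

beta_plain = plaintext_gd(ds, g7, 1.0, 20)        # same circuit, exact arithmetic
beta_sig   = plaintext_gd(ds, "sigmoid", 1.0, 20) # true-sigmoid reference
print(np.max(np.abs(beta - beta_plain.beta)))     # 3.52e-07  (= 2^-21.4)
print(param_mse_nmse(ModelParams(beta), beta_sig))# (0.000945, 0.005953)
print(predict_and_score(ds, ModelParams(beta)))   # accuracy 72.07 %, AUC 0.676
```

The decrypted model matches the plaintext trainer with the same surrogate to
3.5e-7 here (mock backend: pure quantization error); with the real encrypted
backend at the reduced benchmark (n = 256, 10 iterations, N = 512) the
agreement is ~2^-16.6, far below the 2^-11 working precision this method is
held to.  Training with the surrogate instead of the true sigmoid costs
about 0.2 accuracy points (72.07 % vs 72.27 %) and nothing in AUC --
the surrogate's precision loss does not move the decision plane.
Each of the 20 iterations consumed 115 modulus bits, under the optimized
budget figure of 120.

From the shell, against real ciphertexts:

    helogit keygen  --preset desk --seed 7 --out-dir keys/
    helogit encrypt-data --preset desk --data cohort.csv \
            --public-key keys/public.key --out-dir enc/
    helogit train   --preset desk --data-dir enc/ --public-key keys/public.key \
            --n 1024 --degree 3 --iterations 5 --out model.bin
    helogit decrypt-model --preset desk --model model.bin \
            --public-key keys/public.key --secret-key keys/secret.key --out beta.json
    helogit evaluate --data cohort.csv --model beta.json
    helogit budget --degree 3 --logp 28 --n 1024 --alpha 1   # 92 bits/iteration

`train` exits with an error if handed a secret-key blob: the server role
holds public material only.

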