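"""Encrypted training pipeline: packing, AllSum, budget accounting, and the
iteration circuit on the mock backend plus a tiny real-backend run."""

import numpy as np
import pytest

from helogit.backends import EncryptedBackend, MockBackend
from helogit.ckks import BudgetExhaustedError, CapacityError, HEParams, keygen
from helogit.baseline import Dataset, generate_synthetic, plaintext_gd
from helogit.ring import ParameterError
from helogit.securelr import (
    TrainConfig,
    allsum,
    decrypt_model,
    factor_odd_part,
    modulus_budget,
    prepare_client_payload,
    secure_train,
)
from helogit.sigmoid import lsq_sigmoid_fit


@pytest.fixture(scope="module")
def g3():
    return lsq_sigmoid_fit(3, 8.0)


@pytest.fixture(scope="module")
def g7():
    return lsq_sigmoid_fit(7, 8.0)


def mock_backend(n, iters, degree, log_p=28, alpha=1.0):
    per, total = modulus_budget(degree, log_p, max(n, 32), alpha, max(iters, 1))
    params = HEParams(ring_degree=2048, log_q=total, log_q0=log_p + 10, log_p=log_p)
    return MockBackend(params)


class CountingBackend(MockBackend):
    def __init__(self, params):
        super().__init__(params)
        self.rotations = 0

    def rotate(self, ct, shift):
        self.rotations += 1
        return super().rotate(ct, shift)


class TestPayload:
    def test_one_ciphertext_per_attribute(self, g3):
        b = mock_backend(32, 3, 3)
        ds = generate_synthetic(32, 9, seed=0)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        assert len(enc.ciphertexts) == 10          # d + 1

    def test_packing_scaling_example(self):
        # x = (0.5), y = -1, p = 2^28: z = (-1, -0.5), packed integers
        # (-268435456, -134217728) on the scaled grid
        b = mock_backend(32, 3, 3)
        enc = prepare_client_payload(np.array([[0.5]]), np.array([-1.0]), b)
        z0 = b.decrypt_vector(enc.ciphertexts[0])[0]
        z1 = b.decrypt_vector(enc.ciphertexts[1])[0]
        assert round(z0 * 2 ** 28) == -268435456
        assert round(z1 * 2 ** 28) == -134217728

    def test_pads_to_power_of_two(self):
        b = mock_backend(32, 3, 3)
        ds = generate_synthetic(21, 3, seed=1)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        assert enc.padded_slot_count == 32
        assert enc.sample_count == 21
        tail = b.decrypt_vector(enc.ciphertexts[0])[21:]
        assert np.all(tail == 0)

    def test_real_backend_round_trip(self, small_params, small_keys):
        ds = generate_synthetic(16, 2, seed=3)
        backend = EncryptedBackend(small_params, small_keys)
        enc = prepare_client_payload(ds.covariates, ds.labels, backend)
        Z = ds.z_matrix()
        for j, ct in enumerate(enc.ciphertexts):
            got = backend.decrypt_vector(ct)[:16]
            assert np.max(np.abs(got - Z[:, j])) < 2 ** -14

    def test_capacity_error(self, small_params, small_keys):
        backend = EncryptedBackend(small_params, small_keys)
        ds = generate_synthetic(33, 2, seed=3)      # needs 64 slots, have 32
        with pytest.raises(CapacityError):
            prepare_client_payload(ds.covariates, ds.labels, backend)

    def test_bad_labels_rejected(self):
        b = mock_backend(32, 3, 3)
        with pytest.raises(ParameterError):
            prepare_client_payload(np.ones((3, 1)), np.array([1.0, 2.0, -1.0]), b)


class TestAllSum:
    def test_identity_for_single_slot(self):
        b = mock_backend(32, 3, 3)
        ct = b.encrypt_vector([5.0], 1, 28)
        assert allsum(ct, 1, b).values == pytest.approx([5.0])

    def test_brute_force_sum(self):
        b = mock_backend(32, 3, 3)
        ct = b.encrypt_vector([1.0, 2.0, 3.0, 4.0], 4, 28)
        out = allsum(ct, 4, b)
        assert np.allclose(out.values, 10.0)

    def test_zero_padding_neutral(self):
        b = mock_backend(32, 3, 3)
        ct = b.encrypt_vector([1.0, 2.0, 3.0, 0.0], 4, 28)
        assert np.allclose(allsum(ct, 4, b).values, 6.0)

    def test_uses_exactly_log2_k_rotations(self):
        params = HEParams(ring_degree=2048, log_q=300, log_q0=38, log_p=28)
        b = CountingBackend(params)
        ct = b.encrypt_vector(np.arange(16.0), 16, 28)
        allsum(ct, 16, b)
        assert b.rotations == 4

    def test_non_power_of_two_rejected(self):
        b = mock_backend(32, 3, 3)
        ct = b.encrypt_vector([1.0, 2.0, 3.0], 4, 28)
        with pytest.raises(ParameterError):
            allsum(ct, 3, b)

    def test_real_backend_matches(self, small_params, small_keys):
        backend = EncryptedBackend(small_params, small_keys)
        v = np.arange(1.0, 9.0)
        ct = backend.encrypt_vector(v, 8, 28)
        out = backend.decrypt_vector(allsum(ct, 8, backend))
        assert np.max(np.abs(out - v.sum())) < 2 ** -10


class TestBudget:
    def test_printed_formula_examples(self):
        per, _ = modulus_budget(3, 28, 1024, 1.0, 1, optimized=True)
        assert per == 92                     # 3*28 + log2(1024/4)
        per, _ = modulus_budget(3, 28, 1024, 1.0, 1, optimized=False)
        assert per == 150                    # 28*(2+3) + 10

    def test_g7_formulas(self):
        per, _ = modulus_budget(7, 28, 1024, 1.0, 1, optimized=True)
        assert per == 4 * 28 + 8
        per, _ = modulus_budget(7, 28, 1024, 1.0, 1, optimized=False)
        assert per == 28 * 6 + 10

    def test_optimized_always_below_naive(self):
        for deg in (3, 7):
            for n in (64, 256, 1024, 16384):
                for alpha in (0.5, 1.0, 2.0):
                    o, _ = modulus_budget(deg, 28, n, alpha, 5, optimized=True)
                    nv, _ = modulus_budget(deg, 28, n, alpha, 5, optimized=False)
                    assert o < nv

    def test_total_includes_base_modulus(self):
        per, total = modulus_budget(3, 28, 256, 1.0, 7)
        assert total == 7 * per + 38

    def test_unsupported_degree(self):
        with pytest.raises(ParameterError):
            modulus_budget(5, 28, 256, 1.0, 1)


class TestFactoredSurrogate:
    def test_factorization_reconstructs_g3(self, g3):
        lead, y1, quartic = factor_odd_part(g3)
        assert quartic is None
        u = np.linspace(-1, 1, 101)
        c1, c3 = g3.odd_coefficients
        assert np.allclose(lead * u * (u ** 2 - y1), c1 * u + c3 * u ** 3, atol=1e-12)

    def test_factorization_reconstructs_g7(self, g7):
        lead, y1, (U, V) = factor_odd_part(g7)
        u = np.linspace(-1, 1, 101)
        c1, c3, c5, c7 = g7.odd_coefficients
        direct = c1 * u + c3 * u ** 3 + c5 * u ** 5 + c7 * u ** 7
        fact = lead * u * (u ** 2 - y1) * (u ** 4 + U * u ** 2 + V)
        assert np.allclose(fact, direct, atol=1e-10)


class TestTrainingMock:
    def test_zero_iterations_gives_zero_model(self, g3):
        b = mock_backend(32, 1, 3)
        ds = generate_synthetic(32, 3, seed=0)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        cfg = TrainConfig(1.0, 0, g3, 28)
        model = secure_train(enc, cfg, b)
        assert np.all(decrypt_model(model, b) == 0.0)

    def test_first_iteration_is_half_step(self, g3):
        # from beta=0 every inner product is 0 and g(0)=1/2, so the first
        # update is (alpha/2n) * sum_i z_i
        b = mock_backend(32, 2, 3)
        ds = generate_synthetic(32, 3, seed=5)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        model = secure_train(enc, TrainConfig(1.0, 1, g3, 28), b)
        want = ds.z_matrix().sum(axis=0) / (2 * 32)
        assert np.max(np.abs(decrypt_model(model, b) - want)) < 1e-6

    def test_toy_iteration_matches_hand_oracle(self, g3):
        # n=4, d=1: two iterations checked against the update formula
        # beta_j <- beta_j + (alpha/n) sum_i g(-z_i^T beta) z_ij computed by hand
        X = np.array([[0.5], [-0.25], [1.0], [-1.0]])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        b = mock_backend(32, 2, 3)
        enc = prepare_client_payload(X, y, b)
        model = secure_train(enc, TrainConfig(1.0, 2, g3, 28), b)
        got = decrypt_model(model, b)
        Z = np.column_stack([y, X[:, 0] * y])
        beta = np.zeros(2)
        for _ in range(2):
            beta = beta + (1.0 / 4) * (g3(-(Z @ beta)) @ Z)
        assert np.max(np.abs(got - beta)) < 2 ** -15

    @pytest.mark.parametrize("degree,iters", [(3, 25), (7, 20)])
    def test_matches_plaintext_trainer(self, degree, iters, g3, g7):
        g = g3 if degree == 3 else g7
        ds = generate_synthetic(256, 5, seed=13)
        b = mock_backend(256, iters, degree)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        model = secure_train(enc, TrainConfig(1.0, iters, g, 28), b)
        beta_plain = plaintext_gd(ds, g, 1.0, iters).beta
        assert np.max(np.abs(decrypt_model(model, b) - beta_plain)) < 2 ** -11

    def test_padding_neutrality(self, g3):
        # n=24 padded to 32 slots trains identically to the unpadded math
        ds = generate_synthetic(24, 3, seed=9)
        b = mock_backend(24, 5, 3)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        model = secure_train(enc, TrainConfig(1.0, 5, g3, 28), b)
        beta_plain = plaintext_gd(ds, g3, 1.0, 5).beta
        assert np.max(np.abs(decrypt_model(model, b) - beta_plain)) < 1e-6

    def test_budget_accounting_within_optimized_formula(self, g3, g7):
        for g, deg in ((g3, 3), (g7, 7)):
            b = mock_backend(256, 4, deg)
            ds = generate_synthetic(256, 3, seed=2)
            enc = prepare_client_payload(ds.covariates, ds.labels, b)
            model = secure_train(enc, TrainConfig(1.0, 4, g, 28), b)
            per, _ = modulus_budget(deg, 28, 256, 1.0, 4)
            assert model.bits_per_iteration
            assert max(model.bits_per_iteration) <= per

    def test_insufficient_budget_refused_upfront(self, g3):
        params = HEParams(ring_degree=2048, log_q=120, log_q0=38, log_p=28)
        b = MockBackend(params)
        ds = generate_synthetic(64, 3, seed=2)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        with pytest.raises(BudgetExhaustedError, match="no work was started"):
            secure_train(enc, TrainConfig(1.0, 10, g3, 28), b)

    def test_negative_feedback_damps_perturbation(self, g3):
        # a one-off 2^-12 perturbation of beta at iteration 5 moves the final
        # model by less than the end-to-end precision bound 2^-11
        ds = generate_synthetic(256, 5, seed=17)
        iters = 25
        b = mock_backend(256, iters, 3)
        enc = prepare_client_payload(ds.covariates, ds.labels, b)
        cfg = TrainConfig(1.0, iters, g3, 28)
        from helogit.securelr import EncryptedModel, secure_train_iteration, _fold_constant_lane
        zc = _fold_constant_lane(enc, cfg, b)
        runs = []
        for perturb in (False, True):
            model = EncryptedModel([b.zero_ct(enc.padded_slot_count, 28)
                                    for _ in range(6)], 0, b.params.log_q)
            for it in range(iters):
                model = secure_train_iteration(model, enc, cfg, b, zc=zc)
                if perturb and it == 4:
                    for ct in model.betas:
                        ct.values = ct.values + 2.0 ** -12
            runs.append(decrypt_model(model, b))
        assert np.max(np.abs(runs[1] - runs[0])) < 2 ** -11


class TestTrainingRealBackend:
    def test_tiny_real_run_matches_mock_and_plaintext(self, g3):
        # n=16, d=2, g3, 3 iterations on a small ring: the decrypted model
        # agrees with the mock backend and the plaintext trainer
        ds = generate_synthetic(16, 2, seed=4)
        iters = 3
        per, total = modulus_budget(3, 28, 32, 1.0, iters)
        total = 38 + iters * per
        params = HEParams(ring_degree=64, log_q=total, log_q0=38, log_p=28)
        keys = keygen(params, 77)
        real = EncryptedBackend(params, keys)
        mock = MockBackend(params)
        cfg = TrainConfig(1.0, iters, g3, 28)
        beta_real = decrypt_model(secure_train(
            prepare_client_payload(ds.covariates, ds.labels, real), cfg, real), real)
        beta_mock = decrypt_model(secure_train(
            prepare_client_payload(ds.covariates, ds.labels, mock), cfg, mock), mock)
        beta_plain = plaintext_gd(ds, g3, 1.0, iters).beta
        assert np.max(np.abs(beta_real - beta_mock)) < 2 ** -12
        assert np.max(np.abs(beta_real - beta_plain)) < 2 ** -12
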