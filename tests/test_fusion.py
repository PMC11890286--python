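"""Attention integration: closed-form cases, brute-force oracle equivalence,
masking semantics, permutation covariance."""

import numpy as np
import pytest

import ncfuse as nf
from ncfuse.fusion import (AttentionFusion, AttentionProjection, FusionParams,
                           ProjectionParams, QKVParams)
from ncfuse.nn.tensor import Tensor


def brute_force_integrate(encoded, mask, params):
    """Straight-line reimplementation of the integration equations, written
    independently of the package's composition (explicit loops throughout)."""
    M = len(encoded)
    D = params.projection.D
    X = np.zeros((D, M))
    for m in range(M):
        X[:, m] = params.projection.weights[m] @ np.asarray(encoded[m]) \
            + params.projection.biases[m]
    q, k, v = params.qkv, params.qkv, params.qkv
    Q = np.zeros((D, M)); K = np.zeros((D, M)); V = np.zeros((D, M))
    for m in range(M):
        Q[:, m] = q.wq @ X[:, m] + q.bq
        K[:, m] = q.wk @ X[:, m] + q.bk
        V[:, m] = q.wv @ X[:, m] + q.bv
    C = np.zeros((M, M))
    for n in range(M):
        for m in range(M):
            C[n, m] = float(np.dot(Q[:, m], K[:, n])) / np.sqrt(D)
    s = np.zeros(M)
    for m in range(M):
        s[m] = sum(params.attention.wa.reshape(-1)[n] * C[n, m]
                   for n in range(M)) + params.attention.ba
    if mask is None:
        mask = np.ones(M, dtype=bool)
    exp = np.array([np.exp(s[m] - max(s[mask])) if mask[m] else 0.0
                    for m in range(M)])
    A = exp / exp.sum()
    fused = np.zeros(M * D)
    for m in range(M):
        if mask[m]:
            fused[m * D:(m + 1) * D] = A[m] * V[:, m]
    return A, C, fused


class TestProjection:
    def test_identity_projection(self):
        params = ProjectionParams(weights=[np.eye(2)] * 2,
                                  biases=[np.zeros(2)] * 2)
        out = nf.project_modalities([np.array([1.0, 2.0]),
                                     np.array([3.0, 4.0])], params)
        assert np.allclose(out, [[1, 3], [2, 4]])

    def test_zero_input_gives_bias(self):
        b = np.array([0.5, -0.5])
        params = ProjectionParams(weights=[np.eye(2)], biases=[b])
        out = nf.project_modalities([np.zeros(2)], params)
        assert np.allclose(out[:, 0], b)

    def test_dimension_mismatch_names_modality(self):
        params = ProjectionParams(weights=[np.eye(2), np.eye(2)],
                                  biases=[np.zeros(2)] * 2)
        with pytest.raises(ValueError, match="modality 1"):
            nf.project_modalities([np.zeros(2), np.zeros(3)], params)


class TestInteractionMatrix:
    def test_orthonormal_columns_give_scaled_identity(self):
        Q = np.eye(4)[:, :3]                       # orthonormal columns, D=4
        C = nf.interaction_matrix(Q, Q)
        assert np.allclose(C, np.eye(3) / 2.0)     # 1/sqrt(4) on the diagonal

    def test_single_modality(self):
        Q = np.array([[1.0], [2.0]])
        K = np.array([[3.0], [4.0]])
        C = nf.interaction_matrix(Q, K)
        assert C.shape == (1, 1)
        assert np.isclose(C[0, 0], (1 * 3 + 2 * 4) / np.sqrt(2))

    def test_matches_double_loop(self, rng):
        Q, K = rng.normal(size=(2, 5, 3))
        C = nf.interaction_matrix(Q, K)
        for n in range(3):
            for m in range(3):
                assert np.isclose(C[n, m], Q[:, m] @ K[:, n] / np.sqrt(5),
                                  atol=1e-9)


class TestAttentionCoefficients:
    def test_equal_scores_full_mask(self):
        proj = AttentionProjection(wa=np.zeros((1, 3)), ba=1.0)
        A = nf.attention_coefficients(np.zeros((3, 3)), proj)
        assert np.allclose(A, 1 / 3)

    def test_equal_scores_renormalise_over_present(self):
        proj = AttentionProjection(wa=np.zeros((1, 3)), ba=1.0)
        A = nf.attention_coefficients(np.zeros((3, 3)), proj,
                                      mask=np.array([True, True, False]))
        assert np.allclose(A, [0.5, 0.5, 0.0])
        assert A[2] == 0.0                         # exact zero, not tiny

    def test_all_masked_rejected(self):
        proj = AttentionProjection(wa=np.zeros((1, 2)), ba=0.0)
        with pytest.raises(ValueError, match="no modality present"):
            nf.attention_coefficients(np.zeros((2, 2)), proj,
                                      mask=np.zeros(2, dtype=bool))

    def test_matches_hand_softmax(self, rng):
        C = rng.normal(size=(4, 4))
        wa = rng.normal(size=(1, 4))
        ba = float(rng.normal())
        A = nf.attention_coefficients(C, AttentionProjection(wa=wa, ba=ba))
        s = (wa @ C).reshape(-1) + ba
        e = np.exp(s - s.max())
        assert np.allclose(A, e / e.sum(), atol=1e-7)


class TestFuse:
    def test_one_hot_selection(self, rng):
        V = rng.normal(size=(3, 3))
        fused = nf.fuse(V, np.array([0.0, 1.0, 0.0]))
        assert np.allclose(fused[:3], 0)
        assert np.allclose(fused[3:6], V[:, 1])
        assert np.allclose(fused[6:], 0)

    def test_uniform_ones_closed_form(self):
        fused = nf.fuse(np.ones((2, 3)), np.full(3, 1 / 3))
        assert np.allclose(fused, np.full(6, 1 / 3))

    def test_matches_concatenation_loop(self, rng):
        V = rng.normal(size=(4, 3))
        A = rng.dirichlet(np.ones(3))
        fused = nf.fuse(V, A)
        expected = np.concatenate([A[m] * V[:, m] for m in range(3)])
        assert np.allclose(fused, expected)


class TestIntegrate:
    def test_identity_single_modality(self):
        D = 3
        params = FusionParams(
            projection=ProjectionParams(weights=[np.eye(D)],
                                        biases=[np.zeros(D)]),
            qkv=QKVParams(wq=np.eye(D), bq=np.zeros(D), wk=np.eye(D),
                          bk=np.zeros(D), wv=np.eye(D), bv=np.zeros(D)),
            attention=AttentionProjection(wa=np.ones((1, 1)), ba=0.0))
        x = np.array([1.0, -2.0, 0.5])
        res = nf.integrate([x], None, params)
        assert np.allclose(res.A, [1.0])
        assert np.allclose(res.fused, x)

    def test_masked_modality_zeroed_in_A_and_fused(self, rng):
        dims = [4, 5, 3]
        params = nf.random_fusion_params(dims, D=6, rng=rng)
        mask = np.array([True, False, True])
        enc = [rng.normal(size=dims[0]), np.zeros(dims[1]),  # zero placeholder
               rng.normal(size=dims[2])]
        res = nf.integrate(enc, mask, params)
        assert res.A[1] == 0.0
        assert np.allclose(res.fused[6:12], 0.0)
        assert np.isclose(res.A.sum(), 1.0, atol=1e-6)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            M = int(rng.integers(1, 5))
            D = int(rng.integers(2, 9))
            dims = [int(d) for d in rng.integers(2, 9, size=M)]
            params = nf.random_fusion_params(dims, D, rng)
            mask = rng.random(M) < 0.8
            if not mask.any():
                mask[rng.integers(0, M)] = True
            enc = [rng.normal(size=d) for d in dims]
            res = nf.integrate(enc, mask, params)
            A, C, fused = brute_force_integrate(enc, mask, params)
            assert np.allclose(res.A, A, atol=1e-6)
            assert np.allclose(res.C, C, atol=1e-6)
            assert np.allclose(res.fused, fused, atol=1e-6)
            assert np.isclose(res.A.sum(), 1.0, atol=1e-6)

    def test_modality_permutation_covariance(self, rng):
        dims = [3, 4, 5]
        D = 6
        params = nf.random_fusion_params(dims, D, rng)
        enc = [rng.normal(size=d) for d in dims]
        res = nf.integrate(enc, None, params)
        perm = [2, 0, 1]
        params_p = FusionParams(
            projection=ProjectionParams(
                weights=[params.projection.weights[p] for p in perm],
                biases=[params.projection.biases[p] for p in perm]),
            qkv=params.qkv,
            attention=AttentionProjection(
                wa=params.attention.wa[:, perm], ba=params.attention.ba))
        res_p = nf.integrate([enc[p] for p in perm], None, params_p)
        assert np.allclose(res_p.A, res.A[perm], atol=1e-9)
        blocks = res.fused.reshape(3, D)
        assert np.allclose(res_p.fused.reshape(3, D), blocks[perm], atol=1e-9)


class TestFusionLayer:
    def test_layer_matches_functional_api(self, rng):
        dims = [6, 4, 5]
        layer = AttentionFusion(dims, D=8, rng=np.random.default_rng(5))
        params = layer.export_params()
        enc = [rng.normal(size=(7, d)).astype(np.float32) for d in dims]
        mask = rng.random((7, 3)) < 0.7
        mask[~mask.any(axis=1), 0] = True
        fused, A, C = layer.forward([Tensor(e) for e in enc], mask)
        for i in range(7):
            ref = nf.integrate([e[i] for e in enc], mask[i], params)
            assert np.allclose(A.data[i], ref.A, atol=1e-5)
            assert np.allclose(C.data[i], ref.C, atol=1e-4)
            assert np.allclose(fused.data[i], ref.fused, atol=1e-4)

    def test_masked_coefficients_exactly_zero_and_normalised(self, rng):
        layer = AttentionFusion([4, 4, 4], D=8, rng=np.random.default_rng(5))
        enc = [Tensor(rng.normal(size=(10, 4))) for _ in range(3)]
        mask = np.ones((10, 3), dtype=bool)
        mask[:5, 2] = False
        _, A, _ = layer.forward(enc, mask)
        assert (A.data[:5, 2] == 0.0).all()
        assert np.allclose(A.data.sum(axis=1), 1.0, atol=1e-6)
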