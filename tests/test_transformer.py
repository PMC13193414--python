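"""Architecture resolution, eigen initialization contract, forward pass."""

import numpy as np
import pytest

from eigenformer.eigen import correlation_matrix, eigendecompose
from eigenformer.transformer import (
    ModelPlan,
    ParameterSet,
    eigen_initialize,
    estimate_flops,
    flops_formula,
    forward,
    glorot_initialize,
    resolve_dimensions,
)


def toy_spectrum(rng, d=6):
    X = rng.normal(size=(200, d)) @ rng.normal(size=(d, d))
    return eigendecompose(correlation_matrix(X))


def contract_plan(d, h, d_k, gamma=0.5, blocks=1, dropout=0.0):
    return ModelPlan(
        d=d, h=h, d_k=d_k, d_ff=16, blocks=blocks, dropout=dropout,
        gamma=gamma, positional_encoding="none", pooling="last",
    )


class TestResolveDimensions:
    @pytest.mark.parametrize(
        "h, hidden, expected",
        [(11, 40, (4, 44)), (8, 64, (8, 64)), (1, 5, (5, 5))],
    )
    def test_rounding_rule(self, h, hidden, expected):
        assert resolve_dimensions(3, h, hidden) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            resolve_dimensions(3, 0, 10)
        with pytest.raises(ValueError):
            resolve_dimensions(3, 8, 4)


class TestEigenInitialization:
    def test_qkv_tied_exactly(self, rng):
        spec = toy_spectrum(rng)
        plan = contract_plan(6, 3, 4, blocks=2)
        params = eigen_initialize(spec, plan, rng)
        for b in range(2):
            assert np.array_equal(params[f"blk{b}.Wq"].data, params[f"blk{b}.Wk"].data)
            assert np.array_equal(params[f"blk{b}.Wq"].data, params[f"blk{b}.Wv"].data)

    @pytest.mark.parametrize("gamma", [0.5, 1.0])
    def test_head_logit_contract(self, rng, gamma):
        """Pre-softmax score of head i between steps t and s must equal
        sqrt(d_k) * lambda_i^(-2 gamma) * <x_t, v_i><x_s, v_i>."""
        spec = toy_spectrum(rng)
        plan = contract_plan(6, 3, 4, gamma=gamma)
        params = eigen_initialize(spec, plan, rng)
        X = rng.normal(size=(100, 5, 6))
        _, attention = forward(X, params, plan, collect_attention=True)
        scores = attention[0]["scores"]  # (100, h, L, L)
        for i in range(plan.h):
            p = X @ spec.eigenvectors[:, i]  # (100, L) PC scores
            expected = np.sqrt(plan.d_k) * spec.eigenvalues[i] ** (-2 * gamma) * (
                p[:, :, None] * p[:, None, :]
            )
            assert np.abs(scores[:, i] - expected).max() < 1e-8

    def test_2x2_closed_form_logit(self, rng):
        spec = eigendecompose(np.array([[1.0, 0.6], [0.6, 1.0]]))
        plan = contract_plan(2, 2, 1, gamma=0.5)
        params = eigen_initialize(spec, plan, rng)
        x = np.ones((1, 2, 2))  # x_t = x_s = (1, 1)
        _, attention = forward(x, params, plan, collect_attention=True)
        # <(1,1), v_1> = sqrt(2); logit = sqrt(1) * 2 / 1.6 = 1.25
        assert attention[0]["scores"][0, 0, 0, 0] == pytest.approx(1.25, abs=1e-12)

    def test_unit_spectrum_scaling_is_identity(self, rng):
        spec = eigendecompose(np.eye(4))
        plan = contract_plan(4, 2, 3, gamma=1.0)
        params = eigen_initialize(spec, plan, rng)
        X = rng.normal(size=(10, 3, 4))
        _, attention = forward(X, params, plan, collect_attention=True)
        for i in range(2):
            p = X @ spec.eigenvectors[:, i]
            expected = np.sqrt(3) * p[:, :, None] * p[:, None, :]
            assert np.abs(attention[0]["scores"][:, i] - expected).max() < 1e-8

    def test_zero_input_gives_uniform_attention(self, rng):
        spec = toy_spectrum(rng)
        plan = contract_plan(6, 3, 4)
        params = eigen_initialize(spec, plan, rng)
        _, attention = forward(np.zeros((2, 5, 6)), params, plan, collect_attention=True)
        assert np.allclose(attention[0]["weights"], 1 / 5, atol=1e-12)

    def test_degenerate_eigenvalue_rejected(self, rng):
        x = rng.normal(size=30)
        spec = eigendecompose(correlation_matrix(np.column_stack([x, x + 1e-13 * rng.normal(size=30)])))
        plan = contract_plan(2, 2, 2)
        with pytest.raises(ValueError, match="eigenvalue"):
            eigen_initialize(spec, plan, rng)

    def test_head_cycling_beyond_d(self, rng):
        spec = toy_spectrum(rng, d=3)
        plan = contract_plan(3, 5, 2)
        params = eigen_initialize(spec, plan, rng)  # h > d: eigenvectors cycle
        W_in = params["W_in"].data
        assert np.allclose(W_in[0], spec.eigenvectors[:, 0])
        assert np.allclose(W_in[3], spec.eigenvectors[:, 0])  # (3 mod 5) mod 3


class TestForward:
    def test_singleton_softmax_and_eval_determinism(self, rng):
        plan = contract_plan(4, 2, 3, dropout=0.2)
        params = glorot_initialize(plan, rng)
        x = rng.normal(size=(3, 1, 4))
        y1, attention = forward(x, params, plan, collect_attention=True)
        assert np.allclose(attention[0]["weights"], 1.0)
        y2 = forward(x, params, plan)
        assert np.array_equal(y1.data, y2.data)

    def test_attention_rows_are_stochastic_in_every_block_and_head(self, rng):
        plan = contract_plan(5, 3, 4, blocks=3)
        params = glorot_initialize(plan, rng)
        _, attention = forward(rng.normal(size=(4, 6, 5)), params, plan, collect_attention=True)
        assert len(attention) == 3
        for blk in attention:
            assert np.abs(blk["weights"].sum(axis=-1) - 1.0).max() < 1e-6

    def test_forward_pass_matches_independent_reimplementation(self, rng):
        """L=2, d=2, h=1 toy vs a step-by-step reference written directly
        from the block equations (attention, post-norm LN, ReLU FFN)."""
        plan = ModelPlan(d=2, h=1, d_k=2, d_ff=3, blocks=1, dropout=0.0,
                         gamma=0.5, positional_encoding="none", pooling="last")
        params = glorot_initialize(plan, rng)
        for _, t in params.items():
            t.data = rng.normal(scale=0.3, size=t.data.shape)
        x = rng.normal(size=(2, 2))

        def layernorm_ref(v, g, b):
            mu, var = v.mean(), v.var()
            return (v - mu) / np.sqrt(var + 1e-5) * g + b

        # reference forward, one sample, plain loops
        W_in, b_in = params["W_in"].data, params["b_in"].data
        z = x @ W_in.T + b_in  # (2, d_model)
        Wq, Wk, Wv = (params[f"blk0.{n}"].data[0] for n in ("Wq", "Wk", "Wv"))
        q, k, v = z @ Wq, z @ Wk, z @ Wv
        scores = q @ k.T / np.sqrt(plan.d_k)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = w / w.sum(axis=1, keepdims=True)
        mh = (w @ v) @ params["blk0.Wo"].data
        z1 = np.vstack([
            layernorm_ref(z[i] + mh[i], params["blk0.ln1_g"].data, params["blk0.ln1_b"].data)
            for i in range(2)
        ])
        ff = np.maximum(z1 @ params["blk0.W1"].data + params["blk0.b1"].data, 0.0)
        ff = ff @ params["blk0.W2"].data + params["blk0.b2"].data
        z2 = np.vstack([
            layernorm_ref(z1[i] + ff[i], params["blk0.ln2_g"].data, params["blk0.ln2_b"].data)
            for i in range(2)
        ])
        expected = float(z2[-1] @ params["W_out"].data[0] + params["b_out"].data[0])

        got = float(forward(x, params, plan).data[0])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_output_affine_in_head_weights(self, rng):
        plan = contract_plan(4, 2, 3)
        params = glorot_initialize(plan, rng)
        x = rng.normal(size=(5, 4, 4))
        W1 = rng.normal(size=params["W_out"].data.shape)
        W2 = rng.normal(size=params["W_out"].data.shape)
        params["b_out"].data[...] = 0.0

        def y_with(W):
            params["W_out"].data[...] = W
            return forward(x, params, plan).data

        lhs = y_with(0.3 * W1 + 0.7 * W2)
        rhs = 0.3 * y_with(W1) + 0.7 * y_with(W2)
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_dropout_only_in_train_mode(self, rng):
        plan = contract_plan(4, 2, 3, dropout=0.5)
        params = glorot_initialize(plan, rng)
        x = rng.normal(size=(3, 4, 4))
        eval_out = forward(x, params, plan).data
        train_out = forward(x, params, plan, train_mode=True,
                            rng=np.random.default_rng(0)).data
        assert not np.allclose(eval_out, train_out)

    def test_empty_sequence_rejected(self, rng):
        plan = contract_plan(4, 2, 3)
        params = glorot_initialize(plan, rng)
        with pytest.raises(ValueError):
            forward(np.zeros((2, 0, 4)), params, plan)


class TestFlops:
    def test_quadratic_in_length(self):
        plan = ModelPlan(d=8, h=4, d_k=10, d_ff=80, blocks=2)
        assert estimate_flops(plan, 14) > 2 * estimate_flops(plan, 7)

    def test_zero_block_hand_expansion(self):
        L, d, dm, dff = 7, 8, 40, 80
        assert flops_formula(L, d, dm, dff, 0) == 2 * L * dm * d + 2 * L * dm

    def test_dff_term_isolation(self):
        base = dict(L=7, d=8, d_model=40, blocks=3)
        delta = flops_formula(d_ff=100, **base) - flops_formula(d_ff=60, **base)
        assert delta == 4 * 7 * 40 * 40 * 3

    def test_exact_reproducibility(self):
        plan = ModelPlan(d=8, h=11, d_k=4, d_ff=88, blocks=2)
        assert estimate_flops(plan, 7) == estimate_flops(plan, 7)
        assert isinstance(estimate_flops(plan, 7), int)


class TestCheckpoint:
    def test_save_load_roundtrip(self, rng, tmp_path):
        plan = contract_plan(4, 2, 3, blocks=2)
        params = glorot_initialize(plan, rng)
        path = tmp_path / "model.npz"
        params.save(path)
        loaded = ParameterSet.load(path)
        assert loaded.plan == plan
        for k, t in params.items():
            assert np.array_equal(loaded[k].data, t.data)
        x = rng.normal(size=(2, 3, 4))
        assert np.array_equal(forward(x, params, plan).data, forward(x, loaded, plan).data)
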