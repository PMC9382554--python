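"""Ordered-neuron LSTM: cumax contract, gate monotonicity, LSTM limit.

The plain-LSTM oracle below is written independently of the package (no
shared code beyond numpy) so the pinned-master-gate equivalence is a real
dual-route check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segcn.autodiff import Tensor
from segcn.encoder import EncoderParams, cumax, encode, onlstm_cell

RNG = np.random.default_rng(202)


# ------------------------------------------------------------------- cumax


class TestCumax:
    def test_uniform_logits_give_linear_ramp(self):
        np.testing.assert_allclose(cumax(np.zeros(3)).data, [1 / 3, 2 / 3, 1.0])

    def test_singleton_is_one(self):
        np.testing.assert_allclose(cumax(np.array([17.3])).data, [1.0])

    def test_matches_hand_computed_two_point_case(self):
        # softmax(5, -5) = (e^10/(e^10+1), 1/(e^10+1)) then cumulative sum
        p = np.exp(10) / (np.exp(10) + 1)
        np.testing.assert_allclose(cumax(np.array([5.0, -5.0])).data, [p, 1.0], atol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=64))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_monotone_in_unit_interval_ending_at_one(self, logits):
        out = cumax(np.array(logits)).data
        assert np.all(np.diff(out) >= -1e-12)
        assert np.all(out > 0) and np.all(out <= 1 + 1e-9)
        assert out[-1] == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            cumax(np.array([1.0, np.nan]))


# ----------------------------------------------------- independent LSTM oracle


def plain_lstm_reference(X, w):
    """Textbook LSTM forward, straight numpy: f,i,o = sigmoid, candidate =
    tanh, c = f*c_prev + i*cand, h = o*tanh(c)."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    d = w["U_f"].shape[0]
    h = np.zeros(d)
    c = np.zeros(d)
    out = []
    for x in X:
        f = sig(x @ w["W_f"] + h @ w["U_f"] + w["b_f"])
        i = sig(x @ w["W_i"] + h @ w["U_i"] + w["b_i"])
        o = sig(x @ w["W_o"] + h @ w["U_o"] + w["b_o"])
        cand = np.tanh(x @ w["W_c"] + h @ w["U_c"] + w["b_c"])
        c = f * c + i * cand
        h = o * np.tanh(c)
        out.append(h)
    return np.array(out)


def random_params(e, d, chunk, seed):
    return EncoderParams.init(e, d, chunk, np.random.default_rng(seed))


class TestLstmLimit:
    def test_pinned_master_gates_match_reference_lstm(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            e = int(rng.integers(2, 9))
            d = int(rng.choice([4, 8, 16, 32]))
            n = int(rng.integers(1, 11))
            params = random_params(e, d, min(4, d), seed=trial)
            X = rng.normal(size=(n, e))
            state = encode(X, params, pin_master_gates=True)
            ref = plain_lstm_reference(X, {k: t.data for k, t in params.weights.items()})
            np.testing.assert_allclose(state.h.data, ref, atol=1e-6)

    def test_zero_everything_gives_zero_state(self):
        params = random_params(3, 4, 2, seed=0)
        for k in params.weights:
            params.weights[k].data[:] = 0.0
        h, c, *_ = onlstm_cell(Tensor(np.zeros(3)), Tensor(np.zeros(4)), Tensor(np.zeros(4)), params)
        np.testing.assert_array_equal(c.data, 0.0)
        np.testing.assert_array_equal(h.data, 0.0)


# ------------------------------------------------------- master-gate contract


class TestMasterGates:
    def test_monotone_and_bounded_over_random_draws(self):
        rng = np.random.default_rng(5)
        for trial in range(200):
            params = random_params(4, 12, 3, seed=1000 + trial)
            h, c, mf, mi, om = onlstm_cell(
                Tensor(rng.normal(size=4)),
                Tensor(rng.normal(size=12) * 0.1),
                Tensor(rng.normal(size=12) * 0.1),
                params,
            )
            assert np.all(np.diff(mf.data) >= -1e-12)  # forget gate rises 0 -> 1
            assert np.all(np.diff(mi.data) <= 1e-12)  # input gate falls 1 -> 0
            assert np.all((mf.data >= 0) & (mf.data <= 1))
            assert np.all((mi.data >= 0) & (mi.data <= 1))
            np.testing.assert_allclose(om.data, mf.data * mi.data)

    def test_gates_constant_within_chunks(self):
        params = random_params(3, 12, 4, seed=2)
        _, _, mf, _, _ = onlstm_cell(
            Tensor(RNG.normal(size=3)), Tensor(np.zeros(12)), Tensor(np.zeros(12)), params
        )
        for chunk in mf.data.reshape(3, 4):
            assert np.ptp(chunk) == 0.0


# ----------------------------------------------------------------- encode


class TestEncode:
    def test_single_token_equals_single_cell_call(self):
        params = random_params(3, 8, 4, seed=3)
        x = RNG.normal(size=(1, 3))
        state = encode(x, params)
        h, c, *_ = onlstm_cell(Tensor(x[0]), Tensor(np.zeros(8)), Tensor(np.zeros(8)), params)
        np.testing.assert_allclose(state.h.data[0], h.data)

    def test_token_order_matters(self):
        params = random_params(3, 8, 4, seed=4)
        X = RNG.normal(size=(5, 3))
        fwd = encode(X, params).h.data
        perm = encode(X[::-1].copy(), params).h.data
        assert not np.allclose(fwd, perm[::-1])

    def test_output_width_uni_and_bidirectional(self):
        p_f = random_params(3, 8, 4, seed=5)
        p_b = random_params(3, 8, 4, seed=6)
        X = RNG.normal(size=(4, 3))
        assert encode(X, p_f).h.shape == (4, 8)
        state = encode(X, p_f, params_backward=p_b)
        assert state.h.shape == (4, 16)
        assert state.master_forget.shape == (4, 16)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode(np.zeros((0, 3)), random_params(3, 8, 4, seed=7))

    def test_gate_records_satisfy_state_invariants(self):
        params = random_params(4, 12, 3, seed=8)
        X = RNG.normal(size=(6, 4))
        state = encode(X, params)
        assert np.all((state.master_forget >= 0) & (state.master_forget <= 1))
        np.testing.assert_allclose(state.overlap, state.master_forget * state.master_input)


def test_encoder_gradients_match_finite_differences():
    """Analytic gradients of a scalar loss through the full recurrence."""
    params = random_params(4, 8, 4, seed=9)
    X = RNG.normal(size=(4, 4))

    def loss_value():
        return float((encode(X, params).h ** 2).sum().data)

    loss = (encode(X, params).h ** 2).sum()
    loss.backward()
    eps = 1e-5
    for name, p in params.weights.items():
        num = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = p.data[ix]
            p.data[ix] = orig + eps
            hi = loss_value()
            p.data[ix] = orig - eps
            lo = loss_value()
            p.data[ix] = orig
            num[ix] = (hi - lo) / (2 * eps)
        denom = np.linalg.norm(p.grad) + np.linalg.norm(num) + 1e-6
        assert np.linalg.norm(p.grad - num) / denom < 1e-4, name
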