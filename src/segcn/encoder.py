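"""Ordered-neuron LSTM encoder.

The encoder is a standard LSTM augmented with two *master* gates that order
the cell neurons hierarchically.  A cumulative softmax (``cumax``) over a
per-chunk projection yields the master forget gate f̃_t, whose entries rise
monotonically from 0 to 1 along the neuron axis; the master input gate
ĩ_t = 1 − cumax(·) falls from 1 to 0.  Their overlap ω_t = f̃_t ⊙ ĩ_t marks
the neuron segment where old and new information mix; below it the cell
copies history, above it the cell takes the fresh candidate:

    C_t = ω_t ⊙ (f_t ⊙ c_{t-1} + i_t ⊙ ĉ_t) + (f̃_t − ω_t) ⊙ c_{t-1}
                                             + (ĩ_t − ω_t) ⊙ ĉ_t

High-order neurons therefore persist across many steps and capture
phrase-level (shallow syntactic) structure without any parse as input.
Master gates are predicted at chunk granularity (`hidden / chunk_size`
logits, broadcast within chunks) so the cumulative softmax stays sharp at
realistic hidden sizes; pinning both master gates to 1 collapses the cell
to a plain LSTM, which is the oracle used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, softmax


def cumax(logits, axis: int = -1) -> Tensor:
    """Cumulative sum of a softmax: monotone non-decreasing, ends at 1."""
    t = as_tensor(logits)
    if not np.all(np.isfinite(t.data)):
        raise ValueError("cumax requires finite logits")
    return softmax(t, axis=axis).cumsum(axis=axis)


@dataclass
class EncoderParams:
    """Gate parameters: W_x/U_x/b_x for x in {f, i, o, c} plus the two
    master-gate projections mapping (input, hidden) -> n_chunks logits."""

    weights: dict[str, Tensor]
    input_dim: int
    hidden: int
    chunk: int

    @property
    def n_chunks(self) -> int:
        return self.hidden // self.chunk

    @staticmethod
    def init(input_dim: int, hidden: int, chunk: int, rng: np.random.Generator) -> "EncoderParams":
        if hidden % chunk != 0:
            raise ValueError(f"chunk size {chunk} must divide hidden size {hidden}")
        n_chunks = hidden // chunk
        # Glorot-uniform scales keep activation variance stable through depth
        s_in = np.sqrt(6.0 / (input_dim + hidden))
        s_h = np.sqrt(6.0 / (hidden + hidden))
        w: dict[str, Tensor] = {}
        for gate in "fioc":
            w[f"W_{gate}"] = Tensor(rng.uniform(-s_in, s_in, (input_dim, hidden)), requires_grad=True)
            w[f"U_{gate}"] = Tensor(rng.uniform(-s_h, s_h, (hidden, hidden)), requires_grad=True)
            w[f"b_{gate}"] = Tensor(np.zeros(hidden), requires_grad=True)
        # forget bias starts positive so early training keeps memory
        w["b_f"].data += 1.0
        for master in ("mf", "mi"):
            w[f"W_{master}"] = Tensor(rng.uniform(-s_in, s_in, (input_dim, n_chunks)), requires_grad=True)
            w[f"U_{master}"] = Tensor(rng.uniform(-s_h, s_h, (hidden, n_chunks)), requires_grad=True)
            w[f"b_{master}"] = Tensor(np.zeros(n_chunks), requires_grad=True)
        return EncoderParams(w, input_dim, hidden, chunk)

    def parameters(self) -> list[Tensor]:
        return list(self.weights.values())


@dataclass
class EncoderState:
    """Encoder output: hidden states plus per-step master-gate activations
    (broadcast to full width) for introspection/diagnostics."""

    h: Tensor  # n x d (or n x 2d bidirectional)
    cells: list[Tensor]
    master_forget: np.ndarray  # n x d, in [0,1], non-decreasing along axis 1
    master_input: np.ndarray  # n x d, in [0,1], non-increasing along axis 1
    overlap: np.ndarray  # elementwise product of the two


def onlstm_cell(
    x: Tensor,
    h_prev: Tensor,
    c_prev: Tensor,
    params: EncoderParams,
    pin_master_gates: bool = False,
) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
    """One recurrence step; returns (h_t, c_t, f̃_t, ĩ_t, ω_t).

    With ``pin_master_gates`` both master gates are forced to 1 (so ω = 1
    and the update degenerates to the plain-LSTM cell update).
    """
    w = params.weights
    pre = {g: x @ w[f"W_{g}"] + h_prev @ w[f"U_{g}"] + w[f"b_{g}"] for g in "fioc"}
    f = pre["f"].sigmoid()
    i = pre["i"].sigmoid()
    o = pre["o"].sigmoid()
    c_hat = pre["c"].tanh()

    if pin_master_gates:
        ones = Tensor(np.ones(params.hidden))
        f_master, i_master = ones, ones
    else:
        broadcast = np.repeat(np.arange(params.n_chunks), params.chunk)
        pf = x @ w["W_mf"] + h_prev @ w["U_mf"] + w["b_mf"]
        pi = x @ w["W_mi"] + h_prev @ w["U_mi"] + w["b_mi"]
        # relu clamps 1-ulp float spill outside [0, 1] from the cumulative sum
        f_master = (1.0 - (1.0 - cumax(pf)).relu()).take(broadcast, axis=0)
        i_master = (1.0 - cumax(pi)).relu().take(broadcast, axis=0)
    omega = f_master * i_master
    c_t = omega * (f * c_prev + i * c_hat) + (f_master - omega) * c_prev + (i_master - omega) * c_hat
    h_t = o * c_t.tanh()
    return h_t, c_t, f_master, i_master, omega


def _encode_direction(
    X: Tensor, params: EncoderParams, pin_master_gates: bool
) -> tuple[list[Tensor], list[Tensor], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    n = X.shape[0]
    h = Tensor(np.zeros(params.hidden))
    c = Tensor(np.zeros(params.hidden))  # c_0 is a zero-filled vector
    hs, cs, mfs, mis, oms = [], [], [], [], []
    for t in range(n):
        h, c, mf, mi, om = onlstm_cell(X[t], h, c, params, pin_master_gates)
        hs.append(h)
        cs.append(c)
        mfs.append(mf.data)
        mis.append(mi.data)
        oms.append(om.data)
    return hs, cs, mfs, mis, oms


def encode(
    X,
    params: EncoderParams,
    params_backward: EncoderParams | None = None,
    pin_master_gates: bool = False,
) -> EncoderState:
    """Run the recurrence left to right over an n x e embedding matrix.

    When `params_backward` is given, a reversed pass is concatenated on the
    feature axis (bidirectional; output width 2d).
    """
    X = as_tensor(X)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("encode expects a non-empty n x e embedding matrix")
    hs, cs, mfs, mis, oms = _encode_direction(X, params, pin_master_gates)
    rows = [h.reshape(1, -1) for h in hs]
    if params_backward is not None:
        n = X.shape[0]
        rev = Tensor(X.data[::-1].copy(), _parents=(X,), _backward=lambda g: [(X, g[::-1].copy())])
        hb, cb, mfb, mib, omb = _encode_direction(rev, params_backward, pin_master_gates)
        rows = [
            concatenate([rows[t], hb[n - 1 - t].reshape(1, -1)], axis=1) for t in range(n)
        ]
        mfs = [np.concatenate([a, b]) for a, b in zip(mfs, mfb[::-1])]
        mis = [np.concatenate([a, b]) for a, b in zip(mis, mib[::-1])]
        oms = [np.concatenate([a, b]) for a, b in zip(oms, omb[::-1])]
    return EncoderState(
        h=concatenate(rows, axis=0),
        cells=cs,
        master_forget=np.stack(mfs),
        master_input=np.stack(mis),
        overlap=np.stack(oms),
    )
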