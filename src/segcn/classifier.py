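"""Entity-aware classification head.

Sentence, subject-span and object-span representations are pooled from the
processed token features, concatenated in that fixed order (plus an
optional third-entity vector for ternary tasks) and passed through a
one-hidden-layer feedforward network; the final linear + softmax layer
produces the class distribution:  H_final = FFNN([H_sent ; H_s ; H_o]).
Max-pooling is the default (mean available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, softmax


def pool(features, span: tuple[int, int] | None = None, mask: np.ndarray | None = None, mode: str = "max") -> Tensor:
    """Pool an n x D feature matrix to a D vector.

    With a (start, end) span, pooling covers exactly the span's tokens;
    otherwise all valid (unmasked) tokens.  `mode` is "max" or "mean".
    """
    features = as_tensor(features)
    n = features.shape[0]
    if span is not None:
        start, end = span
        if not (0 <= start < end <= n):
            raise ValueError(f"empty or out-of-range span ({start}, {end}) for {n} tokens")
        block = features[start:end]
    elif mask is not None:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            raise ValueError("pooling over a fully masked sequence")
        block = features.take(idx, axis=0)
    else:
        block = features
    if mode == "max":
        return block.max(axis=0)
    if mode == "mean":
        return block.mean(axis=0)
    raise ValueError(f"unknown pooling mode {mode!r}")


@dataclass
class ClassifierParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @staticmethod
    def init(in_dim: int, hidden: int, n_labels: int, rng: np.random.Generator) -> "ClassifierParams":
        s1 = np.sqrt(6.0 / (in_dim + hidden))  # Glorot uniform
        s2 = np.sqrt(6.0 / (hidden + n_labels))
        return ClassifierParams(
            W1=Tensor(rng.uniform(-s1, s1, (in_dim, hidden)), requires_grad=True),
            b1=Tensor(np.zeros(hidden), requires_grad=True),
            W2=Tensor(rng.uniform(-s2, s2, (hidden, n_labels)), requires_grad=True),
            b2=Tensor(np.zeros(n_labels), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def classify(
    h_sent: Tensor,
    h_subject: Tensor,
    h_object: Tensor,
    params: ClassifierParams,
    h_third: Tensor | None = None,
) -> tuple[Tensor, Tensor]:
    """Concatenate pooled vectors, apply the FFNN; returns (logits, probs)."""
    parts = [h_sent, h_subject, h_object]
    if h_third is not None:
        parts.append(h_third)
    x = concatenate(parts, axis=0)
    if x.shape[0] != params.W1.shape[0]:
        raise ValueError(
            f"classifier expects input width {params.W1.shape[0]}, got {x.shape[0]}"
        )
    hidden = (x @ params.W1 + params.b1).relu()
    logits = hidden @ params.W2 + params.b2
    return logits, softmax(logits, axis=-1)
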