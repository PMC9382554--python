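"""Attention diagnostics: heat maps and diagonal-mass statistics.

Three token-by-token matrices summarize how the model distributes
interaction weight over a sentence:

* **A** — scaled dot-product attention computed directly on the word
  embeddings, bypassing the encoder: the pre-fusion picture, typically
  concentrated on the diagonal (local interactions).
* **B** — the model's multi-head attention on the encoder output (head
  average): after shallow syntactic fusion, weight moves off-diagonal.
* **C** — B after Gaussian-kernel equalization: local and nonlocal
  interactions balanced.

``diagonal_mass`` (trace over total) quantifies the local concentration;
equalization should not increase it on diagonal-heavy inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .corpus import RelationInstance
from .features import gaussian_prune
from .model import SEGCN


def diagonal_mass(matrix: np.ndarray) -> float:
    """Fraction of total weight on the diagonal, trace(M) / sum(M)."""
    matrix = np.asarray(matrix, dtype=float)
    return float(np.trace(matrix) / matrix.sum())


def row_entropy(matrix: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each row, rows renormalized first."""
    m = np.asarray(matrix, dtype=float)
    p = m / m.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def attention_matrices(model: SEGCN, instance: RelationInstance) -> dict[str, np.ndarray]:
    """Compute the A / B / C matrices for one instance (all row-stochastic)."""
    if len(instance.tokens) < 2:
        raise ValueError("diagnostics need at least 2 tokens")
    # A: attention straight off the embeddings, no encoder, no projections
    idx = model.vocab.encode(instance.tokens)
    E = model.vocab.embeddings[idx]
    logits = (E @ E.T) / np.sqrt(E.shape[1])
    logits -= logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    A = expd / expd.sum(axis=1, keepdims=True)
    # B: the trained model's raw attention (head average) on encoder output
    if model.processor is None:
        raise ValueError("diagnostics require the feature-capture block")
    _, _, _, graph = model.forward(instance, return_state=True)
    B = np.mean(graph.raw, axis=0)
    # C: B after Gaussian equalization
    kernel = model.kernel
    if kernel is None:
        from .features import build_gaussian_kernel

        kernel = build_gaussian_kernel(model.config.kernel_spec())
    C = gaussian_prune(Tensor(B), kernel).data
    return {"A": A, "B": B, "C": C}


def export_heatmaps(model: SEGCN, instance: RelationInstance, out_dir: str | Path) -> dict:
    """Write A/B/C as text matrices plus a rendered heat-map figure.

    Returns the diagonal-mass fractions.  The text files round-trip to
    bit-identical arrays via ``numpy.loadtxt``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mats = attention_matrices(model, instance)
    masses = {}
    for name, mat in mats.items():
        np.savetxt(out_dir / f"{name}.txt", mat, header=" ".join(instance.tokens))
        masses[name] = diagonal_mass(mat)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (name, mat) in zip(axes, mats.items()):
        im = ax.imshow(mat, cmap="Blues", vmin=0.0)
        ax.set_title(f"{name} (diag mass {masses[name]:.3f})")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.suptitle(f"instance {instance.instance_id}: {' '.join(instance.tokens[:8])}…")
    fig.tight_layout()
    fig.savefig(out_dir / "heatmaps.png", dpi=120)
    plt.close(fig)
    (out_dir / "diagonal_mass.json").write_text(json.dumps(masses, indent=2))
    return masses
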