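"""Feature processor: attention graph, Gaussian-kernel pruning, GCN.

The encoder's hidden states are turned into a soft dependency graph by
multi-head scaled dot-product self-attention: head k produces a
row-stochastic n x n matrix S^k that plays the role of a weighted adjacency
("the potential syntactic tree").  Because attention on recurrent states
tends to spike on the diagonal (local interactions), each S^k is smoothed
by convolving it with a small normalized 2-D Gaussian kernel — the same
operation used to equalize images — and renormalizing rows.  This
"pruning" redistributes weight from local to nonlocal interactions.  Graph
convolution layers then propagate token features over the (self-looped,
degree-normalized) pruned graph.

No spanning-tree decoding is involved: the pruning step is kernel
smoothing of the attention map, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, softmax

_NEG_INF = -1e30


class ConfigError(ValueError):
    pass


# ----------------------------------------------------------------- attention


@dataclass
class AttentionGraph:
    """Per-head token graphs before (`raw`) and after (`pruned`) smoothing."""

    raw: list[np.ndarray]
    pruned: list[np.ndarray]
    mask: np.ndarray | None = None


def attention_adjacency(
    h: Tensor,
    W_q: Tensor,
    W_k: Tensor,
    heads: int,
    mask: np.ndarray | None = None,
    standardize: bool = True,
) -> list[Tensor]:
    """Head-wise row-stochastic attention matrices S^k from hidden states.

    S^k = row-softmax( Q_k K_k^T / sqrt(d_head) ) with Q = h W^Q, K = h W^K
    split column-wise into `heads` equal slices.  Masked (padding) positions
    receive zero weight; rows over valid tokens sum to 1.

    With `standardize` (default) each feature is standardized across the
    sentence before projection.  The scaled dot product assumes O(1)
    inputs; tanh-bounded recurrent states at small widths are far below
    that, which would leave the attention near-uniform and its projections
    without gradient signal regardless of the data.
    """
    h = as_tensor(h)
    n, d = h.shape
    if n == 0:
        raise ValueError("attention over an empty sequence")
    if d % heads != 0:
        raise ConfigError(f"model width {d} not divisible by {heads} heads")
    d_head = d // heads
    if standardize and n > 1:
        centered = h - h.mean(axis=0, keepdims=True)
        scale = ((centered**2).mean(axis=0, keepdims=True) + 1e-8) ** 0.5
        h = centered / scale
    Q = h @ W_q
    K = h @ W_k
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        col_bias = np.where(mask, 0.0, _NEG_INF)[None, :]
    out = []
    for k in range(heads):
        sl = slice(k * d_head, (k + 1) * d_head)
        logits = (Q[:, sl] @ K[:, sl].T) / np.sqrt(d_head)
        if mask is not None:
            logits = logits + Tensor(np.broadcast_to(col_bias, (n, n)).copy())
        out.append(softmax(logits, axis=-1))
    return out


# ------------------------------------------------------------ gaussian kernel


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Discretized 2-D Gaussian: amplitude a, center (x_o, y_o), variances.

    The kernel is evaluated on the odd `size` x `size` integer grid centered
    at (x_o, y_o); with `normalize` the entries are scaled to sum to 1 (the
    amplitude then cancels).
    """

    size: int = 3
    amplitude: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    normalize: bool = True

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ConfigError(f"kernel size must be odd and >= 1, got {self.size}")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ConfigError("kernel variances must be positive")


def build_gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Evaluate g(x, y) = a exp(-((x-x_o)^2/2s_x^2 + (y-y_o)^2/2s_y^2))."""
    r = spec.size // 2
    x_o, y_o = spec.center
    x = np.arange(-r, r + 1) + x_o  # grid centered at the center point
    y = np.arange(-r, r + 1) + y_o
    dx2 = (x - x_o)[:, None] ** 2
    dy2 = (y - y_o)[None, :] ** 2
    k = spec.amplitude * np.exp(-(dx2 / (2 * spec.sigma_x**2) + dy2 / (2 * spec.sigma_y**2)))
    if spec.normalize:
        k = k / k.sum()
    return k


def _crop_kernel(kernel: np.ndarray, n: int) -> np.ndarray:
    """Crop a kernel larger than the matrix to the largest odd size <= n,
    renormalizing so it stays an averaging kernel."""
    size = kernel.shape[0]
    if size <= n:
        return kernel
    eff = n if n % 2 == 1 else n - 1
    cut = (size - eff) // 2
    k = kernel[cut : cut + eff, cut : cut + eff]
    return k / k.sum()


def convolve2d_replicate(M: Tensor, kernel: np.ndarray) -> Tensor:
    """2-D correlation with replicate (edge-clamp) padding, differentiable.

    For a normalized non-negative kernel every output entry is a convex
    combination of its receptive-field inputs, hence bounded by their
    min/max.  (The Gaussian kernel is symmetric, so correlation and
    convolution coincide.)
    """
    M = as_tensor(M)
    n, m = M.shape
    size = kernel.shape[0]
    r = size // 2
    acc: Tensor | None = None
    for a in range(size):
        rows = np.clip(np.arange(n) + a - r, 0, n - 1)
        Mr = M.take(rows, axis=0)
        for b in range(size):
            if kernel[a, b] == 0.0:
                continue
            cols = np.clip(np.arange(m) + b - r, 0, m - 1)
            term = Mr.take(cols, axis=1) * float(kernel[a, b])
            acc = term if acc is None else acc + term
    assert acc is not None
    return acc


def gaussian_prune(raw: Tensor, kernel: np.ndarray) -> Tensor:
    """Equalize an attention matrix: smooth with the kernel, renormalize rows.

    Kernels wider than the matrix are center-cropped and renormalized.
    Row renormalization (division by the row sum, not a second softmax)
    restores row-stochasticity while preserving the smoothed zero pattern.
    """
    raw = as_tensor(raw)
    n = raw.shape[0]
    k = _crop_kernel(np.asarray(kernel, dtype=np.float64), n)
    if not np.all(k >= 0):
        raise ConfigError("pruning kernel must be non-negative")
    if k.shape == (1, 1) and k[0, 0] == 1.0:
        return raw  # delta kernel: exact identity
    smoothed = convolve2d_replicate(raw, k)
    return smoothed / smoothed.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------------ gcn


def gcn_layer(H, A, W, activation: str | None = "relu", mask: np.ndarray | None = None) -> Tensor:
    """One graph-convolution layer H' = sigma( D̃^{-1} Ã H W ), Ã = A + I.

    Self-loops guarantee D̃_ii >= 1, so the row normalization is always
    defined.  Row (not symmetric) degree normalization is used because the
    attention adjacency is asymmetric.  Masked rows are zeroed.
    """
    H, A, W = as_tensor(H), as_tensor(A), as_tensor(W)
    if np.any(A.data < 0):
        raise ValueError("adjacency must be non-negative")
    n = A.shape[0]
    A_tilde = A + Tensor(np.eye(n))
    deg = A_tilde.sum(axis=1, keepdims=True)
    out = (A_tilde / deg) @ H @ W
    if activation == "relu":
        out = out.relu()
    elif activation == "tanh":
        out = out.tanh()
    elif activation is not None:
        raise ConfigError(f"unknown activation {activation!r}")
    if mask is not None:
        out = out * Tensor(np.asarray(mask, dtype=float)[:, None])
    return out


# ------------------------------------------------------------- full processor


@dataclass
class ProcessorParams:
    """Trainable weights of the attention + GCN feature processor."""

    W_q: Tensor
    W_k: Tensor
    gcn_weights: list[list[Tensor]]  # [head][layer]
    W_mix: Tensor  # (heads * gcn_dim) -> out_dim
    b_mix: Tensor
    heads: int
    layers: int

    @staticmethod
    def init(
        d: int, heads: int, layers: int, gcn_dim: int, out_dim: int, rng: np.random.Generator
    ) -> "ProcessorParams":
        if d % heads != 0:
            raise ConfigError(f"width {d} not divisible by {heads} heads")
        s = np.sqrt(6.0 / (d + d))  # Glorot uniform
        gcn_w = []
        for _ in range(heads):
            per_head = []
            din = d
            for _ in range(layers):
                sg = np.sqrt(6.0 / (din + gcn_dim))
                per_head.append(Tensor(rng.uniform(-sg, sg, (din, gcn_dim)), requires_grad=True))
                din = gcn_dim
            gcn_w.append(per_head)
        return ProcessorParams(
            W_q=Tensor(rng.uniform(-s, s, (d, d)), requires_grad=True),
            W_k=Tensor(rng.uniform(-s, s, (d, d)), requires_grad=True),
            gcn_weights=gcn_w,
            W_mix=Tensor(
                rng.uniform(
                    -np.sqrt(6.0 / (heads * gcn_dim + out_dim)),
                    np.sqrt(6.0 / (heads * gcn_dim + out_dim)),
                    (heads * gcn_dim, out_dim),
                ),
                requires_grad=True,
            ),
            b_mix=Tensor(np.zeros(out_dim), requires_grad=True),
            heads=heads,
            layers=layers,
        )

    def parameters(self) -> list[Tensor]:
        out = [self.W_q, self.W_k, self.W_mix, self.b_mix]
        for per_head in self.gcn_weights:
            out.extend(per_head)
        return out


def process(
    h,
    params: ProcessorParams,
    kernel: np.ndarray | None = None,
    use_pruning: bool = True,
    use_feature_capture: bool = True,
    mask: np.ndarray | None = None,
    return_graph: bool = False,
):
    """Full feature-capture pass: attention -> prune -> GCN, heads merged.

    Ablations: ``use_feature_capture=False`` bypasses the whole processor
    (identity on h); ``use_pruning=False`` skips the Gaussian smoothing.
    Head outputs are concatenated and linearly mixed to the output width.
    """
    h = as_tensor(h)
    if not use_feature_capture:
        if use_pruning:
            raise ConfigError("pruning without feature capture is contradictory")
        return (h, AttentionGraph([], [], mask)) if return_graph else h
    if use_pruning and kernel is None:
        raise ConfigError("use_pruning requires a kernel")
    raws = attention_adjacency(h, params.W_q, params.W_k, params.heads, mask=mask)
    head_outputs = []
    pruned_list: list[Tensor] = []
    for S in raws:
        A = gaussian_prune(S, kernel) if use_pruning else S
        pruned_list.append(A)
        H = h
        for W in params.gcn_weights[len(head_outputs)]:
            H = gcn_layer(H, A, W, activation="relu", mask=mask)
        head_outputs.append(H)
    mixed = concatenate(head_outputs, axis=1) @ params.W_mix + params.b_mix
    if mask is not None:
        mixed = mixed * Tensor(np.asarray(mask, dtype=float)[:, None])
    if return_graph:
        graph = AttentionGraph(
            raw=[S.data.copy() for S in raws],
            pruned=[A.data.copy() for A in pruned_list],
            mask=mask,
        )
        return mixed, graph
    return mixed
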