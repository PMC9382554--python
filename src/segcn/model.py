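"""Model configuration and the assembled relation-extraction network.

The network: token embeddings -> ordered-neuron LSTM encoder -> multi-head
attention adjacency -> Gaussian-kernel equalization -> GCN propagation ->
pooled entity-aware feedforward classifier.  Ablation flags reproduce the
reduced variants: ``use_pruning=False`` drops the equalization step and
``use_feature_capture=False`` replaces the whole attention+GCN block with
the identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, log_softmax
from .classifier import ClassifierParams, classify, pool
from .corpus import LabelSet, RelationInstance, Vocabulary, mask_entities
from .encoder import EncoderParams, EncoderState, encode
from .features import (
    AttentionGraph,
    ConfigError,
    GaussianKernelSpec,
    ProcessorParams,
    build_gaussian_kernel,
    process,
)


@dataclass
class ModelConfig:
    """Every hyperparameter and ablation toggle, YAML-serializable.

    Defaults follow the reference setting: 300-d embeddings and hidden
    size, SGD with multiplicative learning-rate decay 0.9 per epoch.
    Chunk size, head count, GCN depth and the kernel are exposed because
    they shape the syntactic machinery; the remaining knobs are ordinary
    training hyperparameters.
    """

    embedding_dim: int = 300
    hidden_size: int = 300
    chunk_size: int = 10
    heads: int = 4
    gcn_layers: int = 2
    gcn_hidden: int | None = None  # default: encoder output width
    out_dim: int | None = None  # D', default: encoder output width
    ffnn_hidden: int | None = None  # default: D'
    kernel_size: int = 3
    kernel_sigma: float = 1.0
    dropout: float = 0.5
    bidirectional: bool = False
    pooling: str = "max"
    lr: float = 0.1
    lr_decay: float = 0.9
    momentum: float = 0.0
    clip_norm: float | None = 5.0  # global gradient-norm clip; None disables
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    patience: int = 5
    use_pruning: bool = True
    use_feature_capture: bool = True
    task_type: str = "binary"  # binary | multiclass | ternary
    trainable_embeddings: bool = True
    mask_entity_tokens: bool = False

    def __post_init__(self):
        if self.hidden_size % self.chunk_size != 0:
            raise ConfigError("chunk_size must divide hidden_size")
        enc_out = self.encoder_out_dim
        if self.use_feature_capture and enc_out % self.heads != 0:
            raise ConfigError(f"encoder output width {enc_out} not divisible by {self.heads} heads")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ConfigError("lr_decay must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.task_type not in ("binary", "multiclass", "ternary"):
            raise ConfigError(f"unknown task_type {self.task_type!r}")
        if self.use_pruning and not self.use_feature_capture:
            raise ConfigError("use_pruning without use_feature_capture is contradictory")

    @property
    def encoder_out_dim(self) -> int:
        return self.hidden_size * (2 if self.bidirectional else 1)

    @property
    def feature_dim(self) -> int:
        """Width D' of the processed token features entering the classifier."""
        if not self.use_feature_capture:
            return self.encoder_out_dim
        return self.out_dim or self.encoder_out_dim

    def kernel_spec(self) -> GaussianKernelSpec:
        return GaussianKernelSpec(size=self.kernel_size, sigma_x=self.kernel_sigma, sigma_y=self.kernel_sigma)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "ModelConfig":
        return ModelConfig.from_dict(yaml.safe_load(Path(path).read_text()))


class SEGCN:
    """The assembled network, holding all trainable parameters."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, label_set: LabelSet):
        if vocab.dim != config.embedding_dim:
            raise ConfigError(
                f"vocabulary dim {vocab.dim} != config embedding_dim {config.embedding_dim}"
            )
        self.config = config
        self.vocab = vocab
        self.label_set = label_set
        rng = np.random.default_rng(config.seed)
        self.embedding = Tensor(vocab.embeddings.copy(), requires_grad=config.trainable_embeddings)
        self.encoder = EncoderParams.init(config.embedding_dim, config.hidden_size, config.chunk_size, rng)
        self.encoder_bw = (
            EncoderParams.init(config.embedding_dim, config.hidden_size, config.chunk_size, rng)
            if config.bidirectional
            else None
        )
        enc_out = config.encoder_out_dim
        if config.use_feature_capture:
            gcn_dim = config.gcn_hidden or enc_out
            self.processor = ProcessorParams.init(
                enc_out, config.heads, config.gcn_layers, gcn_dim, config.feature_dim, rng
            )
        else:
            self.processor = None
        self.kernel = build_gaussian_kernel(config.kernel_spec()) if config.use_pruning else None
        n_pooled = 4 if config.task_type == "ternary" else 3
        d_prime = config.feature_dim
        self.classifier = ClassifierParams.init(
            n_pooled * d_prime, config.ffnn_hidden or d_prime, len(label_set), rng
        )

    # ------------------------------------------------------------ parameters
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.config.trainable_embeddings:
            params.append(self.embedding)
        params.extend(self.encoder.parameters())
        if self.encoder_bw is not None:
            params.extend(self.encoder_bw.parameters())
        if self.processor is not None:
            params.extend(self.processor.parameters())
        params.extend(self.classifier.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.copy()

    # --------------------------------------------------------------- forward
    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if p <= 0 or rng is None:
            return t
        keep = (rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(keep)

    def forward(
        self,
        instance: RelationInstance,
        train_rng: np.random.Generator | None = None,
        return_state: bool = False,
        pin_master_gates: bool = False,
    ):
        """Class log-odds for one instance.

        `train_rng` enables dropout (training mode); without it the pass is
        deterministic.  With `return_state` the encoder state and attention
        graph are returned for diagnostics.
        """
        cfg = self.config
        inst = mask_entities(instance) if cfg.mask_entity_tokens else instance
        idx = self.vocab.encode(inst.tokens)
        X = self.embedding.take(idx, axis=0)
        X = self._dropout(X, train_rng)
        state: EncoderState = encode(X, self.encoder, self.encoder_bw, pin_master_gates)
        h = self._dropout(state.h, train_rng)
        graph: AttentionGraph | None = None
        if self.processor is not None:
            out = process(
                h,
                self.processor,
                kernel=self.kernel,
                use_pruning=cfg.use_pruning,
                use_feature_capture=True,
                return_graph=return_state,
            )
            g, graph = out if return_state else (out, None)
        else:
            g = h
        g = self._dropout(g, train_rng)
        subj = instance.subject
        obj = instance.object
        h_sent = pool(g, mode=cfg.pooling)
        h_s = pool(g, span=(subj.start, subj.end), mode=cfg.pooling)
        h_o = pool(g, span=(obj.start, obj.end), mode=cfg.pooling)
        h_t = None
        if cfg.task_type == "ternary":
            third = instance.span("third")
            if third is None:
                raise ValueError(f"instance {instance.instance_id} lacks a third entity span")
            h_t = pool(g, span=(third.start, third.end), mode=cfg.pooling)
        logits, probs = classify(h_sent, h_s, h_o, self.classifier, h_third=h_t)
        if return_state:
            return logits, probs, state, graph
        return logits, probs

    def loss(self, instance: RelationInstance, train_rng: np.random.Generator | None = None) -> Tensor:
        """Cross-entropy of the gold label for one instance."""
        logits, _ = self.forward(instance, train_rng=train_rng)
        y = self.label_set.index(instance.label)
        return -log_softmax(logits)[y]

    def predict(self, instance: RelationInstance) -> str:
        logits, _ = self.forward(instance)
        return self.label_set.labels[int(np.argmax(logits.data))]

    # ------------------------------------------------------------ checkpoint
    def save(self, path: str | Path) -> None:
        """Self-describing archive: config + label set + vocab + weights."""
        meta = {
            "config": self.config.to_dict(),
            "labels": list(self.label_set.labels),
            "null_label": self.label_set.null_label,
            "tokens": self.vocab.token_to_index,
        }
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, meta=json.dumps(meta), embeddings=self.vocab.embeddings, **arrays)

    @staticmethod
    def load(path: str | Path) -> "SEGCN":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            vocab = Vocabulary(
                {t: int(i) for t, i in meta["tokens"].items()}, archive["embeddings"]
            )
            model = SEGCN(
                ModelConfig.from_dict(meta["config"]),
                vocab,
                LabelSet(tuple(meta["labels"]), meta["null_label"]),
            )
            n = len(model.parameters())
            model.load_state_arrays([archive[f"param_{i}"] for i in range(n)])
        return model
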