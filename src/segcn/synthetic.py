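"""Synthetic relation-extraction corpora with a planted, learnable rule.

Real chemical-protein (multi-class, with a ``None`` class) and
phenotype-gene (binary Yes/No) corpora are large and external; this module
emulates their *format and decision structure* so the full model can be
trained and evaluated offline.  Each instance is a token sequence with one
subject and one object entity; the label is determined by which trigger
word appears strictly between the two entity spans.  Controlled corruption
(`noise_rate`) removes the trigger while keeping the label, which caps any
classifier's accuracy at the rule-oracle ceiling.  Distractor triggers of
other labels are planted *outside* the entity-to-entity path, so a
bag-of-words shortcut fails and the model must use position/structure.
Filler text carries balanced bracket tokens nested to a configurable depth,
giving the encoder hierarchical surface structure to latch onto.

No attempt is made to match real biomedical vocabulary or entity-name
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import EntitySpan, LabelSet, RelationInstance


class ConfigError(ValueError):
    pass


def _default_trigger_map() -> dict[str, tuple[str, ...]]:
    return {"Yes": ("binds", "activates", "inhibits")}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-rule corpus generator.

    Defaults emulate a binary phenotype-gene style task: labels Yes/No with
    ``No`` as the null class, noiseless, sentence lengths 8-30 tokens.
    """

    n_instances: int = 1000
    label_set: LabelSet = field(default_factory=lambda: LabelSet(("No", "Yes"), null_label="No"))
    vocab_size: int = 60
    length_range: tuple[int, int] = (8, 30)
    trigger_map: dict[str, tuple[str, ...]] = field(default_factory=_default_trigger_map)
    nesting_depth: int = 2
    noise_rate: float = 0.0
    seed: int = 0
    ternary: bool = False
    distractor_rate: float = 0.5
    n_entity_names: int = 10

    def __post_init__(self):
        if self.length_range[0] < 5:
            raise ConfigError("minimum sentence length must be >= 5")
        if self.ternary and self.length_range[0] < 8:
            raise ConfigError("ternary instances need minimum length >= 8")
        if not (0.0 <= self.noise_rate < 0.5):
            raise ConfigError("noise_rate must be in [0, 0.5)")
        for label in self.label_set.labels:
            if label == self.label_set.null_label:
                continue
            if not self.trigger_map.get(label):
                raise ConfigError(f"non-null label {label!r} has no trigger words")
        if self.n_fillers < 5:
            raise ConfigError(
                f"vocab_size={self.vocab_size} too small to host "
                f"{self.n_triggers} triggers + {self.n_entity_names} entity names"
            )

    @property
    def n_triggers(self) -> int:
        return sum(len(v) for v in self.trigger_map.values())

    @property
    def n_fillers(self) -> int:
        # brackets take 2 slots of the word inventory
        return self.vocab_size - self.n_triggers - self.n_entity_names - 2

    @property
    def all_triggers(self) -> set[str]:
        return {t for ts in self.trigger_map.values() for t in ts}


def cpr_style_spec(**overrides) -> SyntheticSpec:
    """Multi-class spec shaped like a chemical-protein corpus: a null class
    plus five positive relation types, each with its own trigger words."""
    labels = ("None", "CPR:2", "CPR:3", "CPR:4", "CPR:5", "CPR:6")
    triggers = {
        "CPR:2": ("modulates",),
        "CPR:3": ("upregulates", "activates"),
        "CPR:4": ("downregulates", "inhibits"),
        "CPR:5": ("agonizes",),
        "CPR:6": ("antagonizes",),
    }
    kwargs = dict(
        label_set=LabelSet(labels, null_label="None"),
        trigger_map=triggers,
        vocab_size=80,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def _filler_stream(rng: np.random.Generator, n: int, n_fillers: int, depth: int) -> list[str]:
    """Filler words with balanced brackets nested up to `depth`."""
    out: list[str] = []

    def phrase(d: int) -> None:
        while len(out) < n:
            if d < depth and rng.random() < 0.2:
                out.append("(")
                phrase(d + 1)
                out.append(")")
            else:
                out.append(f"w{rng.integers(n_fillers)}")
            if rng.random() < 0.3:
                return

    while len(out) < n:
        phrase(0)
    return out[:n]


def _place_instance(spec: SyntheticSpec, rng: np.random.Generator, length: int, idx: int) -> RelationInstance:
    labels = spec.label_set.labels
    label = labels[rng.integers(len(labels))]
    null = spec.label_set.null_label
    tokens = _filler_stream(rng, length, spec.n_fillers, spec.nesting_depth)

    n_ent = 3 if spec.ternary else 2
    # entity slots left-to-right with >=1 gap token between consecutive ones
    gap = 2
    max_start = length - (n_ent + (n_ent - 1) * gap)
    if max_start < 0:
        raise ConfigError(f"length {length} too short for {n_ent} entities")
    positions = sorted(int(p) for p in rng.choice(max_start + 1, size=n_ent, replace=True))
    positions = [p + i * (gap + 1) for i, p in enumerate(positions)]
    ent_tokens = rng.choice(spec.n_entity_names, size=n_ent, replace=False)
    entities = []
    roles = ("subject", "object", "third")[:n_ent]
    for role, pos, e in zip(roles, positions, ent_tokens):
        tokens[pos] = f"ent{e}"
        entities.append(EntitySpan(role, pos, pos + 1))

    meta: dict = {}
    if label != null:
        trigs = spec.trigger_map[label]
        corrupted = rng.random() < spec.noise_rate
        paths = [(positions[0], positions[1])]
        if spec.ternary:
            paths.append((positions[1], positions[2]))
        for lo, hi in paths:
            slot = int(rng.integers(lo + 1, hi))
            if corrupted:
                tokens[slot] = f"w{rng.integers(spec.n_fillers)}"
            else:
                tokens[slot] = str(trigs[rng.integers(len(trigs))])
        if corrupted:
            meta["corrupted"] = True

    # distractor: a trigger of a *different* label outside every path
    if rng.random() < spec.distractor_rate:
        other = [t for lb, ts in spec.trigger_map.items() if lb != label for t in ts]
        if other:
            outside = list(range(0, positions[0])) + list(range(positions[-1] + 1, length))
            outside = [p for p in outside if tokens[p] not in [f"ent{e}" for e in ent_tokens]]
            if outside:
                tokens[outside[rng.integers(len(outside))]] = str(other[rng.integers(len(other))])

    return RelationInstance(
        tokens=tokens, entities=entities, label=label, instance_id=f"syn{idx:05d}", meta=meta
    ).validate()


def generate_corpus(spec: SyntheticSpec) -> list[RelationInstance]:
    """Generate `spec.n_instances` examples; identical seed, identical corpus."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    return [
        _place_instance(spec, rng, int(rng.integers(lo, hi)), i)
        for i in range(spec.n_instances)
    ]


def generate_length_stratified(spec: SyntheticSpec, bins: Sequence[tuple[int, int]]) -> list[RelationInstance]:
    """Equal instance counts per length bin (±1), lengths within each bin."""
    for lo, hi in bins:
        if hi <= lo or lo < 5:
            raise ConfigError(f"infeasible length bin ({lo}, {hi}); need 5 <= lo < hi")
    spans = sorted(bins)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ConfigError("length bins must be disjoint")
    rng = np.random.default_rng(spec.seed)
    out: list[RelationInstance] = []
    base, extra = divmod(spec.n_instances, len(bins))
    idx = 0
    for b, (lo, hi) in enumerate(bins):
        count = base + (1 if b < extra else 0)
        for _ in range(count):
            out.append(_place_instance(spec, rng, int(rng.integers(lo, hi)), idx))
            idx += 1
    return out


def rule_oracle_label(inst: RelationInstance, spec: SyntheticSpec) -> str:
    """The planted decision rule: label whose trigger sits on every
    entity-to-entity path, else the null label.  Bayes-optimal on
    uncorrupted instances; errs exactly on the corrupted fraction."""
    spans = sorted(inst.entities, key=lambda e: e.start)
    paths = [
        set(inst.tokens[a.end : b.start]) for a, b in zip(spans, spans[1:])
    ]
    for label, trigs in spec.trigger_map.items():
        if all(path & set(trigs) for path in paths):
            return label
    null = spec.label_set.null_label
    return null if null is not None else spec.label_set.labels[0]


def rule_oracle_accuracy(corpus: Sequence[RelationInstance], spec: SyntheticSpec) -> float:
    """Accuracy of the planted rule on `corpus` — the learnability ceiling."""
    hits = sum(rule_oracle_label(inst, spec) == inst.label for inst in corpus)
    return hits / len(corpus)
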