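"""Instance data model, corpus readers/writers, vocabulary and embeddings.

A relation-extraction example is a pre-tokenized sentence (or concatenated
multi-sentence passage) with marked entity spans and a categorical label.
Two on-disk dialects are supported: JSON-lines (one object per line with
keys ``id``, ``tokens``, ``entities``, ``label``) and a TSV dialect
(``id<TAB>label<TAB>space-joined tokens<TAB>role:start:end ...``).  Spans
are 0-based half-open over tokens everywhere in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

VALID_ROLES = ("subject", "object", "third")

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


class CorpusError(ValueError):
    """Malformed corpus record; message carries the 1-based line number."""


@dataclass(frozen=True)
class EntitySpan:
    role: str
    start: int
    end: int

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise CorpusError(f"unknown entity role {self.role!r}")


@dataclass
class RelationInstance:
    """One supervised example: tokens, entity spans, relation label."""

    tokens: list[str]
    entities: list[EntitySpan]
    label: str
    instance_id: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self, line: int | None = None) -> "RelationInstance":
        where = f" (line {line})" if line is not None else ""
        n = len(self.tokens)
        roles = [e.role for e in self.entities]
        if len(set(roles)) != len(roles):
            raise CorpusError(f"duplicate entity role{where}: {roles}")
        for e in self.entities:
            if not (0 <= e.start < e.end <= n):
                raise CorpusError(
                    f"entity span {e.role}:{e.start}:{e.end} out of range for "
                    f"{n}-token sentence{where}"
                )
        return self

    def span(self, role: str) -> EntitySpan | None:
        for e in self.entities:
            if e.role == role:
                return e
        return None

    @property
    def subject(self) -> EntitySpan:
        s = self.span("subject")
        if s is None:
            raise CorpusError("instance has no subject span")
        return s

    @property
    def object(self) -> EntitySpan:
        s = self.span("object")
        if s is None:
            raise CorpusError("instance has no object span")
        return s


@dataclass(frozen=True)
class LabelSet:
    """Ordered relation labels, optionally with a designated null class."""

    labels: tuple[str, ...]
    null_label: str | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.null_label is not None and self.null_label not in self.labels:
            raise ValueError("null_label must be a member of labels")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def from_instances(instances: Iterable[RelationInstance], null_label: str | None = None) -> "LabelSet":
        seen: list[str] = []
        for inst in instances:
            if inst.label not in seen:
                seen.append(inst.label)
        if null_label is not None and null_label not in seen:
            seen.append(null_label)
        return LabelSet(tuple(sorted(seen)), null_label)


# --------------------------------------------------------------------- I/O


def _instance_from_record(rec: dict, line: int) -> RelationInstance:
    for key in ("tokens", "entities", "label"):
        if key not in rec:
            raise CorpusError(f"missing field {key!r} at line {line}")
    entities = [EntitySpan(str(r), int(s), int(e)) for r, s, e in rec["entities"]]
    inst = RelationInstance(
        tokens=[str(t) for t in rec["tokens"]],
        entities=entities,
        label=str(rec["label"]),
        instance_id=str(rec.get("id", f"i{line}")),
        meta=dict(rec.get("meta", {})),
    )
    return inst.validate(line)


def read_corpus(path: str | Path, format: str = "jsonl") -> list[RelationInstance]:
    """Read a corpus file; records are validated and errors cite line numbers."""
    path = Path(path)
    instances: list[RelationInstance] = []
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "jsonl":
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"invalid JSON at line {line_no}: {exc}") from exc
                instances.append(_instance_from_record(rec, line_no))
            elif format == "tsv":
                parts = line.split("\t")
                if len(parts) != 4:
                    raise CorpusError(f"expected 4 tab-separated fields at line {line_no}, got {len(parts)}")
                inst_id, label, token_str, span_str = parts
                entities = []
                for triple in span_str.split():
                    try:
                        role, start, end = triple.split(":")
                        entities.append(EntitySpan(role, int(start), int(end)))
                    except (ValueError, CorpusError) as exc:
                        raise CorpusError(f"bad span triple {triple!r} at line {line_no}") from exc
                inst = RelationInstance(
                    tokens=token_str.split(" "),
                    entities=entities,
                    label=label,
                    instance_id=inst_id,
                )
                instances.append(inst.validate(line_no))
            else:
                raise ValueError(f"unknown corpus format {format!r}")
    return instances


def write_corpus(instances: Sequence[RelationInstance], path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for inst in instances:
            inst.validate()
            if format == "jsonl":
                rec = {
                    "id": inst.instance_id,
                    "tokens": inst.tokens,
                    "entities": [[e.role, e.start, e.end] for e in inst.entities],
                    "label": inst.label,
                }
                if inst.meta:
                    rec["meta"] = inst.meta
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            elif format == "tsv":
                if any("\t" in t or " " in t for t in inst.tokens):
                    raise CorpusError(
                        f"instance {inst.instance_id}: tokens with whitespace cannot "
                        "be written in TSV format"
                    )
                spans = " ".join(f"{e.role}:{e.start}:{e.end}" for e in inst.entities)
                fh.write(f"{inst.instance_id}\t{inst.label}\t{' '.join(inst.tokens)}\t{spans}\n")
            else:
                raise ValueError(f"unknown corpus format {format!r}")


def mask_entities(inst: RelationInstance) -> RelationInstance:
    """Replace entity tokens with typed placeholders (``<subject>`` etc.).

    Optional preprocessing; some relation-extraction pipelines anonymize the
    entity surface forms so the classifier cannot memorize entity names.
    """
    tokens = list(inst.tokens)
    for e in inst.entities:
        for i in range(e.start, e.end):
            tokens[i] = f"<{e.role}>"
    return replace(inst, tokens=tokens)


# --------------------------------------------------------------- embeddings


def load_embeddings(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Load whitespace-separated text vectors ("word v1 ... vd", UTF-8)."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with Path(path).open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            elif len(values) != dim:
                raise CorpusError(
                    f"embedding dimension mismatch at line {line_no}: "
                    f"expected {dim}, got {len(values)}"
                )
            vectors[word] = np.array(values, dtype=np.float64)
    if dim is None:
        raise CorpusError(f"embedding file {path} is empty")
    return vectors, dim


@dataclass
class Vocabulary:
    """Token -> index map with an embedding matrix.

    Index 0 is padding (zero vector), index 1 the shared unknown token.
    Lookup lowercases (GloVe convention); raw tokens live on the instance.
    """

    token_to_index: dict[str, int]
    embeddings: np.ndarray  # |V| x dim

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def __len__(self) -> int:
        return self.embeddings.shape[0]

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    def index(self, token: str) -> int:
        return self.token_to_index.get(token.lower(), self.unk_index)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.intp)


def build_vocabulary(
    instances: Iterable[RelationInstance],
    embeddings_path: str | Path | None = None,
    dim: int = 300,
    seed: int = 0,
) -> Vocabulary:
    """Collect corpus tokens and attach pretrained or seeded-random vectors.

    Tokens found in the embedding file receive their pretrained vector.
    Tokens absent from it are drawn from a seeded normal with sd 0.4,
    matching the entrywise scale of typical pretrained word vectors so the
    downstream network sees healthy activations even with no embedding
    file at all.  The shared unknown token uses a uniform draw in
    [-0.5/dim, 0.5/dim]; the padding row is all zeros.  Identical corpus
    and seed produce a byte-identical matrix.
    """
    pretrained: dict[str, np.ndarray] = {}
    if embeddings_path is not None:
        pretrained, file_dim = load_embeddings(embeddings_path)
        if file_dim != dim:
            raise ValueError(f"requested dim {dim} but embedding file has dim {file_dim}")
    ordered: list[str] = []
    seen: set[str] = set()
    for inst in instances:
        for tok in inst.tokens:
            low = tok.lower()
            if low not in seen:
                seen.add(low)
                ordered.append(low)
    rng = np.random.default_rng(seed)
    token_to_index = {PAD_TOKEN: 0, UNK_TOKEN: 1}
    rows = [np.zeros(dim), rng.uniform(-0.5 / dim, 0.5 / dim, size=dim)]
    for tok in ordered:
        token_to_index[tok] = len(rows)
        if tok in pretrained:
            rows.append(pretrained[tok])
        else:
            rows.append(rng.normal(0.0, 0.4, size=dim))
    return Vocabulary(token_to_index, np.vstack(rows))
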