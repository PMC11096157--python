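"""Reading, writing and preprocessing of NER / RE corpora.

NER corpora travel in the common CoNLL dialect: one token per line, tag in the
last whitespace-separated column, blank line between sentences, ``-DOCSTART-``
lines ignored.  RE corpora travel as 6-column TSV rows (space-joined tokens,
head start/end, tail start/end, relation label).  All token indices are 0-based
and half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "TaggedSentence",
    "EntitySpan",
    "RelationInstance",
    "Corpus",
    "CorpusError",
    "validate_bio",
    "read_conll",
    "write_conll",
    "spans_from_tags",
    "tags_from_spans",
    "read_re_tsv",
    "write_re_tsv",
    "dedup_split",
    "truncate",
]

_TAG_RE = re.compile(r"^(O|[BI]-[A-Za-z0-9_.\-]+)$")


class CorpusError(ValueError):
    """Malformed corpus content (bad tags, bad spans, bad files)."""


@dataclass(frozen=True)
class EntitySpan:
    """Half-open token interval ``[start, end)`` with an entity type."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TaggedSentence:
    """Token sequence with aligned BIO tags and a source identifier."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]
    source_id: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) != len(self.tags):
            raise CorpusError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def spans(self) -> tuple[EntitySpan, ...]:
        return tuple(spans_from_tags(self.tags))


@dataclass(frozen=True)
class RelationInstance:
    """Sentence with two marked entity spans and a relation label."""

    tokens: tuple[str, ...]
    head: EntitySpan
    tail: EntitySpan
    label: str
    source_id: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        n = len(self.tokens)
        for name, span in (("head", self.head), ("tail", self.tail)):
            if span.end > n:
                raise CorpusError(f"{name} span {span} exceeds {n} tokens")
        if self.head == self.tail:
            raise CorpusError("head and tail must not be identical spans")

    def __len__(self) -> int:
        return len(self.tokens)


Record = Union[TaggedSentence, RelationInstance]


@dataclass(frozen=True)
class Corpus:
    """A homogeneous collection of NER sentences or RE instances."""

    task: str  # "ner" | "re"
    records: tuple[Record, ...]
    type_inventory: frozenset[str] = field(default_factory=frozenset)
    split_name: str = "unsplit"

    def __post_init__(self) -> None:
        if self.task not in ("ner", "re"):
            raise CorpusError(f"unknown task {self.task!r}")
        object.__setattr__(self, "records", tuple(self.records))
        seen = _label_inventory(self.task, self.records)
        inv = frozenset(self.type_inventory) | seen
        object.__setattr__(self, "type_inventory", inv)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_records(self, records: Iterable[Record], split_name: str | None = None) -> "Corpus":
        return Corpus(
            task=self.task,
            records=tuple(records),
            type_inventory=self.type_inventory,
            split_name=self.split_name if split_name is None else split_name,
        )


def _label_inventory(task: str, records: Sequence[Record]) -> frozenset[str]:
    labels: set[str] = set()
    for rec in records:
        if task == "ner":
            if not isinstance(rec, TaggedSentence):
                raise CorpusError("ner corpus may only hold TaggedSentence records")
            labels.update(t.split("-", 1)[1] for t in rec.tags if t != "O")
        else:
            if not isinstance(rec, RelationInstance):
                raise CorpusError("re corpus may only hold RelationInstance records")
            labels.add(rec.label)
    return frozenset(labels)


# ---------------------------------------------------------------------------
# BIO tags <-> spans


def validate_bio(tags: Sequence[str], repair: bool = False) -> tuple[str, ...]:
    """Check a BIO tag sequence; optionally rewrite orphan I- tags to B-.

    An ``I-X`` is an orphan when the previous tag is neither ``B-X`` nor
    ``I-X``.  With ``repair=False`` orphans raise :class:`CorpusError`.
    """
    out: list[str] = []
    prev = "O"
    for i, tag in enumerate(tags):
        if not _TAG_RE.match(tag):
            raise CorpusError(f"invalid tag {tag!r} at position {i}")
        if tag.startswith("I-"):
            etype = tag[2:]
            if prev not in (f"B-{etype}", f"I-{etype}"):
                if not repair:
                    raise CorpusError(f"orphan {tag!r} at position {i}")
                tag = f"B-{etype}"
        out.append(tag)
        prev = tag
    return tuple(out)


def spans_from_tags(tags: Sequence[str], repair: bool = False) -> list[EntitySpan]:
    """Decode maximal B-led entity runs from a BIO sequence, sorted by start."""
    tags = validate_bio(tags, repair=repair)
    spans: list[EntitySpan] = []
    start, etype = None, None
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
            start, etype = i, tag[2:]
        elif tag == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
            start, etype = None, None
        # I- continues the current run (validity guaranteed above)
    if start is not None:
        spans.append(EntitySpan(start, len(tags), etype))
    return spans


def tags_from_spans(spans: Sequence[EntitySpan], length: int) -> list[str]:
    """Encode non-overlapping spans as a BIO sequence of ``length`` tags."""
    tags = ["O"] * length
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    prev_end = -1
    for span in ordered:
        if span.end > length:
            raise CorpusError(f"span {span} exceeds sentence length {length}")
        if span.start < prev_end:
            raise CorpusError(f"overlapping spans at token {span.start}")
        tags[span.start] = f"B-{span.etype}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.etype}"
        prev_end = span.end
    return tags


# ---------------------------------------------------------------------------
# CoNLL


def read_conll(path: str | Path, repair: bool = False, source_id: str | None = None) -> Corpus:
    """Parse a CoNLL-style BIO file into an NER :class:`Corpus`."""
    path = Path(path)
    source = source_id if source_id is not None else path.stem
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if tokens:
            sentences.append(
                TaggedSentence(tuple(tokens), validate_bio(tags, repair=repair), source)
            )
            tokens.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush()
                continue
            if line.startswith("-DOCSTART-"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise CorpusError(f"{path}:{lineno}: expected >=2 columns, got {len(cols)}")
            tokens.append(cols[0])
            tags.append(cols[-1])
    flush()
    return Corpus(task="ner", records=tuple(sentences))


def write_conll(corpus: Corpus, path: str | Path) -> None:
    if corpus.task != "ner":
        raise CorpusError("write_conll expects an NER corpus")
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            for tok, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# RE TSV


def read_re_tsv(path: str | Path, source_id: str | None = None) -> Corpus:
    """Parse 6-column TSV relation instances into an RE :class:`Corpus`."""
    path = Path(path)
    source = source_id if source_id is not None else path.stem
    records: list[RelationInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise CorpusError(f"{path}:{lineno}: expected 6 TSV columns, got {len(cols)}")
            tokens = tuple(cols[0].split())
            try:
                hs, he, ts, te = (int(c) for c in cols[1:5])
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: non-integer span index") from exc
            try:
                rec = RelationInstance(
                    tokens=tokens,
                    head=EntitySpan(hs, he, "HEAD"),
                    tail=EntitySpan(ts, te, "TAIL"),
                    label=cols[5],
                    source_id=source,
                )
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return Corpus(task="re", records=tuple(records))


def write_re_tsv(corpus: Corpus, path: str | Path) -> None:
    if corpus.task != "re":
        raise CorpusError("write_re_tsv expects an RE corpus")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(
                "\t".join(
                    [
                        " ".join(rec.tokens),
                        str(rec.head.start),
                        str(rec.head.end),
                        str(rec.tail.start),
                        str(rec.tail.end),
                        rec.label,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Preprocessing


def _dedup_key(rec: Record):
    if isinstance(rec, TaggedSentence):
        return (rec.tokens, rec.tags)
    return (rec.tokens, rec.head, rec.tail, rec.label)


def dedup_split(
    corpus: Corpus,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[Corpus, Corpus, Corpus]:
    """Remove exact duplicates, then shuffle and cut into train/dev/test.

    Dev and test sizes are floor-based; the remainder goes to train, so
    ``(0.8, 0.1, 0.1)`` on 10 records yields sizes ``(8, 1, 1)``.
    """
    if len(corpus) == 0:
        raise CorpusError("cannot split an empty corpus")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise CorpusError(f"ratios must be positive and sum to 1, got {ratios}")

    seen: set = set()
    unique: list[Record] = []
    for rec in corpus:
        key = _dedup_key(rec)
        if key not in seen:
            seen.add(key)
            unique.append(rec)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    shuffled = [unique[i] for i in order]

    n = len(shuffled)
    n_dev = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_dev - n_test
    train = shuffled[:n_train]
    dev = shuffled[n_train : n_train + n_dev]
    test = shuffled[n_train + n_dev :]
    return (
        corpus.with_records(train, "train"),
        corpus.with_records(dev, "dev"),
        corpus.with_records(test, "test"),
    )


def truncate(sentence: TaggedSentence, max_len: int = 512) -> TaggedSentence:
    """Trim a sentence to its first ``max_len`` tokens (tags stay aligned)."""
    if max_len < 1:
        raise CorpusError("max_len must be >= 1")
    if len(sentence) <= max_len:
        return sentence
    return replace(
        sentence,
        tokens=sentence.tokens[:max_len],
        tags=sentence.tags[:max_len],
    )
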