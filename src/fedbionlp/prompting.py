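"""Few-shot prompt construction for NER and RE (no language model is called).

Prompts follow the usual in-context-learning layout: a task description,
``n_shot`` input -> annotated-output example pairs sampled without
replacement from the training corpus, and a final unanswered query.  NER
outputs use inline paired-tag markup (``<GENE> BRCA1 </GENE>``); RE outputs
are the bare label string.  A best-effort parser recovers entity spans from
annotated text so externally produced completions can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import (
    Corpus,
    EntitySpan,
    RelationInstance,
    TaggedSentence,
    spans_from_tags,
)

__all__ = [
    "PromptSpec",
    "render_annotated",
    "build_fewshot_prompt",
    "sample_eval_subset",
    "parse_annotated_response",
]

DEFAULT_NER_DESCRIPTION = (
    "Extract all named entities from the input sentence and mark each one "
    "inline with paired type tags, e.g. <GENE> ... </GENE>."
)
DEFAULT_RE_DESCRIPTION = (
    "Given the sentence and the two marked entities, answer with the single "
    "relation label that holds between them."
)


@dataclass(frozen=True)
class PromptSpec:
    task_description: str
    n_shot: int = 5
    example_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shot < 0:
            raise ValueError("n_shot must be >= 0")


def render_annotated(sentence: TaggedSentence) -> str:
    """Sentence text with every entity wrapped in ``<TYPE> ... </TYPE>`` tags."""
    spans = spans_from_tags(sentence.tags)
    out: list[str] = []
    by_start = {s.start: s for s in spans}
    ends: dict[int, str] = {s.end: s.etype for s in spans}
    for i, tok in enumerate(sentence.tokens):
        if i in ends:
            out.append(f"</{ends[i]}>")
        if i in by_start:
            out.append(f"<{by_start[i].etype}>")
        out.append(tok)
    if len(sentence.tokens) in ends:
        out.append(f"</{ends[len(sentence.tokens)]}>")
    return " ".join(out)


def _format_example(record, annotated: bool) -> tuple[str, str]:
    if isinstance(record, TaggedSentence):
        text = " ".join(record.tokens)
        return text, render_annotated(record) if annotated else ""
    assert isinstance(record, RelationInstance)
    head = " ".join(record.tokens[record.head.start : record.head.end])
    tail = " ".join(record.tokens[record.tail.start : record.tail.end])
    text = f'{" ".join(record.tokens)} [entity 1: {head}] [entity 2: {tail}]'
    return text, record.label


def build_fewshot_prompt(spec: PromptSpec, train: Corpus | None, query) -> str:
    """Deterministic prompt text: description, n_shot worked pairs, query."""
    if spec.n_shot > 0:
        if train is None or len(train) == 0:
            raise ValueError("a non-empty training corpus is required for n_shot > 0")
        if spec.n_shot > len(train):
            raise ValueError(f"n_shot={spec.n_shot} exceeds train size {len(train)}")
    lines = [spec.task_description, ""]
    if spec.n_shot > 0:
        rng = np.random.default_rng(spec.example_seed)
        idx = rng.choice(len(train), size=spec.n_shot, replace=False)
        for i in idx:
            text, answer = _format_example(train.records[int(i)], annotated=True)
            lines += [f"Input: {text}", f"Output: {answer}", ""]
    query_text, _ = _format_example(query, annotated=False)
    lines += [f"Input: {query_text}", "Output:"]
    return "\n".join(lines)


def sample_eval_subset(test: Corpus, n: int, seed: int) -> Corpus:
    """Uniform sample of ``n`` distinct test records (the scoring subset)."""
    if n > len(test):
        raise ValueError(f"cannot sample {n} records from {len(test)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(test), size=n, replace=False)
    return test.with_records([test.records[int(i)] for i in idx])


def parse_annotated_response(
    text: str, tag_inventory: Sequence[str]
) -> tuple[list[EntitySpan], int]:
    """Recover entity spans from inline paired-tag markup, best effort.

    Returns ``(spans, n_warnings)``.  Span indices refer to the clean token
    sequence with the markup tokens removed.  Malformed fragments (unknown
    types, unclosed or unopened tags, nesting) are skipped and counted.
    """
    inventory = set(tag_inventory)
    spans: list[EntitySpan] = []
    warnings = 0
    clean_pos = 0
    open_type: str | None = None
    open_start = 0
    for raw in text.split():
        if raw.startswith("</") and raw.endswith(">"):
            etype = raw[2:-1]
            if open_type == etype and clean_pos > open_start:
                spans.append(EntitySpan(open_start, clean_pos, etype))
            else:
                warnings += 1
            open_type = None
        elif raw.startswith("<") and raw.endswith(">"):
            etype = raw[1:-1]
            if etype not in inventory or open_type is not None:
                warnings += 1
                open_type = None
                continue
            open_type = etype
            open_start = clean_pos
        else:
            clean_pos += 1
    if open_type is not None:
        warnings += 1  # unclosed tag at end of text
    return spans, warnings
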