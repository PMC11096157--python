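"""Entity-level evaluation under strict and lenient matching, RE macro-F1,
and mean +/- sd aggregation over repeated runs.

Strict matching credits a prediction only when (start, end, type) all agree
with a gold span; lenient matching credits any prediction whose token
interval overlaps a gold span of the same type by at least one token.
Matching is one-to-one and greedy in start order.  Macro scores are the
unweighted mean over entity types (or relation labels) that occur in the
gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, EntitySpan, spans_from_tags

__all__ = [
    "MatchCounts",
    "EvalReport",
    "match_entities",
    "prf",
    "evaluate_ner",
    "evaluate_re",
    "summarize_repeats",
    "report_frame",
    "lenient_macro_f1",
]

SCHEMES = ("strict", "lenient")


@dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    scheme: str = "strict"

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        if self.scheme != other.scheme:
            raise ValueError("cannot add counts from different schemes")
        return MatchCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.scheme
        )


@dataclass(frozen=True)
class EvalReport:
    per_type: dict[str, tuple[float, float, float]]  # type -> (P, R, F1)
    macro_precision: float
    macro_recall: float
    macro_f1: float
    scheme: str
    n_records: int


def _compatible(gold: EntitySpan, pred: EntitySpan, scheme: str) -> bool:
    if scheme == "strict":
        return gold == pred
    if scheme == "lenient":
        return gold.etype == pred.etype and gold.overlaps(pred)
    raise ValueError(f"unknown scheme {scheme!r}")


def match_entities(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan], scheme: str = "strict"
) -> MatchCounts:
    """One-to-one greedy matching of predictions against gold spans.

    Predictions are processed in start order; each is matched to the first
    still-unmatched gold span (also in start order) satisfying the scheme's
    criterion.  tp = matches, fp = unmatched predictions, fn = unmatched gold.
    """
    gold = sorted(gold, key=lambda s: (s.start, s.end))
    for a, b in zip(gold, gold[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping gold spans {a} / {b}")
    pred = sorted(pred, key=lambda s: (s.start, s.end))
    matched = [False] * len(gold)
    tp = 0
    for p in pred:
        for i, g in enumerate(gold):
            if not matched[i] and _compatible(g, p, scheme):
                matched[i] = True
                tp += 1
                break
    return MatchCounts(
        tp=tp, fp=len(pred) - tp, fn=len(gold) - tp, scheme=scheme
    )


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 with the 0/0 -> 0 convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _split_by_type(spans: Sequence[EntitySpan]) -> dict[str, list[EntitySpan]]:
    by: dict[str, list[EntitySpan]] = {}
    for s in spans:
        by.setdefault(s.etype, []).append(s)
    return by


def evaluate_ner(model, corpus: Corpus, scheme: str = "strict") -> EvalReport:
    """Decode each sentence, accumulate per-type match counts, macro-average.

    Predicted tag sequences are IOB-repaired before span decoding so that
    structurally unconstrained taggers can still be scored.  Macro scores
    average over the entity types present in the gold standard.
    """
    if len(corpus) == 0:
        raise ValueError("cannot evaluate on an empty corpus")
    counts: dict[str, MatchCounts] = {}
    gold_types: set[str] = set()
    for sent in corpus:
        gold = spans_from_tags(sent.tags)
        pred = spans_from_tags(model.predict_tags(sent), repair=True)
        gold_by, pred_by = _split_by_type(gold), _split_by_type(pred)
        gold_types.update(gold_by)
        for etype in set(gold_by) | set(pred_by):
            c = match_entities(gold_by.get(etype, []), pred_by.get(etype, []), scheme)
            counts[etype] = counts.get(etype, MatchCounts(scheme=scheme)) + c
    per_type = {
        etype: prf(counts.get(etype, MatchCounts(scheme=scheme)))
        for etype in sorted(gold_types)
    }
    macro = np.array(list(per_type.values())).mean(axis=0)
    return EvalReport(
        per_type=per_type,
        macro_precision=float(macro[0]),
        macro_recall=float(macro[1]),
        macro_f1=float(macro[2]),
        scheme=scheme,
        n_records=len(corpus),
    )


def evaluate_re(model, corpus: Corpus) -> EvalReport:
    """Per-label P/R/F1 from confusion counts; macro over gold labels."""
    if len(corpus) == 0:
        raise ValueError("cannot evaluate on an empty corpus")
    if not (set(l for l in corpus.type_inventory) <= set(model.labels)):
        raise ValueError("model labels do not cover the corpus labels")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    gold_labels: set[str] = set()
    for inst in corpus:
        gold_labels.add(inst.label)
        pred = model.predict_label(inst)
        if pred == inst.label:
            tp[pred] = tp.get(pred, 0) + 1
        else:
            fp[pred] = fp.get(pred, 0) + 1
            fn[inst.label] = fn.get(inst.label, 0) + 1
    per_label = {
        label: prf(
            MatchCounts(tp.get(label, 0), fp.get(label, 0), fn.get(label, 0), "strict")
        )
        for label in sorted(gold_labels)
    }
    macro = np.array(list(per_label.values())).mean(axis=0)
    return EvalReport(
        per_type=per_label,
        macro_precision=float(macro[0]),
        macro_recall=float(macro[1]),
        macro_f1=float(macro[2]),
        scheme="label",
        n_records=len(corpus),
    )


def summarize_repeats(scores: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1; sd = 0 for a single run)."""
    if len(scores) == 0:
        raise ValueError("no scores")
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def lenient_macro_f1(model, corpus: Corpus) -> float:
    """Convenience dev-metric callable for the federation engine."""
    return evaluate_ner(model, corpus, scheme="lenient").macro_f1


def report_frame(report: EvalReport) -> pd.DataFrame:
    """Long-form (type, scheme, P, R, F1) table for CSV export."""
    rows = [
        {"type": t, "scheme": report.scheme, "precision": p, "recall": r, "f1": f}
        for t, (p, r, f) in report.per_type.items()
    ]
    rows.append(
        {
            "type": "macro",
            "scheme": report.scheme,
            "precision": report.macro_precision,
            "recall": report.macro_recall,
            "f1": report.macro_f1,
        }
    )
    return pd.DataFrame(rows)


def format_mean_sd(mean: float, sd: float) -> str:
    """Three-decimal "mean ± sd" cell, the tables' house style."""
    return f"{mean:.3f} ± {sd:.3f}"
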