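"""Synthetic NER / RE corpus generation with controllable source heterogeneity.

Real multi-site biomedical corpora differ in vocabulary and phrasing because
each site writes text under its own protocols (the "sublanguage" problem).
This module emulates that situation: every source owns entity lexicons,
sentence templates and a context vocabulary, and ``make_sources`` controls the
fraction of that material shared across sources.  ``overlap=1`` gives
identically distributed sources (the IID federation setting); ``overlap=0``
gives fully disjoint vocabularies (an extreme non-IID setting); intermediate
values interpolate, which a unigram Jensen-Shannon diagnostic can verify.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .corpus_io import (
    Corpus,
    CorpusError,
    EntitySpan,
    RelationInstance,
    TaggedSentence,
    validate_bio,
)

__all__ = [
    "SourceSpec",
    "GenConfig",
    "make_sources",
    "generate_ner",
    "generate_re",
    "unigram_divergence",
    "DEFAULT_ENTITY_TYPES",
    "DEFAULT_RELATION_LABELS",
]

DEFAULT_ENTITY_TYPES = ("GENE", "DISEASE", "CHEMICAL")
DEFAULT_RELATION_LABELS = ("associated_with", "inhibits", "no_relation")

# Pool sizes per source.  Chosen so that a tenth of a ~1k-sentence corpus does
# not exhaust the lexicon: single clients then face genuinely unseen surface
# forms at test time, as they would with real corpora.
LEXICON_SIZE = 50
N_TEMPLATES = 16
CONTEXT_SIZE = 150

# The canonical gene-disease relation sentence; kept verbatim as a template so
# generated RE corpora contain instances of the familiar shape
# "Mutations of BRCA1 gene are associated with breast cancer".
_CANONICAL_RE_TEMPLATE = (
    "Mutations", "of", ("HEAD", "GENE"), "gene", "are",
    "associated", "with", ("TAIL", "DISEASE"),
)


@dataclass(frozen=True)
class SourceSpec:
    """One data-generating site: lexicons, templates and context vocabulary."""

    source_id: str
    lexicons: dict[str, tuple[tuple[str, ...], ...]]  # etype -> surface forms
    templates: tuple[tuple, ...]  # elements: ("SLOT", etype) or "CTX"
    context_vocab: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.context_vocab:
            raise CorpusError("context_vocab must be non-empty")
        slot_types = {
            el[1]
            for tpl in self.templates
            for el in tpl
            if isinstance(el, tuple)
        }
        for etype in slot_types:
            if not self.lexicons.get(etype):
                raise CorpusError(f"template slot type {etype!r} has no lexicon")


@dataclass(frozen=True)
class GenConfig:
    """Knobs of a single generation run; generation is pure in (spec, cfg)."""

    n_sentences: int
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    relation_labels: tuple[str, ...] = DEFAULT_RELATION_LABELS
    entities_per_sentence: tuple[int, int] = (1, 3)
    tag_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tag_noise_rate < 0.5:
            raise CorpusError("tag_noise_rate must lie in [0, 0.5)")
        if self.n_sentences < 0:
            raise CorpusError("n_sentences must be non-negative")


# ---------------------------------------------------------------------------
# Pseudo-word fabrication

_SYLLABLES = [
    c + v for c in "bcdfghklmnprstvz" for v in ("a", "e", "i", "o", "u", "ae")
]


def _context_word(rng: np.random.Generator) -> str:
    n = int(rng.integers(2, 4))
    return "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), n))


def _entity_form(rng: np.random.Generator, etype: str) -> tuple[str, ...]:
    """A 1-3 token surface form, styled loosely by entity type."""
    n_tok = int(rng.integers(1, 4))
    toks = []
    for _ in range(n_tok):
        if etype == "GENE":
            stem = "".join(
                string.ascii_uppercase[int(i)] for i in rng.integers(0, 26, 4)
            )
            toks.append(stem + str(int(rng.integers(1, 100))))
        else:
            toks.append(etype[:3].lower() + _context_word(rng))
    return tuple(toks)


def _fresh(make, rng: np.random.Generator, n: int, taken: set) -> list:
    out = []
    while len(out) < n:
        item = make(rng)
        if item not in taken:
            taken.add(item)
            out.append(item)
    return out


def _make_template(rng: np.random.Generator, entity_types) -> tuple:
    """A sentence skeleton: context positions interleaved with typed slots."""
    n_slots = int(rng.integers(1, 4))
    n_ctx = int(rng.integers(4, 10))
    elements: list = ["CTX"] * n_ctx
    positions = sorted(rng.choice(n_ctx + 1, size=n_slots, replace=True))
    for off, pos in enumerate(positions):
        etype = str(rng.choice(entity_types))
        elements.insert(pos + off, ("SLOT", etype))
    return tuple(elements)


# ---------------------------------------------------------------------------
# Source construction


def make_sources(
    n_sources: int,
    overlap: float,
    seed: int,
    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES,
) -> list[SourceSpec]:
    """Build ``n_sources`` sites sharing an ``overlap`` fraction of material.

    Each pool (per-type lexicon, templates, context vocabulary) holds a fixed
    number of items; ``round(overlap * size)`` of them come from a common
    shared pool, the rest are private to each source and pairwise disjoint.
    """
    if n_sources < 1:
        raise CorpusError("n_sources must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise CorpusError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def split_pool(make, size: int, taken: set):
        n_shared = round(overlap * size)
        shared = _fresh(make, rng, n_shared, taken)
        privates = [
            _fresh(make, rng, size - n_shared, taken) for _ in range(n_sources)
        ]
        return shared, privates

    taken: set = set()
    lex_pools = {
        etype: split_pool(lambda r, e=etype: _entity_form(r, e), LEXICON_SIZE, taken)
        for etype in entity_types
    }
    tpl_shared, tpl_private = split_pool(
        lambda r: _make_template(r, entity_types), N_TEMPLATES, set()
    )
    ctx_shared, ctx_private = split_pool(_context_word, CONTEXT_SIZE, taken)

    sources = []
    for i in range(n_sources):
        lexicons = {
            etype: tuple(shared + privates[i])
            for etype, (shared, privates) in lex_pools.items()
        }
        sources.append(
            SourceSpec(
                source_id=f"source_{i}",
                lexicons=lexicons,
                templates=tuple(tpl_shared + tpl_private[i]),
                context_vocab=tuple(ctx_shared + ctx_private[i]),
            )
        )
    return sources


# ---------------------------------------------------------------------------
# NER generation


def generate_ner(source: SourceSpec, cfg: GenConfig) -> Corpus:
    """Instantiate templates into BIO-tagged sentences from one source.

    With probability ``cfg.tag_noise_rate`` a sentence has one entity token
    re-tagged ``O`` (annotation-miss noise); an IOB repair pass keeps the
    sequence valid BIO afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.entities_per_sentence
    eligible = [
        t
        for t in source.templates
        if lo <= sum(1 for el in t if isinstance(el, tuple)) <= hi
    ] or list(source.templates)

    sentences = []
    for _ in range(cfg.n_sentences):
        template = eligible[int(rng.integers(len(eligible)))]
        tokens: list[str] = []
        tags: list[str] = []
        for el in template:
            if isinstance(el, tuple):
                etype = el[1]
                forms = source.lexicons[etype]
                form = forms[int(rng.integers(len(forms)))]
                tokens.extend(form)
                tags.extend([f"B-{etype}"] + [f"I-{etype}"] * (len(form) - 1))
            else:
                tokens.append(str(rng.choice(source.context_vocab)))
                tags.append("O")
        if cfg.tag_noise_rate > 0 and rng.random() < cfg.tag_noise_rate:
            entity_positions = [i for i, t in enumerate(tags) if t != "O"]
            if entity_positions:
                flip = int(rng.choice(entity_positions))
                tags[flip] = "O"
                tags = list(validate_bio(tags, repair=True))
        sentences.append(TaggedSentence(tuple(tokens), tuple(tags), source.source_id))
    return Corpus(task="ner", records=tuple(sentences))


# ---------------------------------------------------------------------------
# RE generation


def _relation_templates(source: SourceSpec, labels, rng: np.random.Generator):
    """Per-label relation templates; the template identity fixes the label."""
    ctx = source.context_vocab
    etypes = sorted(source.lexicons)
    head_t = "GENE" if "GENE" in etypes else etypes[0]
    tail_t = "DISEASE" if "DISEASE" in etypes else etypes[-1]
    by_label: dict[str, list[tuple]] = {}
    for label in labels:
        marker = tuple(label.split("_"))
        tpls = []
        if label == "associated_with":
            tpls.append(_CANONICAL_RE_TEMPLATE)
        for _ in range(2):
            pre = tuple(rng.choice(ctx, size=int(rng.integers(1, 3))))
            mid = tuple(rng.choice(ctx, size=1))
            post = tuple(rng.choice(ctx, size=int(rng.integers(0, 2))))
            tpls.append(
                pre + (("HEAD", head_t),) + mid + marker + (("TAIL", tail_t),) + post
            )
        by_label[label] = tpls
    return by_label


def generate_re(source: SourceSpec, cfg: GenConfig) -> Corpus:
    """Generate relation instances with an approximately uniform label mix."""
    if not cfg.relation_labels:
        raise CorpusError("relation_labels must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    by_label = _relation_templates(source, cfg.relation_labels, rng)

    records = []
    for _ in range(cfg.n_sentences):
        label = str(rng.choice(cfg.relation_labels))
        tpls = by_label[label]
        template = tpls[int(rng.integers(len(tpls)))]
        tokens: list[str] = []
        head = tail = None
        for el in template:
            if isinstance(el, tuple) and el[0] in ("HEAD", "TAIL"):
                role, etype = el
                forms = source.lexicons[etype]
                form = forms[int(rng.integers(len(forms)))]
                span = EntitySpan(len(tokens), len(tokens) + len(form), etype)
                tokens.extend(form)
                if role == "HEAD":
                    head = span
                else:
                    tail = span
            else:
                tokens.append(str(el))
        records.append(
            RelationInstance(tuple(tokens), head, tail, label, source.source_id)
        )
    return Corpus(task="re", records=tuple(records))


def generate_re_canonical(source: SourceSpec, gene: str, disease: tuple[str, ...]) -> RelationInstance:
    """The fixed-shape gene-disease instance, with caller-chosen entity text."""
    tokens = ("Mutations", "of", gene, "gene", "are", "associated", "with") + tuple(disease)
    return RelationInstance(
        tokens=tokens,
        head=EntitySpan(2, 3, "GENE"),
        tail=EntitySpan(7, 7 + len(disease), "DISEASE"),
        label="associated_with",
        source_id=source.source_id,
    )


# ---------------------------------------------------------------------------
# Heterogeneity diagnostic


def _unigram_counts(corpus: Corpus) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in corpus:
        for tok in rec.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    return counts


def unigram_divergence(a: Corpus, b: Corpus) -> float:
    """Base-2 Jensen-Shannon divergence between unigram token distributions.

    Bounded in [0, 1]: 0 for identical distributions, 1 for disjoint
    vocabularies.  Serves as the distribution-distance diagnostic behind the
    IID / non-IID distinction.
    """
    if len(a) == 0 or len(b) == 0:
        raise CorpusError("unigram_divergence requires non-empty corpora")
    ca, cb = _unigram_counts(a), _unigram_counts(b)
    vocab = sorted(set(ca) | set(cb))
    p = np.array([ca.get(t, 0) for t in vocab], dtype=float)
    q = np.array([cb.get(t, 0) for t in vocab], dtype=float)
    p /= p.sum()
    q /= q.sum()
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)
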