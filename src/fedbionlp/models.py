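"""Trainable models whose parameters the federation engine averages.

Three families, all float64 numpy with analytically derived gradients:

* :class:`LinearTagger` — per-token softmax over sparse token-identity
  features (current / previous / next token).  The loss is convex in the
  parameters, which makes this the oracle model for federation-equivalence
  tests.
* :class:`TaggerModel` — embedding, single-layer bidirectional tanh RNN
  encoder, linear emission projection and a linear-chain CRF output layer
  (forward-algorithm partition function, Viterbi decoding).  The same
  architecture class as the classical BiLSTM-CRF sequence labeller, at a
  desk-scale size.
* :class:`REModel` — embedding, mean-pooling over head span / tail span /
  whole sentence, and a linear classifier over the concatenated pools.

Every model exposes ``params`` (a :class:`ParamSet`), ``set_params`` and
``loss_and_grad(batch)``; :func:`gradient` adds the FedProx proximal term
``mu * (w - reference)`` on top of the task gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .corpus_io import Corpus, RelationInstance, TaggedSentence

__all__ = [
    "ParamSet",
    "build_vocab",
    "UNK", "BOS", "EOS",
    "crf_log_partition",
    "crf_nll",
    "viterbi",
    "LinearTagger",
    "TaggerModel",
    "REModel",
    "gradient",
    "count_params",
]

UNK, BOS, EOS = 0, 1, 2
_N_RESERVED = 3


class ParamSet(Mapping):
    """Named collection of real arrays closed under linear combination."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self._arrays = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> np.ndarray:
        return self._arrays[key]

    def __iter__(self):
        return iter(self._arrays)

    def __len__(self) -> int:
        return len(self._arrays)

    # Linear algebra -------------------------------------------------------
    def _check_compat(self, other: "ParamSet") -> None:
        if set(self._arrays) != set(other._arrays):
            raise ValueError("ParamSets have different array names")
        for k, v in self._arrays.items():
            if v.shape != other[k].shape:
                raise ValueError(f"shape mismatch for {k!r}: {v.shape} vs {other[k].shape}")

    def __add__(self, other: "ParamSet") -> "ParamSet":
        self._check_compat(other)
        return ParamSet({k: v + other[k] for k, v in self._arrays.items()})

    def __sub__(self, other: "ParamSet") -> "ParamSet":
        self._check_compat(other)
        return ParamSet({k: v - other[k] for k, v in self._arrays.items()})

    def __mul__(self, scalar: float) -> "ParamSet":
        return ParamSet({k: v * float(scalar) for k, v in self._arrays.items()})

    __rmul__ = __mul__

    def copy(self) -> "ParamSet":
        return ParamSet({k: v.copy() for k, v in self._arrays.items()})

    def zeros_like(self) -> "ParamSet":
        return ParamSet({k: np.zeros_like(v) for k, v in self._arrays.items()})

    def sq_norm(self) -> float:
        return float(sum(np.sum(v * v) for v in self._arrays.values()))

    def sq_dist(self, other: "ParamSet") -> float:
        self._check_compat(other)
        return float(
            sum(np.sum((v - other[k]) ** 2) for k, v in self._arrays.items())
        )

    def flatten(self) -> np.ndarray:
        return (
            np.concatenate([self._arrays[k].ravel() for k in sorted(self._arrays)])
            if self._arrays
            else np.zeros(0)
        )

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self._arrays.values()))

    def allclose(self, other: "ParamSet", **kw) -> bool:
        self._check_compat(other)
        return all(np.allclose(v, other[k], **kw) for k, v in self._arrays.items())

    def equal(self, other: "ParamSet") -> bool:
        """Bit-identical comparison."""
        self._check_compat(other)
        return all(np.array_equal(v, other[k]) for k, v in self._arrays.items())


def build_vocab(corpora: Iterable[Corpus]) -> dict[str, int]:
    """Token -> index map with reserved UNK/BOS/EOS rows, sorted for determinism."""
    tokens: set[str] = set()
    for corpus in corpora:
        for rec in corpus:
            tokens.update(rec.tokens)
    return {tok: i + _N_RESERVED for i, tok in enumerate(sorted(tokens))}


def _lookup(vocab: dict[str, int], token: str) -> int:
    return vocab.get(token, UNK)


# ---------------------------------------------------------------------------
# Linear-chain CRF primitives


def crf_log_partition(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
) -> float:
    """log sum over all T^L tag paths of exp(path score), via the forward recursion.

    A path's score is the sum of its per-token emissions, its pairwise
    transitions, and the start/stop terms of its first/last tag.
    """
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a non-empty L x T matrix")
    alpha = start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = emissions[t] + logsumexp(alpha[:, None] + transitions, axis=0)
    return float(logsumexp(alpha + stop))


def _crf_forward_backward(emissions, transitions, start, stop):
    """Log-space forward/backward tables and the log partition function."""
    L, T = emissions.shape
    log_alpha = np.zeros((L, T))
    log_alpha[0] = start + emissions[0]
    for t in range(1, L):
        log_alpha[t] = emissions[t] + logsumexp(
            log_alpha[t - 1][:, None] + transitions, axis=0
        )
    log_beta = np.zeros((L, T))
    log_beta[L - 1] = stop
    for t in range(L - 2, -1, -1):
        log_beta[t] = logsumexp(
            transitions + emissions[t + 1] + log_beta[t + 1], axis=1
        )
    log_z = float(logsumexp(log_alpha[L - 1] + stop))
    return log_alpha, log_beta, log_z


def _crf_gradients(emissions, transitions, start, stop, gold: np.ndarray):
    """NLL value and its gradients wrt emissions / transitions / start / stop."""
    L, T = emissions.shape
    log_alpha, log_beta, log_z = _crf_forward_backward(
        emissions, transitions, start, stop
    )
    node = np.exp(log_alpha + log_beta - log_z)  # L x T marginals
    d_em = node.copy()
    d_trans = np.zeros_like(transitions)
    for t in range(L - 1):
        pair = np.exp(
            log_alpha[t][:, None]
            + transitions
            + emissions[t + 1]
            + log_beta[t + 1]
            - log_z
        )
        d_trans += pair
    d_start = node[0].copy()
    d_stop = node[L - 1].copy()

    gold_score = start[gold[0]] + emissions[np.arange(L), gold].sum() + stop[gold[-1]]
    d_em[np.arange(L), gold] -= 1.0
    d_start[gold[0]] -= 1.0
    d_stop[gold[-1]] -= 1.0
    for t in range(L - 1):
        gold_score += transitions[gold[t], gold[t + 1]]
        d_trans[gold[t], gold[t + 1]] -= 1.0

    nll = log_z - float(gold_score)
    return nll, d_em, d_trans, d_start, d_stop


def crf_nll(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    gold: Sequence[int],
) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    gold = np.asarray(gold, dtype=int)
    emissions = np.asarray(emissions, dtype=float)
    L = emissions.shape[0]
    log_z = crf_log_partition(emissions, transitions, start, stop)
    score = start[gold[0]] + stop[gold[-1]]
    score += sum(emissions[t, gold[t]] for t in range(L))
    score += sum(transitions[gold[t], gold[t + 1]] for t in range(L - 1))
    return float(log_z - score)


def viterbi(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
) -> list[int]:
    """Highest-scoring tag path; ties resolve to the lexicographically
    smallest tag-index sequence.

    The recursion runs backwards (suffix maxima) and the path is then read
    off front-to-back, taking the smallest index at every tie, which yields
    the lexicographic tie-break exactly.
    """
    emissions = np.asarray(emissions, dtype=float)
    L, T = emissions.shape
    # delta[t, j] = best score of the path suffix starting at t with tag j
    delta = np.zeros((L, T))
    delta[L - 1] = emissions[L - 1] + stop
    for t in range(L - 2, -1, -1):
        delta[t] = emissions[t] + np.max(transitions + delta[t + 1], axis=1)
    path = [int(np.argmax(start + delta[0]))]  # argmax takes first (smallest) max
    for t in range(1, L):
        prev = path[-1]
        path.append(int(np.argmax(transitions[prev] + delta[t])))
    return path


# ---------------------------------------------------------------------------
# Linear tagger (convex oracle model)


class LinearTagger:
    """Per-token softmax tagger over current/previous/next token identities."""

    def __init__(
        self,
        vocab: dict[str, int],
        tag_inventory: Sequence[str],
        seed: int = 0,
        init_scale: float = 0.0,
    ):
        self.vocab = vocab
        self.tags = list(tag_inventory)
        self.tag_index = {t: i for i, t in enumerate(self.tags)}
        V = len(vocab) + _N_RESERVED
        T = len(self.tags)
        rng = np.random.default_rng(seed)
        init = lambda *shape: (
            rng.normal(0.0, init_scale, shape) if init_scale else np.zeros(shape)
        )
        self._p = ParamSet(
            {
                "w_cur": init(V, T),
                "w_prev": init(V, T),
                "w_next": init(V, T),
                "bias": init(T),
            }
        )

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self) -> ParamSet:
        return self._p

    def set_params(self, params: ParamSet) -> None:
        self._p._check_compat(params)
        self._p = params.copy()

    # -- features ----------------------------------------------------------
    def _feature_ids(self, tokens: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids = np.array([_lookup(self.vocab, t) for t in tokens], dtype=int)
        prev = np.concatenate(([BOS], ids[:-1]))
        nxt = np.concatenate((ids[1:], [EOS]))
        return ids, prev, nxt

    def _token_scores(self, tokens: Sequence[str]) -> np.ndarray:
        cur, prev, nxt = self._feature_ids(tokens)
        p = self._p
        return p["w_cur"][cur] + p["w_prev"][prev] + p["w_next"][nxt] + p["bias"]

    # -- loss / gradient ---------------------------------------------------
    def loss_and_grad(self, batch: Sequence[TaggedSentence]):
        if not batch:
            raise ValueError("empty batch")
        p = self._p
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        total = 0.0
        for sent in batch:
            cur, prev, nxt = self._feature_ids(sent.tokens)
            scores = self._token_scores(sent.tokens)
            gold = np.array([self.tag_index[t] for t in sent.tags], dtype=int)
            shifted = scores - scores.max(axis=1, keepdims=True)
            logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            L = len(sent)
            total += -logp[np.arange(L), gold].mean()
            d = np.exp(logp)
            d[np.arange(L), gold] -= 1.0
            d /= L * len(batch)
            np.add.at(grads["w_cur"], cur, d)
            np.add.at(grads["w_prev"], prev, d)
            np.add.at(grads["w_next"], nxt, d)
            grads["bias"] += d.sum(axis=0)
        return total / len(batch), ParamSet(grads)

    # -- inference ---------------------------------------------------------
    def predict_tags(self, sentence: TaggedSentence) -> list[str]:
        scores = self._token_scores(sentence.tokens)
        return [self.tags[i] for i in scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# Bidirectional-RNN + CRF tagger


class TaggerModel:
    """Embedding -> bidirectional tanh RNN -> emissions -> linear-chain CRF."""

    def __init__(
        self,
        vocab: dict[str, int],
        tag_inventory: Sequence[str],
        emb_dim: int = 16,
        hidden: int = 16,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.tags = list(tag_inventory)
        self.tag_index = {t: i for i, t in enumerate(self.tags)}
        self.emb_dim = emb_dim
        self.hidden = hidden
        V = len(vocab) + _N_RESERVED
        T = len(self.tags)
        rng = np.random.default_rng(seed)
        u = lambda *shape: rng.uniform(-0.1, 0.1, shape)
        self._p = ParamSet(
            {
                "emb": u(V, emb_dim),
                "wx_f": u(emb_dim, hidden),
                "wh_f": u(hidden, hidden),
                "b_f": np.zeros(hidden),
                "wx_b": u(emb_dim, hidden),
                "wh_b": u(hidden, hidden),
                "b_b": np.zeros(hidden),
                "w_out": u(2 * hidden, T),
                "b_out": np.zeros(T),
                "trans": np.zeros((T, T)),
                "start": np.zeros(T),
                "stop": np.zeros(T),
            }
        )

    @property
    def params(self) -> ParamSet:
        return self._p

    def set_params(self, params: ParamSet) -> None:
        self._p._check_compat(params)
        self._p = params.copy()

    # -- encoder forward pass ----------------------------------------------
    def _encode(self, tokens: Sequence[str]):
        p = self._p
        ids = np.array([_lookup(self.vocab, t) for t in tokens], dtype=int)
        E = p["emb"][ids]  # L x d
        L = len(ids)
        h = self.hidden
        hf = np.zeros((L, h))
        hb = np.zeros((L, h))
        prev = np.zeros(h)
        for t in range(L):
            prev = np.tanh(E[t] @ p["wx_f"] + prev @ p["wh_f"] + p["b_f"])
            hf[t] = prev
        nxt = np.zeros(h)
        for t in range(L - 1, -1, -1):
            nxt = np.tanh(E[t] @ p["wx_b"] + nxt @ p["wh_b"] + p["b_b"])
            hb[t] = nxt
        H = np.concatenate([hf, hb], axis=1)  # L x 2h
        emissions = H @ p["w_out"] + p["b_out"]
        return ids, E, hf, hb, H, emissions

    def emissions(self, tokens: Sequence[str]) -> np.ndarray:
        return self._encode(tokens)[-1]

    # -- loss / gradient ---------------------------------------------------
    def sentence_nll(self, sentence: TaggedSentence) -> float:
        p = self._p
        em = self.emissions(sentence.tokens)
        gold = [self.tag_index[t] for t in sentence.tags]
        return crf_nll(em, p["trans"], p["start"], p["stop"], gold)

    def loss_and_grad(self, batch: Sequence[TaggedSentence]):
        if not batch:
            raise ValueError("empty batch")
        p = self._p
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        total = 0.0
        for sent in batch:
            gold = np.array([self.tag_index[t] for t in sent.tags], dtype=int)
            ids, E, hf, hb, H, em = self._encode(sent.tokens)
            nll, d_em, d_trans, d_start, d_stop = _crf_gradients(
                em, p["trans"], p["start"], p["stop"], gold
            )
            total += nll
            grads["trans"] += d_trans
            grads["start"] += d_start
            grads["stop"] += d_stop
            # emissions layer
            grads["w_out"] += H.T @ d_em
            grads["b_out"] += d_em.sum(axis=0)
            dH = d_em @ p["w_out"].T
            h = self.hidden
            d_hf, d_hb = dH[:, :h], dH[:, h:]
            L = len(ids)
            dE = np.zeros_like(E)
            # BPTT through the forward-direction RNN
            carry = np.zeros(h)
            for t in range(L - 1, -1, -1):
                dh = d_hf[t] + carry
                da = dh * (1.0 - hf[t] ** 2)
                prev_h = hf[t - 1] if t > 0 else np.zeros(h)
                grads["wx_f"] += np.outer(E[t], da)
                grads["wh_f"] += np.outer(prev_h, da)
                grads["b_f"] += da
                dE[t] += p["wx_f"] @ da
                carry = p["wh_f"] @ da
            # BPTT through the backward-direction RNN
            carry = np.zeros(h)
            for t in range(L):
                dh = d_hb[t] + carry
                da = dh * (1.0 - hb[t] ** 2)
                next_h = hb[t + 1] if t < L - 1 else np.zeros(h)
                grads["wx_b"] += np.outer(E[t], da)
                grads["wh_b"] += np.outer(next_h, da)
                grads["b_b"] += da
                dE[t] += p["wx_b"] @ da
                carry = p["wh_b"] @ da
            np.add.at(grads["emb"], ids, dE)
        n = len(batch)
        return total / n, ParamSet({k: v / n for k, v in grads.items()})

    # -- inference ---------------------------------------------------------
    def predict_tags(self, sentence: TaggedSentence) -> list[str]:
        p = self._p
        em = self.emissions(sentence.tokens)
        path = viterbi(em, p["trans"], p["start"], p["stop"])
        return [self.tags[i] for i in path]


# ---------------------------------------------------------------------------
# Relation-extraction classifier


class REModel:
    """Span-pooled linear relation classifier.

    Pools the embedding mean over the head span, the tail span and the full
    sentence, concatenates, and applies a linear map to per-label scores.
    """

    def __init__(
        self,
        vocab: dict[str, int],
        relation_labels: Sequence[str],
        emb_dim: int = 16,
        seed: int = 0,
        init_scale: float = 0.1,
    ):
        self.vocab = vocab
        self.labels = list(relation_labels)
        self.label_index = {l: i for i, l in enumerate(self.labels)}
        V = len(vocab) + _N_RESERVED
        C = len(self.labels)
        rng = np.random.default_rng(seed)
        self._p = ParamSet(
            {
                "emb": rng.uniform(-init_scale, init_scale, (V, emb_dim)) if init_scale else np.zeros((V, emb_dim)),
                "w_cls": np.zeros((3 * emb_dim, C)),
                "b_cls": np.zeros(C),
            }
        )
        self.emb_dim = emb_dim

    @property
    def params(self) -> ParamSet:
        return self._p

    def set_params(self, params: ParamSet) -> None:
        self._p._check_compat(params)
        self._p = params.copy()

    def _pools(self, instance: RelationInstance):
        if instance.head.end > len(instance.tokens) or instance.tail.end > len(instance.tokens):
            raise ValueError("entity span out of range")
        p = self._p
        ids = np.array([_lookup(self.vocab, t) for t in instance.tokens], dtype=int)
        E = p["emb"][ids]
        pooled = np.concatenate(
            [
                E[instance.head.start : instance.head.end].mean(axis=0),
                E[instance.tail.start : instance.tail.end].mean(axis=0),
                E.mean(axis=0),
            ]
        )
        return ids, E, pooled

    def forward(self, instance: RelationInstance) -> np.ndarray:
        """Per-label scores; softmax of these is the predicted distribution."""
        _, _, pooled = self._pools(instance)
        return pooled @ self._p["w_cls"] + self._p["b_cls"]

    def predict_proba(self, instance: RelationInstance) -> np.ndarray:
        s = self.forward(instance)
        s = s - s.max()
        e = np.exp(s)
        return e / e.sum()

    def predict_label(self, instance: RelationInstance) -> str:
        return self.labels[int(np.argmax(self.forward(instance)))]

    def loss_and_grad(self, batch: Sequence[RelationInstance]):
        if not batch:
            raise ValueError("empty batch")
        p = self._p
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        total = 0.0
        d = self.emb_dim
        for inst in batch:
            ids, E, pooled = self._pools(inst)
            scores = pooled @ p["w_cls"] + p["b_cls"]
            shifted = scores - scores.max()
            logp = shifted - np.log(np.exp(shifted).sum())
            gold = self.label_index[inst.label]
            total += -logp[gold]
            dscore = np.exp(logp)
            dscore[gold] -= 1.0
            grads["w_cls"] += np.outer(pooled, dscore)
            grads["b_cls"] += dscore
            dpool = p["w_cls"] @ dscore  # 3d
            dE = np.zeros_like(E)
            L = len(ids)
            hs, he = inst.head.start, inst.head.end
            ts, te = inst.tail.start, inst.tail.end
            dE[hs:he] += dpool[:d] / (he - hs)
            dE[ts:te] += dpool[d : 2 * d] / (te - ts)
            dE += dpool[2 * d :] / L
            np.add.at(grads["emb"], ids, dE)
        n = len(batch)
        return total / n, ParamSet({k: v / n for k, v in grads.items()})


# ---------------------------------------------------------------------------
# Shared helpers


def gradient(model, batch, reference: ParamSet | None = None, mu: float = 0.0) -> ParamSet:
    """Mean task-loss gradient plus the proximal gradient ``mu * (w - reference)``."""
    if not batch:
        raise ValueError("empty batch")
    _, grad = model.loss_and_grad(batch)
    if reference is not None and mu != 0.0:
        grad = grad + mu * (model.params - reference)
    return grad


def prox_loss(model, batch, reference: ParamSet | None = None, mu: float = 0.0) -> float:
    loss, _ = model.loss_and_grad(batch)
    if reference is not None and mu != 0.0:
        loss += 0.5 * mu * model.params.sq_dist(reference)
    return loss


def count_params(model_or_params) -> int:
    """Total scalar count across a model's (or a ParamSet's) arrays."""
    ps = model_or_params.params if hasattr(model_or_params, "params") else model_or_params
    return ps.n_params
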