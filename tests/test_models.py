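import itertools

import numpy as np
import pytest

from fedbionlp.corpus_io import Corpus, TaggedSentence
from fedbionlp.models import (
    LinearTagger,
    ParamSet,
    REModel,
    TaggerModel,
    build_vocab,
    count_params,
    crf_log_partition,
    crf_nll,
    gradient,
    viterbi,
)
from fedbionlp.synthetic import GenConfig, generate_ner, generate_re, make_sources

RNG = np.random.default_rng(20240901)


def brute_force_paths(emissions, transitions, start, stop):
    """Score of every tag path, by exhaustive enumeration."""
    L, T = emissions.shape
    out = {}
    for path in itertools.product(range(T), repeat=L):
        s = start[path[0]] + stop[path[-1]]
        s += sum(emissions[t, path[t]] for t in range(L))
        s += sum(transitions[path[t], path[t + 1]] for t in range(L - 1))
        out[path] = s
    return out


def random_crf(rng, max_L=4, max_T=4):
    L = int(rng.integers(1, max_L + 1))
    T = int(rng.integers(1, max_T + 1))
    return (
        rng.normal(size=(L, T)),
        rng.normal(size=(T, T)),
        rng.normal(size=T),
        rng.normal(size=T),
    )


class TestCrfPartition:
    def test_single_token_two_tags_all_zero(self):
        z = crf_log_partition(np.zeros((1, 2)), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        assert z == pytest.approx(np.log(2.0))

    def test_two_tokens_two_tags_all_zero(self):
        z = crf_log_partition(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        assert z == pytest.approx(np.log(4.0))

    def test_matches_exhaustive_path_sum(self):
        for _ in range(50):
            em, tr, st, sp = random_crf(RNG)
            scores = np.array(list(brute_force_paths(em, tr, st, sp).values()))
            expected = np.logaddexp.reduce(scores)
            assert crf_log_partition(em, tr, st, sp) == pytest.approx(expected, abs=1e-8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            crf_log_partition(np.zeros((0, 2)), np.zeros((2, 2)), np.zeros(2), np.zeros(2))


class TestCrfNll:
    def test_closed_form_single_token(self):
        em = np.array([[10.0, 0.0]])
        nll = crf_nll(em, np.zeros((2, 2)), np.zeros(2), np.zeros(2), [0])
        assert nll == pytest.approx(np.log(1 + np.exp(-10.0)))

    def test_nonnegative_and_matches_enumeration(self):
        for _ in range(20):
            em, tr, st, sp = random_crf(RNG)
            L, T = em.shape
            gold = tuple(int(g) for g in RNG.integers(0, T, L))
            paths = brute_force_paths(em, tr, st, sp)
            logz = np.logaddexp.reduce(np.array(list(paths.values())))
            expected = -(paths[gold] - logz)
            nll = crf_nll(em, tr, st, sp, gold)
            assert nll >= -1e-12
            assert nll == pytest.approx(expected, abs=1e-8)


class TestViterbi:
    def test_per_token_argmax_without_transitions(self):
        em = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert viterbi(em, np.zeros((2, 2)), np.zeros(2), np.zeros(2)) == [0, 1]

    def test_all_zero_scores_tie_break_to_smallest(self):
        assert viterbi(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros(3), np.zeros(3)) == [0, 0, 0]

    def test_matches_exhaustive_argmax_with_lexicographic_ties(self):
        for _ in range(50):
            em, tr, st, sp = random_crf(RNG)
            paths = brute_force_paths(em, tr, st, sp)
            best = max(paths.values())
            winners = sorted(p for p, s in paths.items() if s >= best - 1e-12)
            assert tuple(viterbi(em, tr, st, sp)) == winners[0]

    def test_path_score_never_exceeds_log_partition(self):
        for _ in range(20):
            em, tr, st, sp = random_crf(RNG)
            path = viterbi(em, tr, st, sp)
            score = brute_force_paths(em, tr, st, sp)[tuple(path)]
            assert score <= crf_log_partition(em, tr, st, sp) + 1e-12


class TestParamSet:
    def test_linear_combination_preserves_names_and_shapes(self):
        a = ParamSet({"w": np.ones((2, 3)), "b": np.zeros(2)})
        b = ParamSet({"w": np.full((2, 3), 2.0), "b": np.ones(2)})
        c = 0.5 * a + 0.5 * b
        assert set(c) == {"w", "b"}
        assert np.allclose(c["w"], 1.5)

    def test_self_distance_zero(self):
        a = ParamSet({"w": np.arange(6.0).reshape(2, 3)})
        assert a.sq_dist(a) == 0.0

    def test_shape_mismatch_rejected(self):
        a = ParamSet({"w": np.ones(3)})
        b = ParamSet({"w": np.ones(4)})
        with pytest.raises(ValueError):
            a + b

    def test_count_params(self):
        assert count_params(ParamSet({"w": np.zeros((10, 3))})) == 30
        assert count_params(ParamSet({})) == 0

    def test_tagger_count_matches_declared_dims(self, ner_vocab, tag_inventory):
        V = len(ner_vocab) + 3
        d = h = 4
        T = len(tag_inventory)
        model = TaggerModel(ner_vocab, tag_inventory, emb_dim=d, hidden=h, seed=0)
        expected = (
            V * d + 2 * (d * h + h * h + h) + 2 * h * T + T + T * T + 2 * T
        )
        assert count_params(model) == expected


def _fd_relative_error(model, batch, mu, reference):
    """Directional finite-difference check of the analytic gradient."""
    w0 = model.params.copy()
    g = gradient(model, batch, reference=reference, mu=mu)
    rng = np.random.default_rng(17)
    d = ParamSet({k: rng.normal(size=v.shape) for k, v in w0.items()})

    def loss_at(w):
        model.set_params(w)
        loss, _ = model.loss_and_grad(batch)
        if mu and reference is not None:
            loss += 0.5 * mu * model.params.sq_dist(reference)
        return loss

    h = 1e-6
    numeric = (loss_at(w0 + h * d) - loss_at(w0 + (-h) * d)) / (2 * h)
    analytic = float(np.dot(g.flatten(), d.flatten()))
    model.set_params(w0)
    return abs(numeric - analytic) / max(1e-12, abs(numeric))


@pytest.fixture(scope="module")
def setup():
    source = make_sources(1, 1.0, seed=3)[0]
    ner = generate_ner(source, GenConfig(n_sentences=5, seed=1))
    re = generate_re(source, GenConfig(n_sentences=5, seed=1))
    tags = ["O"] + [
        p + t for t in ("CHEMICAL", "DISEASE", "GENE") for p in ("B-", "I-")
    ]
    return ner, re, tags


class TestGradients:
    @pytest.mark.parametrize("mu", [0.0, 0.5])
    @pytest.mark.parametrize("family", ["linear", "rnn_crf", "re"])
    def test_finite_difference_agreement(self, setup, family, mu):
        ner, re, tags = setup
        if family == "linear":
            model = LinearTagger(build_vocab([ner]), tags, seed=0, init_scale=0.1)
            batch = list(ner)
        elif family == "rnn_crf":
            model = TaggerModel(build_vocab([ner]), tags, emb_dim=5, hidden=4, seed=0)
            batch = list(ner)
        else:
            model = REModel(build_vocab([re]), sorted(re.type_inventory), emb_dim=5, seed=0)
            batch = list(re)
        reference = None
        if mu:
            rng = np.random.default_rng(8)
            reference = ParamSet(
                {k: rng.normal(0, 0.05, v.shape) for k, v in model.params.items()}
            )
        assert _fd_relative_error(model, batch, mu, reference) <= 1e-5

    def test_proximal_term_vanishes_at_mu_zero_and_at_reference(self, setup):
        ner, _, tags = setup
        model = LinearTagger(build_vocab([ner]), tags, seed=0, init_scale=0.1)
        batch = list(ner)
        base = gradient(model, batch)
        ref = model.params.copy()
        assert gradient(model, batch, reference=ref, mu=0.0).equal(base)
        assert gradient(model, batch, reference=ref, mu=10.0).allclose(base)

    def test_empty_batch_rejected(self, setup):
        ner, _, tags = setup
        model = LinearTagger(build_vocab([ner]), tags)
        with pytest.raises(ValueError):
            gradient(model, [])


class TestLinearTaggerTraining:
    def test_full_batch_gd_reaches_perfect_accuracy(self):
        """Convex model on separable synthetic data trains to accuracy 1."""
        source = make_sources(1, 1.0, seed=5)[0]
        train = generate_ner(source, GenConfig(n_sentences=30, seed=7))
        tags = ["O"] + [
            p + t for t in ("CHEMICAL", "DISEASE", "GENE") for p in ("B-", "I-")
        ]
        model = LinearTagger(build_vocab([train]), tags, seed=0)
        batch = list(train)
        for _ in range(200):
            _, g = model.loss_and_grad(batch)
            model.set_params(model.params - 10.0 * g)
        acc = np.mean(
            [t == p for s in train for t, p in zip(s.tags, model.predict_tags(s))]
        )
        assert acc == 1.0


class TestREModel:
    def test_zero_init_gives_uniform_distribution(self, re_corpus):
        model = REModel(
            build_vocab([re_corpus]), sorted(re_corpus.type_inventory),
            emb_dim=4, seed=0, init_scale=0.0,
        )
        proba = model.predict_proba(re_corpus.records[0])
        assert np.allclose(proba, 1.0 / len(proba))

    def test_single_label_model_gives_probability_one(self, re_corpus):
        rec = re_corpus.records[0]
        model = REModel(build_vocab([re_corpus]), [rec.label], emb_dim=4, seed=0)
        assert model.predict_proba(rec)[0] == pytest.approx(1.0)

    def test_outside_tokens_only_move_the_sentence_pool(self, re_corpus):
        """Permuting tokens outside both entity spans changes only the
        sentence-mean pool, so scores shift by exactly that term."""
        model = REModel(
            build_vocab([re_corpus]), sorted(re_corpus.type_inventory),
            emb_dim=4, seed=1,
        )
        rec = next(
            r for r in re_corpus
            if r.head.start > 0 or r.tail.end < len(r.tokens)
        )
        inside = set(range(rec.head.start, rec.head.end)) | set(
            range(rec.tail.start, rec.tail.end)
        )
        outside = [i for i in range(len(rec.tokens)) if i not in inside]
        if len(outside) < 2:
            pytest.skip("no permutable context in sampled instance")
        perm = list(rec.tokens)
        perm[outside[0]], perm[outside[-1]] = perm[outside[-1]], perm[outside[0]]
        from dataclasses import replace

        swapped = replace(rec, tokens=tuple(perm))
        # a permutation leaves the sentence mean unchanged, hence the scores
        assert np.allclose(model.forward(rec), model.forward(swapped))

    def test_span_out_of_range_rejected(self, re_corpus):
        from dataclasses import replace

        from fedbionlp.corpus_io import CorpusError, EntitySpan

        rec = re_corpus.records[0]
        model = REModel(build_vocab([re_corpus]), sorted(re_corpus.type_inventory))
        with pytest.raises((ValueError, CorpusError)):
            bad = replace(rec, head=EntitySpan(0, len(rec.tokens) + 5, "GENE"))
            model.forward(bad)
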