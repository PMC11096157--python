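import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from fedbionlp.corpus_io import Corpus, EntitySpan, TaggedSentence, tags_from_spans
from fedbionlp.evaluation import (
    MatchCounts,
    evaluate_ner,
    evaluate_re,
    format_mean_sd,
    match_entities,
    prf,
    summarize_repeats,
)

G = lambda a, b: EntitySpan(a, b, "GENE")
D = lambda a, b: EntitySpan(a, b, "DISEASE")


def max_matching_tp(gold, pred, scheme):
    """Brute-force maximum one-to-one matching via assignment."""
    from fedbionlp.evaluation import _compatible

    if not gold or not pred:
        return 0
    cost = np.zeros((len(gold), len(pred)))
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            cost[i, j] = -1.0 if _compatible(g, p, scheme) else 0.0
    rows, cols = linear_sum_assignment(cost)
    return int(-cost[rows, cols].sum())


def random_span_sets(rng, length=20, max_spans=5):
    def one():
        cuts = sorted(rng.choice(length + 1, size=2 * max_spans, replace=False))
        spans = []
        for a, b in zip(cuts[::2], cuts[1::2]):
            if rng.random() < 0.6 and a < b:
                spans.append(EntitySpan(int(a), int(b), rng.choice(["GENE", "DISEASE"])))
        return spans

    return one(), one()


class TestMatchEntities:
    def test_exact_match(self):
        c = match_entities([G(0, 2)], [G(0, 2)], "strict")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_boundary_error_strict_vs_lenient(self):
        strict = match_entities([G(0, 2)], [G(1, 3)], "strict")
        lenient = match_entities([G(0, 2)], [G(1, 3)], "lenient")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        assert (lenient.tp, lenient.fp, lenient.fn) == (1, 0, 0)

    def test_type_mismatch_not_credited_leniently(self):
        gold = [G(0, 2), D(4, 5)]
        pred = [G(0, 1), G(4, 5)]
        c = match_entities(gold, pred, "lenient")
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)
        # the greedy result equals the brute-force optimum on this instance
        assert c.tp == max_matching_tp(gold, pred, "lenient")

    def test_overlapping_gold_rejected(self):
        with pytest.raises(ValueError):
            match_entities([G(0, 3), G(2, 5)], [], "strict")

    def test_swap_symmetry_strict(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            gold, pred = random_span_sets(rng)
            try:
                a = match_entities(gold, pred, "strict")
                b = match_entities(pred, gold, "strict")
            except ValueError:
                continue
            assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)

    def test_greedy_matches_bruteforce_strict_and_bounded_lenient(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            gold, pred = random_span_sets(rng)
            for scheme in ("strict", "lenient"):
                greedy = match_entities(gold, pred, scheme).tp
                optimal = max_matching_tp(gold, pred, scheme)
                if scheme == "strict":
                    assert greedy == optimal
                else:
                    assert greedy <= optimal


class TestPrf:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1, 1), (0.5, 0.5, 0.5)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
            ((1, 0, 1), (1.0, 0.5, 2.0 / 3.0)),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert prf(MatchCounts(*counts)) == pytest.approx(expected)


class _FixedTagger:
    """Replays a canned tag sequence per sentence (keyed by first token)."""

    def __init__(self, predictions):
        self.predictions = predictions

    def predict_tags(self, sentence):
        return list(self.predictions[sentence.tokens[0]])


class TestEvaluateNer:
    def _corpus(self):
        sents = [
            TaggedSentence(("s1", "a", "b"), ("O", "B-GENE", "I-GENE")),
            TaggedSentence(("s2", "c"), ("B-DISEASE", "O")),
            TaggedSentence(("s3", "d", "e"), ("O", "B-GENE", "O")),
        ]
        return Corpus("ner", tuple(sents))

    def test_perfect_predictions_give_macro_one(self):
        corpus = self._corpus()
        model = _FixedTagger({s.tokens[0]: s.tags for s in corpus})
        for scheme in ("strict", "lenient"):
            assert evaluate_ner(model, corpus, scheme).macro_f1 == 1.0

    def test_all_o_predictions_give_macro_zero(self):
        corpus = self._corpus()
        model = _FixedTagger({s.tokens[0]: ("O",) * len(s) for s in corpus})
        assert evaluate_ner(model, corpus, "lenient").macro_f1 == 0.0

    def test_hand_tallied_report(self):
        """GENE: one boundary error + one exact hit; DISEASE: one missed gold."""
        corpus = self._corpus()
        model = _FixedTagger(
            {
                "s1": ("O", "B-GENE", "O"),       # gold (1,3,G): strict FP+FN, lenient TP
                "s2": ("O", "O"),                  # gold (0,1,D): FN
                "s3": ("O", "B-GENE", "O"),       # gold (1,2,G): exact TP
            }
        )
        strict = evaluate_ner(model, corpus, "strict")
        # GENE strict: tp=1 fp=1 fn=1 -> P=R=F=0.5 ; DISEASE: 0
        assert strict.per_type["GENE"] == pytest.approx((0.5, 0.5, 0.5))
        assert strict.per_type["DISEASE"] == (0.0, 0.0, 0.0)
        assert strict.macro_f1 == pytest.approx(0.25)
        lenient = evaluate_ner(model, corpus, "lenient")
        # GENE lenient: tp=2 -> perfect; macro = (1 + 0)/2
        assert lenient.per_type["GENE"] == pytest.approx((1.0, 1.0, 1.0))
        assert lenient.macro_f1 == pytest.approx(0.5)

    def test_empty_corpus_rejected(self):
        model = _FixedTagger({})
        with pytest.raises(ValueError):
            evaluate_ner(model, Corpus("ner", ()), "strict")


class _ConstantRE:
    def __init__(self, labels, always):
        self.labels = list(labels)
        self.always = always

    def predict_label(self, instance):
        return self.always


class TestEvaluateRe:
    def _balanced(self):
        from fedbionlp.corpus_io import RelationInstance

        recs = []
        for i in range(10):
            label = "assoc" if i % 2 == 0 else "none"
            recs.append(
                RelationInstance(
                    ("a", "b", "c"), EntitySpan(0, 1, "G"), EntitySpan(2, 3, "D"), label
                )
            )
        return Corpus("re", tuple(recs))

    def test_perfect_classifier(self):
        corpus = self._balanced()

        class Echo:
            labels = ["assoc", "none"]

            def predict_label(self, inst):
                return inst.label

        assert evaluate_re(Echo(), corpus).macro_f1 == 1.0

    def test_constant_prediction_on_balanced_two_labels(self):
        corpus = self._balanced()
        report = evaluate_re(_ConstantRE(["assoc", "none"], "assoc"), corpus)
        # predicted label: P=0.5, R=1 -> F=2/3; other label F=0; macro = 1/3
        assert report.macro_f1 == pytest.approx(1.0 / 3.0)

    def test_matches_sklearn_macro_f1(self):
        """Confusion-count macro-F1 agrees with scikit-learn on random labels."""
        from sklearn.metrics import f1_score

        from fedbionlp.corpus_io import RelationInstance

        rng = np.random.default_rng(3)
        labels = ["r1", "r2", "r3"]
        gold = rng.choice(labels, size=200)
        pred = rng.choice(labels, size=200)
        recs = tuple(
            RelationInstance(("x", "y"), EntitySpan(0, 1, "G"), EntitySpan(1, 2, "D"), g)
            for g in gold
        )
        corpus = Corpus("re", recs)

        class Replay:
            def __init__(self):
                self.i = -1
                self.labels = labels

            def predict_label(self, inst):
                self.i += 1
                return str(pred[self.i])

        ours = evaluate_re(Replay(), corpus).macro_f1
        ref = f1_score(gold, pred, labels=labels, average="macro", zero_division=0)
        assert ours == pytest.approx(ref)

    def test_label_coverage_enforced(self):
        corpus = self._balanced()
        with pytest.raises(ValueError):
            evaluate_re(_ConstantRE(["assoc"], "assoc"), corpus)


class TestSummarizeRepeats:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.8, 0.9, 1.0], (0.9, 0.1)),
            ([0.5], (0.5, 0.0)),
            ([0.7, 0.7, 0.7], (0.7, 0.0)),
        ],
    )
    def test_mean_and_sample_sd(self, scores, expected):
        mean, sd = summarize_repeats(scores)
        assert (mean, sd) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_repeats([])

    def test_three_decimal_formatting(self):
        assert format_mean_sd(0.8764, 0.0044) == "0.876 ± 0.004"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_strict_f1_never_exceeds_lenient_f1(data):
    """Exact-boundary credit is a subset of overlap credit."""
    length = 15

    def draw_spans():
        cuts = sorted(
            data.draw(st.lists(st.integers(0, length), max_size=8, unique=True))
        )
        spans = []
        for a, b in zip(cuts[::2], cuts[1::2]):
            if a < b and data.draw(st.booleans()):
                spans.append(
                    EntitySpan(a, b, data.draw(st.sampled_from(["GENE", "DISEASE"])))
                )
        return spans

    gold, pred = draw_spans(), draw_spans()
    strict = match_entities(gold, pred, "strict")
    lenient = match_entities(gold, pred, "lenient")
    assert strict.tp <= lenient.tp
    assert prf(strict)[2] <= prf(lenient)[2] + 1e-12
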