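"""Rollup matching, precision/recall conventions, time-sliced reports."""

import numpy as np
import pytest

from tcmrec import evaluate as ev
from tcmrec.evaluate import MatchCounts, match_counts, precision_recall
from tcmrec.features import extract_tokens
from tcmrec.pipeline import label_vector

from conftest import random_ontology


def brute_force_counts(onto, predicted, reference):
    pred = {onto.first_category(d) for d in predicted}
    ref = {onto.first_category(d) for d in reference}
    tp = sum(1 for p in pred if p in ref)
    fp = sum(1 for p in pred if p not in ref)
    fn = sum(1 for r in ref if r not in pred)
    return tp, fp, fn


class TestMatchCounts:
    def test_sibling_leaves_count_as_match(self, tiny_onto):
        c = match_counts(tiny_onto, {"X.a.1"}, {"X.b.1"})
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_empty_prediction(self, tiny_onto):
        c = match_counts(tiny_onto, set(), {"X.a.1", "Y.a.1", "W"})
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_identical_sets(self, tiny_onto):
        s = {"X.a.1", "X.a.2", "Y.a.1"}
        c = match_counts(tiny_onto, s, s)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == len(tiny_onto.rollup(s)) == 2

    def test_swap_exchanges_fp_fn(self, tiny_onto):
        a, b = {"X.a.1", "W"}, {"X.b.1", "Y.a.1"}
        c1 = match_counts(tiny_onto, a, b)
        c2 = match_counts(tiny_onto, b, a)
        assert c1.tp == c2.tp and c1.fp == c2.fn and c1.fn == c2.fp

    def test_unknown_drug_rejected(self, tiny_onto):
        with pytest.raises(KeyError):
            match_counts(tiny_onto, {"ghost"}, {"X"})

    def test_category2_level_distinguishes_formulas(self, tiny_onto):
        c = match_counts(tiny_onto, {"X.a.1"}, {"X.b.1"}, level="category2")
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            onto = random_ontology(rng)
            ids = list(onto.nodes)
            pred = set(rng.choice(ids, size=rng.integers(0, 5)))
            ref = set(rng.choice(ids, size=rng.integers(0, 5)))
            c = match_counts(onto, pred, ref)
            assert (c.tp, c.fp, c.fn) == brute_force_counts(onto, pred, ref)


class TestPrecisionRecall:
    @pytest.mark.parametrize("tp,fp,fn,p,r", [
        (3, 1, 2, 0.75, 0.6),
        (0, 0, 0, 1.0, 1.0),
        (6, 0, 6, 1.0, 0.5),
        (0, 4, 0, 0.0, 1.0),
        (0, 0, 5, 1.0, 0.0),
    ])
    def test_examples_and_conventions(self, tp, fp, fn, p, r):
        assert precision_recall(MatchCounts(tp, fp, fn)) == (p, r)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchCounts(-1, 0, 0)

    def test_counts_add(self):
        c = MatchCounts(1, 2, 3) + MatchCounts(4, 5, 6)
        assert (c.tp, c.fp, c.fn) == (5, 7, 9)


class _OracleModel:
    """Stub predictor that reads the reference straight from the dataset
    mapping patient+cutoff -> label indices."""

    def __init__(self, answers, max_num_tokens, n_labels):
        from tcmrec.model import TransformerConfig
        self.cfg = TransformerConfig.desk_scale(
            n_labels=n_labels, max_num_tokens=max_num_tokens, model_dim=32)
        self._answers = answers

    def predict_sets(self, X, M, threshold=None):
        return [self._answers.pop(0) for _ in range(X.shape[0])]


class _EmptyModel(_OracleModel):
    def predict_sets(self, X, M, threshold=None):
        return [set() for _ in range(X.shape[0])]


@pytest.fixture(scope="module")
def eval_setup(small_cohort):
    from tcmrec.embed import EmbedConfig, train_embeddings
    cfg, onto, records = small_cohort
    corpus = [extract_tokens(r, 168.0) for r in records]
    emb = train_embeddings(corpus, EmbedConfig(vector_size=8, epochs=2, seed=0))
    return onto, records, emb


class TestEvaluateTimeline:
    CUTS = (0.0, 24.0, 168.0)

    def test_oracle_predictor_scores_perfectly(self, eval_setup):
        onto, records, emb = eval_setup
        cats = onto.category1_ids()
        answers = []
        for cut in self.CUTS:
            for r in records:
                y = label_vector(r.order_at(cut).drug_ids, onto, cats)
                answers.append(set(np.flatnonzero(y).tolist()))
        model = _OracleModel(answers, 64, len(cats))
        rep = ev.evaluate_timeline(model, records, onto, emb, cats,
                                   cutoffs=self.CUTS)
        assert (rep.precision == 1.0).all() and (rep.recall == 1.0).all()

    def test_empty_predictor_convention(self, eval_setup):
        onto, records, emb = eval_setup
        cats = onto.category1_ids()
        rep = ev.evaluate_timeline(_EmptyModel([], 64, len(cats)), records,
                                   onto, emb, cats, cutoffs=(0.0,))
        assert rep.precision[0] == 1.0 and rep.recall[0] == 0.0

    def test_missing_order_skipped_and_counted(self, eval_setup):
        onto, records, emb = eval_setup
        cats = onto.category1_ids()
        trimmed = [r for r in records]
        trimmed[0] = type(records[0])(
            patient_id=records[0].patient_id,
            demographics=records[0].demographics,
            facts=records[0].facts, orders=[], meta={})
        rep = ev.evaluate_timeline(_EmptyModel([], 64, len(cats)), trimmed,
                                   onto, emb, cats, cutoffs=(0.0,))
        assert rep.n_skipped[0] == 1
        assert rep.n_patients[0] == len(records) - 1

    def test_macro_and_micro_in_unit_interval(self, eval_setup):
        onto, records, emb = eval_setup
        cats = onto.category1_ids()
        for agg in ("micro", "macro"):
            rep = ev.evaluate_timeline(_EmptyModel([], 64, len(cats)), records,
                                       onto, emb, cats, cutoffs=(0.0,), agg=agg)
            assert 0.0 <= rep.precision[0] <= 1.0
            assert 0.0 <= rep.recall[0] <= 1.0


def test_render_table_layout(eval_setup):
    onto, records, emb = eval_setup
    cats = onto.category1_ids()
    rep = ev.evaluate_timeline(_EmptyModel([], 64, len(cats)), records, onto,
                               emb, cats, cutoffs=(0.0, 24.0))
    text = ev.render_table(rep, rep)
    assert "Admission" in text and "In 24 hours" in text
    assert "Test precision (%)" in text
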