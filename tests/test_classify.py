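"""Metrics, cross-validation and the experiment runners."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from negev.classify import (
    ALGORITHMS,
    ConfusionCounts,
    EvalReport,
    ModelSpec,
    confusion,
    cross_validate,
    lexical_baseline,
    micro_average,
    prf,
    run_cue_list_experiment,
    run_split_experiment,
    train,
)
from negev.features import featurize_corpus, vectorize
from negev.synthetic_corpus import GeneratorConfig, generate


def _counts_for(p_pct: float, r_pct: float) -> ConfusionCounts:
    """Integer confusion counts realising exact printed precision/recall
    percentages (one decimal)."""
    p, r = round(p_pct * 10), round(r_pct * 10)  # per-mille integers
    tp = p * r
    fp = (1000 - p) * r
    fn = p * (1000 - r)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


@pytest.mark.parametrize(
    "p_pct, r_pct, f_pct",
    [
        (83.1, 67.1, 74.2),  # best corpus-level random-forest result
        (86.1, 84.5, 85.3),
        (77.6, 63.9, 70.1),
        (31.6, 83.0, 45.8),  # high-recall/low-precision naive Bayes regime
    ],
)
def test_f_score_reproduces_published_worked_examples(p_pct, r_pct, f_pct):
    """The harmonic mean reproduces published F-scores from their printed
    precision/recall pairs after rounding to one decimal."""
    c = _counts_for(p_pct, r_pct)
    p, r, f = prf(c)
    assert round(100 * p, 1) == p_pct
    assert round(100 * r, 1) == r_pct
    assert round(100 * f, 1) == f_pct


def test_prf_zero_convention():
    assert prf(ConfusionCounts()) == (0.0, 0.0, 0.0)


@given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000))
@settings(deadline=None, derandomize=True)
def test_prf_bounds(tp, fp, fn):
    p, r, f = prf(ConfusionCounts(tp=tp, fp=fp, fn=fn))
    assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0
    assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12


def _report(*counts) -> EvalReport:
    return EvalReport([ConfusionCounts(*c) for c in counts], ModelSpec(), 0)


def test_micro_average_identity_and_equal_reports():
    rep = _report((5, 2, 3, 10))
    assert micro_average([rep]) == prf(rep.counts)
    assert micro_average([rep, rep]) == prf(rep.counts)


@given(st.lists(st.tuples(*[st.integers(0, 50)] * 4), min_size=1, max_size=5))
@settings(deadline=None, derandomize=True)
def test_micro_average_pools_counts_not_scores(counts):
    """Micro averaging equals P/R/F of the summed counts, which generally
    differs from the mean of per-report P/R/F."""
    reports = [_report(c) for c in counts]
    pooled = ConfusionCounts()
    for c in counts:
        pooled = pooled + ConfusionCounts(*c)
    assert micro_average(reports) == prf(pooled)


def test_report_aggregate_equals_fold_sum():
    rep = _report((5, 2, 3, 10), (1, 0, 4, 20))
    assert rep.counts == ConfusionCounts(6, 2, 7, 30)


# ---------------------------------------------------------------------------
# training and cross-validation

def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    X = np.c_[y + 0.01 * rng.random(n), rng.random(n)]
    return X, y


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_training_set_perfect_on_separable_data(algo):
    X, y = _separable()
    model = train(X, y, ModelSpec(algo, seed=3))
    c = confusion(y, model.predict(X))
    assert prf(c)[2] == 1.0


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_fixed_seed_reproducible_predictions(algo):
    X, y = _separable(seed=5)
    p1 = train(X, y, ModelSpec(algo, seed=7)).predict(X)
    p2 = train(X, y, ModelSpec(algo, seed=7)).predict(X)
    assert np.array_equal(p1, p2)


def test_single_class_training_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        train(X, np.zeros(10, dtype=int), ModelSpec())


def test_unknown_algorithm_rejected():
    with pytest.raises(ValueError):
        ModelSpec("perceptron")


def test_cross_validation_partition_properties():
    """Fold test sizes differ by at most one and jointly cover each row
    exactly once (aggregate counts sum to n)."""
    X, y = _separable(n=83, seed=9)
    rep = cross_validate(X, y, ModelSpec("decision_tree", seed=1), k=10)
    sizes = [c.tp + c.fp + c.fn + c.tn for c in rep.folds]
    assert sum(sizes) == 83
    assert max(sizes) - min(sizes) <= 1
    assert len(rep.folds) == 10


def test_tiny_minority_class_degrades_with_warning():
    rng = np.random.default_rng(0)
    X = rng.random((40, 3))
    y = np.zeros(40, dtype=int)
    y[:4] = 1
    with pytest.warns(UserWarning):
        rep = cross_validate(X, y, ModelSpec("decision_tree", seed=0), k=10)
    assert len(rep.folds) == 4


def test_permuted_labels_score_near_chance():
    """With labels shuffled independently of the features, cross-validated
    F lands near the positive base rate."""
    rng = np.random.default_rng(21)
    n, base = 600, 0.3
    X = rng.random((n, 6))
    y = (rng.random(n) < base).astype(int)
    rep = cross_validate(X, y, ModelSpec("decision_tree", seed=2), k=10)
    assert abs(rep.f_score - base) < 0.15


# ---------------------------------------------------------------------------
# experiment runners

@pytest.fixture(scope="module")
def tiny_corpus():
    return generate(GeneratorConfig(n_sentences=250, seed=77))


def test_cue_list_experiment_shape_and_sanity(tiny_corpus):
    docs, backend, _ = tiny_corpus
    table = run_cue_list_experiment(docs, backend,
                                    spec=ModelSpec("random_forest", seed=1), k=5)
    assert list(table["cue_list"]) == ["c40", "cCore", "cBioInfer", "cBioScope"]
    assert ((table[["precision", "recall", "f_score"]] >= 0).all()).all()
    # c40 covers every planted cue type, so it cannot trail by much
    assert table.set_index("cue_list")["f_score"]["c40"] >= 0.5


def test_single_lexicon_run_equals_cross_validate(tiny_corpus, c40):
    docs, backend, _ = tiny_corpus
    table = run_cue_list_experiment(docs, backend, lexicons=[c40],
                                    spec=ModelSpec("random_forest", seed=4), k=5)
    rows = featurize_corpus(docs, backend, c40)
    X, y, _ = vectorize(rows)
    rep = cross_validate(X, y, ModelSpec("random_forest", seed=4), k=5)
    assert table.iloc[0]["f_score"] == pytest.approx(rep.f_score)


def test_two_way_split_class_sizes_match_generator(tiny_corpus):
    docs, backend, gold = tiny_corpus
    table = run_split_experiment(docs, backend, mode="two_way",
                                 spec=ModelSpec("random_forest", seed=5), k=5)
    sizes = table.set_index("class")["n_events"]
    n_complex = sum(1 for g in gold if g.is_complex)
    assert sizes["complex"] == n_complex
    assert sizes["simple"] == len(gold) - n_complex


def test_three_way_split_assignment_and_micro_average(tiny_corpus):
    docs, backend, _ = tiny_corpus
    table = run_split_experiment(docs, backend, mode="three_way",
                                 spec=ModelSpec("random_forest", seed=5), k=5)
    classes = set(table["class"])
    assert "micro_average" in classes and classes <= {
        "class_1", "class_2", "class_3", "micro_average"}


def test_three_way_split_rejects_unknown_event_type(tiny_corpus):
    docs, backend, _ = tiny_corpus
    orig = docs[0].events[0].event_type
    docs[0].events[0].event_type = "weird_type"
    try:
        with pytest.raises(ValueError, match="weird_type"):
            run_split_experiment(docs, backend, mode="three_way", k=5)
    finally:
        docs[0].events[0].event_type = orig


def test_baseline_counts_every_event(tiny_corpus):
    docs, backend, gold = tiny_corpus
    c = lexical_baseline(docs, backend, "c40")
    assert c.tp + c.fp + c.fn + c.tn == len(gold)
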