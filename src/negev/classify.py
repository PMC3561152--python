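"""Polarity classifiers, cross-validated evaluation and experiment runners.

Six learning algorithms are supported, each with the settings used in the
negated-bio-event framework (the positive class is always *negated*):

* ``random_forest`` — 10 trees, log2(N+1) features per split, unbounded
  depth;
* ``decision_tree`` — pruned tree, minimum 2 instances per leaf (the
  original C4.5 confidence-threshold pruning has no direct analogue in
  CART; a small fixed cost-complexity alpha stands in);
* ``logistic_regression``;
* ``naive_bayes`` — Gaussian likelihoods on the encoded attributes;
* ``svm_poly`` — polynomial kernel, complexity constant 1.0, with
  attribute normalisation applied inside this spec only;
* ``nearest_neighbor_1`` — IB1: single nearest neighbour under
  normalised Euclidean distance.

Evaluation is 10-fold stratified cross-validation; reports carry raw
per-fold TP/FP/FN/TN so results can be micro-averaged by pooling counts
(never by averaging P/R/F).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import features as ft
from .cue_lexicon import CueLexicon, load_lexicon
from .standoff_io import BIONLP_EVENT_TYPES, Document, is_complex

ALGORITHMS = (
    "random_forest",
    "decision_tree",
    "logistic_regression",
    "naive_bayes",
    "svm_poly",
    "nearest_neighbor_1",
)

#: deterministic given the data (no internal randomisation once seeded)
DETERMINISTIC_ALGORITHMS = frozenset(ALGORITHMS)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "random_forest"
    hyperparams: tuple = ()  # extra (key, value) overrides
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    def params(self) -> dict:
        return dict(self.hyperparams)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative confusion count")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def prf(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F-score (first harmonic mean), 0/0 -> 0."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


@dataclass
class EvalReport:
    folds: list[ConfusionCounts]
    spec: ModelSpec
    fold_seed: int

    @property
    def counts(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.folds:
            total = total + c
        return total

    @property
    def precision(self) -> float:
        return prf(self.counts)[0]

    @property
    def recall(self) -> float:
        return prf(self.counts)[1]

    @property
    def f_score(self) -> float:
        return prf(self.counts)[2]


def micro_average(reports: Iterable[EvalReport]) -> tuple[float, float, float]:
    """Pool raw counts across reports, then compute P/R/F."""
    total = ConfusionCounts()
    for rep in reports:
        total = total + rep.counts
    return prf(total)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
    )


def build_estimator(spec: ModelSpec, n_features: int):
    """Instantiate the scikit-learn estimator for a model spec."""
    p = spec.params()
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 10),
            max_features=p.get("max_features", max(1, int(math.log2(n_features + 1)))),
            max_depth=None,
            random_state=spec.seed,
        )
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(
            min_samples_leaf=p.get("min_samples_leaf", 2),
            ccp_alpha=p.get("ccp_alpha", 1e-3),
            random_state=spec.seed,
        )
    if spec.algorithm == "logistic_regression":
        return LogisticRegression(max_iter=p.get("max_iter", 1000))
    if spec.algorithm == "naive_bayes":
        return GaussianNB()
    if spec.algorithm == "svm_poly":
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("svm", SVC(kernel="poly", C=p.get("C", 1.0), random_state=spec.seed)),
            ]
        )
    if spec.algorithm == "nearest_neighbor_1":
        return Pipeline(
            [("scale", MinMaxScaler()), ("knn", KNeighborsClassifier(n_neighbors=1))]
        )
    raise AssertionError("unreachable")


@dataclass
class TrainedModel:
    estimator: object
    spec: ModelSpec

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)


def train(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> TrainedModel:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = build_estimator(spec, X.shape[1])
    est.fit(X, y)
    return TrainedModel(est, spec)


def cross_validate(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, k: int = 10,
    fold_seed: Optional[int] = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Folds come from a seeded shuffle; every row is tested exactly once.
    When a class has fewer than k members, stratification degrades
    gracefully (with a warning) by capping k at the minority count.
    """
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    seed = spec.seed if fold_seed is None else fold_seed
    minority = int(np.bincount(y).min())
    if minority < k:
        warnings.warn(
            f"minority class has {minority} members < {k} folds; using {minority} folds",
            stacklevel=2,
        )
        k = max(2, minority)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[ConfusionCounts] = []
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], spec)
        folds.append(confusion(y[test_idx], model.predict(X[test_idx])))
    return EvalReport(folds, spec, seed)


# ---------------------------------------------------------------------------
# experiment runners

def run_cue_list_experiment(
    corpus: Sequence[Document],
    backend,
    lexicons: Sequence[CueLexicon | str] = ("c40", "cCore", "cBioInfer", "cBioScope"),
    spec: ModelSpec = ModelSpec("random_forest"),
    k: int = 10,
) -> pd.DataFrame:
    """Re-featurize the corpus once per cue list and cross-validate a fixed
    model, yielding one P/R/F row per lexicon."""
    records = []
    for lex in lexicons:
        lexicon = load_lexicon(lex) if isinstance(lex, str) else lex
        rows = ft.featurize_corpus(corpus, backend, lexicon)
        X, y, _ = ft.vectorize(rows)
        rep = cross_validate(X, y, spec, k=k)
        records.append(
            {"cue_list": lexicon.name, "precision": rep.precision,
             "recall": rep.recall, "f_score": rep.f_score}
        )
    return pd.DataFrame.from_records(records)


def run_algorithm_experiment(
    corpus: Sequence[Document],
    backend,
    lexicon: CueLexicon | str = "cCore",
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    k: int = 10,
) -> pd.DataFrame:
    """Fixed cue list, one cross-validated P/R/F row per learning algorithm."""
    lex = load_lexicon(lexicon) if isinstance(lexicon, str) else lexicon
    rows = ft.featurize_corpus(corpus, backend, lex)
    X, y, _ = ft.vectorize(rows)
    records = []
    for algo in algorithms:
        rep = cross_validate(X, y, ModelSpec(algo, seed=seed), k=k)
        records.append(
            {"algorithm": algo, "precision": rep.precision,
             "recall": rep.recall, "f_score": rep.f_score}
        )
    return pd.DataFrame.from_records(records)


#: three-way event-type split: five "simple product" types, binding, regulation
THREE_WAY_CLASSES = {
    "class_1": ("localization", "transcription", "protein_catabolism",
                "gene_expression", "phosphorylation"),
    "class_2": ("binding",),
    "class_3": ("regulation", "positive_regulation", "negative_regulation"),
}


def run_split_experiment(
    corpus: Sequence[Document],
    backend,
    mode: str = "three_way",
    lexicon: CueLexicon | str = "c40",
    spec: ModelSpec = ModelSpec("random_forest"),
    k: int = 10,
) -> pd.DataFrame:
    """Train/test per event class and micro-average across classes.

    ``three_way`` partitions by event type (the nine shared-task types);
    ``two_way`` partitions into simple vs. complex events.  The returned
    frame has one row per class plus a pooled ``micro_average`` row.
    """
    lex = load_lexicon(lexicon) if isinstance(lexicon, str) else lexicon
    events = [(doc, ev) for doc in corpus for ev in doc.events]
    if mode == "three_way":
        type_to_class = {t: c for c, ts in THREE_WAY_CLASSES.items() for t in ts}
        assignment: dict[str, list] = {c: [] for c in THREE_WAY_CLASSES}
        for doc, ev in events:
            if ev.event_type not in type_to_class:
                raise ValueError(
                    f"event type {ev.event_type!r} outside the {len(BIONLP_EVENT_TYPES)} "
                    "shared-task types"
                )
            assignment[type_to_class[ev.event_type]].append((doc, ev))
    elif mode == "two_way":
        assignment = {"complex": [], "simple": []}
        for doc, ev in events:
            assignment["complex" if is_complex(ev) else "simple"].append((doc, ev))
    else:
        raise ValueError("mode must be 'three_way' or 'two_way'")

    rows_all = {r.event_id: r for r in ft.featurize_corpus(corpus, backend, lex)}
    records = []
    reports: list[EvalReport] = []
    for cls, members in assignment.items():
        cls_rows = [rows_all[f"{doc.doc_id}/{ev.id}"] for doc, ev in members]
        if not cls_rows:
            continue
        X, y, _ = ft.vectorize(cls_rows)
        if y is None or len(np.unique(y)) < 2 or int(np.bincount(y).min()) < 2:
            records.append({"class": cls, "n_events": len(cls_rows),
                            "precision": float("nan"), "recall": float("nan"),
                            "f_score": float("nan")})
            continue
        rep = cross_validate(X, y, spec, k=k)
        reports.append(rep)
        records.append({"class": cls, "n_events": len(cls_rows),
                        "precision": rep.precision, "recall": rep.recall,
                        "f_score": rep.f_score})
    p, r, f = micro_average(reports)
    records.append({"class": "micro_average",
                    "n_events": sum(len(m) for m in assignment.values()),
                    "precision": p, "recall": r, "f_score": f})
    return pd.DataFrame.from_records(records)


def lexical_baseline(
    corpus: Sequence[Document], backend, lexicon: CueLexicon | str
) -> ConfusionCounts:
    """Predict *negated* iff any active cue occurs in the event's sentence.

    The natural straw man: sentences holding a cue need not hold a negated
    event, so this baseline over-predicts and its precision bounds what
    cue presence alone can achieve.
    """
    lex = load_lexicon(lexicon) if isinstance(lexicon, str) else lexicon
    rows = ft.featurize_corpus(corpus, backend, lex)
    y_true = np.array([1 if r.gold_polarity == "negated" else 0 for r in rows])
    y_pred = np.array([1 if r.features["cue_present"] else 0 for r in rows])
    return confusion(y_true, y_pred)
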