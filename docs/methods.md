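# Methods

## Task and model

The package classifies the polarity of gold-annotated bio-events:
*positive* (the event is asserted) versus *negated* (the text asserts its
non-existence). Polarity classification is deliberately separated from
negation-*scope* detection: scopes are contiguous linguistic spans, while
events are information-centred structures whose trigger and participants
may lie outside a cue's scope — roughly half of the events whose trigger
falls inside a scope are not negated, and a substantial share of negated
events sit outside any scope. The model is therefore a per-event
supervised classifier over engineered features rather than a scope
resolver.

An event is represented by one fixed-width feature vector combining six
groups (syntactic, semantic, lexical, lexico-semantic, dependency,
constituency); the full inventory is in `features.FEATURE_GROUPS`.
Missing information is encoded by sentinels (`NONE`, `-1`, `False`)
rather than missing keys, so every vector has the same shape and
one-hot encoding is deterministic (sorted feature names, sorted category
levels, an explicit `NONE` level).

Two policies the literature leaves open are fixed here and isolated
behind single functions so they can be swapped:

* **Cue selection.** When a sentence holds several active cues, the cue
  whose head token is nearest the trigger head drives the cue-dependent
  features (leftmost on ties); deactivated cues are excluded from
  selection but still drive the deactivator features
  (`features.select_cue`).
* **Cue scope.** The syntactic scope of a cue is the contiguous token
  range from the cue to the right edge of the smallest clause-level
  constituent (label `S` or `SBAR`) dominating it, the whole sentence if
  no clause ancestor exists (`parse_layer.cue_scope`). This is the
  dominant convention in the scope-detection literature.

Two further conventions: dependency paths are taken over the *undirected*
graph, with per-edge direction markers (`label/up`, `label/down`)
preserved in the path labels; and the head of a multi-token span is the
token whose dependency head lies outside the span (rightmost on ties), a
standard head-percolation heuristic. Surface distances are measured in
tokens between head tokens. Events whose participants straddle sentence
boundaries are aligned to the sentence containing their trigger, since
all features are computed relative to that sentence.

## Cue lexicons

Four lists are packaged verbatim from their published forms: `c40` (40
entries), `cBioScope` (28), `cBioInfer` (25) and `cCore` (printed size
20, but 19 elements are enumerated; the package follows the elements and
records the printed size separately). Matching is lemma-based and
case-insensitive so inflected forms match citation forms; *lose*/*lost*
remain distinct entries because the source list prints them separately.
Multi-word entries (up to four lemmas, e.g. *with the exception of*) win
over their sub-spans by longest-match, left-to-right scanning. Entries
printed with *(noun)*/*(verb)* match only compatibly tagged tokens.

Only the `not <deactivator>` pattern deactivates a cue (deactivators:
*clear*, *evident*, *known*, *necessarily*, *only*); deactivated matches
are flagged, never dropped. `no`-construction patterns (*no evidence
of*, *no proof*, ...) are not applied: under biological event annotation
those constructions do trigger negated events, even though linguistic
scope annotation treats them as non-negating.

## Parsing backend

All syntactic analysis flows through a backend contract
(`parse_layer.ParserBackend`): anything producing tokens with lemma and
POS, a dependency edge list, and a constituency tree satisfies it. The
package ships a `FixtureBackend` that serves pre-computed parses keyed by
exact sentence text and fails loudly on a miss — never a silent
fallback. The test suite and the generator run entirely on fixture
parses, which keeps every result deterministic and requires no parsing
model at run time; a live tagger/parser stack can be plugged in by
implementing the same contract.

## Classifiers

Six algorithms are wrapped with fixed settings (`classify.ModelSpec`):

| algorithm | settings |
|---|---|
| `random_forest` | 10 trees, `log2(N+1)` features per split (N = total features), unbounded depth |
| `decision_tree` | min 2 instances per leaf; cost-complexity pruning with fixed alpha 0.001 |
| `logistic_regression` | default regularisation, 1000 iterations |
| `naive_bayes` | Gaussian likelihoods |
| `svm_poly` | polynomial kernel, complexity constant C = 1.0, min-max attribute normalisation inside this spec only |
| `nearest_neighbor_1` | 1-NN, normalised Euclidean distance |

The original C4.5-style confidence-threshold pruning (confidence 0.25)
has no direct analogue in CART-style trees; the fixed small
cost-complexity alpha is the package's pruning stand-in, together with
the minimum-leaf constraint. Likewise, a numeric-attribute precision
parameter for naive Bayes has no sklearn counterpart on a one-hot design
matrix; Gaussian likelihoods with default variance smoothing are used.

Evaluation is stratified 10-fold cross-validation from a seeded shuffle.
The positive class is always *negated*. Reports carry raw per-fold
TP/FP/FN/TN; micro-averages pool counts before computing P/R/F (never
averaging the scores themselves). F is the first harmonic mean of
precision and recall; any 0/0 ratio is 0 by convention. When a class has
fewer than k members the fold count degrades to the minority size with a
warning; the per-class splitting experiments skip classes whose minority
polarity has fewer than two members and report NaN for them.

The splitting experiments partition events either three ways by type
(the five "simple product" types localization / transcription /
protein_catabolism / gene_expression / phosphorylation; binding; the
three regulation types) or two ways by complexity (simple vs. complex,
where a complex event has an event-valued participant), train and test
per class, and micro-average across classes.

## Synthetic corpus generator

The generator is first-class, tested code, and its defaults are the
study conditions everything else is measured under:

* sentence negation rate **0.063** (open bio-event corpora range over
  6.1–6.4% of events);
* negated-type mix **12/63/11/6/8** percent for
  inherent/trigger/participant/attribute/contrast (the observed micro
  averages across corpora);
* complex-event rate **0.25** per sentence with a **2.5x** negation
  enrichment on complex events (complex events are observed to be 2.5
  times more likely to be negated); the simple-sentence negation
  probability is scaled so the marginal rate stays at the configured
  value;
* distractor rates of **10% + 10%** among positive sentences
  (deactivated *not only* constructions; stray cues in adverbial
  clauses), chosen so that cue presence alone is a visibly poor
  predictor without dominating the corpus;
* five sentences per document; a closed vocabulary of 20 protein names,
  nine event types realised by transitive verbs, event nouns and
  passives.

Each template hand-specifies its tokens, lemmas, POS tags, dependency
skeleton and constituency bracketing, so fixture parses are exact and
byte-reproducible from the seed. Positive controls mirror the surface
shapes of negated templates (past-tense, infinitival and locative
variants) so that tense or POS alone cannot identify negations — what
separates classes is the cue structure the feature scheme is meant to
capture.

Two annotation choices in hard templates are deliberate:

* **Contrast** sentences ("In contrast to A, B activated C") annotate
  both the positive event and its cue-free negated twin. The twins have
  identical feature vectors by construction, so no cue-driven scheme can
  separate them; this reproduces the known ceiling that cue-free
  negations impose on recall (a contrast-only corpus caps recall at
  chance or below).
* **Participant** negations ("not A but B activated C") annotate only
  the negated event. Its positive twin differs solely in *which*
  conjunct fills the cause slot — a distinction the feature inventory
  (cue–trigger and cue–location relations only) cannot express — so
  annotating both would plant label noise rather than a learnable
  signal; the positive-event-under-cue-scope phenomenon is covered
  instead by the two-clause trigger template and the stray-cue
  distractor.

What the generator does **not** emulate: real lexical diversity,
ambiguous cues with context-dependent polarity (e.g. *loss* as
negative_regulation rather than negation), low-manner indicators used
non-negatively, type-dependent cues, multi-sentence discourse, or parser
noise. Passing the recovery tests therefore shows that the feature
scheme and pipeline recover cue-marked negations under clean conditions
and degrade as designed on cue-free ones — not that corpus-level
F-scores on real data are guaranteed.

## Numerical and I/O conventions

* Character offsets are 0-based, half-open, and `.txt` files carry one
  sentence per line, so sentence alignment is deterministic.
* Standoff record ids are regenerated on write; round-trip equality is
  structural (id-free canonical signatures).
* Negation percentages are reported to one decimal; an empty corpus
  reports the percentage as undefined (`None`), never 0.
* All randomness (generator, fold shuffles, seeded learners) flows from
  explicit integer seeds; two runs from the same seed produce identical
  corpora, feature matrices and predictions.

## Known limitations

* The fixture backend is exact but closed-vocabulary; applying the
  pipeline to real corpora requires supplying a live parser backend or
  pre-computed parses in the fixture dialect.
* Comparison/contrast marker features are not implemented (the contrast
  type is represented in the data but intentionally hard for the current
  inventory).
* Feature ablation operates at the six-group level only.
* The decision-tree pruning analogue and the naive Bayes likelihood
  model are stand-ins, not re-implementations of any specific toolkit's
  variants.
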