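# complang

Simulations of artificial-language learning: how the compositional
structure of a miniature language shapes what a learner memorizes, how
systematically it generalizes, and how much independent learners agree.

## The problem

In artificial-language learning experiments, participants are taught a
small lexicon that maps *scenes* — one of four shapes moving at an angle
in (0, 360] degrees — to character-string *labels*. Languages differ in
their degree of compositional structure: a holistic language uses
idiosyncratic labels (`koko`, `wangsus`), while a compositional one
reuses morphemes systematically (`fas-a`, `fas-e`, `nif-a`). For humans,
more structured languages are easier to learn and support more
systematic generalization. This package provides the machinery to ask
the same question of artificial learners:

- **corpus** — scenes, labels, languages; the 6-dimensional scene
  encoding `one-hot(shape) ++ (sin θ, cos θ)`; CSV/JSON serialization.
- **metrics** — all measures on a common footing:
  - *production similarity* `1 − lev(a,b)/max(|a|,|b|)`,
  - *semantic difference* `1[shape₁≠shape₂] + Δθ/180`,
  - *structure score* (topographic similarity): Pearson r between
    pairwise semantic differences and pairwise normalized edit
    distances over all item pairs,
  - *generalization score*: the same correlation over train×test
    production pairs of one learner,
  - *convergence score*: mean pairwise per-scene production similarity
    across learners,
  - similarity to reference (e.g. human) learners.
- **synthetic** — a generator of language suites spanning low to high
  structure on a shared train/test split (23 + 13 scenes over a
  4-shape × 24-angle grid), with guessing-task distractor sets and
  synthetic reference learners.
- **agent** — a recurrent learner built from scratch: a feedforward
  scene ENCODER, an LSTM label WRITER trained by token-wise
  cross-entropy, and an LSTM label READER aligned to the encoder with a
  symmetric NT-Xent contrastive loss. A single symbol-embedding table is
  shared by the reader input, writer input and (transpose-tied) writer
  output, so the generative and contrastive objectives genuinely couple.
  Training minimizes `L = L_gen + α_con · L_con` with Adam. The network
  and its gradients are implemented on a small reverse-mode autodiff
  written for this package and verified against finite differences.
- **training** — the round protocol of the human experiments: exposure
  (minibatches of 5, both loss terms), guessing (batch 1, stored
  distractor sets; accuracy measured with frozen parameters), production
  (generative term only), then memorization and generalization tests by
  greedy decoding with no updates.
- **pipeline** — the languages × seeds × rounds grid, long-format
  results, structure bins, memorization-error analysis.
- **stats** — linear mixed-effects models (statsmodels MixedLM) of each
  measure on standardized structure score and log round number with
  crossed random intercepts for seed and scene.
- **icl** — an in-context-learning probe: JSON-lines prompts with 23
  demonstrations and one unlabeled query, a completion parser, and
  injected completer functions (no network code).

## Worked example

```python
from complang import (AgentConfig, GeneratorSpec, LearningSession,
                      make_language_suite)

suite = make_language_suite(GeneratorSpec(seed=1))
print([f"{l.name}: {l.structure_score:.2f}" for l in suite])
# ['low-1: -0.04', 'mid-low-1: 0.13', 'mid-1: 0.14',
#  'mid-high-1: 0.51', 'high-1: 0.81']

session = LearningSession(suite[-1], AgentConfig(seed=0))
results = session.fit(n_rounds=10)
print(results.summary())
```

```
Learning session summary
========================
language:            high-1
structure score:     0.808
items (train/test):  23/13
rounds trained:      10
agent seed:          0
final true-label similarity:  0.886
final generalization score:   0.768
final guessing accuracy:      0.739
```

After ten rounds on the high-structure language this agent reproduces
training labels at similarity 0.886, generalizes with a systematicity
(form–meaning correlation) of 0.768, and picks the right scene among 5
candidates 74% of the time. Training the same seed on the low-structure
language of the suite for 60 rounds also memorizes the lexicon
(similarity reaches 1.0) but its final generalization score stays near
0.33 — the structure of the input, not raw learnability, is what drives
systematic generalization.

A command-line interface mirrors the library:

```bash
complang generate --seed 1 --out languages/
complang experiment --suite languages/ --seeds 10 --rounds 40 --out results/
complang stats --results results/results.csv --measure generalization_score
```

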