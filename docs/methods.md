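# Methods

## Scenes, languages, and the structure score

A meaning ("scene") is a pair (shape, angle) with shape ∈ {1,…,4} and
angle in degrees in (0, 360]; angle 0 is normalized to 360 so every
direction has one canonical representation. Agents see a scene as the
6-vector `one-hot(shape) ++ (sin θ, cos θ)` (degrees → radians inside
the transform); the sine/cosine pair makes nearby directions nearby in
input space while keeping every angle distinguishable.

The semantic difference between two scenes is a shape-mismatch indicator
(0/1) plus the angular difference divided by 180. The angular difference
is **circular** by default, `min(|Δ|, 360 − |Δ|)`, bounding the angle
term to [0, 1]: a linear |Δ| would call 15° and 360° nearly maximally
different although their encodings nearly coincide. A `circular=False`
switch provides the linear variant for sensitivity checks.

Form distance between labels is the Levenshtein distance divided by the
longer label's length (computed by `edlib`; an independent dynamic-
programming oracle lives in the fixtures module and the two are checked
against each other in tests). The structure score of a language is the
Pearson correlation between pairwise semantic differences and pairwise
form distances over all unordered item pairs (253 pairs at 23 items);
the generalization score is the same correlation over the 23 × 13
train×test production pairs of a single learner; the convergence score
is one minus the mean of the n·k(k−1)/2 scene-wise pairwise distances
across k learners. Zero-variance correlations are reported as 0 with a
`degenerate` flag rather than NaN so aggregation stays total and the
condition remains auditable.

## Synthetic languages

The generator works on a 4 × 24 scene grid (angles at multiples of 15°),
drawing a shared split of 23 training and 13 test scenes. Compositional
labels are `shapeMorpheme ++ "-" ++ angleMorpheme`: shape morphemes are
distinct CV(V)C syllables; the angle morpheme is an octant letter
repeated 1–3 times, so adjacent grid angles differ by one edit and
different octants replace the letter entirely — string similarity then
tracks angular proximity. Because the realized structure score depends
on which 23 scenes the split happens to draw, the compositional
generator enforces its contract (score ≥ 0.7) by redrawing the split
from derived sub-seeds; this is deterministic per seed. Holistic labels
are independent random CV strings of length 3–8 with uniqueness
enforced; their scores scatter around 0 (|r| ≤ 0.2 in expectation).
Mid-structure languages replace a fraction of compositional labels with
holistic ones; the suite uses replacement fractions (1, 0.75, 0.5, 0.25,
0) and assigns the bin names low…high in order of realized score.

Distractor sets for the guessing task hold 5 candidates per training
item (matching the exposure batch size, which also sets the number of
in-batch distractors): the target, a same-shape foil with the closest
angle, a different-shape foil with a similar angle, and random fills.

Synthetic **reference learners** stand in for human learning data, with
the statistical structure the analysis assumes: memorization productions
are the true labels with per-character substitution noise (default rate
0.05 — small but nonzero, so reference similarity is informative);
generalization productions recombine the shape morpheme of the nearest
same-shape item with the angle part of the nearest-angle item, with
probability `recombination_fidelity × min(1, structure/0.7)` (default
fidelity 0.9), otherwise they are noisy blends of memorized labels. At
fidelity 1 and zero noise on a compositional language the recombination
rule is deterministic, so learners converge perfectly and generalize
systematically. These learners emulate the *aggregate* pattern of human
data (structured input → more systematic, more convergent
generalization); they do not model individual human variation, response
times, or feedback effects, so agreement with them shows that the
pipeline's comparative machinery works, not that the agents match real
humans.

## The recurrent agent

ENCODER is a one-hidden-layer MLP (ReLU) from the 6-vector to a latent
**h** (dimension 50, as are all hidden sizes and the embedding). WRITER
is an LSTM whose initial hidden state is **h** (cell state zero),
primed with the PAD token as begin-of-sequence; at each step its hidden
state is projected to character logits and decoding stops at EOS or 16
characters. READER is a second LSTM over the label's characters whose
final state feeds a fully-connected head to a latent **z**. One
symbol-embedding table is shared by the writer input, the reader input,
and — transpose-tied — the writer output projection; the same encoder
instance serves both components. These couplings are what make the
contrastive task shape the generative one and vice versa, and both are
asserted as parameter-identity invariants in tests.

The generative loss is teacher-forced token-wise cross-entropy (in
nats), averaged over all non-pad target tokens including EOS. The
contrastive loss is the symmetric NT-Xent: cosine similarities between
scene latents and label latents scaled by a temperature (default 0.5;
the coefficient is a config field since no canonical value exists),
cross-entropy in both retrieval directions, averaged. The combined
objective is `L_gen + α_con·L_con` with α_con = 0.1. Parameters use
He-normal initialization and Adam at learning rate 1e-3 with
conventional constants. Greedy argmax decoding is used for all tests
(deterministic); sampling is available. An agent that emits EOS
immediately would produce an empty label with undefined edit distance;
such productions are recorded as a designated single fallback character
and flagged.

Since no neural-network framework is a dependency, the agent runs on a
small reverse-mode automatic-differentiation core written for this
package (`autodiff.py`): tensors over NumPy arrays with the dozen
operations the architecture needs. Its gradients are verified against
central finite differences, and the closed-form loss values (uniform
cross-entropy = ln V, NT-Xent with identical latents = ln batch-size)
provide end-to-end checks.

## Training protocol

Each round runs three blocks, one pass each (pass counts are
configurable; one is the default):

1. **Exposure** — the 23 items in shuffled minibatches of 5 (last batch
   3), one Adam step per batch on `L_gen + α_con·L_con` with the other
   batch members as contrastive distractors. A singleton batch cannot
   form contrastive pairs; its contrastive term is skipped.
2. **Guessing** — batch size 1; per item one step on the same loss, with
   the item's *stored distractor set* as the contrastive candidates.
   Guessing accuracy (argmax of cosine similarity between READER(label)
   and the candidate encodings, ties to the lowest index) is measured
   with the parameters frozen *before* the block's updates, so the
   reported trajectory involves no leakage within the block.
3. **Production** — one pass on the generative term only; the
   contrastive component of the reported loss breakdown is exactly 0.

After the blocks, the agent greedy-produces labels for all 23 training
scenes (memorization test) and 13 held-out scenes (generalization test)
with no parameter updates — a checksum test asserts that testing leaves
every parameter untouched. Shuffling is reseeded per round from the
agent seed, making a whole trajectory reproducible from (config,
language).

## Experiment grid and scaling

The reference design is 100 seeds × 10 languages × 100 rounds (2.3M
memorization and 1.3M generalization evaluations — the bookkeeping is
implemented and tested exactly). The package's own study runs at desk
scale: **5 synthetic languages × 10 seeds × 60 rounds**, chosen so the
full grid trains in minutes on one CPU while the qualitative claims
remain testable — the high/low contrast in final generalization, the
positive rank correlation between structure and generalization across
the suite, memorization reaching 0.8 similarity within 60 rounds, and
the error analysis. The memorization-error analysis defines an error as
any exact mismatch at the final round, computes similarity-to-truth over
errors only, flags zero-error languages, and (in the acceptance test)
pools errors across languages for the rank correlation, mirroring how
the per-error analysis is usually visualized. Structure bins are
equal-membership by score rank, with remainders assigned to the lowest
bins.

## Statistical analysis

Each measure is modeled as `value ~ structure_z + log_round_z +
structure_z:log_round_z` with crossed random intercepts for seed (the
language/seed pair, which also determines the input language) and scene,
fitted by statsmodels' MixedLM via variance components on a single
grouping. Predictors are centered and scaled by default; a center-only
option for the log round number exists because scaling it can hinder
convergence on some designs. Random slopes are not included — the
random-effects structure is intercept-only by design. Reported per term:
β, SE, z = β/SE, and the two-sided normal p. The z-test is asymptotic in
the number of independent groups; the recovery and type-I simulations
therefore use designs with ≥ 40 language×seed groups. Parameter-recovery
tests check that a known slope is recovered within 3 Monte-Carlo SEs and
that the null rejects at ≈ 5%. Reproducing any particular published
coefficient is out of scope: those depend on the original ten input
languages and a 1000-agent grid, while this package targets
direction-of-effect on its own synthetic suites.

## In-context-learning probe

Prompts are JSON lines — 23 demonstrations `{"shape": …, "angle": …,
"word": …}` followed by one query line without a word, no task
description — and are byte-reproducible. The completion function is
injected (`str -> str`); deterministic fake completers (copy,
nearest-neighbour) are provided for tests, and no network code is
included. The parser strips JSON punctuation, truncates multi-word
output to the first token with a flag, and keeps (but flags) characters
outside the default alphabet. Each query is issued independently;
productions are never fed back into the prompt. Completer failures
produce flagged fallback records so a single bad item cannot abort a
probe.

## Known limitations

- Synthetic languages use a fixed 15°-grid angle inventory and a fixed
  distractor-set size (5); the original experiments' exact inventories
  are not public in tabular form here.
- The reference learners are a statistical stand-in, not a cognitive
  model; "similarity to reference" results validate pipeline mechanics
  only.
- NT-Xent temperature and the decoding rule (greedy) are design choices
  the underlying description leaves open; both are exposed in the
  config.
- The mixed-model layer reports asymptotic z-tests; with very few
  languages or seeds the structure effect's test can be mildly
  anticonservative.
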