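# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions behind `picoscreen`, in the order the pipeline runs them.

## Preprocessing

Sentence splitting, tokenisation and lemmatisation are performed by a
deterministic rule-based preprocessor (`picoscreen-rules-1`), recorded by
name in every serialised corpus. Sentences break after `.!?` followed by
whitespace and a capitalised or numeric opener; tokens are
hyphen/apostrophe-joined alphanumeric words, decimal numbers, or single
characters; lemmata come from a small suffix-rule table (plural `-s/-es/
-ies`, verbal `-ed/-ing` with doubled-consonant reduction and final-e
restoration after c/s/u/v/z/g). The rules are crude compared to a
trained biomedical tagger, but they are reproducible, dependency-free, and
shared by every stage, which is what the document-level comparisons
require. All offsets are 0-based and half-open at both character and token
level; title and abstract are split per field, never concatenated.

For the span recogniser only, token surfaces are lowercased and every
digit is mapped to `0`, so numeric mentions share vocabulary entries. The
bag-of-words side instead filters lemmata to those with more than one
character and at least one alphanumeric character that are not on the
shipped stop list (`data/stopwords-en-v1.txt`, a fixed ~150-word English
list; the version string travels with serialised outputs). The LDA filter
is deliberately different: words of letters with optional initial or
internal punctuation (no digits, no trailing punctuation), minus stop
words.

## Nested span recognition

Categories form a two-level hierarchy: P, I, O with 17 fine-grained
subtypes (4 + 7 + 6), written `P.Age`, `I.Pharmacological`, … The IOB tag
set has a B- and I- tag per category plus one outside tag — 41 tags for
the full hierarchy.

**Layering.** A sentence's nested spans become an ordered list of IOB
sequences. Fine-grained spans always occupy the first layer(s); top-level
spans follow, ordered by structural nesting depth (a top-level span
strictly contained in another sits in an earlier layer). This reproduces
both the standard annotation scheme (fine inside top-level) and
coarse-in-coarse nesting such as an intervention mention inside a
population span. Partial overlap within a computed layer is a data error.

**Architecture.** Word embeddings (200-d by default; pretrained vectors in
word2vec text format are supported and kept fixed, with a trainable shared
UNK vector) are concatenated with the final states of a character biLSTM
(28-d embeddings, 28 per direction), giving a 256-d combined embedding. A
sentence biLSTM (128 per direction) and an affine projection produce unary
potentials for a linear-chain CRF with transition, start and end
potentials. The combined width must equal twice the sequence hidden width,
because nested decoding re-applies the sequence layer to its own output:
pass 1 decodes the fine-grained layer from the embedding, pass 2 decodes
top-level spans from the pass-1 hidden states, and so on until a pass
decodes no spans or `max_layers` (default 3) is reached. The top-level
pass always runs even when the fine-grained pass is empty — a sentence
without fine-grained annotation can still carry top-level spans.
Sequence-layer, projection and CRF parameters are shared across passes,
which supports unbounded depth and keeps the parameter count independent
of nesting.

**Training.** The loss is the negative CRF log-likelihood summed over a
sentence's target layers: the (possibly all-O) fine-grained layer, the
top-level layers, **plus one all-O terminator layer** after the last
non-empty layer. The terminator supervises the stopping criterion; without
it the pass after the outermost spans receives no gradient and the decoder
hallucinates spans there (held-out span precision 0.74 versus 0.98 with
the terminator, on the synthetic grammar). Optimisation is Adam over
shuffled batches of sentences with global-norm gradient clipping (5.0),
inverted dropout (0.5 by default) on the embedding and on each biLSTM
output, L2 weight decay (1e-8), and early stopping on development-set
exact-span F1 (patience 5). Training words occurring exactly once are
replaced by UNK with probability 0.5 per occurrence per epoch, which
trains the UNK vector. Gradients are hand-derived (forward-backward
marginals for the CRF, BPTT for both biLSTM levels) and verified against
finite differences in the test suite. Viterbi ties break to the lowest tag
index; a dangling `I-c` decodes leniently as `B-c` at prediction time and
is rejected in strict mode.

The default optimiser settings (learning rate 1e-3, batch 32) follow
common practice for this architecture family; the scaled-down
configuration used in the tests and examples (20-d words, 18-per-direction
sequence biLSTM, 13 tags for a 6-category hierarchy, learning rate 3e-3,
batch 8, dropout 0.1, ≤20 epochs) reaches held-out span F1 ≈ 0.98 on the
synthetic grammar in about a minute on one CPU.

## Features

Five bag groups plus topics, concatenated in a fixed order (`bow_title`,
`bow_titleabs`, `bow_P`, `bow_I`, `bow_O`, `topics`; baseline mode drops
the three PICO groups). Bags are binary and L2-normalised (each present
lemma contributes 1/√m), with empty bags left as zero vectors. The PICO
bags share the title+abstract vocabulary, so their supports are subsets of
the combined bag and the context-word statistics stay comparable;
fine-grained spans are mapped to their top-level parent before bag
construction, and a token under nested spans of different categories
contributes to both bags.

LDA is a collapsed Gibbs sampler (k = 300, α = 1/k symmetric at
initialisation, β = 1/100, 1000 iterations by default) with Minka
fixed-point re-optimisation of an asymmetric α every 50 iterations.
Training documents reuse their final Gibbs counts; unseen documents are
folded in with 100 sampling passes against fixed topic-word counts. Topic
proportions are L2-normalised; empty documents get zero vectors. The model
is fitted per collection, on the collection's own text only. Tests and
examples use k = 20 and 150 iterations, matched to collections of a few
hundred short abstracts.

Vocabularies, topic model and spans are all computed once on the whole
collection before any simulation. None of these consult labels, so the
fixed representation leaks nothing into the simulated screening.

## Screening

The classifier minimises ½‖w‖² + C Σ log(1 + exp(−yᵢ(w·xᵢ + b))) with
C = 1, tolerance 1e-6 and an unregularised intercept (scikit-learn
logistic regression, lbfgs); scores are posterior probabilities, and
ranking ties break by ascending document id everywhere, making every
trajectory deterministic given its trial seed.

*Relevance feedback*: a random batch of 25 is drawn (and extended by
further random batches) until it contains at least one relevant reference;
then train → score unscreened → screen the top 25 → retrain, until the
collection is exhausted (the final batch may be smaller). If the screened
labels are single-class at a retrain — possible when the seed batch holds
only relevant references — that iteration takes a random batch instead.
*Stratified two-fold*: half of each class (floor on odd counts) trains a
single classifier that ranks the held-out half. `monte_carlo` runs trial
t with seed `base_seed + t`, so extending the trial count preserves the
earlier trials.

## Evaluation

`recall_curve` / `wss95` implement recall(i) = TP(i)/(TP(i)+FN(i)),
i_R95 = min{i : recall(i) ≥ 0.95}, WSS@95% = 0.95 − i_R95/N. Note that
with very few relevant references the random-ordering expectation of
i_R95 sits below 0.95N (the maximum of R uniform positions concentrates
near N·R/(R+1)), so the null value of WSS@95% is slightly positive at
small R — visible in the null-calibration study (~+0.03 at R ≈ 16).

F1 is the harmonic mean 2pr/(p+r); zero-denominator precision or recall is
reported as 0 with a flag. Tagging is evaluated token-wise per coarse
category (set-valued membership, so a token under two nested same-category
spans counts once; micro-aggregated over the corpus) and at document level
by comparing the filtered lemma sets of gold versus predicted spans,
skipping documents where both are empty (micro-aggregation over documents
is a documented choice; macro would weight short documents up). The
cross-collection comparison uses the exact one-sided sign test
P(X ≥ s), X ~ Binomial(n, ½), with zero deltas counted as successes by
default (configurable: drop, or half-weight).

## Context-word statistics

Presence is binary at the document level, matching how TP ("inclusions
containing the feature") and FP are counted. For each lemma, the
unrestricted context and each PICO context give paired indicators per
document, with context presence implying unrestricted presence by
construction. The χ² test is Pearson's without continuity correction on
the 2×2 presence-by-label table (df = 1; degenerate margins are flagged
with p = 1). The generalised score test builds one record per
(document, context) where that context is positive, x marking the
restricted context and d the label; with record means x̄, d̄ the score is
S = Σ(x−x̄)(d−d̄) and the variance is cluster-robust over documents,
V = Σ_doc [Σ_records (x−x̄)(d−d̄)]², giving T = S²/V against χ²(1). V = 0
(e.g. a single positive document, or identical context patterns) is
reported as degenerate with p = 1.

The χ²(1) reference distribution is asymptotic: against a label-permutation
oracle its p-values agree to within 0.05 for ≥95% of null lemmata at
around a thousand documents, while at 80 documents the bulk of the
p-value range deviates by up to ~0.2 (tails agree much earlier). The
calibration suite therefore runs at n = 1000 documents per lemma.

Selection requires both p-values below α = 0.01 *and* context PPV above
unrestricted PPV; there is no multiplicity correction by default (a
Bonferroni option exists), every lemma with at least one containing
document is tested, and output rows sort by χ² statistic descending.

## Synthetic data

The generators are the package's study conditions, not conveniences.

*Annotated corpora*: sentences of letter-only nonsense words (suffix-safe,
so one word is one token and digit normalisation cannot collide vocabulary
entries) drawn from role-specific sub-vocabularies; planted top-level
spans of length 2–4, fine-grained sub-spans inside them with probability
0.5, and intervention-inside-population nesting with probability 0.25.
What passing recovery tests show is that the layered decoder can learn
and reconstruct nested structure when span vocabulary is informative; they
say nothing about performance on real biomedical prose, whose lexical
ambiguity, span-boundary vagueness and annotator disagreement the grammar
does not model.

*Screening collections*: every abstract carries one P, one I and one O
span; inclusion labels are Bernoulli with log-odds
intercept + Σ planted contributions, the simplest mechanism inside the
classifier's hypothesis class, so representation differences — not model
mismatch — explain performance differences. The intercept is calibrated by
bisection so the expected prevalence hits the target (default 5%, N = 400,
as in the sparse drug-effectiveness reviews). The default planted lemmata
are five outcome-context keywords with log-odds +5 when inside an outcome
span, occurring in 30% of documents but only one occurrence in five being
in-context: in this dilution regime the unrestricted indicator is weak
while the restricted one is nearly decisive, which is precisely the
situation in which PICO-restricted features should help. With half of all
occurrences in-context the unrestricted bag shadows the context bag and
the advantage disappears — a boundary condition worth knowing when
interpreting the core-claim test.

The word-statistics study uses a denser collection (N = 800, 15%
prevalence, `stats_study_config`): at 20 inclusions a document-level test
cannot reach p < 0.01 for five words simultaneously; at ~120 inclusions
the planted words are recovered 5/5 with no false selections across seeds.

## Known limitations

- The rule-based preprocessor approximates, and sometimes mangles,
  biomedical morphology ("during" → "dur"); stop-word filtering applies to
  lemmata, so such artifacts can escape the list.
- The tagger trains in pure numpy: adequate for the scaled-down synthetic
  studies, but training the full 256/128 architecture on a 43k-sentence
  corpus would take days on one CPU.
- LDA inference for unseen documents is a point estimate from a short
  fold-in chain; topic proportions for very short texts are noisy.
- WSS@95% is reported without any stopping-criterion estimation; the
  saving is theoretical unless a reviewer can detect 95% recall.
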