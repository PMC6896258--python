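# picoscreen

PICO-aware prioritisation of systematic-review reference screening.

Screening the search results of a systematic review means reading thousands
of titles and abstracts and deciding, one by one, whether each reference
meets the review's inclusion criteria. Those criteria are usually phrased in
terms of the PICO elements — the **P**atient/population, the
**I**ntervention (with comparators merged in), and the **O**utcomes.
`picoscreen` implements a screening-prioritisation pipeline built on that
observation, for methodologists and text-mining researchers studying
machine-assisted reviewing:

1. **Nested PICO recognition.** A layered biLSTM-CRF tagger marks PICO
   spans in each sentence, including *nested* mentions (an intervention
   inside a population span, a fine-grained subtype inside a top-level
   span). Each token is embedded as the concatenation of a word vector and
   the final states of a character biLSTM; a sentence biLSTM feeds an
   affine projection into a linear-chain CRF decoded by Viterbi. Nesting is
   handled by an ordered list of IOB sequences per sentence — innermost
   spans first — with the sequence layer re-applied to its own hidden
   output until a pass decodes no spans. The hierarchy has 3 top-level and
   17 fine-grained categories, hence 2×(3+17)+1 = 41 IOB tags. The network
   is implemented directly in numpy with hand-written backpropagation
   (Adam, gradient clipping, dropout, weight decay, early stopping on dev
   span-F1), so it runs anywhere on a CPU.

2. **Relevancy classification.** Each reference is represented by named
   feature groups: a binary, L2-normalised bag of title lemmata, one for
   title+abstract, LDA topic proportions (collapsed Gibbs, k topics,
   α = 1/k, β = 1/100, hyperparameter optimisation every 50 iterations),
   and — in `pico` mode — three more bags holding the lemmata recognised
   inside P, I and O spans. An L2-regularised logistic regression with
   C = 1 scores relevance.

3. **Screening simulation.** Two protocols, each repeated over Monte Carlo
   trials: *relevance feedback* (random seed batch of 25 until it contains
   a relevant reference, then retrain-and-take-top-25 until exhaustion) and
   *stratified two-fold* (train on half of each class, rank the rest).
   Performance is work saved over sampling at 95% recall,

   WSS@95% = 95% − i_R95 / N,

   where i_R95 is the number of references screened when recall first
   reaches 0.95 and N the collection size.

4. **Context-word statistics.** For every (context, lemma) pair the package
   counts the included (TP) and excluded (FP) documents containing the
   lemma, restricted to a PICO context or not, and selects
   "PICO-predictive" words by a dual test at α = 0.01: Pearson's χ² for
   association with the label, and Leisenring-style generalised score test
   (cluster-robust, paired by document) for the context-restricted positive
   predictive value exceeding the unrestricted one.

A synthetic-data module generates both input kinds — annotated corpora with
nested spans, and screening collections whose labels depend on
context-restricted keyword usage — so the entire pipeline is testable
without external corpora.

## Worked example

`examples/` holds one short script per capability. Training the tagger on
the synthetic grammar and decoding a held-out sentence
(`python examples/01_nested_tagging.py`):

```
best dev span-F1 0.966 at epoch 13

tokens: Patdx patux intyx inthx bgefx bgehx bgdzx bgdix bgegx bgbx .
gold:      [('I', 2, 4), ('P', 0, 4)]
predicted: [('I', 2, 4), ('P', 0, 4)]

held-out span precision 0.984  recall 0.984  F1 0.984
```

The decoder recovered both the outer population span and the intervention
span nested inside it. Comparing feature sets on a collection whose
relevance is context-dependent by construction
(`python examples/02_screening_simulation.py`):

```
collection: 400 references, 16 included (4.0% prevalence)
baseline  features:   385 columns, mean WSS@95% = -0.031 (sd 0.017)
pico      features:  1030 columns, mean WSS@95% = 0.101 (sd 0.018)

delta (pico - baseline) = +0.132
```

The baseline bags see the planted keywords everywhere and save no work;
the outcome-restricted bags isolate the predictive usage, so screening
stops about 13% of the collection earlier at 95% recall. The dual-test
word selection on a denser collection
(`python examples/03_context_word_statistics.py`):

```
Tag Lemma      PPV ctx PPV bow     TP/FP     chi2 p       GS p  selected
O   keyex         0.74    0.37     29/10    1.2e-25    5.4e-10  yes
O   keyax         0.66    0.36     27/14    3.6e-20    5.7e-07  yes
...
O   outdx         0.04    0.04      4/96    7.5e-04    1.0e+00  no
```

All five planted keywords — and nothing else — pass both gates: their PPV
roughly doubles when the occurrence is restricted to outcome spans.

## Command line

A thin CLI wraps the library: `picoscreen synth | train-tagger | tag |
simulate | stats | benchmark`, each writing a `manifest.json` with the
arguments and seeds needed to reproduce its outputs. Run
`picoscreen --help` for details.

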