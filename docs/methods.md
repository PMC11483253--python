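# Methods

## The model

`temporalmatch` trains a masked-language-model (MLM) text encoder whose
document embeddings are *temporally distribution-matched*: embeddings of
old-period documents are made statistically indistinguishable from those of
new-period documents, without erasing the semantic content of either. The
training signal combines three terms.

Let `M_e` be the encoder ("generator"). A document is sentence-segmented;
each sentence is embedded (mean pooling over non-special final hidden
states by default) and the first `m` sentence embeddings are stacked into
an `m x d` abstract embedding, zero-padded when the document has fewer than
`m` sentences. A linear *temporal discriminator* `M_d` — `d*m + 1`
parameters including the bias — receives the flattened matrix and predicts
the probability that the document is from the new period (OLD = 0,
NEW = 1). A frozen *anchor* encoder of identical architecture, trained with
MLM only on all documents, embeds the same document.

Per batch, two sub-updates run in order:

1. **Discriminator update.** `M_d` minimizes binary cross-entropy on the
   current generator's embeddings (generator gradients blocked).
2. **Generator update.** With the freshly updated discriminator frozen,
   `M_e` minimizes

       (1 - lambda_adv - lambda_A) * L_MLM
         + lambda_adv * L_adv_flip
         + lambda_A   * L_A

   where `L_MLM` is masked-token cross-entropy, `L_adv_flip` is binary
   cross-entropy against *flipped* temporal labels, and `L_A` is the
   Frobenius distance between the generator's and the anchor's abstract
   embeddings (summed per document, averaged over the batch — the
   per-batch aggregation is our convention, as is the label-flip form of
   the adversarial term; a negated-BCE mode is available via
   `adversarial_mode="negate"`). The anchor term prevents the degenerate
   solution in which the generator defeats the discriminator by collapsing
   all embeddings to a constant.

Defaults: `lambda_adv = lambda_A = 0.3` (MLM weight 0.4), 20 epochs, Adam
at 2e-5 for both components, batch size 16, `m = 20`, hidden size 128 with
2 transformer layers. Masking uses the standard recipe (rate 0.15; of the
selected positions 80% become `[MASK]`, 10% a random content token, 10%
stay). Probabilities are clipped to `[1e-7, 1 - 1e-7]` before logs.
`mlm_corpus_scope` selects whether the MLM term sees only the old/new
labeled documents (default) or all documents including the gap years;
`period_sample_weights` rescales old vs new documents' contributions to the
adversarial and anchor terms (default 1:1).

With `lambda_adv = lambda_A = 0` the loop skips the adversarial machinery
entirely and reproduces the MLM-only baseline trainer bit for bit under a
matched seed — the two trainers share the shuffle and masking streams.

## Numerical core

No deep-learning framework is used: `temporalmatch.nn` is a small
reverse-mode automatic-differentiation engine over numpy arrays with fused
layer-norm, softmax-cross-entropy, scaled-dot-product-attention, and
affine ops, plus transformer-block, LSTM, and Adam implementations. All
model arithmetic is float32; gradients are verified against central finite
differences in the test suite. Training is deterministic given the config
seed on a fixed BLAS: the shuffle and masking generators are spawned from
one seed sequence, and batch operations are ordered.

Degenerate inputs: empty sentences and empty corpora are validation
errors; over-length sentences are truncated to `max_tokens` (keeping the
final separator); a fully padded abstract embedding is valid and scores
`sigmoid(bias)` under the discriminator; the Frobenius term adds 1e-12
inside the square root so its gradient is finite at exactly matching
embeddings.

## Synthetic data

The drift-corpus generator produces the study conditions, not realistic
clinical text. Documents are drawn from a topic mixture: each sentence
samples one of `n_topics` topics, then tokens from the topic's word
distribution. A fraction (default 0.2) of the vocabulary *drifts*: these
words change both their home topic and their base frequency (4x up or
down) between an old and a new word table; new-period documents sample
from `(1 - delta) * old + delta * new` with drift strength `delta`. At
`delta = 0` the periods are identically distributed by construction; at
`delta = 0.8` a multinomial-logistic bag-of-words oracle separates the
periods with held-out accuracy well above 0.75. Both the frequency and the
association component are needed: a linear probe (and the linear
discriminator) can only see drift that moves marginal statistics of the
embeddings.

Concept pairs plant a ground truth for the future-relatedness evaluation.
Each pair reserves two dedicated tokens; per document, with probability
`concept_mention_rate` the pair is mentioned, and with probability equal to
the period's relatedness the two tokens are injected *adjacently in the
same sentence* (otherwise in different sentences). Adjacent injection makes
the co-occurrence directly learnable by masked-token prediction. The
new-period relatedness ranking is strictly decreasing across pairs and the
old-period ranking is its reverse, so the two ground-truth rankings are
strict and maximally different; an all-period model therefore sees a
mixture with little net ranking signal, while a new-period-only model can
recover the new ranking.

Synthetic patients carry three named code-description sequences (previous
diagnoses, current diagnoses, medications), static features (age, distinct
code count), a group label (default 44% female, mirroring a typical
clinical cohort share), and an outcome from a linear predictor over code
presence with an optional group-interaction term: continuous outcomes add
Gaussian noise, binary outcomes are Bernoulli(sigmoid). OLS on one-hot
code indicators recovers the planted coefficients within 3 standard errors
at n = 2000 (verified in the suite).

What the generator does *not* emulate: realistic vocabulary statistics
(Zipf tails, sub-word structure), discourse structure, label noise in
period assignment, or code ontologies. Passing tests show the method's
mechanics — that the adversary removes linearly recoverable period
information while MLM performance and planted relational structure
survive — not clinical-grade performance.

## Evaluations

* **Held-out MLM loss** — masking with a fixed evaluation seed so all
  models see identical corruptions; mean cross-entropy over target
  positions.
* **Temporal probe** — a fresh scikit-learn logistic regression trained on
  frozen flattened abstract embeddings with a seeded, stratified 70/30
  split; held-out accuracy measures remaining linearly recoverable period
  information.
* **Concept similarity** — each concept embedded as a standalone
  single-token input; cosine similarity; Spearman rank correlation between
  a candidate's similarities and those of a reference model trained only on
  new-period documents ("future" reference). Kendall and
  mention-averaged-embedding variants were considered; standalone
  embedding with Spearman is the default protocol.
* **Lambda grid search** — trains one model per `(lambda_adv, lambda_A)`
  point (reduced epochs allowed), scores future-relatedness correlation,
  breaks ties toward smaller `lambda_adv` then smaller `lambda_A`. The
  default grid `{0, 0.1, ..., 0.6}^2` filtered to `sum <= 1` has 46
  points.

## Downstream harness

Task heads train on a frozen encoder (checksum-asserted): every code
description is embedded once and cached; each sequence is aggregated by an
LSTM shared across sequences; the aggregate vectors are concatenated with
scaled static features (plus, for regression, the current primary-diagnosis
embedding) and fed to a two-layer feed-forward head. Regression minimizes
mean squared error (defaults lr 1e-3, 10 epochs); classification binary
cross-entropy (defaults lr 1e-5, 4 epochs). Group-wise evaluation reports
AUC or MAE per group with subject-level percentile bootstrap CIs (2000
resamples); record-count-weighted group MAEs recombine exactly to the
overall MAE (group AUCs do not — a documented non-property).

## Statistics

AUC uses the Mann-Whitney form with ties counted 1/2. The DeLong test uses
midrank placement values (O(n log n)); the Diebold-Mariano test with the
mean-absolute-deviation criterion is applied to exchangeable subjects,
i.e. the lag-0 variant, which equals a paired z-test on absolute errors.
Two-sided p-values throughout; no alpha is hard-coded; zero-variance
cases with zero effect return p = 1 with a degenerate flag. Bootstrap
intervals are percentile, subject-level, seeded; resamples with undefined
metrics (e.g. single-class AUC) are redrawn up to a capped budget and the
failure rate is reported if the cap is hit.

## Reference study conditions

`temporalmatch.experiments` pins one set of conditions used by the test
suite and the acceptance script: vocabulary 500, 1000 + 1000 training
documents (plus 150 + 150 held-out documents drawn from the same topic
tables for MLM evaluation), drift strength 0.8, documents of 6-10
sentences with 8-14 tokens, 20 planted concept pairs at mention rate 0.8;
encoder with 2 layers, hidden size 64, 2 heads, feed-forward width 256
(the standard 4x ratio), `m = 10`; 5 training epochs at batch size 32. Two optimization settings deviate from the
paper-scale defaults, for reasons intrinsic to the desk scale:

* **Generator learning rate 3e-4** (not 2e-5). The full-scale recipe
  fine-tunes a pretrained compact BERT; here the encoder trains from
  random initialization, and at 2e-5 it remains at the uniform-prediction
  level (held-out loss ~ ln V) after 5 epochs. 3e-4 is a standard
  from-scratch pretraining rate for small transformers.
* **Discriminator learning rate 1e-2** (not 2e-5). The discriminator is a
  single linear layer and must be a competent adversary within 5 epochs
  for any matching pressure to exist; at 2e-5 it stays at chance while a
  converged logistic probe finds the period signal easily.

The new-period reference model trains for 10 epochs on the 1000 new-period
documents. The downstream study uses 2000 patients (70/30 patient-level
split), a planted signal code whose one-hot logistic oracle AUC exceeds
0.8, and a classification head at lr 1e-3 for 15 epochs. Both head
settings are scale translations of the full-scale recipe: 1e-5 over 4
epochs presumes a cohort more than an order of magnitude larger, where it
implies thousands of optimizer steps; at n = 2000 the same step budget
requires the larger rate and more epochs, stopping before the overfit
regime (epoch counts are chosen by where held-out loss turns, the same
rule the full-scale recipe uses). Statistical calibration uses 1000 null
replicates at
n = 200, a 20 000-replicate permutation oracle at n = 100, and 500 outer
replicates for bootstrap coverage.

## Known limitations

* The adversary only removes *linearly* recoverable period information —
  by design (the discriminator is linear, as specified).
* Future-relatedness correlations at this scale are noisy; directional
  comparisons are made as medians over three seeds and individual-seed
  values fluctuate.
* Sentence segmentation is a regex boundary detector; abbreviations and
  decimal points in real text would need a statistical segmenter (the
  segmenter is pluggable and its identity is recorded).
* The whitespace tokenizer assumes a closed vocabulary; real corpora need
  a sub-word tokenizer behind the same integer-id interface.
* Checkpoints store raw float32 weights with no versioning beyond the
  embedded config.
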