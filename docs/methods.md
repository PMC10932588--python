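# Methods

## Surprisal backend

The unit of analysis is the information signature of a sentence variant:
per-token surprisal s(w_i) = −log₂ P(w_i | context), in bits.  Two
backends produce it.

**N-gram model.**  An order-k model (default k = 3) over whitespace
tokens.  Sentence starts are padded with k−1 BOS markers, so every visible
word is conditioned and scored; an end-of-sentence event is *counted* at
training time — this is what makes every conditional distribution over the
vocabulary sum to one — but not *scored* by default, so a profile carries
exactly one value per visible word.  The vocabulary is the training token
set plus reserved EOS and UNK types; out-of-vocabulary tokens at scoring
time map deterministically to UNK.  Smoothing is add-k (Lidstone) with
k = 0.01 by default, small enough to barely disturb observed counts while
keeping every surprisal finite on the tiny corpora this package is meant
to run on; maximum likelihood is available for exact-probability work and
raises a diagnostic error on a zero-probability event rather than emitting
infinity.

**Precomputed tables.**  When surprisal comes from an external language
model, profiles are read from a TSV of
(sentence_id, construction, variant_role, occurred, position, token,
surprisal_bits) rows.  The metrics are deliberately token-granularity
agnostic: they operate on whatever tokens the backend emitted, whether
words or subword pieces.  How subword surprisal should be aggregated to
word level is a genuinely open question that the format sidesteps rather
than resolves.

## Metrics

All four scores treat *lower as preferred* and are length-normalized by
default: Δ-UID divides its sum of absolute adjacent differences by the
n−1 transitions, μ-UID and RTM divide their deviation sums by n, and
Low-IC is a mean by definition.  The normalized forms are the defaults
because they are the ones a per-sentence comparison across different
lengths requires; the raw sums remain available via `normalize=False`,
and which convention a given study used for RTM and raw Δ-UID is not
always stated, so both are exposed.  Δ-UID on a single-token profile has
no transitions and is defined as 0 with a warning rather than an error.

The RTM reference value `global_mean` defaults to 4.70 bits, a
conventional working value inside the 4–5 bits/word band typically
measured for human text; it is user-configurable, and
`corpus_mean_surprisal` computes the token-weighted empirical mean of any
profile collection as a data-driven substitute.

## Classification and confusion bookkeeping

A pair is classified by scoring both variants under one metric and
predicting the strictly lower one.  Exact ties (within 1e-9 bits) predict
baseline — conservative against the critical construction — and are
flagged on the prediction so they can be counted; with continuous scores
they are vanishingly rare, but synthetic flat profiles can produce them.
Critical-construction occurrence is the positive class: TP = critical
occurred and predicted, FP = baseline occurred but critical predicted,
and so on.  Confusion counts are stored as reals so the analytic
fair-coin half-counts reuse the same container.  Pairs are scored as
standalone sequences; no cross-pair context enters the decision.

## Statistics

F1 uses the standard 2PR/(P+R) with every 0/0 sub-expression taken as 0,
which keeps degenerate repetitions of the random simulation countable.
The fair-coin expectation on (n_c, n_b) occurred counts is the fractional
matrix (n_c/2, n_b/2, n_c/2, n_b/2); its F1 is exactly 0.5 for balanced
designs and rises with imbalance, which is the entire reason the
calibration battery exists.  The Monte-Carlo random model draws an
independent fair coin per pair and repeats (default 1000 reps, explicit
seed required); quartiles use numpy's linear-interpolation quantile rule,
indistinguishable from the median-unbiased rule at these sample sizes.

χ² against chance is the uncorrected Pearson goodness-of-fit of
(correct, incorrect) versus (N/2, N/2) with df = 1.  No Yates continuity
correction is applied: on a 67-pair construction with 17 correct the
uncorrected statistic is 16.25 where the corrected one would be 15.28,
and the uncorrected form is the one consistent with the published use of
this construction-level test.

The paired t-test contrasts a per-construction F1 vector with the random
baseline's per-construction mean F1 over the simulation reps, one-sided
for model > random.  The baseline vector could alternatively be a single
seeded simulation run; the mean over reps is the default because it is
stable under reseeding.  All-zero differences return the no-signal
convention t = 0, p = 0.5 (flagged degenerate); constant nonzero
differences, where t is unbounded, raise instead of reporting a number.

## Synthetic data

The generator produces the statistical shape of the real inputs, not
language.  Signatures are a deterministic shape (flat, ramp, alternating,
spike; `amplitude` in bits) plus Gaussian token noise (`fluctuation` =
SD), clipped at zero because surprisal is non-negative.  Clipping slightly
biases low-mean/high-noise signatures upward; tests that need exact
algebra use noiseless shapes.

Pair datasets honour the per-construction occurred-variant counts exactly
and control `discriminability`: the probability that the occurred variant
is the one preferred by a designated generating metric.  Each pair draws
two signatures with independently random mean (3–8 bits), amplitude (1–5
bits), noise SD (0.5–2 bits) and length (default 10–35 tokens, the span
of typical sentence-pair material); score ties under the generating
metric are redrawn.  Defining discriminability operationally at the pair
level, rather than as an effect size in bits, makes measured classifier
accuracy an unbiased estimator of the dial — the module's core
calibration property, verified at d ∈ {0.5, 0.7, 0.9, 1.0} with 1000
pairs against a 3-binomial-SE band.  Because the two variants' means and
shapes are drawn independently, separability under one metric does not
transfer to another, which the leakage test asserts for spike-shaped
datasets.

What passing these tests shows is that the *pipeline* is correct and
calibrated; synthetic signatures carry none of the construction-specific
surprisal structure of real alternation data, so they say nothing about
whether any uniformity hypothesis is true of language.

## Orchestration and determinism

`run_full_evaluation` computes, per construction × metric, the confusion
matrix, F1 and accuracy; adds majority-class accuracy, the random-model
simulation summary, χ² against chance, and the paired t contrasts
(reported in the manifest; they need at least two constructions).  One
root seed drives everything: per-construction simulation seeds are drawn
from a generator initialised with it, and the manifest records them, so a
rerun with the same config reproduces byte-identical CSVs (statistics are
written at 3 decimals).  An `Average` row is appended to the F1 and
accuracy grids when more than one construction is present.

Problem sizes throughout the tests and the acceptance script — 1000
simulation repetitions, 1000-pair recovery sweeps, 10 000-rep calibration
checks — are the package's default study conditions and run in seconds.

## Limitations

* The n-gram backend is intentionally simple (no interpolation or
  Kneser-Ney); it exists to make the pipeline self-contained, not to
  compete with neural surprisal.
* Word-level aggregation of subword surprisal is unspecified by the
  profile format (see above).
* The evaluation treats pairs independently and two-way only; multi-way
  alternations and multifactorial analyses (prosody, processing load) are
  out of scope.
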