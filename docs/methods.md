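# Methods

## Problem framing

The unit of prediction is a single cytosine on a transcript (1-based,
fully closed coordinates on the transcript, never the genome — sites
arrive pre-mapped, and no liftover is attempted). The model sees only the
2w+1-nt window centred on the candidate; w defaults to 10. Windows
overhanging a transcript end are padded with `N` rather than discarded:
discarding would silently shrink test sets for sites near transcript
ends, and the padding count is recorded on the window. RNA input is
normalised to the DNA alphabet (U→T) on read, since the feature encodings
are defined over {A,C,G,T}.

When several transcripts of one gene carry sites, the representative is
the mRNA-biotype transcript with the most modification sites; ties break
by longer sequence, then lexicographically smaller id, so selection is
deterministic. If a gene has no mRNA transcript the selection falls back
to all biotypes with a warning.

## Feature encodings

Both schemes emit 4 components per position, position-major, 5'→3',
(2w+1)×4 = 84 features at the default w:

* **one-hot** — identity bits; `N` is the all-zero vector (an absent
  state, not a fifth symbol).
* **physicochemical + accumulated frequency** ("feng") — ring number,
  chemical functionality, hydrogen-bond count as three fixed bits
  (A:111, G:100, C:010, T:001) plus the running frequency of that
  nucleotide among window positions 1..i, divided by the number of non-`N`
  bases seen so far. `N` encodes as zeros and is excluded from later
  denominators so the fraction stays interpretable. The frequency is
  computed over the extracted window, not the whole transcript: a
  prediction server only ever sees windows, and local encoding is
  cacheable. A `full_sequence=` argument exposes the whole-input
  normalisation for comparison. Whether the original accumulated-frequency
  formulation normalises by position index or sequence length is ambiguous
  in the literature; this package normalises by (observed) position index
  and flags the alternative.

## Dataset construction

Positives are deduplicated on (transcript_id, position) — a site shared
by two tissues enters the pooled "comprehensive" set once. A quarter of
positives (exactly `round(0.25·n)`) is held out as the independent test
set; the split shuffles a canonically sorted list with a seeded PRNG, so
it is a pure function of (inputs, seed) regardless of input order.

Training negatives are sampled uniformly without replacement from the
unmodified C's of transcripts carrying training positives, exactly
`min(k·n_pos, available)` of them (k = 30 by default; the 1:10/1:30/1:50
grid is exposed). Test negatives are *all* candidate C's on transcripts
carrying test positives, minus anything already spent on training — the
"1:all" convention that mirrors a real scan. Restricting test negatives
to test-side transcripts (rather than the whole transcriptome) is a
deliberate choice; the alternative is noted but not implemented.

For tissue-specific benchmarking, each tissue's test set additionally
drops every (transcript, position) present in any other tissue's training
set — positives or sampled negatives — so inter-tissue tests only see
tissue-specific samples. A tissue's own training set is never modified.

## Learners

The production model is `sklearn.ensemble.RandomForestClassifier` with
300 trees (n_tree and the 1:30 ratio being the cross-validated optimum of
the protocol this package implements) and a fixed seed. Baselines:
logistic regression, Gaussian naive Bayes, and a decision tree with
min_samples_split=35, max_depth=30 and ccp_alpha=1e-5 — ccp_alpha being
the nearest scikit-learn analogue of an rpart-style complexity parameter
(exact rpart pruning semantics are not chased; the mapping is recorded in
every model manifest). Scores are positive-class probabilities, never
votes: FPR calibration needs a continuous score.

## Stringency thresholds

Three published levels: high/medium/low at nominal false-positive rates
1%/5%/10%. For level α on n calibration negatives the cutoff is the
⌈(1−α)·n⌉-th smallest negative score — equivalently, the smallest
observed score t with `frac(score > t) ≤ α`. This is deliberately
conservative at tie blocks. Calibration negatives are drawn from
training-side transcripts, never test-side, so the evaluation protocol
never leaks; with fewer than 1/α negatives the threshold is flagged as
coarse. The empirical FPR attained on fresh negatives carries two
sampling errors (threshold estimation plus evaluation binomial), so
deviations up to roughly 1.4× the plain binomial standard error are
expected.

## Evaluation

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) raise on zero
denominators instead of returning silent zeros. ROC curves sweep unique
scores, merge tied scores into single diagonal segments, and always
include (0,0) and (1,1); AUC is computed both as the trapezoidal area and
as the rank-based Mann–Whitney concordance (ties counting ½). The two
routes are mathematically identical and the test suite holds them to
1e-12; `sklearn.metrics.roc_auc_score` is used in tests as an independent
cross-check only. Fixed-threshold external servers appear as single
(FPR,TPR) points via a helper, never as curves. No AUC-difference
significance tests (e.g. DeLong) are provided.

The cross-tissue benchmark reports AUC of predictor i on test set j;
missing test sets yield NaN cells, never zeros.

## Synthetic study conditions

The generator emulates mapped m5C site sets at desk scale. Defaults,
chosen once as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| n_transcripts | 100 | ~50k candidate C's: large enough for 1:30 sampling, 2000-negative calibration and 1:all test sets to be simultaneously meaningful |
| length_range | 1500–2500 nt | typical mRNA scale |
| base_composition | uniform | neutral background |
| tissues | 3 (two mouse, one human cell line) | smallest set where intra/inter structure is a matrix, not a pair |
| motifs | distinct 9-mers, C anchor, pairwise ≥6/8 flank mismatches | genuinely different signals per tissue |
| motif_fidelity | 0.85 | context preference is statistical, not exact: per non-anchor position the consensus base appears with probability 0.85. This keeps held-out AUC high (~0.98) without degenerate perfect separation, and gives the forest a continuous negative-score distribution that FPR thresholds can actually resolve |
| positive_rate | 3 per transcript per tissue (Poisson) | ~1 positive per 150 candidate C's — the dozens-to-hundreds imbalance real scans face |
| label_noise | 0 | the clean default; when set, each implant is recorded as negative with that probability and a matching expected number of background C's are recorded as spurious positives |

Implantation overwrites background sequence at non-overlapping loci
(rejection sampling a motif-free background would bias the positive
rate); the anchor C itself is never mutated. What the generator does
**not** model: read-level bisulfite conversion error, transcript
expression (all transcripts equally covered), soft secondary-structure
context, shared motif families between related tissues, and genuine m5C
sequence preferences. Passing the end-to-end tests therefore demonstrates
that the machinery recovers a planted statistical signal under realistic
imbalance — not that any particular AUC will be attained on experimental
data.

## Numerical and degenerate-input conventions

* Splits/samples draw from `numpy.random.default_rng`; every public
  entry point takes an explicit seed, and derived streams use seed
  sequences so stages are independent.
* `round(0.25·n)` is implemented as `floor(0.25·n + 0.5)` to avoid
  banker's rounding surprises; collections of fewer than 4 sites warn and
  force at least one test site.
* Negative sampling with an exhausted pool caps at the pool with a
  warning; an empty pool is an error (training would be impossible).
* Tied scores: single diagonal ROC segments, ½ concordance, conservative
  threshold placement (above).
* Model bundles are a directory with a standalone JSON manifest
  (algorithm, hyperparameters, scheme, w, tissue, seed, thresholds, tool
  version) plus a joblib payload protected by a SHA-256 checksum;
  corruption or a format-version mismatch raises instead of silently
  mispredicting.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the default conditions above
(100 transcripts, three tissues, ~700 training positives with 1:30
negatives for the comprehensive model) and compact variants (12–40
transcripts) for unit-level checks; these sizes were chosen as the
package's own desk-scale reference conditions.

## Known limitations

* The comprehensive/tissue predictors are only as transferable as their
  training tissue set; off-diagonal AUCs well below 0.5 on synthetic data
  reflect actively misleading foreign motifs, a sharper effect than real
  tissues show.
* FPR thresholds are calibrated against the synthetic negative
  distribution; on real transcriptomes the negative score distribution
  differs and thresholds should be recalibrated on matched negatives.
* `cp`→`ccp_alpha` is an approximation of rpart's complexity pruning.
* The CLI's `predict` scans every C; for chromosome-scale inputs use the
  `--sites` restriction.
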