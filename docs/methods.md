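# Methods

## Problem and data

PrkC is a *Bacillus subtilis* membrane Ser/Thr kinase. The benchmark is a
manually curated table of 36 experimentally identified PrkC phosphosites in
14 substrate proteins, embedded in the package as a TSV (accession, 1-based
position, gene, organism, PubMed ids) and validated at load time (36 rows, 14
distinct accessions, unique site keys). Negatives are all other S/T residues
of the same substrates — 512 on the canonical sequences the curators used.
Sequences are not bundled; `fetch_substrates` downloads the 14 UniProt
records on demand. Because UniProt sequence versions drift, dataset assembly
fails loudly (`ResidueMismatchError`) when a curated position no longer
carries S/T, rather than silently skipping and corrupting the 36/512 counts;
the negative count is recomputed from the supplied FASTA and reported, not
assumed.

## Windows and encoding

The prediction unit is the 31-mer window (flank half-width 15) centered on a
candidate S/T. Windows overhanging a terminus are padded with `X`, which the
encoding treats as an ordinary 21st symbol — terminal proximity thereby
becomes an implicit feature, unavoidable in a frequency-of-observed-symbol
encoding (the curated table itself contains near-terminal sites, e.g. ptsH
position 12). Non-standard letters in input FASTA (B, Z, U, O…) map to `X`
with a warning.

The location-feature encoding assigns to window position *i* the occurrence
frequency of the window's own residue at that position among the positive
training peptides (features 1–31) and among the negative training peptides
(features 32–62). Frequencies are raw counts over the class size with **no
pseudocounts** by default: an unseen (position, residue) pair scores exactly
0. An additive-smoothing parameter exists for experimentation but defaults to
0, since the plain occurrence frequency is the defining property of the
encoding. The center position is encoded like every other (it carries the
S-vs-T preference). Within cross-validation the frequency matrices are fitted
on the training folds only; a `leaky` option fits them once on the full
dataset to quantify what that form of leakage would change, and is never the
default.

Standardization is min–max to [0, 1] fitted on training vectors. Raw features
are already frequencies in [0, 1], so this is near-identity and fully
reproducible; constant features map to 0 and out-of-range query values are
clipped.

## Classifier and thresholds

An RBF-kernel SVM (scikit-learn `SVC`, libsvm backend) with the deployed
hyperparameters `C = 32.0`, `γ = 0.5`; a paired grid search over powers of
two (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³) maximizing pooled cross-validated AROC is
available, with ties broken toward smaller C then smaller γ. **No class
weighting** is applied despite the ~1:14 imbalance: the predictor's operating
points are set afterwards by threshold calibration, and the conservative raw
boundary of the unweighted SVM is exactly why the calibrated cutoffs come out
negative. Probability calibration is not used; all thresholds live on the
decision-value axis.

Scoring uses the explicit dual expansion Σᵢ αᵢ·K(svᵢ, x) + b over the stored
support vectors, so a model serialized to JSON (schema-versioned; floats
survive JSON round-trip exactly) scores identically after reload, without the
fitting backend. Training canonicalizes window order by (accession, position),
making the fit order-invariant.

The deployed model is trained on the full dataset; its high/medium/low
cutoffs come from pooled out-of-fold scores of a seeded stratified 10-fold
cross-validation, chosen as the smallest observed score reaching empirical
specificity ≥ 0.95 / 0.90 / 0.85 (prediction = positive at score ≥ cutoff; a
target of 0 yields a −∞ sentinel; an unreachable target raises). Published
cutoff values from any particular historical fit are artifacts of its exact
sequences and folds and are deliberately not reused.

## Evaluation

Folds are stratified per class — with 36 positives, unstratified 10-fold
splits can produce positive-free folds — and sized within ±1 per class.
Metrics are micro-averaged on pooled out-of-fold scores. Sn, Sp and Ac are
exact ratios; MCC uses the standard Matthews formula
(TP·TN − FN·FP)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)) — the test suite verifies
that this formula reproduces, to the printed precision, every published MCC
and accuracy value from the confusion tables implied by the published Sn/Sp
at 36/512, which is the evidence that the standard formula underlies those
numbers. Metrics with zero denominators are reported as undefined, never as
0. ROC curves sweep all distinct score cutoffs with ties grouped; AROC is the
trapezoidal area and equals Mann–Whitney pairwise counting with ties at ½ (a
brute-force oracle in the tests).

## Enrichment table

The logo-style comparison of residues around phosphosites is replaced by a
testable table: for each (offset −15…+15, residue incl. X) cell, positive
vs negative presence frequencies are compared by a two-proportion z-test with
pooled variance, falling back to Fisher's exact test unless every expected
count exceeds 5 — with 36 positives the exact test therefore carries most
cells. The original logo software's internal test is not documented, so this
choice is explicit and configurable; directions (enriched/depleted/n.s.) use
α = 0.05 with no multiple-testing correction by default (matching how logo
displays are read; a Bonferroni flag exists). The center offset 0 is included
since the S-vs-T preference is itself informative.

## Synthetic benchmark

The generator emulates the benchmark's structure: background proteins with
uniform residue composition (a composition table can be supplied), planted
S/T sites whose flanking offsets carry preferred residues with probability
*e* (the effect size), all other S/T positions labeled negative. The default
preference map mirrors the residue preferences observed around PrkC sites —
K at −10/−4/+7/+11, R at −9/−1, H at −13/+12, A at −5/−3, G at −2, F at +3
(where the observed preferences overlap at an offset, one residue was chosen
per offset so planted effects stay analytically simple). Defaults are 50
proteins of 350–450 residues with 4 sites each, giving ≈200 positives and
≈2000 negatives at roughly the benchmark's 1:10 class ratio; default effect
size 0.8. Planted sites are kept ≥31 residues apart and inside the
window-complete interior, so positive windows never overlap and every planted
offset falls within the protein; hard negatives near planted sites are kept.
At a planted cell the expected positive-minus-negative frequency difference
is ≈ e·(1 − 1/20), which the `empirical_effect` oracle checks.

What passing synthetic tests shows: the pipeline recovers planted
position-specific preferences (pooled 10-fold AROC ≥ 0.90 at e = 0.8,
chance-level at e = 0, monotone in between) and calibrates thresholds to
their specificity targets. What it does not show: performance on real
substrates, where signals are weaker, composition is biased, sites cluster
(e.g. 10 autophosphorylation sites on the kinase itself), and homologous
windows violate independence across folds.

## Numerical choices and limitations

- Seeds: every stochastic step (generation, fold assignment) is driven by an
  explicit integer seed; SVM fitting is deterministic given the canonical
  window order. Identical inputs and seed reproduce results bit-for-bit.
- Score comparisons after JSON round-trip agree to < 1e-9 (exact on one
  platform); kernel-expansion scores match the backend's decision function to
  < 1e-8.
- The problem sizes used by `scripts/acceptance.py` are the generator
  defaults above; the metric-arithmetic section uses the implied 36/512
  confusion tables directly.
- With only 36 positives, per-fold positive counts are 3–4 at 10-fold;
  pooled (not per-fold-averaged) metrics are the only stable summary, which
  is also why pooled sensitivities are multiples of 1/36.
- The predictor is specific to PrkC; no cross-kinase generalization is
  claimed. Homology between query and training substrates inflates apparent
  performance — predictions on training substrates are flagged via
  `seen_in_training`.
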