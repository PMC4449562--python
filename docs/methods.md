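# Methods

## The model

A linear B-cell epitope predictor over fixed-length peptide windows
(12–20 residues; 20 is the default and the best-performing window in the
original study design this package implements). Classification has three
stages, trained strictly in this order on training rows only:

**Encoding.** The anchoring pair composition of a peptide of length *l*
assigns one feature to every ordered residue pair `X.{i}Y` with *i*
intervening positions, *i* = 0 … *I*. The feature value is
*k*/(*l* − *i* − 1): occurrences over the number of length-(*i* + 2)
windows, so each gap stratum of a standard-residue peptide is a
composition summing to exactly 1. The space has 400·(*I* + 1) dimensions
in canonical gap-major order (`A.{0}A … Y.{0}Y, A.{1}A, …`). Occurrences
are counted at every start position independently (overlaps allowed).
The model assumes composition at short spacings carries the signal and
discards absolute position entirely.

**Feature selection.** A per-column pooled-variance two-sample Student's
*t*-test (two-sided, df = n₁ + n₂ − 2) between positive and negative
training rows; columns with *p* < cutoff survive. The classic pooled test
is used rather than Welch's because group sizes are balanced by
construction and the method is defined that way. No multiple-testing
correction is applied: the cutoff (default 0.5; 1.0 = no filtering) is a
tuned dial for noise suppression, swept over {0.2, 0.4, 0.5, 0.6, 1}
during model selection, not a significance claim.

**Classifier.** A soft-margin SVM with RBF kernel
K(x, x′) = exp(−γ‖x − x′‖²) (libsvm via scikit-learn). C and γ are chosen
by exhaustive search over C ∈ {2⁻¹², 2⁻¹⁰, …, 2²} × γ ∈ {2⁻⁵, 2⁻³, …, 2⁹}
(64 candidates), scored by stratified inner 5-fold CV on the training
rows; the tuning metric defaults to AUC (accuracy available). Ties break
toward the smallest C, then the smallest γ — the least complex model
among equals. Predicted label is the sign of the decision value
(threshold 0).

## Evaluation protocol

Stratified fivefold cross-validation with in-fold model building: for
each outer fold the *t*-test filter is fit, the grid searched, and the
SVM trained on the 4/5 training partition alone; the held-out 1/5 is
scored once. Encoding is computed once for all peptides — it is
per-peptide and label-free, hence leakage-safe. Final metrics **pool**
the concatenated held-out predictions of all five folds (per-fold values
are also reported); pooling is chosen over averaging because a single
pooled ROC is what a deployed threshold faces.

Metrics are Acc = (TP+TN)/(TP+FP+TN+FN), Sen = TP/(TP+FN),
Spe = TN/(TN+FP), MCC = (TP·TN − FP·FN)/√((TN+FN)(TN+FP)(TP+FN)(TP+FP)),
and AUC in the Mann–Whitney rank form (ties count ½), which equals the
trapezoid area under the empirical ROC to machine precision. Degenerate
denominators: a zero factor under the MCC root gives MCC = 0; an empty
Sen/Spe denominator gives 0.

The deployment path (`train_final_model`) fits selection and tuning on
all rows and is used for blind-set scoring and antigen scanning.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap` (I) | 3 | largest number of intervening residues; 400·(I+1) features. I = 3 matches α-helix i→i+4 spacing and won the original I ∈ {2,3,4} sweep |
| `p_cutoff` | 0.5 | *t*-test survival threshold (strict <); 1.0 disables filtering |
| `c_grid`, `gamma_grid` | 2⁻¹²…2² / 2⁻⁵…2⁹, steps of 2² | SVM grid, 64 candidates |
| `inner_folds` | 5 | grid-search CV folds inside each training partition |
| `tuning_metric` | auc | inner-loop selection criterion |
| window | 20 | peptide length; epitopes standardized to it before encoding |
| `identity_threshold` | 0.8 | greedy redundancy filter (fraction of matching positions) |

All stochastic steps (fold shuffling, inner CV, sampling, generation)
take explicit seeds; per-fold streams are derived via `SeedSequence` so
runs are bit-reproducible.

## Dataset construction

Raw epitopes of arbitrary length are standardized to the window:
shorter ones are extended symmetrically with flanking antigen residues
(odd deficit: the extra residue goes C-terminal; an exhausted flank
borrows from the other; an antigen too short to supply the window rejects
the record with a reason), longer ones trimmed symmetrically (odd excess:
extra trim C-terminal). Negatives are windows drawn uniformly over all
(sequence, offset) positions of a background proteome, rejecting any
window string-equal to a positive — equality of full windows, not
substring containment, since all windows share one length. Redundancy is
then reduced by a greedy filter that keeps a peptide iff its ungapped
identity to every kept peptide is below 80%. This is a deliberate
simplification of CD-HIT-style clustering (no k-mer prescreen, no
length-ordered representatives): adequate for fixed-length peptide sets,
but not byte-compatible with CD-HIT output. Order of operations:
standardize → filter.

Non-standard residues (B, J, O, U, X, Z) are kept in sequences and
flagged, but never counted as pair members; the encoding denominator
keeps the window geometry, so degenerate positions dilute the
composition rather than renormalizing it.

## The synthetic generator

`PlantSpec`/`generate` emulate the method's core premise — certain gapped
residue pairs occur more often in epitopes. Negatives are i.i.d. windows
from a background residue distribution (uniform by default); positives
are background windows into which each planted pair is written, with
probability `enrich_prob` and at a uniform random valid start,
overwriting the two anchor positions (overwriting rather than inserting
preserves window length; later plants may clobber earlier ones, so the
realized enrichment of early-listed pairs is below `enrich_prob` — a
documented, harmless property at 10 pairs).

Defaults are the package's standard study conditions: 200 + 200 20-mers,
10 fixed pairs (2 at gap 0, 2 at gap 1, 3 at gap 2, 3 at gap 3),
`enrich_prob = 0.9`, uniform background. These sizes keep a full nested
CV with the 64-candidate grid to a few seconds while leaving the planted
signal strong and the null clean.

What passing on synthetic data shows: the encoder, filter, tuner and
cross-validation machinery are correct, leakage-free and reproducible.
What it does not show: performance on real epitopes. Real peptide data
have non-uniform residue composition, correlated features from homology,
physicochemical structure (hydrophilicity, flexibility) and label noise,
none of which the generator attempts to mimic. Published benchmark
figures for this family of methods (AUC ≈ 0.75–0.81 on curated epitope
sets) should be expected only on comparable real datasets, which are not
shipped here.

## Numerical choices and degenerate inputs

- *t*-test columns with exactly zero pooled variance: *p* = 1 when group
  means agree (pure noise, exactly what the filter exists to drop), 0
  when they differ. An empty selection raises a configuration error
  rather than training on nothing.
- Gap strata with non-positive denominator (*l* ≤ *i* + 1) are zero
  blocks; no division is performed.
- The grid search precomputes squared-distance matrices per inner fold
  and derives each candidate's kernel from them — algebraically identical
  to refitting an RBF SVM per candidate, roughly 60× cheaper.
- AUC uses midranks, so heavy score ties are handled exactly; ROC points
  keep all thresholds so the trapezoid identity holds to 1e-12.
- Model archives are single JSON files (metadata + serialized solver
  state); metadata is readable without deserializing the solver, and a
  format-version mismatch fails loudly rather than mispredicting.

## Known limitations

- The greedy identity filter is quadratic in dataset size; fine at
  thousands of peptides, not designed for proteome scale.
- Only fixed-length windows are modeled; variable-length epitope sets
  must be standardized first (`build-dataset` does this).
- No probability calibration: scores are signed margins, comparable
  within one model only.
- Class imbalance is not reweighted; the intended datasets are balanced
  by construction.
- Scanning scores overlapping windows independently; no smoothing or
  per-residue aggregation is applied.
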