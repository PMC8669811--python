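# Methods

## Problem and model

`aipkit` treats anti-inflammatory peptide identification as binary
classification of short amino-acid sequences (length ≥ 5, the 20 standard
residues). The model is a pipeline: compositional descriptors, univariate
feature ranking, incremental subset selection, and a random-forest
classifier. Nothing in the pipeline uses structural or physicochemical
information; the working assumption is that class membership is
detectable from residue and dipeptide usage alone.

## Descriptors

**AAC** — per-residue frequencies, `N(j)/L`; 20 features, rows sum to 1.

**DDE** — for each of the 400 ordered dipeptides *j* = (a, b):

    DC(j)  = n_j / (L - 1)
    TM(j)  = (C_a / CN) · (C_b / CN)
    TV(j)  = TM(j) · (1 - TM(j)) / (L - 1)
    DDE(j) = (DC(j) - TM(j)) / sqrt(TV(j))

`C_a` is the number of sense codons encoding residue a and `CN = 61` the
total sense-codon count of the standard genetic code (stop codons
excluded); the table is configurable. TM lies strictly inside (0, 1), so
TV is never zero and no epsilon guard is needed (asserted by test). DDE
depends on the sequence only through its adjacent-dipeptide counts and
its length; a dipeptide absent from the sequence gets a negative value.

**GDC** — for gap g, ordered pairs at positions (i, i+g); a sequence of
length L contributes L − g pairs, and counts are normalised per sequence.
The pair convention (i, i+g) — rather than i, i+g+1 — is what makes g = 4
encodable for the minimum length 5 (exactly one pair, the termini), which
is the reason gaps 1–4 are the supported range. Sequences with L ≤ g are
rejected with the record named.

Feature order is fixed (alphabetical residues; row-major alphabetical
pairs) and block prefixes (`AAC:`, `DDE:`, `GDC1:` …) keep concatenated
matrices unambiguous, so saved matrices and models are portable.

## Feature selection

ANOVA score per feature: `S(t) = S_B²(t)/S_W²(t)` with the usual
between/within mean squares; for two groups this is the one-way F
statistic, and the implementation is tested to agree with an independent
F computation to 1e-10 relative error. Degenerate cases: zero
within-group variance with distinct means → +inf sentinel (perfectly
discriminative, ranked first); constant feature → 0. Ties in the ranking
keep original column order for stability.

IFS evaluates the leading k ranked features for k = step, 2·step, …, plus
the cap (full set by default), scoring each subset by pooled stratified
CV of the forest, and keeps the objective-maximising size (ties → the
smaller subset, for parsimony). The objective defaults to AUC and may be
any of SN/SP/ACC/MCC/AUC. Ranking happens once per training set, not per
inner fold.

## Unbiased reporting: selection nested in the folds

Running ANOVA+IFS on a dataset and then cross-validating the chosen
subset on the same data re-uses every label twice; on pure-noise data
(effect 0 below) that protocol measurably inflates pooled AUC above
chance (we observed ≈ 0.55–0.64 across seeds). The headline CV report
therefore re-runs the entire selection inside each training fold and
scores only the fold's held-out peptides; on null data this pools to
AUC ≈ 0.5 as it should. Selection on the complete training set is still
what defines the final deployable model — the two roles are separated in
`run_pipeline` (nested report vs `fit_final` artifact).

## Classifier

Random forest with WEKA-style defaults: 100 trees, `⌊log₂ d⌋ + 1`
candidate features per split (computed exactly at fit time; `sqrt` or an
integer are available for matching other backends), unlimited depth,
seeded. Prediction score is the positive-class vote fraction; the hard
label threshold is 0.5, with a score of exactly 0.5 classed positive.
Models persist as a joblib blob plus a JSON sidecar (schema tag, config,
feature names, class counts); prediction refuses matrices whose feature
names or order differ from training, naming the first mismatch.

## Evaluation

SN, SP, ACC from exact confusion counts; MCC with the convention that a
zero denominator factor yields 0. ROC is swept over all distinct score
thresholds; AUC equals the Mann–Whitney probability with ties credited ½
(verified against an O(n²) pairwise enumeration to 1e-12). Cross-validation
uses stratified, shuffled, seeded folds; the headline report pools
out-of-fold scores (per-fold reports are also returned, since pooled and
fold-averaged summaries can differ on imbalanced data).

## Synthetic data generator

The generator emulates two peptide classes whose separability is
controlled per channel:

* `effect` — compositional divergence. Positives draw residues i.i.d.
  from `p⁺ = p_base + (effect/2)·d`, negatives from
  `p⁻ = p_base − (effect/2)·d`, with `d` the ±1/10 contrast between the
  two alphabet halves. The total-variation distance between the class
  compositions equals `effect` exactly (design constant c = 1).
  Distributions that would leave [0, 1] are rejected, never clipped.
* `dipeptide_effect` — transition bias. Positives become a first-order
  Markov chain whose transitions up-weight same-half successor residues
  by `1 + ε` and cross-half ones by `1 − ε`. For the uniform base the
  rows are exactly normalised and the stationary composition stays
  uniform, so AAC carries (almost) no signal while DDE/GDC do. The
  residual AAC signal is a genuine dispersion effect — chains that
  prefer staying within a half produce overdispersed half-compositions —
  and is small (AUC ≈ 0.55 at ε = 0.4) compared to the DDE channel.

Defaults: 200+200 peptides, lengths uniform on [5, 30] (chosen as a
realistic short-peptide range; the reference datasets for this problem
state only the minimum 5), uniform base composition for analytic
transparency (a UniProt-like preset is available), seeded end to end.
The generator makes no claim of biological realism — no motifs, termini
preferences or modifications — so passing tests demonstrate that the
pipeline recovers compositional/transition signal at realistic sample
sizes, not that real AIPs are identifiable at any particular accuracy.

## Problem sizes and numerical choices

Calibration and signal-recovery runs use 200+200 peptides with IFS step
200 over the 820-feature AAC+DDE+GDC-gap1 matrix and 5-fold nested CV —
small enough for quick desk runs, large enough that the null band
[0.40, 0.60] and the signal threshold (AUC ≥ 0.85 at effect 0.3) are
comfortably resolved. Feature matrices serialise to TSV with `%.17g`
formatting and parse back with round-trip float precision, so
write-then-read is bit-exact. All estimator randomness (forest, folds,
generator) flows from explicit integer seeds; two identically seeded
end-to-end runs produce byte-identical JSON reports.

## Known limitations

* Comparison descriptors (CKSAAGP, CTriad, GAAC, GDPC, GTPC, TPC) are not
  implemented; `register_encoder` exists as the plugin point.
* Only the random forest ships; alternative classifiers can be passed to
  the selector but no tuned configurations are provided.
* Redundancy reduction (CD-HIT-style clustering) is out of scope and
  assumed to have been applied upstream of any real dataset.
* Pooled CV metrics on strongly imbalanced data should be read together
  with the per-fold reports; the package computes both but optimises AUC
  by default.
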