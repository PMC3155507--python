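# Methods

This note documents the models and procedures implemented in `betaturn`,
the defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic fixtures can demonstrate.

## Turn labeling

Ground-truth β-turn labels come from the geometric definition: a start
index *i* qualifies when |Cα(*i*) − Cα(*i*+3)| < 7 Å (strict inequality)
and the quadruple *i..i+3* is not helical. The helix exclusion is
configurable because "does not form an α-helix" is ambiguous for partial
overlaps: the default `all` mode rejects a candidate only when all four
residues are flagged helix (the weakest reading); `any` mode rejects on
any helical residue. With no helix mask, every residue counts as
non-helix. These labels are self-consistent geometric ground truth; they
do not reproduce the hydrogen-bond and dihedral criteria of
structure-annotation programs, and turn types (I, II, VIII, …) are not
classified.

## Shape-string transfer

The predictor is pure homology transfer, not machine learning. Hits with
e-value strictly below 10⁻⁵ are sorted ascending (ties broken by database
id for determinism) and consumed greedily: an aligned pair (t, d) writes
the database shape character at d onto target position t only if no
better-ranked hit already claimed t. "Matched part" is read
per-position, so target positions gapped inside one hit remain available
to later hits. One pass is made over the ranked list; leftover fragments
are not re-searched. Unclaimed positions become `X`, and the reported
coverage is the non-`X` fraction.

Prediction accuracy is the fraction of **all** positions whose predicted
character equals the reference (`X` never matches). A `covered_only`
variant restricts the denominator to assigned positions; the all-positions
default is the stricter and more informative convention since it charges
the method for what it cannot cover.

Two search backends exist behind one interface. The built-in backend is
a deterministic local aligner (BLOSUM62, gap open −11 / extend −1) whose
e-value is the Karlin–Altschul-style surrogate K·m·n·e^(−λs) with
λ = 0.267, K = 0.041 (the standard gapped BLOSUM62 constants). Only the
*order* of these surrogate e-values matters to the greedy transfer; they
are not calibrated database e-values. The PSI-BLAST adapter shells out
to `psiblast` (XML output, iteration count configurable, one iteration
by default) and converts HSPs to aligned index pairs. A naive quadratic
identity filter (`filter_by_identity`, default 30 % threshold) is
provided for de-redundanting fixture-scale databases only.

## Feature encoding

Per residue: 20 logistic-scaled PSSM values, 3-bit one-hot secondary
structure (H, E, C order), 9-bit one-hot shape (S, R, U, V, K, A, T, G,
X order); the per-residue block order PSSM | SS | shape is fixed and
stored with trained models so mismatched encodings are refused. The
window of 8 slides without terminal padding, so a chain of length L
yields L − 7 samples and the first two and last five residues are never
window centers. A window is labeled positive exactly when a turn starts
at window offset 2, i.e. the turn's four residues coincide with the
central four; a looser any-overlap labeling is available behind a flag.
Double logistic scaling is an error, not a warning, because it silently
compresses the feature range. Non-standard amino acids map to `X` and
carry their PSSM row unchanged; they contribute no one-hot bits only in
the sense that `X` is not an SS state (it is a ninth shape state).

Window scores are mapped back to residues, when asked, by an explicit
reducer: a residue's score is the maximum over windows whose central
four contain it. This is reporting plumbing; all headline measures are
computed at the window (sample) level.

## Two-layer model

K-means (k-means++ init, 10 restarts, Euclidean, seeded) splits the
positive training windows into two clusters on the raw feature vectors;
clusters are renumbered so cluster 1 is the larger (ties by lower
centroid norm). Each cluster trains an RBF SVM against negatives drawn
uniformly without replacement at round(3 × n_pos), independently per
cluster (overlap between the two negative draws is allowed). Probability
outputs use libsvm's Platt-style sigmoid calibration, recorded in the
model archive. The default hyperparameters are (C, γ) = (0.5, 2⁻⁷) for
both clustered models and (32, 8) for the second layer; with
`grid_search` enabled, each classifier's pair is re-optimized over
C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³ (step ×4) by 5-fold inner CV accuracy, ties
to the smallest C then smallest γ.

The clustered models are *variable generators*, not predictors: after
fitting they are frozen (serialized bytes identical before and after
second-layer training, asserted in tests), every sample passes through
both, and the second layer is trained on the 4-vectors
(p₁⁺, p₁⁻, p₂⁺, p₂⁻) of **all** training samples with their original
labels. In plain (non-CV) training the second layer therefore sees
meta-features produced by generators fit on overlapping data, which is
optimistic; cross-validation avoids this by refitting both layers per
fold. An empty K-means cluster triggers up to five reseeded retries
before erroring. All sub-seeds (clustering, negative sampling,
calibration, per-fold training) derive deterministically from the master
seed.

## Evaluation protocol

Folds are random equal-size partitions at the sample level (remainder
spread one per fold), matching the protocol the model was designed
under; windows from one chain may land in different folds, which leaks
local sequence context between training and test. A chain-level
alternative would remove that leakage but changes the protocol, so
sample-level remains the default. Zero-denominator conventions:
Q_predicted is 0 with a warning when nothing is predicted positive;
MCC is 0 when any marginal is empty; Q_observed raises, because an
evaluation set without observed positives is invalid. AUC uses midrank
tie handling and is verified in tests against a brute-force
Mann–Whitney pairwise count.

## Synthetic fixtures

The generators exist to make the pipeline's statistical assumptions hold
by construction, so that recovery is a meaningful check of the
machinery:

- **Geometry**: an extended Cα chain (3.8 Å steps, d(i, i+3) = 11.4 Å)
  with a hairpin template at each requested turn start that brings
  exactly that quadruple to ≈5.4 Å. The template occupies six residues,
  so requested starts must be ≥ 6 apart; every construction is verified
  against the distance predicate before returning.
- **Feature world**: positives drawn from two compact Gaussian modes
  (σ = 0.03) separated by 10σ along a random direction inside the unit
  cube, negatives uniform; ~2 100 samples at a 1:3 class ratio, 32
  features. This is the fixture for clustering-recovery and
  cross-validation checks.
- **Shape world**: targets with random 8-state shape strings; database
  entries are copies under new ids with point mutations (default rate
  0.1) in both sequence and shape, optionally truncated to create `X`
  regions; a mock backend returns surrogate e-values e^(−matches),
  monotone in mutation count.
- **Full study**: the same machinery written to disk in the tool's
  external formats, with synthetic PSSMs whose turn-residue rows carry a
  +5 mean shift on eight columns, coil-enriched secondary structure and
  turn-state-enriched shape strings (10 % noise each) so the planted
  signal survives encoding.

Defaults (48 chains of 44–60 residues for the feature world, 30 chains
of 30–60 residues for the on-disk study) keep every test and the
acceptance script within seconds on one CPU while leaving enough samples
per fold for stable measures.

What passing these fixtures does **not** show: performance on real
proteins. Real turn signals are far weaker and noisier than the planted
modes, real amino-acid composition and PSSM marginals are not emulated,
and the near-perfect desk-scale measures are a property of the
construction, not a performance claim. The fixtures validate the
machinery — greedy transfer, encoding, stacking, fold bookkeeping — not
the biology.

## Known limitations

- Turn labels approximate, and turn types are outside, what dihedral-based
  annotation provides.
- The built-in aligner's surrogate e-values are order-correct but not
  calibrated; absolute thresholds are only meaningful with the PSI-BLAST
  backend.
- Sample-level folding allows homology leakage between folds (see
  above); this is the documented default, not an oversight.
- The single-SVM baseline uses the first-layer (C, γ) on the raw
  features; its own grid optimum might differ.
- Shape strings are consumed from a database; computing them from 3-D
  structures, and sequence-based shape prediction for uncovered
  positions, are out of scope.
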