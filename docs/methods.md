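# Methods

## Descriptor model

A peptide is modelled as a string over the 20 proteinogenic canonical amino
acids; ambiguity codes and non-natural residues are hard errors, and the
minimum length is 3 so that the tripeptide block always has at least one
window. All composition blocks are normalized by the chain length *L*
(counts divided by *L*, not by the window count), which makes block sums
carry exact identities used as invariants: the AAC block sums to 1, DPC to
(L−1)/L, TPC to (L−2)/L, and each CKSAAGP gap-k slice to max(L−k−1, 0)/L.
A window-count normalization is available behind `normalize_by="windows"`
for users who prefer per-window frequencies.

The default configuration concatenates AAC (20) + DPC (400) + TPC (8000) +
CKSAAGP (5 groups × gaps 0–15 = 400) + 5 physicochemical + 5 atomic + 1
length descriptor = **8831** features. The layout is configurable; the
feature-name scheme (`BLOCK_subscript`) is normative so persisted models can
verify column alignment byte-for-byte.

### CKSAAGP grouping

The default 5-way physicochemical partition is aliphatic {G,A,V,L,M,I},
aromatic {F,Y,W}, positive {K,R,H}, negative {D,E} and polar non-charged
{S,T,C,P,N,Q}. Feature names use the five distinct codes (ALI, ARO, PC, NC,
PNC); report displays collapse the two hydrophobic groups to the alias `H`,
the convention used in the CPP literature's importance plots. Five groups —
not the three of the display legend — are required for the 400-entry block
of the 8831 accounting.

### Charge model

Net charge at a given pH is the Henderson–Hasselbalch sum of fractional
protonation states over the ionizable groups: N-terminus and K/R/H side
chains contribute +1/(1+10^(pH−pKa)); C-terminus and D/E/C/Y side chains
contribute −1/(1+10^(pKa−pH)). The default pKa table (configurable) is
N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1 —
a widely used sequence-analysis default chosen so that outputs are exactly
reproducible rather than tied to a particular library version. Z(pH) is
strictly decreasing, positive at pH 0 and negative at pH 14, so pI is its
unique root; bisection on [0, 14] iterates until |Z| < 1e−9, comfortably
inside the 1e−6 contract verified by tests and cross-checked against a
0.001-pH grid scan. Net charge is reported at pH 7.0 by default
(physiological conditions).

### Scales, mass, atoms

GRAVY is the Kyte–Doolittle mean hydropathy by definition. The second
"hydrophobicity" descriptor defaults to the Eisenberg consensus scale — a
deliberate design choice where any single published scale would do, kept
distinct from GRAVY so the two features are not duplicates; both scales are
selectable by name. Molecular mass uses average (not monoisotopic) masses
derived from standard atomic weights and the free amino-acid formulas, with
one water per peptide bond removed; the same formula table drives the atomic
block, so mass and atom counts cannot disagree. Atomic frequencies are the
whole-molecule C/H/N/O/S counts (residues + one water) divided by *L*.

## Feature selection

Step 1 is a per-feature two-sided Mann-Whitney U test between the two
classes, keep iff p < α = 0.05, with **no** multiple-testing adjustment by
default — the filter is reproduced as practiced, raw p-values over all
features; a Benjamini–Hochberg switch exists for users who want it.
Constant features are assigned p = 1 and dropped. The exact null
distribution is used when both samples have ≤ 8 observations and no ties;
otherwise the normal approximation with tie and continuity corrections. The
statistic itself is computed by scipy; the test suite checks it against an
independent exhaustive-permutation oracle.

Step 2 fits an extremely-randomized-trees ensemble on the surviving features
and keeps the top-k (default 522) by mean impurity-decrease importance,
descending, with alphabetical tie-break for determinism. The pipeline
driver enforces the order: filter first, ranking second.

A centered truncated SVD (scikit-learn PCA) is provided for model
exploration; centering makes the reported explained-variance fractions
interpretable, and component requests beyond the centered rank are clamped
with a warning.

## Classifier

The default learner is an extremely-randomized-trees ensemble with 500
unpruned trees, Gini impurity, √d candidate features per split, no
bootstrap, seed 42 — recorded verbatim in every model bundle. Random
forest, gradient boosting (xgboost), SVM and MLP are selectable
alternatives with no bespoke logic; SVM/MLP get per-column standardization
fitted on training folds only. The decision threshold is 0.5, exposed as a
parameter.

Stage 2 (high vs low uptake efficiency) trains on the five atomic
frequencies only. Chaining is a presentation choice made explicit: stage-2
scores are reported only for stage-1 positives, and are otherwise an
explicit "not applicable", never a silent score.

Cross-validation is stratified 10-fold with shuffling under the given seed.
`cross_validate` scores a fixed feature matrix; `cross_validate_pipeline`
additionally refits the Mann-Whitney filter and the ERT ranking inside each
training fold. The distinction matters: selecting features on the full data
before CV leaks the held-out folds into the selection and inflates
null-data AUC well above chance, so the pipeline-level estimate is the
fold-honest one and is what the acceptance checks use.

Model bundles persist as a directory: JSON manifest (format version,
hyperparameters, ordered feature names, SHA-256 of each estimator file,
SHA-256 of the training data) plus joblib-serialized estimators. Loading
verifies version and hashes; prediction refuses matrices whose columns
differ from the training columns in name, order or count — no silent
re-alignment.

## Synthetic data

The generator emulates the compositional structure that separates CPPs from
non-CPPs: positives draw residues i.i.d. with R and K up-weighted by an
enrichment factor e (default 4), negatives with D and E up-weighted by e;
lengths are uniform on 5–30 residues (the field's "short peptide" range).
This yields cationic, nitrogen-rich positives (median pI > 7) and
anionic, oxygen-rich negatives, a mean net-charge gap of several units at
e = 4, and exchangeable classes at e = 1 (a true null). The efficiency
generator makes both classes CPP-like and up-weights the nitrogen-rich
residues R, N, Q, H by (1 + atomic_shift) in the high class, so the
normalized nitrogen frequency separates the classes with a tunable effect
size and shift 0 is again a null. Label noise, when requested, flips a
fixed fraction of labels post hoc.

What the generator does **not** emulate: positional or secondary-structure
signal, the similarity structure of curated benchmark sets (sequence
identity caps, artificial-negative heuristics), or real uptake-assay noise.
Passing tests therefore demonstrate that the pipeline recovers planted
compositional/physicochemical signal and stays at chance under the null —
not that it attains any particular accuracy on experimental CPP benchmarks,
which requires the external curated datasets.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the study's desk scale:
500 peptides per class for the stage-1 pipeline (10-fold CV, fold-honest
selection), ten generator seeds for the marker-recovery sweep, 140 per
class for the efficiency stage (its real-world training size), and
reduced sizes (≈ 30–150 per class, 50–100 trees) for unit-level checks.
Determinism is part of the contract: identical seeds give byte-identical
predictions, and save→load→predict is bit-stable.

Tie-breaks and degenerate inputs: equal importances order alphabetically;
all-constant matrices select nothing and the pipeline then falls back to a
majority-class prediction in CV; metrics with zero denominators are flagged
undefined and printed as "–" rather than coerced to 0; AUC uses the rank
formulation (exact, ties ½) and is test-verified against trapezoidal ROC
integration to 1e−12.

## Known limitations

* Benchmark-grade performance claims require the external curated CPP
  datasets; this package ships none and makes no such claims on its own.
* The pKa table, hydrophobicity scale and CKSAAGP partition are defensible
  defaults, not uniquely determined by the literature; all are
  configurable, and published results using other conventions will differ
  in the third decimal of physicochemical descriptors.
* The two-stage chaining assumes stage-2 training data (known CPPs with
  measured uptake) is representative of stage-1 positives at prediction
  time.
* i.i.d. residue sampling means the synthetic data cannot probe
  order-sensitive descriptors (DPC/TPC/CKSAAGP) beyond what composition
  implies.
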