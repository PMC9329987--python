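# Methods

## Problem setting

Given circRNA sequences annotated with a single sub-cellular locality out of
eight compartments (Exosome, Cytosol, Nucleus, Membrane, Nucleolus,
Nucleoplasm, Chromatin, Insoluble Cytoplasm), the task is multi-class,
single-label prediction from the residue string alone. The package covers the
full pipeline: descriptor extraction, descriptor fusion, benchmark cleaning,
and cross-validated evaluation of five classical classifiers. Sequences are
normalized to the RNA alphabet on input (uppercase, T→U); ambiguity codes are
dropped by default with a logged count (`strict` mode rejects them instead) —
locality databases rarely document how ambiguous residues were handled, so a
permissive-but-logged default was chosen.

## Descriptors

All descriptors slide linear windows with stride 1 and normalize frequency
blocks by the number of valid windows (m−k+1 for k-mers), not by sequence
length. Although circRNAs are circular molecules, windows do not wrap around
the backsplice junction: the inputs are the linear sequence records that
databases distribute, and no principled wrap-around rule exists for them.

Two definitions deserve explanation because the literature is loose about
them:

- **PseudoKNC** is implemented as the *cumulative* tuple composition over
  sizes 1…K (dimension 4+16+…+4ᴷ). A plain K-tuple composition would be
  identical to the k-mer descriptor; the cumulative form matches common
  pseudo-KNC toolkit implementations and keeps the two descriptors genuinely
  distinct.
- **EIIP** is the fixed-length trinucleotide form: feature t =
  (EIIP(t₁)+EIIP(t₂)+EIIP(t₃)) × f(t) over the 64 trinucleotides, with the
  published per-residue constants (A 0.1260, C 0.1340, G 0.0806, U 0.1335).
  A per-position EIIP signal has variable length and cannot feed fixed-input
  classifiers directly.

For the gapped descriptors a configuration with gap = G emits concatenated
blocks for g = 1…G, so increasing G strictly adds information and the grid
over G is nested; a `cumulative_gap=False` flag restores the single-g form.
A gap value whose window exceeds the sequence contributes an all-zero block
rather than an error, so short sequences degrade gracefully.

Reverse-complement canonicalization maps each k-mer to the lexicographic
minimum of itself and its reverse complement (A↔U, C↔G), giving 10, 32 and
136 canonical forms at k = 2, 3, 4.

Encoders are vectorized (integer codes + `bincount`); the test suite holds
them to within 1e−12 of naive window-enumeration oracles.

## Fusion

A fusion spec is a set of descriptors with pairwise-distinct ids; vectors are
concatenated in id-sorted order with id-prefixed feature names, so component
order never changes the output. Fusion is plain concatenation without
rescaling — the tree ensembles that dominate this task are scale-invariant;
SVM users should standardize the fused matrix themselves. Each component
defaults to its best standalone hyperparameters (k = 5 for the k-mer family,
gap = 5 for tri-mono-kgap, gap = 2 for di-mono-kgap).

## Dataset preparation

Three cleaning stages, each logged in a provenance map of survivor counts:

1. **Multi-locality filter** — records annotated to more than one compartment
   are discarded (the task is single-label).
2. **Deduplication** — identical residue strings across tissues collapse to
   the first record when their labels agree; identical strings with
   conflicting labels are dropped entirely, keeping labels unambiguous.
3. **Cross-class redundancy reduction** — a greedy reducer in the spirit of
   CD-HIT-2D: classes are visited in descending size order (schema order
   breaks ties) and a record is removed when its identity to any retained
   record of an earlier class reaches the threshold (default 0.8).
   Within-class similarity is never grounds for removal. Identity is the
   count of identical residues in the best global alignment (match +1,
   mismatch 0, unit gap penalty — the gap penalty shapes the alignment only)
   divided by the shorter sequence's length, the CD-HIT convention. A
   provably safe 4-mer-sharing bound skips alignments for pairs that cannot
   reach the threshold.

The largest-first visiting order is a design choice: redundancy-reduction
tools do not fix which member of a cross-class pair is removed, and removing
from the smaller class preserves the majority classes' coverage.

## Synthetic data

Each class is a first-order Markov chain over (A, C, G, U) with uniform
initial distribution. Class c's transition matrix is
(1−d)·U + d·S_c, where U is the uniform matrix and S_c puts 0.7 of row i's
mass on successor (i+1+c) mod 4 and 0.1 elsewhere; the divergence d ∈ [0, 1]
is the single separability knob. d = 0 makes all classes identically uniform
(a true null), d = 1 gives strongly separable chains. First-order chains are
the minimal model visible to every descriptor family: transition preferences
drive the k-mer/kgap features directly, and the induced stationary
composition feeds Z-curve and EIIP. Lengths are uniform on 213–2,000 —
the lower portion of the circRNA length range, capped to keep grid searches
fast. Custom transition matrices and initial distributions can be supplied
explicitly; rows must sum to 1 within 1e−9.

The generator can also inject cleaning decoys (multi-locality rows, exact
cross-tissue duplicates, 10%-mutated cross-class near-duplicates) to exercise
the preparation pipeline end to end.

What the generator does *not* emulate: backsplice-junction structure,
genome-derived composition, length–class correlation, or class imbalance
beyond what `class_sizes` requests. Passing tests therefore demonstrate that
the pipeline recovers a planted compositional signal, not that any accuracy
level transfers to real circRNA data.

## Classifiers, metrics and validation

The zoo is random forest, XGBoost, AdaBoost, SVM and Gaussian naive Bayes,
built on scikit-learn/xgboost with every seed threaded from the caller.
Multi-class SVM uses the one-vs-rest decision function; margins are converted
to pseudo-probabilities by a softmax so that ROC analysis applies uniformly
across models.

Metrics are computed from the confusion matrix. Accuracy is the trace over
the total; specificity TN/(TN+FP), F1 and MCC are computed one-vs-rest per
class with the standard binary formulas and macro-averaged over the classes
present in the evaluated records. The macro average was chosen because the
per-class binary definitions generalize to multi-class only through
averaging, and macro weighting is the convention that does not let the
dominant class mask minority-class failure. A class whose ratio is undefined
(zero denominator) contributes 0 and is flagged in the report. AUROC is
one-vs-all per class via the tie-averaged rank (Mann–Whitney) formula,
macro-averaged over classes present in the truth; classes without negatives
are skipped with a warning.

Cross-validation is stratified and seeded (records are id-sorted before fold
assignment so input order is irrelevant). Stratification matters here:
benchmark classes can be as small as ~20 members, and unstratified 10-fold
splits would regularly produce test folds missing whole classes. When the
smallest class has fewer members than the requested fold count, the fold
count is downgraded to that size with an explicit warning, never silently.

Grid search is exhaustive over the featurizer × model grid with bounds
k ∈ 2–5, gap ∈ 2–5, 20–200 estimators, gini/entropy criteria,
linear/polynomial/RBF kernels, and naive-Bayes smoothing 1e−9–1e−1. The best
entry maximizes mean CV accuracy with ties broken by macro F1 and then by
lexicographic configuration label, so results are deterministic. The search
is run over CV means, not nested within CV; reported figures are model-
selection optima, not unbiased generalization estimates.

## Problem sizes and numerical choices

The end-to-end planted-signal check uses 200 sequences (two classes of 100),
k-mer k = 3 features, a 100-tree random forest and 10-fold CV — accuracy
≥ 0.9 at divergence 1.0, and chance-level behaviour at divergence 0
established by a 19-permutation label-shuffle test (p > 0.05). Unit tests use
smaller sets (dozens of sequences, lengths 60–300) chosen so the whole suite
runs in well under a minute apart from that end-to-end check. Encoder
agreement with the brute-force oracles is asserted at 1e−12 (pure counting
arithmetic admits essentially no float error); stationary-distribution
convergence of the generator is checked at length 10,000 with tolerance 0.02.

## Known limitations

- No reproduction of any real-database benchmark: results on synthetic data
  establish correctness of the machinery, not biological performance.
- No over-/under-sampling for class imbalance, no feature selection after
  fusion, no probability calibration, no deep models.
- The redundancy reducer is greedy and order-dependent by design; a different
  class-visiting order can retain a different (equally valid) survivor set.
- SVM pseudo-probabilities from softmaxed margins are monotone in the margins
  but not calibrated; their AUROC is meaningful, their absolute values are not.
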