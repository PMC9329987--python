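# circloc

Sequence descriptors, descriptor fusion and a multi-class evaluation harness
for predicting the sub-cellular localization of circular RNAs (circRNAs) from
raw sequence alone.

circRNAs are covalently closed non-coding RNAs whose compartment of residence
(exosome, cytosol, nucleus, ...) conditions their regulatory role, yet is
expensive to determine experimentally. `circloc` provides the computational
side of that problem for bioinformaticians benchmarking sequence-based
predictors: it turns residue strings into fixed-length statistical vectors,
fuses descriptors, cleans locality-annotated sequence collections into
benchmark datasets, and evaluates classical machine-learning classifiers under
stratified cross-validation.

## What is implemented

**Seven sequence descriptors.** For a sequence S = R₁R₂…R_L over {A, C, G, U}
(T is mapped to U on input):

- **k-mer** — normalized counts of the m−k+1 stride-1 windows, dimension 4ᵏ.
- **RC-kmer** — k-mers collapsed with their reverse complements (A↔U, C↔G);
  at k = 2 the 16 dimers reduce to 10 canonical features.
- **PseudoKNC** — cumulative tuple composition over sizes 1…K
  (dimension Σᵢ 4ⁱ, e.g. 1364 at K = 5).
- **Z-curve** — the three signed counts
  x = (A+G)−(C+U), y = (A+C)−(G+U), z = (A+U)−(G+C).
- **EIIP** — trinucleotide electron–ion interaction pseudopotential:
  (EIIP(t₁)+EIIP(t₂)+EIIP(t₃)) · f(t) for each trinucleotide t, using
  A = 0.1260, C = 0.1340, G = 0.0806, U = 0.1335.
- **DiMonoKGap / TriMonoKGap** — counts of a di-/tri-nucleotide followed,
  after a gap of g skipped bases, by a single nucleotide; gap = G emits the
  concatenated blocks g = 1…G (64 resp. 256 features per block).

**K-order fusion.** Any subset of the seven descriptors concatenated in
canonical order; `enumerate_fusions(k)` generates all C(7, k) subsets
(21 second-order fusions, 120 across orders 2–7).

**Dataset preparation.** Multi-locality records are discarded, exact
duplicates across tissues collapsed (conflicting labels dropped), and
cross-class near-duplicates removed by a greedy CD-HIT-2D-style reducer at a
global-alignment identity threshold of 0.8 (identity = identical aligned
residues / shorter length), visiting classes largest-first over an
eight-compartment schema (Exosome, Cytosol, Nucleus, Membrane, Nucleolus,
Nucleoplasm, Chromatin, Insoluble Cytoplasm).

**Evaluation harness.** Random forest, XGBoost, AdaBoost, SVM (one-vs-rest,
softmaxed margins for scores) and Gaussian naive Bayes, under seeded
stratified 10-fold cross-validation with exhaustive grid search. Metrics:
accuracy, macro one-vs-rest specificity TN/(TN+FP), macro F1, macro per-class
MCC, and one-vs-all AUROC by the tie-averaged rank method.

**Synthetic data.** Per-class first-order Markov chains over (A, C, G, U)
with a single `divergence` knob interpolating between indistinguishable
classes (0) and strongly separable ones (1), lengths uniform on 213–2,000.

## Worked example

Simulate two weakly divergent classes, then cross-validate a k-mer/random
forest pipeline:

```sh
circloc simulate --classes 2 --sizes 60,60 --divergence 0.05 --seed 11 --out-dir sim
circloc evaluate --fasta sim/sequences.fasta --labels sim/labels.tsv \
    --descriptor kmer --k 3 --model rf --folds 10 --seed 11 --out report.json
```

prints

```
wrote 120 sequences to sim
mean accuracy 0.842 (macro F1 0.836) over 10 folds
```

and `report.json` carries the full mean report:
`accuracy 0.842, specificity_macro 0.842, f1_macro 0.836, mcc_macro 0.707,
auroc_macro 0.932`. At divergence 0.05 each class's transition matrix sits
only 5% of the way from uniform toward its signature, so trinucleotide
composition separates the classes well (AUROC 0.93) but not perfectly; the
same data with `--descriptor zcurve --model nb` reaches only accuracy 0.450 —
whole-sequence base balance barely sees a signal that lives in transition
preferences. At `--divergence 1.0` the same pipeline is error-free, and at
`--divergence 0` it sits at chance.

The same workflow is available programmatically:

```python
from circloc import (DescriptorConfig, GeneratorSpec, ModelConfig,
                     cross_validate, sample_dataset)

data = sample_dataset(GeneratorSpec(class_sizes=(60, 60), divergence=0.05, seed=11))
result = cross_validate(data, DescriptorConfig("kmer", k=3),
                        ModelConfig("random_forest"), folds=10, seed=11)
print(result.mean_report.as_dict())
```

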