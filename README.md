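# mirclass

`mirclass` classifies mature microRNAs (miRNAs) as disease-associated or
background from three families of descriptors: sequence characteristics,
predicted target genes, and the signaling pathways those targets belong to.
It is aimed at computational-biology groups building miRNA biomarker panels
(e.g., for non-invasive cancer diagnostics from liquid-biopsy miRNAs) who
want the whole path — descriptor generation, attribute selection, training,
and evaluation — as one reproducible, scriptable pipeline instead of a chain
of GUI tools and ad hoc scripts.

## What it computes

**Descriptors.** For each mature miRNA sequence *s* over {A,C,G,U}:
nucleotide counts *n_b* and frequencies *f_b = n_b / |s|*, length, GC
fraction, single-strand molecular weight MW(s) = Σ m(s_i) + 18.0 Da,
Watson–Crick hydrogen-bond capacity 3(n_G + n_C) + 2(n_A + n_U), the 16
dinucleotide frequencies, and binary presence flags for a configurable motif
panel. From a target-prediction table (miRDB-export style) and pathway gene
sets (TSV/GMT), it adds binary `gene_<SYMBOL>` attributes (prediction score
≥ 80 by default) and `path_<name>` attributes (≥ 1 high-confidence target in
the pathway's gene set).

**Attribute selection.** Attributes are ranked by information gain,
IG(a) = H(C) − H(C | a) in bits, after Fayyad–Irani MDL discretization of
numeric attributes — the behavior of WEKA's `InfoGainAttributeEval`.

**Classifier.** The headline model is a discrete Bayesian-network classifier
with naive structure: P(C | x) ∝ P(C) Π_j P(x_j | C), with MDL-discretized
numerics and conditional probability tables smoothed by a pseudo-count
α = 0.5. Baselines behind the same contract: Gaussian naive Bayes,
entropy-split and random decision trees, and a random forest
(scikit-learn). `BayesNetClassifier`, `InfoGainSelector` and
`MDLDiscretizer` are scikit-learn estimators and compose with sklearn
pipelines.

**Evaluation.** Stratified k-fold cross-validation (default k = 5) with
pooled out-of-fold scores: accuracy, class-weighted precision/recall/F,
ROC curve with trapezoidal AUC (equal to the normalized Mann–Whitney U
statistic), PR curve with step-integral AUPRC, and a learning-curve
experiment over training-set sizes.

**Synthetic benchmark.** Because real positive/background miRNA sets are
study-specific, `mirclass.synthdata` generates miRBase-shaped FASTA, target
tables and pathway sets with a controllable class signal in three orthogonal
channels (GC composition, a spiked motif, target-gene incidence), so every
stage is testable offline.

## Worked example

```bash
mirclass synth --seed 3 -o run        # 100 positive + 100 background miRNAs
mirclass featurize --fasta run/sequences.fasta --labels run/labels.csv \
    --targets run/targets.tsv --pathways run/pathways.tsv -o run/features.arff
mirclass rank --table run/features.arff --top 3
mirclass eval --table run/features.arff -o run/report.json
```

Output of `rank` and `eval` on this draw:

```
class entropy: 1.000000 bits
attribute	info_gain
gc_fraction	1.000000
f_U	0.862119
f_GG	0.845676

metric	value
accuracy	1.0000
precision	1.0000
recall	1.0000
f_measure	1.0000
auc	1.0000
auprc	1.0000
```

The benchmark's default class signal is strong (GC shift 0.6, motif spike
0.9 vs 0.1), so GC fraction alone separates the classes — its information
gain of 1.0 bit equals the class entropy of the balanced label set — and
5-fold cross-validated accuracy and AUC are 1.0. Weaker signals
(`--gc-shift 0.15 --motif-p-pos 0.6 --motif-p-neg 0.4 --gene-shift 0.1`)
land accuracy in the 0.7–0.85 range where attribute selection and
classifier choice start to matter. `train` and `predict` complete the loop
on new, unlabeled miRNAs:

```bash
mirclass train --table run/features.arff -o run/model.json
mirclass predict --model run/model.json --table run/features.arff -o run/pred.csv
```

`pred.csv` holds one positive-class probability and a 0.5-threshold label
per miRNA.

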