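# rnafam

Predicting the functional family of short non-coding RNAs (ncRNAs,
≤ 200 nt — tRNA, rRNA, snRNA/snoRNA, miRNA, riboswitches and other
cis-regulatory elements, …) **from raw sequence alone**, without
computing secondary structure.

The package is aimed at researchers who want to annotate large volumes
of short transcripts by family: structure-based annotators fold every
candidate (O(N⁵)–O(N⁷) per sequence), while the encodings here are
linear or near-linear in sequence length and feed standard deep
networks.

## What it does

* **Lightweight encodings.** Non-overlapping k-mer one-hot vectors
  (k ∈ {1,2,3}; a 100-nt sequence at k = 2 becomes 50 binary vectors of
  16 entries), and two-dimensional foldings of the sequence onto
  Hilbert, Morton (Z-order) and Snake (boustrophedon) space-filling
  curves (16×16, 16×16 and 15×15 grids at 200 nt). Three padding
  schemes: `random`, `constant`, and `new` (a dedicated symbol outside
  the DNA alphabet).
* **Classifiers.** A standard CNN with 0–3 convolution blocks
  (kernel 3, 32·2^i filters, ReLU, max-pool, 50% dropout; dense
  1000/500; softmax; Adam), an improved 5-layer CNN (batch norm, Leaky
  ReLU, Gaussian noise every 2 layers, 20% dropout, dense 128/64;
  AMSGrad at 5·10⁻⁴), and bidirectional LSTMs (50/100/150 units) over
  unpadded k-mer sequences. All run on a compact numpy training core
  included in the package — no GPU or deep-learning framework needed.
* **Rigorous evaluation protocol.** Homology-aware 84/8/8 splits (no
  validation/test sequence within normalized-Hamming similarity 0.50 of
  a same-class training sequence), a length-only decision-tree screen
  for length-predictable classes, boundary-noise robustness experiments
  (composition-preserving flanks of 0–200% of the sequence length), and
  dinucleotide-preserving shuffles as non-functional decoys.
* **Rejection of non-functional or uncertain sequences.** Monte Carlo
  Dropout (N_mc = 50 stochastic forward passes) with two uncertainty
  estimators on the class-probability sample p_ik:

      H = −Σ_k p̄_k · log₂(p̄_k + ε)                      (Information Entropy)
      D = p̄_k₁ − c·σ_k₁ − (p̄_k₂ + c·σ_k₂),   c = 0.6     (Top Difference)

  rejecting when H > ⅓·log₂C or D < 0.
* **Synthetic benchmark.** A generator of multi-family datasets with
  planted motifs, overlapping length distributions and controlled
  composition, so the full pipeline can be exercised and tested with no
  external download.

## Worked example

```python
import numpy as np
from rnafam import (KmerEncoder, NeuralSequenceClassifier, SplitConfig,
                    SyntheticSpec, classification_report,
                    generate_family_dataset, similarity_aware_split)

# 3 families x 300 sequences with planted family motifs
dataset, _ = generate_family_dataset(
    SyntheticSpec.easy(n_families=3, n_per_family=300, seed=7))
split = similarity_aware_split(dataset, SplitConfig(seed=7))

encoder = KmerEncoder(k=1, max_len=200, padding="new").fit()
clf = NeuralSequenceClassifier(family="cnn_standard", n_conv_layers=1,
                               batch_size=64, max_epochs=40, seed=0)
clf.fit(encoder.transform(split.train.records),
        np.array(split.train.labels()),
        validation_data=(encoder.transform(split.validation.records),
                         np.array(split.validation.labels())))

pred = clf.predict(encoder.transform(split.test.records))
report = classification_report(split.test.labels(), pred)
print(f"test accuracy {report.accuracy:.2f}  kappa {report.kappa:.2f} "
      f"mcc {report.mcc:.2f}")
```

```
test accuracy 0.90  kappa 0.85 mcc 0.85
```

Accuracy is the fraction of the 71 homology-filtered held-out sequences
assigned their true family; kappa and MCC correct that agreement for
chance (0 would mean guessing, 1 perfect), so the shallow network
recovers the planted family structure well from raw sequence at this
small training size. The full-scale checks below use 8 families × 500
sequences and reach higher accuracies.

The same workflow is available from the shell:

```bash
rnafam simulate --families 8 --per-family 500 --seed 1 --easy --out data/sim
rnafam split data/sim.fasta data/sim.tsv --seed 1 --out data/sim
rnafam train data/sim.train.fasta data/sim.train.tsv \
    --val-fasta data/sim.validation.fasta --val-labels data/sim.validation.tsv \
    --arch cnn1 --rep 1mer --out models/cnn1
rnafam reject models/cnn1 data/sim.test.fasta --estimator entropy --out rej.tsv
```

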