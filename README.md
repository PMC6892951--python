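# pepconv

Per-allele prediction of peptide–MHC class I binding with a small
convolutional network over anchor-preserving 15mer encodings.

MHC class I molecules present short intracellular peptides (mostly 8–15
residues) on the cell surface; predicting which peptides an HLA allele
binds is the computational core of epitope discovery and neoantigen
vaccine design. `pepconv` is for immunoinformaticians who want a compact,
fully reproducible allele-specific predictor and a test bed for its
feature engineering:

1. **Length normalization.** Every 8–15mer is mapped onto a canonical
   15-symbol frame using an artificial padding residue `X`, placed so that
   the two anchor-bearing segments of the 9-residue binding core (original
   residues 1–4 and 6–9) are never interrupted: peptides of length ≥ 9 are
   right-padded; an 8mer gets a single gap at frame position 5 so its
   residues 5–8 land on core pockets 6–9.
2. **Dual encodings.** A peptide is featurized either as a 15×21
   extended-BLOSUM62 matrix (row = substitution-score vector of the
   residue at each frame position; `X` is one-hot against itself) or as a
   4×15 chemical-property matrix with rows *sequence index* (1–21),
   *Eisenberg consensus hydropathy* (0 for `X`), *polarity class* (0–4),
   and *peptide length* — or both stacked (25×15).
3. **Per-allele CNN.** A classifier with two 1-D convolution layers of 20
   filters each (ReLU, max pooling), a dense head and a sigmoid output is
   trained per allele on binary binder labels (quantitative affinities cut
   at 500 nM, eluted ligands as positives), and evaluated by shuffled
   five-fold cross-validation with F1 = 2·TP/(2·TP + FN + FP) and
   ROC AUC.
4. **Length-preference probe.** A trained model scores 10,000 random
   peptides (1,250 per length 8–15); the length distribution of the
   top-scoring 2% reveals the allele's apparent length preference.

Because real training corpora live in external databases, the package
ships a first-class synthetic-data generator that plants a recoverable
anchor-pocket motif, hydropathy bias and length preference, so the whole
pipeline is testable end to end.

## Worked example

```python
import numpy as np
from pepconv import (MotifSpec, PeptideConvNet, auc_score,
                     generate_allele_dataset, probe_model)

ds = generate_allele_dataset(MotifSpec(), n=2000, seed=7)     # synthetic allele
peps, labels = ds.peptides, np.asarray(ds.labels)

rng = np.random.default_rng(7)
idx = rng.permutation(len(peps))
tr, te = idx[:1600], idx[1600:]

model = PeptideConvNet(random_state=7)          # faithful preset: 2x20 filters
model.fit([peps[i] for i in tr], labels[tr])
auc = auc_score(labels[te], model.decision_scores([peps[i] for i in te]))
print(f"held-out AUC {auc:.3f}")

report = probe_model(model, seed=7)
print(f"modal probe length {report.modal_length}, "
      f"9mer share {report.proportions.get(9, 0):.2f}")
```

Output:

```
held-out AUC 0.972
modal probe length 9, 9mer share 0.38
```

The held-out AUC of 0.97 says the network recovered the planted
anchor-pocket motif from 1,600 training examples; the probe's modal
length of 9 (38% of the top 2% of 10,000 random peptides) recovers the
planted 9mer preference — the behaviour expected of a class I allele.

The same workflow is available from the shell:

```bash
pepconv synth --n 2000 --seed 7 --out run/synthetic.tsv
pepconv train run/synthetic.tsv --outdir run/train --seed 7
pepconv evaluate run/synthetic.tsv --outdir run/eval --seed 7
pepconv lengthpref --models run/train/models --outdir run/pref --seed 7
```

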