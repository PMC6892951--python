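# Methods

## The prediction problem

An MHC class I molecule binds peptides in a groove whose specificity is
dominated by a 9-residue core; pockets at core positions 1, 4, 6, 7 and 9
("anchors") contribute most of the binding energy, while flanking residues
matter less. `pepconv` casts binding prediction as per-allele binary
classification: given an allele and a peptide of length 8–15, output the
probability that the peptide is a binder.

## Length normalization

Alleles bind peptides of several lengths, but a fixed-size input is needed
for matrix encodings. Every peptide is therefore embedded in a 15-symbol
frame over a 21-letter alphabet (the 20 standard amino acids plus an
artificial residue `X` that is related only to itself). The placement rule
is deterministic and keeps the anchor-bearing segments intact:

* L ≥ 9: residues occupy frame positions 1..L; positions L+1..15 are `X`.
* L = 8: residues 1–4 occupy positions 1–4, one `X` sits at position 5,
  residues 5–8 occupy core pockets 6–9, then `X` to position 15.

This is the simplest rule under which original residues 1–4 and 6–9 are
never interrupted by padding. Other placements (e.g. distributing the gap
differently for mid-length peptides) satisfy the same constraint; the rule
is centralized in `peptides.normalize_to_15mer` so it can be swapped.
Positions are 1-based everywhere, matching anchor nomenclature.
Ambiguity codes (B, Z, J, U, O) are rejected rather than mapped to `X`,
because `X` carries padding semantics; lowercase input is uppercased.

## Feature encodings

Three interchangeable views of the normalized frame, all emitted
channels × 15 so they can feed the same network:

* **substitution** (21 channels): each position contributes its row of a
  21×21 extended BLOSUM62 table. The 20×20 block is the canonical NCBI
  BLOSUM62 integer matrix, embedded verbatim with an sha256 checksum; the
  `X` row/column is all zeros except `X–X` = 1.
* **chemical** (4 channels): sequence index (alphabet position 1–21, 21
  iff `X`), Eisenberg consensus hydropathy (0 for `X`), polarity class
  (0 = padding, 1 = nonpolar, 2 = polar uncharged, 3 = acidic,
  4 = basic), and the original peptide length repeated across the frame.
* **stacked** (25 channels): both of the above concatenated.

No scaling is applied by default — raw table values are the faithful
input — but per-channel standardization is available (`standardize=True`)
for experiments. The default network input is the chemical view, the
distinctive feature set of the method; the substitution and stacked modes
are exposed because either could plausibly drive the classifier, and the
choice is a single constructor argument.

## The classifier

`PeptideConvNet` (faithful preset): two 1-D convolution layers over the
15-position axis with 20 filters each, kernel width 3, each followed by
ReLU and non-overlapping max pooling of width 2; a dense layer of 64 ReLU
units with dropout 0.25; a single sigmoid output. Feature rows enter as
channels rather than as a second spatial axis, because the 4 chemical
rows are unordered categories, not a spatial dimension. Training
minimizes binary cross-entropy (computed in logit space for stability)
with Adam (learning rate 1e-3), mini-batches of 32, up to 100 epochs, and
early stopping on an internal 10% validation split (patience 10, best
weights restored). Weights use He-normal initialization.

The forward and backward passes are written directly in numpy, which
keeps the dependency surface minimal and makes runs bit-reproducible:
identical seed, data and configuration give identical weights. Training
refuses degenerate inputs (fewer than two examples, or a single class)
and aborts with diagnostics if the loss becomes non-finite.

Defaults with units and rationale:

| parameter | default | notes |
|---|---|---|
| `encoding_mode` | `chemical` | 4×15 property matrix; see above |
| `n_filters` | 20 | per convolution layer (fixed in the faithful preset) |
| `kernel_size` | 3 | positions; smallest window spanning a pocket and its neighbours |
| `pool_size` | 2 | positions |
| `dense_units` | 64 | conventional small head |
| `dropout` | 0.25 | regularization for dozens-to-thousands of examples per allele |
| `learning_rate` | 1e-3 | Adam default scale |
| `batch_size` | 32 | — |
| `max_epochs` / `patience` | 100 / 10 | early stopping on validation loss |
| `threshold` | 0.5 | probability cut turning scores into class calls for F1 |
| `random_state` | 42 | pinned for reproducibility |

One model is trained per allele on all its lengths (the 15mer frame is
what makes mixed-length training possible). A variant that trains four
submodels per allele by length group (L ≤ 8, L = 9, L = 10, L ≥ 11) is
provided as `LengthGroupedConvNet`; groups with single-class data fall
back to their base rate.

## Data handling

Measurement tables are delimited text with at least `allele` and
`peptide` columns; the full dialect also carries measurement value,
inequality, type, source and original allele. Labels: quantitative
affinity ≤ 500 nM is a binder (the field's IEDB convention; the cut is
configurable), with inequality-aware resolution — `<v` is positive only
when v ≤ cut, `>v` negative only when v ≥ cut, anything else is
indeterminate and quarantined with a reason. Qualitative `Positive*` /
`Negative` calls map to 1/0; eluted-ligand detections are positives.
Duplicate (allele, peptide) pairs keep one record, preferring
quantitative over qualitative over eluted-ligand provenance. Alleles are
retained only with strictly more than 20 examples. Cross-validation uses
a seeded global shuffle followed by k near-equal folds (remainder to the
earliest folds); stratified folds are available but off by default.
Every input row ends up either retained or quarantined with a reason —
nothing is dropped silently.

## Evaluation

Per fold: F1 = 2TP/(2TP + FN + FP) at the 0.5 probability cut and
Mann–Whitney AUC (ties counted half). A fold whose training or held-out
portion lacks a class is skipped and reported, not averaged. When no
example is positive and none is predicted positive the F1 denominator is
zero; the score is defined as 0 and flagged (`f1_is_degenerate`) so
degenerate alleles are never hidden in a cohort mean. Across alleles:
mean, median and sample standard deviation (ddof 1; 0 for a single
allele) of per-allele mean F1 and AUC, an F1 histogram over the bins
< 0.5, 0.5–0.9, > 0.9, and an AUC decile histogram.

## Length-preference probe

10,000 random peptides — 1,250 per length 8–15, residues uniform over
the 20 standard amino acids (a background-frequency table can be supplied
instead of the uniform draw at generation time by sampling externally) —
are scored by a trained model; the top 2% (exactly ⌈0.02·N⌉ = 200, ties
broken by stable input order) are selected and their original-length
distribution reported with its mode.

## The synthetic-data generator

Real per-allele corpora are external, so the generator emulates one
allele's dataset with planted, recoverable structure; its defaults define
the reference conditions used throughout the tests:

* n = 2,000 examples, half positive;
* anchor pockets 1, 4, 6 and 9 prefer {R,K}, {D,E}, {I,L} and {F,W}
  respectively — chemically distinctive pairs (basic, acidic, aliphatic,
  aromatic) so every feature view can express them;
* positives' lengths follow a 9mer-peaked distribution
  (8: .08, 9: .60, 10: .12, 11: .06, 12: .04, 13: .04, 14: .03, 15: .03),
  matching the class I norm; negatives draw lengths uniformly;
* positives' non-anchor residues carry a mild hydropathy bias
  (weights ∝ exp(0.5 · hydropathy)), reflecting the hydrophobic
  preference of proteasomal products; negatives are uniform;
* label noise 0 by default (configurable flip rate < 0.5).

Two design points deserve emphasis. First, anchors are planted at
*frame* positions, not raw-peptide indices: anchors model groove pockets,
and aligning residues to pockets is precisely what the length
normalization does — an 8mer's fifth residue occupies pocket 6. Planting
at raw indices would give shorter peptides a smaller, easier motif and
distort the probe's length readout. Second, the anchor preference is
probabilistic — each pocket carries a preferred residue with probability
`motif_strength` (default 0.9) — because a deterministic motif would make
the label a function of anchors alone; a discriminative model then has no
incentive to learn the planted length preference or hydropathy bias, and
the probe's modal length becomes unidentifiable. Probabilistic anchors
are also the biologically sane reading: real motifs are preferences, not
rules.

`motif_strength` acts as a single signal dial s ∈ [0,1]: it scales the
anchor probability, multiplies the hydropathy bias, and interpolates the
positive length distribution toward uniform. At s = 0 positives and
negatives are drawn from identical distributions, so any classifier must
score at chance — the generator's own null control. Anchor enrichment
among positives is checkable by plain frequency counting
(`anchor_enrichment`), independent of any model.

What the generator does **not** emulate: real HLA motif chemistry,
inter-allele similarity, the extreme per-allele sample-size skew of
public corpora, assay noise structure, or mass-spectrometry detection
bias. Passing the synthetic-recovery tests therefore demonstrates that
the pipeline can extract planted anchor/length/hydropathy structure at
realistic sample sizes — not that it attains any particular accuracy on
real measurement data.

## Numerical and procedural choices

* Reference problem sizes: n = 2,000 examples per synthetic allele,
  five-fold cross-validation, 10,000-peptide probes — large enough that
  the recovery statistics are stable across seeds, small enough for
  interactive runs.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cross-validation folds, weight initialization, batching and
  dropout are all seed-deterministic.
* Batch prediction equals one-at-a-time prediction to 1e-6 (pure
  feed-forward inference, no batch-dependent state).
* Ties at the probe's top-2% boundary are broken by stable input order.
* The embedded BLOSUM62 block is checksummed at load; the test suite
  additionally cross-checks it against Biopython's copy.

## Known limitations

* No pan-allele transfer: alleles with few examples get weak models, and
  nothing is shared across alleles.
* The 500 nM labeling cut is a convention; measured affinities near the
  cut produce labels more uncertain than the model's probabilities
  acknowledge.
* The probe scores random peptides far outside the training
  distribution; its length readout reflects model extrapolation as well
  as learned preference.
* Inference-time behaviour is deterministic, but exact bit-reproducibility
  across BLAS builds is not guaranteed for the trained weights.
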