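# Methods

## Problem and model

Pyrrolidone carboxylic acid (PCA, pyroglutamate) forms by cyclization of a
glutamine residue, almost exclusively at Q. `pcasite` predicts whether an
*internal* glutamine (residue position > 1; the N-terminal chemistry is a
different problem and is out of scope) is a PCA modification site, from
sequence-derived features alone.

Each candidate site is represented by a 21-residue window: the Q at window
site 11 plus 10 flanking residues on each side. Windows that run off a
protein terminus are padded with `-`. Positive windows come from annotated
sites, deduplicated on the full 21-mer (first occurrence kept); negatives
are drawn uniformly without replacement from the remaining internal Q
windows (also deduplicated against positives and among themselves) at a 1:5
positive:negative ratio. The draw takes an explicit integer seed that is
recorded in the run metadata, because an unseeded draw would make the
dataset irreproducible.

### Feature space

Every window site contributes features from up to 7 property families:

| family | per site | source |
|---|---|---|
| PSSM conservation scores | 20 | PSI-BLAST ASCII profile (log-odds block) |
| Atchley amino-acid factors | 5 | embedded table |
| disorder score | 1 | per-residue track (e.g. a VSL2-style predictor) |
| secondary structure (one-hot helix/strand/other) | 3 | per-residue track |
| solvent accessibility (one-hot buried/exposed) | 2 | per-residue track |
| interface / surface conservation propensity | 2 | embedded tables |
| evolutionary gain/loss index | 1 | embedded table |
| side-chain carbon deviation | 1 | computed from the window |

The center site always holds Q, so its residue-identity families (Atchley
factors, interface/surface, gain/loss) are constant and are omitted: 27
features at the center, 35 at each of the 20 flanking sites, 35·20 + 27 =
727 columns at the default flank of 10. Column order is a pure function of
the flank: sites ascending; within a site PSSM (alphabetical), AAFactor,
Disorder, SS, ACC, InterfaceSurface, GainLoss, CarbonDeviation.

Pad positions contribute 0 to every feature. The carbon-deviation feature
is each residue's side-chain carbon count minus the mean count over its own
window, with pads counted at the 20-amino-acid mean (3.35); the 21 values
of any window therefore sum to zero. The sign convention (residue minus
window mean) is recorded in the matrix metadata; the phrase "deviation from
the mean" is directionally ambiguous, and the cosine classifier and the
discretized mutual information are insensitive to a consistent global flip
of this one column family.

PSSM values are the log-odds integers of the PSI-BLAST ASCII profile (not
the percentage block), used raw; an optional z-score switch exists in
`encode_dataset` but defaults off, since the cosine distance is
scale-sensitive and the choice must be explicit.

### Embedded tables

The Atchley five-factor solution (polarity, secondary structure, molecular
volume, codon diversity, electrostatic charge) is reproduced from the
published values; the factors are centered over the 20 amino acids. The
gain/loss index and the interface/surface conservation propensities are
single-valued per-residue tables whose published sources are qualitative
trends rather than a canonical numeric table; the embedded defaults encode
those trends (C/M/H/S/F as evolutionary gainers, P/A/G/E as losers;
hydrophobic and aromatic residues enriched at interfaces, polar/charged on
surfaces) and can be overridden from CSV. Side-chain carbon counts are
chemical constants (G=0 … W=9).

## Feature ranking: mRMR

Features are ranked by greedy maximum-relevance minimum-redundancy.
Relevance of feature f is the mutual information MI(f, c) with the class;
redundancy is the mean MI with the already-selected set. Round 1 picks the
most relevant feature; round h+1 picks

argmax over remaining f of [ MI(f, c) − (1/h) Σ_{s selected} MI(f, s) ].

This difference form (MID) is the default; the quotient form (MIQ) is a
switch. MI is the plug-in estimate over the empirical joint distribution,
in bits; marginals are computed from integer counts before a single
division, which keeps mathematically equal values bitwise equal. Continuous
columns are discretized per column before estimation with a three-state
mean ± σ rule (below μ−σ → 0, within → 1, above μ+σ → 2), mirroring common
mRMR practice; equal-frequency binning and categorical passthrough are
alternatives. Ties at any round break toward the lowest column index, so
the full ranking is deterministic and invariant to row order.

## Classifier and evaluation

The classifier is the 1-nearest-neighbor rule under the cosine
dissimilarity D(x,y) = 1 − ⟨x,y⟩/(‖x‖‖y‖) ∈ [0, 2]; a query takes the label
of the closest training sample, ties toward the lowest sample index.
Evaluation is jackknife (leave-one-out): each sample is predicted by all
the others, and the confusion counts give

* Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
* MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC = 0
  whenever a factor under the root vanishes (standard convention).

`nna_distance` rejects zero vectors (the cosine is undefined); inside the
batch jackknife a zero-norm row — possible when a small feature prefix
zeroes a sample — is given similarity 0 (distance 1) to everything, a
convention that keeps the sweep defined without privileging either class.

### Incremental feature selection

IFS evaluates the jackknife on growing prefixes of the mRMR ranking
(k = 1..N at stride 1; a stride parameter exists for coarse sweeps and
always includes the full set). The optimal feature set is the smallest
prefix attaining the maximum MCC. The sweep maintains the Gram matrix of
the growing prefix incrementally — adding one ranked column's outer product
per step — so a full stride-1 sweep costs O(N·n²) rather than O(N²·n²);
equivalence with the per-subset jackknife is tested on integer-valued
matrices, where floating summation order cannot perturb an argmin.

`analyze_feature_set` reports how an optimal set distributes over the 8
families and the 21 sites, the numeric content of the usual composition
bar charts; `position_frequencies` computes the per-site residue
frequencies behind a sequence logo (rendering is out of scope).

## Synthetic data

The generator ships the study conditions as defaults: 333 positives, 1:5
negatives, flank 10 (1998 windows of 21 residues). Two routes honor the
same `SyntheticSpec`:

* **window + profile route** — random sequences (uniform residue
  composition by default, configurable) with a planted internal Q per
  protein, plus synthetic annotation tracks: integer PSSM rows, uniform
  disorder in [0,1], categorical SS/ACC calls. A bias parameter can shift
  the tracks of positive windows at chosen sites; bias 0 makes every
  marginal label-independent. This route exercises dataset → annotations →
  encoder end to end and its matrices satisfy all encoder invariants.
* **direct matrix route** — unit-variance Gaussian noise columns;
  informative columns have the positive-class mean shifted by
  `effect_size` noise standard deviations. Under a full window schema,
  one-hot families remain valid one-hots and become informative through
  class-dependent category probabilities instead of mean shifts.

What the generator does not emulate: evolutionary correlation structure in
PSSMs, real sequence motifs around PCA sites, and the correlated
disorder/structure tracks of real predictors. Passing planted-signal tests
therefore demonstrates the statistical machinery (ranking recovers
informative columns; IFS finds a compact high-MCC prefix), not performance
on real annotations — real-data accuracy depends on the external profile
generators (PSI-BLAST, a disorder predictor, a secondary-structure
predictor) that this package only parses.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale, chosen so the
statistical checks are stable over seeds: dataset arithmetic at the full
333/1665 scale (cheap), and planted-signal recovery at n = 600 samples ×
200 columns with 10 informative columns at effect size 3, evaluated over 5
seeds. At these sizes the whole pipeline is deterministic given the seed;
every artifact records the resolved configuration and its hash.

## Known limitations

* "Internal" is interpreted as position > 1 (configurable); no numeric
  definition exists beyond the internal/N-terminal split.
* Negative-pool identity is full 21-mer identity; site-level identity is a
  stricter alternative the data do not disambiguate.
* The gain/loss and interface/surface default values are documented trend
  encodings, not canonical published tables; override them for real
  analyses.
* Only the jackknife evaluator is shipped; k-fold is out of scope, as are
  alternative classifiers.
* N-terminal PCA sites are excluded by design.
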