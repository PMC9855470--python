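# Methods

## Model and assumptions

`chemfuse` treats a compound library as an ordered list of molecules, each
with a canonical SMILES, a binary DILI label, and an optional, partially
missing seven-assay in vitro profile (HepG2, Huh7, CYP1A2, CYP2A6, CYP2C9,
CYP2D6, CYP3A4 on a pChEMBL-like scale). The method assumes only that the
label is *statistically* associated with some of the representations — it
fits no predictive model. Its output is descriptive: a fused 2-D map in
which label-enriched regions of the individual representations are
amplified and label-balanced regions are suppressed.

The pipeline is: featurize → embed each representation to 2-D → score a
3×3 region grid per embedding with the quadrant weight QW → multiply
coordinates by their region's QW → min-max normalize each axis → sum across
representations. Clustering efficiency is the mean within-class pairwise
distance (Euclidean and Manhattan) — lower within-positive means indicate
tighter clustering of hepatotoxic compounds.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| t-SNE perplexity | 30 | effective neighbor count | standard mid-range value; auto-shrunk below (n−1)/3 with a warning for small libraries |
| t-SNE iterations | 1000 | optimizer steps | enough for stable layouts at n ≤ a few thousand |
| t-SNE theta | 0.5 | Barnes–Hut accuracy (0 = exact) | usual speed/accuracy trade-off |
| seed | 42 | integer | t-SNE is stochastic; every run is seeded, and multi-representation runs derive one seed per representation (seed + index) |
| grid size k | 3 | cells per axis | 3×3 is the method; other k exposed for exploration only |
| QW formula | `prose` | — | see "Design choices" |
| qw_offset | 0 | added to every cell QW | 0 is faithful (QW = 0 cells collapse to the origin); a positive offset restores injectivity for users who need it |

## Representations and encoding decisions

- Fingerprints are used as raw bits (already commensurate); the six
  physicochemical properties are z-scored (population SD) before embedding
  because daltons and counts would otherwise dominate the Euclidean
  geometry. Constant columns map to zeros.
- cLogP is the Crippen atom-contribution estimate; other tools' logP
  values differ in absolute terms, which is immaterial here since logP is
  one of six features feeding a rank-free embedding.
- MACCS exposes exactly the 166 public keys (the internal 167-slot
  convention's unused slot 0 is dropped).
- In vitro missing values are imputed to the observed per-assay mean
  (i.e. 0 after z-scoring) and flagged in seven companion mask columns, so
  missingness itself is visible to the embedding. An assay observed in no
  compound becomes an all-zero column and is logged, not fatal.
- Euclidean distance is used for t-SNE on all representations, including
  bit vectors, where it is monotone in Hamming distance.

## Quadrant weighting

The grid spans the bounding box of the *positive* compounds — min/max of
their coordinates per axis, split into three equal-width intervals; the
outer rows/columns extend to ±infinity so every compound (including
negatives outside the box) is assigned to exactly one cell. Membership uses
half-open intervals [lo, hi) with a closed last bin. If the positives are
coincident on an axis the grid falls back to the full-dataset range on that
axis, with a warning.

Two QW conventions are implemented. The default (`prose`) is
QW = ((A − NA)·100/n)/2: symmetric, zero when a cell is balanced, +50/−50
when all n compounds are positive/negative and in one cell, and positive
exactly when the cell is positive-enriched — the property every downstream
step relies on. The `literal` option, −(A·100)/n + (NA·100/n)/2, preserves
an alternative printed form of the score whose sign structure contradicts
the enrichment interpretation; it is provided for comparison only.

Weighting multiplies *both* coordinates by the cell's scalar QW. This is
deliberately non-injective: balanced cells collapse to the origin and
negative cells reflect through it. Normalization happens *after* weighting.

## Fusion

Per axis, NWtSNE = (WtSNE − min)/(max − min); a constant axis maps to zeros
with a warning. The consensus is the unweighted element-wise sum of the
normalized spaces, so coordinates lie in [0, k] for k sources. The sum is
computed over sorted addends per coordinate, making fusion exactly (bitwise)
invariant to the order the spaces are listed in. The consensus sum is not
re-normalized to [0, 1]. An unweighted variant (skip the QW stage) is
exposed to quantify the weighting's contribution. Two presets name the
source subsets of interest: `all5` and `rdkit+invitro`.

## Evaluation

Means and SDs are computed over all C(n_c, 2) unordered within-class pairs;
SDs are population SDs (the pair set is the whole population of interest,
not a sample from it). Cross-class mean distance is reported as
supplementary output. `compare_spaces` ranks spaces by within-positive mean
(stable sort; ties keep input order) and flags whether every fused space
precedes every single-representation space.

## Synthetic data generator

The generator emulates a curated DILI table: ~30 % positive fraction
(configurable), drug-like molecules assembled from a packaged pool of 28
scaffold templates (14 carrying halogen, sulfur or phosphorus — atom
classes over-represented among hepatotoxic drugs) combined with 23
substituents and variable alkyl tails, all RDKit-validated, canonical and
unique. With the `structure` signal on, positives draw hetero scaffolds
with probability 0.8 and negatives draw plain scaffolds with probability
0.8 (the symmetric choice makes the structural signal two-sided); with the
`invitro` signal on, positives' assay values are Normal(base + effect, sd)
versus Normal(base, sd) for negatives, with base 5.0, effect 1.5 and sd 1.0
by default and 10 % of entries masked missing at random.

What it does *not* emulate: real structure–toxicity relationships (no
toxicophores, no SAR), realistic assay correlation structure, or the label
geometry of any real library. Tests passing on synthetic data therefore
demonstrate that the machinery amplifies a planted label signal — not that
any particular real library will show the same distance magnitudes. In
particular, the bounded-reproduction check runs on a synthetic n=471
stand-in and reproduces the strong qualitative compression (fused
within-positive means ~30× below single-space means) while the absolute
fused within-positive level remains above the level reported for the real
curated library whose geometry the generator does not model.

## Numerical choices and degenerate inputs

- Determinism: fixed (matrix, reducer, params, seed) gives byte-identical
  coordinates; the CLI writes the resolved config into every output
  directory and builds outputs in a temp directory renamed atomically.
- PCA is computed by SVD of the column-centered matrix with the
  largest-magnitude loading of each component forced positive, so axes are
  reproducible and row-order invariant; a rank-1 input yields a null
  second axis.
- Loader: unparseable SMILES rows are dropped and counted; duplicate
  canonical SMILES collapse to the first occurrence (conflicting labels are
  warned about, not merged); canonicalization only — no salt stripping or
  tautomer normalization.
- Embedding requires n ≥ 4; weighting requires ≥ 1 positive; evaluation
  requires ≥ 2 compounds per class; normalization requires n ≥ 2.

## Problem sizes

The test suite and the reproduction script use n = 471 (three seeds) for
the full five-representation pipeline, n = 200 for signal recovery, and
n = 40–120 elsewhere; a full 471-compound five-representation run takes
~10 s on one CPU.

## Known limitations

- QW weighting is non-injective by design; compounds in QW = 0 cells become
  indistinguishable in that space.
- The 3×3 grid is coarse; enrichment below cell scale is invisible.
- t-SNE coordinates are implementation- and seed-dependent, so absolute
  distance values are comparable only within one run; only within-run
  orderings and ratios are meaningful.
- Fusing a weak view with a strong one can dilute the strong view's
  clustering; the consensus is typically, not universally, better than the
  best single representation on the default synthetic conditions.
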