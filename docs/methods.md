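# Methods

This note documents the models, formulas, conventions and design choices
behind `thermostab`, in the spirit of a methods supplement: everything a
user needs to know to interpret the features, the training protocol and
the synthetic benchmarks. No empirical number is stated here that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Data model and curation

A record is `(id, sequence, species?, OGT?, Tm?)`. Sequences are
uppercased and validated against the 20 standard one-letter codes;
records containing any other symbol (B, J, O, U, X, Z, `*`, `-`, ...) are
**deleted**, not masked — the curation policy used for cellular
melting-temperature compilations, where ambiguous residues make many
descriptors undefined. Tm values must be finite and inside a
plausibility window of [0, 150] °C; rows with non-numeric or implausible
Tm are excluded and counted.

Duplicates are defined by identical sequence string (ids may differ);
the first occurrence is kept. The minimum sequence length for dataset
inclusion is 31 residues: the sequence-order descriptors with the
default lag of 30 need length > lag, and 31 is the weakest constraint
that makes every default descriptor well-defined. Both the length floor
and the blind-split fraction (default 10%) are configurable; the split
draws `round(fraction × N)` records without replacement from a seeded
generator and partitions the data exhaustively and disjointly.

## 2. Descriptor battery

All families operate on validated sequences and produce named,
fixed-order blocks; `featurize` concatenates enabled families in the
fixed order `aac, dpc, windip, grp, ctd, autocorr, socn, qso, paac,
apaac, triad, physchem` (2,041 features at defaults). Records shorter
than a family's precondition raise an error naming the record and
family; a permissive flag drops them instead. Degenerate inputs
(homopolymers) follow documented finite conventions throughout — no
NaN/inf ever enters a feature matrix.

### Composition families

- **aac** (20): residue frequencies; sums to 1.
- **dpc** (400): frequencies of ordered adjacent pairs among the L−1
  pairs; sums to 1.
- **grp** (12): counts and frequencies of six physicochemical groups —
  hydrophobic (V,I,L,F,M,W,Y,C), negatively charged (D,E), positively
  charged (R,K,H), conformational (G,P), polar (N,Q,S), other (A,T).
- **triad** (343): conjoint-triad counts of consecutive residue triples
  over the classical 7-class grouping ({A,G,V}, {I,L,F,P}, {Y,M,T,S},
  {H,N,Q,W}, {R,K}, {D,E}, {C}); counts sum to L−2.

### Windowed dipeptide counts (windip, 441)

Counts of ordered pairs over a **21-symbol alphabet** (20 standard
residues plus one reserved placeholder for non-standard symbols; the
placeholder row/column is structurally zero for validated sequences),
accumulated over all sliding windows of length 21: windows are
`seq[j:j+21]` for every start `j` with at least two residues remaining
(stride 1, terminal windows truncated at the right end). Equivalently,
the adjacent pair starting at position `i` is counted with multiplicity
`min(i+1, 20)`. Only a 21-symbol alphabet yields exactly 21² = 441
ordered pairs, which fixes both conventions. The window length is
configurable (`window`, default 21).

### CTD (147)

Composition/Transition/Distribution over the seven classical three-class
partitions (hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility).
Per property: 3 class fractions; 3 transition frequencies (unordered
class pairs among adjacent residues, normalized by L−1); and 15
distribution values — for each class, the 1-based position of its first,
25%, 50%, 75% and last occurrence as a percentage of sequence length
(the k-th quantile occurrence is the `ceil(q·n_class)`-th one; an absent
class contributes five zeros).

### Autocorrelation (360 at defaults)

For each scale (standardized to mean 0, population SD 1 over the 20
residues) and lag d = 1..30:

- normalized Moreau–Broto: `(1/(L−d)) Σ p_i p_{i+d}`;
- Moran: `[(1/(L−d)) Σ (p_i−p̄)(p_{i+d}−p̄)] / [(1/L) Σ (p_i−p̄)²]`;
- Geary: `[(1/(2(L−d))) Σ (p_i−p_{i+d})²] / [(1/(L−1)) Σ (p_i−p̄)²]`.

If the scale is constant over the sequence, Moran and Geary are 0/0;
the convention is 0 with a logged warning. The default scale set is
Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, side-chain mass
and Grantham polarity; any name→scale mapping can be supplied.

### Sequence-order descriptors (socn 60, qso 100)

Coupling numbers `τ_d = Σ_i d²(p_i, p_{i+d})`, d = 1..30, under two
squared residue distance matrices, each normalized to max 1:

- **grantham** — the published Grantham (1974) chemical distance matrix;
- **pcd** — a physicochemical distance built from the classical PAAC
  scale triplet: `d²(a,b) = mean of squared differences of standardized
  hydrophobicity, hydrophilicity and side-chain mass`. This is the
  package's own construction in the spirit of physicochemical distance
  matrices used for quasi-sequence-order descriptors.

QSO mixes the 20 composition terms with the τ vector:
`X_r = f_r / (1 + w Στ)` and `X_{20+d} = w τ_d / (1 + w Στ)` with
default weight w = 0.1; each matrix's block sums to 1 by construction.
Homopolymers give τ = 0 and QSO reduces to pure composition.

### PAAC / APAAC (50 + 80 at defaults)

Classical pseudo amino-acid composition with λ = 30 and weight 0.05:
correlation factors `θ_k` are the sequence mean of the squared-difference
correlation over the standardized scale triplet; the 20+λ vector is
`f/(1+wΣθ)` and `wθ/(1+wΣθ)` and sums to 1. Amphiphilic PAAC replaces θ
with 2λ product-correlation terms (hydrophobicity and hydrophilicity
separately per lag); the vector still sums to 1 (τ terms may be
negative).

### Physicochemical block (28)

A fixed, versioned inventory (the classic whole-sequence parameter
families, reconstructed as an explicit 28-column block): length;
molecular weight (average isotopic; Biopython's ProtParam); mean residue
weight (MW − water)/L; theoretical pI (Bjellqvist pKa set); net charge
at pH 7 and charge density (net charge / length); counts and fractions
of negatively (D+E) and positively (R+K) charged residues; atomic
composition C/H/N/O/S plus total atoms (per-residue formulas + one
water); instability index (Guruprasad DIWV weights, 10/L scaling);
aliphatic index (Ikai, mole percent); GRAVY (mean Kyte–Doolittle);
aromatic fraction (F+W+Y); tiny fraction (A+C+G+S+T); N-end-rule
half-lives for mammalian reticulocyte, yeast and E. coli hosts, encoded
in hours with open intervals (">20 h", ">10 h") at their lower bound
(the unknown E. coli value for N-terminal Pro is encoded in the ">10 h"
class); Gill–von Hippel extinction coefficients at 280 nm (all-reduced,
and all cysteines paired as cystines) and the two corresponding
absorbance-0.1% values (extinction / MW).

## 3. Model and selection protocol

**Regressor.** LightGBM (`LGBMRegressor`) with library-default
hyperparameters — the deliberate choice is *no* tuning — pinned to one
thread, `deterministic=True` and a fixed seed so that identical data and
seed give bit-identical models and predictions. Training requires ≥ 10
rows and finite features/targets. Prediction aligns columns strictly by
name; a missing column is an error (never silent reindexing), extra
columns are ignored after reordering.

**Cross-validation.** Shuffled k-fold (default k = 10) with metrics
computed on the pooled out-of-fold predictions; every record is
predicted exactly once by a model that never saw it.

**RFE.** An explicit elimination loop: fit on the surviving features,
drop the 10% least important by split-gain importance (at least one;
ties broken by column order), repeat. The step is a fraction of the
*remaining* features, keeping the path short at thousands of features
and fine-grained near small sizes; drops are clamped so the path lands
exactly on every requested size. The default size grid is
{50, 100, 200, 300, 500, 1000, 2000, 3000, all}; each size is scored by
cross-validation (default 3-fold; 10-fold available) and the best PCC
wins, **ties toward the smaller size** — fewer features cover the
combination space better and resist overfitting. The default
final-model stop criterion is a fixed 200-feature set
(`select_final`). **RFECV** scores every size on the 10%-step path with
3-fold CV (default) and picks the best the same way.

**Baselines.** An optional same-folds bake-off: decision tree, random
forest, linear SVR, gradient-boosted trees, LightGBM, an MLP with
hidden layers (20, 20, 20), ReLU and LBFGS, and XGBoost when installed —
all with library defaults, evaluated with the same five measures.

**Persistence.** A joblib bundle carrying the ensemble, the ordered
selected-feature contract, hyperparameters, seed, package and library
versions, and a fingerprint of the descriptor configuration;
load-then-predict is bit-identical, a corrupted file or a major-version
library mismatch is an explicit error, and a descriptor-config mismatch
at predict time warns.

## 4. Metrics

Population (1/N) normalization everywhere, matching the written
formulas literally rather than the n−1 sample convention: PCC as
covariance over the product of SDs (implemented with a single square
root so that `pcc(y, y)` is exactly 1.0); RMSE/MSE/MAE as the usual
error means; R² = 1 − SSres/SStot with SStot about the mean of the
experimental values (may be negative; the mean predictor scores exactly
0). Zero-variance inputs make PCC and R² explicit errors, not NaN.
MSE is reported in °C² (its natural unit, even where comparison tables
in the literature label it °C). The 3-class binning assigns boundary
values upward: Tm < 55 → low, 55 ≤ Tm < 65 → mid, Tm ≥ 65 → high; the
published interval notation leaves the boundaries unassigned, and the
half-open convention guarantees a total partition.

## 5. Synthetic data: what it emulates, and what it does not

The generator draws i.i.d. sequences (uniform residue composition by
default, configurable simplex; lengths uniform in 50–1000) and plants

    Tm = 50 + Σ_f w_f · z(feature_f) + N(0, σ),  σ = 3 °C by default,

where z(·) is the cohort z-score of a named descriptor. The default
signal uses 10 cheap descriptors — the six group frequencies, GRAVY,
length, charge density and aromatic fraction. The weights (3–5 °C per
SD, mixed signs) were fixed by a design calculation on the generator's
own feature correlation structure: the six group frequencies are
compositionally closed (hence negatively correlated) and GRAVY tracks
the hydrophobic fraction, so weights were sized for a planted-signal SD
of ≈ 13 °C against the 3 °C noise floor (attainable PCC ≈ 0.97), and
the resulting Tm distribution spans roughly 25–100 °C — the range seen
in cellular melting-temperature compilations. Noise uses a separate
seeded stream so sequences are unchanged when only noise settings vary.
An optional block structure adds per-block intercept shifts that mimic
species-level Tm offsets; it is off by default. A pure-numeric variant
(i.i.d. Gaussian features, sparse ±weights on the first k columns)
serves selection benchmarks where exact feature independence and a
known informative set matter; note the exact collinearity of the full
group-frequency block means *linear* identifiability of all ten default
sequence weights is impossible by design — recovery tests use an
identifiable subset.

What passing the recovery benchmarks shows: the pipeline can find a
10-descriptor signal among hundreds of noise features, estimate it to
near the noise floor out of sample, and keep ≥ 8/10 planted features at
an aggressive RFE stop. What it does not show: real proteomes are not
i.i.d. sequences, real Tm signal is not linear in ten descriptors, and
real effect sizes are far weaker — published benchmarks on measured
cellular Tm data land near PCC 0.75–0.80, not 0.95. The synthetic
results validate the machinery, not the biological difficulty.

## 6. Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's
own benchmark conditions: 2,000 records for recovery and null checks,
2,000 × 500 for selection benchmarks, 100 random sequences per
descriptor-oracle comparison (tolerance 1e-10 relative; normalization
identities at 1e-12; metric oracles at 1e-12 on 1,000 random pairs).
pI bisection runs to Biopython's ProtParam default tolerance. All
randomness flows from explicit integer seeds; every CLI run logs the
package version, seed and descriptor-config fingerprint to stderr.

## 7. Known limitations

- The descriptor inventory is a self-contained reconstruction of the
  classical families, not a bit-level match of any external descriptor
  package (lag settings and scale choices are documented above and
  configurable).
- The `pcd` distance matrix is this package's construction from the
  PAAC scale triplet; results under it are internally consistent but
  not numerically interchangeable with other physicochemical distance
  matrices in the literature.
- Half-life features are coarse N-end-rule lookups; open intervals are
  floor-encoded.
- No structure-derived or charge-density (quantum-theoretic) features.
- RFECV on the full 2,000-feature battery is computationally heavy at
  10-fold CV; the default 3-fold keeps it tractable.
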