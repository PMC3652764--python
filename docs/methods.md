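# Methods

## Scope and model

`psse` treats a protein as its 3-state predicted secondary-structure string
s ∈ {H, E, C}^N and its structural class as one of four SCOP-style labels
(all-α, all-β, α/β, α+β). The package computes two families of per-protein
statistics — content-based and position-based — and feeds them to a
multi-class RBF-SVM evaluated by the jackknife test. Nothing in the package
predicts secondary structure itself; PSIPRED (or any 3-state predictor) is
upstream, and only its output string is consumed. The 3-state alphabet is
strict: 8-state DSSP letters are rejected rather than silently reduced,
because every statistic below is defined on H/E/C.

Positions are 1-based and inclusive throughout; the worked example used in
the tests assigns position 1 to the first residue.

## Content-based features

All nine families operate on the sequence or its maximal-run segment
decomposition (segments are maximal; adjacent segments carry different
elements; expanding the list reconstructs the string — property-tested).

Conventions that the defining formulas leave open:

* **CMV denominator.** The composition moment vector of order k divides the
  summed k-th powers of occurrence positions by (N−1)(N−2)…(N−k), where N is
  the sequence length — the only length in scope. Orders are restricted to
  k ∈ {1, 2} (the "first and second order" CMV); k ≥ N raises a
  degenerate-input error rather than returning an arbitrary value.
* **Normalized average segment length** is AvgSeg/N, by analogy with
  NMaxSeg = MaxSeg/N and by the feature's name.
* **3-pattern normalization.** Window counts are divided by the number of
  interior positions N−2, so the 12 fractions sum to 1 and do not confound
  with chain length; boundary residues have no complete window and are
  excluded. A `normalize=False` flag restores raw counts for comparison
  with conventions that may have used them.
* **Alternation and TPM** are computed on the reduced segment sequence
  (coil segments deleted, helix→α, strand→β, order kept). A TPM row with no
  outgoing transitions is emitted as zeros, keeping the 4-feature block
  fully populated. The alternation count is divided by N, not by the
  reduced-sequence length.
* **Absent elements.** Segment statistics and CMV return 0 for an element
  that never occurs, so feature rows are always complete; the parallel vs
  anti-parallel β-sheet proportion is out of scope (it requires topology
  information a 3-state string does not carry).

## Position-based features

For element δ, the occurrence positions are differenced into interval
distances; a distance of 1 means two residues of the same segment. The
distance distribution is per-sequence and per-element, and is summarized by
the truncated moments Semi-E_k and Semi-D_k. Two deliberate numerical
choices:

* **No renormalization after truncation.** Semi-E_k and Semi-D_k sum only
  the first k probability terms; they equal the ordinary mean/variance only
  when k covers every observed distance (property-tested: C_k = C_F exactly
  for k ≥ max observed distance, and Semi-E_k is non-decreasing in k).
* **C_k = Semi-E_k / √Semi-D_k.** The defining material is internally
  inconsistent — prose describing a variance-over-mean ratio next to a
  formula reading mean-over-variance and a statement that the quantity is
  the *reciprocal coefficient of variation*. Reciprocal CV is mean over
  standard deviation, which fixes the square root; that reading is the
  default. `PBFParams(variance_ratio=True)` exposes the literal
  mean-over-variance formula for comparison.
* **Degeneracy.** When an element occurs fewer than twice, or all its
  distances are equal (zero variance), C_k is undefined; a configurable
  `degenerate_value` (default 0) is emitted. C_k is strictly positive
  whenever defined, so 0 is distinguishable from any real value.

The truncation bound k defaults to "full" (C_F). k = 5 is a useful cheap
surrogate: in real predicted structures almost all interval distances are
small, so a modest k already captures the distribution (and the tests pin
C_5 = √5 on the worked example).

## Classification protocol

Features are standardized to zero mean and unit variance over the dataset
before the RBF kernel (constant columns become all-zero). Without scaling,
raw segment lengths (tens) would dominate fractions (≤1) in the kernel
distance; a `--no-scale` flag restores raw features.

Hyperparameters (C, γ) are selected once per dataset and feature set by
grid search over the 11 × 11 powers of two 2⁻⁵…2⁵, scoring each pair by
stratified 10-fold CV (folds shuffled by the run seed; the fold count drops
to the smallest class size when classes are small, with a warning).

**Tie-breaking.** The CV accuracy surface plateaus at its maximum over wide
(C, γ) regions, so exact ties are the rule, not the exception. The tied
candidates are sorted by (C, γ) and the *median* one is chosen. The plateau
edges are both failure modes: the low-C corner is a barely fitted machine
whose tiny functional margins tie in class-balanced CV yet collapse under
the jackknife (whose training splits are never balanced — removing one test
sample leaves its class one short, and a near-prior classifier then votes
against it systematically); the high-C/high-γ edge borders overfitting.
Choosing the plateau centre keeps the selection maximally far from both.
This was adopted after observing the low-C edge produce jackknife
accuracies of 0.0–0.5 on datasets where every other tied candidate scored
0.9–1.0.

Selection is not nested inside the jackknife by default — the chosen pair
is reused for every leave-one-out fold, which mirrors the common protocol
but is mildly optimistic because the selection saw every sample.
`nested=True` (CLI `--nested`) repeats the grid search inside each fold for
an honest estimate at roughly n times the cost.

Accuracies: per class TP_j/|C_j| and overall ΣTP_j/Σ|C_j|; the report
object enforces the identity that the overall value equals the
class-size-weighted mean of the per-class values.

The 14-feature combined preset `pbf11cbf` uses an 11-column content-based
block — content_H/E/C, maxseg_H/E, nmaxseg_H/E, avgseg_H/E, nalt, cmv1_H —
plus the three C_F features. The precise 11-column composition is a
documented default spanning the widely used families, not a canonical list;
it is fully overridable via `FeatureSetSpec`.

## Synthetic data generator

The generator emits sequences segment-by-segment: a Markov chain over
segment *types* (self-transitions forbidden, so runs are maximal) with
geometric segment *lengths* (memoryless, one mean per type, minimum 1),
stopping at a target length drawn uniformly from 100–300 residues.
Generation is at the segment level because every feature in the package is
a function of segments and gaps; this gives direct analytic control, e.g.
the expected helix content of an alternating H/C chain is
mean_H/(mean_H + mean_C) by renewal theory (tested to within 3 standard
errors at 200 sequences).

The four presets caricature the class architectures: all-α (H/C
alternation, mean helix 9, mean coil 5), all-β (E/C alternation, mean
strand 5), α/β (interleaved H/E with short coils of mean 3 — high NAlt),
α+β (an H/C half followed by an E/C half — low NAlt). Segment means and
chain lengths are realistic orders of magnitude chosen once as defaults,
not literature estimates.

Reproducibility is bit-exact: sequence i of class c is generated from
`SeedSequence(seed, spawn_key=(c, i))`, so any subset regenerates
identically regardless of order.

**What passing on synthetic data shows — and does not.** The presets are
linearly-separable caricatures: within-class parameters are homogeneous,
lengths are geometric, and there is no predictor noise, no class overlap
(marginal α+β vs α/β architectures), and no length/composition confounding
as in real benchmark sets. End-to-end accuracy on them demonstrates that
the pipeline is wired correctly and that the features separate classes in
the designed directions; it says nothing about accuracy on real
low-identity benchmarks, which require external corpora and PSIPRED runs
and are out of scope here.

## Problem sizes

The default test and acceptance runs use 50 sequences per class (200
total), an 11 × 11 grid with 10-fold CV (121 × 10 fits on ≤14 features)
and a 200-fold jackknife — a few seconds end to end. Invariant suites run
over 1000 random strings per property.

## Known limitations

* Non-nested hyperparameter selection (default) is optimistic; use
  `--nested` for unbiased estimates.
* The `.ss2` reader consumes PSIPRED VFORMAT only; confidence columns are
  parsed and discarded since no feature uses them.
* C_k's degenerate value conflates "element absent" with "perfectly
  regular spacing"; both are rare in real chains of realistic length but
  common in very short test strings.
* The 11-column content block of `pbf11cbf` is a default guess (see above),
  so published accuracies tied to a specific 11-feature set are not
  directly comparable without overriding it.
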