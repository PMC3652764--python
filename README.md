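# psse — statistical features of predicted protein secondary structures

`psse` extracts statistical features from 3-state predicted secondary-structure
sequences (strings over H = α-helix, E = β-strand, C = coil, as produced by
PSIPRED and similar predictors) and uses them to predict a protein's SCOP-style
structural class (all-α, all-β, α/β, α+β) with an RBF-kernel SVM scored by the
jackknife (leave-one-out) test. It is aimed at structural bioinformaticians
working with low-sequence-identity ("twilight-zone") proteins, where
homology-based class assignment is unreliable but predicted secondary structure
still carries a strong class signal.

## The features

**Content-based features (CBF).** Nine classical families computed from the
sequence and its maximal-segment decomposition: element content
Content_SE = Count_SE / N; first/second-order composition moment vectors
CMV¹, CMV² (position-weighted element counts normalized by (N−1)(N−2)…);
longest and average segment length per element, raw and normalized by N;
3-pattern window fractions (each interior residue classified as inside a
segment, at its left/right interface, or isolated); the normalized
helix–strand alternation frequency NAlt; and the 2×2 transition probability
matrix of the coil-free segment sequence.

**Position-based features (PBF).** For each element δ, the occurrence
positions Po(δ) are differenced into interval distances Dis(δ) between
successive occurrences. Their empirical distribution P(Dis(δ)=n) is summarized
by truncated moments

    Semi-E_k(δ) = Σ_{n≤k} n·P(n),    Semi-D_k(δ) = Σ_{n≤k} n²·P(n) − Semi-E_k²,

(probabilities deliberately *not* renormalized after truncation) and the
feature is the reciprocal coefficient of variation

    C_k(δ) = Semi-E_k(δ) / √Semi-D_k(δ),

with C_F(δ) denoting the untruncated version. C_k(δ) captures how regularly δ
recurs along the chain — information invisible to any content-based feature:
two sequences with identical element content but rearranged segments get
different C_k profiles.

**Combined sets.** Any CBF family can be combined with the PBF block
(`content+cf`, `tpm+cf`, …). The preset `pbf11cbf` is a 14-feature set: an
11-column content-based block plus the three C_F(δ) features.

## Worked example

The canonical example string `CCHHHHEEEEECCCCCHHH` (N = 19):

```python
from psse import (SSSequence, positions, interval_distances,
                  element_distribution, c_k, PBFParams, content, nalt)

s = SSSequence("toy", "CCHHHHEEEEECCCCCHHH")
print("Po(C) =", positions(s, "C"))
print("N(C)  =", interval_distances(positions(s, "C")))
d = element_distribution(s, "C")
print("C_5(C) = %.5f" % c_k(d, PBFParams(k=5)))
print("C_F(C) = %.5f" % c_k(d, PBFParams()))
print("content =", {k: round(v, 4) for k, v in content(s).items()})
print("NAlt = %.5f" % nalt(s))
```

prints

```
Po(C) = (1, 2, 12, 13, 14, 15, 16)
N(C)  = (1, 10, 1, 1, 1, 1)
C_5(C) = 2.23607
C_F(C) = 0.74536
content = {'H': 0.3684, 'E': 0.2632, 'C': 0.3684}
NAlt = 0.10526
```

Reading the numbers: coil occupies positions 1–2 and 12–16, so six of its
seven inter-occurrence distances are 1 (same segment) and one is 10 (the gap
spanning the helix and strand). Truncating at k = 5 drops the 10, leaving a
low-variance distribution and a large C_5 = √5; including it (C_F) inflates
the variance and pulls the ratio down to 0.745. NAlt = 2/19 because the
coil-free segment sequence (α, β, α) changes state twice over 19 residues.

## Command line

```sh
psse simulate --n 50 --seed 1 --out seqs.fasta --labels labels.tsv
psse extract  --ss seqs.fasta --features pbf11cbf --out features.csv
psse eval     --ss seqs.fasta --labels labels.tsv --features pbf11cbf \
              --folds 10 --seed 1 --out report.json
```

`simulate` writes a class-typed synthetic dataset (SS-FASTA + labels TSV),
`extract` writes a feature CSV, and `eval` runs grid search (C, γ over
2⁻⁵…2⁵) plus the jackknife and writes a JSON/CSV report with per-class and
overall accuracies. Every command persists its resolved configuration next to
its output. Real data drop in the same way: SS-FASTA or PSIPRED `.ss2` files
plus a two-column id→class table.

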