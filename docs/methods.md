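# Methods

## The problem and the correction

Deep networks over one-hot encoded biological sequences are trained only on
points that satisfy a per-position probability constraint: at each of the L
positions, the A category coordinates (A = 4 for DNA, 20 for protein) sum
to one. Geometrically the data support is a translate of the zero-sum
hyperplane {v : Σ_a v_a = 0} inside each position's A-dimensional category
space, with normal direction n = (1/√A)(1, …, 1). Off that simplex the
network is free to express arbitrary function behavior, because no training
or test example ever constrains it there. The component of the input
gradient along n is therefore unidentified — noise from the optimizer's
arbitrary choices — while the in-plane component is the part supported by
data.

The correction removes the normal component by orthogonal projection:

    G_corrected[l, a] = G[l, a] − μ_l,    μ_l = (1/A) Σ_a G[l, a]

i.e. subtract, at every position, the mean attribution across categories.
This is exactly the least-squares projection of each gradient row onto the
zero-sum hyperplane (the package tests this against a generic linear
projector I − nnᵀ). Useful consequences, all tested as invariants:

* idempotence and linearity (so the correction commutes with the averaging
  inside SmoothGrad, expected gradients, and ensemble means);
* per-row norm contraction, with the Pythagorean decomposition
  ‖G‖² = ‖G_∥‖² + ‖G_⊥‖², where ‖G_⊥‖ = |Σ_a G_la|/√A;
* the signed angle α between a gradient row and the simplex plane obeys
  sin α = (G·n)/‖G‖; corrected rows have α = 0 everywhere.

Angles are reported **signed** (sign of G·n) because their empirical
distribution over positions is approximately zero-centered, which is only
expressible with a sign; exceedance fractions use |α|. Rows with zero norm
have no direction and are flagged invalid rather than assigned 0°, so
exceedance fractions are not deflated by dead positions.

Methods that only use forward passes (in silico mutagenesis) never leave
the simplex and need no correction; the package deliberately does not touch
them.

## Synthetic benchmark

The generator emulates a billboard model of regulation: motifs contribute
independently, anywhere in the sequence, with no positional grammar.
Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| sequences | 20,000 × 200 nt | standard desk-scale benchmark size |
| split | 0.7 / 0.1 / 0.2 | train/valid/test, stratified by class |
| motifs per sequence | k ~ Uniform{3,4,5}, with replacement | a regulatory code of a few sites |
| positive pool | 10 PFMs: CEBPB, GABPA, MAX, SP1, YY1 + reverse complements | five well-characterized factors with distinct cores |
| negative pool | the 10 core + 100 background PFMs | negatives may contain core motifs, rarely a positive combination |
| background | equiprobable (0.25 each) | maximally uninformative null |

Placement uses rejection sampling of uniform starts under a non-overlap
constraint (1,000 retries, then a hard error naming the offending draw).
Every nucleotide is sampled from the ground-truth row, so the generating
matrix M (PFM columns inside placements, 0.25 outside) is pixel-level truth
for scoring attributions. A single seed fans out to per-sequence
`SeedSequence` streams, making generation order-independent and
byte-reproducible.

The embedded PFMs are synthetic: constructed from the published consensus
sites of the five factors (and 24 other well-known factors for background),
with strong cores (dominant base 0.88) and softer flanks, plus
procedurally generated random-consensus PFMs to fill the background pool to
100. They have realistic information-content profiles but are not database
matrices; a JASPAR/MEME-format loader lets users substitute real ones.
What passing tests show is therefore that the correction behaves as claimed
on a controlled billboard task — not that any particular biological motif
set is recovered from real assay data.

## Models and training

Two CNNs (each with ReLU or clamped-exponential first-layer activation;
four variants total), batch normalization before every hidden activation,
single sigmoid output:

* **shallow**: conv(24 filters, 19) → pool 50 → conv(48, 3) → pool 2 →
  dense 96; dropout 0.1/0.2.
* **deep**: conv(24, 19) → conv(32, 7) → pool 4 → conv(48, 7) → pool 4 →
  conv(64, 3) → pool 3 → dense 96; dropout 0.1/0.2/0.3/0.4/0.5.

Training: binary cross-entropy, Adam at 1e-3, batches of 100, learning rate
×0.2 when validation AUC fails to improve for 3 epochs, weights restored
from the best-validation-AUC epoch, L2 1e-6 on conv/dense parameters
(batch-norm excluded). The desk-scale default is a 30-epoch cap with
early-stopping patience 5; a 100-epoch run is one constructor argument
away. Weight initialization is fan-in-scaled He normal with a configurable
gain, since initialization magnitude is known to modulate how far the
learned function strays off-simplex.

The network stack is plain numpy with explicit backward passes; the same
reverse pass that trains the model yields input gradients, so attribution
needs no second machinery and the gradient is checked against central
finite differences (float64, directional, relative error ≤ 1e-3 at step
1e-3 — individual coordinates can sit on ReLU/max-pool kinks, so the
directional form is the stable contract).

Batch-norm uses momentum 0.9 and ε = 1e-3; attribution always runs in
evaluation mode (running statistics, no dropout), where the layer is affine
and input gradients are well defined.

### Off-simplex training penalty

`off_simplex_penalty` (mean over positions of ‖G_⊥‖², pluggable
sum/max reductions) can be added to the loss at weight λ. Differentiating
it w.r.t. parameters needs second-order information, which the plain-numpy
stack does not carry, and a finite difference *of gradients* is biased for
ReLU/max-pool networks (kink crossings contaminate the estimate — verified
directly during development). Training therefore descends a stochastic
surrogate: with per-position random signs r and the direction
R_{l,a} = r_l/√A, the squared symmetric difference quotient
q² = [(F(x+δR) − F(x−δR))/2δ]², normalized by N·L, equals the penalty in
expectation as δ → 0 (δ = 0.1 by default, `penalty_delta`). The surrogate
is an ordinary differentiable function of the parameters — its backprop
gradient is exact (tested against numerical differentiation) and costs two
extra forward/backward passes per batch. The penalty's exact published
form is not public; mean squared orthogonal magnitude is this package's
choice, and the training-level tests assert the directional claim:
training with λ > 0 lowers mean |G·n|, paired over seeds.

## Attribution and evaluation

Saliency, integrated gradients (left-Riemann over 20 points from an
all-zeros baseline; trapezoid optional), SmoothGrad (25 samples, σ = 0.1,
noise applied off-simplex with no renormalization, deliberately), expected
gradients (10 mononucleotide-shuffle references, reusing the integrated-
gradients step count). Gradients are taken at the pre-sigmoid logit by
default (`output="prob"` switches to the sigmoid output; for per-sequence
rank or cosine metrics the two differ only by a positive per-sequence
scalar, so the choice is immaterial there).

Scoring against ground truth, per sequence:

* **cosine similarity** between the full flattened map and M − 1/A.
  Centering removes the uniform background, and because (M − 1/A) rows are
  zero-sum, the correction cannot change this dot product — only the map's
  norm — which is itself a tested invariant. A motif-positions-only variant
  exists behind a flag.
* **interpretability AUROC/AUPR** over per-position grad-times-input
  C_i = Σ_j S_ij X_ij, positives I_i > 0.1 bits, negatives I_i = 0,
  intermediate positions excluded; midrank AUROC and step-wise
  average-precision AUPR (scikit-learn implementations, cross-checked
  against a brute-force concordant-pair count).
* **ensemble difference reduction** 1 − ‖after − ens‖/‖before − ens‖ per
  position, for proxy-truth comparisons when no ground truth exists;
  positions with zero before-distance are NaN-flagged. The desk-scale
  proxy ensemble defaults to 10 models (2 filter counts × 5 seeds), a
  scaled-down stand-in for the full 50-model (10 filter counts × 5 seeds)
  configuration.

## Numerical and scale choices

* Idempotence of the projection holds to machine precision, not bitwise: a
  second pass removes a row mean of order ε·‖row‖.
* `arcsin` arguments are clipped to [−1, 1] to absorb rounding.
* Equal grad-times-input scores are handled by midranks (AUROC) and by
  average precision's step integral (AUPR), both exact under ties.
* Float32 is the training default (~2× faster); float64 is used wherever a
  test compares against finite differences or closed forms.
* Desk-scale problem sizes used by the shipped tests and the acceptance
  script: one 20,000-sequence dataset with a 30-epoch-capped deep-ReLU
  training for angle diagnostics (validation AUC ≈ 0.95), 500 test maps
  for exceedance and stratification, and smaller trial counts than a full
  50-trial study for the directional improvement checks. These sizes are
  the package's default study conditions; the full-scale settings remain
  plain configuration.

## Known limitations

* The benchmark is a billboard model: no motif grammar, no real genomic
  background, no soft/low-information motif columns beyond the designed
  flanks. Conclusions transfer to real assays only qualitatively.
* The improvement delivered by the correction grows with model quality and
  with how far the learned function strays off-simplex; for weakly trained
  models (validation AUC ≲ 0.8 on this task) the per-sequence deltas can
  straddle zero. Among the three ground-truth metrics, the cosine gain is
  structural (the projection preserves the dot product with the zero-sum
  centered truth while shrinking the map norm, so cosine rises whenever the
  map points the right way), whereas the grad-times-input AUROC/AUPR gains
  depend on the per-position gradient mean being pure noise: in models
  whose motif filters encode little mismatch (negative-weight) evidence,
  that mean retains a trace of signal and the rank metrics can move
  marginally either way. The benchmark reports all three, before and
  after, so this regime is visible rather than averaged away.
* The CNN stack is CPU-oriented and single-threaded by design; it is not a
  general-purpose deep-learning framework, and only the printed
  architectures are supported.
* The training loop is deterministic given a seed on a fixed platform, but
  bit-level reproducibility across BLAS builds is not guaranteed; summary
  metrics are stable to far tighter tolerances than any test asserts.
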