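# Methods

## Overview

`seqmotion` treats a protein's continuous conformational heterogeneity as a
small set of *linear motions*: per-residue fields of 3D displacement vectors
x⃗ᵢₖ (an L×K×3 tensor for a protein of L residues and K motions). The package
covers the full cycle:

1. **Ground truth.** Collections of experimentally determined conformations
   of close homologs are read as Cα traces, superposed onto a reference with
   a weight-aware least-squares (Kabsch) rotation, and decomposed by PCA of
   the positional covariance. The top K components, normalised so that
   Σᵢ‖x⃗ᵢₖ‖² = L, are the ground-truth motions; their eigenvalues measure
   variance contributions.
2. **Prediction.** A lightweight 1D convolutional network maps an L×d
   per-residue sequence embedding (produced by any protein language model;
   the package never runs one) to K motion tensors. Because no 3D structure
   is seen, predictions live in an arbitrary global orientation.
3. **Invariant comparison.** Training and evaluation both use a weighted
   aligned sum-of-squares error that minimises over a global orthogonal
   transform R ∈ O(3) (reflections allowed), a component permutation P and
   signed per-component scalings S:

       L = (1/L) · min_{R,S,P} Σᵢ wᵢ ‖R(PXᵢᴳᵀ)ᵀ − (SXᵢ)ᵀ‖²_F

   with wᵢ the fraction of conformations resolving residue i. The
   transformation is applied to the ground truth so that gradients with
   respect to the prediction are a plain quadratic. Per-pair evaluation
   uses SSE, its null-prediction maximum SSE_max = (1/L)Σ wᵢ‖x⃗ᵢ‖² and
   their ratio NSSE ∈ [0,1]; NSSE < 0.6 is the conventional "acceptable"
   cutoff, < 0.2 near-perfect.
4. **Orientation.** An extracted component inherits from Kabsch optimality
   the zero-angular-velocity property Σᵢ C⃗ᵢ × x⃗ᵢ = 0. To anchor a
   prediction on a conformation C we solve Σᵢ C⃗ᵢ × (R x⃗ᵢ) = 0 for
   R ∈ SO(3): through a unit quaternion this is a system of three quadrics
   on the 3-sphere, hence at most four rotations.

## Loss evaluation order and exact invariances

The minimisation is sequential: (P, R) first, then the closed-form scalings
S_kk = Σ wᵢ (x⃗ᵢₖᴳᵀ⁻ᵗʳᵃⁿˢ)ᵀx⃗ᵢₖ / Σ wᵢ‖x⃗ᵢₖ‖². All K! permutations are
enumerated; for each, the rotation comes from the SVD of the weighted
cross-covariance *without* a determinant correction, so the optimum may be a
pseudo-rotation (det R = −1). Two numerical choices make the final loss
exactly invariant (to round-off) under rescaling or flipping individual
predicted components, as the joint minimum is in theory:

* the Procrustes step sees predicted components normalised to unit weighted
  norm (magnitude cannot steer the rotation), and
* the 2^K component sign combinations are enumerated alongside the K!
  permutations, with the candidate ranked by the final scaled loss.

Ties between permutations break lexicographically. The ablation toggles
(`allow_reflection`, `allow_permutation`, `allow_sign_flip`) restrict the
search space and can only increase the loss; sign flips are otherwise
absorbed by negative S_kk. During training, P, R and S are recomputed on
every forward pass and held constant for differentiation, so
∂L/∂x⃗ᵢₖ = (2/L)wᵢS_kk(S_kk x⃗ᵢₖ − x⃗ᵢₖᴳᵀ⁻ᵗʳᵃⁿˢ).

A genuinely joint (R, S) optimum could differ from the sequential one; we
keep the sequential protocol (with the sign/normalisation refinement above)
and treat the gap as part of the method definition.

## Network and training

Architecture: per-residue linear layer d→h, two 1D convolutions h→h with
filter sizes 15 and 31 (odd, symmetric zero padding, length-preserving),
and K parallel linear heads h→3; leaky-rectifier activations
(slope 0.01) and dropout after each activation. Defaults: h = 256 (the
inter-layer width is a free design choice, exposed in `ModelConfig`),
dropout 0.8, Adam at learning rate 1e-2, batch size 64, 500 epochs, no
learning-rate schedule. Batches zero-pad on the right; activations beyond a
sample's true length are re-zeroed after every layer, which makes a padded
batch bitwise-consistent with single-sequence inference and keeps padded
rows out of the loss and of the convolution statistics.

The implementation is pure NumPy with hand-written backpropagation (verified
against central finite differences to ~1e-7 relative error on a frozen
quadratic objective) and a standard Adam optimiser. The best checkpoint is
selected by mean validation loss (training loss when no validation split is
given), with both curves recorded per epoch in eval mode. The train/
validation/test split is random by protein at 70/15/15. Data augmentation
pairs one embedding with up to five motion sets extracted from alternative
reference conformations, each entering as a separate sample; alternative
references are chosen greedily, each maximising the RMSD to the previous
one.

## Subspace metrics

RMSIP between the ground-truth and predicted K-motion subspaces is computed
after Gram–Schmidt orthogonalisation of the predictions (index order for
the standalone function, best-to-worst loss order inside the matched
procedure — both orders span the same subspace, so the value is identical):

    RMSIP = sqrt( (1/K) Σₖ Σₗ ( x̂ₖᴳᵀ · x̂ₗᵒʳᵗʰᵒ )² )

with unit-normalised flattened 3L-vectors. The square root follows the
standard definition in the normal-mode literature (0.70 excellent, 0.50
fair). Near-dependent predicted components (residual norm below 1e-8 of the
original after projection) are dropped with a warning and the average runs
over the surviving D ≤ K vectors, which avoids inflating the overlap through
redundancy. RMSIP is computed unweighted; only the SSE machinery uses
confidence weights.

The matched-subspace report additionally (i) matches predictions to
ground-truth components bijectively by greedy ascending NSSE, (ii) applies
one global O(3) rotation of the ordered ground truth onto the ordered
orthogonalised predictions, and (iii) tabulates pairwise normalised inner
products, Pearson correlations of the aligned flattened vectors, and NSSE
under optimal scaling only. Note the globally aligned pairwise products are
reported separately from the (alignment-independent) RMSIP field: rotating
one subspace changes individual inner products, so a "RMSIP" recomputed
from the rotated products would not equal the canonical definition.

## Orientation solver

Writing R through a unit quaternion q turns each component of
Σᵢ C⃗ᵢ × (R x⃗ᵢ) into a quadratic form qᵀQₐq (the 4×4 symmetric Qₐ are
assembled from the cross-covariance Σᵢ C⃗ᵢ x⃗ᵢᵀ and a fixed basis of
quaternion quadrics). Three quadrics in projective 3-space intersect in at
most eight points; q and −q give the same rotation, hence at most four
solutions. The system {qᵀQₐq = 0, ‖q‖² = 1} is solved by a vectorised
64-start damped Gauss–Newton iteration; converged quaternions are merged
when closer than 5e-4 (≈1e-3 rad geodesic), and candidates with
cross-product residual below 1e-6·‖C‖·‖x‖ are flagged exact. When no exact
solution exists (noisy predictions), the best local minima are returned
non-exact; the solver never silently picks a candidate — callers (or the
evaluation mode, which scores each candidate's NSSE under optimal scaling
only) choose. Orientation is solved per component by default, since the
constraint is stated per motion tensor; a shared-rotation mode is available.
Trajectories deform a conformation as C + a·x⃗ over 10 evenly spaced
amplitudes by default and are written as multi-model PDB.

The orientation problem is only well-conditioned when the motion is
correlated with the structure over long wavelengths: the constraint
Jacobian is tr(G)I − Gᵀ with G = Σᵢ C⃗ᵢ x⃗ᵢᵀ, which is near zero for
structure-decorrelated high-frequency fields. Collective, domain-like
motions — the kind the extraction filters retain — give a well-behaved
system; per-residue jitter does not.

## Synthetic data generator

Fixtures emulate the statistical structure the extraction assumes:
conformations scattered around a base Cα trace along a few orthogonal
displacement fields plus isotropic noise, observed in random rigid frames,
optionally with unresolved residues. Defaults and ranges (chosen once as
realistic study conditions): traces are noisy helices with 3.8 Å spacing;
amplitudes (2.0, 1.0) Å — typical 2–3 Å RMSD diversity with a 4:1 planted
eigenvalue ratio and the ≥1.5× separation that keeps eigenvectors
identifiable; coordinate noise 0.05–0.3 Å (crystallographic-uncertainty
scale); L ∈ [30, 200], M ∈ [5, 50] in dataset sweeps.

Three constructions make the planted parameters exactly identifiable, so
recovery error measures the method rather than sampling artefacts:

* planted fields are chain-smoothed (Gaussian kernel, σ ≈ L/12 residues),
  giving collective long-wavelength motions like real principal components;
* they satisfy the Eckart conditions (zero net translation and angular
  momentum w.r.t. the base) and are additionally projected out of the
  mutual curl fields e⃗ⱼ × V⃗ₖ, making them insensitive, to first order, to
  which (deformed) conformation serves as superposition reference;
* the per-component amplitude series are centred, decorrelated and rescaled
  to their exact target sample variance, so the planted spectrum is the
  realised spectrum even at M = 5.

Surrogate embeddings are standard normal L×d matrices; in informative mode
the first 3·K columns carry the planted displacements through a fixed
random mixing (shared across proteins, so a single linear decoder exists)
plus a 5% noise floor. Informative embeddings give the training loop a
learnable signal; non-informative ones are the random-input negative
control.

What passing on fixtures does **not** show: real collections have
non-linear deformations, correlated experimental noise, alignment errors
and sequence variation between members — none of which the generator
emulates — and real embedding-to-motion learnability is a property of
protein language models, not of the surrogate construction. The fixtures
validate the machinery (extraction, loss algebra, orientation, training
mechanics), not biological predictive power.

## Numerical choices and degenerate inputs

* Weighted PCA multiplies coordinates by √wᵢ before decomposition;
  displacements are un-weighted on output. Each conformation is centred at
  its own weighted centroid (so the Kabsch cross-product identity holds
  exactly); unresolved residues are imputed at the residue's resolved mean,
  contributing zero deviation. Eigenvector signs are fixed by making the
  largest-magnitude entry positive.
* Residue correspondence across members uses positional mapping on residue
  numbers (collections are sets of close homologs); full MSA construction
  is out of scope. Alternate locations keep the highest-occupancy Cα.
* Superposition uses proper rotations (det +1); a collinear reference
  raises a rank error. All-zero motions raise degenerate-motion errors;
  zero-norm predictions get scaling 0 with a warning; degenerate
  ground-truth components are excluded from best-match minima with a
  warning.
* Collectivity κ = (1/L)exp(entropy) is computed on per-atom squared
  displacement norms renormalised to sum to one, which satisfies both
  boundary cases (κ = 1 for identical displacements, 1/L for a single
  moving atom); the literal per-coordinate sum (upper bound 3 for isotropic
  motions) is available behind `per_coordinate=True`.
* Bootstrap success rates use 1000 resamples of ⌈N^(2/3)⌉ proteins with
  replacement.
* Indices are 0-based internally and 1-based in all file outputs.

## Problem sizes in the shipped tests and acceptance script

The test-suite and `scripts/acceptance.py` sizes are the package's own
desk-scale choices: fixture sweeps of 50–100 collections (L ≤ 200,
M ≤ 50), 1000-draw random baselines at L ∈ {33, 100, 662}, 1000 random
orientation instances, 10⁵-sample rotation oracles, and learning smoke
tests with 26 proteins, width 16 and 200 epochs. PDB-scale training with
real language-model embeddings uses the same code paths through the CLI
but is not exercised by the tests.

## Known limitations

* The discussion-level reading of the loss as a many-to-one matching (each
  ground-truth motion to its closest prediction) differs from the bijective
  permutation implemented here; we implement the bijective form.
* The sequential (P,R)-then-S optimisation is a heuristic for the joint
  minimum; no claim of global optimality over R×S is made.
* Hidden widths between the printed layers of the reference architecture
  are not public; `hidden=256` is a stated free choice.
* The orientation solver is numerical; the ≤4-solution property is
  verified empirically (1000 instances) rather than symbolically.
* Multi-chain assemblies, PDB-wide clustering and elastic-network baselines
  are out of scope; externally produced motion files can still be scored
  through the evaluation module.
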