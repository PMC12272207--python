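# Methods

## Model and scope

`enct` implements network control theory on the *edges* of weighted
structural connectomes. The node connectome is a symmetric nonnegative
adjacency matrix A over N parcellated regions with zero diagonal; weights
below an absence threshold (default 0.001, matching the numerical noise
floor of deterministic tractography pipelines) are treated as no
connection. Controllability is defined in the discrete-time setting and
control energy in the continuous-time setting — the two conventions under
which these measures were introduced for neuroimaging — so the package
deliberately mixes settings rather than unifying them.

## Line-graph transform

Edges are enumerated in row-major upper-triangular order (deterministic
given A, so feature vectors align across subjects). The incidence matrix
places √w_α at both endpoint rows of edge α; this is the unique symmetric
assignment satisfying the defining identity C Cᵀ = A + D with D the
weighted strength matrix. The edge adjacency is CᵀC off the diagonal with
the diagonal forced to zero: the raw CᵀC diagonal (2w_α) is an
edge-self-coupling that has no meaning in an adjacency, and every
downstream formula (Gramian, eigenmodes, energy) expects a zero-diagonal
coupling matrix. Consequently A_E[α,β] = √(w_α w_β) exactly when edges
α, β share one endpoint.

Cross-subject feature alignment uses the full N(N−1)/2 upper-triangle
index (7140 features at N = 120); node pairs with no edge in a given
subject receive value 0 by default, or NaN under the missing-value
convention (`align_edge_values(..., fill=np.nan)`). Whether absent edges
should be zeros or missing is genuinely open; zero is the default because
it keeps downstream linear models applicable without imputation, and the
flag is exposed so users can make the other choice.

## Controllability

Both A and A_E are rescaled by 1/(1 + |λ|max) before controllability is
computed. The rescaling guarantees Schur stability (spectral radius < 1)
for any symmetric input, hence convergence of the infinite-horizon
Gramian; the factor is recorded in every profile. Average controllability
of element k is Trace(W_k) for the single-input matrix B = e_k. Two exact
routes are provided: a discrete-Lyapunov solve (`average_controllability`,
general control masks) and, for full per-element profiles, the closed form
Trace(W_k) = [(I − A²)⁻¹]_kk valid for symmetric A, evaluated through one
eigendecomposition (`average_controllability_all`). The two agree to
machine precision and both are tested against a truncated series oracle.
Values satisfy AC ≥ 1 (the τ = 0 term contributes 1).

Modal controllability is φ_k = Σⱼ (1 − λⱼ²) v_kj² over an orthonormal
eigenbasis. After stabilization φ ∈ [0, 1] elementwise and
Σφ = M − trace(A²); for degenerate eigenvalues φ is basis-independent
because only Σⱼ f(λⱼ) v_kj² over an orthonormal set enters (tested by
explicit eigenspace rotations).

## Optimal control energy

The activation task drives the stabilized edge system from rest (x₀ = 0)
to a target with 1 on the activated edges and 0 elsewhere, minimizing a
state-tracking term plus a ρ-weighted input cost under the hard terminal
constraint x(T) = x_T. The first-order conditions form a linear
state/costate system; the solver builds the augmented propagator
exp(G·t) (G contains the drift, the −BBᵀ/2ρ coupling, the −2I tracking
feedback, and the constant forcing 2x_T), obtains the initial costate
from one linear solve enforcing the terminal condition, and steps the
trajectories on a uniform grid. Defaults: T = 1, 1000 steps (step 0.001),
ρ = 1, B = identity (all edges receive input). The boundary solve checks
the condition number and falls back to least squares with a warning above
10¹²; the terminal residual is always reported and warned about above
1e−4 relative.

Continuous-time stabilization is A/(1 + |λ|max) − I (eigenvalues in
(−2, 0)), the convention of connectome control-energy studies; both the
factor and the shift are logged in the result settings.

Reported energy is ∫‖u*(t)‖² dt by trapezoidal quadrature on the closed
grid of n_steps + 1 points (both endpoints included — needed by the
quadrature; per-element energies therefore sum exactly to the total).
Note the naming tension inherited from the field: the objective includes
a tracking term, yet "energy" refers to the input integral alone; the
package implements the objective exactly and reports the input integral.
Normalized activation energy divides the total by the number of target
edges; `decompose_energy_by_pairs` splits per-edge energies over canonical
network-pair labels, conserving the total exactly.

Because the optimality system is linear and x₀ = 0, energy scales
quadratically in the target (E(c·x_T) = c²E(x_T)), and energy is
non-increasing in ρ; both are tested, and the solver is validated against
an independent `solve_bvp` integration to 1e−6 relative.

## Null models

Each null preserves the binary degree sequence exactly (Maslov–Sneppen
double-edge swaps; default 10 attempted swaps per edge, configurable — the
conventional budget, since the appropriate number is not standardized) and
the weight multiset exactly, and approximates the nodal strength sequence
by sequential rank matching: weights are placed largest-first on the edge
whose endpoints have the largest product of residual target strengths,
decrementing the residuals after each placement. On 60-node synthetic
connectomes the null-vs-empirical strength correlation is ≈ 0.99. Graphs
too small or too dense to admit a legal swap return a weight-reshuffled
copy with a warning.

Nonparametric p-values use a +1 pseudo-count, p = (1 + #beats)/(1 + n),
so p is never 0 and is exactly 1/(n+1) when the empirical value beats
every null; two-sided p doubles the smaller one-sided value, capped at 1.
Multiplicity is handled by Benjamini–Hochberg FDR (via statsmodels).
Nulls are generated from whatever connectome is passed in — typically the
group average, per-subject if desired.

## Connectome-based predictive modeling

CPM follows the standard protocol: per training fold, two-sided Pearson
p < 0.01 feature selection split by sign; summary score per subject
(positive-sum minus negative-sum by default; positive-only and
negative-only modes are exposed because the single-number convention in
the literature is not unique); one-variable linear regression; held-out
prediction. Fold splits are a deterministic function of (seed, repeat), so
competing feature sets can be compared on identical splits;
`compare_feature_sets` reports the proportion of repeats where set A fails
to beat set B, counting ties as ½ (so identical inputs give exactly 0.5
and strict dominance gives 0). Degenerate folds (no selected features, or
constant scores) predict the training mean and are counted in the log
rather than failing the run.

## Synthetic data

The generator emulates what tractography-derived connectomes look like
statistically, not biophysically: contiguous canonical-network blocks
(within-network density 0.35, between 0.15 — a realized whole-matrix
density near 0.19, in the range of QA-thresholded deterministic
tractography at ~120 nodes), log-normal weights exp(N(−2.5, 0.8²))
emulating the positive skew of QA values, and the 0.001 absence
threshold. Cohorts share the group topology; subject weights are the
group weights times a per-subject global log-normal factor (sd 0.1,
modeling documented individual differences in overall connectome
strength — this factor is what gives edges realistic positive
cross-subject correlations) times independent per-edge log-normal noise
(sd 0.2). Both factors are mean-corrected (exp(σz − σ²/2)) so the cohort
mean converges to the group matrix. Planted phenotypes standardize the
chosen signal columns, combine them with equal weights, and add Gaussian
noise scaled so the signal R² matches the request.

What passing tests therefore show: the machinery is correct on networks
with realistic sparsity, weight skew, block structure, and inter-subject
correlation. What they do not show: behavior under spatial embedding,
distance-dependent connectivity, measurement artifacts correlated with
anatomy, or non-linear brain dynamics — none of which the generator
attempts.

Because the cohort model has a shared global factor, a *single* null
(noise) phenotype draw can exhibit a chance whole-sample correlation with
that factor which cross-validation cannot remove; null calibration is
therefore estimated by averaging over independent null-phenotype draws.

## Numerical choices and degenerate inputs

* Symmetry tolerance on input matrices: 1e−8 (exact symmetrization after
  validation); negative weights are rejected naming the offending cell.
* Stabilization uses the spectral radius max|λ| (equals the largest
  eigenvalue for nonnegative symmetric matrices), never an estimate.
* Empty graphs yield empty edge networks and empty profiles; isolated
  nodes are allowed and receive NaN in node-mean maps.
* Empty energy targets are defined as zero energy with a warning rather
  than an error, so batch sweeps over network pairs do not abort on an
  empty pair.
* Edge lists, fold splits, swaps, and all generators are reproducible from
  integer seeds through `numpy.random.Generator`/`SeedSequence`; replaying
  a seed is bit-for-bit identical.

## Problem sizes

The test-suite and acceptance runs use 60-node connectomes (≈ 300 edges)
for controllability and null ensembles, 6-element systems for the
boundary-value energy oracles, and a 300-subject, 1000-feature cohort for
CPM — sizes at which every independent oracle (dense BVP integration,
brute-force enumeration, 10⁴-term series) is itself trustworthy. The
implementation is O(L³) in edge count via dense eigendecompositions and
matrix exponentials; a 120-node connectome with a few thousand edges is
practical for controllability, while the energy solver's 2L+1-dimensional
exponential makes whole-connectome energy runs the slow path, as expected
for edge-centric analyses.

## Known limitations

* Undirected, nonnegative networks only; signed functional connectivity
  has no agreed edge-centric control semantics and is out of scope.
* Single-edge control inputs for eAC follow the L×1 input convention; a
  multi-element mask is exposed but is not the default.
* The discrete/continuous split (controllability vs energy) is inherited
  from the measures' origins; no attempt is made to reconcile them.
* Strength preservation in nulls is approximate by construction; exact
  strength-preserving rewiring of weighted graphs is a different (harder)
  null family.
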