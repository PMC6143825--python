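# Methods

`groupsice` builds sparse functional brain sub-networks from multi-subject
ROI time series and classifies two groups (patients vs. controls) from the
resulting connectivity features. This note documents the models, the
numerical choices, the synthetic-data generator, and the limits of what the
test suite demonstrates.

## The model stack

**Inputs.** A cohort of M subjects, each an (n_t × P) matrix of regional
mean time series (P atlas regions, n_t time points), plus a binary label per
subject. Time points are treated as exchangeable samples of a zero-mean
P-variate distribution; no temporal model is fitted.

**Stage 1 — shared-topology detection.** For each target region p, the
remaining P−1 regions are candidate predictors, and one subset E_p shared by
all subjects is selected by the ℓ2,1-penalized multi-subject regression

    β̂_p = argmin_β  Σ_m ‖x_p^m − X_p^m β_p^m‖₂² + φ ‖β_p‖₂,₁ ,

where β_p is the (P−1)×M coefficient matrix (one column per subject) and
‖·‖₂,₁ sums the Euclidean norms of its rows. The row-wise penalty zeroes
whole rows, so a predictor is kept for all subjects or for none: the
topology is identical across the group while coefficient values remain
individual. The penalty φ is chosen per target on a grid by the Bayesian
information criterion

    BIC(φ) = Σ_m ln ESS(m) + d · ln(n_t) / n_t ,

with ESS(m) subject m's residual sum of squares and d the number of nonzero
coefficients. E_p is the set of predictors with nonzero rows at the winning
φ.

**Stage 2 — sparse network construction.** For each (target p, subject m)
the expanded subset Ẽ_p = [p, E_p] is covaried and the sparse inverse
covariance estimated by

    Θ̂ = argmin_{Θ≻0}  −log det Θ + tr(SΘ) + λ ‖Θ‖₁ ,

where ‖Θ‖₁ sums the absolute values of *all* entries, the diagonal
included. The first column of Θ̂ (diagonal dropped) is the target's weight
vector; scattering each target's vector into column p of a P×P matrix gives
the subject's connectivity matrix Θ_m (asymmetric by construction; a flag
offers (Θ+Θᵀ)/2 for graph use). The non-sparse baseline replaces the
penalized precision by partial correlations

    Π_ij = −(Σ⁻¹)_ij / sqrt((Σ⁻¹)_ii (Σ⁻¹)_jj) ,

either whole-brain (``partial`` mode) or restricted to Ẽ_p
(``group-partial``). ``sice`` applies the penalized estimator to the whole
brain without topology detection; ``group-sice`` is the full stack.

**Stage 3 — classification.** Each Θ_m is flattened row-major into a
P²-length feature vector (8,100 features at P = 90, zeros included), and a
Gini decision tree (no depth limit, minimum leaf 1, fixed seed) is trained.
Generalization is estimated by nested leave-one-out cross-validation: the
outer loop holds out one subject; an inner leave-one-out loop over the
remaining M−1 subjects evaluates every λ in the pool end-to-end (networks
rebuilt, tree retrained) and passes the inner-accuracy maximizer (ties:
smallest λ) to the outer fold. ACC/SEN/SPE come from the pooled outer
confusion counts (patient class positive); the ROC is a descending threshold
sweep of the tree's positive-leaf proportions with tied scores grouped, and
the AUC its trapezoidal area (equal to the Mann–Whitney concordance with
ties counted ½).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| φ grid | 0.05…0.95 step 0.05 | topology penalty candidates, within (0,1); BIC picks per target, ties toward the smallest (denser, more conservative) |
| λ pool | 0.05…0.95 step 0.05 | network penalty candidates searched by the inner CV loop |
| group-lasso stop | Δβ̂ (Frobenius) < 1e−6 or 100 sweeps | the iteration cap mirrors the topology solver's published behavior; the tolerance avoids wasted sweeps |
| SICE stop | ΔΘ̂ (entrywise abs sum) < 1e−6, cap 200 sweeps | cap leaves headroom; typical runs need < 20 |
| numeric zero (rows) | ℓ2 norm < 1e−6 × largest row norm | relative, hence scale-robust |
| ESS floor | 1e−12 | keeps the BIC finite on interpolating fits (with a warning) |
| condition threshold | 1e12 | beyond this the covariance is treated as singular and partial correlation refuses |
| topology_scope | `all_subjects` | detection precedes cross-validation, reproducing the framework's described sequencing — **note this leaks test information into the selected structure**; `train_only` refits E_p inside each outer fold for a leakage-free estimate |

Standardization: the Stage-1 regression mean-centers and unit-norm-scales
every response and design column (penalized coefficients are then comparable
across φ); Stage-2 covariances use raw mean-centered series, since the
estimator is defined on covariances, not correlations.

## Solvers and numerical choices

*Group lasso.* Block coordinate descent over rows with the group
soft-threshold update (exact row minimization on standardized inputs,
objective monotone). Cyclic descent alone crawls on strongly correlated
designs — on cohorts drawn from a Gaussian graphical model it left Δβ̂
around 1e−4 after 100 sweeps — so each sweep is followed by a
majorize–minimize (IRLS) refinement of the currently active rows, iterated
to its own fixed point: solving (2G_m + φ diag(1/‖β_j‖)) β_m = 2b_m
minimizes the standard quadratic upper bound of the group penalty tangent
at the iterate. The refinement touches only active rows (exact zeros are
preserved), each step is accepted only if the objective does not increase,
and large active sets — which occur far from the sparse optimum, where the
slow tail never bites — get a light touch since the solves cost |A|³. This
brings convergence to tens of sweeps even when a near-boundary row enters
the support slowly.
φ_max = 2·max_j ‖X_jᵀy‖₂ (from the subgradient condition at β = 0) is
exposed for testing; above it the solver returns the exact zero matrix.

*Sparse inverse covariance.* Block coordinate descent over columns: with
the diagonal penalized, the working covariance starts at S with S_ii + λ on
the diagonal and each column update is a lasso subproblem solved by
coordinate descent (JIT-compiled). λ = 0 short-circuits to the dense
inverse (S must be positive definite). Convergence is declared when the sum
of absolute entrywise changes of Θ̂ between sweeps falls below the
tolerance; exceeding the sweep cap raises, carrying the final change.
Estimates are symmetrized and eigenvalue-checked before return.

*Degenerate inputs.* Constant predictor columns are flagged and excluded
from the group fit for every subject (keeping the shared-support semantics
well defined); a constant target raises. Empty E_p yields a zero column
with a warning. Single-class *training blocks* inside tiny LOOCV folds
(unavoidable at M = 3) predict the constant present class; the public
classifier constructor still raises on single-class input.

*Tie-breaks.* BIC ties take the smallest φ; inner-accuracy ties take the
smallest λ; connection-frequency ties order by feature column index. All
randomness descends from named substreams of one seed, so adding a stage
never perturbs another stage's draws and reruns are bit-identical.

## The synthetic cohort generator

The generator draws each subject's rows i.i.d. from N(0, Θ⁻¹) where Θ is
the subject's group precision matrix: a sparse symmetric matrix with a
known support, unit baseline diagonal, off-diagonal magnitudes ~0.3
(± U[0.8, 1.2] scatter), diagonally loaded until the smallest eigenvalue
reaches 1e−3. A Gaussian graphical model is used because the sparse
estimator's likelihood is exactly the Gaussian one — the generating
precision *is* the estimand. The two groups share a base support except on
a small flipped-edge set (the signal the classifier must find); per-subject
individuality multiplies each nonzero entry by (1 + U[−0.1, 0.1]),
preserving the support — topology shared, strengths individual.

Study conditions for end-to-end comparisons (`COMPARISON_COHORT`): P = 90
regions (the atlas parcellation size used throughout), base support 180
edges (mean degree 4, a small-world-like sparsity), 6 flipped edges, 10+10
subjects, n_t = 300. The region count matters: with P ≪ n_t the dense
inverse covariance is well-conditioned and the partial-correlation baseline
saturates, erasing the regime (n_t within a few multiples of P) in which
sparse estimation earns its advantage. End-to-end runs use a reduced
5-point φ grid {0.15…0.75} and λ pool {0.1, 0.25, 0.4, 0.55, 0.7} and
small seed counts; these sizes are the package's choice of desk-scale
problem sizes.

**What the generator does not emulate:** temporal autocorrelation
(hemodynamics, scanner drift), non-Gaussian tails, motion or physiological
artifacts, site effects, and any group difference beyond precision-support
flips. Passing tests therefore demonstrate correctness of the estimators
and the validation machinery under the model's own assumptions — not
performance on real resting-state data.

## Known limitations

- The default `all_subjects` topology scope uses all subjects (test ones
  included) for structure detection; accuracy estimates under it are
  optimistic. Use `train_only` when an unbiased estimate matters.
- Decision-tree scores on small cohorts are coarse (pure leaves give 0/1
  scores), so ROC curves are few-pointed staircases.
- The λ pool is shared across subjects within a fold; no per-subject
  penalty optimization is attempted.
- Cross-validated accuracy on 20-subject cohorts has high variance; the
  comparison table should be read over seeds, not from a single run.
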