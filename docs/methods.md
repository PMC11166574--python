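# Methods

## Kinetic model and estimation

Each gene is modeled by linear splicing kinetics whose transcription rate
depends on the attractor the cell occupies:

    dU/dt = α_c − β U,      dS/dt = β U − γ S.

Because (α, β, γ) are only identified up to a common scale, γ is fixed at 1;
spliced counts are therefore in degradation-normalized units. Near steady
state the residuals ε = α_c − βU and η = βU − γS are treated as i.i.d.
zero-mean Gaussians, so maximum likelihood reduces to the
membership-weighted least-squares loss

    𝒥(α, β) = Σ_c Σ_k (α_c − β U_k)² ρ_kc + Σ_k (β U_k − S_k)² + λ Σ_c α_c² + λ β².

𝒥 is a convex quadratic in (α_1..α_K, β), so its global minimizer is closed
form. Eliminating α_c = m_c β with m_c = Σ_k U_k ρ_kc / (Σ_k ρ_kc + λ)
(exact for any fixed β) and solving the scalar normal equation gives

    β* = Σ_k U_k S_k / ( Σ_k U_k² + Σ_kc (U_k − m_c)² ρ_kc + λ(1 + Σ_c m_c²) ).

The λΣm² term in the denominator arises from differentiating the ridge
penalty through the induced α(β); dropping it would make the formula
stationary only at λ = 0. With one-hot memberships and λ = 0 the estimator
reduces to the familiar per-cluster indicator form. Genes are estimated
independently and results do not depend on evaluation order. Degenerate
genes (denominator 0, e.g. U identically zero at λ = 0) are flagged with
α = β = 0 rather than raised; a negative closed-form β (pathological input
only) is clipped to 0 with a warning so it can never enter a kernel
exponent.

The per-gene multistability score 1 − 𝒥/(N_C(Var U + Var S)) is at most 1,
reaches 1 only for a zero-loss fit, and is −∞ for genes constant in both
layers (they are excluded from estimation at load). It is evaluated on a
held-out 20% of cells (split stratified by the current hard assignment so
small attractors appear in both folds); training-fold scores are reported
for diagnosis but gene refiltering uses the test fold, since the filter's
purpose is generalization.

## Transition tensor, kernels and mixture

The tensor v[k, layer, c, g] stacks the attractor-specific residual
velocities (unspliced layer α_c − βU, spliced layer βU − S; the latter is
attractor-independent by construction). The membership-averaged velocity
V = Σ_c ρ_kc v[k,·,c,·] drives the inner-product kernel
w_kl = exp(V_u·ΔU + V_s·ΔS) over the cell kNN graph, stabilized by
subtracting each row's max exponent before exponentiation (exact — softmax
is shift-invariant), then row-normalized. Only the genes passing the
multistability filter enter the velocity kernel. The inner-product form is
used for dynamics; the cosine form is used only for visualization
streamlines and pathway graphs, where direction rather than magnitude
matters.

The similarity kernel is a Gaussian affinity on the top principal
components of the concatenated [U, S] matrix with adaptive per-cell
bandwidths (median neighbor distance), symmetrized on the union sparsity
pattern and Markov-normalized — i.e. one diffusion-map step; using the raw
affinity matrix instead is a documented alternative we did not take. The
spatial kernel applies the same construction to physical coordinates with
a global median-distance bandwidth. All kernels share one sparsity pattern
(union of the expression-kNN and spatial-kNN graphs) so the convex mixture
P = w₁P^v + w₂P^c + (1−w₁−w₂)P^s is well defined entrywise; without
coordinates the spatial weight folds into the similarity term,
P = w₁P^v + (1−w₁)P^c. Defaults: k = 30 expression neighbors on 30 PCs,
k = 8 spatial neighbors, w₁ = 0.5, w₂ = 0.3 — field-conventional values,
all config-exposed. Row sums are verified to 1e-10 after every assembly.

## Coarse-graining

The random walk is decomposed into K fuzzy macrostates by rotating its
top-K real Schur vectors (sorted by eigenvalue modulus) into the
probability simplex: inner-simplex (index-search) initialization, then
refinement of the (K−1)² free rotation parameters maximizing the crispness
objective trace(diag(1/A[0,:]) AᵀA) under the Roeblitz–Weber feasibility
construction; failures fall back to the initialization with a warning. If
the requested K would split a complex Schur pair, K is auto-adjusted with
a warning. Memberships are clipped to [0,1] and row-renormalized; the
coarse chain is P_cg = (χᵀDχ)⁻¹ χᵀDPχ with D = diag(π) where π is the
stationary distribution (floored by 1e-10 uniform mass so disconnected
chains still project; irreducible chains are perturbed below 1e-10).
Dense Schur is used below 5,000 cells and a Krylov eigenbasis above.
Hard assignments break ties toward the lowest attractor index, and
attractor identity across iterations is fixed by Hungarian matching of
membership columns, so labels and convergence monitoring are stable.

## Iteration

Each round: (1) estimate kinetics on the training fold under ρⁿ;
(2) score genes on the test fold and refilter (every round by default; a
once-after-round-1 mode exists); (3) rebuild tensor → averaged velocity →
velocity kernel → mixture → coarse-grain → ρⁿ⁺¹; (4) stop when the mean
absolute membership change after column matching falls below 1e-3 (default)
or at max_iter = 20. Neither constant is externally prescribed; both are
config-exposed. K defaults to the number of initial-label categories
(one-hot initialization; labels come from prior annotation or any
clustering the user supplies). The fit is deterministic given the seed —
the train/test split is the only randomness. A callback receives each
round's monitor record and may stop the iteration, which is the scriptable
equivalent of interactive threshold/weight adjustment; fewer selected genes
than the floor (3, capped at the gene count) aborts with guidance to lower
the threshold.

## Dynamical manifold, transition paths, streamlines

Cells are placed at y_k = Σ_c ρ_kc μ_c where μ_c is the membership-weighted
attractor center in a 2-D embedding (top-2 PCs of [U,S] by default —
deterministic; nonlinear embeddings optional for figures). A K-component
full-covariance Gaussian mixture is EM-fitted to {y_k}, initialized with
means μ_c and weights from the coarse chain's stationary distribution;
covariances are floored at 1e-6×(span)². The landscape φ(y) = −ln 𝒫(y) is
evaluated on a 200×200 grid over the 10%-padded bounding box with the
density floored at 1e-12 before the log.

Transition-path theory runs on the coarse K-state chain by default (a
cell-level mode on P exists but is costly). Forward committors solve the
linear system on interior states; backward committors use the
time-reversed chain π_j P_ji/π_i, so nonreversible dynamics are handled.
Reactive flux f_ij = π_i q⁻_i P_ij q⁺_j is netted (f⁺ = max(f − fᵀ, 0));
the rate is the net flux out of the source, and pathways are extracted
greedily by repeated widest-path (max-bottleneck) search with capacity
subtraction, each path's flux fraction being its bottleneck over the rate.
Fractions sum to ≤ 1 because the decomposition may truncate. An
unreachable target yields a flagged zero-flux result, not an exception.

Streamline projection supports a linear mode (velocity through the
least-squares loadings of the embedding on the joint state) and a
nonlinear, cosine-kernel mode: cosine similarities between a cell's joint
velocity and neighbor displacement vectors are softmax-converted to
transition probabilities and the arrow is the expected embedded
displacement minus the uniform baseline. Attractor-specific views restrict
to cells with ρ_kc > 0.2 by default.

## Pathway analysis

Gene sets (GMT files) are intersected with the selected multistability
genes; sets below the overlap floor (default 3) are skipped with a log
entry. Each surviving pathway's cosine velocity graph is computed from the
gene-set-restricted averaged tensor on the shared kNN pattern and flattened
with one shared edge ordering — absent edges are zero-filled, the only
convention that keeps the vectors comparable. Pathways are compared by
Pearson correlation, embedded by UMAP on the principal components of the
correlation matrix (random initialization below 10 pathways, where spectral
init is ill-posed), and clustered by k-means with k ∈ [2, min(10, n−1)]
chosen by mean silhouette. Results are invariant to pathway input order up
to relabeling (names are processed sorted).

## Synthetic benchmarks

The toggle switch is a symmetric two-gene mutual-inhibition circuit,
f_i = 0.1 + 2/(1 + S_j⁴), β = γ = 1, additive noise σ = 0.1 on both layers,
integrated by Euler–Maruyama (dt = 0.01) with negative values clamped to
zero after every step (clamping, not reflection). It has exactly two
stable fixed points at (U,S) ≈ (2.097, 0.198)/(0.198, 2.097) per gene and
a symmetric saddle between them — verified by a census that integrates
noise-free from random initial conditions and keeps endpoints with strictly
stable numerical Jacobians. Cells are trajectory snapshots at regular
intervals after a burn-in, pooled over a 5×5 grid of starts so both basins
and the saddle region are populated; ground-truth velocity layers are the
drift evaluated at each sampled state (an identity checked in tests), and
ground-truth labels are the basin reached by noise-free integration.

The EMT circuit cascades a SNAIL/miR-34 toggle (TGFB-like signal entering
SNAIL production additively, 0.35·signal) into a ZEB/miR-200 toggle
(ZEB production gated by a SNAIL Hill activation; SNAIL also represses
miR-200 so the intermediate state disappears at high signal), plus slaved
ECAD/VIM/TWIST marker genes; σ = 0.08. The deterministic census gives one
epithelial state below signal ≈ 1.0, three coexisting states (E, ICS, M)
for signal ∈ [1.4, 2.0], and a single mesenchymal state above ≈ 2.2.
Datasets pool snapshots across signal levels (default 0, 1.0, 1.8, 2.5,
4.0, spanning all regimes); basin labels are defined at the tristable
reference signal 1.7 so each cell maps to E, ICS or M.

A third generator draws directly from the linearized attractor model
(cells at U = α_c/β plus Gaussian noise at 10% of signal scale, S = βU
plus noise) for parameter-recovery experiments with known β.

What the generators emulate: multistable splicing kinetics, basin-hopping
noise, signal-driven bifurcations, pooled snapshot sampling. What they do
not: count discreteness and technical dropout, library-size variation,
batch effects, gene-gene correlation beyond the circuit topology, and
realistic gene counts — so passing tests demonstrate correctness of the
method's machinery on data satisfying its assumptions, not robustness to
every artifact of real experiments.

## Problem sizes and numerical choices

Tests and the reproduction script use desk-scale sizes chosen as the
package's own defaults: toggle datasets of 300–2,000 cells (the estimator
is within ~1% of true β at 2,000), EMT datasets of a few hundred cells,
coarse-graining oracles on 10–60-state chains, and 100,000-walker
Monte-Carlo committor checks. Row-stochasticity is enforced to 1e-10,
membership rows to 1e-8, committor residuals to 1e-10. Ties in hard
assignment go to the lowest attractor index. All randomness flows from a
single seed via documented sub-seeding (trajectory seeds drawn below 2³¹).

## Known limitations

The attractor assumption does not model oscillatory dynamics (e.g. strong
cell-cycle signal). The zeroth-order per-attractor expansion of the
production rate ignores higher-order gene interactions. λ enters the m_c
denominator as printed-above even though adding it to a membership sum
mixes units; at the default λ = 0.01 the effect is negligible. Root and
target states for transition-path analysis must be supplied by the user.
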