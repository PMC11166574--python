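# stt — spatial transition tensor analysis of single-cell splicing dynamics

`stt` reconstructs multistable cell-state dynamics from joint unspliced (U)
and spliced (S) mRNA count matrices, optionally constrained by spatial
coordinates. Standard RNA-velocity models assume one global equilibrium per
gene; `stt` instead assumes the cell population occupies **K attractors**,
each with its own transcription rate, and quantifies how cells move between
them. It is aimed at researchers analyzing scRNA-seq or spatial
transcriptomics (Visium, Stereo-seq, HybISS-like) data with spliced and
unspliced layers.

## Model

Per gene (degradation rate normalized to 1 by scale invariance), in
attractor *c*:

    dU/dt = α_c − β U
    dS/dt = β U − S

Given soft attractor memberships ρ (each cell's row on the K-simplex), the
kinetic parameters minimize the regularized least-squares loss

    𝒥(α, β) = Σ_c Σ_k (α_c − β U_k)² ρ_kc + Σ_k (β U_k − S_k)² + λΣ_c α_c² + λβ²,

which is a convex quadratic with a closed-form solution. The per-cell,
per-attractor residual velocities form a 4-D **transition tensor**
v ∈ ℝ^{N_C×2×K×N_G}; its membership-weighted average drives an
inner-product velocity kernel w_kl = exp(V_u·ΔU + V_s·ΔS) that is mixed
with a gene-expression similarity kernel and (when coordinates exist) a
spatial Gaussian kernel into one row-stochastic cellular random walk
P = w₁P^v + w₂P^c + (1−w₁−w₂)P^s. The walk is coarse-grained into K fuzzy
attractors by Schur-vector rotation (GPCCA), giving new memberships; the
scheme alternates until the memberships stop changing. Downstream, the
coarse chain supports transition-path theory (committors, reactive flux,
ranked paths), a Gaussian-mixture "dynamical manifold" landscape
φ(y) = −ln 𝒫(y), per-cell transitional entropy ε_i = −Σ_c ρ_ic ln ρ_ic, and
pathway-level tensor-similarity clustering.

A per-gene **multistability score** 1 − 𝒥/(N_C(Var U + Var S)), evaluated
on a held-out fold, filters the genes that actually exhibit multistable
kinetics; a monitor reports train/test score distributions each round.

## Worked example

Simulate the bistable two-gene toggle switch (mutual Hill inhibition with
additive noise, Euler–Maruyama with clamping at zero) and fit the model:

```python
import stt

sim = stt.simulate_toggle_switch(n_cells=1000, seed=0)
res = stt.STTModel(sim.dataset, w1=0.5, lam=0.01).fit(max_iter=10, seed=0)
print(res.summary())
```

```
Spatial transition tensor fit
================================================================
cells: 1000   genes: 2   attractors: 2
rounds run: 1   converged: True
selected multistable genes: 2 (threshold 0.5)
kernel weights: w1=0.5 w2=0.3   lambda=0.01

           beta   alpha_0   alpha_1  score_train  score_test  selected
gene
gene0  0.993671  0.213617  2.059388     0.988400    0.988184      True
gene1  0.993384  2.056499  0.219204     0.989245    0.987570      True

coarse-grained transition matrix P_cg:
       attr0  attr1
attr0    1.0    0.0
attr1    0.0    1.0
stationary distribution: [0.5817 0.4183]
```

The estimated splicing rate β ≈ 0.99 recovers the simulator's true value
β = 1, and the two per-attractor transcription rates α (≈0.21 / ≈2.06 per
gene, mirrored between the two genes) match the low/high expression states
of the two basins. Both genes score ≈0.99 on held-out cells — the
multistable model explains almost all of their variance. The coarse chain
is near-identity at this noise level: basin switches are rare, and
transition-path analysis quantifies them,

```python
tpt = res.transition_paths(source=[0], target=[1])
# tpt.rate -> 3.9e-07 ; tpt.paths -> [((0, 1), 1.0)]
```

while `res.entropy` flags the few saddle-region cells (median entropy
1.5e-4; cells between the basins approach ln 2). The seven-gene EMT
circuit (`stt.simulate_emt_circuit`) behaves analogously with three
attractors — epithelial, intermediate and mesenchymal — and flux from E to
M passing through the intermediate state.

A command-line pipeline wraps the same steps:

```bash
stt simulate toggle --n-cells 2000 --seed 0 --out toggle.h5ad
stt fit toggle.h5ad --seed 0 --out fitted.h5ad
stt dynamics fitted.h5ad --source 0 --target 1 --out tpt.json
```

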