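# Methods

## Model

`lorentzvae` implements a variational autoencoder for raw single-cell count
matrices (scRNA-seq genes or scATAC-seq peaks) whose latent space is shaped
by a hyperbolic-geometry regularizer. The generative picture is standard
for count-based VAEs: each cell i has a latent code z_i ∈ R^d with a unit
Gaussian prior; the decoder maps a code to a softmax over features, scaled
by the cell's observed library size, giving count means
μ_ij = softmax(decoder(·))_ij · Σ_k x_ik, so predicted means conserve each
cell's total exactly. Counts are scored under one of four families:
Poisson, negative binomial (mean–dispersion form, Var = μ + μ²/θ with one
free θ_j per feature, stored as log θ_j and optimized jointly), and their
zero-inflated mixtures ZIP/ZINB, whose dropout probability π_ij comes from
a second affine head on the shared decoder's hidden layer with a logistic
squash. NB is the default for RNA; ZINB for accessibility data, which is
far sparser (≈90–95% zeros vs ≈60–80%).

The distinctive element is a *dual latent pathway*. The sampled code z is
used twice:

1. the primary path decodes z directly (reconstruction loss L_recon1);
2. the bottleneck path compresses z to l_e ∈ R^{d_c} (d_c ≪ d) and expands
   it back to l_d ∈ R^d through two purely affine maps, then decodes l_d
   with the *same* decoder (L_recon2).

Both codes are lifted onto the hyperboloid model of hyperbolic space by the
exponential map at the origin, exp_o(v) = (cosh‖v‖, sinh‖v‖·v/‖v‖), and the
geometric loss is the mean squared geodesic distance
d_H(u,w) = arccosh(−⟨u,w⟩_L) between exp_o(z_i) and exp_o(l_{d,i}).
Hyperbolic space accommodates tree-like structure with low distortion, so
penalizing hyperbolic disagreement between the full code and its
bottleneck reconstruction pushes the model to keep hierarchical relations
in the few directions the bottleneck can carry. The total loss is

    L = λ_r1 L_recon1 + λ_r2 L_recon2 + λ_geo L_geo + β L_KL,

with the KL term normalized per cell and per latent unit,
(1/2Nd) Σ (σ² + μ² − 1 − log σ²).

Numerical rules for the geometry, applied identically in the numpy
reference (`geometry.py`) and the differentiable training path: the
arccosh argument α = −⟨u,w⟩_L is clamped to α ≥ 1 + 1e−8 (hence the
self-distance is arccosh(1+1e−8) ≈ 1.41e−4, not exactly zero — tests
assert against the clamp floor); for α > 1e4 the asymptotic form log(2α)
is used (the branches agree to < 1e−8 at the switch); the exp map takes
its ‖v‖ = 0 branch below 1e−12 to avoid 0/0.

## Architecture and training

Encoder and decoder each have one 128-unit hidden layer (affine → layer
normalization → ReLU), producing μ and log σ² heads (encoder) or the
softmax/π heads (decoder). log σ² is clamped to [−10, 10]. Defaults follow
the reference configuration: d = 10, d_c = 2, hidden 128, λ_r1 = λ_r2 =
β = 1.0, λ_geo = 5.0, Adam at 1e−4, batch size 128, global gradient-norm
clipping at 1.0. The default epoch budget is 400 with early stopping
(patience 20, min-delta 1e−4 on total loss), both configurable. Training
is single-threaded CPU numpy; with a fixed seed, runs are bit-reproducible
(the documented determinism contract). A non-finite loss aborts with a
diagnostic naming the first bad component.

Because no deep-learning framework is a dependency, the package carries
its own compact reverse-mode automatic-differentiation engine
(`_autodiff.py`): a tape of numpy primitives (dense algebra, layer norm,
log-softmax, log-gamma, the clamped arccosh) sufficient for these
networks. Every primitive's gradient is tested against central finite
differences.

Variant switches reproduce the experimental axes: `use_main_path` /
`use_bn_path` ablate a pathway (ablating the bottleneck also removes the
geometric loss; disabling both is rejected); `geo_anchor="two_views"`
replaces the bottleneck anchor with a second posterior sample, so the
geometric loss acts between exp_o(z⁽¹⁾) and exp_o(z⁽²⁾) (the shared
decoder still reconstructs from z⁽¹⁾ and from l_d); `detach_anchor=True`
stops gradients through the anchor side, the "deterministic anchor"
reading. By default the geometric loss back-propagates into both
pathways. λ_geo defaults to 5.0, the declared reference value; the sweep
harness covers {1, 5, 10} since larger weights are also reported
favorably.

## Preprocessing

RNA: the top 5,000 highly variable genes are selected on raw counts by
standardized variance under a mean–variance trend — a cubic polynomial
regression of log10 variance on log10 mean supplies the expected SD,
counts are standardized by it and clipped at √N, and genes are ranked by
the clipped variance (the common count-based HVG scheme, implemented
loess-free). The encoder input is then log1p → per-gene z-score (SD floor
1e−8, so constant genes map to 0 and indices stay aligned) → clip at ±10
SD. Selection runs on raw counts before normalization so the two steps
stay independent.

ATAC: peaks are restricted to those accessible in 1%–95% of cells, TF-IDF
normalized (TF_ij = x_ij/Σ_k x_ik, IDF_j = log(1 + N/n_j), scaled by
s = 1e4), ranked by TF-IDF variance, and the top 10,000 kept. The variance
ranking runs after the accessibility filter. The encoder input is the
TF-IDF values of the selected peaks, additionally z-scored and clipped
like RNA — the standardization is our addition for training stability and
can be switched off (`standardize_atac=False`).

In both modalities the likelihood target is the raw integer counts of the
selected features, never the normalized matrix, and library sizes are the
row sums **over the selected features**, which makes the softmax-mean
identity Σ_j μ_ij = library_size_i exact and testable.

## Evaluation battery

All metrics consume a latent matrix (posterior means by default; a seeded
posterior sample is available behind a flag).

* Clustering: NMI/ARI of seeded k-means (k = number of reference classes,
  10 restarts) against labels; ASW/CAL/DAV of the reference labels on the
  latent; coupling degree COR = mean |Pearson ρ| over ordered pairs of
  latent dimensions (constant dimensions count as 0, with a warning).
* 2-D embedding fidelity, against UMAP and t-SNE projections: Spearman
  correlation of upper-triangle pairwise distances; co-ranking quality
  Q_NX(K) split at K_max = argmax_K [Q_NX(K) − K/(N−1)] (the standard
  co-ranking boundary) into Q_local (mean below) and Q_global (mean
  above); Q_embed = mean of the three. Distance ties break by index, so
  results are deterministic. For N > 1000 these O(N²) scores use a seeded
  uniform subsample of 1000 cells.
* Intrinsic diagnostics of the covariance eigenspectrum λ₁ ≥ … ≥ λ_k
  (ε = 1e−8 throughout): compactness M_dim = 1 − (d_eff − 1)/(k − 1) with
  d_eff the 95%-variance count; spectral decay S_decay =
  logistic(|β|)·λ₁/Σλ with β the slope of log(λ_i + ε) on the index —
  note the sign: the logistic is taken of +|β| so the score *increases*
  with decay steepness, matching its stated meaning (the alternative
  orientation decreases with steepness and contradicts it); participation
  ratio P_ratio = (Σλ)²/(k Σλ²); anisotropy A_score =
  tanh((log(λ₁+ε) − log(λ_k+ε))/4), with ε inside both logs so the score
  is finite at λ_k = 0; trajectory directionality T_dir = λ₁/(Σ_{i≥2}+ε),
  which is unbounded and is capped at 1 inside the composite while the
  raw value is also reported; noise resilience N_res =
  min(0.1(λ₁+λ₂)/(Σ_{i≥3}+ε), 1). Composites: Q_core = mean(M_dim,
  S_decay, P_ratio, A_score) and Q_overall = 0.5 Q_core +
  0.3 min(T_dir,1) + 0.2 N_res.
* Batch mixing iLISI: per cell, a Gaussian kernel over its 3·perplexity
  nearest neighbors is calibrated by binary search to entropy
  log(perplexity); kernel mass is summed per batch and the score is
  1/Σ_j p_j², averaged over cells; a single batch gives exactly 1 and B
  fully mixed batches approach B. Neighborhoods shrink (with a warning)
  when N < 3·perplexity + 1.

## Synthetic study conditions

The generators produce the regime the model assumes, so everything is
testable without downloads. Cluster log-intensity profiles sit on the
leaves of a binary tree: each level adds N(0, de_strength²) perturbations
to the parent profile, so nearby leaves share programs — the hierarchical
structure the hyperbolic regularizer targets. A cell's count vector is
NB(lib_i · softmax(profile), θ_j) via a gamma–Poisson draw, with gene-wise
θ_j ~ U(θ_range) and log-normal library sizes (defaults μ = log 2000,
σ = 0.3, a plausible scRNA-seq depth). Optional per-batch gene-wise
log-scalings add batch effects; a trajectory mode interpolates profiles
along 1-D pseudotime (the centered noiseless log-mean matrix is rank one
by construction). ATAC mode applies Bernoulli(π) dropout on the NB counts
(ZINB); its defaults (2000 peaks, wider baseline spread, θ ∈ [0.5, 2],
π = 0.5) put the global zero fraction in 90–95%, versus 60–80% for the
RNA defaults.

What the generators do not emulate: UMI/read-level noise, ambient RNA,
doublets, realistic gene–gene covariance beyond the tree programs, or any
particular real dataset's moments. Passing tests therefore demonstrate
correctness of the machinery and qualitative behavior in the assumed
regime, not performance on real tissues.

## Problem sizes used in the checks

The structure-recovery check trains the default model on 2000 cells × 500
genes with 10 hierarchical clusters for 100 epochs (five training seeds;
k-means ARI on the latent, median ≥ 0.7; the 10-epoch moving average of
total loss strictly decreases). Ablation directionality uses 600 × 200
with 8 clusters, 80 epochs, five seeds, medians. Batch mixing uses
800 × 200, two batches, gene-wise effect SD 0.6. The likelihood-family
comparison holds out 150 of 700 ATAC-mode cells and compares per-cell NLL
medians over five seeds. These sizes were chosen as the smallest at which
the respective effects are stable.

## Known limitations and open choices

* At these synthetic conditions one reported ablation direction does not
  reproduce: the full model's participation ratio is *lower* than the
  no-bottleneck ablation's. The geometric tie pulls z toward the rank-2
  affine image of the bottleneck, concentrating variance in two
  directions, while a plain VAE on strongly identifiable clusters keeps
  many informative dimensions. On real data, where unregularized VAEs
  often under-use their latent space, the direction can differ. The
  corresponding check is left failing rather than weakened, and the
  behavior is documented here.
* Whether the two-view geometric variant shares one decoder for both
  reconstructions is an open reading; the implementation assumes yes.
* Evaluation uses posterior means by default; sampled-z evaluation is one
  flag away and changes spectrum-based scores (sampling adds ≈ unit
  variance in under-used dimensions).
* The trainer is plain numpy on one CPU: fine at desk scale (thousands of
  cells, hundreds-to-thousands of features), not engineered for atlas
  scale.
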