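# Methods

## The model

`ddparcel` divides the N elements of a spatial map into contiguous clusters
("parcels") such that the connectivity between any two parcels is as uniform
as possible. The generative model is

    c  ~  dd-CRP(alpha, f)
    A_mn, sigma2_mn  ~  Normal-Inverse-chi^2(mu0, kappa0, sigma0^2, nu0)
    D_ij  ~  Normal(A_{z(c)_i, z(c)_j}, sigma2_{z(c)_i, z(c)_j})

where the distance-dependent Chinese restaurant process assigns every
element a link `c_i` to itself (weight `alpha`) or to one of its spatial
neighbors (weight 1; `f_ij = 1` iff i and j are neighbors). The parcellation
`z(c)` is the set of undirected connected components of the link graph.
Because links can only follow neighbor edges, *every* reachable parcellation
is spatially contiguous, and the number of parcels K is not fixed in
advance — both properties come from the prior, not from post-hoc repair.

For each parcel pair (m, n), the connectivities between their elements form
one "block" of D, modeled as Normal with latent mean and variance under a
conjugate Normal-Inverse-chi² prior. Conjugacy gives the block marginal in
closed form from the sufficient statistics (count L, mean d̄, sum of squared
deviations s):

    p(D_mn) = Γ(nu_mn/2)/Γ(nu0/2) · sqrt(kappa0/kappa_mn)
              · (nu0·sigma0²)^(nu0/2) / (nu_mn·sigma2_mn)^(nu_mn/2) · π^(−L/2)

    kappa_mn = kappa0 + L,  nu_mn = nu0 + L,
    sigma2_mn = (nu0·sigma0² + s + L·kappa0/(kappa0+L)·(mu0 − d̄)²) / nu_mn.

The π exponent scales with the number of observations in the block (L);
this is the only reading under which the expression is a normalized
marginal, which the test suite confirms against direct 2-D quadrature of
the Normal × NIχ² integral. All likelihood computation is done in the log
domain through log-gamma; raw Γ evaluation overflows for realistic block
sizes.

### Conventions

* **Diagonal.** Self-connectivity D_ii is excluded from normalization, all
  block statistics, and variance explained (`diagonal_defined=False` by
  default). A correlation diagonal is trivially 1 and carries no parcel
  information.
* **Symmetric matrices.** Each unordered observation counts once: the
  included entries are the strict upper triangle. Counting both orders
  would double every datum's likelihood contribution. A within-parcel block
  of size p therefore has L = p(p−1)/2 entries (p(p−1) when asymmetric);
  the likelihood product runs over unordered parcel pairs m ≤ n (all
  ordered pairs when asymmetric). Within-parcel blocks are part of the
  product.
* **Normalization.** Inputs are standardized to zero mean, unit variance
  over the included entries so `sigma0_sq` is comparable across datasets.
* **Labels.** Clusters are numbered 1..K ordered by smallest member index,
  making serialized output deterministic. Element ids are 0-based
  everywhere.

## Inference

Collapsed Gibbs sampling resamples one link at a time. Removing `c_i`
splits i's parcel into at most two components (a link graph loses exactly
one edge). Candidates that keep the removal-induced partition share one
baseline likelihood; candidates that merge two parcels are scored through
the merged/split likelihood ratio, evaluated block by block with the exact
pooling identity

    s_K = s_K' + s_K'' + |D_K'||D_K''| / (|D_K'|+|D_K''|) · (d̄_K' − d̄_K'')²,

so a merge costs O(K) block updates and no pass over the data. Splits
recompute only the smaller fragment's blocks from the data; the larger
fragment's statistics are recovered by inverting the pooling identity.
A per-pass drift guard in the test suite verifies the incremental score
stays within 1e-6 of a from-scratch recomputation.

Sweeps visit elements in a fresh uniform random permutation each pass
(guarding against order artifacts; the sweep order is otherwise a free
choice). Ties between equal-probability candidates are broken by the run's
RNG. The reported solution is the highest-posterior state visited (MAP over
the trajectory); no burn-in or convergence criterion is imposed, and the
number of passes is an explicit parameter (default 30).

**Initialization** (`ward-auto`): spatially constrained Ward cuts are scored
under the model at K ∈ {2, 4, 8, …, N}, refined by ±25% steps around the
running best until no new candidate improves (the prior term reduces to
K·log alpha because a spanning-tree cluster carries exactly one self-link).
Links are then set to a uniform random spanning tree (Wilson's algorithm)
within each cluster. Fixed-K Ward and fully random initialization are also
available; the choice mainly affects how many passes are needed, not the
solution quality.

**Hyperparameters.** Defaults alpha = 10, mu0 = 0, kappa0 = 1e-4, nu0 = 1.
The one consequential parameter is `sigma0_sq`, the prior expected
within-block variance on the normalized scale: smaller values make parcels
smaller. The synthetic experiments use 0.01; the flow experiments use 10.
There is no default — it must be chosen per run.

## Baselines

All four comparison methods consume the fingerprint dissimilarity

    W_ij = sqrt( Σ_{a≠i,j} (D_ia − D_ja)² + Σ_{a≠i,j} (D_ai − D_aj)² )

and a target K (taken from the model's inferred K in comparisons, since
none of them can choose K):

* **local similarity** — remove neighbor edges above a threshold chosen so
  the retained-edge graph has K components (single linkage on the spatial
  graph). Component count is a step function of the threshold; when tied
  weights skip K, the closest achievable count ≥ K is taken and smallest
  adjacent components merged down, with a warning.
* **normalized cut** — K-way spectral partition of the neighbor similarity
  S = 1/W (capped at 1e12 for coincident fingerprints), kmeans
  discretization. Spatially disconnected clusters are split and the count
  repaired by merging smallest adjacent clusters.
* **region growing** — seeds are elements whose worst neighbor
  dissimilarity is a local minimum over their neighborhood (ties by index;
  seeds are augmented by the same statistic if fewer than K); regions grow
  by attaching the unassigned neighbor with smallest dissimilarity to its
  region's seed, then constrained Ward merges the grown regions to K.
* **Ward** — agglomerative clustering with Ward's linkage restricted to
  merges of spatially adjacent clusters, implemented via the Lance-Williams
  update on squared dissimilarities (no installed package offers
  connectivity-constrained Ward on a precomputed dissimilarity). On a
  complete graph it reproduces classical Ward linkage exactly, which the
  tests check against scipy.
* **random parcellations** — iterative uniform merges of adjacent clusters
  down to K; the chance envelope for NMI comparisons.

## Synthetic data

The grid generator draws a K×K block-mean matrix A with iid standard-normal
entries (mirrored when a symmetric matrix is requested) and samples each
included entry of D as Normal(A_{z_i z_j}, sigma²). Three fixed 18×18
layouts are provided: `squares9` (nine equal 6×6 squares — the equal-size
regime where spectral methods are competitive), `stripes6` (horizontal
stripes of heights 6, 4, 3, 2, 2, 1, including two small adjacent stripes),
and `nonuniform5` (an L-shaped region of 180 elements plus rectangles of
72, 36, 24 and 12). The layouts are versioned constants of this package:
they realize the qualitative designs (equal sizes / unequal stripes /
strongly nonuniform regions) rather than copying any published figure
pixel-for-pixel, so absolute curve values are comparable only within this
artifact. A three-spiral geometry (consecutive-along-arm plus
nearest-point-between-arm adjacency, K = 3) probes non-grid topology.

What the generator emulates is exactly the model's own assumptions —
Gaussian blocks with homogeneous variance and exact block structure. Real
connectivity matrices are spatially smooth, heavy-tailed, and only
approximately blocked, so passing recovery tests demonstrates correct
inference under the stated model, not robustness to model misspecification.
The flow simulator (Poisson mover counts around a population-proportional
chance rate, with a within-community rate multiplier) breaks the Gaussian
assumption and provides that check in a milder form.

## Evaluation

NMI uses the contingency-table form with natural logarithms (the ratio is
base-invariant) and geometric-mean normalization. Single-cluster labelings
raise rather than scoring 0, so sweep code must handle degeneracy
explicitly. Variance explained is 1 − SS_res/SS_tot over included entries
with block means as fitted values; it is non-decreasing under refinement.

## Flow preprocessing

Units below a population threshold (default 10,000) are merged iteratively:
the globally smallest unit joins its smallest within-group neighbor, ties
broken by unit id, with the merged unit keeping the lexicographically
smaller id. Flows internal to a merged unit fall onto the ignored diagonal.
Chance normalization divides each mover count by
(ΣM)·P_a·P_b/(ΣP)², so 1 is chance level; the result is nonnegative and
asymmetric. No distance/gravity correction is applied — the normalization
is deliberately population-only.

## Problem sizes and numerical choices

The recovery studies use the 18×18 grid (N = 324, ~10,000 Gibbs steps for
30 passes, a few seconds per run) and 20 replicates per condition, matching
the scale at which the synthetic comparisons are defined. The acceptance
script averages each reported quantity over 5 independent replicates to
damp single-draw Monte-carlo noise. Degenerate inputs fail fast: constant
matrices cannot be normalized, disconnected spatial graphs are rejected at
initialization, and zero-variance totals make variance explained undefined.
Un-pooling (the split fast path) clamps sums of squares at zero to absorb
rounding; the drift guard bounds the accumulated error.

## Known limitations

* Exact MAP is not guaranteed — the sampler reports the best visited state,
  and the posterior is multimodal at high noise.
* Likelihood evaluation assumes the block-Normal model; heavy-tailed inputs
  should be variance-stabilized (e.g. log-transformed counts) first.
* The dense W matrix used by the baselines is O(N²) memory; the sampler
  itself also stores the dense connectivity matrix, which bounds practical
  N well below the sizes the model could in principle handle with sparse
  storage.
* `normalized_cut` relies on a spectral relaxation plus repair; it is not
  an exact minimizer (exact normalized cut is NP-complete).
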