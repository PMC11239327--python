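# Methods

## Model

`hmmbiclust` fits a Bayesian hierarchical model that clusters the rows
(samples) of an n x p expression matrix while simultaneously classifying,
within each sample cluster, every column (feature/gene) into one of three
states: overexpressed (1), underexpressed (2), or irrelevant (3).  Each
(cluster, state) pair defines a bicluster — a rectangle of samples x
features — giving 3K biclusters for K clusters.

Observations are conditionally normal,

    y_ij | z_i = k, rho_jk = l  ~  Normal(mu_jkl, sigma2_jkl),

with a hierarchical prior on the per-feature means:

    mu_jk1 ~ Normal(mu_k1, sigma2_k1),  mu_k1 > 0   (overexpressed)
    mu_jk2 ~ Normal(mu_k2, sigma2_k2),  mu_k2 < 0   (underexpressed)
    mu_jk3 = 0                                       (irrelevant)

The irrelevant-state variance sigma2_j3 is shared across clusters.  Under
the *constrained* variants, |mu_kl| carries a normal prior left-truncated at
t > 0, which pins the biological meaning of states 1 and 2; without the
constraint the two relevant labels are exchangeable and are re-sorted
post hoc (`align_variant_labels`, state 1 gets the larger mean).

Features are assumed pre-ordered by external biological similarity (e.g., a
GO semantic-similarity seriation; `order_features` implements a greedy
nearest-neighbour seriation for any user-supplied similarity matrix).  Along
this order the states of each cluster's features form a first-order Markov
chain with a shared 3x3 transition matrix xi and uniform initial
distribution, so neighbouring features are encouraged to share a state.
The *NoHMM* variants replace the chain with i.i.d. uniform states.

Cluster labels are i.i.d. categorical with probabilities Omega.  Priors are
conjugate throughout: Dirichlet for Omega and the rows of xi, truncated (or
plain) normal for mu_kl, inverse-gamma IG(a0, b0) for every variance.

One modelling detail deserves a note: the complete-data likelihood counts
each cluster's state-chain prior once per *cluster*, not once per sample.
This is the only factorisation consistent with the Gibbs conditionals (the
label conditional carries no chain factor; each site conditional carries
single transition factors), and it gives the chain of an empty cluster a
well-defined prior.

## Gibbs sampler

Each sweep updates, in order: Omega; all mu_jkl then all mu_kl; all
variances; xi; the labels z (independently per sample); and the state
chains rho (a single-site systematic scan j = 1..p per cluster — site 1
couples only to its right neighbour, site p only to its left; the uniform
initial distribution cancels in the normalization).  All probability work
is done in log space with probabilities below 1e-300 treated as log zero.
The scan's inner loop is numba-compiled when numba is importable, with an
identical pure-python fallback.

For the mean conditional of the underexpressed state the magnitude
statistic enters with its sign flipped (|mu_k2| is truncated below at t, so
its posterior location is −M_k2/(c + N_k2) for prior mean 0); the
overexpressed state uses +M_k1.  This is the conjugate form; a literal
reading that feeds the signed sum into the magnitude posterior would pin
mu_k2 at −t regardless of the data.

**Initialization.**  Latents start uniform at random (z ~ categorical(1/K),
rho_jk ~ categorical(1/3) i.i.d.).  The continuous parameters consumed
before their first conditional update start at neutral, cluster-exchangeable
values: every variance at b0/a0, cluster means at ±max(1, t) (one unit of a
standardized expression scale), Omega and xi uniform.  Symmetry here is
essential, not cosmetic: with p ~ 1000 features the label conditional is
extremely peaked, and any systematic head start for one cluster (for
example, initializing mu_kl from its diffuse prior, whose draws have
magnitude ~ sqrt(1000)) moves *every* sample into one cluster on the first
sweep.  An emptied cluster then redraws its per-feature parameters from the
prior, fits nothing, and never wins a sample back — the collapse is
absorbing.  With exchangeable starts the first sweeps keep the clusters
balanced and the separation emerges from the data.

**Truncated-normal draws** use `scipy.stats.truncnorm`, which is stable far
into the tail.  Inverse-gamma draws are scale / Gamma(shape).

**Known dynamical limitations** (properties of the exact single-site
conditionals, documented rather than patched):

* At very low noise the relevant-state labels can freeze in a mixed
  configuration — per-feature means adapt to the data under either label,
  and label swaps require a lucky prior draw.  The constraint resolves this
  at moderate noise; at sigma2 << 1 only the partition, not the state
  labelling, should be trusted.
* Without the Markov prior (NoHMM variants), irrelevant features flip into
  relevant states whenever their freshly drawn candidate mean happens to fit;
  an equilibrium fraction of spurious relevant features persists and drags
  the cluster-level means toward zero.  The chain prior is what suppresses
  this in the full model — the NoHMM variants measurably underperform it.

## Point estimates, DIC, evaluation

The point summary is the joint MAP over retained draws: the draw maximizing
complete-data log-likelihood plus the continuous-parameter log prior (a
likelihood-only ranking is available).  A single draw is internally
consistent, so no cross-draw relabelling is needed.  Biclusters are the 3
state sets of every cluster with at least `min_cluster_size` samples
(default 3).

DIC is estimated as −(4/S) Σ_s log p(y | θ_s, z_s, ρ_s) + 2 log p(y | MAP),
with observation likelihoods conditional on the sampled latents (the
marginal over z, rho is intractable).  `dic_scan` derives each K's seed from
(seed, K) so grids are order-independent, and reports empty-cluster
diagnostics; elbow selection is left to the user, as tiny-cluster solutions
past the truth are flagged rather than auto-rejected.

Bicluster agreement uses the pairwise F1 = 2 r c / (n_A + n_B) on shared
samples (r) and features (c), the one-sided best-match average S(M1, M2),
and the symmetrized mean of both directions.  Evaluation against truth
includes the irrelevant-state rectangles, so both collections hold 3K
rectangles; empty rectangles score 0 against everything.

## Synthetic data

`simulate` reproduces the two study designs: 100 overexpressed plus 100
underexpressed features, either leading the feature order (setting 1) or
scattered uniformly (setting 2), among p = 1000 features by default;
cluster means mu_k1 = (k+1)/2, mu_k2 = −(k+1)/2, mu_k3 = 0; homoscedastic
normal noise with variance 1 or 2.  Cluster sizes are balanced
deterministically (first ⌈n/K⌉ samples to cluster 1, and so on) so the
ground truth is reproducible; multinomial assignment is available.  The
generator does not emulate correlated/redundant irrelevant features,
heavy-tailed noise, or cluster-specific relevant-feature sets — recovery on
these data shows the sampler works under the model's own assumptions, not
that real expression data satisfies them.

## Problem sizes and tolerances

The bundled end-to-end checks run the simulation scenarios at 2000
iterations with 1000 burn-in and 3–5 replicates (the package's default
desk-scale protocol; applications use 10000/5000).  Conjugate kernels are
checked against closed-form or quadrature moments at 1e5 draws within 4
standard errors; site conditionals are checked against exhaustive
enumeration of a 27-chain toy to 1e-10; long-run scan frequencies against
the enumerated posterior at 1e5 sweeps within 4 Monte-Carlo standard
errors.  Standardization uses the sample (ddof = 1) standard deviation and
rejects constant features.
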