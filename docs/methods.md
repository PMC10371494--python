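# Methods

## Substitution model

All models are continuous-time reversible Markov processes on {A, C, G, T}
with generator `Q_ij = rho_ij * pi_j` (i ≠ j), diagonal set so rows sum to
zero.  `pi` is the stationary frequency profile (a point on the 4-simplex,
entries floored at 1e-8) and `rho` the six symmetric exchangeabilities over
unordered pairs (AC, AG, AT, CG, CT, GT).  Two identifiability conventions:
`rho` is normalized to mean 1 (symmetric across pairs, and friendlier to
Dirichlet-style proposals than pinning one entry), and every matrix is
rescaled to one expected substitution per unit time at stationarity, so a
branch length always reads as expected substitutions per site.  In mixtures
each component matrix is individually normalized, keeping that single
interpretation of branch lengths across components.

Transition probabilities use the spectral decomposition of the
symmetrized generator (`Q` is similar to a symmetric matrix under the
`sqrt(pi)` transform), so eigenvalues are real and `exp(Qt)` is exact up to
one `eigh` per matrix; tiny negative entries from rounding are clipped at
zero.

## Rate heterogeneity

Site rates follow a gamma law with mean 1 and variance `1/alpha`,
discretized into `ncat` (default 4) equal-probability categories.  Each
category's rate is the **mean** of its quantile bin (computed from the
regularized incomplete gamma function), renormalized to average exactly 1.
Bin means rather than medians preserve the unit mean by construction; the
choice matters little beyond that and is exposed nowhere.

## Mixtures of frequency profiles

A mixture component owns only its profile `pi_c`; exchangeabilities, gamma
shape and branch lengths are shared.  Finite mixtures carry explicit
weights on the simplex and keep their declared dimension (components may
shrink toward zero weight but are never deleted).  The Dirichlet-process
version holds an explicit site allocation, a concentration parameter, and
the occupied profiles; emptied components are removed immediately, so the
occupied count never exceeds the number of sites.

Site likelihoods integrate rate categories by equal-weight averaging and
components by log-sum-exp over weighted component likelihoods.  Identical
site patterns are collapsed before pruning; a test asserts collapsing
changes values by nothing.  Conditional-likelihood vectors are rescaled at
every internal node with a log accumulator, which keeps 100+-taxon,
high-divergence evaluations finite.  Missing data (`-`, `?`, `N`, IUPAC
codes) enter the pruning recursion as partially observed states whose leaf
conditionals are 1 on every compatible nucleotide; an all-missing column
has likelihood exactly 1.  The likelihood is evaluated from an arbitrary
fixed internal root; reversibility makes the choice immaterial (asserted
by a re-rooting test at 1e-10).

## Priors

Stand-ins for standard Bayesian phylogenetics defaults, all configurable
in `Priors`:

| parameter | prior | default |
|---|---|---|
| branch lengths | iid Exponential | mean 0.1 |
| profile `pi_c` | Dirichlet | flat (1,1,1,1) |
| exchangeabilities `rho/6` | Dirichlet | flat |
| mixture weights | Dirichlet | flat |
| gamma shape `alpha` | Exponential | mean 1 |
| DP concentration | Exponential | mean 10 |

## MCMC

One cycle applies, in fixed order: a multiplier move per branch length, a
Dirichlet simplex move on `rho/6`, a multiplier move on `alpha`, the
mixture update, and a Dirichlet simplex move per profile.  Single and
finite-mixture models are sampled against the marginal (component-summed)
likelihood; the finite-mixture update is an MH move on the weight simplex.
DP models hold an explicit allocation: one sweep runs the
auxiliary-component allocation sampler (m = 3 fresh auxiliary profiles per
site, recycling a removed singleton's profile as the first auxiliary, so
the scheme stays valid without conjugacy), a Metropolis refresh of each
occupied profile against its member sites, and a beta-augmentation Gibbs
draw of the concentration; branch/exchangeability/shape moves then
condition on the allocation.  With the likelihood term disabled the
allocation sweep reduces exactly to the Chinese restaurant process, which
the tests exploit.

Dirichlet proposals are centred on the current point
(`Dirichlet(c·x + 0.1)`) with exact Hastings ratios; proposals falling
below the 1e-8 profile floor are rejected, truncating the stationary law
to the floored simplex (negligible mass for the targets used here).
Proposal scales adapt toward mid-range acceptance during burn-in only;
the post-burn-in kernel is fixed, preserving stationarity.  Every retained
cycle is a snapshot (no thinning): 1500 cycles with 500 burn-in leave
K = 1000 draws.  One master seed drives a `SeedSequence` tree, so runs are
bitwise reproducible.

The topology is **fixed** throughout — a deliberate deviation from
full phylogenetic practice, where topology would be sampled too.  Model
ranking by cross-validation is the target here, and tree-search moves are
out of scope; absolute CV scores may shift relative to a
topology-sampling run, but the paired model comparisons are unaffected by
a shared fixed tree.  Chains on data are initialized at the supplied
branch lengths; prior-only chains initialize from the priors.

For DP posterior snapshots, the predictive weights used when scoring new
columns are the occupancy fractions `n_c / n` of the allocation at that
cycle; the prior mass `conc/(n+conc)` for an unseen component is dropped,
a standard truncation whose error vanishes as the learning set grows.

## Cross-validation protocol

One replicate: draw a testing set of round-half-even(n/5) columns
uniformly without replacement (learning set = the rest), fit each model by
MCMC on the learning set, and score the testing set as
`Σ_n ln[(1/K) Σ_k p(D_n|θ_k)]`, the inner average taken in probability
space by log-sum-exp.  "Repeat five times" is read as five *independent*
random splits (a disjoint 5-fold mode is also provided).  Within a
replicate every model is scored on the same split — the paired design is
what makes Δ ± SD meaningful at five replicates — and `relative_scores`
refuses to difference scores from different splits.  Relative scores are
reported per replicate and summarized as mean ± SD; `per_site_ratio`
converts a Δ over n sites into nats/site and the `exp(Δ/n)`
fold-improvement of the average column.

## Synthetic data

The simulator draws, per site, a component from the mixture weights and a
rate category uniformly (the discrete categories the inference model uses,
so recovery tests carry no discretization mismatch; a continuous-gamma
switch exists for robustness experiments), then evolves a root state from
the component's stationary profile down the tree.  Ground truth (model,
per-site component, per-site category) is serialized next to the
alignment.

Benchmark scenarios fix the study conditions:

- **S1** single GTR+Γ, 8 taxa × 2000 sites, α = 0.5, with a *fixed*
  canonical generating model (π = (0.35, 0.18, 0.24, 0.23), transition-
  biased ρ = (0.7, 3.0, 0.2, 0.45, 5.0, 1.3) before mean-1 scaling).  A
  recovery benchmark needs identifiable targets: a random ρ draw can place
  two exchangeabilities within a fraction of a posterior standard
  deviation at n = 2000, where rank recovery is impossible in principle.
- **S2** three skewed profiles (Dirichlet 0.2) sharing equal
  exchangeabilities, 10 taxa × 1500 sites — pattern heterogeneity only.
- **S3** single GTR+Γ with α = 0.3, 8 taxa × 1000 sites — strong rate
  heterogeneity only.
- **S4** per-site profiles from a realized Dirichlet process
  (concentration 5), 10 taxa × 1000 sites — richness that saturates small
  finite mixtures.

Trees are random sequential-join topologies with Exponential(0.1) branch
lengths; weights for multi-component scenarios come from Dirichlet(5)
(moderately even, so every component is learnable).  What the simulator
does **not** emulate: indels and alignment error, codon structure and
selection, branch-heterogeneous (non-stationary) composition, and
among-site dependence.  Passing recovery and ranking tests therefore shows
sampler and scorer correctness under the model class, not robustness to
real-data violations of it.

## Problem sizes and numerical choices

The directional ranking experiments use a reduced protocol (2 replicates,
600 cycles, 200 burn-in) on the scenario sizes above — enough for the
signs of the relative scores, which is what those experiments assert; the
parameter-recovery run uses the full 1500/500 schedule.  Tolerances:
simplex sums to 1 at 1e-12, generator row sums at 1e-10, detailed balance
at 1e-12, oracle equivalence of pruning vs. brute-force enumeration at
1e-12 in log-likelihood, F81 closed form at 1e-10.  Monte-Carlo checks use
3 standard errors with batch-means SEs for correlated chains.  Degenerate
inputs: zero-length branches give exact identity transition matrices; an
all-gap column scores ln 1 = 0 under every model; a site with zero
likelihood under every component or every posterior draw raises an error
naming the site rather than silently propagating -inf.

## Known limitations

Fixed topology (above); no convergence diagnostics beyond the trace file
(apply standard tools externally); the DP sampler's per-site auxiliary
draws make DP chains markedly slower than finite-mixture chains at equal
data size; finite mixtures are label-switching-symmetric, so per-component
posterior summaries are only meaningful after relabeling (the package
reports allocation-invariant quantities); sensitivity to the stand-in
priors is untested territory.
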