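# Methods

This note documents the models implemented in `latdiv`, the defaults
and their rationale, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter when reproducing or
extending the analysis.

## The question and the analysis design

A latitudinal diversity gradient can arise because net diversification
(speciation − extinction) is systematically faster at low latitudes, or
because cold-climate habitats are geologically young and lineages
rarely adapt to them, so extratropical assemblages have had less time
to accumulate species. The two explanations leave different signatures
on a dated phylogeny with per-species latitudinal ranges:

1. conserved latitudinal affinity with young, phylogenetically
   clustered extratropical clades (time/conservatism), versus
2. a negative correlation between net diversification rate and
   absolute latitude (rate).

`latdiv` quantifies both signatures: assemblage phylogenetic diversity
against richness-matched nulls, trait-evolution models of binary
latitudinal affinity with ancestral-state reconstruction, and direct
rate–latitude association tests.

## Latitudinal affinity as a binary character

A species is **extratropical** when the midpoint of its latitudinal
range lies poleward of the tropic boundary, 23.43655°; midpoints
exactly at the boundary are coded extratropical (a documented
tie-break; the constant is exposed as
`traitmodels.TROPIC_BOUNDARY`). Binary coding is preferred over a
continuous midpoint because most species ranges fall entirely inside or
outside the tropics, and continuous reconstructions drift toward
intermediate (i.e., tropical) values in deep time by averaging alone.

### Mk2 and epoch models

The trait evolves by a two-state continuous-time Markov chain with
rates q01 (tropical→extratropical) and q10 (reverse), per lineage per
my. Likelihoods use Felsenstein pruning with the closed-form 2×2
transition probabilities; per-node rescaling guards against underflow.
Three candidate models are compared by AIC = 2k − 2 lnL:

| model | constraint | k |
|---|---|---|
| symmetric | q01 = q10 | 1 |
| asymmetric | free rates | 2 |
| two-epoch symmetric | symmetric rate q_old above age τ, q_young below | 3 |

The asymmetric two-epoch model is not a candidate: its likelihood
surface is too poorly behaved to optimize reliably, so it is excluded
by design. For the epoch model, branches crossing τ are split and the
branch matrix is the chronological product
`P_old(a_parent − τ) · P_young(τ − a_child)`; the boundary instant
itself belongs to the young epoch (a measure-zero convention). The
boundary is profiled over τ = 1…120 mya at 1-my steps (clipped below
the root age); at each τ both rates are refit, and the profile reports
the log-likelihood gain over the homogeneous symmetric fit. Because the
homogeneous optimum is always included among the starting points, the
gain is non-negative by construction.

**Root prior.** Flat (½, ½) by default, with the stationary
distribution available as an option for sensitivity checks. For the
symmetric models the two coincide.

**Optimization.** Rates are optimized on the log scale with L-BFGS-B,
bounds 1e-9…1e3 per my, multistart over 1e-4…1 (five log-spaced
starts; the asymmetric fit adds two off-diagonal starts), relative
tolerance 1e-10. Mk2 surfaces are ridged when transitions are sparse;
the multistart plus the warm-started sweep (full multistart refreshed
every 20 grid points) was verified against an independent
matrix-exponential oracle. Data with zero likelihood (e.g. both rates 0
with mixed tip states) report lnL = −inf rather than raising.

### Marginal ancestral states and stochastic mapping

Marginal node probabilities combine the pruning down-pass with an
up-pass carrying the likelihood of everything outside each node's
subtree; tip rows reproduce the observed states exactly. Stochastic
character maps are drawn by backward-filtering/forward-sampling of node
states followed by endpoint-conditioned path sampling on each branch
(rejection sampling, switching to uniformization when the expected
event count on a branch exceeds 10). Node-state frequencies across maps
converge on the marginal probabilities — the package's internal
crosscheck, enforced in the acceptance suite at 10,000 maps within
three binomial standard errors.

### State-specific lineages through time

Node marginals are interpolated **linearly in time** along each branch;
terminal branches use the observed tip state as their young endpoint.
This matches the endpoint-and-distance interpolation used for mapping
traits on trees; exact conditional interpolation under the Markov model
is deliberately out of scope. On a 1-my grid from the present to the
root age (rounded up), a lineage counts as high-confidence tropical
when 1 − p > 0.90 and high-confidence extratropical when p > 0.90 —
strict inequalities, so a probability exactly at the threshold counts
in neither class. Expected counts (Σp, Σ(1−p)) always sum to the plain
LTT.

## Phylogenetic diversity

MPD is the mean patristic distance over all unordered species pairs.
Latitudinal bands are half-open `[lo, lo+width)` from −90° with the
poleward-last band closed (a partition without double counting; the
open/closed convention for species spanning band edges is a documented
choice). A species joins every band its [min, max] latitude interval
intersects. Null distributions resample richness-matched tip sets
uniformly from the whole tree (100 replicates by default); observed and
null values are centered on the null mean, so clustered assemblages
give negative centered MPD. Species names are matched exactly after
whitespace trimming; unmatched names are logged and excluded, mirroring
pruning to valid species.

MPD is insensitive to within-clade topology randomization from
grafting: for species in two different terminal clades the patristic
path runs through fixed backbone nodes, so cross-clade distances are
identical across grafting seeds (enforced as an invariant).

## Clade grafting

Terminal clades (species lists) replace placeholder tips on the
backbone at their stems. Within a clade, topology follows the
uniform-join (Yule/labeled-histories) distribution; the crown age is
drawn uniform on (0, stem age) and the remaining internal-node ages
i.i.d. uniform on (0, crown age), ranked so successive joins are
strictly older. This scheme is a documented substitute for any
particular empirical randomization: it guarantees valid ultrametric
subtrees, and the downstream assemblage statistics depend only on the
backbone (previous section). Backbone node ages are untouched by
construction.

## Diversification rates and latitude

Per-tip rates can be supplied directly (e.g. from a Bayesian
rate-shift analysis); otherwise clade rates come from the stem-age
method-of-moments estimator `r = ln(n(1−ε)+ε)/t` with relative
extinction ε ∈ {0, 0.5, 0.9} as a sensitivity axis. Net diversification
is the unit of analysis throughout; speciation/extinction decomposition
is out of scope.

**Clade-wise PGLS.** ln(rate) is regressed on mean |midpoint latitude|
across clades with a Brownian-motion error covariance (shared
root-to-MRCA path lengths on the clade-level tree). When rate
uncertainties are available, weights w = 1/SD², normalized to mean 1,
enter as a diagonal inflation `mean(diag C)/w` — inverse-variance
weighting is the canonical reading of "preferentially weight clades
with less uncertainty". Without weights the covariance is the plain
Brownian matrix, under which the t-test on the slope is exactly
calibrated (verified: type-I error 0.03–0.07 at α = 0.05 over 500
Brownian simulations).

**STRAPP-style permutation.** The observed Spearman (optionally
Pearson) correlation between tip rates and tip |latitude| is compared
against a null built by permuting regime-level rate values across the
monophyletic rate regimes; tips inherit their regime's permuted value,
preserving the configuration of rate shifts while breaking the
rate–trait pairing. p = (1 + #{|null| ≥ |obs|})/(1 + n_perm). A single
regime has no exchangeable units: the test returns p = 1 with a warning
flag. Within-regime rate noise mildly perturbs exchangeability; at the
simulated noise level (lognormal, log-sd 0.2) the realized type-I error
stays in the 0.02–0.08 band.

**Tropical thinning.** Removing a random fraction f of tropical species
and recomputing the richness-based clade rates biases the latitude
slope upward (tropical clades lose n, hence apparent rate), which is
the direction that can manufacture a spurious *positive*
rate–latitude trend — useful for judging whether tropical undersampling
could mask or mimic a real signal.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analysis
assumes: complete constant-rate birth–death trees conditioned on
survival (resimulation on extinction; tip-count conditioning cuts the
tree uniformly within the waiting interval after the target count is
reached), exact Gillespie trait histories (optionally with an epoch
rate shift), ranges whose midpoints respect the affinity coding
(half-widths uniform on 0.5–15°, so most ranges sit wholly inside or
outside the tropics), clade-partition rate regimes with
`rate = regime rate × exp(β·|lat|/90) × lognormal noise`, and
incidence by latitude-interval overlap.

Not emulated: spatially explicit range evolution, diversity-dependent
diversification, fossilized-birth-death sampling, longitude structure,
and real-world sampling artifacts (synonymy, dubious records,
undersampling). Passing calibration tests on these generators therefore
demonstrates the correctness and statistical calibration of the
machinery under its own assumptions, not robustness to every feature of
empirical data.

Default study conditions (chosen once, before any calibration was run):
trees of a few hundred tips rescaled to a 140-my root (the scale of
comprehensively sampled backbone phylogenies of old insect clades),
homogeneous trait rate q = 0.01/my, tropical root state, and, for
epoch scenarios, τ = 34 mya — the Eocene–Oligocene cooling that
motivates the conservatism prediction — with q_old = 0.001 and
q_young = 0.01/my. The 10× magnitude was selected by an a priori power
scan as the regime where the breakpoint is most identifiable: slower
rates leave too few transitions to date the shift, faster rates
saturate tip states.

### A known limit: localizing the epoch boundary

The profile argmax localizes τ from latent transition times that are
only resolved to the branch they occur on. On a 512-tip, 140-my tree
the expected branch length crossing 34 mya is roughly 1/λ ≈ 25 my, so
even at a 10× rate shift the argmax lands within ±5 my of the truth in
only ~60% of replicates (within ±10 my in ~85%). This is a property of
the estimator under these conditions, not an optimization artifact:
likelihoods match an independent matrix-exponential oracle to 1e-14 and
failing profiles are smooth. Consistently, mean fitted breakpoints on
real data can sit well away from an a priori boundary even when a
recent acceleration is genuine. A related identifiability limit:
a *late acceleration* of symmetric change is largely mimicked by
asymmetric homogeneous rates (AIC often prefers the k=2 model on such
data), whereas a deceleration (fast old epoch, slow young epoch) is
attributed to the epoch model essentially always.

## Determinism and problem sizes

Every stochastic routine takes a seed; the pipeline derives per-stage,
per-tree seeds from one global seed via
`SeedSequence([global_seed, tree_index, stage_index])`, so identical
configurations yield byte-identical outputs. The acceptance script
scales replicate counts to desk size: 100 oracle trees, 10,000
stochastic maps, 10 breakpoint and 10 homogeneous sweep replicates at
512 tips, 50 rate-recovery fits, 1000 random assemblages (100 nulls
each), 200 STRAPP and 500 PGLS null simulations, 60 full-test runs, and
20 randomized grafting replicates; the test suite uses 20 replicates
for the breakpoint experiment. Ultrametricity tolerance is 1e-6 my
(grafted trees accumulate floating-point drift); trees are written with
12 significant digits so read/write round-trips preserve branch lengths
to better than 1e-9 relative.
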