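# Methods

`morphclock` implements Bayesian tip-dating of morphological character
matrices: a discrete-character substitution model with ascertainment
correction, relaxed morphological clocks, fossilized birth-death (FBD) tree
priors with optional sampled ancestors and piecewise-constant (skyline)
rates, Metropolis-Hastings MCMC, stepping-stone model selection, and the
downstream summaries and regressions used to compare model combinations.
This note records the model definitions, the numerical conventions, the
design decisions that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Character evolution

Characters are unordered with `k` observed states. The Mk model gives every
state the same exchange rate; with stationary frequencies `pi` the
transition probabilities take the F81-style form
`P_ij(v) = e^{-b v} d_ij + (1 - e^{-b v}) pi_j` with
`b = 1/(1 - sum pi^2)`, which normalizes branch lengths to expected
substitutions per character. Because compiled matrices contain variable
characters only, each character's likelihood is conditioned on variability
(Mkv): `L / (1 - sum_s L_const(s))`, with one correction term per
state-count class (characters are exchangeable within a class under Mk) and
the constant pseudo-patterns evaluated under exactly the same rate and
frequency mixture as the data. A character scored as missing in every taxon
is accepted with a warning and contributes only the correction term.
Inapplicable (`-`) scores are treated as missing, and ambiguity sets
contribute partial likelihood 1 for each included state.

Among-character rate variation uses equal-weight discrete categories whose
rates are category *means* (not medians) of a mean-1 gamma (shape `a`) or
mean-1 lognormal (log-sd `a`) density; four categories by default. Category
means keep the mixture mean exactly 1.

Asymmetric state frequencies follow a quantile-midpoint discretization of
the symmetric Dirichlet: for binary characters, midpoints of
`Beta(a_dir, a_dir)`; for `k > 2`, a focal-state construction using
`Beta(a_dir, (k-1) a_dir)` quantile midpoints rotated over all focal states
so the category-weighted mean frequency is exactly uniform. The
concentration `a_dir` is sampled uniformly on [0.05, 20] when the
asymmetric model is active. At `a_dir = 20` the mixture is numerically
indistinguishable from the symmetric model (tested to within 0.1 log units
on fixtures). The number of rate and frequency categories is a package
default (4), not an empirical datum.

The likelihood engine propagates all rate categories in one broadcast
pruning pass with the constant pseudo-patterns appended as extra columns,
and per-column rescaling against underflow. It is tested against exhaustive
enumeration over interior-node states on small trees for every
ACRV/frequency combination.

## Clocks

All clocks convert branch durations `t` (Myr) into expected substitutions
around a base rate `c` (substitutions/character/Myr):

* **strict** - `v = c t`.
* **IGR** (uncorrelated) - each `v` is a free parameter with prior
  `Gamma(mean = c t, variance = c t nu)`; `nu -> 0` collapses to strict.
* **TK02** (autocorrelated) - node rates evolve as geometric Brownian
  motion: the child rate is lognormal with linear-scale mean equal to the
  parent rate and log-variance `nu t`; the root rate equals `c`; the branch
  rate is the arithmetic mean of its endpoint rates.

Zero-duration branches (sampled-ancestor attachments) force `v = 0` (IGR)
or child rate = parent rate (TK02) with no density contribution.

The informative base-rate prior uses the tree-height construction: median
non-clock tree height in substitutions divided by the median root-prior
age. The lognormal variant takes log-mean `ln(ratio)` and log-sd
`exp(ratio)`; the latter is an unusual construction (a "broad" sd obtained
by exponentiating the ratio) but is implemented verbatim as the source
analyses specify it. The gamma variant is parameterized by (mean, sd),
default sd 0.5, converted internally to shape/rate. Clock variance
parameters carry an Exponential(rate 10) hyperprior by default
(configurable). Partitioned analyses unlink the full clock per partition
(own `c`, `nu`, branch quantities) on a shared time tree; a partition
smaller than `2n - 1` characters (one expected change per branch) triggers
a warning.

## Tree priors

The FBD process is parameterized by net diversification `d = lambda - mu`,
turnover `r = mu/lambda`, fossil-sampling proportion `s = psi/(mu + psi)`
and extant-sampling probability `rho`. Densities are assembled from the
standard auxiliary functions `c1`, `c2`, `p0(t)`, `q(t)`; each observed
lineage spanning `(s_old, e)` contributes `q(s_old)/q(e)`, each non-root
bifurcation `lambda`, each fossil sampling event `psi` (tips additionally
`p0(y)`), each extant tip `rho`. The density is conditioned on the root age
(the root's own split is not scored) and on both root lineages leaving at
least one sampled descendant. The pure-birth and birth-death limits
(`psi -> 0`, `rho = 1`) are verified against independently coded closed
forms.

Skyline (SFBD) variants make the parameters piecewise constant between
shift times, with `p0` and `q` chained continuously across slice
boundaries; an event exactly at a boundary belongs to the older slice. Two
masks are supported: all three parameters free per slice (`sdr`, `3l` free
parameters for `l` slices) or fossil sampling only (`s`, `l + 2`).

Sampling strategies: `fossiltip` (no sampled ancestors), `random` (sampled
ancestors allowed), `diversity` (diversified extant sampling with cutoff
`x_cut`, ancestors allowed) and `nosa_diversity` (diversity with the
ancestor moves disabled). Under diversified sampling all speciation events
and fossils in the sampled tree must predate `x_cut`; extant-tip edges are
`q`-integrated down to `x_cut` only, and each surviving lineage contributes
the probability of non-extinction from `x_cut` to the present. This is this
package's documented rendering of the youngest-node construction; `rho`
defaults to 1 (a single living representative). Default parameter priors:
Exponential(10) on `d`, Uniform(0,1) on `r` and `s`; the low-extinction
("LExct") variant replaces the turnover prior with Beta(1, 9).

Root calibrations: offset-exponential (offset 247.2 Ma, mean 287 Ma by
default) or truncated normal with hard bounds ("NoR"-style; the truncation
parameters are configuration since only the bounds are externally fixed,
e.g. 298.9 Ma). Fossil tip ages carry uniform priors over their
stratigraphic ranges and are sampled as parameters.

## MCMC

Single-chain Metropolis-Hastings per run (no Metropolis coupling), at least
two independent runs. Proposals: node/root/tip-age slides, a tree-scale
move, narrow exchange and a fixed-dimension SPR whose pruned attachment
node carries its clock variables (with count- and interval-based Hastings
terms), multiplicative scalers for rates/variances/shapes, reflected
sliders for bounded FBD parameters, a joint base-rate x branch-values
rescaling, a compensatory rate-age move (ages up, rates down; the
likelihood is invariant under all clock models), a prior-redraw of branch
quantities (an exact Gibbs update when sampling the prior), and an IGR
variance-dispersion ridge move. Per-partition likelihoods are cached and
recomputed only for partitions a proposal can affect; notably, under the
IGR clock age-only moves never touch the likelihood. The caching is tested
to give bit-identical chains against full recomputation.

Sampled-ancestor add/delete moves form a reversible-jump pair on the
zero-duration-tip representation: deleting a branch pins the attachment age
to the fossil age and drops the edge's clock variables (their prior
densities and the uniform attachment-age density enter the acceptance
ratio); adding a branch draws the attachment age uniformly and the clock
variables from their priors. Zeroing the pair's weights is exactly the
"no sampled ancestors" device.

Defaults: burn-in fraction 0.25, sampling interval from the run
configuration, ASDSF split-inclusion threshold 0.10 with the population
standard deviation across runs. PSRF is the classic between/within-run
variance ratio; ESS uses the initial-positive-sequence autocorrelation
estimate. Constant traces report ESS = n with a degenerate PSRF of 1.

**What "sampling from the prior" can and cannot check.** With the
likelihood disabled the chain targets the *joint* prior. Marginals of the
base clock rate, clock variance and ACRV shape are provably identical to
their marginal priors (their conditional factors integrate to one), and the
engine reproduces them to KS < 0.05. The marginals of root age and of the
FBD parameters, however, are genuinely reweighted by the tree prior once
the tip and fossil census is fixed - the net diversification marginal, for
example, deviates strongly from its Exponential prior at high effective
sample size. This is a property of the model, not a sampler defect; the
root-age marginal is therefore validated by cross-run agreement rather
than against the calibration density.

## Model selection

Stepping-stone marginal likelihoods use power posteriors
`prior x likelihood^beta` at `beta` values from quantiles of Beta(0.4, 1)
(50 steps at study scale; fewer at desk scale), run hot-to-cold with each
step seeding the next, 25% per-step burn-in, and a log-sum-exp-stabilized
estimator using the samples at the lower `beta` of each interval.
Comparisons are reported as `2 ln BF` with the conventional interpretation
bands. The estimator is validated against the conjugate binomial marginal
likelihood and for shift invariance.

## Summaries and regressions

Majority-rule consensus (threshold 0.5, compatible lower-frequency clades
not added) and greedy maximum-compatibility trees, with per-clade posterior
probability, median age, 95% highest-posterior-density interval (shortest
sorted window) and median relative branch rate (branch rate / base rate,
per partition; > 1 accelerating). Node ages are summarized as medians
because the age posteriors are broad and skewed; a child median exceeding
its parent's is clipped to the parent with the repair count recorded.
Equal-frequency clades in the MCT are ordered lexicographically by taxon
set. Ages for a clade are summarized over the samples containing that
clade.

Downstream statistics are ordinary least squares on per-clade point
estimates (as in the source figures): partition rate vs partition rate
(integration), HPD range vs median age (node-depth precision bias), with
slope, intercept, R^2, p and n reported and no thresholded verdicts.

## Parsimony (validation grade)

Fitch counting with uncertainty sets and polytomy-aware folding, invariant
to root placement; random-addition-sequence starts followed by full
tree-bisection-reconnection hill climbing over adjacency-map topologies;
implied weighting maximizes the concave fit `sum K/(K + h_i)` with
homoplasy `h_i` = observed minus minimum conceivable steps (observed states
minus one), default concavity `K = 12`. Zero-length collapsing beyond split
canonicalization and TNT-specific search strategies are out of scope.

## Synthetic data

The generator grows complete birth-death trees forward from the root age
with piecewise-constant rates, Poisson fossilization along lineages,
random-`rho` or diversified extant sampling (one representative per lineage
crossing `x_cut`; no fossils younger than the cutoff), and prunes unsampled
lineages; fossils with sampled descendants become zero-duration sampled
ancestors, or are attached as short-branch tips when ancestor-free trees
are requested. Fossil ages are wrapped in uniform reporting ranges of 2-10
Myr. Characters evolve under Mk with continuous ACRV rates and the
configured true clock; constant characters are rejected and resimulated,
and the fraction of direct autapomorphies (characters variable through a
single taxon) is steered toward a target by rejection only - states are
never edited.

The default study-shaped conditions emulate a mostly extinct clade sampled
from the Triassic onward: root age 270 Ma, a fossil-sampling drop at 145 Ma
(`s` 0.45 -> 0.15), diversified sampling with `x_cut` = 66 Ma, ~25-45 taxa
with one surviving lineage, three anatomical partitions of 47/44/38
characters and a 17% autapomorphy target. Base rates default to 0.005
substitutions/character/Myr, i.e. roughly two to four expected changes per
character over the whole tree - the regime implied by the compiled matrix's
parsimony-step (about two steps per character) and autapomorphy statistics;
note this is lower than the posterior base-rate scale of the source
analyses, because the generator calibrates to matrix-level change counts
rather than to posterior rate estimates. A `desk` scale (root 150 Ma,
10-30 taxa, 60 characters) keeps the same structure for fast closed-loop
testing.

What passing tests on these data do *not* show: the generator draws
characters independently (no correlation structure), codes no inapplicable
hierarchies, uses clean stratigraphic ranges, and its trees are far smaller
than real compiled matrices; recovery results at desk scale demonstrate
correctness of the machinery, not field performance on real data.

## Problem sizes and numerical choices

Closed-loop validation uses desk-scale campaigns chosen as the package's
own test design: credible-interval coverage over 20 replicates of 6-14 taxa
by 35 characters (50k generations each), skyline fossil-sampling-drop
recovery over 10 replicates, planted-integration recovery over 10
replicates of three 80-character partitions with the true topology fixed (a
constrained-run design), and a 5-replicate diversity vs no-sampled-ancestor
contrast at 60k generations. Tolerances: mixture means to 1e-9; skyline
degeneracy to 1e-9 log units; oracle equality to 1e-9; strict-clock limits
to 1e-6. Gamma branch draws are floored at 1e-12 to avoid underflow to
exactly zero at very small shapes. Ties and degenerate inputs follow the
rules stated above (older slice at boundaries, clipped child medians,
lexicographic MCT tie-break).

## Known limitations

Single-threaded, full-posterior re-evaluation per proposal (desk-scale
data); no Metropolis coupling, checkpointing or adaptive tuning beyond
fixed proposal scales; diversified sampling supports one extant
representative per surviving lineage; no origin-conditioned FBD variant; no
ordered characters or parsimony-informative-only ascertainment; regressions
are not phylogenetically corrected (deliberately, matching the figures they
reproduce).
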