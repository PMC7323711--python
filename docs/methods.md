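# Methods

## The problem

Bayesian tip dating places fossil taxa as dated terminals in a
phylogeny. When a fossil's age is uncertain it is usually given a uniform
tip-age prior and its own MCMC move, which silently *decouples* the ages
of fossils that came from the same locality: two specimens from one
bedding plane can end up millions of years apart within a single
posterior sample. A second, related problem is that a series of
fossil-bearing layers often has a known vertical (stratigraphic) order
even though the absolute age bounds of the layers overlap, and
conventional independent tip priors cannot express that.

`stratatips` addresses both with two MCMC proposals on *fossil sites* —
sets of tips sharing one age parameter with uniform bounds:

* **Linked site-age move.** Draw one age a' ~ Uniform(min, max) for the
  site and apply it to every member tip simultaneously. The draw spans
  the full bounds, so the move is symmetric (log-Hastings 0). If any
  member tip would become as old as its parent node the proposal is
  hard-rejected (counted as a rejection without evaluating the
  posterior; equivalent to giving the proposed state prior probability
  zero).
* **Ordered site-age move.** As above, plus a hard rejection whenever
  the draw would make a site strictly older than a site *below* it, or
  strictly younger than a site *above* it, at the neighbouring sites'
  current ages. The acceptable window therefore tracks the rest of the
  sequence as the chain runs, and the induced ("effective") prior on
  each site's age is non-uniform even though every declared prior is
  uniform. Exact ties are allowed; under the continuous draw they have
  measure zero, and rejecting them would spuriously freeze sites with
  identical bounds.

Taxa not assigned to any site are treated as single-taxon sites, which
makes the conventional independent-tip-ages analysis the special case
where every site has one member (`independent_sites` performs exactly
that reduction).

## Model stack

The surrounding model is deliberately minimal but complete enough to
exercise the operators against data.

**Likelihood.** Lewis's Mk model for discrete morphology: a k-state
symmetric CTMC with stationary frequencies 1/k and unit expected rate,
so P_stay(t) = 1/k + (k-1)/k · exp(-k t/(k-1)). Each character uses its
own observed state count k_c (floored at 2). Among-character rate
variation is discrete-gamma with four equal-weight categories; category
rates are the *means* of the quantile bins of Gamma(alpha, alpha)
(mean-of-bin rather than median-of-bin, so the mixture mean is exactly 1
and tests can be deterministic). The Mkv variable-characters correction
divides each character's likelihood by 1 - P(constant pattern), computed
per distinct k_c with the same branch lengths and gamma mixture.
Missing cells contribute partial likelihood 1 for every state. Branch
lengths in substitutions/character are duration (Ma) x clock rate x a
per-branch rate multiplier.

**Clock.** Uncorrelated lognormal relaxed clock: multipliers are iid
lognormal with mean 1 in real space and sdlog equal to the clock
standard deviation (continuous multipliers, not discretised rate
categories — the site operators do not interact with this choice).

**Tree prior.** Serially-sampled birth-death process (birth λ, death μ,
Poisson fossil sampling ψ with removal on sampling), conditioned on the
origin time, all tips ψ-samples, no extant (ρ) sampling and no sampled
ancestors — tips are always terminal and parent ages are strictly older
than child ages. Writing p0(t) for the probability that a lineage at
age t leaves no sampled descendants (the Riccati equation
p0' = -(λ+μ+ψ)p0 + μ + λp0², p0(0)=1), each branch contributes the
propagator q(parent)/q(child) with d log q/dt = -(λ+μ+ψ) + 2λ p0(t),
each bifurcation λ, each tip ψ. The density telescopes to

    f(T | x0) = λ^(m-1) ψ^m · q(x0) · Π_internal q(x_i) / Π_tips q(y_j)

with the closed-form q built from c1 = sqrt((λ-μ-ψ)² + 4λψ) and
c2 = -(λ-μ-ψ)/c1. The test suite checks this closed form against a
numerical integration of the same ODEs that shares no code with it.
The origin age gets an improper uniform prior above the root; the
density's decline in x0 keeps the posterior proper.

**Hyperpriors.** Clock rate: exponential(mean 0.003) offset by 0.0016
(support [0.0016, ∞)); clock sd: exponential(1); gamma shape:
Uniform(0, 10]; birth rate: lognormal with mean 0.14 *in real space* and
sdlog 0.9 (μ_log = ln 0.14 − 0.9²/2); death rate: exponential(0.1);
sampling rate: exponential(0.03). Out-of-support values are encoded as
log-prior −∞, never as exceptions.

## Sampler

Single-threaded Metropolis–Hastings; one generation is one proposal;
acceptance probability min(1, exp(Δ log posterior + log Hastings));
hard rejections count as rejections. Everything is reproducible from the
config seed; multiple runs are simply distinct seeds.

Standard moves: uniform slide of an internal node between its oldest
child and parent (symmetric); scale of the root's offset above its
oldest child, and of the origin's offset above the root (a raw
multiplicative scale at ~415 Ma magnitudes proposes ~100 Ma jumps and
never mixes; the offset scale is a univariate scale move with the usual
−log f Hastings term); narrow exchange (swap a node with its uncle,
hard-rejected if ages forbid it); multiplicative scale moves with
f ~ Uniform(1/β, β) on the positive unbounded scalars; a reflected
uniform random walk for the gamma shape (a scale move mixes badly near 0
on a bounded uniform support); and a multiplicative walk on one branch
rate multiplier. Operator weights default to one unit per site taxon for
the site moves, with fixed documented weights for the rest; every weight
can be overridden (weight 0 disables a move, which is how fixed-tree or
prior-isolation analyses are configured).

The likelihood kernel keeps per-node conditional likelihood arrays and
recomputes only the nodes a proposal dirties (the changed nodes and
their root-ward ancestors); a rejected proposal restores the cache by
recomputing the same node set at the restored state, which is bitwise
deterministic. Constant patterns for the Mkv correction ride along as
pseudo-characters in the same buffers. The pruning and tree-prior
kernels are numba-compiled.

Initialisation: site ages start at bound midpoints, clamped by one
topological pass so no ordered pair starts inverted; when no starting
tree is supplied one is built coalescent-style above the oldest tip by
random joins with exponential increments. A zero-probability initial
state raises an error naming the offending component. Burn-in is applied
at summary time (default 10%), never at logging time, so raw traces are
complete.

## Summaries

HPD intervals are Chen–Shao shortest-window intervals (the smallest
window over sorted samples containing ⌈level·n⌉ of them). Inter-site
comparisons are per-sample paired fractions with ties counted 1/2. The
per-sample age range of a taxon set is the mean over post-burn-in
samples of (max − min) of their ages — identically 0 in a linked run.
ESS uses the initial-positive-sequence (Geyer) truncation of the
autocorrelation sum. Consensus trees are rooted 50% majority-rule
consensi computed from clade (not unrooted split) frequencies, since the
trees are dated and rooted; clades are admitted strictly above the
threshold, labelled with their frequencies, and node ages are not
annotated (topology and support only).

## Synthetic data and what it does (not) show

The generator simulates the birth-death-sampling process forward from
the origin (same model family as the tree prior), evolves Mk characters
with the same discrete-gamma mixture the likelihood uses (per-character
category drawn uniformly), resimulates constant characters when Mkv data
are wanted, and masks cells uniformly at random for missing data.

The default fixture emulates the empirical regime that motivates the
package: ~20 fossil taxa (simulated with λ=0.45, μ=0.15, ψ=0.2 per Ma
from an origin at 428 Ma, truncated at 406 Ma), two disjoint four-taxon
sites whose true shared ages are drawn inside the Lochkovian window
(419.2–410.8 Ma) and whose declared bounds are that whole window, other
taxa dated individually with ±0.5–1.5 Ma windows, and ~100
binary/ternary characters evolved at 0.02 substitutions/character/Ma
with mild rate relaxation (sdlog 0.1) and 10% missing data. The
acceptance experiments use a scaled-down variant (12-tip target, 50–60
characters, fixed true topology, 10⁶-generation chains) chosen so the
whole battery runs on one desk CPU in minutes; the published-scale
analyses this mimics used 2×10⁸ generations.

What passing these tests shows: the operators target exactly the
intended joint prior (rejection-sampling oracle), the likelihood and
tree prior are correct (enumeration and ODE oracles, grid-oracle
posterior), and linking truly-shared ages sharpens site-age estimates
relative to independent dating on data generated under the model's own
assumptions. What it does not show: robustness to model violation —
real morphological matrices have correlated characters, non-random
missingness, ordered or polymorphic codings (rejected at read time), and
fossil sites whose specimens do *not* share one age; none of these are
simulated.

## Numerical choices and limitations

* Site proposals are full-bounds uniform redraws, not windowed walks:
  symmetric, and they mix in a handful of sweeps at these scales.
* Ordering rejects only strict inversions (ties allowed, see above).
* Tip-age proposals that would overtake the parent are hard-rejected
  rather than dragging the parent along.
* Gamma categories: mean-of-bin; renormalised so the mixture mean is
  exactly 1 (guards against ppf round-off at extreme shapes).
* The Mkv denominator uses log1p(−P_const) and returns −∞ if P_const
  reaches 1 numerically.
* Trace files carry 12 significant digits; write-then-read is the
  identity at that precision. Tree logs store durations as branch
  lengths plus the root age per tree, so absolute ages round-trip.
* Interleaved NEXUS, polymorphic codings `{01}` and ordered characters
  are out of scope and rejected with clear errors; characters observed
  in fewer than two states are treated as binary with a warning.
* No sampled ancestors, no multifurcating input trees, no multi-tree
  linked dating, no adaptive operator tuning, and no convergence
  diagnostics beyond ESS.
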