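# Methods

## Model class and time convention

All models are continuous-time binary branching processes with
per-lineage birth (speciation) rate λ and death (extinction) rate μ
shared across contemporaneous lineages, plus a present-day sampling
fraction ρ ∈ (0, 1]: the Yule process (μ = 0), the constant-rate
birth–death process (BDP), and the generalized BDP (GBDP) whose rates
are deterministic functions of time. Rate variation across lineages
(state-dependent models) is out of scope.

Every public API measures time as **age**: present = 0, increasing into
the past. The stem age t₀ is where the process starts with one lineage;
node ages t₁ > t₂ > … > t_{n−1} are the data. Time is unitless (the
examples use Myr). Piecewise-constant rates are right-continuous in age
at a change point c: the young-side rate applies at age exactly c, the
old-side rate just above it. Tied node ages — a measure-zero event under
every model here — are kept in input order by stable sorting, and an age
exactly equal to an epoch boundary T joins the young epoch, consistent
with the change-point convention.

## Transition probabilities

With R(t) = ∫₀ᵗ(λ−μ)ds, G(t) = ∫₀ᵗ λe^R ds and D(t) = 1/ρ + G(t), the
solution of the extinction Riccati equation with initial conditions
p₀(0) = 1 − ρ, p₁(0) = ρ is

    1 − p₀(t) = e^{R(t)}/D(t),        p₁(t) = e^{R(t)}/(ρ D(t)²).

The p₁ form follows from the observation that λ(1 − p₀) is the
logarithmic derivative of D, which collapses the nested integral
∫λp₀ that otherwise requires double quadrature. Consequences used
throughout:

* **Exactness for piecewise-constant rates.** R, log G and the death
  analogue log K = log ∫μe^R are accumulated per piece in log space
  (`logaddexp` over closed-form piece terms), so likelihoods of
  piecewise models involve no quadrature at all and are stable for
  n ≈ 10⁴–10⁵ tips.
* **Cumulative pulled rate for free.** Λ_p(t) = ∫₀ᵗ λ(1−p₀) =
  log(ρD(t)).
* **An internal cross-check.** The classical complete-sampling product
  form p₁ = (1−p₀)(1−η) is written in forward process time; reflected
  into the age parametrization its inner integral becomes
  H(t) = e^{−R(t)}K(t), and the identity 1 + G = e^R + K makes the two
  routes agree exactly. The package computes both (they share no
  integral) and the tests assert agreement to 1e−8.

Constant-rate closed forms are 0/0-degenerate at λ = μ; all entry points
switch to the analytic limits (ρ = 1: p₀ = λt/(1+λt), p₁ = 1/(1+λt)²)
when |λ−μ| < 1e−8·max(λ, μ, 1). Continuity across the switch is tested
at 1e−6. Supercritical long-time evaluation uses e^{−rt}-factored forms
so nothing overflows.

Tabulated (arbitrary-callable) rate models use one dense 8193-point
Simpson grid per model (rebuilt if queried beyond its range) with cubic
spline interpolants — accurate to ~1e−8 for smooth rates, and cached so
repeated likelihood evaluations cost one interpolation each.

Independent oracles: `*_ode` functions integrate the defining ODEs with
DOP853 at rtol 1e−12 and are used only in tests.

## Likelihoods and conditioning

The joint Yule density of ages and tip count given the stem age carries
the labelled-history factor (n−1)! from rank-ordering speciation events;
the same factor is included in the GBDP and GYP likelihoods so that
model nesting is exact (it is shared by congruent models and cancels
from all comparisons). Combinatorial factors go through `lgamma`; all
values are natural-log; impossible data return −∞ rather than raising,
because optimizers probe boundaries.

Conditioning is an explicit caller choice, because the schemes differ:

* **joint**: f(t, n | t₀);
* **given stem and n**: implemented by two independent routes —
  joint/Pr(n|t₀), and the order-statistics product of truncated
  exponential kernels — asserted equal to 1e−12;
* **given root and n**: the printed closed form registers the root age
  with a rate-density factor λe^{λt₁}; the *root-started* density
  (two lineages at t₁, factor p₁(t₁)², rate products from i = 2) is
  also provided, because that is the form invariant under λ↔μ;
* **survival** (GBDP default): the joint divided by 1 − p₀(t₀), the
  probability the stem leaves any sampled descendant. Congruent models
  share the survival-conditioned likelihood exactly; their raw joints
  differ by precisely this stem factor, which is why survival is the
  default for `gbdp_loglik`.
* **epoch counts** (two-epoch models): the likelihood conditions on
  (I, J), the per-epoch event counts; the `kernel` form drops the
  data-only log (I+J)! that the `full` form keeps — MLEs are invariant
  to the choice.

**Label switching.** The stem- and root-started conditioned constant-rate
BDP densities are invariant under swapping λ and μ (p₁ is itself
swap-symmetric; the λᵏ factors cancel against the descendant-count law),
so the two parameter sets are non-identifiable from conditioned data;
the unconditioned joint is not invariant. `label_switch_check`
quantifies the deviation (≤ 1e−10 in tests).

**Mass-extinction epoch model.** A lineage arising at age t > T leaves
one sampled descendant with probability obtained by averaging over its
descendant count m just before the event, exactly one of which survives
(probability mp(1−p)^{m−1}) and remains unbranched thereafter. The
geometric series sums to

    p₁*(t) = p·x·e^{−λ₁T} / (p + x(1−p))²,  x = e^{−λ₀(t−T)},

which is the stable factored equivalent of the textbook closed form
written with e^{λ₀t} factors (multiply numerator and denominator by
e^{−2λ₀t}); the series, evaluated at the elapsed old-epoch time t − T,
equals it term-for-term, and the truncated series (tail < 1e−14) is kept
as the test oracle. As p → 1 the epoch likelihood reduces continuously
to the plain two-epoch one.

## Congruence

`pulled_rate` returns λ_p(t) = λ(t)(1−p₀(t)) and Λ_p(t) = log(ρD(t))
exactly. Two verifications are exposed: the per-age identity
λ(t)p₁(t) = λ_p(t)e^{−Λ_p(t)} on a user grid (≤ 1e−8 by contract; in
practice machine precision), and the end-to-end equality of the GBDP and
pulled-GYP log-likelihoods on data (≤ 1e−6). Enumeration of further
congruent (λ, μ) pairs is provided only through the BDP↔variable-Yule
construction; general congruence-class search is out of scope.

## Simulators

*Order statistics.* Conditioned on (n, t₀), the n−1 ages are i.i.d.
draws from the kernel ∝ λ(x)p₁(x) on [0, t₀]: inverse-CDF in closed form
for the Yule case, inverse-CDF on a 2049-point normalized grid
otherwise. The grid kernel is validated against the analytic CDF and
against the forward simulator by KS tests.

*Forward events.* Exact stochastic simulation from one lineage at t₀ to
the present: per-segment exponential waiting times for (piecewise-)
constant rates (restarting at segment boundaries is exact by
memorylessness), thinning against a 1.05× grid bound for tabulated
rates; at the mass-extinction age each extant lineage survives
independently with probability p; ρ-sampling at the present. Total
extinction is a flagged result, not an error. One seeded generator per
simulation; the seed is recorded.

*Pruning.* The reconstructed tree keeps exactly the birth events with
sampled descendants on both sides; this is computed in O(total lineages)
on the lineage records (used for the large simulation studies) and also
materialized as a dendropy tree with unary vertices suppressed. Both
routes are asserted to agree. Reconstructed trees are ultrametric and
strictly binary; ultrametricity of imported newick is checked to
1e−6 × height to tolerate rounding in real timetrees.

*Random labelled histories.* Because all topologies with the same ranked
ages are equally likely under these models, a uniform labelled history
is built by attaching each successive speciation to a uniformly chosen
extant lineage; this inverts the LTT extraction exactly and serves as a
round-trip oracle.

## Inference

Closed-form two-epoch MLEs and Fisher information are evaluated at the
MLE; an empty epoch leaves its rate flagged locally non-identifiable and
the other rate is still estimated. The numerical MLE is L-BFGS-B on the
negative log-likelihood with 5 starts (the given initial point plus
log-uniform draws over the box, seeded), observed information by central
finite differences with steps eps^{1/3}·max(|θ|,1), and standard errors
from the inverse information when positive definite. The
mass-extinction fit defaults its box to two decades around the plain
two-epoch closed-form estimates. Profile intervals locate the
likelihood-ratio cutoff (default 1.92, the χ²₁ 95% level) by Brent root
finding, profiling the remaining parameters at each point, with
open-endpoint flags when a bound is not bracketed inside the box. T, t₀
and p are treated as known throughout; estimating them is out of scope.

## What the synthetic data do and do not show

The generators *are* the models: simulated data match the likelihoods'
assumptions exactly (known change point, exact ages, complete or
Bernoulli sampling, instantaneous extinction). Passing tests therefore
demonstrate internal correctness and the information-theoretic points
(congruence, label switching, the post-extinction information collapse),
not robustness to what real timetrees add: estimated and biased
divergence times, calibration uncertainty, gene-tree/species-tree
conflict, and non-contemporaneous (fossil) tips — all outside this
package's scope.

Problem sizes were chosen so the whole suite runs in well under a minute
of simulation time while keeping Monte-Carlo standard errors far below
the asserted tolerances: 1e5 replicates for tip-count laws, 2×10³ for
conditional KS comparisons, 200 replicates for coverage, five seeds for
the K-Pg-like study (each tree 10³–10⁵ tips).

## Known limitations

* The Wald interval for the old-epoch rate undercovers badly when the
  old epoch contains only a handful of events: conditioning a sparse
  epoch on I ≥ 5 selects extreme trajectories and the inverse-mean MLE
  is strongly right-skewed, so coverage sits near 75–83% rather than
  the nominal 95%. Profile intervals are the honest summary in that
  regime and are what the package reports for the simulation study.
* Incomplete sampling is the field's standard Bernoulli-at-present
  model; clade-biased or diversified sampling is not implemented.
* Tabulated rate models trade exactness for a fixed Simpson grid
  (~1e−8); pathologically rough rate functions can defeat both the grid
  and the thinning bound (the simulator raises if the bound is
  violated).
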