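# Methods

This note documents the statistical machinery in `raidnet`, the assumptions
behind the synthetic study generator, the numerical choices, and the known
limitations.

## Association indices and the closest-associate network

Associations come from group sightings under the gambit of the group: all
members of an observed group are assumed to be associating. For a pair
(A, B), `AI = N_AB / (N_A + N_B + N_AB)`, where `N_AB` counts sightings
containing both and `N_A`, `N_B` count sightings containing exactly one.
The index is symmetric and lies in [0, 1]; it is undefined for a pair with
no sightings at all and is 0 for pairs never co-sighted.

A *sighting is a set*: duplicate member rows are collapsed with a warning,
and single-member records are rejected at parse time (a group needs two or
more individuals); a config flag lets them count toward the lone male's
total only.

**Focal-male filter.** An individual enters the analysis only if (a) he has
at least 15 group sightings and (b) each of his top-2 positive-AI associates
("frequent associates") was himself sighted at least 15 times. Condition (b)
tests raw sighting counts, not retention: a male is excluded when his
strongest associations involve under-sampled males, because his own rank
ordering would then be unreliable. The filter is iterated until stable; with
the count-based condition this settles after one extra pass. The top-2
interpretation of "frequent associates" was chosen because only the two
closest associates enter the downstream models.

**Ranks and the network.** Associates are ranked 1..n−1 by descending AI;
ties are broken by larger N_AB, then lexicographic id, so every ordering is
deterministic. The directed closest-associate network draws an arc from each
focal male to his top-k (default 2) associates, requiring positive AI by
default, so out-degree can fall below k.

**Feature table.** Per focal male: own age and life-history age class
(10–14, 15–19, 20–30, 31–44, 45+ years — early/late dispersal, first musth,
ascent to, and attainment of peak reproduction), and for each associate rank
r the associate's raiding status `status_r` and relative age
`relage_r = age(associate) − age(focal)` (negative for younger associates),
the raider count among the top five, and `status_r × relage_r` interactions
for r = 1, 2.

## Logistic regression

Newton–Raphson on the binomial log-likelihood with step-halving (the step is
halved until the log-likelihood does not decrease, making it monotone across
iterations). Convergence: largest absolute score component < 1e-8, at most
25 iterations. The covariance is the inverse observed information; AIC is
2p − 2ℓ. Rank-deficient designs raise an error naming the collinear columns.

**Separation.** When any |coefficient| exceeds 15 during iteration while the
likelihood is still improving, the MLE is taken to be non-existent
(complete or quasi-complete separation); the fit keeps the last iterate,
sets `separated`, and the Wald table is marked unreliable. This arises
naturally in age-class models where the youngest class has zero raiders: the
class log-odds are −∞ and any finite printed coefficient is an artifact of
whatever stopping rule the software used. We deliberately flag rather than
emulate a specific truncation; the *relative* ordering of the class effects
is still informative and is what the tests assert (odds of raiding rising
monotonically across age classes). Firth-penalized regression would be the
principled estimator under separation but is out of scope.

## Randomization nulls

Wald tests are inappropriate for associate-derived predictors because the
associations of one male are not independent of his associates'. Two
Monte-Carlo schemes (default 1000 replicates, plain-proportion empirical
p-values) are provided:

* **Predictor shuffle** — permute the predictor rows jointly against the
  fixed response and refit. Exchangeable under the null; type-I error at
  α = 0.05 is calibrated (checked over 500 null simulations).
* **Associate pool** — for each focal male, replace the tested associate's
  attributes with those of a male drawn uniformly from his n−1 potential
  associates. Status and relative age are taken from the *same* sampled male
  (an `independent_draws` option decouples them). This mirrors the original
  design; note that because several focal males can share one real
  associate, the observed statistic has extra variance the pool null does
  not reproduce, so this scheme can be mildly anticonservative — a property
  of the design it reproduces, not a defect of the implementation.

Empirical p = #{|β_rep| ≥ |β_obs|}/n_reps. Replicates with separation or
failed convergence are excluded from the null (truncated coefficients would
distort the tail) and counted in the ensemble metadata; a warning is
attached if more than 10% of replicates are unusable. A smoothed
(r+1)/(n+1) estimator is available but off by default.

## Community structure

The directed top-2 network is symmetrized (arc in either direction → one
undirected edge) before clustering, because the modularity quotient used is
Newman's undirected form. Girvan–Newman removes the highest-edge-betweenness
edge repeatedly (ties broken lexicographically for determinism) and the
nested component partition maximizing Q is returned. On small graphs the
result is validated against exhaustive partition enumeration and against an
independent Girvan–Newman implementation.

The modularity null draws uniform simple graphs with the observed node and
edge counts (degree-nonpreserving, matching an edge-shuffle; a
degree-preserving double-edge-swap variant is available) and compares the
observed Q with the null maximum-Q distribution.

**Cluster composition tests** permute the attribute values across all
individuals, holding cluster sizes fixed, and report per cluster the
observed statistic (proportion of a binary trait, or mean), the null mean ±
SE (replicate SD / √n_reps), and a two-sided p-value with "at least as
extreme" operationalized as absolute deviation from the null mean. For a
binary trait this null is exactly hypergeometric, which provides the
independent oracle used in the tests. One caveat is documented rather than
resolved: for clusters whose observed proportion sits almost exactly at the
null mean, different tail conventions give p anywhere between ~0.9 and 1.0,
and no single convention reproduces every published near-null p-value; the
absolute-deviation convention is the package's fixed choice.

## Directed ERGM

`Pr(X = x) = κ⁻¹ exp(θ·z(x))` over simple directed graphs. Statistics
(λ = 2 damping, configurable ≥ 1; `g(d) = λ[1 − (1 − 1/λ)^d]`):

| statistic | form |
|---|---|
| arc | Σ x_ij |
| reciprocity | mutual dyads Σ_{i<j} x_ij x_ji |
| AinS | Σ_i λ²[(1−1/λ)^{din_i} − 1 + din_i/λ] |
| AT_T | Σ_{arcs (i,j)} g(L2(i,j)), L2 = # two-paths i→k→j |
| AinAoutS | Σ_i g(din_i) g(dout_i) |
| OneInAoutS | Σ_i 1{din_i ≥ 1} g(dout_i) |
| AinOneOutS | Σ_i g(din_i) 1{dout_i ≥ 1} |
| source | Σ_i 1{dout_i ≥ 1, din_i = 0} |
| abs_diff(a) | Σ_{arcs} |a_i − a_j| |
| match(r) | Σ_{arcs} 1{r_i = r_j} |
| reciprocal_match(r) | Σ_{i<j} x_ij x_ji 1{r_i = r_j} |

These follow the alternating-statistic literature; other software may
normalize by constant factors, which leaves signs, zeros and significance
unchanged — no numeric coefficient from any external fit is claimed or
compared. A negative `abs_diff(age)` parameter means associated individuals
are closer in age than chance (age homophily); positive `match(raider)`
means trait homophily.

**Sampling** is Metropolis on uniform ordered-pair single-arc toggles with
acceptance min(1, exp(θ·Δz)); change statistics are computed incrementally
in O(n) per proposal with the two-path matrix maintained in place.
Library defaults are burn-in 20n² and thinning 5n² proposals.

**Fitting** is Robbins–Monro stochastic approximation. Phase 1 simulates at
the starting point (arc parameter at logit of observed density, others 0) to
estimate the statistic covariance D. Phase 2 runs 4 sub-phases of
(7 + 2^(k+1))·max(p, 4) iterations, updating θ ← θ − a·D⁻¹(z(X_t) − z_obs)
with the gain a (initial 0.25) halved per sub-phase and step norms clipped
at 1 to guard against early blowups. Phase 3 simulates (default) 1000
networks at θ̂: convergence requires |t_k| = |mean(z_k) − z_obs,k|/sd(z_k) <
0.1 for every fitted statistic; standard errors are the square roots of the
diagonal of the inverse statistic covariance (the exponential-family Fisher
information). Up to 3 restarts from the current estimate. Degenerate inputs
(e.g. a saturated graph) produce zero simulation variance, infinite
t-ratios, and a clean `converged=False`. Goodness of fit for statistics not
used in fitting reuses the phase-3 sample (|t| < 1 convention).

For dyad-independent specifications (arc + dyadic covariates) the MLE is
exactly the logistic regression of arc indicators on the covariates; the
test suite checks the stochastic fitter against that closed form within its
simulation error.

## Synthetic study generator

The generator emulates the design the analysis assumes, so every stage is
testable without field data. What it reproduces:

* **Population**: 58 males, ages ≥ 10 from a discretized gamma (shape 1.7,
  scale set so the mean is 25.2 years, truncated at 60) — right-skewed with
  the 10–19 bins dominating, mean matching the grand mean implied by the
  published per-cluster ages. The shape is a config knob.
* **Trait**: raider ~ Bernoulli(logit⁻¹(β₀ + 0.074·age)); β₀ is calibrated
  by numeric integration over the age distribution so the expected raider
  fraction is 21/58 (≈ 0.362). Both coefficients are configurable.
* **Communities**: six blocks of sizes 8/10/12/12/9/7, assigned by sorting
  on age plus Gaussian noise (SD = the age-homophily scale), so communities
  differ in mean age as the published clusters do.
* **Sightings**: per-male count targets from a negative binomial
  (dispersion r = 0.55, mean 36) clipped to [15, 107], chosen to match the
  published mean 36 / median 18 / max 107; groups are seeded by a focal male
  picked in proportion to his remaining count deficit, with members drawn
  from his community with probability 1 − ε (ε = eps_between, default 0.05)
  and weighted by exp(−|Δage|/σ) (σ = 8 years default) and by remaining
  deficit. Group sizes follow a truncated geometric on [2, 12] (p = 0.35,
  mean ≈ 3.9); group sizes were not published, so these are stated defaults.
  Realized counts track the targets with a small passive-membership
  overshoot.
* **Transmission overlay**: one synchronous pass after a first top-2 network
  is built — each non-raider whose top-2 associates include a strictly older
  raider converts with probability τ (default 0.3). A single pass keeps the
  generative model identifiable (a one-season snapshot); the overlay is not
  iterated to a fixed point.
* **Determinism**: per-stage streams derive from one master seed by fixed
  offsets; identical (config, seed) reproduces every file byte-for-byte.

What it does **not** emulate: spatial ranging, seasonal/temporal structure
in sighting effort (dates are decorative), female or family-group structure,
demography across years, observation error in ages, or imperfect raider
detection. Passing tests therefore show the *pipeline* recovers planted
structure under the stated design; they do not validate the ecological
assumptions themselves.

Problem sizes used in the test suite (large-population slope recovery at
n = 5000; ERGM recovery on 24-node networks with a reduced phase-3 sample;
power curves over ~14 seeds at 199 null replicates) are the package's
desk-scale defaults for fast, reproducible validation; library defaults keep
the full 1000-replicate / 1000-network settings.

## Known limitations

* The associate-pool null inherits the mild anticonservatism of the original
  design when focal males share associates (see above).
* The Robbins–Monro fitter's convergence flag depends on the phase-3 sample
  size; with short samples a correct fit can fail the |t| < 0.1 screen by
  Monte-Carlo noise. Estimates are unaffected; rerun with a larger
  `phase3_samples` when the flag matters.
* Alternating-statistic normalizations may differ from other ERGM software
  by constant factors; compare signs and significance, not raw magnitudes.
* Girvan–Newman returns the best partition on its nested removal chain,
  which is not always the global modularity optimum (verified against
  exhaustive enumeration on small graphs).
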