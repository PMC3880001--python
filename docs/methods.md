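# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `dualframe`.

## 1. The design being simulated

The target of the simulation is a continuous national health survey design
with these stages, all implemented exactly as stated:

1. **Stratification** by 21 health-board-like regions; the annual household
   target is allocated to strata by *power allocation*, stratum share ∝
   (census persons)^q with q = 0.5 by default. Largest-remainder rounding,
   minimum one meshblock per stratum. The exponent interpolates between
   national efficiency (q = 1, proportional) and equal stratum precision
   (q = 0).
2. **List (roll) sample**: a stratified PPS-without-replacement draw of
   meshblocks with size measure equal to the count of electoral-roll
   addresses flagged for Māori descent, followed by a simple random sample of
   `roll_addresses_per_mb` (default 10) of those addresses per selected
   meshblock, or all if fewer.
3. **Area sample**: drawn *after* the roll sample from the remaining
   meshblocks (the two meshblock sets are disjoint by construction), by
   randomized-order systematic PPS with inclusion probabilities
   π_i = m_h N*_i f_i / Σ N*_j f_j, where f_i is the targeting factor
   (coefficients 0.31, 0.37, 0.09, 0.20 on square-rooted Pacific/Asian
   meshblock and area-unit densities, plus the constant 0.03; the five
   coefficients sum to 1). Certainty units (π ≥ 1) are pinned at 1 and the
   remainder rescaled, iteratively, so Σπ = m_h exactly.
4. **Households**: an equal-probability sample at fraction c/N*_i (c = 20
   households per meshblock by default). The realized take H_i·c/N*_i is
   fractional when the meshblock has grown or shrunk since the census; it is
   resolved by *stochastic rounding* (floor plus a Bernoulli on the
   fraction), which keeps the per-household probability exactly min(c/N*_i, 1)
   and therefore keeps household probabilities proportional to f_i within a
   stratum. Deterministic rounding would bias household probabilities.
5. **Persons**: one adult (15+) uniformly at random per responding household
   and one child (0–14) if any, ignoring ethnicity, so that selection
   probabilities remain computable for every respondent.
6. **Quarters**: selected meshblocks from both frames are randomized to
   quarters within strata, balanced up to remainder, so each quarter is
   itself a probability sample.
7. **Nonresponse** (optional): independent Bernoulli per household with a
   configurable response probability; default 1.0, since the package's
   purpose is design comparison rather than nonresponse modelling.

### Size measure

The PPS size measure N*_i and the within-meshblock fraction both use **census
dwelling counts**. With person counts in the within-meshblock fraction, an
unchanged meshblock would not yield c households, and household probabilities
would pick up a spurious persons-per-dwelling factor breaking the
"∝ f_i within stratum" property. Stratum-level allocation uses census person
counts. The meshblock table carries both.

### Roll take calibration

The number of roll meshblocks per stratum r_h is chosen so the *exact* PPS
expectation of the roll household take, T(r) = Σ π^R_i(r)·min(10, R_i),
best matches the stratum's roll household target (roll share, default 15%,
of the stratum household allocation). r_h is additionally capped so no roll
meshblock becomes a certainty selection: a certainty roll meshblock would
permanently exclude its non-roll households from the area frame and hence
from the covered population. Because meshblock takes are integers, the
achievable roll share is quantized; `DesignPlan.expected_roll_share` reports
the exact planned value (typically within 0.01–0.02 of the configured share
at small simulation scales).

## 2. Pooled dual-frame inclusion probabilities

A respondent's weight is the inverse of the probability of entering the
*pooled* sample. With the roll stage drawn first,

π(person) = π^R(MB)·(take_R/R)·p(person)·1{household on roll}
          + E_S[1{MB ∉ S}·π^A(MB | S)]·min(c/N*, 1)·p(person),

where S is the random set of roll-selected meshblocks in the stratum and
π^A(·|S) is the area PPS probability renormalized on the reduced frame. The
expectation over S is computed

* **exactly** when the roll take is 0 or 1 meshblock (the outcome law is then
  the marginal π) or when the stratum has at most 8 roll-eligible
  meshblocks: the randomized-order systematic PPS set distribution is
  enumerated over all orderings of the non-certainty units, exploiting that
  for a fixed ordering the selected set is piecewise constant in the uniform
  start, so interval lengths give exact set probabilities;
* by **Monte-Carlo conditioning** otherwise (default 2,000 simulated roll
  outcomes, cached per distinct outcome set). The permutation enumeration is
  factorial in the stratum size, so the exact path is reserved for small
  strata; 8 units (40,320 orderings) is the practical comfort limit.

The marginal area probability per meshblock always equals its π by the
systematic-PPS construction; only the *conditioning on the roll outcome*
needs enumeration.

On a micro population, empirical per-person selection frequencies over 10⁵+
replicate draws match these probabilities within binomial noise (see the
acceptance tests); Horvitz–Thompson totals of the all-ones variable are
unbiased for the adult population count on the NZ-like population.

## 3. Estimators

* **Prevalences**: Hájek (ratio) estimator — weighted mean with estimated
  denominator — restricted to the subpopulation. Chosen over pure
  Horvitz–Thompson because prevalence denominators are estimated in practice.
* **Variance**: delete-a-group jackknife. PSUs (meshblocks) are randomly
  grouped into G groups (default 100, or the PSU count if smaller) within
  strata; replicate g zeroes group g and rescales the remaining weights to
  the full-sample stratum weight totals, so every replicate column reproduces
  stratum totals exactly. Variance = (G−1)/G·Σ_g(θ̂_g − θ̂)². Design strata
  holding a single sampled PSU are merged with the following stratum before
  grouping (collapsed-stratum device); with G equal to the PSU count in one
  stratum the method reduces to delete-one jackknife. The jackknife ignores
  finite-population corrections, as usual.
* **Design effect**: jackknife (or Monte-Carlo) variance over the binomial
  SRS benchmark p(1−p)/n_sub at the same subpopulation sample size.
* **ICC**: one-way ANOVA estimator (MSB − MSW)/(MSB + (k₀−1)MSW) with the
  unequal-group-size adjustment k₀ = (N − Σn_i²/N)/(I−1), clipped to [0, 1].
* **Response rate**: the RR3-style definition — interviews over eligible
  cases plus an estimated eligible share e of unknown-eligibility cases, with
  e defaulting to the eligibility rate among resolved cases.

## 4. Design-effect decomposition

Kish's rule for unequal weighting without clustering,
var(Ŷ) ≈ (1+C²_w)/n · S², applied to a ladder of four designs sharing the
same person sample size n — (a) SRS of people; (b) stratified SRS, power
allocation; (c) stratified SRS of households, one adult each; (d) the actual
design — factorizes deff(d vs a) into three weight-variation ratios
(1+C²)(next)/(1+C²)(prev) and three sample-size ratios n(prev)/n(next). Both
are estimated from the realized design-d sample alone:
n̂_sub(x) = Σ w_i π_xi and 1+Ĉ²_sub(x) = Σ(wπ)Σ(w/π)/(Σw)², with sums over
*subpopulation respondents* (the sample-size estimator is restricted to the
subpopulation because subpopulation sample sizes are the quantity of
interest). The A-ladder estimator of 1+C² is ≥ 1 by Cauchy–Schwarz with
equality iff π_x is constant on the subpopulation sample.

Counterfactual probabilities: π_a = n/N adults; π_b = n_h/N_h with n_h from
power allocation on census person counts and N_h the stratum adult count
(the ladder is a person-level abstraction, so person counts stratify it);
π_c = (n_h/HH_h)·(1/adults in household), which yields expected person
sample n_h exactly because every generated household contains an adult;
π_d is the realized pooled probability. n defaults to the realized adult
respondent count. Components are kept at full precision internally; rounding
to 2 decimals happens only at presentation.

The decomposition is validated two ways: a null design (single stratum,
equal-size meshblocks, one-adult households, no roll) returns exactly 1 in
every row; and on the NZ-like population the six-row product tracks the
realized Monte-Carlo variance ratio (design d vs SRS at the same total n)
within 25% for a zero-ICC outcome. For outcomes with positive ICC the
product understates the realized deff, as the ladder deliberately excludes
clustering.

## 5. The synthetic population generator

The generator reproduces the structural features this design exploits; its
defaults are the study conditions.

* **Strata**: person targets geometrically spaced over 30,000–460,000
  (geometric spacing spans the range deterministically and reproduces the
  size skew). `nz_like_population_config(total_persons=...)` rescales all
  strata proportionally; area-unit size shrinks with √scale so a scaled
  population keeps enough independent spatial units for spatial statistics
  to be meaningful.
* **Meshblocks**: household counts lognormal with mean 40 and CV 0.70
  (the lognormal is a modelling choice; only the mean and CV are pinned
  down), grouped into area units of 20 meshblocks (≈800 dwellings).
* **Ethnic densities**: an area-unit-level latent Gaussian field per
  ethnicity, transformed through expit (logit-normal densities), with
  meshblock densities drawn Beta around the area-unit value (concentration
  κ = 60). The latent means are calibrated by Gauss–Hermite quadrature so
  marginal densities match the configured prevalences (Māori 0.15, Pacific
  0.07, Asian 0.11), and the latent correlations are calibrated — again by
  quadrature, accounting for the beta-jitter attenuation
  corr_MB = corr_AU·√(r₁r₂) — so the meshblock-level density correlations
  match their targets: Asian–Pacific +0.14, Asian–Māori −0.15, and
  Māori–Pacific +0.30 (the last is not pinned by published figures; the
  positive default reflects the co-concentration of both groups in
  lower-socioeconomic areas). Unattainable targets raise an error reporting
  the closest achievable correlation.
* **Households**: each household carries independent Bernoulli ethnicity
  flags at the meshblock density (size-bias-corrected so the *person-level*
  share matches the density), members inherit the flags (total-response
  style, overlaps allowed). Household size is shifted Poisson,
  1 + Poisson(μ−1), with μ the maximum of the flag-specific means (Pacific
  4.2, Asian 3.4, Māori and baseline 2.6) — this is what makes
  one-per-household selection undersample Pacific and Asian adults, the
  effect the decomposition's row (d) measures. The first member is an adult;
  later members are children with probability 0.33 (≈20% children overall).
* **Roll flags**: households containing a Māori adult are on the roll with
  probability 0.8 (the default coverage mirrors the ~20% miss rate of proxy
  identification of Māori; configurable).
* **Outcomes**: binary, generated from beta-distributed meshblock prevalences
  with mean p and a+b = (1−ρ)/ρ, which makes the within-meshblock ICC of the
  outcome exactly ρ; ρ = 0 pins every meshblock at p. Optional additive
  per-ethnicity shifts are applied at person level (they perturb the overall
  prevalence slightly; calibration holds exactly at zero shifts).
* **Census drift**: `census_snapshot(pop, drift)` perturbs the *current*
  dwelling count multiplicatively with mean relative change `drift` and
  random sign, leaving all census-time quantities untouched; drift 0 returns
  the truth. Since the generated household list is the census-time truth,
  drifted current counts above the list are capped at the list when a draw
  is executed (growth since the census is out of the simulated universe).
* **RNG**: one master seed; every stage pulls a named substream
  (`_rng.substream`), so stages and replicates are independently re-runnable
  and everything is bit-reproducible.

What the generator does **not** emulate: real geography or spatial
autocorrelation *between* area units, age structure beyond the adult/child
split, correlated nonresponse, institutional populations, and within-area
socioeconomic gradients. Passing tests therefore demonstrate the internal
statistical coherence of the design machinery under controlled conditions,
not the numerical values any real survey would realize.

## 6. Coefficient optimizer

The targeting coefficients live on the unit simplex (the published set sums
to 1.00, which motivates the constraint). Candidates are scored with a Kish
anticipated-variance proxy per subpopulation — (1+C²_sub)/n_sub·p(1−p),
computed from frame-level person probabilities π ∝ n_h f_i / Σ N_j f_j —
importance-weighted and minimized by multi-start Nelder–Mead on a softmax
parameterization. The original coefficients were fitted against historical
survey and census data that are not reproducible here; the synthetic-frame
proxy is an openly declared surrogate, so the package checks directional and
optimality properties (constant factor optimal when only all-ethnicity
precision matters; subpopulation importance pushes its coefficients up;
agreement with dense grid search on restricted problems), not the published
coefficient values. Clustering penalties are excluded from the default proxy;
a per-subpopulation multiplier hook (`cluster_multiplier`) is available.

## 7. Problem sizes used in tests

The test suite runs the full pipeline at reduced but structurally faithful
scales chosen to keep the suite fast while leaving Monte-Carlo error well
inside each tolerance: a 24-household micro population with exact enumeration
for probability exactness (1.2×10⁵ replicate draws), an NZ-like 50,000-person
population with a 1,250-household annual draw (1/10 of the full design's
12,500) for unbiasedness (500 replicates), decomposition coherence (400
replicates), and ICC recovery, and n = 2,000 with 500 replicates for the
Kish identity. Stochastic tests are seeded and therefore deterministic.

## 8. Known limitations

* Joint (second-order) inclusion probabilities of the systematic PPS draw are
  not computed; variance estimation relies on the jackknife, which is exactly
  how the production survey treats them.
* The exact roll-outcome enumeration is factorial; large strata fall back to
  Monte-Carlo conditioning, which leaves O(1/√n_mc) noise in pooled
  probabilities (and a small Jensen bias in weights, negligible at the
  default 2,000 outcomes).
* The roll share is quantized by integer meshblock takes at small scales.
* Calibrated/post-stratified weighting, seasonal adjustment, and trend
  estimation are out of scope.
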