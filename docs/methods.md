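# Methods

This note documents the models, estimators, parameter choices and known
limitations of `oifnet`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and normalization

The unit of analysis is a community census: strictly increasing census dates,
a nonnegative species × time count matrix (fractional counts are allowed —
area-normalized counts of planktonic taxa are a real case), and per-date
surface and bottom water temperature, averaged into a single mean-temperature
covariate. Species are z-scored over the *full* record (sample standard
deviation, denominator L−1); all window and temperature-range subsets inherit
these global z-scores rather than renormalizing, so a subset retains the
information of where it sits in the record. Raw counts are kept alongside,
because presence/absence diversity α(t) = #{i : count_i(t) > 0} is only
meaningful on counts (a z-score is negative at an absence). Seasonality is
deliberately not removed and gaps are not imputed; the series is treated as
evenly indexed by census number.

Temperature ranges use half-open-upward interior bins — [10,15), [15,20),
[20,25) — with closed extreme bins (−∞,10] and [25,∞); a point at exactly
15.0 °C goes up. The convention is arbitrary but fixed and tested.

Sliding windows follow G = ⌊(L−l)/Δl⌋ + 1. Time windows hold exactly l
consecutive census points; temperature windows are half-open [T, T+5) °C
intervals whose lower bound advances by 1 °C, the first window being
[5,10) °C. The canonical layouts (l = 24, Δl = 2 over L = 285 → G = 131;
l = 10, Δl = 1 over L = 31 → G = 22) are asserted exactly.

## Information-theoretic estimators

All quantities are in bits. Transfer entropy is first-Markov-order:
TE_{i→j}(u) = I(x_j(t+1); x_i(t+1−u) | x_j(t)). The source–target delay u is
selected per ordered pair by maximizing the *lagged* mutual information
I(x_i(t−u); x_j(t)) over u = 0..10, ties broken toward the smaller delay
(parsimony). Negative raw TE values are numerical artifacts and are clamped
to zero; clamping plus downstream thresholding is the noise control. An
optional seeded circular-shift permutation null is available but off by
default.

Three estimators are provided:

* **gaussian** (default): MI = −½log₂(1−r²); TE from the 3×3 correlation
  matrix of (y⁺, y, x_lag) as half the Granger log-variance ratio. It is
  parameter-free and deterministic, has closed-form oracles (checked in the
  tests against −½log₂(1−ρ²), ½log₂(1+SNR) and an independent two-regression
  OLS oracle on random VAR(1) systems), and is exact for linear-Gaussian
  dynamics — which is also why the synthetic generator is linear-Gaussian.
  A near-deterministic source→target map drives the conditional variance to
  zero; the variance ratio is floored at 1e−12 so the TE stays finite.
* **kernel**: box-kernel plug-in with Chebyshev radius 0.5 × pooled standard
  deviation (the bandwidth is a free parameter; 0.5 sd is a common default).
  Used as a rank cross-check — the tests require Spearman ≥ 0.8 agreement
  with the gaussian estimator on linear-Gaussian communities — not as the
  default, because plug-in kernel entropies carry an n-dependent bias.
* **binned**: 8 equal-width bins per dimension; exact for genuinely discrete
  data (the 1-bit deterministic binary copy channel is asserted exactly).

Species-level Shannon entropy treats each unique abundance value as one
event, which is the natural convention for count data; fixed-width binning is
available for continuous input.

In *windowed* sweeps the delay scan is capped at u ≤ l//8. Scanning 11 lags
on a 24-point window both discards sample and roughly doubles the noise floor
of the TE estimates through max-selection bias; the cap affects sliding
windows only, never whole-record inference.

## Network assembly and thresholds

Self-interactions are never computed. Threshold modes: `fixed` (default 0.01
bits), `pareto20` (keep the ⌈0.2·n(n−1)⌉ largest off-diagonal weights; ties
at the cutoff are all kept, so the count can exceed the nominal 42 at n=15 —
logged), and `alpha_opt` (grid search over pooled distinct weights, at most
100 quantiles, minimizing the RMSE between per-window effective diversity
α_e and observed taxonomic α; a correlation objective is available; ties
prefer the larger threshold, i.e. the sparser network). If the observed α is
constant *and* no threshold can reach it, the optimizer warns and falls back
to 0.01. Effective diversity counts species with any nonzero incident weight,
using absolute values for forward compatibility with signed matrices.

## Stability and trend surface

Per window: full complex eigenvalue spectrum of the thresholded W, dominant
eigenvalue = maximum real part (for a nonnegative matrix this is the
Perron–Frobenius eigenvalue, real and bounded by the extreme row sums — both
facts are asserted), DS = |Re ξ_max|, TI = ΣW, α_e, and mean window
temperature. Species entirely absent from a subset (all raw counts zero) are
removed before eigen-analysis, shrinking the effective dimension; the record
is flagged. A binarized (adjacency) variant of the sweep is available in
parallel with the weighted one. Temperature→stability causality is
TE(window temperature → Re ξ_max) per temperature range at the MI-selected
delay.

Monotone-trend assessment uses a one-sided Mann–Kendall test (implemented via
Kendall's τ against the window index). It is a convenience diagnostic: MK
assumes exchangeable errors, so it should only be applied to records from
**non-overlapping** windows. During benchmark design we measured that MK on
half- or two-thirds-overlapping windows is anticonservative (false-positive
rates up to ~3× nominal); the packaged detection benchmark therefore uses
strictly non-overlapping windows.

Competitive-vs-cooperative divergence per window reports the dominant
eigenvalues of the two role submatrices, their difference, and the KL
divergence between the groups' weight distributions (20 equal-width bins over
the pooled range, additive smoothing 1e−6).

## Link salience and keystones

Effective distance is 1/W (∞ for absent links and the diagonal). For every
reference node r, the shortest-path tree is the union of links on *any*
minimal-distance path from r (all co-minimal predecessors contribute, which
makes the result deterministic under ties); SAL is the mean of the n
indicator matrices, so every value lies on the {0, 1/n, …, 1} grid. Trees are
directed out-trees by default; an undirected variant (max-symmetrized W) is
available because the original formulation of the measure was undirected.
Dijkstra trees are cross-checked against exhaustive simple-path enumeration
on small random digraphs. "Most salient" links are those with SAL ≥ ½;
keystone counts credit, configurably, the source, the target, or both
endpoints of the top-k most salient links (the field's "reference terminal
node" phrasing is ambiguous, so all three conventions are always reported).

## Distribution and scaling fits

Power-law fits are continuous maximum likelihood with a KS-optimal lower
cutoff (for fixed cutoff the closed form γ̂ = 1 + n/Σln(y/y_min) is asserted
to 1e−9). Regimes follow the moment-finiteness cutpoints γ≤2 / 2<γ≤3 / γ≥3.
Exponents are reported both in the density convention (γ) and the exceedance
convention (γ−1) to avoid the classic off-by-one ambiguity of epdf plots.

The double-Pareto (broken power law) fit grid-searches the break over the
50–99 % sample quantiles with per-regime maximum likelihood (truncated Pareto
below the break — a 1-d root solve — and Pareto above) and empirical mixing
proportions; the winning break maximizes the joint likelihood. The broken
model is only accepted if it beats the single power law by a BIC-style
penalty of 1.5 ln n for its three extra parameters — with a flat penalty the
50-candidate break search overfits genuinely single-regime samples.

Family selection compares power-law and shifted-exponential log-likelihoods
on a *common tail containing at least half the sample*: with an
unconstrained KS-chosen cutoff, the short upper tail of an exponential
passes for a power law in roughly a quarter of simulations. Constrained this
way the selector is essentially always right at n = 2000 (asserted ≥ 90 %
per family in the acceptance suite).

Taylor's law is the OLS slope of log sd against log mean of raw abundance
across species (= ν/2 in the variance convention); the exponential
temperature response X = X_min·e^{kT} is OLS of ln(abundance) on temperature
over strictly positive counts, with the Pearson correlation of raw abundance
vs temperature reported alongside.

## Synthetic communities

The generator's defaults are the study conditions it emulates: 15 species,
285 census points at 24 samples/year (~12 years), seasonal temperature
17 ± 9 °C with noise sd 1.2 °C and a slow warming trend of 0.25 °C/year
(range ≈ 6–31 °C), a competitive block (species 4–9) that is temperature-
synchronized (k = +0.08 per °C, near the middle of the empirical range of
competitive semi-log slopes) and fully mutually coupled, a cooperative
remainder that is weakly, sparsely coupled (background edge probability 0.15,
strength 0.15), heavier-tailed (log-noise sd 1.0 vs 0.5) and essentially
temperature-neutral (k = −0.01), and two rare cooperative species whose
counts are zero-inflated at rate 0.3.

Dynamics are a latent-Gaussian VAR(1) on log abundance with observed counts
round(exp(scale + z + η)). Two calibration details matter:

* **Temperature forcing.** The naive choice b = k does not make k the
  realized semi-log abundance–temperature slope, because the AR filter
  amplifies and phase-lags shared forcing (for the default block the realized
  slope is ~2.7× k). The generator therefore solves S·b = k, where S is the
  matrix of noise-free unit-forcing response slopes, computed by n
  deterministic passes; by linearity the realized slope of every species then
  equals its configured k, and `growth_fit` recovers it within a few percent
  at L = 2000.
* **Edge identifiability.** A fully mutually coupled block is nearly
  collinear — any member predicts a block-driven target about equally well —
  so ground-truth edges *out of* the block would be unattributable to a
  specific source by any bivariate estimator. The sparse background edges
  are therefore sourced from the weakly correlated cooperative species. This
  is a property of bivariate transfer entropy (conditioning only on the
  target's own past), not of this implementation, and it is the main caveat
  when reading inferred edges out of strongly synchronized guilds in real
  data.

The benchmark for the critical-slowing-down detection surface is a separate,
deliberately minimal community (`csd_benchmark_config`): 15 species coupled
in a directed ring (strength 0.15, self-memory 0.2, observation log-noise
0.35, no temperature forcing). The null keeps the coupling stationary; the
alternative multiplies it by up to 5.2× with a square-root ramp shape — the
squared coupling, to which pairwise information transfer is roughly
proportional, then grows linearly over the record — under a hard spectral-
radius cap of 0.95. Design rationale, learned the hard way and verified
empirically: (i) slow near-critical collective modes (radius ≳ 0.97) are
largely invisible to windowed conditional TE because the target's own past
absorbs the slow mode, so the ramp must intensify *fast* transfer; (ii) a
ring keeps every species identifiable and carries a genuine cycle, so the
dominant eigenvalue of the inferred matrix responds as well as TI; (iii) the
detector tests TI and DS from non-overlapping 20-point windows (14
independent points over the record) with one-sided Mann–Kendall at
Bonferroni-corrected α = 0.02 per indicator. Measured operating
characteristics at these frozen settings: power ≈ 0.95 and false-positive
rate ≈ 0 over 40 independent replicates (the acceptance script re-measures
both at run time on 20+20 replicates).

What the generator does *not* emulate: species invasions/extinctions,
observation effort changes, fishing pressure, multispecies nonlinearities
(Lotka–Volterra saturation, thresholds), or spatial structure. Passing the
recovery benchmarks therefore demonstrates estimator correctness on the
stated dynamics, not performance guarantees on real surveys — in particular,
strong seasonal synchronization inflates a spurious TE floor among
temperature-following species (visible in the generator when forcing is on),
and trend detection against that floor is correspondingly harder than in the
unforced benchmark.

## Numerical conventions

Base-2 logarithms throughout. Delay ties break small; threshold-optimizer
ties break large (sparser). Gaussian MI caps r² at 1−1e−15; kernel counts
include the query point so plug-in probabilities are never zero; histogram
entropies drop empty cells. Exponent of exp() in the generator is clipped at
30 to guard overflow for strongly amplified latent states. All stochastic
components take explicit seeds; identical configuration and seed reproduce
bitwise-identical outputs, and the CLI stamps every artifact with the hash of
its archived run configuration.

## Known limitations

* Bivariate TE with first-order conditioning cannot separate direct from
  common-driver or chained influence; the within-guild collinearity caveat
  above is the practical consequence.
* The gaussian estimator captures linear dependence only (a purely quadratic
  temperature→stability map would be invisible); the kernel estimator is the
  escape hatch at the cost of a bandwidth choice.
* Windowed TE at l ≈ 24 carries an estimation floor that scales with the
  number of species pairs; trend indicators should be compared across windows
  of identical length only.
* The α-optimal threshold search is a 1-d grid and assumes the observed α
  series is on the same windows as the inferred matrices.
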