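# Methods

This note documents the statistical models implemented in `mrpop`, the
numerical choices behind the sampler and projection engine, what the
synthetic-data generator does and does not emulate, and known limitations.

## 1. Observation model

Every component of change — interregional migration, mortality, fertility,
immigration, emigration — is modelled on the same likelihood:

    Y_c ~ Poisson(μ_c K_c),     log μ_c ~ Normal(𝓜_c, σ²)

per cross-classified cell `c`. The lognormal layer captures over-dispersion
beyond Poisson variability; σ has a half-t(ν = 2.5, scale = 0.5) prior. The
latent `log μ_c` is kept as a per-cell parameter (augmented form) rather
than marginalised, which preserves the over-dispersion structure exactly.

Exposures: mid-year populations (mortality, emigration), female mid-year
populations over the reproductive ages (fertility), cohort-aligned
populations five years before the census (migration; a migrant recorded at
terminal age x was at risk at age x−5 in the origin region, and recorded
first-age-group migrants — children born within the interval — take the
first age group's period-start population), and identically 1 for
immigration, which is modelled as counts because no well-defined population
at risk exists.

## 2. Predictors

Per component (AS, OA, … are two-way interactions on the log scale; terms
of the form X₁ + X₂κ(t) are bilinear pairs):

| component  | predictor 𝓜 | time effects |
|---|---|---|
| migration  | c + AS + OA + DA + OD₁ + OD₂κ₁(t) + A₁ + A₂κ₂(t) | two AR(1) with drift |
| mortality  | c + RA + RS + AS₁ + AS₂κ(s,t) | sex-paired random walk with drift |
| fertility  | c + RA + A₁ + A₂κ₁(t) + R₁ + R₂κ₂(t) | driftless AR(1) (keeps TFR forecasts level) |
| immigration / emigration | c + R·1(t ≥ 2004) + RA + AS₁ + AS₂κ₁(s,t) + R₁ + R₂κ₂(t) | sex-paired VAR(1); AR(1) with drift |

Identification is soft (hierarchical priors) except for two hard
constraints: each κ series equals zero in its first observed period, and
each bilinear loading vector sums to one — its last element is one minus
the sum of the free elements, whose prior is MVN(ι/L, L⁻²Ψ⁻¹) with Ψ = I+J.
Mortality deliberately carries no region–time bilinear term: regional
differences are held constant over time, which prevents regional life
expectancies from crossing implausibly in the forecast.

Priors: main-effect blocks N(0, s²) with s ~ half-t(2.5, 0.5); interactions
N(0, 0.2²); intercept N(0, 5) (5 read as a variance); migration OD means
α_ij = α_ji with standard-normal prior and half-t scale; drift
φ₁ ~ N(0, 2²); autoregression φ₂ ~ N(0.5, 0.2²) truncated to [0, 1];
innovation sds half-N(0, 1); the sex-pair correlation has an LKJ(2) prior.
The paired covariance is Σ = DΩD with D = diag(σ_M, σ_F): D holds the
marginal standard deviations and Ω the correlation (the only reading under
which D's definition is dimensionally consistent).

The 2004 break term for international migration is region-specific and
given the main-effect (hierarchical half-t) prior rather than the 0.2-sd
interaction prior, because a definitional change can shift a region's level
by much more than ±0.2 on the log scale.

## 3. Posterior computation

The sampler is a blocked Metropolis-within-Gibbs scheme built around the
conditional-Gaussian structure of the augmented model:

- **Latent log-rates.** Vectorised random-walk Metropolis with per-cell
  proposal scale 2.38/√(λ_c + 1/σ²) (local curvature) and the matching
  Hastings correction. Acceptance sits near 0.44 by construction.
- **Linear blocks** (intercept, interactions, main effects, OD means,
  break coefficients): exact conjugate Gaussian draws via weighted bincounts.
- **Sum-to-one loadings**: scalar Gibbs over the free elements, using the
  conditional of the constrained MVN prior; the constraint holds exactly in
  every draw.
- **κ paths**: one exact joint Gaussian draw per sweep covering *all* κ
  series of the model plus any break coefficients. The time-series priors
  contribute block-tridiagonal precision; series that load on the same cells
  are coupled through the likelihood. Sampling them jointly matters because
  loadings near their uniform prior mean make the series nearly collinear
  (the decomposition is only identified to the extent the loadings differ
  from uniform), and a region-level break step is nearly collinear with a
  step in the region κ path.
- **Dynamics parameters** (drift, autoregression, innovation scales,
  correlation): slice sampling under the *path-marginalised* posterior —
  the Gaussian κ path is integrated out in closed form (log-determinant plus
  quadratic form of the block-tridiagonal system). Conditioning the
  innovation scale on the current path creates a funnel in which neither
  can move; collapsing removes it. The path is redrawn immediately after so
  the pair is updated as one block.
- **Scales** (σ, hierarchical sds, OD scale): univariate slice sampling on
  the log scale with half-t / half-normal priors.

Initialisation is data-driven and deliberately diverse across chains:
latent log-rates start at log((Y+½)/K); each bilinear pair starts at the
rank-1 SVD of its double-centred level × time log-rate margin (the
alternating updates otherwise start on a saddle at uniform loading / zero κ
where neither block sees a gradient); successive chains cycle through the
SVD start, a randomly rescaled SVD start and the neutral
(uniform-loading/flat-path) start, plus small jitter. The weakly identified
trend decompositions can hold several posterior basins, and chains started
diversely represent them far better than replicate chains from one point. Chains are deterministic given the seed
(independent `SeedSequence` streams). Split-R̂ and effective sample size are
computed for σ and κ checkpoints; values above 1.01 are recorded as
warnings, not errors — the weakly identified κ decompositions legitimately
mix slowly, and several moderately long chains approximate that posterior
better than one long chain. Default fits therefore use 4 chains.

## 4. Forecasting

Per posterior draw: κ paths are simulated forward from their fitted
dynamics; all other parameters are held at their drawn values; the future
predictor is rebuilt, lognormal noise N(0, σ²) is added, and the result is
exponentiated. No Poisson sampling is applied at forecast time — forecast
uncertainty covers rates, not count-level variability, matching standard
demographic practice.

## 5. Projection engine

Five-year steps on the female-dominant multiregional accounting:

- S̄ₓ (conditional survivorship proportions, rows = origin) come from the
  forecasted out-migration probabilities; diagonals are one minus the
  off-diagonal row sums, which must stay below one.
- P̄ₓ = ½(S̄ₓ + S̄ₓ₋₅); the youngest group uses ½(S̄₀² + S̄₀); the
  open-ended group uses P̄_z = S̄_z.
- P^DE un-conditions on mortality and emigration:
  P^DE_rr = (1 − 5/2(d_r+e_r)) / (1 + 5/2 Σ_k P̄_rk(d_k+e_k)); a violated
  5/2(d+e) < 1 precondition raises (and excludes the draw in
  `project_horizon`, with a logged count) rather than being clipped.
- Sₓ = (I + Pₓ₊₅) Pₓ (I + Pₓ)⁻¹ and the infant matrix
  S₋₅ = [I + (I+P₀)⁻¹(I−P₀)]⁻¹. P̄/P are kept in the row-origin
  orientation the un-conditioning formula is written in; the survivorship
  sandwich acts on population column vectors and is therefore applied to
  the transposed matrices. A dedicated asymmetric two-region test pins the
  orientation.
- Survivors of the open-ended group advance with that group's own
  transition matrix (S_z ≡ P_z); the terminal group accumulates them plus
  entrants from below.
- Births: 5/2 Σₓ (Bₓ + Sₓ Bₓ₊₅)(K_xF + ½G_xF) with Bₓ diagonal matrices of
  *annual* region fertility rates, split 105:100 into males and females
  *before* sex-specific infant survivorship (the split-then-survive order
  matters once S₋₅ differs by sex, and keeps the sex ratio exact at birth).
- Annual forecasts aggregate to quinquennial inputs as means of the five
  annual rates (levels preserved) and sums of the five annual immigration
  counts.

## 6. Summaries

TFR_r = 5 Σₓ f_rx over the reproductive window. Life expectancy at birth
uses an abridged period life table consistent with the engine's linear
person-years assumption: q_x = 5d/(1 + 2.5d), L_x = 5(l_x + l_{x+5})/2,
open-ended closure L_z = l_z/d_z. Quantiles use linear interpolation
(deterministic across platforms); intervals are nested by construction.
Other life-table conventions (different a₀, different closures) shift e₀ by
a few tenths of a year; this package uses exactly one convention throughout.

## 7. Synthetic data generator

The generator emulates the shape of an eight-region national system:
8 regions with populations from ~0.2 to ~7 million, 18 age groups
(0–4 … 85+), two sexes, annual vital series 1981–2011 (31 points),
quinquennial migration 1986–2011 (6 points) and a 2004 immigration/
emigration break. One smooth population surface supplies all exposures, so
the system is internally consistent. Truths are drawn in-support: age
profiles are demographically shaped (Gompertz-like mortality with an infant
floor, a bell-shaped fertility schedule peaking near age 28 with TFR around
2, labour-mobility humps for migration), component intercepts equal their
profile means, loadings come from the constrained bilinear prior, κ paths
are simulated from their declared dynamics (moderate drifts, innovation sds
0.05–0.08), and the overdispersion sd is 0.05.

What the generator does **not** emulate: measurement error and census
undercount, demographic-accounting feedback (exposures do not react to the
simulated deaths and flows), cohort effects, shocks or policy breaks other
than the single definitional break, and zero-inflation in tiny cells.
Passing recovery tests therefore demonstrate that the inference machinery
recovers a correctly specified data-generating process at realistic
dimensions and signal-to-noise — not robustness to real-data artefacts.

A note on the recovery criterion: with loadings drawn from their prior, the
split of a common time trend between two bilinear terms is weakly
identified, so per-series κ coverage fluctuates between data realisations;
pooled across all series and components it sits near nominal. The fits used
in the recovery checks (4 chains × 700 warmup + 300 kept draws) are sized
for one CPU; the problem sizes are the generator defaults (8 regions ×
18 ages × 2 sexes × 31/6 periods; 8,9k–12k cells per component).

## 8. Known limitations

- Movement ("event") migration accounting is out of scope; migration is
  transition (census) data only.
- The baseline population is treated as error-free.
- Single principal component per bilinear pair; no rotation of age
  profiles; no coherent male–female life-expectancy convergence.
- The GLM screening harness (`select_model`) scores simplified
  (bilinear-free) candidates by log-rate RMSE over positive-count cells and
  BIC with p = rank of the design; zero-count cells are excluded from the
  RMSE, which is documented rather than solved.
- Very small cells (expected counts ≪ 1) will show slower latent-rate
  mixing; the per-cell Metropolis step is exact but local.
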