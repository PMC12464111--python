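# Methods

## Perceptual model

Each information source — advice accuracy (social, `a`) and the blue-win
indicator (nonsocial, `c`) — is tracked by an independent binary 3-level
Hierarchical Gaussian Filter with the standard variational updates: the
level-1 prediction is the logistic of the previous level-2 mean; the
level-2 prediction variance is σ₂ + exp(κμ₃ + ω); the level-2 posterior
adds the binary outcome precision μ̂₁(1−μ̂₁); level 3 is updated by the
precision-weighted volatility prediction error
δ₂ = (σ₂ + Δμ₂²)/σ̂₂ − 1, with meta-volatility ϑ inflating its variance.
A non-positive level-3 precision raises an error naming the trial — the
same failure mode as the reference toolbox implementation.

Free learning parameters are κ and ϑ per source, both estimated on (0, 1)
via logit transforms. The tonic log-volatility ω is a fixed, configurable
constant, **ω = −2.5**. Rationale: the individual differences of interest
live in κ and ϑ; ω is chosen so the effective tonic level-2 step
exp(κμ₃ + ω) at typical states (κ ≈ 0.5, μ₃ = 1) equals e⁻², the
operating point of the canonical binary-HGF toolbox defaults. Much more
negative values (e.g. −4) decouple the volatility level almost entirely:
profiling the session likelihood shows it is then flat to ±0.05 nats in ϑ
over its whole range, which contradicts the premise that these parameters
are measurable at all. Initial states default to μ₂₀ = 0 (equiprobable),
σ₂₀ = 1, μ₃₀ = 1, σ₃₀ = 1. Variances are floored at 1e−8 and
probabilities clamped to [1e−8, 1−1e−8]; floor hits are counted in the
trajectory diagnostics.

Baselines: a 2-level HGF (fixed step exp(ω), ω free per source in
fitting), a per-source Rescorla–Wagner delta rule (α ∈ (0,1)), and a
scalar Kalman filter (per-source process variance, shared observation
variance; both estimable — the posterior-vs-prior divergence is reported
per subject so a "posterior stuck on the prior" failure is detectable).

## Response model

The probability that the advised card wins integrates the two sources by
precision-ratio arbitration, b = (ζπ_aμ̂_a + π_cμ̂_c)/(ζπ_a + π_c), with
binary prediction precision π = 1/(μ̂(1−μ̂)) and social weight ζ (prior
mean 1 = equal weighting). Choices follow the unit-square sigmoid
P(y=1) = b^β/(b^β + (1−b)^β).

Wagers follow a compressive confidence mapping onto the 1–10 scale,

  w\* = 1 + 9·logistic(ψ₀ + ψ₁·|2b − 1| − ψ_vol·v̄),

where v̄ is the mean predicted log-volatility of the two sources relative
to its initial belief, and ψ_vol ≥ 0. The volatility term is part of this
package's wager model by design: in the response-model lineage this task
descends from, wager magnitude reflects the uncertainty of beliefs —
including environmental (volatility) uncertainty — not only the
decisiveness of the integrated prediction, and the task's hallmark
behavioural effect (markedly lower wagers in volatile phases) cannot
arise from |2b−1| alone, whose phase modulation is an order of magnitude
too small. Models without a volatility level have no such term. The wager
likelihood is a Gaussian around w\* (SD σ_w); simulated wagers are rounded
and clamped to 1..10 while the likelihood stays continuous — a documented
approximation that slightly biases σ_w upward near the scale ends.

## Inversion and model selection

MAP estimation maximizes choice + wager log-likelihood plus a Gaussian
prior over transformed parameters, with seeded multistart L-BFGS-B
(default 8 starts: prior mean plus draws at half the prior SD; objective
tolerance 1e−6). Default priors (transformed space): ζ ~ N(0,1) in log
space (native prior mean 1), β ~ N(0,4) log, κ/ϑ ~ N(0,1) logit,
ψ₀, ψ₁, ψ_vol ~ N(0,4) identity, σ_w ~ N(0,4) log; 2-level ω ~ N(−2.5,4).
Filter instability under a candidate parameter vector contributes a large
finite penalty rather than an exception, so the optimizer retreats.

Laplace evidence is −NLJ(MAP) + d/2·ln 2π − ½ ln det H with a
central-difference Hessian; if the Hessian is not positive definite after
step-size retries the LME is flagged unavailable while BIC (computed from
the likelihood alone with n_obs = 2 × trials, one choice and one wager
observation per trial) remains. Group comparison reports fixed-effects
sums/means of BIC and LME and random-effects Bayesian model selection via
the variational Dirichlet scheme (α₀ = 1), with exceedance probabilities
from seeded Dirichlet Monte Carlo (10⁵ draws).

## Synthetic cohort

Trait scores emulate the study's sampling design: SRP-SF totals are drawn
from a truncated normal (mean 62, SD 18, range 29–145) with the reference
distribution's top and bottom quartiles oversampled (23.3% / 46.5% /
30.2%; exactly 20/40/26 at n = 86), then split into facet scores
(interpersonal/affective/lifestyle 7 items, antisocial 8; noisy shares,
largest-remainder rounding, so facets sum to the total). Item-level
simulation is out of scope.

Agent parameters are lognormal/logit-normal with centres at the reported
group values (κ_c 0.62, κ_a 0.46) and dispersions keeping native ranges
admissible (logit SD 0.7 for κ and ϑ; log SD 0.5 for ζ). Three centres
were calibrated once against printed behavioural statistics of the study
population and then frozen: β (centre 1.2) so overall accuracy ≈ 63% and
advice-taking ≈ 62% approximate the reported 60.1% / 57.6%; ψ₀ (centre
−0.7) so the mean wager ≈ 5.4; ψ_vol (lognormal centre 5.0) so the
within-subject wager phase effect matches the reported d ≈ 1.1.

Planted effects couple the trait ranks to κ_a (ρ = −0.235) and to the
theta amplitude coefficient (ρ = −0.385) through a Gaussian copula on the
normal scores of the trait ranks, ρ_pearson = 2 sin(πρ_s/6). By default
the copula noise is residualized against the trait scores in-sample and
the mixing weight solved by bisection so each finite cohort *realizes*
the planted rank correlation (to rank resolution) instead of only in
expectation: with n = 80–86 the sampling SD of a Spearman coefficient
(~0.11) would otherwise swamp the planted value, and the purpose of the
plant is to measure pipeline attenuation, not seed luck. The plant leaves
the parameter margins untouched (rank preservation, tested).

A rare tail draw of (κ, ϑ) can destabilize the filter on a given input
realization (the level-3 precision turns non-positive); such an agent is
not an admissible generating process for that session, so its volatility
parameters are contracted toward the centre (logit-space ×0.8 per step)
until the filter runs, and the adjusted values become that agent's true
parameters. No contraction was needed in 3,440 agent-sessions across 40
seeds at the default scale; the guard exists so a tail seed cannot crash
the pipeline.

All generating sessions share **one** trial-input realization — the study
presented the same fixed trial order to every participant — while
fitted-parameter simulations redraw only response noise on that same
sequence (the generic simulator can also draw fresh inputs per run).

## EEG generation and analysis

Epochs are channels × trials × samples at 500 Hz, −500…+1500 ms
(end-inclusive, 1001 samples). The generator sums spectrally shaped 1/f
Gaussian noise (SD 10 µV) and a Hanning-windowed 6 Hz burst over
100–400 ms whose amplitude is base (8 µV) × participant coefficient ×
condition gain (incorrect 1.5× correct) × lognormal trial jitter, with an
FCz-maximal topography. It deliberately omits ocular/cardiac artifacts,
channel correlations and non-stationarities of real EEG — so passing
tests demonstrate that the *analysis pipeline* is correct and sensitive
at realistic SNR, not that it is robust to artifacts.

The TFR uses complex Morlet wavelets, width 3 cycles
(σ_t = 3/(2πf)), unit energy, truncated at ±4σ_t, over 40 linearly
spaced frequencies 1–40 Hz (linear spacing makes "40 steps within
1–40 Hz" exact); convolution is FFT-based and validated against a direct
convolution oracle at 1e−6 relative. Samples within half a wavelet of the
epoch edge are NaN; a frequency whose wavelet exceeds the epoch is
flagged entirely invalid rather than raising. Theta summaries average
4–8 Hz, 100–400 ms, over Fz/FCz/Cz (and per electrode), per condition
(all/correct/incorrect/phase × source); power is used raw by default, a
dB baseline (−500…−200 ms) is optional. The offline 0.01–40 Hz band-pass
for continuous synthetic data is a detrend + order-10 zero-phase
Butterworth low-pass cascade (the 0.01 Hz corner has a longer time
constant than any epoch-scale record, where a recursive high-pass
contributes only edge transients); it attenuates a 45 Hz probe by >20 dB
relative to in-band tones.

## Statistics

The 2 × 2 within-subject GLM is computed exactly via contrast scores: for
two-level factors each effect's F equals the squared paired t on the
per-participant contrasts and η_p² = F/(F + df₂) (cross-checked against a
general repeated-measures ANOVA implementation at 1e−8). Zero error
variance yields an infinite F flagged degenerate. Spearman correlations
use average-rank ties with seeded percentile-bootstrap CIs (1000
resamples in the report; 9999 for the recovery fingerprints); Cohen's d
CIs are bootstrap percentile. No multiple-comparison correction is
applied by default (the design mirrors planned comparisons); a
Benjamini–Hochberg switch exists. ζ is tested against 1 — the stated
prior-mean null — and the report footer notes the alternative zero-null
phrasing. Performance accuracy is implemented as percent correct; the
points-weighted reading of "accuracy" is noted as ambiguous and not used.

## Problem sizes and determinism

Defaults chosen as the package's working scale: recovery experiments use
86 agents × 160 trials with 10 fitted-parameter simulations per agent and
8 optimizer starts (≈ 35 s on one core thanks to the compiled filter
kernels); model comparison uses a 30-agent cohort; the theta pipeline
synthesizes 80 participants × 160 trials × 5 channels and restricts the
TFR to the 4–8 Hz bins it summarizes. Every stochastic step takes an
explicit seed; sub-seeds derive from `numpy.random.SeedSequence`, and all
reported quantities are bit-reproducible given the seed.

## Known limitations

κ and ϑ are weakly identified from 160 trials of choices and wagers: the
session log-likelihood carries well under one nat across most of their
range, so truth-to-estimate recovery correlations for the coupling
parameters plateau around 0.3–0.6 under these study conditions (response
parameters ζ, β, ψ·, σ_w recover at 0.7–0.95, and recovery rises with
trial count — both tested). Estimate-to-estimate designs, wider κ scales,
or response models that expose per-source uncertainty more directly all
raise these ceilings. The Rescorla–Wagner baseline, sharing the
arbitration response model, imitates the HGF predictions closely on this
task; it is separated decisively only by random-effects model selection,
not by raw BIC sums. The wager likelihood ignores the discreteness and
censoring of the 1–10 scale; the advisor-rating probe questions are not
modelled as responses.
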