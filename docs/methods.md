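# Methods

This note documents the models, conventions and numerical choices behind
`poprime`, and what the synthetic-data tests do and do not establish.

## Task geometry and conventions

Eight positions sit on a circle, indexed 0–7 clockwise from the top; the
four search items occupy all four positions of one parity (square = even,
diamond = odd). The indexing convention is arbitrary — every rule depends
only on circular distance and position identity. A useful geometric fact
falls out of the parity structure: a configuration switch vacates all
previously occupied positions, so "target at a previously empty position"
(TN) transitions coincide exactly with configuration switches, while TT/TD
transitions keep the configuration. Lag-k transition classification reuses
the lag-1 classifiers on (trial n, trial n−k) pairs and crosses block
boundaries within a session; whether the original analyses conditioned on
intermediate trials is not documented, so unconditional lag-k pairs are
used here.

## Evidence-accumulation models

**LATER.** RT = τ + D/r with D = θ − S₀ and r ~ N(μ, σ²) per trial. The
rate distribution is truncated to r > 0 and renormalized; without
truncation the reciprocal-normal leaks probability mass to t < τ, making
the likelihood improper. The density is

f(t) = [D/(t−τ)²] · φ((D/(t−τ) − μ)/σ) / (σ · Φ(μ/σ)),  t > τ.

With no starting-point updating, (θ, S₀, μ) share a scale degree of
freedom; only functionals such as D/μ and D/σ are identifiable, and tests
assert only those in that regime. Starting-point updates (log prior odds)
fix the scale.

**DDM.** A Wiener process with drift r, diffusion coefficient s and
absorbing boundaries {0, θ}, starting at z = θ/2 + S₀ (S₀ in the same
log-odds units as the LATER starting level; z is clamped to
[10⁻³θ, (1−10⁻³)θ]). The scaling parameter s is treated as the diffusion
coefficient only — it does not multiply the drift. The first-passage
density is the exact series solution, evaluated in normalized time with
the small-time/large-time switch and per-element truncation depth chosen
for ≤10⁻⁸ error; this bounds approximation error tighter than any fixed
closed-form surrogate, and the model-comparison conclusions depend on the
density shape, not on a particular approximation. The sampler is
Euler–Maruyama with a Brownian-bridge boundary-crossing correction
(crossing probability exp(−2(a−x₁)(a−x₂)/(s²Δt)) per step), which removes
the leading-order discretization bias and makes Δt = 10⁻³ s adequate
(validated against the series density at KS < 0.01).

**Modulation.** The active rules yield a per-trial triple
(ΔS₀, κ_total, δτ): starting-point shifts and NDT offsets add across
rules, rate scales multiply; the identity is (0, 1, 0). Rate scaling
multiplies the mean rate only, not its spread — scaling σ as well would
change the RT variance in ways the weight-resource interpretation does not
imply. ΔS₀ is signed toward the boundary of the UV state that actually
occurs, so a positive shift is a head start toward the correct response.

## Updating rules

Three updating variables (UVs): RCF (notch top/bottom), color polarity,
target position. The registry holds 12 RCF levels, 8 color levels and 10
position levels (each including no-update), giving 2 × 12 × 8 × 10 = 1920
models.

**Bayesian S₀ rules (PI/PD/PG/PS).** The belief over the Bernoulli
parameter of the UV is a discretized distribution on a 101-point midpoint
grid over (0, 1) (grid size configurable). The forgetting step mixes the
belief with the Beta(β₀, β₀) start (weight 1 − α), which no conjugate
family closes over — hence the grid. Midpoints avoid the endpoint
singularities of Beta(β₀, β₀) for β₀ < 1 and keep the posterior
predictive strictly inside (0, 1), so log odds are always finite. At
α = 1 the grid's posterior predictive matches the conjugate Beta–Bernoulli
closed form to better than 10⁻⁴ (tested over random sequences). The PG
variant blends the Bernoulli likelihood with a flat likelihood, weight ωᵈ
(d = circular distance to the target); PS applies its Gaussian spatial
mixing of the eight per-position beliefs immediately after the
starting-point read-out and before the Bayes step, so one-back updates are
still fully position-specific.

**Read/update ordering.** Belief and weighted rules apply the state
accumulated through trial n−1 to trial n, then update — matching the
worked narratives of the weight dynamics. Binary and step rules condition
on the current trial's repetition indicator and are therefore
update-then-apply: a value-agnostic scalar applied blind would predict no
one-back effect at all, contradicting the defining property of these
rules. On a session's first trial every modulation is the identity and the
repetition indicator is treated as neutral (no step).

**Zero-sum distractor inhibition.** For the distractor-inhibition rules
(weighted rate/NDT with independent target and distractor budgets), the
printed per-distractor term does not sum to zero over the eight positions,
contradicting the stated conservation of total weight. The implementation
follows the stated intent: each distractor loses Δd/3 (NDT: gains), each
of the five non-distractor positions gains Δd/5 (NDT: loses), which is
exactly zero-sum; the literal printed form remains available behind a
compatibility flag (`literal_eq10`). Conservation (Σκ = N, Σδτ = 0) is
enforced by construction and tested over 10⁴ random updates.

**Sign convention for position-dependent step NDT.** The per-position
step-NDT rules shorten the non-decision time at the target position after
a UV repetition and lengthen it after a switch, consistent with the rules'
described purpose (the printed update equation carries the opposite sign).

**Composition across UVs.** One rule per UV is active at a time; the
factorial design never states how their outputs combine, so the package
composes them in the way that preserves each rule's single-UV semantics:
rate scales multiply, ΔS₀ and δτ add.

Rule states depend only on the stimulus sequence — never on responses or
RTs — and advance on every trial, including error and censored trials.
States persist across blocks within a session and reset between sessions
(the cross-validation design, where held-out blocks still drive updating,
requires exactly this continuity).

## Likelihood and fitting

A session's negative log-likelihood is one forward pass in trial order:
trials that are correct and inside the RT window [0.2, 1.5] s contribute
−log f(rt) under the modulated EA density (LATER density, or the DDM
correct-boundary sub-density); all other trials contribute nothing but
still advance the rule states. A trial whose density underflows (e.g.
rt ≤ τ_eff) contributes a finite per-trial penalty of 50 nats rather than
propagating non-finite values. LATER's distance to threshold is clamped at
10⁻³θ and τ_eff at 0 during optimization so that intermediate parameter
vectors always yield a finite objective.

Optimization is nested, mirroring the inner/outer parameter split of the
model. The outer parameters are τ plus 0–3 parameters per active rule; the
inner parameters are the four EA parameters (LATER: θ, S₀, μ, σ; DDM: θ,
S₀, r, s). Because rule states depend only on stimuli and outer
parameters, the per-trial modulations are computed once per outer point,
and the inner objective is fully vectorized over trials. The inner
optimizer is bounded L-BFGS-B (numerical gradients) from a moment-based
start (reciprocal-RT statistics for LATER) plus jittered restarts; the
outer optimizer is Nelder–Mead through a logistic transform onto the
parameter boxes, with restarts. Default boxes: α ∈ [0, 0.999],
β₀ ∈ [0.5, 50], ω ∈ [0.01, 0.99], κ ∈ [0.2, 1], Δ ∈ [0, 1] (rate) or
[0, 0.2 s] (NDT), τ ∈ [0.05, 0.45 s]; the rule engines additionally
validate the mathematically admissible ranges (e.g. α ∈ [0, 1], κ ∈ (0, 1],
ω strictly inside (0, 1)). None of these boxes is data-derived; they exist
to keep densities proper. All stochastic pieces (restart jitter,
simulation) derive from a single integer seed, so fits are reproducible.

Free-parameter counting: k = 4 (inner) + 1 (τ) + Σ rule parameters;
AIC = 2k − 2 log L. Relative AIC subtracts the overall winner's AIC per
participant-session before averaging, so the winner is exactly 0.

**Coordinate search.** Each updating-rule factor is swept with the other
two fixed (round 1: no-update; later rounds: current best), across the
EA-model levels; a factor's best level minimizes the mean AIC over
participants, sessions and EA levels, with ties broken toward fewer
parameters, then registry order. Rounds repeat until a full round changes
nothing (round cap 6); the final EA model is the level with the lower mean
AIC at the winning rule combination. Exhaustive enumeration of all 1920
cells is provided for small problems.

**Cross-validation.** Eight folds, one per block. A fold's fit masks the
held-out block's likelihood terms only — its stimuli still drive the rule
states — and the held-out block is then scored at the fitted parameters.
The training summary averages each block's log-likelihood over the seven
folds containing it and sums over blocks, putting train and test totals on
the same 8-block scale.

## Temporal profiles

Normalized RT = RT − (participant-session mean over valid trials);
sessions are normalized independently, so each session's normalized mean
is exactly zero. For each lag k = 1…8, trial n is classified by the
transition from trial n−k (color repeat/switch; TT/TN/TD; or RCF
repeat/switch × TT/TN/TD), and normalized RTs are averaged first within
participant (pooling sessions), then across participants with
normal-approximation 95% CIs (the CI method in the original figures is not
stated). Model profiles replace each valid trial's RT with the fitted
model's expected RT under that trial's modulation — numerically integrated
over the analysis window [0.2, 1.5] s and renormalized — minus the
session's observed mean RT, and aggregate over exactly the same trials as
the data rows. Excluded trials carry no RT but still define transition
context for later trials.

## Synthetic data

The generator reproduces the design's constraints: 8 blocks × 112 trials
per session, balanced TT/TD/TN transition counts (differing by at most 1,
from a shuffled balanced deck), near-equal per-position target counts
(greedy choice with random tie-breaking among the positions a transition
type permits; TT transitions force the position, leaving a small slack),
a 50/50 color repeat/swap and a uniformly random notch. The constraints
fix the marginals, not the sampler — the deck-plus-greedy scheme is this
package's choice.

Forward simulation draws RTs from the modulated EA model: truncated-normal
rates for LATER, bridge-corrected Euler–Maruyama paths for the DDM.
Error generation is a stand-in, since errors are excluded from the
likelihood and the original error process is not specified: DDM errors are
wrong-boundary absorptions (intrinsic to the model); LATER has no error
mechanism, so a lapse probability yields uniform-random responses. The
simulation deadline is set to 1.5 s — the outlier bound — rather than the
task's 1-s response window, so censoring and outlier exclusion coincide;
which of the two governed the analysed RT range in the original study is
ambiguous, and this choice is the simpler one.

What passing tests show: the pipeline recovers parameters and generating
rules from data whose generative structure it knows exactly. What they do
not show: robustness to contaminant processes real data contain (fast
guesses, post-error slowing, fatigue drifts, dual-timescale priming
kernels), none of which the generator emulates.

## Default ground-truth values

Simulated studies use LATER(θ=1, S₀=0, μ=5/s, σ=1/s, τ=0.3 s) — mean RT
≈ 0.5 s, the typical magnitude for speeded singleton search — with
weighted-rate color updating (α=0.8, Δ=0.2), producing a lag-1 color
repetition benefit near 90 ms that decays over 3–5 trials; position
simulations add weighted-rate-with-distractor-inhibition (α=0.9, Δt=0.3,
Δd=0.2) and the position-gradient Bayesian starting point for the RCF
(α=0.9, ω=0.5, β₀=2). DDM checks use θ=2 with unit drift and diffusion
for the density oracles and r=3, s=2, τ=0.3 s (accuracy ≈ 0.95) when
error trials matter. These values were chosen once as plausible for the
paradigm and are the package's documented study conditions.

## Problem sizes in the test and acceptance runs

Parameter recovery fits 2 sessions × 896 trials; model recovery runs the
coordinate search on 1 session × 448 trials per replicate with the LATER
model and a restricted color-rule registry (no-update, binary rate,
weighted rate; other factors fixed to no-update); cross-validation checks
use 8 blocks × 56 trials; profile self-consistency uses 8 simulated
participants evaluated at the generating parameters. These sizes keep the
full verification suite to a few minutes while leaving every effect many
standard errors from its decision threshold.

## Known limitations

- No collapsing bounds, across-trial drift variability ("full" DDM
  variants), or urgency signals.
- No hierarchical/group-level estimation and no Bayesian posterior
  sampling over parameters; fits are per participant-session (or jointly
  over a listed set of sessions with shared parameters).
- No rules coupling color and response history, and no dual-timescale
  decay kernels.
- The exact membership of the 12/8/10 rule lists is reconstructed from the
  rule definitions and the factor structure; the source analyses never
  print the lists verbatim.
- Whether boundary separation was shared across sessions in the original
  fits is unstated; here every fitted session (or session set) carries its
  own EA parameters.
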