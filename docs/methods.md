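# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the design decisions made where the design was genuinely
open. Everything quantitative stated here is computed by the test suite or
by `scripts/acceptance.py`.

## Population model

The feature axis is the circle of motion directions, sampled on a uniform
grid (default 360 points, 1°). All angles at the interface are degrees.

**Spatial dimension.** The modelled stimulus fills the display and spatial
attention is uniform, so the spatial receptive-field and suppressive filters
contribute only a constant factor. The implementation therefore uses a
single uniform spatial channel; the spatial widths that a two-dimensional
implementation would carry (5° receptive fields, 20° suppressive kernel)
are inert under this stimulus and are absorbed into the response scale.
This is exact under spatial uniformity, not an approximation.

**Profiles and normalization conventions.** Stimulus bands and the
attention field are von Mises profiles `exp(κ(cos Δ − 1))`, peak-normalized
to 1, using the narrow-distribution equivalence κ ≈ 1/σ² (σ in radians) to
convert Gaussian widths to concentrations. The excitatory tuning filter and
the suppressive pooling filter are sum-normalized to unit mass, which gives
the suppressive drive weighted-average semantics: `sum(S) = sum(A·E)`
exactly, and the semi-saturation constant σ stays on the response scale.
Peak versus sum normalization of the filters only rescales constants that
the fitted σ and d′-scale absorb.

**Convolution.** Circular convolution is computed spectrally (real FFT);
a literal wraparound-sum path is kept and the two are tested to agree to
1e-10. The convolution of nonnegative arrays is clipped at zero to remove
FFT roundoff at the 1e-16 level, which otherwise leaks tiny negative drives
into downstream validation.

**Exponent placement.** `cⁿ` multiplies the stimulus image before the
tuning filter, matching the drive notation `E(θ; cⁿ)`; for a fixed stimulus
shape this is equivalent up to constants to applying it after.

**The ciN normalization field.** The coherence-independent extension is
implemented with the normalization constant *divided* by
`N(θ) = 1 + g·vonMises(θ; cue) ≥ 1`, so that attention *weakens*
normalization for units tuned near the attended direction — the sign of
effect the extension exists to produce. A `cin_divides` switch exposes the
opposite (multiplicative) reading for completeness. A version of N(θ)
dropping below 1 far from the cue (enhanced normalization for far-away
directions) is not implemented: no printed form pins it down. The two ciN
gains (narrow and broad focus) are separate free parameters, reflecting the
finding that the attentional contribution to normalization grows when
attention is focused.

**Degenerate inputs.** Zero coherence returns an identically zero response
(σ > 0 assumed); a zero normalization constant combined with a zero
stimulus raises an undefined-response error. Single-component stimuli (the
test display) are allowed.

## Linking stage

Predicted performance is `d′ = scale × R` at the unit tuned to the cued
component (valid trials) and at the unit tuned to the other component
(invalid trials), from one simulation per cueing condition with attention
on the cue. No separate "attend-wrong-direction" simulation is run, and the
invalid readout carries attention only at its baseline of 1; a mild
secondary focus on the uncued direction (which instructed observers may
deploy) is deliberately not modelled. One scale parameter is shared by all
four predicted curves. The linking stage is linear, so every attentional
effect in the predictions originates in the population model. Because both
the drive and the pool scale exactly as cⁿ, the predicted curves are exact
Naka-Rushton functions; a fast closed-form readout path exploits this
inside fitting loops and is tested to agree with the reference
simulation path to 1e-12.

## Gain regimes of the base model

With a broad suppressive pool the attended unit's numerator is enhanced but
the pool is shared with the unattended component, producing response gain
(d′max scales by the effective attentional gain, c₅₀ essentially fixed).
With a very narrow pool (12.3°) attention multiplies drive and pool alike,
producing coherence gain (c₅₀ shifts by gain^(−1/n), d′max fixed). Two
caveats make the closed forms regime statements rather than identities:

* the *effective* gain is the enhancement actually applied to the readout
  drive, `[(A·E)/E]` at the attended unit relative to the unattended one —
  slightly below 1 + γ because the attention profile is not flat over the
  stimulus band. Tests measure it independently of the curve fits.
* the input-gain limit additionally requires the attention field to be
  approximately constant over the pool and the band while remaining
  selective across the 135° component separation. κ = 2 (σ ≈ 40°) satisfies
  these inequalities and is used in that check; the study's narrow-focus
  κ = 15 varies too fast over a 12.3° pool and leaves a residual response
  gain of up to ~12%.

## Behavioural analysis

d′ = z(p_CW|CW) − z(p_CW|CCW). Perfect proportions are corrected by the
standard 1/(2N) rule before the quantile so d′ stays finite; this is the
conventional choice and the only place the analysis departs from the raw
formula. A proportion-correct variant (p(correct) − 0.5 in place of d′) is
available as a robustness flag.

The joint Naka-Rushton fit estimates (d′max, c₅₀) per curve with the slope
shared per subject (9 parameters for 4 curves); `per_condition` (2 slopes)
and `free` (4 slopes) parameterizations are available for the
AIC/BIC comparison that justifies the shared slope. Fitting is bounded
least squares with a seeded Latin-hypercube multi-start plus one
data-informed start; equal-SSE ties break to the lexicographically smallest
parameter vector for reproducibility. Curves whose fitted c₅₀ exceeds the
highest tested coherence are flagged as non-saturating.

Subject exclusion follows the saturation screen: a subject is excluded when
any monitored curve rises by Δd′ ≥ 1 between the two highest coherence
levels (boundary value excludes). Whether "any" curve or the mean curve is
monitored is configurable; "any" is the default.

Offset binning uses minimal circular differences. Cue–test offsets are
split into three equal-width bins over [0°, jitter + JND] — the possible
range given ±10° direction jitter and the JND-scaled change; both terms
are configurable since the exact range is a design quantity, not a
measured one. Cue–sample offsets use the fixed bins 0–2°, 3–6°, 7–10°,
implemented with half-open edges at 2.5° and 6.5° so continuous jitter
reproduces the integer groupings. For invalidly cued trials the reference
is the inferred uncued direction (the cue rotated by ±135°, whichever is
nearer the probed component).

JND estimation fits a cumulative Gaussian to p(clockwise) as a function of
signed direction change by probit maximum likelihood (via statsmodels);
the JND is the fitted σ and the bias the fitted mean. With one pre-test
session (450 trials over ±14°) the slope is determined only to about 10%,
so accuracy claims at the 5% level refer to the estimator's mean over
sessions, not to a single session.

## Model fitting and selection

Variants are fitted to observed d′ tables covering 2 conditions × 2
validities by minimizing the SSE of predicted versus observed d′ over the
variant's free parameters — 5 for the base model (two attention gains, σ,
n, scale), +1 for the free suppressive width, +1 for the self-normalization
weight, +2 for the ciN gains. Bounds: γ ∈ [0, 10], σ ∈ [1e-4, 10],
n ∈ [0.5, 6], scale ∈ [1e-3, 100], w ∈ [0, 1], g ∈ [0, 50], suppressive
width ∈ [5°, 180°]. The SSE surface has plateaus (notably a σ–scale
trade-off), hence 32 Latin-hypercube starts by default; parameters ending
on a bound are flagged. The default fit target is the across-subject mean
coherence-response function; per-subject tables (stacked rows) fit equally
well through the same interface with variant parameters shared across
subjects. Model fits use a 120-point grid — doubling the resolution
changes readout responses by well under 0.5%.

Comparison enforces nesting structurally: the fitted base-model solution is
embedded as a warm start in every extension (each extension contains the
base model exactly), and a residual violation beyond 1e-6 triggers one warm
refit. Information criteria are the Gaussian least-squares forms
AIC = n·ln(SSE/n) + 2k and BIC = n·ln(SSE/n) + k·ln(n) with additive
constants dropped; only orderings among variants are meaningful, not
absolute values. The F-test is
F = ((SSE_r − SSE_f)/(k_f − k_r)) / (SSE_f/(n − k_f)).

## Virtual observer

The generator reproduces the study design: 2 cue types × 75% validity × 6
coherence levels (1.6–100%) × 6 reference directions (0° and ±45° around
leftward and rightward motion), exactly balanced within each 576-trial
session (8 repeats per cue-type × coherence × direction cell), 5 sessions
per subject; validity is an independent Bernoulli draw. Both motion
components are jittered ±10°; the separation is 135° before jitter, so
realized separations span 135 ± 20°. The probed direction is the cued
component on valid trials and the 135°-away component on invalid trials;
the test direction rotates the probe by the subject's JND (default 12.86°,
the pre-test population mean) with a random sign.

Responses are independent Bernoulli draws from an equal-variance
signal-detection observer: at true sensitivity d′ the clockwise-response
probabilities are Φ(d′/2 − b) and Φ(−d′/2 − b) given a clockwise or
counter-clockwise change. The criterion b defaults to 0 (observers are
trained to negligible bias) but is exposed. This is the minimal trial-level
noise model consistent with the d′ analysis; it ignores sequential and
learning effects, inter-subject variability beyond the sampled noise,
lapses, and stimulus-level variability (no dots are rendered — only
decision-level statistics). Passing tests therefore validate the pipeline's
statistical machinery under its own assumptions, not the adequacy of those
assumptions for real observers.

Ground-truth curves are either given directly as (d′max, c₅₀) per
cue-condition × validity cell with a shared exponent, or derived from a
population-model configuration by evaluating its predicted curves at the
design's coherence levels and refitting them jointly.

All randomness flows from one seed through named spawned substreams
(design, responses, optimizer starts); identical seeds give byte-identical
trial tables.

## Demo configuration

`configs/demo_cin.yaml` is a ciN configuration with the physiologically
motivated broad pool (180°): exponent 1.5, σ = 0.06, attention gains
0.35/0.30 (narrow/broad), ciN gains 1.5/0.4, scale 1.55. Its derived
ground truth has narrow-condition curves (d′max, c₅₀) of (3.45, 0.115)
valid versus (2.58, 0.214) invalid, and broad-condition (2.92, 0.156)
versus (2.56, 0.177) — coherence plus response gain under a narrow focus,
predominantly response gain under a broad one, with effect sizes on the
scale of the empirical literature. The parameters were chosen for this
qualitative pattern and for curves that saturate within the tested
coherence range.

## Problem sizes and statistical limits

Simulation studies use 100 replicates for recovery and identifiability
checks and 50 full-study replicates for model selection; model-selection
replicates simulate six subjects at 120 trials per cue × validity ×
coherence cell (2880 trials per subject) and fit the across-subject mean
curves, the scale at which the model comparison is defined.

At single-subject trial counts the per-point d′ standard error is ≈ 0.24,
which puts a hard information limit on single-subject Naka-Rushton
coefficient recovery: the joint shared-slope estimator attains a median
relative c₅₀ error of ~17% and d′max error of ~9%, and matches both a
per-curve oracle with the true exponent fixed and a full binomial
maximum-likelihood fit — the limit is in the data, not the estimator.
Recovery at the few-percent level requires pooling (e.g. six subjects, or
~480 trials per cell).

## Known limitations

* The steady-state model has no dynamics; it cannot address temporal
  aspects of attentional deployment.
* Spatial attention phenomena are out of scope by construction (space is
  collapsed).
* Attentional effects on neuronal variability and inter-neuronal
  correlations are not modelled; the linking stage translates mean
  responses only.
* Decision-level accounts (differential weighting of the two motion
  components) are observationally close to the ciN extension on this
  design and are not implemented or distinguished here.
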