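# Methods

## Orientation space and the noise density

Orientation is periodic with period 180°. The package realizes this by
angle doubling (θ → 2θ), the standard convention for orientation data:
the report-noise distribution is then a true von Mises on the full
circle. Expressed per degree of orientation,

    f(θ)_σ = exp(κ(σ)·cos(πθ/90)) / (180·I₀(κ(σ))),

which integrates to 1 over any 180° span. The width parameter σ is the
circular standard deviation of the doubled-angle distribution mapped
back to orientation degrees, σ(κ) = (90/π)·√(−2·ln(I₁(κ)/I₀(κ))); its
numerical inverse (Brent's method on the scaled Bessel ratio, round-trip
accurate to < 1e−8°) supplies κ. Exponentially scaled Bessel functions
keep σ as small as 0.5° (κ ≈ 3×10³) overflow-free; σ large enough that
the mean resultant length underflows (> ~215°) falls back to the
small-κ expansion and the density degrades gracefully to uniform.

Signed errors live in (−90°, +90°] with −90 mapped to +90; orientations
in (0°, 180°]. Orientations are treated as continuous degrees even
though stimuli sit on a 180-value grid — the uniform guess term 1/180
per degree is exact either way, and responses come from a continuous
wheel.

## The six mixture models

Every model is a mixture over a trial's signed error θ of a target von
Mises (mean 0), a uniform guess component with mass γ, and zero or more
flanker ("misreport") von Mises components centred at the flankers'
observed offsets θ\*ᵢ — the flanker means are data, not free
parameters. One σ is shared by all von Mises components. Free-parameter
counts: S 2, M 3, 2M 4, 2B 5, 4M 6, 4B 7. The pooled model M splits its
single β equally over the trial's m flankers, making it the
equal-weights special case of 2M/4M — an identity the tests verify to
1e−9 in log-likelihood.

**Bias variants (2B/4B).** The μ parameter shifts the mean of the
*target* component only, and the model is fitted on outward-realigned
errors (signs flipped per trial so the first-outer flanker's offset is
positive), so μ > 0 means a pull toward the outer flanker. This is the
minimal model of an averaging bias on top of misreport weighting;
shifting all components jointly would be an alternative parameterization
we did not adopt, since the scientific question is whether the *target
representation* is dragged outward. Flanker components keep their
(realigned) observed means. Non-bias models are fitted on raw errors;
because all their components are symmetric, realignment leaves their
likelihood exactly invariant (tested), so AICc values remain comparable
across the two framings.

## Fitting

Each observer × condition is fitted independently by maximum likelihood.
The mixture weights (P_T, γ, β₁..βₘ) are reparameterized through a
softmax with the target weight as reference category, and σ (bounds
0.5°–80°) and μ (±45°) through scaled logistics, so the optimizer
(L-BFGS-B with finite-difference gradients) works unconstrained and the
simplex constraint γ + Σβ ≤ 1 holds exactly at every iterate. Default
20 random restarts per fit: weights drawn from a flat Dirichlet over
the simplex, σ and μ from a Latin hypercube over their bounds, all from
a generator seeded by the fit config — a fit is bit-reproducible given
(data, seed). Convergence tolerance 1e−8 (relative, on the negative
log-likelihood); parameter points whose likelihood underflows receive a
large finite penalty rather than ±inf so the finite-difference gradient
stays defined. No hierarchical pooling, no standard errors: point
estimates only.

AICc = −2 log L + 2k + 2k(k+1)/(n−k−1); comparisons sort ascending,
ties broken toward fewer parameters, then catalog order (S, M, 2M, 2B,
4M, 4B). Candidate sets per condition: uncrowded {S}; two-flanker
{S, M, 2M, 2B}; four-flanker {S, M, 4M, 4B} — the independent-misreport
model with the wrong component count is never fitted. In the
outward-target geometry (`exp2`) the two-flanker condition has no 1O
flanker, so no outward realignment exists and the bias variant is
dropped from that condition's candidate set.

## Synthetic data

The generator emulates the experimental design end to end: per observer
200 trials in each of three conditions (uncrowded / two-flanker /
four-flanker, 600 total), target and flanker orientations uniform on
the discrete 1°–180° grid, every flanker rejected until it differs from
the target by ≥ 15° (circular, period 180; acceptance probability
150/179 per draw), hemifields balanced, trial order randomized. Two
radial geometries at 1.5° centre-to-centre spacing: `exp1` (target 7°;
flankers 5.5°/8.5° or 4°/5.5°/8.5°/10°) and `exp2` (target shifted one
position outward to 8.5°; flankers 5.5°/7° — both inner — or
4°/5.5°/7°/10°). Flankers are not constrained against *each other*,
only against the target. Block structure and timing are not modelled;
hemifield and eccentricity are metadata and never enter the likelihood.

Responses are sampled generatively from any of the six models: latent
source ~ categorical(P_T, γ, βᵢ); target/flanker sources add von Mises
noise of width σ, guesses are uniform over the wheel. The latent source
is recorded per trial so recovery tests can condition on the truth. For
bias models the generative μ-shift is applied toward the 1O flanker
(sign-matched to the realignment convention).

The default scenario loads misreport mass on the first outer flanker
(two-flanker: β₁I = 0.05, β₁O = 0.25; four-flanker: β = 0.07, 0.07,
0.24, 0.07 for 2I, 1I, 1O, 2O) with γ = 0.05, σ = 15° (uncrowded:
γ = 0.03, σ = 12°) — group-level values typical of radial orientation
crowding with the inner–outer asymmetry. What the generator does *not*
emulate: sequential effects, lapses correlated in time, observer
heterogeneity (all synthetic observers share the generating
parameters), oblique-orientation anisotropies, and response-wheel motor
noise beyond the modelled σ. A green recovery test therefore
establishes that the estimator inverts the model family at realistic
trial counts — not that real observers obey the family.

## Derived summaries

* **Precision** — errors converted to radians; default 1/variance
  (rad⁻²), with 1/SD (rad⁻¹) behind a config switch, since both
  conventions circulate; the default follows the inverse-variance
  definition. Group averaging is per-observer precision first, then the
  mean. Zero variance yields an infinite-precision sentinel plus a
  warning rather than an exception.
* **Report rates** — from independent-misreport fits: each flanker
  role's fitted β plus a target row with P_T; group means and SDs are
  plain arithmetic across observers.
* **Mean error** — the per-observer summary reports the linear mean of
  signed errors; the circular mean is available from `circ_moments` and
  coincides to rounding at the observed magnitudes (< a few degrees).
* **Flanker-relative histograms** — counts of response-minus-flanker
  differences in 10° bins (configurable), for plotting and eyeballing
  only; no inference is built on them.

Inferential statistics on the group tables (ANOVA, t-tests, effect
sizes) are out of scope; the pipeline emits the per-observer quantities
those tests consume.

## Numerical choices and limitations

* Simplex handled by reparameterization, not penalties: constraints are
  exact, at the cost of a boundary that is reached only asymptotically
  (a true β = 0 fits as β ≈ 1e−8, which is inside every stated
  tolerance).
* Batch simulations in the test suite use 8 restarts per fit (10 for
  single large-n fits) instead of the default 20 to stay inside time
  budgets; for these few-parameter models the restart count affects
  runtime, not the recovered optimum (different seeds agree to 1e−4 in
  log-likelihood, tested).
* Exact numerical equality with fits from other toolboxes is not a
  goal; recovery and model-ordering properties are. Estimator settings
  elsewhere (MAP vs MLE, start grids) differ legitimately.
* AICc model selection at n = 200 trials reliably separates models
  whose distinctive weights differ by ≳ 0.15; smaller contrasts need
  more trials, and the no-false-complexity control only bounds the mean
  spurious advantage, not per-observer noise.
* The loader for external datasets is the canonical CSV schema
  (`observer_id, experiment, condition, hemifield, target_ori,
  ori_3I…ori_2O, response_ori`); mapping a deposit's own column layout
  onto it is left to the user because deposit formats vary.
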