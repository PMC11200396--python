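# Methods

This note records the models behind `isobolo`, the choices made where the
design was genuinely open, and what the validation suite does and does not
establish.

## Endpoint model

One plate well contributes one row (group, drug, concentration, replicate,
assay, signal). Replicates are aggregated by arithmetic mean with
dispersion reported as SEM = sd/√n, the convention of the assay literature
this pipeline serves. Viability is 100·signal/mean(control signal);
values above 100% are reported as-is and only clipped where a 0–1 effect
fraction is required, so no raw information is lost in the endpoint table.
Cytoprotection is the viability difference against the untreated-insult
(OGD/R) group mean; its SEM combines the two group SEMs in quadrature.
LDH blank and maximum-release wells are averaged before the window formula
is applied. Standard curves (GSH, pNA) are straight-line OLS over the
calibrated range — the assays are single-range calibrations with no
documented nonlinearity — and inverse prediction flags (but does not clip)
negative concentrations.

## Concentration–response model

Effect fractions are modelled as

    E(C) = F(a + b·x),  x = log10 C [µM],

with F the standard normal CDF (probit, default) or the logistic CDF
(logit). The log10 metameter is the field standard and makes every ECp
exactly equivariant under unit changes. EC50 = 10^(−a/b);
ECp = 10^((F⁻¹(p) − a)/b).

**Estimation.** The per-concentration effects entering the fit are
continuous normalised viability means, not quantal counts, and the plate
noise is homoscedastic on the signal scale. Each mean is therefore modelled
as Gaussian around the link curve with variance σ²/nᵢ, and the parameters
minimise the replicate-weighted residual sum of squares
Σ nᵢ(eᵢ − μᵢ)². A binomial-variance (quantal) weighting was evaluated and
rejected: it assigns near-saturated points far more influence than the
constant-variance noise justifies, and in Monte Carlo at this design it
biased the mixture-ray EC50 by roughly +9%/−12% at interaction parameters
0.5/0.1 — an order of magnitude more than the homoscedastic fit (≤ 1.8%
everywhere tested).

**Numerics.** Levenberg–Marquardt with an analytic Jacobian
(`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e−12, ≤ 600
evaluations) from a deterministic start: the least-squares line of the
link-transformed effects on x, the classical first iterate of probit
analysis. There are no random restarts, so fits are bit-reproducible. The
test suite verifies against a 200×200 brute-force grid over
(slope ∈ (0.1, 10], log EC50 ∈ [−3, 3]) maximising the identical Gaussian
kernel that the optimiser never does worse than the grid. Fewer than 4
distinct positive concentrations is an error; a fitted negative slope or a
curve observed entirely on one side of 50% effect produces a warning, not
an error. Observed fractions are clipped to [0, 1] when built from
endpoints; a tiny ε = 1e−6 guard applies only where a link transform of an
observation is needed (initialisation).

**Uncertainty.** Parameter covariance is σ̂²(JᵀWJ)⁻¹ with σ̂² estimated on
k − 2 degrees of freedom from the k design points. ECp standard errors
come from the delta method on the log scale and are mapped to µM as
value·ln(10)·sd(log₁₀ECp). The 95% CI uses the t quantile on k − 2 df —
with the residual variance estimated from 8 points, the normal quantile
is noticeably anti-conservative — and is exponentiated from the log scale,
so it is asymmetric in µM and always positive. At the reference design
(8 concentrations, 9 replicates, Gaussian well noise of 5% of the dynamic
range) simulation shows ~96% coverage and ~1% median relative EC50 error;
at double that noise, ~93% and ~2%.

**Effect normalisation.** Cytoprotection effect fractions are
(viability − baseline)/(ceiling − baseline) with baseline = the estimated
untreated-OGD/R viability and ceiling = 100 (control). Zero-concentration
wells anchor the normalisation but never enter the log-scale fit.

## Combination design and isobole analysis

A fixed-ratio ray at EC50 fraction f has design point
(f·EC50_A, (1−f)·EC50_B); the ratio labels "1:1"/"1:4"/"4:1" are metadata
for f = 0.5/0.25/0.75. Design arithmetic is kept at full precision;
display rounding is a formatting concern handled separately, because the
published tables this mirrors round components to 1–2 decimals and their
printed totals are sums of rounded components.

EC50_T = f·EC50_A + (1−f)·EC50_B with SEM by independent linear error
propagation, √(f²·sem_A² + (1−f)²·sem_B²) — the composite-additive
variance. For the reference inputs (10.06 ± 0.22, 0.07 ± 0.004, f = 0.25)
this gives 0.055; published work on the same numbers reports 0.013 by an
unstated method, so the pipeline uses the propagated value by default and
accepts a user-supplied SEM through the potency-summary input route.

EC50_E is fitted from the mixture dilution series on the total
concentration scale (the ray's component split is bookkeeping, recovered
by proportional decomposition). The comparison of EC50_T and EC50_E is
Welch's t on (value, SEM, n) triples with Welch–Satterthwaite degrees of
freedom and a two-sided p. The classification requires both the index
side (I < 1 or > 1) and p < α; an index statistically indistinguishable
from the additivity line is reported as additive regardless of its point
value. This guards against calling synergy on noise and mirrors the
practice of testing EC50_T vs EC50_E before declaring an interaction.

When the dilution-series data follow one specific ray, the assessment is
paired with that ray's f (config `ray_f_a`, default 0.25) rather than with
whichever candidate design point happened to score the highest mean
cytoprotection — under an interaction uniform across rays the candidates
are equi-effective in expectation and the "best" one is a noise coin-flip.
The observed best candidate is still reported.

## Synthetic experiment generator

The generator emulates the study structure the analysis assumes:
9 replicates/group, control at 100% and OGD/R baseline at 47.19% of
control, monotherapy Hill curves (default EC50s 10.06 and 0.07 µM, Hill
slope 2 — the published curves' steepness is not recoverable, so 2 is a
modelling default exposed in config) on the two 8-point series
(6.04–30.6 µM; 0.047–0.24 µM), and Gaussian noise on the raw signal scale
with sd 5% of the control signal (published group SEMs of ~1.5–6% of mean
motivate this default).

Combinations follow a Loewe model with one scalar interaction parameter ψ:
the joint effect solves C_A/ECe_A + C_B/ECe_B = ψ with ECe the inverse
Hill curves, found by bracketed root-finding (Brent, xtol 1e−12) on the
effect fraction — the left side is strictly decreasing, so the root is
unique. ψ = 1 is additive and reduces exactly to the monotherapy curves;
ψ < 1 synergy; ψ > 1 antagonism. Because the inverse Hill at half effect
equals the EC50 for any slope, the ray through the additive design point
has true 50% total concentration exactly ψ·EC50_T, so the pipeline's
interaction index estimates ψ directly — the closed form the recovery
tests rely on.

The simulated dilution series uses factor 2 with 4 levels each side of the
ray's design total (center excluded, as the center was assayed in the
candidate-ray stage): the series must bracket the mixture EC50 down to
ψ = 0.1, which a narrower series cannot. The stand-alone
`dilution_series` helper defaults to 3 levels each side.

Randomness: one root seed; per-arm child streams are spawned
deterministically, so any arm can be regenerated independently and two
runs with the same seed produce byte-identical CSVs.

**What the generator does not emulate:** plate spatial/edge effects,
optical artifacts, non-Gaussian or heteroscedastic noise,
effect-level-dependent interactions (ψ is constant across effect levels),
and mechanistic ROS/GSH/caspase kinetics. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to those real-data features.

## Validation problem sizes

The suite checks, per run: oracle equivalence on 20 random curves
(200×200 grid); EC50 recovery and CI coverage over 500 simulated curves at
the reference design; interaction-index recovery (mean within ±0.03 of
ψ ∈ {0.1, 0.5, 1.0}) over 200 full-pipeline simulations per ψ; and the
acceptance script re-estimates ψ = 0.1 over 100 simulated experiments.
The whole suite completes in well under a minute on one CPU.

## Known limitations

- Potency CIs reflect fit uncertainty only. The shared control-mean and
  OGD/R-baseline estimates shift a whole curve coherently; that
  normalisation uncertainty is not propagated, and full-pipeline CI
  coverage for a single monotherapy EC50 is consequently below nominal
  (~70% in simulation) even though the interaction index — a ratio in
  which these shifts largely cancel — remains essentially unbiased.
  Summary-level inference (the Welch test) uses the supplied SEMs as-is.
- Both links assume a symmetric sigmoid with asymptotes pinned at the
  normalisation bounds; there is no 4-parameter logistic with free
  asymptotes, and no model selection between probit and logit (the user
  chooses; probit is the default; at the median the two agree within 2%
  on symmetric data).
- Two-drug, fixed-ratio designs only: no checkerboards, no ≥3-drug
  mixtures, no Bliss/HSA/ZIP alternatives, and only the 50% isobole is
  constructed.
- The Welch test treats EC50_T and EC50_E as independent; they share the
  monotherapy data only through the additive formula, which is a
  reasonable but not exact independence.
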