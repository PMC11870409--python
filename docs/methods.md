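# Methods

## The model family

Soluble FLT1 (sFLT1, sVEGFR1) is constitutively synthesized and secreted by
endothelial cells. The package tracks two well-mixed pools per cell —
intracellular sFLT1 `I` and extracellular (secreted) sFLT1 `X`, both in
molecules per cell — connected by mass-action processes:

    dI/dt = α − β·I(t−τ) − γ·I(t−τ) [+ ε·X]
    dX/dt =     β·I(t−τ) − δ·X      [− ε·X]

| parameter | meaning | units | reference value |
|---|---|---|---|
| α | production (translation) rate | #/cell/h | 1.419×10⁵ |
| β | secretion rate constant | 1/h | 5.123×10⁻² |
| γ | intracellular degradation rate constant | 1/h | 1.215×10⁻¹ |
| δ | extracellular degradation rate constant | 1/h | 5.743×10⁻² |
| τ | maturation delay | h | 1.958 |
| ε | internalization rate constant (optional) | 1/h | 0 |
| κ | production decay rate constant (optional) | 1/h | 0 |

Three processes are optional and their on/off combinations define eight
candidate structures M1–M8 (M1: plain ODE model; M2: maturation delay only;
M3 internalization; M4 production decay; M5 delay+internalization; M6
delay+decay; M7 internalization+decay; M8 all three). The maturation delay
τ represents transit through the secretory pathway: newly made protein can
neither be secreted nor degraded until τ hours after synthesis, which turns
the ODEs into delay differential equations. Internalization (ε) moves
extracellular protein back inside. Production decay replaces the abrupt
production stop at the start of a pulse-chase chase phase with
`α·exp(−κ·t)`, modeling gradual washout of labeled amino acids; note a model
*without* this process is the κ→∞ (not κ=0) limit of one with it.

The reference ("median") parameter set ships with the package
(`sflt1kin/data/median_params.yaml`): the component-wise median of accepted
multistart fits of M2 to three published time-course designs. Its closed
forms: I_SS = α/(β+γ) ≈ 8.2×10⁵ #/cell, X_SS = (β/δ)·I_SS ≈ 7.3×10⁵ #/cell,
T50_I = ln2/(β+γ) ≈ 4.0 h, T50_X = ln2/δ ≈ 12.1 h. The compound constants
c1 = αβ ≈ 7.27×10³ #/cell/h² and c2 = β+γ ≈ 0.173 /h are the ensemble
invariants of the fit: with δ and τ they pin all observable dynamics,
leaving one residual degree of freedom along which α, β, γ trade off
(`params_from_beta` walks this ridge; `theoretical_bounds` gives its
extremes, e.g. min I_SS = c1/c2²).

## Simulation protocols

**Constitutive secretion.** A pre-simulation from an empty system
(I = X = 0, zero delay history) runs until the intracellular steady-state
criterion is met: less than 0.5% change in I over a sliding 20 h window,
evaluated on the reporting grid with first-crossing semantics (trivially
satisfied when both window endpoints are zero, e.g. α = 0). The media change
at t = 0 resets X to 0; I and its delay history carry over untouched.
Reported span 24–72 h at 1-minute intervals. The pre-simulation gives up at
2000 h (configurable): well-fitting parameters converge within ~40–60 h
(T50_I ≈ 4 h), and the cap only triggers for pathological rates, which the
fitter treats as a penalty. Very long delays can also defeat steady-state
initialization; such failures are reported, not masked.

**Pulse-chase.** Only labeled protein is modeled, so the system starts
empty; production runs for the 20-minute pulse; at t = 0 (chase clock) the
media change resets X and production switches to 0 (or `α·e^{−κt}`, with
the decay clock starting at the media change). Chase reported for 10 h. A
diagnostic signature of the delay: labeled X stays exactly zero until
τ − 20 min into the chase.

## Numerics

The equations are linear and non-stiff at biologically plausible rates, so
the integrator is a fixed-step classic RK4 on a uniform grid, compiled with
numba. The step is the 1-minute reporting interval, reduced when a
first-order rate would endanger stability (h ≤ 0.5/max(β+γ, δ+ε)) or when
the delay is shorter than a step (h ≤ τ keeps every delayed lookup in the
already-computed past — the method of steps). Delayed values I(t−τ) are read
off the stored grid by linear interpolation; τ need not divide the step.
Verified accuracy against closed forms is ≤10⁻⁶ relative, far inside the
10⁻⁴/10⁻³ (delayed) and 10⁻¹²/10⁻⁸ (non-delayed) targets the protocol
definitions ask for. Tiny negative values from round-off are clamped to 0
each step; divergence (genuinely unstable delayed feedback at extreme
τ·(β+γ)) is detected and surfaced as an error.

Degenerate and boundary cases: delays ≤ 10⁻⁵ h (0.036 s) are integrated as
ODEs (relative error O(τ·(β+γ)) ≤ 10⁻⁴ over the allowed rate range), which
also realizes the exact DDE→ODE limit. When κ·h > 30 — the labeled pool
e-folds ≥30 times within one step — chase production is set exactly to zero
(error < 10⁻⁵·α), making the abrupt-stop model an exact boundary point of
the production-decay family; this matters for nested model comparison.
Discontinuities (media-change reset, production switch-off) are handled by
segmenting at the known event times rather than event detection.

## Cost function and fitting

Each dataset is simulated under its own scenario and converted to its own
units: relative datasets normalize each species at the dataset's anchor time
(e.g. X at 24 h, I at 0 h); absolute datasets convert #/cell to ng/mL via
`value × cells_per_mL × molar_mass / N_A` (fixture defaults 10⁵ cells/mL,
110 kDa; an optional per-dataset free scale factor can replace fixed
constants). The cost is the unweighted sum of squared relative errors over
all included observations. Preprocessing drops points flagged as excluded
and collapses replicates to per-time means.

Multistart bounded least squares (scipy trust-region-reflective, ftol =
xtol = 10⁻⁸, relative finite-difference step 10⁻⁴, ≤400 evaluations per
start). Rate parameters with strictly positive bounds (α, β, γ, δ) are
optimized in log10 — priors span orders of magnitude — while τ, ε, κ stay
linear so the process-absent boundary (0) is reachable. Default sampling
ranges (log-uniform; uniform for τ): α ∈ [10³, 10⁷], β, γ, δ ∈ [10⁻⁴, 10],
τ ∈ [0, 8] h, ε ∈ [10⁻³, 10], κ ∈ [10⁻², 10²]; bounds extend κ to 10⁴ so
the nesting boundary is effectively reachable. All ranges are configurable.
Non-finite residuals and simulation failures at trial points map to a large
constant penalty so the optimizer retreats.

The *accepted* subset of an ensemble holds fits within 10% of the minimum
cost, plus an absolute slack (`cost_floor`, default 10⁻⁶ ≈ RMS relative
error 2×10⁻⁴): on noiseless data every converged fit is perfect and the
minimum is solver round-off, so a purely relative filter would arbitrarily
keep one fit and make ensemble statistics meaningless.

## Model selection

AICc = n·ln(C/n) + 2k + 2k(k+1)/(n−k−1), natural log, with k = active
parameters + 1. Because residuals are relative, rescaling all data and
predictions by a common factor shifts every model's score equally and the
ranking is invariant. Each model is additionally warm-started from the best
fit of every sub-model with one process fewer (new parameter at its absent
boundary: τ = 0, ε = 0, κ at its upper bound), which guarantees that adding
a process never increases the best attainable cost on any dataset, up to
solver tolerance.

## Sensitivity, fluxes, inhibition

Local sensitivities are one-sided forward differences at a +10% bump
(matching the experimental-analysis convention, not centered differences);
T50_X uses the closed form ln2/δ, with a grid-crossing estimator as
cross-check. Global scans use 25 log-spaced factors over 0.01–100×.
Fluxes are reconstructed from the trajectory and its stored delayed
intracellular series, so flux balance against finite-difference derivatives
is a genuine invariant test, not a tautology.

Inhibition multiplies one target parameter by (1−f): applied after baseline
pre-equilibration (chemical/acute) or throughout (genetic/chronic). τ
inhibition is included for completeness although constitutive outputs are
insensitive to it. Inversion of an observed fold change solves for f on the
fold-change scale by bisection to |Δf| ≤ 10⁻³ after a 21-point monotonicity
pre-scan (responses are monotone in f for this model class; a violation
raises instead of silently bisecting). Observations beyond the f = 1
ceiling, or opposite in direction to the model's response, return explicit
infeasibility verdicts. Note that for acute inhibition of β or γ the
extracellular courses differ transiently from chronic inhibition (the
intracellular pool re-equilibrates over 1/(β′+γ′) hours) and only converge
asymptotically; the common claim that they are identical holds exactly only
for δ and at plot resolution for β, γ.

## Synthetic data

Three templates mirror the published experimental designs: `hornig_like`
(constitutive, X only, absolute ELISA-like units, grid {1,3,6,12,24,48,72} h
with 3 h pre-flagged excluded), `kinghorn_like` (constitutive, X and I,
relative Western-like units anchored at X(24 h)/I(0 h), grid
{0,2,4,8,24,48,72} h), `jung_like` (pulse-chase, X and I, relative units
anchored at X(8 h)/I(0 h), grid {0,0.5,1,2,4,6,8,10} h with 10 h excluded).
Exact published grids live in supplementary material not reproduced here;
these defaults exercise every preprocessing rule. Noise is multiplicative
lognormal with unit mean, CV configurable (default 0.10 — immunoassay and
densitometry errors are roughly proportional); replicates default to 3.
Observations whose noiseless value is zero are omitted (below any limit of
quantitation; relative error undefined).

What the generator does *not* emulate: blot saturation, background
subtraction, cell proliferation over 72 h, heterogeneous cells, or
correlated replicate errors. Passing recovery tests therefore demonstrate
the estimator's correctness and the data designs' information content, not
robustness to every real-data pathology.

## Problem sizes used in the shipped checks

Recovery experiments use 50 starts on the three-design noiseless mix
(≈30 collapsed observations); model comparison uses 8 starts per model
(plus nested warm starts) on 10%-CV data and 4 starts on noiseless data.
These sizes were chosen so the full pipeline demonstrates the
identifiability structure (δ, τ, c1, c2 pinned; α, β, γ spread >10-fold;
an absolute intracellular observation collapsing the spread) with
comfortable margin while keeping a complete run in minutes.

## Known limitations

- Two compartments only: no organelle resolution, no ECM/cell-surface
  binding of extracellular sFLT1, no VEGF/PlGF ligand interactions, no
  receptor dimerization, no mRNA-level regulation — all outside scope.
- A fixed maturation delay idealizes what is biologically a distribution of
  transit times.
- Very long delays interact with steady-state initialization (the criterion
  window can sit inside a delay-induced oscillation); such cases fail
  loudly rather than being special-cased.
- Intracellular accumulation larger than the full-secretion-block ceiling,
  or opposite-direction responses, cannot be explained by any f — the
  inversion reports these as infeasible rather than inventing mechanisms.
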