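# Methods

## Model

The package treats a catchment as a bundle of independent stream tubes.
Each landscape point drains to the outlet with a travel time τ drawn from
the catchment's travel-time distribution (TTD) f(τ); along the way nitrate
is removed by first-order denitrification at rate k. The flow-averaged
outlet concentration is the convolution of the per-parcel source function
with the decayed TTD,

    C(t) = ∫₀^∞ Cs(t−τ) f(τ) e^{−kτ} dτ,

and all scenario results are reported relative to the pre-change steady
state C_bc = ∫ Cs0 f(τ) e^{−kτ} dτ (for an exponential TTD,
C_bc = Cs0/(1+μk)).

**Source zone.** After conversion, the readily mineralizable legacy soil
organic N stock decays first-order (rate λ) and the mineralized N is
flushed from the soil-column water volume Vw = n·s·V by recharge Q. The
solution is a two-exponential source function with mode rates λ
(mineralization-limited tail) and γ = Q/(s·n·V) (flushing). Assumptions:
complete cessation of fertilization on converted parcels, a single
well-mixed soil column, plant uptake and litter return folded into the
baseline. With the case-study parameters γ ≈ 0.86 1/y, so flushing is fast
and the λ mode controls the multi-year tail.

**Conversion patterns.** A conversion of fraction p of the area maps onto a
truncation of the TTD: frontal (converted tubes are those with
τ ≤ F⁻¹(p)), distal (τ ≥ F⁻¹(1−p)), random (independent Bernoulli(p)
flags, so the converted tubes reproduce the full TTD). Converted tubes
deliver Cs(t−τ) once their water arrives (τ ≤ t); everything else delivers
Cs0. The distal pattern therefore has a hard onset lag F⁻¹(1−p) before any
benefit appears.

## Parameters

| parameter | meaning | unit | packaged default | why |
|---|---|---|---|---|
| Mson0 | mineralizable legacy soil organic N | 100 kg/ha (held as 10 g/m²) | case study | ~6 kg/ha/y accumulation over ~70 y of intensive row crop, ~25% readily mineralizable |
| Cs0 | pre-change source-zone nitrate-N | 15 mg/L | case study | mid-range of tile-drainage/groundwater nitrate under corn–soybean rotations |
| λ | legacy depletion rate | 0.16 1/y | case study | matches groundwater chronosequence decline under converted parcels |
| Q | mean annual recharge | 129.5 mm/y (0.1295 m/y) | case study | site water balance |
| s, n, V | saturation, porosity, column depth | 0.5, 0.3, 1 m | case study | defines Vw and hence γ |
| μ | mean travel time (exponential TTD) | 21.6 y | case study | calibrated groundwater-flow-model particle tracking |
| k | denitrification rate band | 0.24 ± 0.08 1/y | case study | reported range for shallow till/outwash aquifers |
| p, pattern | converted fraction and spatial pattern | 0.41, random | case study | observed conversion extent; parcel availability drove the spatial pattern |

Internal unit canon: years, metres, g/m², g/m³ ≡ mg/L. Config files accept
kg/ha and mm/y and are converted on load.

## Numerical choices

* **Closed forms, stably.** The exponential-TTD scenario solutions contain
  coefficients c1 = (1+μk)/(1+μk−λμ) and c2 = (1+μk)/(1+μk−γμ) that
  diverge when σ = 1/μ + k equals λ or γ, though the solution itself stays
  finite. Every term is therefore evaluated through a single primitive,
  ∫ e^{−r(t−τ)−στ} dτ over a window, written so all exponents are ≤ 0 (no
  overflow) and the (r−σ) → 0 cancellation goes through `expm1`; the exact
  equality branch is the analytic t·e^{−λt} limit. No caller-visible
  threshold switching is needed, and the scenario-comparison parameter set
  (λ = 0.23, μ = 21.6 y, k = 0.18 1/y), which sits essentially on the
  σ = λ manifold, evaluates to full precision.
* **Degenerate source.** The source closed form itself is undefined when
  Q = λ·s·n·V (the two mode rates coincide). The default is an explicit
  `DegenerateParameterError`; an opt-in `degenerate="limit"` returns the
  analytic limit (Cs0 + (λ·Mson0/Vw)·t)·e^{−λt}. Silent near-singular
  arithmetic is the main hazard of the two-exponential form, so it is never
  papered over.
* **Quadrature.** The general-TTD engine uses adaptive quadrature
  (epsabs 1e−13, epsrel 1e−11) with the structural breakpoints (evaluation
  time, quantile split) passed to the integrator; unbounded exponential
  supports are cut where the decayed envelope e^{−στ} retains < ~1e−15 of
  its mass. Tabulated densities are piecewise-linear with an exact
  piecewise-quadratic CDF and a segment-wise quadratic-inversion quantile.
* **Root finding.** Lag inversions (time to a source-zone reduction, time
  to a CR target) expand brackets geometrically and locate the *first
  downward crossing* by linear scan before Brent refinement, because the
  source function is non-monotone when N > Cs0 (mineralization initially
  outruns flushing — true for λ = 0.23 with the case-study parameters).
  Absolute time tolerance 1e−8 y.
* **Ties and dominance.** Pareto extraction sorts by p ascending and keeps
  strict time improvements, so ties in time keep the smaller p (p is the
  cost proxy).
* **cr_t clipping.** Just after the distal onset with a rising source the
  ratio can exceed 1 by a few 1e−4 (physically: converted tubes briefly
  deliver more than Cs0); CR_t is clipped to [0, 1].

## Stream-tube Monte-Carlo oracle

The simulator draws τ_i from the TTD (one RNG stream; travel times first,
then Bernoulli flags for the random pattern only), applies the scenario's
conversion rule per tube, and flow-averages
[converted & arrived ? Cs(t−τ_i) : Cs0]·e^{−kτ_i} with equal discharge per
tube — the weighting implied by the analytic scenario integrals. Standard
errors of the ratio-of-means are delta-method estimates. The suite checks
the ensemble against the closed forms at 10⁶ tubes (3-SE criterion) and
verifies the 1/√n error scaling; runs are deterministic at fixed seed and
fixed ensemble size only.

## Synthetic data and what tests show

The fixture generator emulates the external inputs a real application
supplies: a tabulated TTD (a discretized exponential with μ = 21.6 y on
τ ∈ [0, 150] y, standing in for a flow-model export), a 13-year synthetic
"observed" outlet record (the full-legacy model trajectory for the packaged
configuration plus Gaussian noise, sd 0.3 mg/L), and a parameter file on
the σ = λ manifold. These reproduce the *structure* of real inputs — not
inter-annual hydrologic variability, spatially correlated conversion
patterns, measurement-method biases, or non-exponential TTD shapes of real
catchments — so passing tests demonstrate internal consistency of the
model chain and its numerics, not field validity of the parameters.

## Design choices

* The closed forms and the quadrature engine are independent code paths and
  are cross-checked property-style over randomized parameter sweeps (plus
  the Monte-Carlo oracle as a third route); the analytic path is the
  default for exponential TTDs.
* The distal closed form is implemented from direct integration of the
  scenario integral (branch value 1 before onset; continuity at the branch
  point holds to machine precision), with the subtracted exponential terms
  carrying e^{−σt} and the γ mode carrying e^{−γt}.
* CR_inf uses the t → ∞ closed forms for exponential TTDs and decayed-mass
  quadrature otherwise, avoiding slowly converging long-time trajectory
  evaluation; the random pattern returns exactly p by construction.
* Problem sizes in the test suite (10⁵–10⁶ Monte-Carlo tubes, 200-draw
  parameter sweeps, ~4000-knot tabulated grids) keep the full suite in the
  seconds range while leaving Monte-Carlo standard errors small enough for
  meaningful 3-SE comparisons.
* The library is the interface; the CLI is a thin convenience layer, with
  percentages in human output and fractions in machine output.

## Known limitations

* Time-invariant recharge, k and TTD; no inter-annual hydrologic
  variability.
* Complete-cessation sources only (the step and two-exponential forms);
  partial fertilizer reductions would need an extended source function.
* Spatially uniform k; no coupling between denitrification and carbon
  availability.
* The (p, μ) contour generator reproduces qualitative orderings of
  published contour surfaces; figure-read values from surfaces with
  incompletely specified source parameters are not reproduced exactly.
* No economic cost model: the converted fraction p is the cost proxy.
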