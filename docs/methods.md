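# Methods

## Retention model

The package assumes linear solvent strength (LSS) behaviour in
reversed-phase gradient LC: the retention factor of an analyte in a binary
mobile phase with strong-solvent volume fraction φ is
k(φ) = k_w·e^(−S·φ), with k_w the retention factor in pure weak solvent
and S the solvent-strength slope. Both are intrinsic to one combination of
analyte, stationary phase chemistry, mobile-phase pair and temperature;
changing any of these invalidates the parameters (temperature and
stationary-phase dependence are out of scope).

**Log convention.** `ln_kw` and `S` are stored in natural-log units,
because the retention law is written with a natural exponent. Much of the
chromatographic literature tabulates log₁₀ k_w with a base-10 slope;
convert such values by multiplying both by ln 10 ≈ 2.3026.

**Initial retention.** k₀ = exp(ln_kw − S·φ₀) — the retention factor in
the starting eluent, *including* k_w. This is the only definition
consistent with the retention law itself and with the magnitude k₀ ~ 10³
that makes the calibration expansion below work.

**Elution regimes.** A single linear ramp φ₀ → φ₀+Δφ over t_G, delayed by
the dwell time t_D, gives three cases, dispatched in `retention_time`:

1. *Pre-gradient elution* (t₀·k₀ ≤ t_D): the analyte exits before the
   gradient front can catch it inside the column, so elution is isocratic:
   t_R = t₀·(1+k₀). The front, travelling at the mobile-phase velocity,
   catches the analyte at fractional position t_D/(t₀·k₀); the condition
   is exactly that this exceeds the column length.
2. *In-ramp elution*: t_R = t₀·[1 + t_D/t₀ + (1/b)·ln(1 + b·(k₀ − t_D/t₀))]
   with b = Δφ·S·t₀/t_G, accepted when t_R ≤ t₀ + t_D + t_G (the ramp has
   not fully passed the outlet). S = 0 (b = 0) is handled by the analytic
   isocratic limit rather than division.
3. *Post-ramp elution*: the closed form does not model the 100%-B plateau
   that follows a real ramp, so analytes still retained when the ramp ends
   are integrated numerically (below) with φ clamped at φ₀+Δφ.

A non-positive logarithm argument raises a diagnostic error; it can only
arise from mutually inconsistent inputs, never from case 1, which is
dispatched first.

**Migration oracle.** `migrate_oracle` integrates the migration equation
dz/dt = u₀/(1+k(φ(t,z))) with φ(t,z) = φ₀ + Δφ·clip((t − t_D − z·t₀)/t_G, 0, 1),
using fixed-step classical RK4 and linear interpolation of the outlet
crossing. It is deliberately independent of the closed form: the test
suite checks agreement to < 10⁻³ min over 100 seeded parameter draws
(default step 10⁻³ min; the clip introduces derivative kinks that cap the
scheme's order locally, which the step size comfortably absorbs). The same
integrator serves as the production path for regime 3.

## Two-gradient parameter estimation

`fit_lss` solves t₁ = t_R(g₁; ln_kw, S), t₂ = t_R(g₂; ln_kw, S). For a
trial S, the in-ramp formula inverts in closed form for k₀ from (g₁, t₁),
eliminating ln_kw; the residual in t₂ is then one-dimensional in S. The
residual is scanned on a geometric grid over S ∈ [1, 100] (expanded by
factors of 10 if needed) and the bracketed sign change polished with
Brent's method. This is monotone, derivative-free and robust, which a raw
2-D Newton iteration on the original system is not. The system is exactly
determined (two equations, two unknowns); no least-squares pooling over
more than two gradients is attempted. Identical gradient programs raise a
degenerate-system error, and a steepness ratio max(b₁,b₂)/min(b₁,b₂) < 3
sets a warning flag (`check_steepness_ratio`) — below that ratio the
residual valley is shallow and noise amplification sets in.

## Affine autocalibration

First-order propagation of small instrument-parameter errors
(t₀ → t₀+δt₀, t_D → t_D+δt_D, b → b+δb) through the in-ramp formula shows
every predicted time moves as t_R → α·t_R + β with compound-independent
α, β, up to a term of order 1/k₀ that is discarded (k₀ ~ 10³ in gradient
work; the package never computes it). `fit_affine` estimates (α, β) by
unweighted ordinary least squares of *predictions on observations* —
the direction in which the model statement is written; at the R² ≈ 1
correlations where calibration is meaningful the choice of direction is
numerically immaterial, and no weighting scheme is imposed.
`apply_calibration` inverts the map: t_cal = (t_pred − β)/α.

Only compounds with experimental provenance should calibrate a mixed
library: calibrating with QSRR-predicted parameters injects their error
into every corrected time. The CLI accepts any calibrant list (the caller
controls eligibility); a single calibration fit is shared by experimental
and QSRR predictions.

## Annotation

For every (feature, adduct, compound) triple the two relative criteria are
|q·mz + m_add − m|/m < tol_mass and |t_obs − t_pred|/t_pred < tol_rt, both
*strict* (boundary hits excluded) and RT error normalised by the
*predicted* time. tol_rt is provenance-dependent: 0.5% for experimental
parameters (level 2+), 5% for QSRR (level 2) by default. tol_mass defaults
to 5 ppm, a configurable value typical of Orbitrap-class accuracy rather
than an intrinsic constant of the method. All passing triples are
reported — multiple adducts of one compound on one feature are not
deduplicated — sorted within a feature by √(rel_mass² + rel_rt²), ties by
compound id (the underlying match set is unordered; the sort only
stabilises output).

The built-in adduct registry holds the five positive-mode forms
[M+H]⁺, [M−H₂O+H]⁺, [M−2H₂O+H]⁺, [M−3H₂O+H]⁺, [M+Na]⁺ with shifts
assembled from the CODATA proton mass, monoisotopic water and the Na⁺ ion
mass (electron subtracted), and verified in the tests against an
independent isotope-mass table (pyteomics). The `mass_shift` sign
convention is neutral mass = charge·mz + mass_shift.

**Evaluation.** The success rate is (distinct true identities recovered by
at least one of their features) / (distinct true identities present in the
library); counting distinct identities rather than raw features keeps the
rate in [0, 1] when one standard yields several adduct features. The
misattribution rate is (annotations naming a compound other than the
feature's truth) / (all annotations over truth-bearing features). The
tolerance sweep applies each grid value to both provenance classes with
the mass tolerance fixed; the match count and the success rate are
monotone non-decreasing in the tolerance (asserted internally), the
misattribution rate need not be. Multiplicity statistics are computed per
*annotated* feature; a gamma distribution (location 0) is fitted by
maximum likelihood with method-of-moments starting values, and its
50/75/90% quantiles reported as interpolated percentiles. All-equal counts
short-circuit to that value (the MLE is undefined at zero variance).

## Synthetic scenarios

`SyntheticScenario` defaults describe the separation the engine was
characterised on and a steroid-like library: φ₀ = 0.02, Δφ = 0.98,
t_G = 14 min, t₀ = 0.8 min, t_D = 0.75 min (a 0.375 mL dwell volume at
0.5 mL/min); masses uniform on 250–500 Da; ln_kw ~ U(5, 11),
S ~ U(15, 40), which keeps k₀ above exp(4.2) ≈ 67 everywhere and near 10³
typically; retention-time noise SD 0.005 min (UHPLC run-to-run
reproducibility); 20% of compounds in isomer clusters of 2–3 sharing an
exact mass. Decoy features are placed with neutral masses in 600–900 Da,
disjoint from the library window, so they are unmatchable by construction
(deterministic, no rejection sampling). Randomness uses NumPy's PCG64
generator with CRC32-keyed substreams per stage, so a fixed seed gives
identical output across platforms.

What the generator does *not* emulate: ionisation efficiency and abundance,
peak shapes and co-elution artefacts, isotope envelopes, adduct
cross-talk in peak picking, and QSRR parameter error structure (QSRR rows
differ only by their provenance flag). Passing closed-loop tests therefore
demonstrates correctness of the matching and calibration machinery under
the model's own assumptions, not field performance on real samples.

## Benchmark protocol

`lssannot.benchmarks.calibration_benchmark` measures calibration efficacy:
70 compounds, observed times from the true gradient, predictions with t₀,
t_D and t_G each scaled by 1.03, five calibrants at the 10/30/50/70/90th
percentiles of the observed elution order, affine correction applied to
the 65 held-out compounds. Note that scaling all three time parameters
uniformly is an *exact* global time dilation (b is unchanged), so the
affine fit removes it to rounding error; the protocol demonstrates the
best case the autocalibration is designed for, while the mixed
perturbation used elsewhere in the test suite (t_G scaled inversely,
changing b) exercises the first-order-only regime. Problem sizes
throughout the suite (70-compound libraries, 200-feature fixtures, 100
oracle draws, 10⁴ gamma draws) are chosen to pin the statistics down while
keeping any single check in the seconds range.

## Annotation JSON schema (version 1.0)

Top level: array, one entry per input feature, in input order.

```json
{
 "feature": {"mz": 321.592, "rt": 3.51073},
 "matches": [
  {"compound_id": "...", "name": "...", "adduct": "[M+H]+",
   "level": "2plus" | "2", "predicted_rt_min": 3.51073,
   "rel_mass_error_ppm": 0.0, "rel_rt_error_pct": 0.0,
   "metadata": {"iupac": "...", "cas": "...", "smiles": "...",
                 "pathway": "...", "xrefs": "..."}}
 ]
}
```

Floats carry 6 significant digits; keys are sorted; output is byte-stable
for identical inputs. Units: minutes, ppm and percent as the key names
state.

## Known limitations

- Single-ramp gradients only; multi-segment programs are not modelled
  (the post-ramp plateau is handled, a second ramp is not).
- The quadratic (curved) extension of the LSS law is not implemented;
  strongly non-LSS analytes will show systematic prediction error that
  calibration cannot remove.
- QSRR parameter *generation* is out of scope; QSRR rows are consumed as
  data with a provenance flag.
- Feature detection, isotopic-pattern scoring and MS/MS matching are
  upstream/downstream of this package.
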