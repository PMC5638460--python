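# Methods

This note documents the models, estimators, numerical choices and known
limitations of hemolig. It is written for users who need to judge whether
the defaults fit their data, and what the test suite does and does not
establish.

## Spectral species decomposition

A measured Soret-region spectrum is modelled as
S(λ) = Σ_k c_k R_k(λ) + b with c_k ≥ 0 and b an unconstrained constant.
The references R_k are pure-species spectra (oxy, deoxy, met) on a common
wavelength grid; the default fitting window is 380–500 nm, where the three
species differ most. Nonnegativity is physical — species concentrations
cannot be negative — and is enforced by bounded-variable least squares
(`scipy.optimize.lsq_linear`, method `bvls`), not by clipping an
unconstrained solution, because clipping biases the remaining coefficients.
The baseline is a single wavelength-independent offset; sloped baselines are
out of scope. A basis whose references are collinear (identical up to scale)
is rejected up front, since the coefficient split would be arbitrary.

Fractional saturation is Y = c_oxy/(c_oxy + c_deoxy). The met coefficient
is reported but excluded from Y: ferric hemes do not bind O₂ and oxidation
is treated as a separate correction. During oxygenation runs the met
coefficient is left free rather than fixed at zero, so slow oxidation during
a titration shows up in the output instead of distorting the oxy/deoxy
split.

## Hill fitting

The Hill equation Y = pO₂ⁿ/(P₅₀ⁿ + pO₂ⁿ) is fitted on the untransformed
saturation scale by Levenberg–Marquardt/TRF least squares
(`scipy.optimize.curve_fit`). The classical linearised Hill plot,
log₁₀[Y/(1−Y)] vs log₁₀ pO₂, distorts the error structure (errors on Y near
0 or 1 blow up on the logit scale) and is used only to initialise: its
slope starts n, and log-linear interpolation to Y = 0.5 starts P₅₀. Bounds
are P₅₀ ∈ (0, 1000] Torr and n ∈ [0.3, 6]; standard errors come from the
Jacobian at the optimum. Curves whose saturations all lie on one side of
0.5 yield an extrapolated P₅₀ and are flagged with a warning rather than
rejected, since low- and high-affinity extremes (e.g. low pH + ATP) can
push the measurable window off-centre.

Heme concentrations use ε = 13.4 mM⁻¹cm⁻¹ (mean of A540 and A569 of the
ferrous CO adduct) or ε = 150 mM⁻¹cm⁻¹ at the 405 nm Soret maximum, per
heme. Temperatures are kelvin internally; Celsius is converted with 273.15
at the interfaces.

## Thermodynamic linkage

Two-point formulas are the default (matching how such tables are computed);
with more than two points, ordinary least squares on the linearised axes
(log₁₀P₅₀ vs pH or 1/T) is used, which reduces exactly to the two-point
form for n = 2. The van't Hoff constant is kept at the printed precision
4.574 (= R·ln10 in cal mol⁻¹ K⁻¹) rather than re-derived, so that reported
enthalpies match tabulated digits. ΔH_corrected = ΔH_raw + 3 kcal/mol
removes the heat of O₂ solubilisation (−3 kcal/mol). ΔH is symmetric under
exchange of the two (P₅₀, T) pairs — both the temperature factor and
Δlog P₅₀ change sign — and the implementation preserves this exactly.

`extrapolate_p50` fits log₁₀P₅₀ against 1/T at an anchor pH, evaluates at
the target temperature, and applies a Bohr shift φ·(target pH − anchor pH).
Both plots are treated as linear; this is an extrapolation, valid only as
far as linearity holds (for these hemoglobins, demonstrated over 15–25 °C
and pH 6.7–7.8). Rounding to one decimal happens only in the report layer.

Note that Bohr coefficients recomputed from *rounded* tabulated P₅₀ pairs
can differ from independently tabulated φ values by 0.1 or more; the
package always reports what it computes from its inputs and does not force
agreement.

## Flash-photolysis kinetics

The model is fixed at two stretched-exponential geminate components plus
two exponential bimolecular components; no model selection is performed (a
1-geminate variant is available via `n_geminate=1` for low-SNR traces).
Parameter bounds keep the phases separated and prevent label swapping:
β ∈ (0.3, 1], geminate τ ∈ [10⁻⁹, 10⁻⁴] s, bimolecular apparent rates
∈ [1, 10⁶] s⁻¹. R is identified as the faster bimolecular component; the
`RebindingModel` constructor relabels (swaps) R/T if given the other order.

Traces are assumed log-spaced in time and weighted uniformly, which
equalises leverage across the ~8 decades from 10 ns to 1 s (standard
flash-photolysis practice). Fitting uses lmfit/least-squares on log₁₀ of
the time constants and rates for conditioning, with a deterministic
initialisation: a crude two-exponential peel of the tail (t ≥ 10⁻⁴ s)
seeds the bimolecular phase, and the residual early amplitude seeds the
geminate terms at τ = 100 ns / 1 μs, β = 0.9.

Degenerate traces with a single bimolecular component are an identifiability
limit: the two exponential rates collapse and the amplitude split between
them becomes a flat direction of the objective. When the fitted rates agree
within 5 %, the amplitudes are merged into the fast (R) component and a
warning is attached; without this, the solver cannot reach its tolerances
and the reported 50/50 split would be an artefact of the parameterisation.

`global_fit` shares the geminate lifetimes/stretches and the bimolecular
rate *constants* k_on,R and k_on,T across traces, constraining each trace's
apparent rates to k_on·[CO]; amplitudes stay free per trace, because
allosteric effectors (ATP, urea, pH) shift the R/T populations, not the
rate constants. [CO] comes from Henry's law with a bundled aqueous
solubility table (9.8×10⁻⁴ M atm⁻¹ at 25 °C, 1.06×10⁻³ at 20 °C,
1.15×10⁻³ at 15 °C; linear interpolation, overridable). Every k_on output
records the [CO] used.

## Displacement and autoxidation

Displacement traces are fitted to A(t) = A_∞ + ΔA·e^(−t/τ); k_off,R = 1/τ,
with the standard error propagated by the delta method. The offset makes
the estimate invariant under affine transformation of the absorbance axis.
Traces spanning fewer than 3 lifetimes are fitted but flagged.

Autoxidation series are converted to met fractions by two-component
unmixing (oxy + met + offset) and k_ox is the OLS slope over points with
met fraction ≤ 10 % conversion. Within that window 1 − e^(−kt) deviates
from its tangent by < 6 %, so the initial-slope estimator carries a small
systematic *underestimate* of k_ox of that order (shrinking the window
trades bias for variance; the window is configurable and reported). The
default window follows the convention of fitting only the "initial phase";
no mechanistic rate law (pH dependence, superoxide chemistry) is modelled.

## Synthetic data

The generators produce every input type with the statistical structure the
estimators assume, so the whole pipeline is testable without instrument
data:

- equilibrium curves: 5 saturation steps evenly spaced in Y over
  [0.2, 0.8], pO₂ from the exact Hill inverse, Gaussian noise (sd 0.01) on
  Y only;
- photolysis traces: 40 points/decade over 10⁻⁸–1 s, normalised to the
  first sample, Gaussian noise sd 0.01 on N;
- displacement: 500 linear samples, amplitude 0.5 AU over offset 0.4 AU;
- autoxidation: met fraction 1 − e^(−k_ox t) every 30 min for 20 h;
- reference spectra: Gaussian-band sums on a 1 nm grid with Soret maxima at
  415 (oxy), 430 (deoxy) and 405 nm (met), absorbance noise sd 0.002 AU.

Noise is additive, Gaussian and homoscedastic per signal type — a
deliberate simplification; real detectors show shot-noise scaling,
baseline drift and correlated errors, none of which are emulated. Geminate
parameters (8 % total amplitude, τ = 100 ns and 1 μs, β = 0.8) are
declared assumptions of the generator: published kinetic tables report only
the bimolecular phase, and "small geminate amplitude" is the only available
constraint. Passing round-trip tests therefore demonstrates estimator
correctness under the assumed noise model, not robustness to every
instrument artefact.

The bundled presets carry the measured 25 °C/pH 7.4 parameter sets of the
three Greenland-shark Hb isoforms (P₅₀/n_H ± ATP, k_off,R, k_ox, R/T
fractions, k_on,R/k_on,T), plus the 15 °C and pH 6.7 equilibrium values
used by the linkage stage, so the pipeline can emit synthetic analogues of
the study's summary tables. All generators are pure functions of their
arguments including the seed (`numpy.random.default_rng`), and the pipeline
spawns per-stage seeds from a single root seed, making reports
byte-reproducible.

## Problem sizes in the validation suite

Monte-Carlo checks use 200 replicates for Hill and k_off recovery and 100
replicates for R/T-fraction recovery; the R/T study fits a (1, 0.1) atm CO
pair globally per replicate, mirroring the global-analysis protocol under
which those fractions are defined. The brute-force unmixing oracle runs on
30-wavelength instances with a coarse-then-fine exhaustive grid
(step 0.05 over [0, 1.5]³, refined at 10⁻³ around the coarse minimum),
against which the solver agrees to within the fine grid step.

## Known limitations

- No Adair/MWC equilibrium models and no Torr↔molar O₂ conversion; the
  Hill fit is an empirical summary, not a mechanistic model.
- No instrument-response deconvolution, transient-spectra SVD, or
  master-equation R/T relaxation modelling; the 2+2-component decomposition
  is the fixed kinetic description.
- The single-trace R/T amplitude split is poorly conditioned when
  k_R/k_T ≲ 4; use `global_fit` across CO pressures whenever possible.
- Linkage extrapolations inherit the linearity assumptions of the van't
  Hoff and Bohr plots and should not be pushed far outside the calibrated
  ranges.
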