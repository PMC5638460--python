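# hemolig

Analysis toolkit for the equilibrium and kinetic characterisation of
hemoglobin–ligand binding, built around the assays used to study the
hemoglobin system of the Greenland shark *Somniosus microcephalus*: thin-layer
O₂-equilibrium curves, Soret-band spectral decomposition, laser flash
photolysis of the CO adduct, stopped-flow O₂→CO displacement, and
autoxidation time courses. It is aimed at comparative physiologists and
protein biophysicists who need a reproducible path from raw instrument-style
traces to the derived quantities those studies tabulate: P₅₀ and n_H, Bohr
coefficients and O₂-linked proton release, van't Hoff oxygenation enthalpies,
R/T-state populations and bimolecular rate constants, k_off,R and k_ox.

## Models

**O₂ equilibrium.** Fractional saturation follows the Hill equation
Y = pO₂ⁿ / (P₅₀ⁿ + pO₂ⁿ), fitted by nonlinear least squares on the
saturation scale (the Hill plot is used only to initialise). Saturations are
obtained from absorbance spectra by nonnegative linear unmixing against oxy,
deoxy and met reference spectra plus a constant baseline offset;
Y = c_oxy / (c_oxy + c_deoxy).

**Thermodynamic linkage.** The Bohr coefficient is φ = Δlog₁₀P₅₀/ΔpH, with
≈ 4·|φ| O₂-linked protons released per tetramer. The oxygenation enthalpy
between two temperatures is ΔH = −4.574·[T₁T₂/(T₁−T₂)]·Δlog₁₀P₅₀/1000
kcal/mol (4.574 = R·ln10 in cal mol⁻¹ K⁻¹), reported after removing the
−3 kcal/mol heat of O₂ solubilisation. Because van't Hoff
(log₁₀P₅₀ vs 1/T) and Bohr (log₁₀P₅₀ vs pH) plots are linear over the
working ranges, P₅₀ can be extrapolated to temperatures outside the
instrument's range (e.g. 0 °C for a polar species).

**Flash-photolysis kinetics.** The post-photolysis deoxy fraction is
modelled as two stretched-exponential geminate terms plus two exponential
bimolecular terms,
N(t) = Σᵢ Aᵢ·exp[−(t/τᵢ)^βᵢ] + A_R·e^(−k_R t) + A_T·e^(−k_T t),
where the fast/slow bimolecular components are rebinding to R- and T-state
tetramers. f_R = 100·A_R/(A_R+A_T) measures the extent of the R→T switch,
and k_on = k_app/[CO] (Henry's-law conversion from CO pressure) gives the
bimolecular rate constants. A global fit across CO pressures and ±effector
conditions shares all rate parameters and frees only the amplitudes.

**Displacement and autoxidation.** O₂→CO displacement traces are
mono-exponential with rate k_off,R; autoxidation is quantified as the OLS
slope of the met fraction (from two-component spectral unmixing) over the
initial ≤10 % of conversion.

## Worked example

```python
import hemolig as h

# equilibrium: generate a 5-step curve for the ATP-bound isoform and fit it
curve = h.simulate_equilibrium_curve(P50=14.4, n=1.8, noise_sd=0.01, seed=7)
fit = h.fit_hill(curve)
print(f"P50 = {fit.P50:.2f} Torr, nH = {fit.nH:.2f}")
# P50 = 14.50 Torr, nH = 1.77

# linkage: enthalpy and 0 C extrapolation from a 15/25 C P50 pair
raw, corrected = h.vant_hoff_dH(5.5, 298.15, 2.9, 288.15)
grid = h.P50Grid([(298.15, 7.4, False, 5.5), (288.15, 7.4, False, 2.9)])
print(f"dH = {corrected:.1f} kcal/mol, "
      f"P50(0 C) = {h.extrapolate_p50(grid, 273.15, 7.4):.1f} Torr")
# dH = -7.9 kcal/mol, P50(0 C) = 1.0 Torr

# kinetics: global fit of a CO-pressure pair, shared rate constants
preset = h.PRESETS["hb1_stripped"]
traces = [h.simulate_photolysis_trace(preset.rebinding_model(a), co_atm=a,
                                      condition=preset.condition())
          for a in (1.0, 0.1)]
gf = h.global_fit(traces)
fR, fT = h.rt_fractions(gf.models[0])
print(f"R = {fR:.0f}%, T = {fT:.0f}%, kon_R/kon_T = {gf.kon_R/gf.kon_T:.1f}")
# R = 84%, T = 16%, kon_R/kon_T = 3.9
```

The printed numbers mean: the ATP-bound isoform half-saturates at ~14 Torr
with moderate cooperativity; oxygenation of the stripped protein is
exothermic by ~8 kcal/mol so its O₂ affinity rises steeply toward 0 °C
(P₅₀ ≈ 1 Torr); and after photolysis 84 % of the bimolecular phase rebinds
to R-state molecules, whose CO on-rate exceeds the T-state's 3.9-fold.

A command-line interface mirrors the library:

```bash
hemolig simulate --scenario hb1_atp --seed 42 --out fixtures/
hemolig hill --curve fixtures/equilibrium.csv --config fixtures/condition.yaml --out fit.json
hemolig pipeline --seed 1 --out reports/
```

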