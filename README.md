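# quenchbind

Analysis toolkit for protein–ligand binding studied by intrinsic
fluorescence quenching, built around the hemoglobin–nilvadipine system: a
tryptophan donor (λex 295 nm, emission band near 340 nm) titrated with an
absorbing drug at several temperatures.

The package covers the standard workflow end to end:

- **Inner-filter correction** — F_corr = F_obs · 10^((A_ex + A_em)/2).
- **Stern–Volmer analysis** — OLS of F₀/F = 1 + K_SV[Q]; bimolecular rate
  constant k_q = K_SV/τ₀ (τ₀ = 5.71 ns) and a static/dynamic mechanism call
  from the temperature trend of K_SV and the diffusion limit (~10¹⁰ M⁻¹s⁻¹).
- **Modified Stern–Volmer binding fit** — OLS of
  log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q] for the association constant K_a
  and binding-site number n.
- **van't Hoff thermodynamics** — ln K_a vs 1/T gives ΔH° (−slope·R) and
  ΔS° (intercept·R) with R = 1.987 cal K⁻¹ mol⁻¹; ΔG° = −RT ln K_a per
  temperature; Ross–Subramanian force classification; hemoglobin-bound drug
  fraction f = K_a·C/(1 + K_a·C).
- **FRET** — overlap integral J = ∫Fε λ⁴dλ / ∫Fdλ (λ in cm, J in M⁻¹cm³),
  Förster radius R₀⁶ = 8.79×10⁻²⁵·κ²·n⁻⁴·φ·J, efficiency E = 1 − F/F₀,
  distance r = R₀((1−E)/E)^(1/6), and the 0.5R₀ ≤ r ≤ 1.5R₀ validity window.
- **Conformational probes** — Soret-band peak shifts, synchronous-scan
  (Δλ = 15/60 nm) summaries, and EEM peak picking with Rayleigh-scatter
  masking and percent-of-reference tables.
- **Synthetic data** — seeded generators for titrations, donor/acceptor
  spectral pairs, per-concentration emission scans, and two-peak EEMs, so
  every stage is testable against known ground truth.

The regression steps are scikit-learn-style estimators
(`SternVolmerRegression`, `ModifiedSternVolmerRegression`,
`VantHoffRegression`) with `fit`/`predict` and fitted attributes
(`K_sv_`, `K_a_`, `dH_kcal_per_mol_`, …); the module-level functions wrap
them for titration-series inputs.

## Worked example

```python
from quenchbind import vant_hoff_fit, forster_radius, bound_fraction

# association constants (M^-1) measured at three temperatures
thermo = vant_hoff_fit([(298, 0.3380e4), (303, 0.6467e4), (310, 1.4667e4)])
print(f"dH = {thermo.dH_kcal_per_mol:.2f} kcal/mol")
print(f"dS = {thermo.dS_cal_per_mol_K:.2f} cal/(mol K)")
print(f"force class: {thermo.force_class}")
for pt in thermo.per_temperature:
    print(f"  {pt.T_K:.0f} K  dG = {pt.dG_kcal_per_mol:.2f}  TdS = {pt.TdS_kcal_per_mol:.2f} kcal/mol")
print(f"R0 = {forster_radius(1.854e-14):.4f} nm")
print(f"Hb-bound fraction = {100 * bound_fraction(0.6467e4, 2.3e-3):.1f}%")
```

prints

```
dH = 22.42 kcal/mol
dS = 91.39 cal/(mol K)
force class: hydrophobic
  298 K  dG = -4.81  TdS = 27.23 kcal/mol
  303 K  dG = -5.28  TdS = 27.69 kcal/mol
  310 K  dG = -5.91  TdS = 28.33 kcal/mol
R0 = 2.7253 nm
Hb-bound fraction = 93.7%
```

Binding is endothermic and entropy-driven (ΔH°, ΔS° > 0 — hydrophobic
contacts dominate), spontaneous at all three temperatures (ΔG° < 0), the
donor–acceptor pair sits at a Förster radius of ~2.7 nm, and at whole-blood
hemoglobin concentration (2.3 mM) about 94% of free drug is sequestered.

## Command line

```sh
quenchbind simulate --config sim.yaml    # synthetic dataset + manifest
quenchbind quench   --config quench.yaml # sv_fits / binding_fits / thermo CSVs + mechanism call
quenchbind fret     --config fret.yaml   # J, R0, E, r, validity
quenchbind eem      --config eem.yaml    # EEM peak table vs a reference
```

Configs are YAML mappings (`output_dir`, input paths, and optional
assumption overrides such as `tau0_s`, `kappa2`, `refr_index`, `phi`,
`correct_ife`); every run writes a `run_header.json` recording the
assumptions used.

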