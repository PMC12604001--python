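# Methods

## Model and assumptions

The package analyses steady-state fluorescence quenching of a protein donor
(tryptophan, λex 295 nm, emission band near 340 nm) by a titrated ligand,
under the static-quenching picture: a non-fluorescent ground-state complex
forms with association constant K_a, so intensity falls with ligand
concentration while the excited-state lifetime is untouched. All fits are
ordinary least squares on the linearised forms conventional in this field;
uncertainties are OLS standard errors.

**Inner-filter correction.** Observed intensities are corrected as
F_corr = F_obs·10^((A_ex+A_em)/2), where A_ex and A_em are the ligand's
absorbances at the excitation and emission wavelengths. The zero-ligand
reference F₀ receives the identical treatment (trivially a no-op there),
so the F₀/F ratio is unbiased. The correction assumes a centred 1 cm
cuvette and absorbances well below ~2.

**Stern–Volmer.** F₀/F = 1 + K_SV[Q], fitted over the points with [Q] > 0
plus the anchoring reference ratio of 1 at [Q] = 0. The intercept is left
free rather than forced to 1: a free intercept is how published K_SV ± SE
values arise, and its deviation from 1 (flagged beyond ±0.1) is a useful
curvature/offset diagnostic. k_q = K_SV/τ₀ with τ₀ = 5.71 ns by default
(the donor lifetime without quencher). Points brighter than F₀ at [Q] > 0
("anti-quenching", possible at low noise levels) are retained here with a
warning — the linear form remains defined for them.

**Modified Stern–Volmer.** log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀[Q]. The
logarithm base is base-10, the standard double-log convention, so the
intercept gives K_a directly as 10^intercept. Points with F ≥ F₀ have no
defined transform and are excluded with a warning; at least three usable
points are required. K_a's standard error follows from the intercept SE by
the delta method (SE·K_a·ln10).

**Mechanism call.** Static if every k_q exceeds the diffusion-controlled
limit (10¹⁰ M⁻¹s⁻¹ by default) or K_SV strictly decreases with temperature
(two or more temperatures); dynamic if k_q stays at or below the limit and
K_SV strictly increases; ambiguous otherwise. Every triggered criterion is
recorded verbatim in the call's evidence list — the caller sees *why*, not
just the label.

**van't Hoff.** ln K_a = −ΔH°/(R·T) + ΔS°/R fitted against 1/T, with
R = 1.987 cal K⁻¹ mol⁻¹. This calorie-based constant (not 8.314 J) is the
convention of the quenching literature this package serves; energies are
kcal/mol and entropies cal/(mol·K) throughout. The fit assumes ΔH° constant
over the (narrow, 298–310 K) range; a ΔCp-resolved non-linear van't Hoff is
out of scope. ΔG° is reported per temperature from −RT ln K_a — the path
used for published tables — while ΔH° − TΔS° is carried as a separate
cross-check field; on a consistent dataset the two agree within the fit's
residual scale (≤ 0.02 kcal/mol on the three-temperature reference data).

**Force classification.** Ross–Subramanian sign rules: ΔH°>0 ∧ ΔS°>0 →
hydrophobic; ΔH°<0 ∧ ΔS°<0 → hydrogen bond / van der Waals; ΔH°≈0 ∧ ΔS°>0
→ electrostatic; anything else → mixed. "≈0" needs a concrete cut; we use
|ΔH°| < 1 kcal/mol, comfortably below the magnitude of genuinely
enthalpy-driven systems while wide enough to catch near-athermal binding.

**Bound fraction.** f = K_a·C/(1 + K_a·C) for a binder at concentration C
(e.g. tetrameric hemoglobin at 2.3 mM in whole blood). Single-site binding
with ligand ≪ binder, so binder depletion is ignored.

**FRET.** J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ evaluated by trapezoidal quadrature
on the union of the two wavelength grids restricted to their common
interval; λ is converted to cm internally so J carries M⁻¹cm³ — the
8.79×10⁻²⁵ prefactor of R₀⁶ = 8.79×10⁻²⁵·κ²·n⁻⁴·φ·J presumes exactly that
unit system. The donor normalisation makes J invariant to emission
rescaling, so emission spectra may be in arbitrary units; the acceptor
spectrum must be absolute molar absorptivity (a normalised absorbance curve
is rejected — divide by concentration × path length first). No
extrapolation is performed anywhere: disjoint supports give J = 0 with a
warning rather than an invented overlap. Defaults κ² = 2/3 (isotropic
dipole averaging), n = 1.33 (aqueous buffer), φ = 0.118 (tryptophan donor
quantum yield); all three are explicit parameters because they are
assumptions, not constants. E = 1 − F/F₀ and r = R₀((1−E)/E)^(1/6) are
exact mutual inverses; the result object enforces
E = R₀⁶/(R₀⁶ + r⁶) to 10⁻⁹ relative. Validity reporting checks the closed
interval 0.5R₀ ≤ r ≤ 1.5R₀ and the practical 2–8 nm FRET window.

**Peak analysis.** Peaks are the argmax on the sampled grid — with 1–10 nm
instrument steps, sub-sample (parabolic) refinement would be false
precision — and ties break toward the shorter wavelength. Percent-of-
reference values are kept at full precision internally and rounded to one
decimal only at report time. EEM peak picking masks the first-order
(|λem−λex| < 20 nm) and second-order (|λem−2λex| < 20 nm) Rayleigh ridges
(half-width configurable; instruments and gratings differ), then takes 3×3
local maxima above a relative prominence floor (5% of the brightest
unmasked cell by default). The floor exists because cells hugging the mask
boundary can register as spurious local maxima of the truncated landscape,
and it simultaneously suppresses noise-floor bumps; nearby candidates
within 20 nm on both axes merge into the stronger one.

## Synthetic data: what it emulates, and what it does not

The generator produces the assay the analysis assumes: protein at 5 μM,
ligand 0–50 μM in 11 steps, temperatures 298/303/310 K, F₀ = 1000 a.u.
Affinity follows K_a(T) = exp(−ΔH°/(R·T) + ΔS°/R) with defaults
ΔH° = 22.42 kcal/mol, ΔS° = 91.39 cal/(mol·K) (an entropy-driven,
hydrophobically bound system; K_a ≈ 3.4–14.7×10³ M⁻¹ across the range);
alternatively a fixed K_a may be pinned for single-temperature studies.
Quenching follows the modified-SV functional form (F₀−F)/F = K_a[Q]^n
directly — deliberately the model the analysis fits, so noiseless recovery
is exact by construction and any deviation is an implementation defect, not
model error. Ligand absorbances grow linearly with concentration
(ε_ex = 4×10³, ε_em = 1×10³ M⁻¹cm⁻¹, 1 cm path, peaking at A_ex = 0.2 at
50 μM), and the emitted intensity is pre-attenuated by the inner-filter
factor so the correction inverts it exactly. Multiplicative Gaussian noise
(sd = `noise_rel_sd`, default 0) is applied last. The FRET pair is a
unit-height Gaussian donor (340/15 nm) and a Gaussian acceptor
(358/30 nm, peak ε = 1.7×10⁴ M⁻¹cm⁻¹) chosen once to land the overlap
integral near 1.9×10⁻¹⁴ M⁻¹cm³ and R₀ near 2.7 nm — the scale of a
tryptophan/dihydropyridine pair. EEMs hold two Gaussian features, an
aromatic side-chain band at (280, 334) nm and a peptide-backbone band at
(230, 326) nm, with amplitudes 1046 and 523 a.u., quench factors and
emission shifts programmable per peak, over a small seeded uniform noise
floor (0.2 a.u.).

Because the generator shares the analysis's functional form, passing
recovery tests demonstrates correctness of the estimation chain, **not**
robustness to model misspecification in real data: no ligand depletion
(free ≈ total ligand), no baseline drift or scatter in 1-D spectra, no
wavelength-dependent instrument response, no heteroscedastic detector
noise, and the emission blue shift (capped at 3 nm, linear in
concentration) is a rigid translation rather than a band-shape change.

All randomness flows from a single `numpy.random.default_rng(seed)` stream
per generator call — reproducibility over parallelism.

## Numerical choices

- OLS via `scipy.stats.linregress`; slopes and intercepts carry its
  standard errors. Degenerate inputs (constant response) report r² = 1 with
  zero slope rather than NaN.
- Trapezoidal quadrature (`numpy.trapezoid`) on union-refined grids;
  halving a smooth fixture's step moves J by < 10⁻⁴ relative.
- Linear interpolation only, never extrapolation; resampling onto a grid
  containing original nodes preserves their values exactly.
- Spectrum files are delimiter-auto-detected (comma/tab/whitespace),
  decimal-point only; duplicate wavelengths are an error, unordered rows
  are sorted.
- k_q = K_SV/τ₀ is computed, never stored independently, so the identity
  holds to machine precision.

## Known limitations

- K_a from the double-log intercept is intrinsically noise-amplified: the
  intercept sits at [Q] = 1 M, ~5 decades outside a micromolar titration
  window, so percent-level intensity noise produces order-of-magnitude
  scatter in single-titration K_a estimates (the directly fitted slopes
  K_SV and n remain accurate to a few percent). Replicated titrations or
  non-linear fitting in the native domain would be needed for tight K_a
  confidence intervals; the linearised estimator is retained because it is
  the method this workflow standardises.
- Static quenching is inferred, not proven: lifetime-resolved data are the
  definitive discriminator and are out of scope.
- Single-site, non-depleting binding model throughout; no cooperative or
  multi-site isotherms.
- CD spectra are read as generic curves only; secondary-structure
  deconvolution is out of scope, as are docking and MD.
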