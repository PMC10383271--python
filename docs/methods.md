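# Methods

This note records the models, parameter choices, and numerical decisions
behind `plasmabind`, and what the synthetic-data round trips do and do
not demonstrate about real instrument data.

## Quenching model and inner-filter correction

Observed intensities at the emission maximum are corrected for the
inner-filter effect multiplicatively, F_corr = F_obs·10^((A_ex+A_em)/2),
with A_ex and A_em the sample absorbances at the excitation and emission
wavelengths.  The correction factor is independent of intensity and
strictly increasing in total absorbance; a negative absorbance is
rejected as invalid input.

The Stern–Volmer analysis fits F0/F_corr = 1 + K_sv[Q] by ordinary least
squares with a *free* intercept.  Pinning the intercept to 1 would hide
calibration problems; instead a drift |intercept − 1| > 0.1 is surfaced
as a quality warning.  The quencher concentration [Q] is the total added
ligand; depletion of free ligand by binding is ignored, which is the
same approximation the double-log binding law itself makes, so generator
and fit share one model by construction.

The mechanism classifier is rule-based: *static* requires K_sv strictly
decreasing with temperature (relative tolerance 1e-3 to absorb float
noise) and every k_q = K_sv/τ0 above the diffusion-controlled collisional
ceiling (default 2×10¹⁰ dm³ mol⁻¹ s⁻¹); *dynamic* requires the opposite
pattern; anything else is reported as ambiguous with the failing
criterion named, and a single temperature as indeterminate.  τ0 defaults
to 1×10⁻⁸ s, the standard order of magnitude for intrinsic tryptophan
fluorescence; it is configurable everywhere it appears.

A consequence worth stating: binding constants of order 10–100 dm³/mol
(as reported for the glycoprotein complexes here) give k_q ≈ 10⁹
dm³ mol⁻¹ s⁻¹ at micromolar concentrations, *below* the collisional
ceiling, so the classifier honestly returns "ambiguous" for those
complexes even when K_sv decreases with temperature.  The pipeline
reproduces the arithmetic of such fits as printed sources do; it does
not adjudicate their physical consistency.

## Binding constant and stoichiometry

log₁₀((F0−F)/F) is regressed on log₁₀[Q] over the inner-filter-corrected
points; K_b = 10^intercept and n = slope.  The Q = 0 reference is
excluded (its logarithm is undefined), as is any point with F ≥ F0 at
Q > 0 (excluded with a warning; at least three usable points are
required).  Base-10 logarithms are used throughout; the estimates are
invariant to the base.  |n − 1| > 0.2 flags non-1:1 binding (threshold
configurable).  With n = 1 and noiseless static data the double-log K_b
equals the Stern–Volmer K_sv identically, which the tests assert.

A conditioning caveat: on the micromolar titration grid the intercept
log₁₀K_b lies about six decades outside the sampled log₁₀[Q] range, so
intensity noise in the slope is amplified ~10⁶-fold into K_b.  Noiseless
round trips are exact regardless, but the stochastic recovery checks
(1% multiplicative noise, fixed seeds, K_b within 10%, n within 0.1) are
run on a grid with [Q] of order 0.1 mol/dm³, where the intercept sits
near the data and the check measures estimator accuracy rather than
extrapolation conditioning.

## van't Hoff thermodynamics

ln K_b is regressed on 1/T: ΔH° = −slope·R, ΔS° = intercept·R, with
R = 8.314 J mol⁻¹ K⁻¹.  The natural logarithm is the dimensionally
consistent choice and is the default; a strict decadic-log audit mode
(`log_base="10"`) is available for comparison against sources that print
the law with "log".  ΔG°(T) = ΔH° − TΔS°; when the fit is exact this
coincides with −RT ln K_b(T) to 1e-9 relative, an identity the tests
verify.  Force classification follows the Ross–Subramanian sign rules
with a near-zero enthalpy tolerance of 5 kJ/mol (evaluated before the
sign rules); energies are SI joules internally.

## Site-marker displacement

Percent replacement 100·(F0−F)/F0 is computed on raw marker intensities
— no inner-filter correction is applied in this assay, which tracks a
marker's emission rather than the protein's.  Negative values
(enhancement) and non-monotone profiles are legal data and are surfaced
as quality notes.  Site assignment compares markers of one protein at
the largest ratio common to all profiles (configurable); a margin below
2 percentage points is a tie (indeterminate).  Default ratio ladders
follow the assay designs: 1:0–1:10 in 8 steps for the albumin markers,
9 steps (including 1:6 and 1:8) for the glycoprotein marker.

## CD decomposition

Spectra are modelled as convex combinations of three component spectra:
alpha-helix (negative Gaussian bands at 209 and 222 nm, widths 4.5 and
5.0 nm — narrow enough that both minima stay resolved in helix-rich
mixtures), beta-sheet (one negative band at 215 nm, width 8 nm), and
random coil (a weak negative exponential shoulder rising toward
205 nm).  Turns are folded into the coil component, since only helix and
sheet percentages are interpreted downstream.  The bundled basis is a
versioned synthetic construction (`CD_BASIS_VERSION`), *not* a published
reference set: all round-trip results are self-consistent
generator↔decomposer statements, and absolute percentages on real
instrument spectra (or agreement with proprietary deconvolution
software) are not claimed.  Changes between spectra decomposed against
one fixed basis are the meaningful output.

The fractions solve min ‖y − Σ f_iB_i‖² subject to f_i ≥ 0, Σ f_i = 1.
With three components the convex QP is solved exactly by enumerating all
seven candidate active sets and solving each equality-constrained KKT
system; the feasible candidate with the smallest residual is the global
optimum.  The solver is deterministic, returns simplex-valid fractions
for arbitrary input (including pure noise), and is cross-checked in the
tests against an exhaustive 0.01-resolution grid search.  A basis with
condition number above 1e8 is rejected as degenerate.  Mean-residue
ellipticity conversion, [θ] = θ_mdeg/(10·l_cm·c_res), is linear and
invertible; when the residue concentration is unknown the decomposition
runs on raw millidegrees against the raw-mdeg basis, which leaves the
fractions unchanged because the basis and spectrum scale together.

Destabilization verdict: any structural fraction changing by more than
5 percentage points (configurable) between two decompositions flags the
protein as destabilized.

## Synthetic data generator

The generator's defaults are the study conditions: protein 1×10⁻⁶
mol/dm³; ligand:protein ratios 0, 0.4, …, 2.0; temperatures 297, 303,
308 K; marker ratio ladders as above; CD ratios 1:0–1:5 on a 205–250 nm
grid at 0.5 nm.  Titrations are drawn from the exact static-quenching
law F_corr = F0/(1 + K_b(T)[Q]^n), with K_b(T) either constant (kb_ref)
or exp(−ΔH°/(RT) + ΔS°/R) when the enthalpy/entropy pair is given;
`GroundTruth.from_kb_and_enthalpy` anchors a chosen ΔH° so that K_b at
297 K equals a target constant.  Inner-filter attenuation is applied to
the observed (not corrected) intensities via A = ε_eff·[Q] with
ε_eff = 0 by default (no absorbance magnitudes are prescribed for the
assay; nonzero values are exercised in dedicated tests).  Titration and
displacement noise is multiplicative Gaussian, (1 + N(0, σ_rel)); CD
noise is additive with SD scaled to the spectrum's peak magnitude,
because CD spectra cross zero and relative noise there is ill-defined.
A collisional variant (F0/F = 1 + K_sv[Q] with temperature-increasing
K_sv) exists solely to exercise the dynamic branch of the mechanism
classifier.  All randomness flows through `numpy.random.default_rng`
seeded from the design, so equal seeds give bit-identical output.

What passing round trips show: that each fit inverts its own
data-generating model exactly (noiseless) or stably (1% noise).  What
they do not show: robustness to photobleaching, scattering, drift, pH
effects, ligand depletion, or model misspecification — none of which
the generator emulates.

The default simulated study anchors the six protein–ligand complexes at
their published 297 K binding constants and uses package-chosen
exothermic enthalpies (−60 kJ/mol for albumin, −30 kJ/mol for the
glycoprotein complexes), consistent with the reported decrease of K_b
with temperature and the van der Waals/H-bond force class; per-complex
displacement strengths and helix-loss schedules likewise follow the
reported qualitative ordering (site-2 preference with the site-2 marker
displaced about twice as much, helix losses of 1.6–2.4 pp for albumin,
sheet-compensated losses ≤ 2 pp for the glycoprotein).

## Compounds and drug-likeness

Monoisotopic [M+H]+ masses use principal-isotope masses (C 12.000000,
H 1.0078250, N 14.0030740, O 15.9949146, Cl 34.9688527 Da) plus the
proton mass 1.0072765 Da — the proton, not a hydrogen atom, is the
physically correct [M+H]+ adduct and matches published calcd values at
four decimal places (±0.0005 Da for all twelve registry compounds).
The formula grammar covers element symbols with optional counts only
(no parentheses or hydrates; the registry needs none).  Average atomic
weights back the conventional molecular-weight checks of the rule
filters.

Descriptors are inputs rather than computed from structure (the source
values come from an external predictor); HBA is interpreted as the
classic N+O count.  Rule limits: Lipinski MW ≤ 500, logP ≤ 5, HBD ≤ 5,
HBA ≤ 10; Veber rotatable bonds ≤ 10, TPSA ≤ 140 Å² (boundary values
pass).  BOILED-Egg membership is a point-in-rotated-ellipse test in the
(TPSA, WLOGP) plane; the bundled white/yolk ellipse coefficients are
external constants from the original BOILED-Egg publication and are
plain configuration, replaceable per call.

## Problem sizes and determinism

All computations are closed-form or small least-squares problems: six
point titrations, ≤ 9-point displacement ladders, 91-point CD spectra,
and 4×4 linear solves in the QP.  The full test suite and the
acceptance script each complete in seconds on one CPU, and every
stochastic path is seed-deterministic.

## Known limitations

Single-site power-law binding only (no Scatchard/Hill or global
multi-site models); no combined static+dynamic quenching or FRET
analysis; no time-resolved lifetimes; no temperature-dependent ΔC_p in
the van't Hoff fit; no quantitative competitive-binding model behind the
displacement statistic; CD limited to a three-component synthetic basis
in 205–250 nm; descriptor computation from structure is out of scope.
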