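# Methods

## Scope and model

`enzybind` implements the analysis chain used to characterise a
small-molecule inhibitor of a fluorescent enzyme (the reference setting is
porcine pancreatic lipase inhibited by plant anthocyanins, read out with a
p-nitrophenyl ester substrate at 405 nm and tryptophan emission at
300–400 nm): blank-corrected inhibition rates and a probit IC50;
Lineweaver–Burk kinetics with an inhibition-type verdict; Stern–Volmer and
double-log quenching fits with a static/dynamic mechanism call; and a
two-temperature van't Hoff thermodynamic profile with intermolecular-force
classification. Group-comparison statistics, extraction chemistry, in-vivo
endpoints and microbiome analyses are out of scope.

## Inhibition and IC50

The rate formula `100·(1 − (b−B)/(a−A))` assumes the chromogenic signal is
linear in product formed and that the sample blank *B* captures the
inhibitor's own absorbance. Raw replicate rates may fall outside [0, 100]%
under noise; they are clamped to the physical range at aggregation, and the
per-dose *means* are clamped to a configurable [0.5, 99.5]% before the
probit transform, which is undefined at 0/1 — the standard probit-analysis
device. The probit regression is unweighted least squares on transformed
means (a weighted variant would require replicate-level variance modelling
that endpoint plate data rarely support); the zero-dose point anchors QC
but is excluded from the fit (log of 0). The IC50 confidence interval uses
the delta method on log₁₀ IC50 = −intercept/slope; Fieller's theorem would
be more exact near slope ≈ 0 but the difference is negligible for
well-conditioned dose ranges, a documented simplification.

## Kinetics

Per dose, 1/V is regressed on 1/[S] without weights, for parity with the
classical plot; V_max is taken from the inverse of the mean reciprocal
intercept, K_m,app per dose from slope × V_max, and K_i from the regression
K_m,app = K_m(1 + [I]/K_i). The inhibition-type verdict compares the
relative spread of per-dose V_max (default tolerance 5%) with the
monotonicity of K_m,app; whenever both parameters move inconsistently the
verdict is *mixed* — a competitive call is never the fallback. The
reversibility diagnostic uses velocity-vs-enzyme lines: intercepts within
5% (relative to the slope scale) of the origin with strictly falling slopes
read reversible; monotone non-increasing slopes with shifted intercepts
read irreversible; non-monotone slopes read indeterminate.

Reciprocal-space regression amplifies noise at low velocities, and with the
study's substrate grid (0.4–1.6 mg/mL, all ≥ 1.6 × K_m) the zero-dose line
determines K_m weakly. Two nonlinear estimators are therefore provided:
`michaelis_menten_fit` (per-dose direct fit, the cross-check oracle — on
noiseless data it agrees with the reciprocal fit to < 10⁻⁶ relative) and
`fit_competitive_global`, a joint 3-parameter fit of
V = V_max[S]/(K_m(1+[I]/K_i)+[S]) across all doses. The global fit is the
recommended estimator on noisy data: the high-dose curves probe apparent
K_m values well inside the substrate grid, tightening K_m and K_i several-
fold relative to the chained per-dose route (median relative errors at 2%
noise: ≈2.8% K_m, 0.7% V_max, 3.0% K_i versus ≈6.7%, 0.7%, 13% for the
Lineweaver–Burk chain).

## Quenching

Each spectrum reduces to its maximum intensity F and peak wavelength, ties
broken toward the longer wavelength so a red shift is never under-reported;
area-based reduction is deliberately not the default because the headline
quantity in this assay family is the *maximum* fluorescence. The
Stern–Volmer fit constrains the intercept to 1 (the law has none free); an
unconstrained fit is attached as a diagnostic. K_q = K_sv/τ₀ holds exactly
by construction, with τ₀ = 10⁻⁸ s by default (tryptophan lifetime). The
double-log fit uses base-10 logarithms throughout; points with F ≥ F₀ are
excluded with a warning. Mechanism classification is total and
deterministic: static requires K_q > 2×10¹⁰ L mol⁻¹ s⁻¹ at every
temperature and (with ≥ 2 temperatures) K_sv strictly decreasing in T;
dynamic requires the complementary pattern; every conflict is
indeterminate.

## Thermodynamics

ΔG = −RT ln K (R = 8.314 J mol⁻¹ K⁻¹), ΔH from the two-point van't Hoff
slope (assumed temperature-independent over the 10 K interval), ΔS from
the Gibbs–Helmholtz identity — all energies computed in J and converted to
kJ/mol (ΔG, ΔH) and J mol⁻¹ K⁻¹ (ΔS) at a single point to avoid 1000×
slips. Note the two-point ΔH estimate is invariant under swapping the two
(K_a, T) pairs, as physics requires. Force classification follows the
Ross–Subramanian sign rubric with explicit near-zero bands (defaults
1 kJ/mol for ΔH, 5 J mol⁻¹ K⁻¹ for ΔS) so the "ΔH ≈ 0" electrostatic
branch has a defined width; sign patterns outside the three canonical
cells are indeterminate. A consistency checker recomputes ΔG from any
user-supplied (K_a, ΔG) table and flags rows disagreeing by more than
0.2 kJ/mol — wide enough for 3-significant-figure rounding of K_a, narrow
enough to catch mislabelled or transposed rows.

## Synthetic data generator

The generator emulates the study designs with known truth: probit
dose–response for the plate assay (slope 2.0 probit/decade by default,
giving ≈10–76% inhibition across the 0.4–4.0 mg/mL grid — the
dose-dependent range such assays report); the competitive rate law (with
noncompetitive/uncompetitive variants) for velocities; proportional
velocity-vs-enzyme lines with dose-reduced slopes (reversible) or shifted
intercepts (irreversible); and Gaussian emission bands (σ = 25 nm, centre
340 nm) whose peak intensities obey (F₀−F)/F = K_a[Q]ⁿ — the Stern–Volmer
law at n = 1 — with a 0.1 nm red shift per unit quencher:enzyme molar
ratio. Peak centres are snapped to the 0.05 nm wavelength grid so that
noiseless sampled maxima satisfy the binding law to machine precision.
Noise is multiplicative Gaussian (relative SD `noise_sd`), truncated at
zero: plate readers and fluorometers have signal-proportional error and
negative signals are unphysical. Replicates are realised as plate wells;
titration spectra are single scans. Quencher dilution of the enzyme is
neglected (designs specify final molar ratios). Identical (design, truth,
seed) inputs give bit-identical outputs.

What the generator does **not** emulate: inner-filter attenuation,
scattering baselines, plate spatial effects, substrate depletion over the
endpoint incubation, or model misspecification (real titrations are not
exactly single-site). Passing round-trip tests therefore demonstrates
estimator correctness and noise behaviour under the stated models, not
robustness to those artefacts.

## Problem sizes and numerical choices

The recovery studies use the published grids — 8 inhibitor doses × 3
replicate wells, 8 × 7 dose–substrate velocities, 8 titration ratios on a
2001-point wavelength grid — and 200 seeded replicate studies at 2%
relative noise for the median-error summaries; all fits are linear least
squares or small curve_fit problems, so the full suite and the acceptance
script each run in seconds.

## Known limitations

- **K_a identifiability in the double-log fit.** K_a = 10^intercept is
  evaluated at lg[Q] = 0 while the data live at lg[Q] ≈ −5.6…−4.0, an
  extrapolation of ≈4.8 decades: the relative K_a error is ≈|lg Q̄|·ln 10
  ≈ 11 × the standard error of n. At 2% measurement noise this yields a
  median relative K_a error near 12% even though n itself recovers to
  ≈1.3% — an intrinsic property of the estimator and concentration range,
  not a fitting defect. K_sv (slope-only, intercept pinned) does not
  suffer from it.
- **Two-point van't Hoff.** With only a 10 K temperature span, small
  relative errors in the two K_a values propagate ≈90-fold into ΔH, so
  noisy fitted binding constants can flip the force classification;
  feeding the thermodynamics stage with precise (e.g. averaged or
  published) constants is advised.
- **Verdict sensitivity.** The competitive verdict compares the *range* of
  eight per-dose V_max estimates against a 5% tolerance; at ≥2% velocity
  noise this range frequently exceeds the band and the verdict degrades to
  mixed — by design, since silently calling competitive would be worse.
  The tolerance is configurable.
- The delta-method IC50 CI is symmetric on the log scale and degenerates
  when the probit fit is exact (zero residual df); a warning is attached.
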