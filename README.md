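# enzybind

Characterisation of small-molecule enzyme inhibitors from three standard
bench experiments, built for the pancreatic-lipase / polyphenol setting but
applicable to any chromogenic enzyme assay with a fluorescent (tryptophan)
target:

1. **Endpoint plate assay → inhibition rate and IC50.** Four absorbance
   roles per dose — control blank *A*, uninhibited reaction *a*, no-enzyme
   sample blank *B*, inhibited sample *b* — give the blank-corrected
   inhibition rate

   > rate (%) = [1 − (*b* − *B*)/(*a* − *A*)] × 100

   Replicate rates are aggregated per dose and the IC50 is estimated by
   probit regression: Φ⁻¹(fraction inhibited) is fitted linearly against
   log₁₀(dose), and IC50 = 10^(−intercept/slope), with a delta-method 95%
   CI.

2. **Steady-state velocities → inhibition type and K_m, V_max, K_i.**
   Velocity-vs-enzyme lines at fixed substrate diagnose reversibility
   (lines through the origin with slopes falling with dose ⇒ reversible;
   parallel, shifted lines ⇒ irreversible). Lineweaver–Burk analysis fits
   1/V against 1/[S] per inhibitor dose: for a competitive inhibitor
   K_m,app = K_m(1 + [I]/K_i) rises with dose while V_max is shared, and
   K_i follows from regressing K_m,app on [I]. The verdict (competitive /
   noncompetitive / uncompetitive / mixed) is read from which parameter
   moves; ambiguous patterns are *mixed*, never silently competitive. A
   direct nonlinear Michaelis–Menten fit and a global competitive-model
   fit across all doses are provided as the statistically preferred
   estimators.

3. **Fluorescence titration → binding constants, mechanism,
   thermodynamics.** Emission spectra (300–400 nm) at rising quencher
   concentration [Q] reduce to peak intensities F (F₀ at [Q] = 0). The
   Stern–Volmer law F₀/F = 1 + K_sv[Q] gives K_sv and the bimolecular rate
   constant K_q = K_sv/τ₀ (τ₀ ≈ 10⁻⁸ s); the double-log law
   lg[(F₀−F)/F] = lg K_a + n·lg[Q] gives the binding constant and number
   of sites. K_q above the diffusion limit (2×10¹⁰ L mol⁻¹ s⁻¹) with K_sv
   falling as temperature rises ⇒ static quenching. From K_a at two
   temperatures, ΔG = −RT ln K, the van't Hoff ΔH, and ΔS = (ΔH−ΔG)/T
   classify the dominant forces (ΔH<0, ΔS<0 ⇒ hydrogen bonds + van der
   Waals; ΔH>0, ΔS>0 ⇒ hydrophobic; ΔH≈0, ΔS>0 ⇒ electrostatic).

Because raw instrument data for such studies are rarely deposited, the
package ships a first-class synthetic-data generator
(`enzybind.synthetic_data`) that emulates all three experiments under
known ground truth — the published dose grids, triplicate wells,
multiplicative measurement noise — so every fit can be validated by
round trip.

## Worked example

```python
from enzybind import synthetic_data as sd, inhibition as inh, kinetics as kin
from enzybind import quenching as q, thermodynamics as th

design = sd.AssayDesign(noise_sd=0.005, seed=42)
truth = sd.GroundTruth(Ksv_by_T={293.0: 15.53e4, 303.0: 9.69e4})

fit = inh.fit_ic50(inh.aggregate_dose_response(sd.generate_plate_assay(design, truth)))
vs = sd.generate_velocity_series(design, truth)
km, vmax, ki = kin.fit_competitive_global(vs)
lb = kin.lineweaver_burk(vs)
fits = q.analyze_titrations(sd.generate_titration(design, truth))
res = th.analyze(th.ThermoInput(Ka1=fits[293.0].Ka, T1=293.0,
                                Ka2=fits[303.0].Ka, T2=303.0))
```

and the fitted quantities format to:

```
IC50 = 1.80 mg/mL (95% CI 1.78-1.81, R2 = 1.000)
Km = 0.252 mg/mL, Vmax = 5.47 /min, Ki = 0.89 mg/mL (Lineweaver-Burk verdict: competitive)
293 K: Ksv = 1.56e+05 L/mol, Kq = 1.56e+13 L/(mol s), Ka = 1.57e+05 L/mol, n = 1.00  [static]
303 K: Ksv = 9.66e+04 L/mol, Kq = 9.66e+12 L/(mol s), Ka = 9.69e+04 L/mol, n = 1.00  [static]
dH = -35.7 kJ/mol, dG(293 K) = -29.1 kJ/mol, dS(293 K) = -22.3 J/(mol K)  [hbond_vdw]
```

Reading: the inhibitor halves lipase activity at 1.80 mg/mL; it is a
competitive, reversible inhibitor (K_m rises with dose, V_max does not);
quenching is static (K_q ≫ 2×10¹⁰, K_sv falls with temperature) with one
binding site; binding is spontaneous and enthalpy-driven with both ΔH and
ΔS negative, i.e. dominated by hydrogen bonds and van der Waals contacts.

The same analyses run from CSV files via the CLI:

```
enzybind synth --out fixture/ --seed 42 --noise-sd 0.005
enzybind run --plate fixture/plate.csv --kinetics fixture/kinetics.csv \
             --type-plot fixture/type_plot.csv \
             --manifest fixture/spectra/manifest.csv --out report/
```

which writes `report/report.json` (schema-stable, byte-reproducible) and a
human-readable `report/report.txt`.

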