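# depotflow

Quantitative analysis for polymer-assisted ethanol tumor ablation studies.

Percutaneous ethanol injection ablates tumors by coagulative necrosis, but
neat ethanol leaks away from the injection site. Mixing in ethyl cellulose
(EC) — ethanol-soluble, water-insoluble — makes the injectate precipitate
into a depot on tissue contact, slowing ethanol release. `depotflow`
implements the analysis pipeline such a preclinical study needs, end to end,
for researchers characterizing intratumoral drug-delivery kinetics:

* **`raman`** — convert timed Raman spectra of the tumor surface into a
  relative ethanol concentration time course by non-negative least-squares
  unmixing against pure ethanol/tissue reference spectra.
* **`transport`** — forward-simulate the two-compartment Fickian assay
  (ethanol well below, tumor slab above) and invert it to estimate the
  effective diffusion coefficient *D*<sub>T</sub> and evaporation loss
  *K*<sub>EV</sub> from a concentration series.
* **`morpho`** — segment injection zones in fluorescence images and score
  them by compactness 4π*A*/*P*² and by spherical retention volume
  *V*₁ = (4/3)π*r*₁³ from a central cross-section.
* **`volumetrics`** — necrotic volume from serial-section areas by the
  Riemann sum *V* = Σ *A*(*x*ᵢ)Δ*x*, plus dose-normalized ratios and group
  fold-changes.
* **`cohort`** — caliper volumes *V* = *W*²·*L*/2, dose arithmetic (mL/kg →
  µL), time-to-1500 mm³ surrogate survival, Kaplan–Meier and log-rank,
  adverse-event chi-squared (df = 1), Welch ANOVA + Tukey HSD, and Grubbs
  outlier screening.
* **`synth`** — seeded generators for every input the pipeline consumes
  (spectral mixtures driven by the transport model, disk-plus-lobe injection
  images, spherical section profiles, exponential-growth cohorts, Bernoulli
  adverse-event tables), so the whole pipeline runs without external data.

## The transport model

The diffusion assay stacks a well of neat ethanol (height *h*<sub>E</sub> =
1.5 cm, diffusivity *D*<sub>E</sub> = 10⁻⁵ cm²/s) beneath a tumor slab of
measured height *h*<sub>T</sub>, separated by an ethanol-permeable membrane
(partition coefficient Φ<sub>ET</sub> = 1). Concentration obeys

    ∂c/∂t = D ∂²c/∂x²

on the stacked domain, with zero flux at the bottom, flux continuity plus
the partition jump c_T = Φ_ET·c_E at the interface, and an evaporative Robin
condition −D_T ∂c/∂x = K_EV·c at the exposed tumor surface. The observable
is c at the tumor surface — exactly what the Raman probe reads. Fitting the
simulated surface curve to the measured one by bounded multi-start nonlinear
least squares yields *D*<sub>T</sub> and *K*<sub>EV</sub>. See
`docs/methods.md` for numerics, variants, and assumptions.

## Worked example

Generate a synthetic Raman acquisition whose mixing fraction follows the
transport model with *D*<sub>T</sub> = 1.9×10⁻⁶ cm²/s, unmix it, and refit:

```python
from depotflow import synth, raman
from depotflow.transport import TransportParams, fit_transport, rise_schedule
from depotflow.synth import SyntheticTruth

truth = TransportParams(D_T=1.9e-6, K_EV=1e-6, h_T=0.5)
schedule = rise_schedule(truth, n_points=60)        # spans the rise
basis = synth.gen_basis_spectra(64, seed=1)
spectra = synth.gen_raman_timeseries(
    SyntheticTruth(params=truth, noise_sd=0.01, seed=7, schedule=schedule), basis)
series = raman.build_series(spectra, basis)         # NNLS unmixing per spectrum
fit = fit_transport(series, TransportParams(D_T=1e-6, h_T=0.5), n_starts=3, seed=0)
print(f"D_T = {fit.params_hat.D_T:.3e} cm^2/s")
```

Output:

```
D_T = 1.892e-06 cm^2/s  (truth 1.9e-06)
K_EV = 9.956e-07
SSE = 4.522e-04, converged = True
95% CI half-width on D_T: 1.32e-08
```

The fitted diffusion coefficient recovers the generating value to 0.4%
under 1% spectral noise; the confidence half-width comes from the local
Gauss–Newton curvature of the fit.

A command-line interface wraps the same functions for file-based use:

```bash
depotflow unmix --manifest spectra/manifest.csv --basis basis.csv --out series.csv
depotflow fit-diffusion --series series.csv --h-t 0.5 --out fit.json
depotflow morpho --image img.tif --rule absolute:1000 --out metrics.json
depotflow necrosis --profile profile.csv --injected-ul 150 --out vol.json
depotflow cohort-stats --cohort cohort.csv --out stats.json
```

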