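# probekit

Analysis toolkit for pH-responsive fluorescent bioimaging probes
(meso-dimethylaminonaphthyl BODIPY dyes and similar acid-activated
fluorophores). It covers the computational side of a probe-characterization
study end to end:

* **Ensemble absorption spectra** — Boltzmann-weighted, Gaussian-broadened
  spectra from per-snapshot excitation tables of an MD trajectory:
  ω<sub>i</sub> = e<sup>−ΔE<sub>i</sub>/kT</sup> / Σ<sub>j</sub>
  e<sup>−ΔE<sub>j</sub>/kT</sup>, with each frame's sticks broadened by
  area-normalized Gaussians (FWHM in nm) and band maxima extracted.
* **Solvation structure** — spatial distribution functions (nm⁻³) of
  solvent O/H/C atom classes around a rigid-body-superposed solute from
  nanodroplet trajectories, with isosurface thresholding and Gaussian cube
  export.
* **Protonation equilibria** — linear pKa-vs-ΔH calibration
  (pKa = slope·ΔH + intercept, per chemical class) and pH speciation of
  multi-site bases from stepwise macroscopic pKa values.
* **Titration analysis** — four-parameter dose-response fit
  y = A1 + (A2−A1)/(1+10^((log x₀ − x)·p)) of fluorescence-vs-pH data; the
  midpoint log x₀ is the apparent pKa.
* **Imaging assays** — resazurin viability percentages, Pearson
  colocalization with Costes automatic background thresholds, per-cell mean
  intensities, and pH-dependent fluorescence gain.
* **Synthetic data** — seeded generators for all of the above, each
  planting a ground truth the analysis must recover.

Intended users: spectroscopists and cell biologists quantifying
acid-activated probes, and computational chemists post-processing
semi-empirical excited-state output over MD ensembles.

## Worked example

```python
import probekit as pk

# 1. Ensemble spectrum from 200 synthetic MD frames (planted band 505 nm)
frames = pk.gen_excitations(n_frames=200, seed=7, center_nm=505.0)
spec = pk.ensemble_spectrum(frames, pk.EnsembleConfig())
print("lambda_max:", pk.lambda_max(spec, window=(420, 620)))

# 2. Fit a noisy pH titration generated from the published parameter set
truth = pk.DoseRespParams(a1=0.0052, a2=1.08597, log_x0=2.86045, p=-1.61012)
data = pk.gen_titration(truth, noise_sd=0.01, seed=7)
fit = pk.fit_doseresp(data)
est = pk.pka_from_fit(fit)
print(f"A1={fit.a1:.4f}  A2={fit.a2:.4f}  log_x0={fit.log_x0:.5f}  p={fit.p:.4f}")
print(f"pKa = {est.display} (SE {est.stderr:.4f}), adj R^2 = {fit.adj_r_square:.5f}")

# 3. Colocalization of a synthetic red/green pair with planted correlation 0.7
d = pk.gen_cell_images(seed=7, rho=0.7)
res = pk.costes_thresholds(d["pair"])
print(f"pearson_r={res.pearson_r:.3f}  "
      f"thresholds=({res.costes_threshold_red:.0f},{res.costes_threshold_green:.0f})")
```

prints

```
lambda_max: 505.0
A1=0.0045  A2=1.0746  log_x0=2.86313  p=-1.6617
pKa = 2.86 (SE 0.0059), adj R^2 = 0.99888
pearson_r=0.694  thresholds=(46,46)
```

Reading the output: the ensemble band maximum lands on the planted 505 nm
center; the refit from noisy data recovers the generating parameters within
their standard errors, and the midpoint reads as pKa 2.86; the pixelwise
correlation recovers the planted mixing correlation 0.7 within sampling
error, with the Costes scan placing the background cutoff at intensity 46.

A command-line interface mirrors the library
(`probekit spectra|sdf|pka|titration|coloc|viability|phgain|simulate|run`);
`probekit run --config cfg.yaml` executes configured stages end to end and
writes a JSON summary with a provenance block (version, seed, config hash).

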