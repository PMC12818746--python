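# Methods

This note documents the models implemented in `probekit`, the choices made
where the underlying procedures left room for interpretation, and what the
synthetic-data generators do and do not emulate.

## Ensemble absorption spectra

**Model.** A chromophore in explicit solvent samples many solvent
arrangements; its observable absorption spectrum is modeled as the
Boltzmann-weighted average over sampled MD snapshots. For frame *i* with
total energy *E<sub>i</sub>* (solute + solvent shell),

  ΔE<sub>i</sub> = E<sub>i</sub> − min<sub>j</sub> E<sub>j</sub>,
  ω<sub>i</sub> = exp(−ΔE<sub>i</sub>/kT) / Σ<sub>j</sub> exp(−ΔE<sub>j</sub>/kT)

with *T* = 300 K and *k* = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹. Weights are
computed as a shifted softmax, so arbitrarily large energy spreads neither
overflow nor collapse to all-zero. No outlier-energy cutoff is applied: the
weighting itself suppresses high-energy frames exponentially.

**Broadening.** Each stick excitation (λ, f) contributes an
*area-normalized* Gaussian in the wavelength domain, scaled by its
oscillator strength, with σ = FWHM / (2√(2 ln 2)). Area normalization (as
opposed to peak-height normalization) keeps the integral of a band equal to
its total oscillator strength for every FWHM choice, so relative band
weights survive a change of broadening width. Broadening is performed
directly in nm; no energy-domain conversion is applied, because the
broadening parameters in this workflow are stated in nm.

Two widths are conventional: 10 nm FWHM for analysis and 55 nm FWHM to
match the width of experimental bands for display. Whether a wide spectrum
should be the 10 nm result re-smoothed or the sticks re-broadened at 55 nm
is ambiguous in the source workflow; `probekit` applies each FWHM **per
excitation** (never as a second smoothing pass), and both widths are plain
config options (`per_frame_fwhm`, `display_fwhm`).

**Defaults.** Grid 250–800 nm at 1 nm; spectra are not normalized on
output (`normalize_max` exists for plotting). Band maxima (`lambda_max`)
break ties toward the shortest wavelength.

## Spatial distribution functions

**Model.** The SDF is the mean number density (nm⁻³) of a solvent atom
class in a voxel grid fixed to the solute. Every frame's solute is
rigid-body superposed (Kabsch, proper rotations only — mirror images are
never reflected) onto frame 0's solute, all solute atoms weighted equally;
the same transform transports the solvent; selected atoms are binned; the
per-voxel density is mean count per frame / voxel volume. Conservation
holds by construction: Σ density × voxel volume = mean in-grid atom count.

**Reference pose.** The reference is frame 0's solute expressed in its
*principal-axes frame* (centroid at the origin, axes ordered by gyration
eigenvalue, signs fixed by projection skewness, handedness by cross
product). This makes the grid solute-intrinsic: applying one global rigid
motion to every atom of every frame leaves the SDF bit-identical, which a
lab-frame grid would not. Near-symmetric solutes with degenerate gyration
eigenvalues have no unique pose; the solutes used here are asymmetric.

**Defaults.** Cubic grid of edge 34 Å (the 15 Å droplet radius plus a 2 Å
margin, both sides), spacing 0.5 Å. Densities are absolute number
densities, *not* normalized into a g(r)-style ratio, because isosurface
thresholds in this workflow are quoted in absolute nm⁻³ (40 for water O/H,
15 for octanol carbons). The carbon class `"C"` aggregates C1…C8 of
octanol; individual positions are selectable by role label (`"C1"`…).
Coordinates are Å throughout, densities nm⁻³, cube files Bohr (the cube
convention); all conversion factors live in `probekit.constants`.

The grid spacing and averaging window behind the published density figures
are not stated anywhere; the defaults above are this package's own, and
figure-level visual agreement is explicitly not a test target.

## pKa calibration and speciation

**Calibration.** pKa is estimated from the deprotonation enthalpy ΔH
(kJ/mol, 298 K) of the conjugate acid via an ordinary least-squares line
pKa = slope·ΔH + intercept, fitted per chemical class (aromatic amine vs
benzimidazole) — a single line cannot serve both moieties. `residual_sd`
is √(SS<sub>res</sub>/(n−2)), defined as 0 for an exact two-point fit.
298 K is fixed by the thermochemistry semantics of the input enthalpies.

**Speciation.** Microstate populations are computed from *stepwise
macroscopic pKa values supplied explicitly*, not from energies: the
relative abundance of a microstate is Π over its bound protons of
10^(pKa<sub>step</sub> − pH), evaluated in log₁₀ space and normalized per
pH point (overflow-safe at any pH). Exactly one microstate must be neutral;
proton counts are declared, never enumerated automatically. A helper
(`microstates_from_enthalpies`) builds single-proton states from ΔH via a
calibration line for the energy-based route.

A known caveat: for the two-site benzimidazole compound, published pH-4
population estimates (~60% neutral for the formyl compound, ~64%/35% for
the benzimidazole compound) are *not* reproducible from the tabulated pKa
values under standard stepwise equilibria (pKa 3.47 gives ≈77% neutral at
pH 4). The speciation module is therefore validated against an explicit
partition-function oracle, not against those percentages.

## Dose–response titration fitting

**Model.** y = A1 + (A2 − A1)/(1 + 10^((log x₀ − x)·p)), with x = pH. The
fitted midpoint log x₀ is reported as the apparent pKa (displayed to two
decimals). Fitting is unweighted Levenberg–Marquardt (lmfit) from generic
starts: A1 = min(y), A2 = max(y), log x₀ = median(x), |p| = 1 with the
sign of the empirical slope. The parameterization is degenerate under
(A1, A2, p) → (A2, A1, −p); fits are canonicalized to p < 0, placing A1 at
the high-pH asymptote (the natural orientation for acid-activated probes).
Per-parameter standard errors, reduced χ² and adjusted R² are reported.
Intensities can optionally be max-normalized before fitting; both modes are
supported because the scale of published asymptotes (A2 ≈ 1.09) suggests a
near-unity normalization upstream.

Noiseless data generated from any parameter set with |p| ∈ [0.3, 5] and an
in-range midpoint refit to better than 10⁻⁶ relative; this self-consistency
is the package's primary quantitative acceptance check.

`fold_change` is the model-based ratio y(pH_low)/y(pH_high); experimental
fold changes from raw spectra are out of scope (the raw spectra are not
available), so no experimental ratio is a test target.

## Imaging and plate statistics

**Viability.** 100 × (treated − blank̄)/(control̄ − blank̄) per replicate,
reported as mean ± SEM per condition. Values outside [0, 100] are reported
as computed and flagged, never clipped. The statistic is invariant to a
common additive offset on all readings.

**Pearson colocalization.** The plain pixelwise correlation of two 8-bit
channels, with optional mask. Zero-variance channels are an error.

**Costes thresholds.** Total-least-squares (orthogonal) regression
G = a·R + b over all pixels; candidate red thresholds are scanned downward
from 255 in steps of 1, paired green threshold a·T + b; the result is the
first (largest) T at which the correlation of pixels below *both*
thresholds is ≤ 0. Sub-threshold pixel sets that are too small or constant
are skipped; if the scan exhausts (perfectly correlated images) the
thresholds fall to the channel minima; if the whole-image correlation is
already ≤ 0 the thresholds are undefined and the result is flagged. The
implementation is verified against an exhaustive 256-level scan on seeded
synthetic images. Because it is unstated whether published correlation
values were taken above or below thresholds, both the whole-image r and the
above-both-thresholds r are reported.

**Gain.** 100 × (F_acid − F_neutral)/F_neutral, with F_neutral > 0
required. Per-cell means use supplied labeled masks; segmentation is out of
scope.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and are
byte-identical for a fixed seed. Their purpose is statistical, not
physical: each plants a ground truth the matching analysis operation must
recover.

* **Excitation tables** — one dominant visible band (default center 505 nm,
  σ 5 nm, strength ≈ 0.8) plus two weaker UV bands; frame energies
  exponentially spread with scale kT at 300 K. Emulates the shape of
  semi-empirical excited-state output, not its physics.
* **Nanodroplets** — rigid asymmetric solute at the origin; solvent (rigid
  3-site water or a 10-atom octanol chain with O/H/C1…C8 role labels)
  placed by rejection sampling inside the droplet radius with a 1.8 Å
  minimum inter-atomic distance; optional hot spot pinning one molecule at
  a fixed solute-relative site in a chosen fraction of frames; an
  independent random global rigid motion per frame (which SDF alignment
  must undo). Defaults: 90 waters or 10 octanols, 15 Å radius. No
  force-field realism is claimed — only the geometric/role structure the
  SDF machinery consumes.
* **Titrations** — pH 2.2–8.7 in 0.05 steps by default, exact sigmoid plus
  homoscedastic Gaussian noise. (Real plate data are heteroscedastic; for
  midpoint-recovery testing the homoscedastic model is sufficient and
  keeps the 3·SE coverage analysis exact.)
* **Cell images** — cells as disk masks, nuclei in a blue channel; red and
  green are built from the shared-signal mixing model
  G = √|ρ|·S + sgn(ρ)·…, R = √|ρ|·S + √(1−|ρ|)·N with S, N_r, N_g
  independent and identically distributed puncta textures, so the planted
  correlation is exactly ρ. Puncta centers are uniform over the field by
  default: confining them to cell disks (`confine_puncta=True`) looks more
  cell-like but imprints the shared cell geometry on all three latent
  fields and biases the realized correlation a few hundredths above ρ.
  Channels are affinely mapped to 8 bit (mean 100, sd 20 counts) with a
  small intensity-dependent Gaussian "shot" floor — a Gaussian
  approximation to Poisson noise at 8-bit scale, sufficient to stress the
  Costes scan without dominating the variance. Cell radii are clamped to a
  quarter of the field so small test images remain valid.
* **Viability plates** — treated means placed at blank + (control−blank)·
  v/100 so the expected statistic equals the planted viability; Gaussian
  replicate noise.

What passing these tests shows: the estimators recover the parameters of
data that match their own model assumptions. What it does not show:
robustness to optics (PSF, bleed-through beyond the mixing model),
force-field accuracy, chemical-shift effects on pKa, or plate-reader
drift.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small problem sizes chosen to
exercise every code path at full statistical strength: nanodroplets of
15–30 solvent molecules over ≤ 10 frames (the density arithmetic is
size-independent), 64² images for the exhaustive Costes oracle (256-level
scans), 512² images for correlation recovery (±0.05 at that pixel count),
100 replicates for coverage checks. Tolerances: weight normalization
1e-12, SDF conservation 1e-9, superposition recovery 1e-9 Å, speciation
normalization 1e-10, noiseless refit 1e-6 relative (1e-4 at the acceptance
gate). Degenerate inputs (empty frames, collinear geometries, constant
channels, zero-variance titrations) raise `ValueError` with a diagnostic
rather than returning NaN.

## Known limitations

* The calibration line for the benzimidazole class cannot be validated
  against published multi-site rows that are internally inconsistent with
  the two-point amine line; it is validated on self-consistency and
  synthetic recovery instead.
* `speciation` handles macroscopic stepwise constants only; microscopic
  tautomer resolution would need explicit microstate free energies.
* The Costes scan quantizes thresholds at integer intensity (native for
  8-bit data); sub-integer thresholds are not searched.
* XYZ parsing assumes a constant atom count and ordering across frames, as
  produced by standard MD writers.
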