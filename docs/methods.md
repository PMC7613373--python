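# Methods

## Scope and model chain

`cncmap` estimates aboveground canopy nitrogen content (CNC, g/m²) from
VSWIR canopy reflectance through a hybrid chain: physically simulated
training data, statistical compression, and a probabilistic regressor.
The chain is

1. leaf optics (plate model) → canopy bidirectional reflectance (4-stream
   turbid medium) on a 1 nm grid, 400–2500 nm;
2. Gaussian-SRF convolution to a sensor band table, then the harmonized
   band subset (centers in [470, 2143] nm minus the water-vapour windows
   [1345, 1510] and [1795, 2000] nm — 207 bands for the shipped table);
3. centered PCA to 20 components, fit once on the training database and
   reused unchanged for validation spectra, non-vegetated spectra and
   image pixels;
4. exact GP regression on the scores with the scaled Gaussian kernel;
5. per-pixel mean, SD, CV% and a CV>20% validity mask.

## Radiative transfer

**Leaf.** The leaf is `N_struct` absorbing plates; one layer's optical
depth is `Σ_i C_i k_i(λ) / N_struct` over chlorophyll, carotenoids,
anthocyanins, water, protein and carbon-based constituents.  Surface terms
use the average Fresnel transmissivity `tav(α, n)` evaluated by 64-node
Gauss–Legendre quadrature (top surface α = 40°, internal interfaces 90°);
the multi-layer stack follows the Stokes system with guarded opaque
(`t → 0`) and conservative (`r + t → 1`) limits.  Energy conservation
`r + t ≤ 1` holds by construction and is property-tested.

**Synthetic optical constants.**  The refractive index, the six specific
absorption coefficient spectra and the reference dry-soil spectrum are
*parametric synthetic stand-ins*: Gaussian absorption features placed at
the documented wavelengths (chlorophyll 430/662 nm, water 970/1200/1450/
1940 nm, protein 910/1020/1510/1730/1980/2054/2172/2300 nm, broad CBC
SWIR absorption) with amplitudes of realistic magnitude.  The published
laboratory calibration tables are not redistributable here, so simulated
spectra are qualitatively realistic (pigment absorption, NIR plateau,
water bands, subtle SWIR protein features) but not quantitatively
identical to any calibrated leaf-optics version.  Every quantitative
result in the tests is therefore internal to this model family.

**Canopy.**  Four-stream SAIL-type solution: ellipsoidal (Campbell)
leaf-inclination distribution parameterized by the average leaf angle
(nine 10° bins), Verhoef-style geometric/volume-scattering coefficients,
hot-spot single-scattering integral (20-step exponential quadrature), and
a Lambertian soil boundary `ρ_soil(λ) = α_soil · ρ_ref(λ)`.  The bare-soil
limit (LAI→0 reproduces the soil spectrum to <1e−3) and NIR saturation
are tested.  Sun zenith is fixed at 30°, view at nadir; the relative
azimuth defaults to 0 and is irrelevant at nadir.

## Sampling and labeling

Training states are drawn independently: uniform marginals for
`N_struct` [1, 2.5], `C_ab` [0, 80] µg/cm², `C_w` [0.001, 0.02] cm,
`C_xc` [0, 15] µg/cm², `C_anth` [0, 2] µg/cm², `CBC` [0.001, 0.01] g/cm²,
`α_soil` [0, 1], `ALA` [30, 70]°, `HotS` [0.01, 0.5]; truncated Gaussians
(rejection sampling) for `C_p` (mean 0.0015, SD 0.0005, bounds
[0.001, 0.0025] g/cm²) and `LAI` (mean 3, SD 2, bounds [0.1, 7]).
Labels are `CNC = LAI · C_p · 10⁴ / 4.43` exactly; the default database
holds 1000 samples and adds **no** artificial spectral noise — sample
selection, not noise injection, is the mechanism that adapts the model to
imperfect data.

## Spectral processing

* **Resampling:** each sensor band is a Gaussian SRF with
  σ = FWHM/2.3548, sampled on the 1 nm grid and normalized to unit sum —
  linear, constant-preserving, and identical whether applied before or
  after band subsetting.
* **Despiking:** a band is an artifact when it is a local extremum and
  rises above *both immediate neighbours* by more than 0.018 reflectance
  units (the classic single-band spike test).  This deliberately spares
  genuine features such as the green peak, whose band-to-band increments
  are small.
* **Window exclusion:** closed intervals, membership tested on band
  centers; the shipped default is the twelve-window noisy-region list.
* **Gap filling:** a smoothing cubic spline through the surviving bands,
  roughness penalty chosen by generalized cross-validation (GCV); by
  default the spline *fills only masked bands*, so the full chain —
  harmonized subset → despike → windows → fill — is exactly idempotent.
  A `smooth_valid_bands` switch smooths the whole curve instead.
  The harmonized subset runs first so a second pass sees the same grid and
  reproduces the same spline bit for bit.

The shipped 239-band sensor table (`prisma_like_bands_synthetic.csv`) is a
*synthetic* nominal table for a PRISMA-class VSWIR spectrometer: ~6.3 nm
sampling in the retained regions, coarser in the excluded ones, engineered
so the harmonization filter retains exactly 207 bands.

## Gaussian process regression

Targets are mean-centered (zero-mean prior); the offset is restored at
prediction.  The kernel self-similarity used for the predictive variance
is `k** = ν` (latent function); observation-level intervals optionally add
σ_n².  The negative log marginal likelihood and its analytic gradient with
respect to log θ are minimized with L-BFGS-B; starts are the median-
distance length-scale / var(y) signal / 0.1·sd(y) noise heuristic plus
restarts drawn log-uniformly around it (σ_b offsets in [−3, 1], ν in
[−2, 2], σ_n in [−3, 2] nats).  The wide, asymmetric σ_b exploration
matters: the evidence surface has a spurious optimum at tiny length-scales
("explain everything as noise") that captures a large share of naive local
starts.  Cholesky failures retry with diagonal jitter 1e−10·ν escalating
tenfold to 1e−6·ν.  Inside the active-learning loop the kernel is
isotropic and each refit warm-starts from the previous optimum with a
single start (maxiter 40); the final model is ARD with full restarts.

## Active learning and augmentation

Maximin aggregation implements "most remote": the candidate maximizing the
minimum squared Euclidean distance to the current training set, ties
broken by smallest sample id.  Acceptance demands a *strict* RMSE decrease
on the validation set, so the recorded trace is strictly decreasing and
the final model never validates worse than the initial one; rejected
candidates are removed permanently (single pass until pool exhaustion,
optional iteration cap).  R² is recorded but never used for acceptance.
Non-vegetated spectra are projected through the *existing* PCA (no refit)
and appended with label 0 g/m² — the only physically coherent nitrogen
content for soil, water and man-made surfaces.

## Mapping and uncertainty

Per valid pixel: preprocess (skipped when the cube is already on the
harmonized grid) → project → predict; predictions run in tiles purely for
memory and are independent of tiling.  The relative uncertainty is
CV% = 100·σ/μ with latent-function σ by default; pixels with μ ≤ 1e−6 g/m²
are flagged invalid rather than given infinite CV.  The default mask
threshold is CV > 20%, the accuracy goal used for terrestrial essential
climate variables.  Cube I/O covers ENVI (BSQ/BIL/BIP, text header with
wavelength/fwhm arrays) and HDF5; model bundles serialize to a single
`.npz` whose round-trip leaves predictions bit-identical.

## Synthetic data: what it does and does not show

The field campaign and the satellite scene that the original workflow was
tuned against are not publicly available, so `cncmap.synthetic` emulates
their structure: wheat-like and corn-like parameter trajectories across a
growth stage (differing in leaf angle, LAI and protein trajectories),
multiplicative spectral noise (default SD 3% of reflectance, a sensor +
canopy-heterogeneity proxy), additive label noise (default 1 g/m²,
destructive-sampling error), and optional retargeting of the label
mean/SD via the linear CNC–LAI relation.  Scenes are patchworks of fields
(per-field state, lognormal within-field LAI variation, SD 0.1 in log
units) and non-vegetated patches built from smooth parametric soil /
water / man-made endmembers.

Because synthetic "field" spectra come from the *same* radiative-transfer
family as the training data (plus noise), validation results here are an
optimistic upper bound: they demonstrate that the machinery — selection,
fitting, uncertainty, masking — behaves correctly, not that the model
transfers to real canopies, real sensor artifacts or real soil spectra.

## Problem sizes and numerical choices in the test suite

The acceptance-style tests run the study-scale configuration: a
1000-sample database, 30-record campaign (3% spectral / 1 g/m² label
noise), single-pass AL over the full pool, and a 64×64 scene; unit tests
use a 150-sample database.  The GP parameter-recovery experiment (ν = 1,
σ_b = 1, σ_n = 0.1, N = 200, 20 seeds) uses an identification-oriented
input design — a jittered 12×12 lattice (spacing 1.3 length-scales, 134
sites) plus 66 near-duplicate twin sites (offset SD 0.05) — because the
lattice coverage pins down ν and σ_b while the twins pin down σ_n; with
uniform random inputs the maximum-likelihood estimate of log ν genuinely
fluctuates beyond ±0.3 in a nontrivial fraction of draws.

Key defaults: despike threshold 0.018 (reflectance), spline penalty GCV,
PCA components 20, AL initial fraction 0.10, non-vegetated count 24, CV
mask 20%, GP jitter ladder 1e−10·ν → 1e−6·ν, restart count 5 (final fit).

## Known limitations

* Optical constants and the sensor band table are synthetic stand-ins;
  absolute reflectance values and variance shares are specific to them.
* No atmospheric correction, georeferencing, destriping or GeoTIFF
  support; ENVI/HDF5 only.
* The validation generator cannot expose model-structure mismatch with
  real vegetation (shared RTM family).
* Exact GP scaling limits pools to a few thousand samples — the very
  motivation for the sample-reduction step.
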