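# Methods

This note records the scientific and numerical choices behind the package:
what is modeled, what is deliberately simplified, and what the synthetic
phantoms can and cannot demonstrate about real data.

## Nuclide and planning arithmetic

⁹⁰Y is treated as a pure beta emitter with half-life 64.05 h and mean
energy per decay Ē = 0.9327 MeV. The absorbed-dose constant
Δ = 49.67 J/GBq is stored separately because the planning literature
quotes it directly; `RadionuclideSpec` refuses construction if the two
disagree by more than 1% (the defaults agree to 0.08%). Doses assume
permanent implantation and complete local absorption, which is the
standard glass-microsphere planning assumption: the spheres lodge in the
microvasculature and beta bremsstrahlung losses (~1%) are neglected.

Sphere-count accounting keeps counts real-valued internally and rounds
only for display; rounding before the embolic-volume product would
compound error in the second significant figure. The vial-reduction
planner exposes a possibly surprising fact: the retained *fraction* is
independent of the reduction date (decay scales retained and discarded
spheres alike), so the date only affects the bench activity handled.

## Beta spectrum

The emission spectrum shipped in `data/y90_beta_spectrum.csv` is computed
from relativistic Fermi theory with the unique-first-forbidden shape
factor C(W) = q² + λp². The textbook spectrum with λ = 1 has a mean of
0.947 MeV, 1.6% above the evaluated 0.9327 MeV — mostly limitations of the
point-charge Fermi-function approximation. Rather than carry that bias
into every dose, λ = 0.9134 is fixed once so the spectral mean equals the
evaluated mean beta energy. This is a calibration to a nuclear-data
constant, performed before any dosimetry, and is the only fitted quantity
in the physics chain. The packaged 1024-point table reproduces the
evaluated mean to 0.03%; sampling is by inverse CDF.

## Electron transport and the dose-point kernel

Transport is a deliberately simple condensed-history model: electrons
travel on straight radial tracks, losing energy according to CSDA range
tables for water (19 points, 10 keV–2.5 MeV, embedded in
`betaspec.py`) scaled to tissue density (default 1.03 g/mL), down to a
1 keV cutoff where the residual is deposited locally. Secondary electrons,
bremsstrahlung and medium heterogeneity are not modeled; the medium is a
uniform water-like block, matching the uniform-brain-block setting of
full Monte Carlo kernel calculations.

A literal straight-track model overstates radial penetration because real
tracks are sinuous: it puts only 83% of the energy within 5.4 mm and gives
X90 = 6.3 mm, whereas the accepted X90 for ⁹⁰Y in soft tissue is ~5.3 mm.
A constant **detour factor of 0.84** (radial displacement per unit path
length, a standard magnitude for MeV electrons in water) maps path length
to radius; with it the kernel has X90 = 5.27 mm and 90.9% of its energy
within 5.4 mm. The detour factor is energy-independent — a simplification;
in reality it falls at low energies — so the kernel core is slightly
sharper than a full Monte Carlo kernel would be.

The scoring grid is truncated at the radius enclosing 99.9% of the emitted
energy (≈8.3 mm; configurable, and small test kernels may truncate much
tighter). The truncated residual is redistributed proportionally so the
kernel always sums to the mean sampled energy: convolution then conserves
energy exactly and the uniform-activity limit reproduces the MIRD dose to
within the spectrum-sampling error regardless of truncation radius. The
kernel records its pre-rescale in-grid fraction in metadata.

Monte Carlo scoring is vectorized (half-voxel steps, `bincount`
accumulation); 10⁶ histories on a 36 μm grid take ~40 s on one CPU. At
10⁶ histories the axis-flip asymmetry is ~1.7% in relative L2 and energy
closure against Ē holds to <0.1%.

## Dose maps

The microCT route bins each sphere's total decays (activity/λ) into the
voxel containing its center — at 36 μm a 27.5 μm sphere is sub-voxel, so
no spreading is performed — and convolves with the kernel using
zero-padded FFT (`scipy.signal.fftconvolve`, linear convolution; circular
wrap-around would alias dose across the anatomy). The PET route (local
deposition method) is transport-free by definition. "Actual" (truncated
delivery) maps scale extended maps by 1 − 2^(−t/T½); this is exact for
every positively homogeneous metric (mean, max, D_x) but not for V_x,
which is recomputed.

## Synthetic phantoms

The phantom is a treated-hemisphere ellipsoid containing a spherical
tumor mass, a deep-gray (thalamus/basal ganglia surrogate) ellipsoid, and
an optional necrotic core with zero placement density. Defaults describe a
scaled-down hemisphere in a 40 mm field at 150 μm (≈16 mL hemisphere,
8 mm-radius mass); full-hemisphere grids at the 8.74 μm microCT resolution
are far beyond desk scale, so detection works on millimeter-scale tiles at
8.74 μm while dosimetry works on the 36–150 μm field. All sizes are
configurable.

Sphere placement is an inhomogeneous point process with per-voxel density
1 in normal tissue and R in viable tumor (R controllable over the
study-reported dose T:N range 1.93–3.02 and beyond). Activities are split
uniformly (nominal equal loading); per-sphere activity variation is out of
scope. An optional clustering parameter strings spheres along short random
segments as a crude vessel surrogate; it is a stand-in, not calibrated to
real microsphere cluster statistics, and is off by default.

The microCT renderer is phenomenological — sphere indicator × amplitude,
resampled (5³ midpoint supersampling), Gaussian PSF, additive Gaussian
noise — not a projection/reconstruction simulation. Consequently passing
detection tests demonstrates robustness to PSF blur, Poisson-like crowding
and additive noise, but not to beam hardening, fixation artifacts, ring
artifacts or intensity inhomogeneity in real scans. The integrated
above-background intensity of one sphere is the documented constant
amplitude × V_sphere/V_voxel, which the default parameters put at ≈1.47×10⁴
(amplitude 900 over background 100, noise σ = 15, SNR ≫ 10). The PET
renderer bins activities at 2–4 mm and applies a normalized 5 mm-FWHM
Gaussian PSF with edge renormalization, conserving total activity to
1 part in 10⁶; it does not simulate sinogram statistics or reconstruction.

## Detection

Thresholding uses the supplied absolute value, otherwise
max(Otsu, median + 6·MAD σ): Otsu alone degenerates when bright voxels are
a vanishing fraction of the histogram. Components under 26-connectivity;
per-component sphere count = round(integrated above-background intensity /
single-sphere reference), integrating over a one-voxel dilation so PSF
tails below threshold still count. The reference defaults to the median
component integral (self-calibrating when most components are single
spheres; the estimate lands within 0.1% of the analytic constant on the
default tile). Multi-sphere components are split by watershed seeded at
the strongest local maxima (ties: intensity, then lexicographic voxel
order — determinism), with a deterministic weighted k-means fallback when
maxima are merged. Measured performance: sub-0.1-voxel RMSE for isolated
spheres; precision = recall ≈ 0.985 with 0.22-voxel RMSE at one sphere per
(75 μm)³, the densest regime tested.

## T:N recovery and its physical ceiling

A property worth stating precisely: the mass-to-cortex *mean-dose* ratio
of a convolved map is strictly below the *placement* density ratio,
because beta cross-fire exports energy across the mass boundary. With
energy-weighted mean deposition radius r̄ ≈ 2.5 mm and mass radius
a = 8 mm, the one-sided leakage is ≈ 0.75·r̄/a ≈ 0.19 at the surface
layer; measured on the default phantom the attenuation is ~9% (dose T:N
≈ 2.7 for an achieved placement ratio ≈ 3.0). The end-to-end recovery test
therefore compares the dose T:N to the achieved placement ratio recorded
in `GroundTruth`, and the ~9% attenuation is expected physics, not error.
Only a mass several centimeters across would make the two ratios agree to
a few percent. Study-reported T:N values are themselves dose ratios, so
this does not affect fidelity to measured data.

## Numerical conventions

Grids are 0-based and voxel-centered (world = index × spacing + origin)
with half-open voxel ownership; units are fixed at the interface (mm, GBq,
Gy, hours). D_x interpolates linearly between sorted voxel ranks and never
reads from the binned DVH; V_x uses strict ">" (configurable "≥"), and no
worked numeric pair in the source material disambiguates the two, so both
are exposed. DVH bin width defaults to 1 Gy. Kernel validation enforces
energy closure within 1% and a non-increasing mean per-voxel radial
profile with 25% shot-noise headroom. All stochastic stages take explicit
seeds and are bit-reproducible; the pipeline writes a config-hash/seed/
version provenance block with every output.

## Problem sizes used in the checks

Convolution oracle: 64³ grid, 50 spheres, 0.72 mm kernel. MIRD limit: 64³
at 150 μm, 1.5 mm kernel. Kernel invariants: 10⁶ histories. Detection
default tile: 128³ voxels at 8.74 μm, 200 spheres; density sweep to one
sphere per (75 μm)³ on 96³. End-to-end: default 267³ phantom at 150 μm,
2×10⁴ spheres, full-range kernel. These sizes were chosen so the whole
suite runs in minutes on a single CPU while every stated invariant is
exercised at meaningful statistics.

## Known limitations

* The kernel is not a full coupled electron–photon Monte Carlo: no
  secondaries, no bremsstrahlung transport, no energy-dependent detour.
* PET rendering and LDM dosimetry inherit no partial-volume correction;
  small-mass doses are underestimated exactly as they are in practice.
* The placement process is spatially unstructured within regions apart
  from the optional segment clustering; real microsphere distributions
  follow vascular trees.
* Cortex is "hemisphere minus mass minus deep gray" by construction; no
  separate brainstem/cerebellum exclusion is modeled beyond the phantom's
  hemisphere definition.
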