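# Methods

## The physical problem

A xanthophyll (lutein or zeaxanthin) dissolved in a fluid DMPC bilayer is,
to a good approximation, a rigid rod: a conjugated polyene chain with a
hydroxylated ring at each end and an electronic transition dipole nearly
parallel to the chain.  Two angles describe its arrangement: the tilt ν of
the transition dipole against the bilayer normal (optically observable) and
the tilt φ of the polyene axis itself (accessible through simulation).  The
package implements both measurement chains plus the synthetic instruments
needed to exercise them, and the structural analyses that explain the tilt
as hydrophobic mismatch: the ring-to-ring span of the molecule (~32.6 Å)
exceeds the hydrophobic core thickness of the membrane (~25 Å), so the rod
must incline for its polar rings to sit at the two polar interfaces.

## Imaging route

### Photoselection law

At a point of the equatorial ring making an angle θ with the excitation
polarization axis, the local membrane normal lies in the image plane along
the radius.  A dipole tilted ν from that normal, with uniformly distributed
azimuth ψ about it (free rotation of the chromophore about the normal, fast
on the imaging time scale), absorbs with probability ⟨(μ·E)²⟩_ψ.  Writing
μ = cosν·n̂ + sinν(cosψ·t̂₁ + sinψ·t̂₂) and averaging over ψ gives

    I(θ) ∝ cos²ν cos²θ + (sin²ν/2) sin²θ.

At cos²ν = 1/3 (magic angle 54.74°) the modulation vanishes.  A
brute-force Monte-Carlo dipole average is kept as an independent oracle in
the test suite.  The renderer multiplies this law by a Gaussian radial
membrane profile (the bilayer is far below optical resolution, so the ring
cross-section is effectively the PSF), convolves with a Gaussian PSF and
applies per-pixel Poisson noise.

Detection: the default "sum-channels" mode models total-fluorescence
detection, with the two stored channels summing (via I_VV + 2G·I_VH) to the
law above.  The "split" mode models the polarizing-cube detection for
anisotropy maps, with the emission dipole collinear with the absorption
dipole (polyene assumption); channel intensities are ψ-averages of
(μ·E)²(μ·V̂)² and (μ·E)²(μ·Ĥ)², computed on an equispaced ψ grid, which is
exact for these low-order trigonometric polynomials.

### Sector statistic and its inversion

The ring is integrated over four 10°-half-angle cones: along the
polarization axis (left–right) and perpendicular to it (up–down), inside a
radial annulus of ±2 effective ring widths; the median intensity outside
1.5 ring radii is subtracted as background.  In the zero-width-cone limit
the ratio is F_ud/F_lr = ½tan²ν, inverted as ν = arctan√(2·F_ud/F_lr)
(`orientation_angle`).  For finite cones the expected sector integrals are
cos²ν⟨cos²θ⟩ + (sin²ν/2)⟨sin²θ⟩ with the moments averaged over the actual
mask pixels; at ν = 20° the reduced formula is biased by ~1.4° for 10°
cones, so `RingOrientationEstimator` inverts the exact finite-cone relation
by default (`cone_correction=False` restores the reduced formula).  With
this correction, noise-free renders at ν ∈ [20°, 60°] are recovered to
better than 0.05°.

Pixel weighting inside the sectors is uniform: the statistic is a ratio of
congruent masks, so any common radial weighting cancels.  Ring geometry is
taken from image metadata or re-fit by an intensity-weighted centroid and
mean radius of the Otsu-thresholded image.

### Shot-noise budget

The default render budget (8 expected photons per pixel at the ring crest,
ring radius 60 px) puts a few thousand photons into the four sectors and
propagates to a ~1–1.5° standard deviation of ν across repeat vesicles —
the spread scale of the experimental replicate sets this emulates.  Error
falls as the inverse square root of the sector photon count (~0.6° at 10⁴
photons/sector).

### Lifetimes, confocal volume, Raman

Decay histograms are fit with I(t) = Σ Aᵢ exp(−t/τᵢ) (1–3 components) by
Poisson-weighted least squares with log-parameterized lifetimes; amplitudes
are reported as fractions αᵢ summing to one and the amplitude-weighted mean
⟨τ⟩ = Σ αᵢτᵢ.  Instrument-response convolution is ignored (lifetimes are
assumed long against the IRF).  The confocal volume uses the Gaussian
ellipsoid formula V = π^{3/2}x₀²z₀.  Raman maps are formed by per-pixel
trapezoidal integration of the C=C stretch region (default 1500–1550 cm⁻¹)
after subtracting a straight baseline anchored at the band edges; the
resonance condition couples scattering to the same transition dipole, so the
band image carries the same photoselection law and can be fed to the sector
analysis unchanged.

## Simulation route

### Langevin stand-in for biased MD

Each umbrella window is generated by an overdamped Euler–Maruyama walker on
U(z) = PMF(z) + ½k(z−z₀)², with reflecting walls at the grid edges, unit
friction, dt = 0.01 (k·dt/γ ≈ 0.03 for the stiffest total curvature, giving
a ≤2% discretization bias of stationary variances), temperature 320 K
(RT = 0.6359 kcal/mol).  Every 10th step is recorded and the first 10% of
the record discarded as burn-in (walkers start at the bias center, as after
a steering pass).  Excursions beyond 20% of the grid span raise a
divergence error.  The inner loop is numba-compiled; trajectories are
bit-reproducible per seed.

The default window layout mirrors the production protocol: harmonic spring
k = 3 kcal mol⁻¹ Å⁻², centers 0, 1.2, …, 10.8 Å plus 11.8 Å.

### WHAM

The self-consistent equations are iterated in log space (log-sum-exp) on
0.1 Å bins — resolving the 1.2 Å window spacing with 12 bins per window —
until window offsets move less than 10⁻⁷ kcal/mol (max 10⁵ iterations).
Empty bins carry NaN.  Adjacent windows (by center) must share at least one
populated bin; otherwise a connectivity error reports the gaps.  The
profile is invariant (exactly, up to the final min-shift) to a common
constant added to the offset initialization.

### Uncertainty

Per window, the integrated autocorrelation time is estimated by Geyer's
initial-positive-sequence rule (τ = 1 + 2Σρₖ, truncated where adjacent
autocorrelation pairs turn nonpositive; 1 for white noise), and the series
is resampled in moving blocks of length ⌈2τ⌉ (windows must contain at
least two blocks).  WHAM is re-solved per replicate; per-bin standard
deviations across replicates give the profile error, and pushing every
replicate through the mapping and distribution steps gives the standard
error of the mean tilt.  Free-energy profiles carry an arbitrary additive
constant, so recovery errors (RMSD against a known input) are computed
after removing the mean offset over sampled bins.

### Mapping and distribution

The coordinate z is the bilayer-normal projection of a rigid lever of
length ℓ = 11.8 Å (the fully vertical value of the coordinate, where the
steering protocol starts), so φ = arccos(z/ℓ): 11.8 Å ↦ 0° (vertical),
0 Å ↦ 90° (horizontal).  The free-energy *curve* is mapped by plain
substitution, G_φ(φ) = G_z(z(φ)), errors carried through unchanged — a
one-to-one relabeling of the abscissa that preserves the location of the
minimum.  The probability *distribution* defaults to the solid-angle
convention p(φ) ∝ exp(−G_φ/RT)·sinφ (an axis free to point anywhere on the
hemisphere), switchable to the bare Boltzmann factor: both conventions are
defensible for a membrane-embedded rod and the choice moves the mean by a
few degrees, so it is exposed as `jacobian=`.  The horizontal penalty is
the minimum of G_φ over φ > 70° (the horizontal classification threshold,
boundary exclusive) relative to the global minimum, and population ratios
are exp(ΔG/RT) with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹.

### Reference landscape

`demo_pmf` tabulates, over z, an asymmetric tilt well: minimum at φ = 25°,
a steep harmonic wall toward vertical (0.012 kcal/mol/deg², the cost of
pushing hydrophobic rings into the polar region) and a soft saturating rise
of 2.8 kcal/mol toward horizontal — the qualitative shape of the xanthophyll
tilt landscape.  Its exact Boltzmann mean (33.90° with the sinφ convention)
is the ground truth for end-to-end recovery tests; the chain recovers it
within a few tenths of a degree at the default sampling.

## Membrane geometry

* **Hydrophobic thickness.**  The chain-atom density midplane is
  re-estimated as the density-weighted center (translation invariance); the
  plateau is the mean density within ±5 Å of it; D_h is the distance
  between the first half-plateau crossings scanning outward in each leaflet
  (linear interpolation).  Scale-invariant by construction.  The
  half-crossing definition is operational and configurable — electron-density
  conventions would differ.
* **Ring–ring distance.**  Per frame |(r₁−r₂)·n̂|, histogrammed in 0.5 Å
  bins, mode = center of the fullest bin; frames missing a ring are skipped
  and counted.  For a rigid rod of length L at tilt φ the mode is L·cosφ
  (32.6 Å at 40° → 25.0 Å).
* **Hydrogen bonds.**  Geometric criterion, donor–acceptor ≤ 3.5 Å AND
  donor–H–acceptor ≥ 150°, both boundaries closed — a common convention,
  configurable.  Occupancy is the mean satisfied-contact count per frame,
  by orientation class; the relative loss is 1 − horizontal/vertical, and
  an empty class is reported as undefined, never as zero.

## What the generators emulate — and what they do not

The GUV renderer reproduces the cos² photoselection modulation, shot noise
and PSF blur, but not high-NA depolarization, refractive-index mismatch,
membrane undulations, out-of-focus light or multi-vesicle fields; passing
round trips therefore validate the estimator chain, not the optics of a
real microscope.  The Langevin sampler produces the correct stationary
statistics and realistic autocorrelation, but 1-D overdamped dynamics on a
prescribed landscape says nothing about force-field accuracy or orthogonal
relaxation in real MD.  Toy membrane frames have binomially independent
H-bond sites and a rigid molecular axis; real trajectories correlate both
in time.  The structural numbers of the real bilayer system (well at ~25°,
D_h = 24.8 Å, ring-span mode 25 Å, H-bond losses of roughly a third)
appear in tests only as constructed fixtures exercising the geometry and
arithmetic, not as reproductions from raw data.

## Problem sizes and runtimes

Default test and acceptance sizes: 150 000 Langevin steps per window
(13 500 recorded samples after stride and burn-in; ~148 000 total across 11
windows), 40–60 bootstrap replicates, 9 vesicles of 160×160 px at 8
photons/px.  The full suite runs in under a minute on one CPU; the
acceptance script in ~10 s.  Sampling scales linearly if tighter recovery
is wanted.

## Known limitations

* WHAM only (no MBAR), 1-D coordinate, harmonic biases.
* The finite-cone inversion assumes the ideal photoselection law; real
  depolarization effects would need a calibration of the sector moments.
* Lifetime fitting has no IRF deconvolution and no global (multi-pixel)
  analysis.
* The distance→angle mapping assumes a rigid lever of fixed length ℓ;
  chain flexibility would make ℓ a distribution.
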