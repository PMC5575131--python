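# xanthotilt

Tilt-angle determination of membrane-embedded xanthophylls (lutein,
zeaxanthin) in a single DMPC lipid bilayer, by two independent routes:

1. **Imaging route — photoselection linear dichroism.**  In a polarized
   fluorescence (or resonance-Raman) image of a giant unilamellar vesicle
   (GUV) equatorial cross-section, a chromophore whose transition dipole
   makes an angle ν with the local membrane normal produces a ring whose
   intensity is modulated as

       I(θ) ∝ cos²ν · cos²θ + (sin²ν / 2) · sin²θ

   with θ the ring position measured from the excitation polarization axis.
   Integrating the ring in narrow sectors perpendicular (F^Up–Down) and
   parallel (F^Left–Right) to the polarization axis gives the ratio

       F^Up–Down / F^Left–Right = ½ tan²ν

   which is inverted to ν.  Per-pixel anisotropy maps
   r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH), multi-exponential lifetime fits
   ⟨τ⟩ = Σ αᵢτᵢ, the confocal volume V = π^{3/2}x₀²z₀ and Raman
   band-integration imaging (1500–1550 cm⁻¹) complete the chain.

2. **Simulation route — umbrella sampling + WHAM.**  Biased windows of the
   bilayer-normal distance z between the two halves of the conjugated chain
   (harmonic springs k = 3 kcal mol⁻¹ Å⁻², 11 windows at 0–10.8 Å step
   1.2 Å plus 11.8 Å, 320 K) are unbiased with the weighted histogram
   analysis method into a free-energy profile G(z), with per-bin errors from
   an autocorrelation-aware moving-block bootstrap.  The profile is mapped
   one-to-one onto the polyene-axis tilt, φ = arccos(z/ℓ) with ℓ = 11.8 Å,
   and the Boltzmann distribution p(φ) ∝ exp(−G/RT)·sinφ yields the mean
   tilt, the free-energy cost of the horizontal arrangement (φ > 70°) and
   equilibrium population ratios exp(ΔG/RT).

Synthetic-data generators replace the microscope and the MD engine — a
cos²-law ring renderer with Poisson shot noise and Gaussian PSF, an
overdamped Langevin sampler of a prescribed 1-D free-energy landscape, toy
membrane frames with prescribed hydrogen-bond occupancy — so every stage is
testable offline against known ground truth.  Membrane-geometry analyses
(hydrophobic core thickness D_h, bilayer-normal projected ring–ring
distance, hydrogen-bond occupancy by orientation class) connect the tilt to
its structural cause, the hydrophobic mismatch between the ~32.6 Å
ring-to-ring span of a xanthophyll and the ~25 Å hydrophobic core of a
fluid DMPC bilayer.

The estimation cores are scikit-learn-style estimators
(`RingOrientationEstimator`, `WhamEstimator`, `LifetimeModel`) with
`fit`/`get_params` and trailing-underscore fitted attributes; module-level
functions (`orientation_angle`, `wham`, `fit_lifetimes`, …) are thin
wrappers.

## Worked example

```python
import json
from xanthotilt import GuvRenderSpec, render_guv_image, RingOrientationEstimator
from xanthotilt.pipeline import demo_pmf, true_mean_phi, run_umbrella_workflow
from xanthotilt.synthetic import simulate_umbrella_run, paper_window_centers

# imaging route: one noisy vesicle rendered at a true tilt of 40 deg
pair = render_guv_image(GuvRenderSpec(tilt_nu=40.0, seed=1))
est = RingOrientationEstimator().fit(pair)
print(json.dumps(est.report(), indent=2))

# simulation route: 11 umbrella windows on a known landscape
pmf = demo_pmf()
windows = simulate_umbrella_run(pmf, paper_window_centers(), n_steps=150_000, seed=42)
rep = run_umbrella_workflow(windows, n_boot=40, seed=0)
print(f"mean phi = {rep['mean_phi_deg']:.2f} +/- {rep['stderr_mean_phi_deg']:.2f} deg "
      f"(truth {true_mean_phi(pmf):.2f})")
```

prints

```
{
  "nu_deg": 41.080024846900905,
  "ratio": 0.3888477530329783,
  "F_ud": 273.08,
  "F_lr": 702.28,
  "background": 0.0,
  "n_pixels": 704
}
mean phi = 34.31 +/- 0.40 deg (truth 33.90)
```

The sector ratio 0.389 of the noisy ring inverts to ν = 41.1°, one shot-noise
standard deviation (~1°) from the rendered truth of 40°; the umbrella chain
recovers the known Boltzmann mean tilt of 33.90° to within its own
propagated standard error.

A command-line interface exposes the same stages:

```sh
xantho simulate --out run/ --seed 1          # synthetic GUVs + windows
xantho analyze-guv --vv run/guv/vesicle_00_vv.tif \
    --vh run/guv/vesicle_00_vh.tif --geometry run/guv/vesicle_00_geometry.json
xantho wham --manifest run/umbrella/window_manifest.json --out g.csv
xantho orientation-report --profile g.csv --ell 11.8 --temp 320
```

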