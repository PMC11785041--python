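# sfxm — single-image resolution estimation for scanning fluorescence X-ray microscopy

Scanning fluorescence X-ray microscopy (SFXM) raster-scans a focused X-ray
spot across a tissue section while an energy-dispersive detector records
characteristic fluorescence, yielding one quantitative 2D map per element
(Ca, Fe, Zn, ...). The spatial resolution actually achieved in such a map
depends not only on the focusing optic but on the photon statistics of the
particular element's signal — so it must be measured per image, and ideally
from that single image (two-image Fourier ring correlation costs extra dose
and beamtime).

`sfxm` implements the power-spectral-density approach for this, together
with the closed-form beamline photometry used to characterize a microprobe
station, and a synthetic-map generator so every stage can be validated
against known ground truth.

## Method

For an elemental image with pixel steps Δx, Δy (μm), the exit-wave amplitude
is ψ(x, y) = √(image + offset), where the offset is the magnitude of the most
negative pixel (spectrum fitting can produce small negatives; a constant
offset only changes the zero-frequency term). With the unnormalized DFT
Ψ(uₓ, u_y) of ψ, the power spectral density

    S(uₓ, u_y) = |Ψ(uₓ, u_y)|²

is averaged over annuli of u_r = √(uₓ² + u_y²), optionally restricted to
±30° azimuthal sectors about either frequency axis for directional
estimates. On a log-log plot the radial profile falls off as a power law and
flattens into the Poisson noise floor:

    S(u_r) ≈ P·u_rᵃ  (a < 0),   floor S_nf = ⟨S⟩ above the knee.

A least-squares line through (log u_r, log S) below the knee gives P and a;
the knee frequency solves P·uᵃ = S_nf, i.e. u_knee = (S_nf/P)^(1/a). The
Rose criterion (signal-to-noise ratio SNR_res = 5 for a high-quality
detection) defines the resolution frequency and the resolution estimate

    u_res = (SNR_res·S_nf / P)^(1/a),   δ_res = 1 / (2·u_res).

The same fit defines the Wiener filter W(u_r) = P·u_rᵃ / (P·u_rᵃ + S_nf)
for noise suppression, applied to the exit wave in the Fourier domain.

Photometry companions: absolute flux Φ = K_E·g_s·V_out from a calibrated
photodiode; effective beam width W/cos θ under sample tilt; detector
distance from an inverse-square fit I(Δd) = α/(d_sd + Δd)²; solid angle
Ω = A_active/d_sd²; and fluence per time dF/dt = Φ/(π·δ_x·δ_y).

## Worked example

```python
from sfxm import (SyntheticSpec, generate, map_psd_profile,
                  suggest_ranges, analyze_profile)

spec = SyntheticSpec(nx=512, ny=512, dx=1.0, dy=1.0, a_true=-3.5,
                     mean_counts=200.0, seed=1)
emap = generate(spec).map                      # Poisson-sampled counts
profile = map_psd_profile(emap)                # exit wave -> PSD -> S(u_r)
fit = analyze_profile(profile, suggest_ranges(profile))
print(fit.a, fit.S_nf, fit.delta_res)
```

Running `python examples/resolution_from_synthetic.py` (this exact
pipeline) prints:

```
fitted power law: P = 34.99, a = -3.450 (true -3.5)
noise floor S_nf = 6.374e+04 (Poisson prediction N_pix/4 = 6.554e+04)
knee frequency u_knee = 0.1135 /um
u_res (SNR = 5) = 0.0712 /um
estimated resolution delta_res = 7.02 um
```

The fitted slope recovers the generator's ground truth within 0.05; the
noise floor lands on the closed-form Poisson prediction N_pix/4 (the
variance of √(Poisson counts) tends to 1/4, and white per-pixel noise of
variance v has a flat unnormalized-DFT spectrum at N_pix·v); and δ_res says
structure finer than ~7 μm is buried under the counting noise of this
200-count/pixel image. Other examples cover directional (sector) estimates,
Wiener filtering, and station photometry.

## Command line

```sh
sfxm synth --kind power_law_field --nx 512 --ny 512 --seed 1 -o map.tiff
sfxm resolve -i map.tiff --dx 1 --dy 1 --element Ca \
     --signal-range 0.005 0.05 --noise-range 0.3 0.7 -o report.json
sfxm photometry --config station.yaml
sfxm wiener -i map.tiff --dx 1 --dy 1 --heuristic-ranges -o filtered.tiff
```

`resolve` accepts HDF5 (`--dataset`, `--channel-names`, repeated
`--element`), TIFF, or delimited text; `--sector both` adds per-axis
δ_res,x / δ_res,y records. Fit ranges are explicit by default because the
estimate is (weakly) sensitive to the selection; `--heuristic-ranges` opts
into an automatic choice that is labelled as such in the JSON report.

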