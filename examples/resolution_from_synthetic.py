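"""Estimate spatial resolution of a single image from its power spectrum.

Generates a synthetic fluorescence map whose structure has a known spectral
slope and count level, then runs the full pipeline: square-root exit wave,
2D PSD, radial average, power-law + noise-floor fit, and the Rose-criterion
(SNR = 5) resolution.
"""

import numpy as np

from sfxm import (SyntheticSpec, analyze_profile, generate, map_psd_profile,
                  suggest_ranges)

spec = SyntheticSpec(nx=512, ny=512, dx=1.0, dy=1.0, a_true=-3.5,
                     mean_counts=200.0, seed=1)
result = generate(spec)
print(f"synthetic map: {spec.nx} x {spec.ny} px, true slope {spec.a_true}, "
      f"mean {result.map.values.mean():.1f} counts/px")

profile = map_psd_profile(result.map)
ranges = suggest_ranges(profile)
fit = analyze_profile(profile, ranges)

print(f"signal fit range: {ranges.signal_lo:.4f}-{ranges.signal_hi:.4f} /um, "
      f"noise range: {ranges.noise_lo:.4f}-{ranges.noise_hi:.4f} /um")
print(f"fitted power law: P = {fit.P:.4g}, a = {fit.a:.3f} "
      f"(true {spec.a_true})")
print(f"noise floor S_nf = {fit.S_nf:.4g} "
      f"(Poisson prediction N_pix/4 = {spec.nx * spec.ny / 4:.4g})")
print(f"knee frequency u_knee = {fit.u_knee:.4f} /um")
print(f"u_res (SNR = {fit.snr_res:g}) = {fit.u_res:.4f} /um")
print(f"estimated resolution delta_res = {fit.delta_res:.2f} um")
print()
print("delta_res is the half-period of the highest frequency at which the")
print("image signal still exceeds the Poisson noise floor five-fold; larger")
print("values mean coarser effective resolution.")
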