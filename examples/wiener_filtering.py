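"""Wiener-filter a photon-limited map using its own fitted PSD model.

The same (P, a, S_nf) triple that defines the resolution estimate defines
the Wiener weights W(ur) = P ur^a / (P ur^a + S_nf): frequencies dominated
by signal pass through (W ~ 1), frequencies dominated by the Poisson floor
are suppressed (W ~ 0).
"""

import numpy as np

from sfxm import (SyntheticSpec, analyze_profile, apply_wiener, generate,
                  map_psd_profile, suggest_ranges)

spec = SyntheticSpec(nx=256, ny=256, a_true=-3.5, mean_counts=50.0, seed=11)
result = generate(spec)
noisy = result.map

profile = map_psd_profile(noisy)
fit = analyze_profile(profile, suggest_ranges(profile))
smoothed = apply_wiener(noisy, fit)

def rms_error(values):
    return np.sqrt(np.mean((values - result.truth) ** 2))

print(f"fit: a = {fit.a:.3f}, S_nf = {fit.S_nf:.4g}, "
      f"delta_res = {fit.delta_res:.2f} um")
print(f"RMS error vs ground truth, raw counts:     {rms_error(noisy.values):.3f}")
print(f"RMS error vs ground truth, Wiener output:  {rms_error(smoothed.values):.3f}")
print()
print("The filtered map is closer to the noiseless truth because the flat")
print("high-frequency Poisson floor has been attenuated while the power-law")
print("signal band is preserved.")
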