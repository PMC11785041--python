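# Methods

## Model and assumptions

A fluorescence map is treated as an incoherent intensity image. Its
"exit wave" is the square root of the image, after offsetting by the
magnitude of the most negative pixel (full-spectrum fitting can leave small
negative residuals; the constant offset affects only the zero-frequency
coefficient). The analysis assumes:

* the underlying structure has an isotropic (or sector-wise) power-law
  spectrum S(u_r) ≈ P·u_rᵃ with a < 0 over the fitted band — the standard
  behaviour of natural and tissue images, with |a| typically 3–4 though
  steeper slopes occur and no prior is imposed on the fit;
* counting noise is Poisson and uncorrelated between pixels, so its
  spectrum is flat; at mean rates above a few tens of counts the variance
  of √counts approaches 1/4, putting the floor at S_nf ≈ N_pix/4 under the
  unnormalized DFT convention;
* signal and noise cross at a well-defined knee inside the sampled
  frequency band. When the SNR_res crossing falls beyond the band the
  result is flagged `out_of_band` and reported un-clamped: the image is
  then optic- rather than noise-limited and δ_res is a bound, not an
  estimate.

δ_res = 1/(2·u_res) is a half-period criterion: it asks at which spatial
period the image content still exceeds the noise floor by the Rose factor,
not the width of a point-spread function.

## Conventions and numerical choices

* **Array axes.** `values[iy, ix]`: first index is the slow (y) scan axis
  with step `dy`, second the fast (x) axis with step `dx`. Step sizes are
  pure per-axis metadata; orientation bookkeeping (rotated acquisitions)
  is the caller's responsibility.
* **DFT normalization.** Unnormalized forward transform. Any common
  rescaling of P and S_nf cancels inside (SNR·S_nf/P)^(1/a), so the choice
  cannot move u_knee, u_res or δ_res; fixing it makes the noise-floor law
  exactly N_pix·Var and the test oracles exact.
* **Padding.** Odd dimensions are extended by one row/column filled with
  the mean of the exit wave (post-square-root, since that is the image
  being transformed), putting u_r = 0 on a pixel of the even grid. For an
  even length N and step d the frequency axis runs from −1/(2d) to
  ((N/2−1)/(N/2))/(2d) in steps of 1/(N·d).
* **Radial binning.** Uniform bins in u_r from 0 to the largest frequency
  present in the kept pixel set (corners included); the u_r = 0 pixel is
  excluded; bin statistic is the arithmetic mean (consistent with the
  expectation argument behind the flat noise floor); empty bins carry a
  zero count and are excluded from fits. Default bin count is
  `min(nx, ny) // 2`, one bin per resolvable step of the smaller axis.
* **Sectors.** The acute angle between (uₓ, u_y) and the sector axis is
  compared against the half-angle (default ±30°): strictly `< h` for x
  sectors and `≥ 90° − h` for y sectors, i.e. half-open boundaries, so the
  two 45° sectors tile the off-axis plane exactly once and ties are
  deterministic. Axis rows/columns belong to their own sector.
* **Fitting.** Ordinary least squares on (ln u_r, ln S), unweighted. The
  noise floor is the plain mean over the chosen high-frequency bins. Fit
  ranges are explicit inputs; a labelled heuristic (noise = top 20% of
  frequencies; signal = the decade ending where the profile last exceeds
  10× the provisional floor, which keeps the fit below the knee) exists
  for batch and synthetic work. A fitted a ≥ 0 marks the result invalid
  rather than raising, so multi-element batches complete.
* **Wiener filtering.** Weights are computed on the native (unpadded) DFT
  grid, the u_r = 0 coefficient passes with weight 1, and the output is
  re-squared with the offset subtracted; small negatives are preserved
  rather than clipped so the operation stays linear-algebraically honest.
* **Inverse-square distance fit.** Initialization is deterministic
  (α₀ = I(Δd_min)·(Δd_max − Δd_min + 10)², d₀ = 10 mm) with positive
  bounds and tight tolerances, so results are bit-reproducible; verified
  to recover noiseless distances in [5, 100] mm to 1e−6 relative.
* **Units.** Detector geometry in mm, resolutions and pixel steps in μm,
  preamplifier gain in μA/V at the interface (converted to pA/V
  internally), solid angle in sr, fluence per time in photons/(μm²·s).
  Display rounding (2 significant figures for fluence, 2 decimals for sr)
  happens only at presentation; full precision is retained and serialized.

## Synthetic data: what it emulates and what it does not

The generator produces the two spectral ingredients the analysis relies on:
a structure field with prescribed isotropic slope (white Gaussian noise
shaped by u_r^(a/2) in Fourier space, zero-frequency set from the requested
mean, shifted non-negative — a DC-only change — and rescaled), and
per-pixel Poisson sampling at a target mean count. Defaults are chosen as
realistic for micrometer-scale tissue maps: slope −3.5 (inside the 3–4
band typical of such images), RMS structure contrast 0.5 about the mean,
and 200 mean counts per pixel — a level at which the knee sits mid-band so
both the power-law and the floor are measurable. Separate RNG streams for
the field and the Poisson draws make a count-level change the exact
analogue of a dwell-time change on the same sample.

Passing tests on these maps demonstrate the estimator's correctness under
its own model: power-law signal, stationary Poisson noise, no detector
artifacts. Real maps additionally contain spectrum-fitting residuals,
fly-scan correlations along the fast axis, detector dead time and
background structure that can bend the profile away from a single power
law; on such data the explicit-range interface (and inspection of the
profile) matters, and slopes well outside [−4, −3] do occur. The spot-pair
generator is a real-space sanity check only: it confirms δ_res is finer
than an obviously resolved separation, not a PSF measurement.

Problem sizes used in the automated checks (512² maps for slope recovery,
256² for the noise-floor and count-level trends, 5–10 seeds) are the
package's chosen validation conditions; they keep every stage's statistics
comfortable while the whole suite runs in seconds.

## Design choices on genuinely open points

* The HDF5 reader takes a user-specified dataset path plus a channel-name
  index instead of hard-coding one vendor layout: spectrum-fitting
  packages differ, and no on-disk schema is canonical.
* The report is plain JSON so downstream tooling and tests can assert
  fields mechanically; writers never round.
* The upper frequency limit of an even-length axis is taken as
  ((N/2−1)/(N/2)) × Nyquist, the standard even-grid DFT asymmetry.
* The CLI requires explicit fit ranges unless the heuristic is requested
  by flag, because δ_res moves by a few percent with the selection; every
  report records the ranges actually used.
* Out-of-band resolutions are reported with a flag instead of being
  clamped to Nyquist: silent clamping would hide optic-limited cases.

## Known limitations

* Single-image PSD resolution is a statistical statement about frequency
  content, not a two-image correlation; structured backgrounds that mimic
  a power law can bias it.
* No windowing/apodization is applied before the DFT; strong edge
  discontinuities leak power into the high-frequency band and can raise
  the apparent floor on small maps.
* The noise floor estimate assumes stationary counting statistics across
  the field; strongly varying dwell or live time per pixel violates this.
* Directional estimates inherit the shorter frequency band of a coarser
  axis; with very anisotropic steps the x- and y-sector fits may not
  cover comparable decades.
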