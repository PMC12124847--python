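# Methods

## The model

`rfspoil` simulates the pseudo steady state of RF-spoiled gradient-echo
(FLASH / SPGR / T1-FFE) sequences. One repetition consists of an RF pulse of
flip angle α and phase φ_n, free evolution under the gradient schedule of one
TR, and an unbalanced net gradient moment (the spoiler) that dephases the
transverse magnetization by an integer number of cycles per voxel. The RF
phase follows the quadratic cycle

    φ_n = n(n+1)ψ/2   (mod 360°),

so the *phase difference increment* ψ is the single knob of the spoiling
mechanism. Vendors hard-code ψ = 50°, 115.4°, 117° or 150°; ψ = 169° is the
value recommended in the T1-mapping literature. With ideal spoiling the
steady-state signal equals the Ernst amplitude

    S_Ernst(TR/T1, α) = M0 (1 − E1) sin α / (1 − E1 cos α),  E1 = e^(−TR/T1),

maximal at the Ernst angle α_E = arccos(E1). Real phase cycles only
approximate this; the package quantifies the mismatch by

    ε = (100%/N) Σ_k |S⁺(α_k) − S_Ernst(α_k)| / S_Ernst(α_k)

over the standard grid of N = 18 flip angles (5°…90°, step 5°). Smaller ε
means better spoiling (a curve that is a constant multiple 1+x of the Ernst
curve has ε = 100x%).

## Extended phase graph with diffusion

The magnetization of a voxel is represented by configuration states: Fourier
coefficients F_k (transverse) and Z_k (longitudinal) of the intra-voxel
dephasing angle, where order k counts multiples of the per-TR spoiler moment.
Operators:

* **RF pulse** — mixes (F_k, F₋ₖ*, Z_k) with one unitary 3×3 matrix at every
  order; implemented over the full ladder k ∈ [−K, K].
* **Relaxation** — F decays with exp(−τ/T2), Z with exp(−τ/T1), Z₀ regrows
  toward M0; exact for any sub-interval partition of the TR.
* **Gradient shift** — F_k → F_{k+1} once per TR, when the accumulated
  moment reaches one order quantum.
* **Diffusion** — each amplitude is attenuated by exp(−bD). For a transverse
  state whose spatial frequency moves linearly from q₁ to q₂ over duration τ
  (a gradient lobe), b = τ(q₁² + q₁q₂ + q₂²)/3 per axis — the exact integral
  of q(t)²; a longitudinal state sits at constant q with b = τq². Axes add
  (isotropic D). The intra-TR trajectory uses the true fractional moment
  accumulated by the lobes, not just the integer order, so the b-value of the
  prephaser/readout/spoiler waveform is exact for rectangular lobes.

Only the readout gradients and the slice spoiler are modeled; phase-encoding
and slice-selection gradients are balanced within each TR and contribute
negligible diffusion weighting. Both axes repeat identically every TR, so a
single integer order indexes the two-axis spatial frequency (k·Δq_readout,
k·Δq_slice) and b-values sum over the axes.

The acquired signal S⁺ is |F₀| directly after the pulse — the integral of M⁺
over the dephasing angle. Echo-time relaxation is *not* folded in: it would
multiply all signals by a common exp(−TE/T2)-type factor that cancels under
the normalizations this signal feeds (and would make the short-T2 regime
appear badly spoiled for a trivial reason). `sample="te"` switches to
sampling at the echo if the raw echo amplitude is wanted. S⁻ is |F₀| at the
end of the TR, just before the next pulse.

## Numerical policy

* **Convergence.** The magnitude |F₀| in the pseudo steady state is
  repetition-invariant, but the approach is slow for long T1. The engine runs
  max(2000, 10·T1/TR) pulses and reports the mean of |F₀| over the final 100
  pulses, with the peak-to-peak spread of that window as a residual
  (warned above 1e−4·M0). All simulations are deterministic; results are
  bit-reproducible.
* **Truncation.** A pathway must spend one TR transverse per order gained,
  so |F_k| ≤ exp(−k·TR/T2); the ladder is capped where that bound falls below
  the amplitude floor (default 1e−12·M0, configurable; floor 0 disables
  truncation). Periodically the active window is re-shrunk to the live
  orders. The floor changes steady-state signals by < 1e−9 relative.
* **Phase arithmetic.** n(n+1)ψ/2 mod 360° is reduced with exact integer
  arithmetic in millidegrees (all practical ψ are whole millidegrees), so the
  cycle does not drift at large n.
* **Grid keys.** Parameter-space cells are keyed by integer tenths of
  log10(T1/TR) and log10(T2/TR) (−10…23, i.e. ratios 0.1…200), avoiding float
  drift in axis values; cells with T2 > T1 are never simulated.

## The default protocol

The bundled protocol reproduces a 7 T liquid-phantom 3D GRE acquisition:
TR = 20 ms, TE = 4 ms, voxel 0.30 mm (readout) × 0.78 mm (slice), readout
bandwidth 50 kHz, matrix 100, spoiling moments 3 cycles/voxel (readout) and
3.76 cycles/voxel (slice). The lobe layout is a *documented approximation*:
a 1 ms prephaser ending at the plateau start, a readout plateau sized from
bandwidth and matrix and centered on TE (so the echo forms at TE), and
1.5 ms end-of-TR spoilers on both axes. The published gradient table of the
original acquisition is not part of this package; any exact layout can be
entered via the config file (`lobes:` list) and all timings are arguments of
`build_default_protocol`. Diffusion-free results are independent of the
layout (only the net moment matters); with diffusion, ε values inherit the
waveform approximation and should be read as accurate to it — qualitative
orderings (e.g. ψ = 169° yielding the lowest ε for medium-to-high D) are
asserted by the test suite under this default waveform.

Resolution scaling multiplies all gradient amplitudes by 1/factor and the
voxel sizes by factor: cycles/voxel is invariant while the absolute
dephasing per mm — hence the diffusion weighting — scales inversely with
voxel size.

## Synthetic phantom measurements

`generate_measurement` emulates the ROI evaluation of magnitude images: per
flip angle it draws `roi_voxel_count` voxel magnitudes |s + n| with complex
Gaussian noise (per-channel σ, in units of M0) and records their mean — a
Rician ROI mean, with the magnitude bias floor σ²/(2s) that real magnitude
data have. σ and the ROI size are free parameters (the reference experiments
report no SNR); defaults σ = 0.005, ROI = 500 voxels. Curves are normalized
at the measured flip nearest the Ernst angle (within 2.5°), where curves for
all ψ coincide for the phantom parameter sets; the division factor is
retained so absolute curves (and hence ε) are recoverable exactly.

What the generator does *not* emulate: k-space acquisition and
reconstruction, coil sensitivity and receiver-gain structure, B1
inhomogeneity across the ROI, T2*/TE decay (a common factor removed by the
normalization), and spatially correlated noise. Passing pipeline tests
therefore demonstrate correctness of the processing chain, not fidelity of
any particular scanner's noise.

## Verification

* The RF operator is checked against a dense isochromat ensemble rotated
  with plain 3×3 rotation matrices and Fourier-transformed back.
* The full engine at D = 0 matches the independent isochromat-ensemble
  simulation of the signal integral to < 1e−6 (in practice ~1e−15) after
  every pulse of 200-pulse trains.
* Interval diffusion attenuation matches Simpson quadrature of the
  spatial-frequency trajectory to 1e−9 relative.
* Closed-form limits: TR ≫ T2 and very large D both collapse the signal onto
  the Ernst amplitude (< 0.1% deviation); with D = 0 the signal depends on
  (T1/TR, T2/TR) only.
* Reference ε values for the diffusion-free parameter sets are reproduced to
  the printed decimal (see `tests/test_acceptance.py` and
  `scripts/acceptance.py`).

## Known limitations

* One known bound from the literature is exceeded marginally: with D = 0 the
  T2 < TR region is often summarized as ε < 1%, but at the edge row
  T2/TR = 0.79 with very long T1 the converged value reaches ε ≈ 1.26%
  (confirmed independently by the isochromat oracle). The package reports
  the computed value.
* Isotropic diffusion only; no exchange/magnetization transfer, slice
  profile, B1 inhomogeneity, or transient (pre-steady-state) contrast.
* Rectangular gradient lobes (piecewise-constant amplitude); ramps can be
  approximated by splitting a lobe into steps.
* The isochromat oracle is defined for D = 0; diffusion correctness is
  established at the operator level against quadrature instead.
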