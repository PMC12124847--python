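# rfspoil

Simulation and analysis of RF spoiling in gradient-echo MRI, with diffusion.

RF-spoiled gradient-echo sequences (FLASH, SPGR, T1-FFE) combine an
unbalanced spoiler gradient with a quadratically cycled RF phase
φ_n = n(n+1)ψ/2 to suppress transverse coherences and deliver T1-weighted
signal. Ideally the steady-state signal equals the Ernst amplitude

    S_Ernst(TR/T1, α) = M0 (1 − E1) sin α / (1 − E1 cos α),   E1 = e^(−TR/T1),

with no T2 dependence. In reality the suppression is approximate, and how
good it is depends on the phase difference increment ψ (vendors use 50°,
115.4°, 117° or 150°; the T1-mapping literature recommends 169°), on T1/TR
and T2/TR, and — in free liquids especially — on diffusion, which attenuates
the imperfectly spoiled dephased magnetization. `rfspoil` is for MR
physicists who need to know, for a given liquid or tissue and protocol, how
far a given ψ strays from ideal spoiling.

The package provides:

* an extended-phase-graph (EPG) engine with diffusion: configuration states
  F_k/Z_k evolved by RF mixing, relaxation, gradient shift and per-interval
  exp(−bD) attenuation with exact b-values of the gradient waveform;
* an independent isochromat-ensemble simulator of the same signal integral
  (the cross-check oracle for the EPG engine at D = 0);
* Ernst closed forms and the spoiling-quality metric
  ε = (100%/N) Σ |S⁺(α_k) − S_Ernst(α_k)| / S_Ernst(α_k) over the standard
  18-flip grid (5°…90°, step 5°) — smaller ε, better spoiling;
* sweep pipelines: ε over a log-spaced (T1/TR, T2/TR) grid, ε versus voxel
  size (gradient amplitudes scale inversely with resolution), and ε tables
  for named substances with diffusion on/off;
* a synthetic phantom-measurement generator (Rician ROI noise,
  Ernst-angle normalization) so the full measured-vs-simulated comparison
  pipeline runs without scanner data.

## Worked example

```python
from rfspoil import (STUDIED_PSI, build_default_protocol, compute_epsilon,
                     ernst_angle, zur_reference)

schedule = build_default_protocol()   # TR 20 ms, TE 4 ms, 0.30 mm voxel,
                                      # spoilers 3 / 3.76 cycles per voxel
tissue = zur_reference(schedule.tr)   # T1 = T2 = 20 TR, no diffusion

print(f"Ernst angle: {ernst_angle(schedule.tr / tissue.t1):.1f} deg")
for psi in STUDIED_PSI:
    print(f"psi = {psi:6.1f} deg   epsilon = {compute_epsilon(schedule, tissue, psi):5.1f} %")
```

prints

```
Ernst angle: 18.0 deg
psi =   50.0 deg   epsilon =  15.2 %
psi =  115.4 deg   epsilon =   5.5 %
psi =  117.0 deg   epsilon =  14.6 %
psi =  150.0 deg   epsilon =  17.9 %
psi =  169.0 deg   epsilon =   6.1 %
```

For these relaxation times (T1/TR = T2/TR = 20, the classic benchmark
parameterization) the signal-vs-flip-angle curves of ψ = 115.4° and 169°
deviate from the ideal (Ernst) curve by ~5–6% on average over the flip grid,
while 50°, 117° and 150° miss it by ~15–18% — a contrast difference that is
plainly visible in images of low-diffusion liquids. The `examples/`
directory walks through each capability: signal curves with and without
diffusion, parameter-space maps, resolution sweeps, and the synthetic
phantom pipeline.

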