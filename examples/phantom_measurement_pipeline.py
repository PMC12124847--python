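"""End-to-end synthetic phantom experiment.

Generates a noisy ROI measurement of the silicone-oil phantom for the five
studied phase difference increments, normalizes every curve at the flip angle
nearest the Ernst angle (where curves for all psi coincide), and compares
against noise-free simulations -- the same processing applied to real
scanner ROI exports.
"""

import numpy as np

from rfspoil import (
    PRESETS,
    STUDIED_PSI,
    SpoilingScheme,
    build_default_protocol,
    compare_measured_simulated,
    ernst_angle,
    generate_measurement,
    normalize_at_ernst,
    signal_curve,
)

schedule = build_default_protocol()
spec = PRESETS["SiliconeOil"]
flips = tuple(np.arange(5.0, 91.0, 5.0))
schemes = tuple(SpoilingScheme(p) for p in STUDIED_PSI)

measured = generate_measurement(
    spec, schemes, flips, schedule, noise_sigma=0.005, roi_voxel_count=500, seed=7
)
measured = normalize_at_ernst(measured, schedule.tr / spec.tissue.t1)
print(f"curves normalized at {measured.normalization_flip:.0f} deg "
      f"(Ernst angle {ernst_angle(schedule.tr / spec.tissue.t1):.1f} deg)")

simulated = {s.psi: signal_curve(schedule, spec.tissue, s, flips) for s in schemes}
report = compare_measured_simulated(measured, simulated)
print(report.round(4).to_string(index=False))
print(
    "\nresiduals at the noise level of the synthetic ROI confirm the"
    " measurement chain reproduces the simulated curves"
)
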