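"""Spoiling quality versus voxel size for grey matter at 3 T.

Halving the voxel size doubles the gradient amplitudes, which doubles the
diffusion weighting of every dephased configuration: epsilon falls toward 0
at high resolution (not necessarily monotonically).
"""

from rfspoil import (
    PRESETS,
    SweepConfig,
    build_default_protocol,
    voxel_size_sweep,
)

config = SweepConfig(
    psis=(50.0, 115.4, 169.0),
    voxel_sizes=(0.075, 0.15, 0.3, 0.6, 1.2),
    n_pulses=1500,
)
table = voxel_size_sweep(
    config, PRESETS["GreyMatter3T"].tissue, build_default_protocol()
)

print("epsilon [%] vs readout voxel size, grey matter (D = 0.8e-3 mm^2/s):")
print(
    table.pivot(index="voxel_mm", columns="psi_deg", values="epsilon_pct").round(2)
)
print("\nsmaller voxels -> stronger spoiler dephasing per mm -> better spoiling")
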