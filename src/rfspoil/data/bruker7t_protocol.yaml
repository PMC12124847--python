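# RF-spoiled 3D gradient-echo protocol of the 7 T liquid-phantom study.
# The lobe layout generated from these parameters is a documented
# approximation (1 ms prephaser, readout plateau centered on TE sized from
# bandwidth and matrix, 1.5 ms end-of-TR spoilers); add an explicit `lobes:`
# list to enter a measured gradient table instead.
protocol:
  tr: 20.0                 # ms
  te: 4.0                  # ms
  voxel_readout: 0.30      # mm
  voxel_slice: 0.78        # mm
  readout_cycles: 3.0      # net spoiling moment, cycles per voxel (3 * 2pi)
  slice_cycles: 3.76       # cycles per voxel on the slice axis
  readout_bandwidth_khz: 50.0
  matrix_readout: 100
  prephaser_duration: 1.0  # ms
  spoiler_duration: 1.5    # ms
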