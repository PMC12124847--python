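"""Map the spoiling quality over a small (T1/TR, T2/TR) slab.

A coarse version of the full parameter-space sweep: epsilon is computed on a
sub-grid of the log10 axes for one psi and printed as a matrix (rows:
log10(T2/TR), columns: log10(T1/TR); NaN marks unphysical T2 > T1 cells).
The full 34x34 half-grid with five psi values runs the same way and is
resumable through SweepConfig(cache_path=...).
"""

from rfspoil import SweepConfig, build_default_protocol, grid_sweep

config = SweepConfig(
    psis=(115.4,),
    t1_tenths=(0, 8, 16, 23),   # T1/TR = 1 .. 200
    t2_tenths=(0, 8, 16, 23),   # T2/TR = 1 .. 200
)
grid = grid_sweep(config, build_default_protocol())

print("epsilon [%] for psi = 115.4 deg, D = 0, TR = 20 ms")
print(grid.matrix(psi=115.4).round(2))
worst = grid.argmax()
print(
    f"\nworst cell of this slab: epsilon = {worst.epsilon_pct:.1f}% at "
    f"log10(T1/TR) = {worst.log10_t1_tenths / 10:.1f}, "
    f"log10(T2/TR) = {worst.log10_t2_tenths / 10:.1f}"
)
print("spoiling degrades toward long T2/TR, where dephased history persists")
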