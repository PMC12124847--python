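"""Ernst closed forms, the epsilon spoiling-quality metric, and sweep pipelines.

Ideal spoiling means the steady-state signal of the RF-spoiled gradient echo
equals the Ernst amplitude

    S_Ernst(TR/T1, alpha) = M0 (1 - E1) sin(alpha) / (1 - E1 cos(alpha)),
    E1 = exp(-TR/T1),

which is maximal at the Ernst angle ``alpha_E = arccos(E1)`` and carries no T2
dependence.  How closely a given phase difference increment psi approaches
this is quantified by epsilon, the flip-angle-averaged absolute relative
deviation of the simulated curve from the Ernst curve in percent:

    epsilon = 100 / N * sum_k |S+(alpha_k) - S_Ernst(alpha_k)| / S_Ernst(alpha_k)

over the standard grid of N = 18 flip angles, 5..90 deg in 5 deg steps.
Smaller epsilon means better spoiling.

Three pipelines map epsilon over the studied parameter spaces:

* :func:`grid_sweep` -- a (T1/TR, T2/TR) grid, log10 axes from -1 to 2.3 in
  steps of 0.1 (34 values, cells with T2 > T1 masked), for sets of psi,
  diffusion coefficient and TR;
* :func:`voxel_size_sweep` -- epsilon versus readout voxel size, realized by
  scaling the gradient amplitudes inversely with the voxel size;
* :func:`substance_table` -- epsilon for named substances, with the diffusion
  coefficient as given and forced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_model import (
    SpoilingScheme,
    TRSchedule,
    build_default_protocol,
    scale_resolution,
)
from .signal_engine import (
    DEFAULT_FLIPS,
    SignalCurve,
    TissueParams,
    signal_curve,
)

__all__ = [
    "STUDIED_PSI",
    "ErnstCurve",
    "ernst_amplitude",
    "ernst_angle",
    "epsilon",
    "SweepConfig",
    "EpsilonGrid",
    "grid_sweep",
    "voxel_size_sweep",
    "substance_table",
    "compute_epsilon",
    "zur_reference",
    "plot_epsilon_map",
]

#: The five phase difference increments under study (four vendor values plus
#: the 169 deg increment recommended for T1 mapping).
STUDIED_PSI = (50.0, 115.4, 117.0, 150.0, 169.0)


def ernst_amplitude(tr_over_t1, flip_deg, m0: float = 1.0):
    """Ideally spoiled steady-state amplitude (saturation recovery).

    Vectorized over both arguments; returns values in units of m0.
    """
    tr_over_t1 = np.asarray(tr_over_t1, dtype=float)
    if np.any(tr_over_t1 <= 0):
        raise ValueError("TR/T1 must be > 0")
    a = np.deg2rad(np.asarray(flip_deg, dtype=float))
    e1 = np.exp(-tr_over_t1)
    return m0 * (1.0 - e1) * np.sin(a) / (1.0 - e1 * np.cos(a))


def ernst_angle(tr_over_t1) -> float | np.ndarray:
    """Ernst angle arccos(exp(-TR/T1)) in degrees (vectorized)."""
    tr_over_t1 = np.asarray(tr_over_t1, dtype=float)
    if np.any(tr_over_t1 <= 0):
        raise ValueError("TR/T1 must be > 0")
    out = np.degrees(np.arccos(np.exp(-tr_over_t1)))
    return float(out) if out.ndim == 0 else out


def epsilon(curve: SignalCurve, tr_over_t1: float, m0: float = 1.0) -> float:
    """Flip-angle-averaged absolute relative deviation from the Ernst curve, %."""
    ref = ernst_amplitude(tr_over_t1, curve.flip_angles, m0=m0)
    if np.any(ref == 0):
        raise ValueError(
            "Ernst amplitude vanishes on the flip grid; epsilon is undefined "
            "(use flip angles > 0)"
        )
    return float(100.0 * np.mean(np.abs(curve.s_plus - ref) / np.abs(ref)))


def compute_epsilon(
    schedule: TRSchedule,
    tissue: TissueParams,
    psi: float,
    flips: Sequence[float] = DEFAULT_FLIPS,
    **engine_kwargs,
) -> float:
    """Simulate one curve and return its epsilon (convenience wrapper)."""
    curve = signal_curve(
        schedule, tissue, SpoilingScheme(psi), flips, **engine_kwargs
    )
    return epsilon(curve, schedule.tr / tissue.t1, m0=tissue.m0)


@dataclass(frozen=True)
class ErnstCurve:
    """Ideally spoiled reference curve over a flip grid.

    ``amplitudes[k] = S_Ernst(tr_over_t1, flip_angles[k])``; the curve is
    zero at 0 deg and maximal at the Ernst angle.
    """

    tr_over_t1: float
    flip_angles: np.ndarray
    amplitudes: np.ndarray

    @classmethod
    def compute(
        cls, tr_over_t1: float, flip_angles: Sequence[float] = DEFAULT_FLIPS,
        m0: float = 1.0,
    ) -> "ErnstCurve":
        flips = np.asarray(flip_angles, dtype=float)
        return cls(
            tr_over_t1=tr_over_t1,
            flip_angles=flips,
            amplitudes=ernst_amplitude(tr_over_t1, flips, m0=m0),
        )

    @property
    def ernst_angle(self) -> float:
        return float(ernst_angle(self.tr_over_t1))


def zur_reference(tr: float = 20.0) -> TissueParams:
    """The reference parameter set T1/TR = T2/TR = 20, no diffusion."""
    return TissueParams(t1=20.0 * tr, t2=20.0 * tr, d=0.0)


#: Integer-tenths log10 axis of the default grid: -1.0 .. 2.3 step 0.1.
DEFAULT_TENTHS = tuple(range(-10, 24))


@dataclass
class SweepConfig:
    """Configuration of the epsilon sweep pipelines.

    Grid axes are specified as integer tenths of log10(T1/TR) and
    log10(T2/TR) so cells have exact keys (no float drift in axis values).
    """

    flips: tuple[float, ...] = DEFAULT_FLIPS
    psis: tuple[float, ...] = STUDIED_PSI
    d_values: tuple[float, ...] = (0.0,)
    tr_values: tuple[float, ...] = (20.0,)
    t1_tenths: tuple[int, ...] = DEFAULT_TENTHS
    t2_tenths: tuple[int, ...] = DEFAULT_TENTHS
    voxel_sizes: tuple[float, ...] = (0.1, 0.15, 0.2, 0.3, 0.45, 0.6, 0.9, 1.2)
    n_pulses: int | None = None
    window: int = 100
    floor: float = 1e-12
    cache_path: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.flips or not self.psis:
            raise ValueError("flip grid and psi set must be non-empty")


GRID_COLUMNS = [
    "tr_ms",
    "d_mm2_per_s",
    "psi_deg",
    "log10_t1_tenths",
    "log10_t2_tenths",
    "epsilon_pct",
]


@dataclass
class EpsilonGrid:
    """Long-format epsilon table over (TR, D, psi, T1/TR, T2/TR) cells.

    Cells with T2 > T1 are absent (never simulated).  ``matrix`` pivots one
    (psi, d, tr) slice into a 2D array with log10(T2/TR) rows and
    log10(T1/TR) columns, with unphysical cells as NaN.
    """

    table: pd.DataFrame

    def matrix(self, psi: float, d: float = 0.0, tr: float = 20.0) -> pd.DataFrame:
        sel = self.table[
            (self.table.psi_deg == psi)
            & (self.table.d_mm2_per_s == d)
            & (self.table.tr_ms == tr)
        ]
        pivot = sel.pivot(
            index="log10_t2_tenths", columns="log10_t1_tenths", values="epsilon_pct"
        )
        pivot.index = pivot.index / 10.0
        pivot.columns = pivot.columns / 10.0
        return pivot

    def argmax(self) -> pd.Series:
        """Row of the grid with the largest epsilon."""
        return self.table.loc[self.table.epsilon_pct.idxmax()]

    def best_psi(self, d: float = 0.0, tr: float = 20.0) -> pd.DataFrame:
        """Per-cell argmin over psi; ties break toward smaller psi."""
        sel = self.table[
            (self.table.d_mm2_per_s == d) & (self.table.tr_ms == tr)
        ].sort_values("psi_deg", kind="stable")
        idx = sel.groupby(["log10_t2_tenths", "log10_t1_tenths"])[
            "epsilon_pct"
        ].idxmin()
        out = sel.loc[idx, ["log10_t2_tenths", "log10_t1_tenths", "psi_deg", "epsilon_pct"]]
        return out.reset_index(drop=True)


def _load_cache(path: Path) -> pd.DataFrame:
    if path.exists():
        return pd.read_csv(path)
    return pd.DataFrame(columns=GRID_COLUMNS)


def grid_sweep(config: SweepConfig, schedule: TRSchedule | None = None) -> EpsilonGrid:
    """Epsilon over the (T1/TR, T2/TR) grid for each (psi, D, TR).

    Cells violating T2 <= T1 are skipped.  Each cell runs one vectorized
    simulation over the whole flip grid.  With a ``cache_path`` set, finished
    cells are appended to a CSV as they complete and are not recomputed on a
    rerun, so a long sweep is resumable.
    """
    cache = None
    if config.cache_path is not None:
        cache_file = Path(config.cache_path)
        cache = _load_cache(cache_file)
    rows: list[dict] = []
    for tr in config.tr_values:
        sched = (
            build_default_protocol(tr=tr)
            if schedule is None
            else (schedule if schedule.tr == tr else build_default_protocol(tr=tr))
        )
        for d in config.d_values:
            for psi in config.psis:
                for j in sorted(config.t2_tenths):
                    t2_ratio = 10.0 ** (j / 10.0)
                    for i in sorted(config.t1_tenths):
                        if i < j:  # T2 > T1: unphysical cell
                            continue
                        if cache is not None:
                            hit = cache[
                                (cache.tr_ms == tr)
                                & (cache.d_mm2_per_s == d)
                                & (cache.psi_deg == psi)
                                & (cache.log10_t1_tenths == i)
                                & (cache.log10_t2_tenths == j)
                            ]
                            if len(hit):
                                rows.append(hit.iloc[0].to_dict())
                                continue
                        t1_ratio = 10.0 ** (i / 10.0)
                        tissue = TissueParams(
                            t1=t1_ratio * tr, t2=min(t2_ratio, t1_ratio) * tr, d=d
                        )
                        eps = compute_epsilon(
                            sched,
                            tissue,
                            psi,
                            flips=config.flips,
                            n_pulses=config.n_pulses,
                            window=config.window,
                            floor=config.floor,
                        )
                        row = {
                            "tr_ms": tr,
                            "d_mm2_per_s": d,
                            "psi_deg": psi,
                            "log10_t1_tenths": i,
                            "log10_t2_tenths": j,
                            "epsilon_pct": eps,
                        }
                        rows.append(row)
                        if cache is not None:
                            pd.DataFrame([row]).to_csv(
                                cache_file,
                                mode="a",
                                header=not cache_file.exists(),
                                index=False,
                            )
    table = pd.DataFrame(rows, columns=GRID_COLUMNS).astype(
        {"log10_t1_tenths": int, "log10_t2_tenths": int}
    )
    return EpsilonGrid(table=table)


def voxel_size_sweep(
    config: SweepConfig,
    substance: TissueParams,
    base_schedule: TRSchedule,
) -> pd.DataFrame:
    """Epsilon versus readout voxel size for one substance.

    Each voxel size rescales the base schedule's gradient amplitudes
    (smaller voxel -> stronger gradients -> more diffusion weighting) while
    the spoiling moment in cycles per voxel stays fixed.  Returns a table
    ordered by voxel size with columns voxel_mm, psi_deg, tr_ms, epsilon_pct.
    """
    if any(v <= 0 for v in config.voxel_sizes):
        raise ValueError("voxel sizes must be positive")
    base_voxel = base_schedule.voxel_size[0]
    rows = []
    for voxel in sorted(config.voxel_sizes):
        sched = scale_resolution(base_schedule, voxel / base_voxel)
        for psi in config.psis:
            rows.append(
                {
                    "voxel_mm": voxel,
                    "psi_deg": psi,
                    "tr_ms": base_schedule.tr,
                    "epsilon_pct": compute_epsilon(
                        sched,
                        substance,
                        psi,
                        flips=config.flips,
                        n_pulses=config.n_pulses,
                        window=config.window,
                        floor=config.floor,
                    ),
                }
            )
    return pd.DataFrame(rows)


def substance_table(
    substances: Mapping[str, TissueParams],
    psis: Sequence[float] = STUDIED_PSI,
    trs: Sequence[float] = (20.0, 50.0),
    schedule_factory: Callable[[float], TRSchedule] | None = None,
    flips: Sequence[float] = DEFAULT_FLIPS,
    **engine_kwargs,
) -> pd.DataFrame:
    """Epsilon matrix for named substances: psi rows, substance/TR/D columns.

    Every substance is evaluated both with its diffusion coefficient as given
    (``diffusion='on'``) and with D forced to zero (``diffusion='off'``);
    both coincide for substances with D = 0.
    """
    if schedule_factory is None:
        schedule_factory = lambda tr: build_default_protocol(tr=tr)
    columns: dict[tuple, list[float]] = {}
    for name, tissue in substances.items():
        for tr in trs:
            sched = schedule_factory(tr)
            for diff_flag, d in (("on", tissue.d), ("off", 0.0)):
                key = (name, tr, diff_flag)
                sub = TissueParams(t1=tissue.t1, t2=tissue.t2, d=d, m0=tissue.m0)
                columns[key] = [
                    compute_epsilon(sched, sub, psi, flips=flips, **engine_kwargs)
                    for psi in psis
                ]
    out = pd.DataFrame(columns, index=pd.Index(list(psis), name="psi_deg"))
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["substance", "tr_ms", "diffusion"]
    )
    return out


def plot_epsilon_map(
    grid: EpsilonGrid,
    psi: float,
    d: float = 0.0,
    tr: float = 20.0,
    ax=None,
    vmin_log10: float = -2.0,
    vmax_log10: float = 2.2,
):
    """Heat map of log10(epsilon) over the (T1/TR, T2/TR) plane (optional).

    Rendering is a convenience for inspection; no pipeline depends on it.
    """
    import matplotlib.pyplot as plt  # deferred: rendering is optional

    mat = grid.matrix(psi, d=d, tr=tr)
    if ax is None:
        _, ax = plt.subplots()
    img = ax.imshow(
        np.log10(mat.values),
        origin="lower",
        aspect="auto",
        vmin=vmin_log10,
        vmax=vmax_log10,
        extent=(
            mat.columns.min(),
            mat.columns.max(),
            mat.index.min(),
            mat.index.max(),
        ),
        cmap="viridis",
    )
    ax.set_xlabel("log10(T1/TR)")
    ax.set_ylabel("log10(T2/TR)")
    ax.set_title(f"log10(epsilon), psi={psi} deg, D={d} mm^2/s, TR={tr} ms")
    plt.colorbar(img, ax=ax, label="log10(epsilon / %)")
    return ax
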