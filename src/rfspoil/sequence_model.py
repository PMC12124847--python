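"""RF phase cycle and gradient-lobe schedule of one repetition interval.

An RF-spoiled gradient-echo sequence combines an unbalanced gradient schedule
(the spoilers) with a quadratically increasing RF pulse phase
``phi_n = n(n+1) psi / 2`` controlled by the phase difference increment psi.
This module provides the phase cycle, a :class:`TRSchedule` describing the
gradient lobes of one TR on the readout and slice axes, a builder for the
default protocol layout (prephaser + readout plateau centered on the echo
time + end-of-TR spoilers), resolution scaling, and the partition of a
schedule into :class:`~rfspoil.epg_core.EvolutionInterval` pieces consumed by
the EPG engine.

The default lobe layout is a documented approximation of a real product
sequence: the prephaser lasts 1 ms and ends where the readout plateau starts,
the plateau is sized from the readout bandwidth and matrix and is centered on
TE, and both spoilers sit at the end of the TR.  Every timing and amplitude
can be overridden, either directly or through a YAML config file
(:mod:`rfspoil.config`), so an exact measured gradient table can be entered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

from .epg_core import EvolutionInterval

__all__ = [
    "GAMMA_RAD_PER_MS_MM_MT_M",
    "SpoilingScheme",
    "PulseIndex",
    "GradientLobe",
    "TRSchedule",
    "ConfigurationError",
    "quadratic_phase",
    "build_default_protocol",
    "scale_resolution",
    "schedule_to_intervals",
]

#: Proton gyromagnetic ratio expressed as rad/(ms * mm) of dephasing per mT/m
#: of gradient amplitude: gamma = 2.6752218744e8 rad/s/T.
GAMMA_RAD_PER_MS_MM_MT_M = 2.6752218744e8 * 1e-6 * 1e-3

AXES = ("readout", "slice")


class ConfigurationError(ValueError):
    """Raised for inconsistent sequence timing or gradient configuration."""


@dataclass(frozen=True)
class SpoilingScheme:
    """RF spoiling scheme: the phase difference increment psi in degrees."""

    psi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi < 360.0:
            raise ValueError(f"psi must be in [0, 360) degrees, got {self.psi}")


@dataclass(frozen=True)
class PulseIndex:
    """Non-negative RF pulse counter n."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("pulse index must be >= 0")


def quadratic_phase(scheme: SpoilingScheme, n: "PulseIndex | int") -> float:
    """Phase of the n-th RF pulse, ``n(n+1) psi / 2`` reduced modulo 360.

    For psi values that are whole millidegrees (all values in practical use)
    the reduction is done in exact integer arithmetic so the cycle does not
    drift at large n; otherwise a float fallback is used.
    """
    idx = n.n if isinstance(n, PulseIndex) else int(n)
    if idx < 0:
        raise ValueError("pulse index must be >= 0")
    tri = idx * (idx + 1) // 2
    mdeg = round(scheme.psi * 1000.0)
    if abs(scheme.psi * 1000.0 - mdeg) < 1e-9:
        return (tri * mdeg % 360000) / 1000.0
    return math.fmod(tri * scheme.psi, 360.0)


@dataclass(frozen=True)
class GradientLobe:
    """Rectangular gradient lobe on one axis.

    ``amplitude`` is in mT/m (signed), ``duration`` and ``start_time`` in ms
    within the TR.  The dephasing moment of the lobe is
    ``gamma * amplitude * duration`` in rad/mm.
    """

    axis: str
    amplitude: float
    duration: float
    start_time: float

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.duration <= 0:
            raise ValueError("lobe duration must be > 0")
        if self.start_time < 0:
            raise ValueError("lobe start_time must be >= 0")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def moment(self) -> float:
        """Dephasing moment in rad/mm."""
        return GAMMA_RAD_PER_MS_MM_MT_M * self.amplitude * self.duration


@dataclass(frozen=True)
class TRSchedule:
    """Gradient schedule of one repetition interval.

    ``voxel_size`` and ``spoil_cycles`` are (readout, slice) pairs; the net
    per-TR dephasing on each axis is ``2 pi * cycles / voxel`` rad/mm and the
    lobes must sum to it (validated in :func:`schedule_to_intervals`).
    """

    tr: float
    te: float
    lobes: tuple[GradientLobe, ...]
    voxel_size: tuple[float, float]
    spoil_cycles: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.te < self.tr:
            raise ConfigurationError(
                f"need 0 < TE < TR, got TE={self.te}, TR={self.tr}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be > 0")
        for lobe in self.lobes:
            if lobe.end_time > self.tr + 1e-9:
                raise ConfigurationError(
                    f"lobe on {lobe.axis} ends at {lobe.end_time} ms > TR"
                )

    @property
    def dephasing_per_tr(self) -> tuple[float, float]:
        """Net per-TR dephasing per axis (rad/mm): one configuration order."""
        return tuple(
            2.0 * math.pi * c / v for c, v in zip(self.spoil_cycles, self.voxel_size)
        )

    def net_lobe_moment(self, axis: str) -> float:
        """Signed sum of lobe moments on one axis (rad/mm)."""
        return sum(l.moment for l in self.lobes if l.axis == axis)


def build_default_protocol(
    tr: float = 20.0,
    te: float = 4.0,
    voxel_readout: float = 0.30,
    voxel_slice: float = 0.78,
    readout_cycles: float = 3.0,
    slice_cycles: float = 3.76,
    readout_bandwidth_khz: float = 50.0,
    matrix_readout: int = 100,
    prephaser_duration: float = 1.0,
    spoiler_duration: float = 1.5,
) -> TRSchedule:
    """Default TR schedule: prephaser, readout plateau around TE, spoilers.

    The readout plateau lasts ``matrix / bandwidth`` ms and traverses the full
    k-space width ``2 pi / voxel`` rad/mm, so the echo (zero cumulative
    readout moment) forms exactly at TE.  End-of-TR spoilers on both axes top
    the net dephasing up to ``readout_cycles`` / ``slice_cycles`` cycles per
    voxel.  ``readout_cycles = 0`` yields a balanced readout axis (the spoiler
    becomes a rewinder).
    """
    if min(tr, te, voxel_readout, voxel_slice) <= 0:
        raise ConfigurationError("tr, te and voxel sizes must be positive")
    if te >= tr:
        raise ConfigurationError(f"need TE < TR, got TE={te}, TR={tr}")
    gamma = GAMMA_RAD_PER_MS_MM_MT_M
    plateau_duration = matrix_readout / readout_bandwidth_khz  # ms
    plateau_start = te - plateau_duration / 2.0
    if plateau_start - prephaser_duration < 0:
        raise ConfigurationError(
            "readout plateau and prephaser do not fit before TE; "
            "increase TE or shorten the prephaser"
        )
    spoiler_start = tr - spoiler_duration
    if spoiler_start < te + plateau_duration / 2.0:
        raise ConfigurationError("spoilers overlap the readout plateau")

    plateau_moment = 2.0 * math.pi / voxel_readout  # full k-space width
    prephaser_moment = -plateau_moment / 2.0  # echo at TE
    net_readout = 2.0 * math.pi * readout_cycles / voxel_readout
    readout_spoiler_moment = net_readout - plateau_moment - prephaser_moment
    slice_spoiler_moment = 2.0 * math.pi * slice_cycles / voxel_slice

    lobes = [
        GradientLobe(
            axis="readout",
            amplitude=prephaser_moment / (gamma * prephaser_duration),
            duration=prephaser_duration,
            start_time=plateau_start - prephaser_duration,
        ),
        GradientLobe(
            axis="readout",
            amplitude=plateau_moment / (gamma * plateau_duration),
            duration=plateau_duration,
            start_time=plateau_start,
        ),
    ]
    if readout_spoiler_moment != 0.0:
        lobes.append(
            GradientLobe(
                axis="readout",
                amplitude=readout_spoiler_moment / (gamma * spoiler_duration),
                duration=spoiler_duration,
                start_time=spoiler_start,
            )
        )
    if slice_spoiler_moment != 0.0:
        lobes.append(
            GradientLobe(
                axis="slice",
                amplitude=slice_spoiler_moment / (gamma * spoiler_duration),
                duration=spoiler_duration,
                start_time=spoiler_start,
            )
        )
    return TRSchedule(
        tr=tr,
        te=te,
        lobes=tuple(lobes),
        voxel_size=(voxel_readout, voxel_slice),
        spoil_cycles=(readout_cycles, slice_cycles),
    )


def scale_resolution(schedule: TRSchedule, factor: float) -> TRSchedule:
    """Rescale the voxel size: ``factor = new_voxel / old_voxel``.

    All gradient amplitudes are scaled by 1/factor and the voxel sizes by
    factor, so the spoiling moment in cycles per voxel is invariant while the
    absolute dephasing (hence the diffusion weighting) scales with resolution.
    Halving the voxel size doubles the amplitudes.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    lobes = tuple(
        replace(lobe, amplitude=lobe.amplitude / factor) for lobe in schedule.lobes
    )
    return replace(
        schedule,
        lobes=lobes,
        voxel_size=tuple(v * factor for v in schedule.voxel_size),
    )


def _edge_times(schedule: TRSchedule, tol: float = 1e-9) -> list[float]:
    edges = {0.0, schedule.te, schedule.tr}
    for lobe in schedule.lobes:
        edges.add(lobe.start_time)
        edges.add(min(lobe.end_time, schedule.tr))
    ordered: list[float] = []
    for t in sorted(edges):
        if not ordered or t - ordered[-1] > tol:
            ordered.append(t)
    # snap the final edge onto TR
    ordered[-1] = schedule.tr
    return ordered


def schedule_to_intervals(
    schedule: TRSchedule,
) -> tuple[list[EvolutionInterval], int]:
    """Partition one TR into piecewise-constant evolution intervals.

    Returns the interval list and the index of the interval that starts at
    TE (the echo/sampling point).  Interval durations sum to TR and per-axis
    moments sum to the schedule's net dephasing; a tiny float mismatch from
    amplitude rounding is renormalized so the re-indexing at the end of the TR
    is exactly one order quantum.  Overlapping lobes on the same axis raise
    :class:`ConfigurationError`.
    """
    for axis in AXES:
        on_axis = sorted(
            (l for l in schedule.lobes if l.axis == axis), key=lambda l: l.start_time
        )
        for a, b in zip(on_axis, on_axis[1:]):
            if b.start_time < a.end_time - 1e-9:
                raise ConfigurationError(f"overlapping lobes on the {axis} axis")

    edges = _edge_times(schedule)
    net = schedule.dephasing_per_tr
    # raw per-interval moment rates
    raw: list[tuple[float, list[float]]] = []
    totals = [0.0, 0.0]
    for t0, t1 in zip(edges, edges[1:]):
        dur = t1 - t0
        mid = 0.5 * (t0 + t1)
        rates = []
        for ai, axis in enumerate(AXES):
            rate = sum(
                GAMMA_RAD_PER_MS_MM_MT_M * l.amplitude
                for l in schedule.lobes
                if l.axis == axis and l.start_time - 1e-9 <= mid <= l.end_time + 1e-9
            )
            rates.append(rate)
            totals[ai] += rate * dur
        raw.append((dur, rates))
    # validate and renormalize the tiny float drift
    scale = [1.0, 1.0]
    for ai in range(2):
        if abs(net[ai]) > 0:
            if abs(totals[ai] - net[ai]) > 1e-6 * max(1.0, abs(net[ai])):
                raise ConfigurationError(
                    f"lobe moments on the {AXES[ai]} axis sum to {totals[ai]:.6g} "
                    f"rad/mm but the schedule declares {net[ai]:.6g}"
                )
            scale[ai] = net[ai] / totals[ai]
        elif abs(totals[ai]) > 1e-9:
            raise ConfigurationError(
                f"lobe moments on the {AXES[ai]} axis sum to {totals[ai]:.6g} "
                "rad/mm but the schedule declares a balanced axis"
            )

    intervals: list[EvolutionInterval] = []
    cum = [0.0, 0.0]
    te_index = -1
    for (t0, _), (dur, rates) in zip(zip(edges, edges[1:]), raw):
        if abs(t0 - schedule.te) < 1e-9:
            te_index = len(intervals)
        moment = tuple(rates[ai] * dur * scale[ai] for ai in range(2))
        intervals.append(
            EvolutionInterval(
                duration=dur, moment=moment, start_offset=tuple(cum)
            )
        )
        cum = [cum[ai] + moment[ai] for ai in range(2)]
    if te_index < 0:  # pragma: no cover - TE is always inserted as an edge
        raise ConfigurationError("no interval boundary at TE")
    return intervals, te_index


def total_duration(intervals: Iterable[EvolutionInterval]) -> float:
    return sum(iv.duration for iv in intervals)
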