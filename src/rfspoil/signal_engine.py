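"""Steady-state signal of the RF-spoiled gradient echo, plus the isochromat oracle.

The quadratically phase-cycled sequence reaches a *pseudo steady state*: the
individual configuration amplitudes keep changing with the pulse counter n,
but the magnitude of the demodulated voxel signal |F_0| becomes
repetition-invariant.  :func:`steady_state_signal` and :func:`signal_curve`
drive the EPG ladder over many repetitions and report

* ``s_plus``  -- |F_0| directly after the RF pulse (the acquired signal, the
  integral of M+ over the intra-voxel dephasing angle), and
* ``s_minus`` -- |F_0| at the end of the repetition interval, directly before
  the next pulse.

Echo-time relaxation is deliberately not folded into ``s_plus``: it would
multiply every signal by the same exp(-TE/T2)-like factor, which cancels in
the normalized comparisons this signal is used for (set ``sample="te"`` to
sample the echo at TE instead).

Convergence policy: ``max(2000, 10 * T1/TR)`` pulses are simulated; the
reported value is the mean of |F_0| over the final ``window`` (default 100)
pulses and the peak-to-peak spread over that window is reported as the
residual.  A residual above 1e-4 * m0 triggers a warning.  The simulation is
fully deterministic.

:func:`isochromat_signal` is an independent brute-force check of the same
physics for D = 0: a dense uniform ensemble of isochromats with per-TR
precession angles theta in (-pi, pi] is evolved with plain 3x3 rotations and
relaxation, and the ensemble-mean transverse magnetization is the discrete
version of the signal integral.  It shares no code with the EPG ladder.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .epg_core import (
    longitudinal_b_values,
    transverse_b_values,
)
from .sequence_model import (
    SpoilingScheme,
    TRSchedule,
    quadratic_phase,
    schedule_to_intervals,
)

__all__ = [
    "TissueParams",
    "SignalCurve",
    "ConvergenceReport",
    "IsochromatEnsemble",
    "steady_state_signal",
    "signal_curve",
    "simulate_batch",
    "isochromat_signal",
    "curve_to_csv",
    "DEFAULT_FLIPS",
]

#: Flip-angle grid used throughout: 5 deg .. 90 deg in 5 deg steps (N = 18).
DEFAULT_FLIPS = tuple(float(a) for a in range(5, 91, 5))


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and diffusion parameters of one substance.

    t1, t2 in ms; d is the isotropic diffusion coefficient in mm^2/s; m0 the
    equilibrium magnetization (signals are reported in units of m0).
    """

    t1: float
    t2: float
    d: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1 >= self.t2 > 0:
            raise ValueError(f"need T1 >= T2 > 0, got T1={self.t1}, T2={self.t2}")
        if self.d < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.m0 <= 0:
            raise ValueError("m0 must be > 0")


@dataclass
class ConvergenceReport:
    """Per-flip convergence bookkeeping of a steady-state simulation."""

    n_pulses: int
    window: int
    residual: np.ndarray  # peak-to-peak of |F_0| over the window, per flip
    converged: np.ndarray  # residual <= tolerance, per flip
    tolerance: float


@dataclass
class SignalCurve:
    """Steady-state signal magnitudes over a flip-angle grid for one psi."""

    flip_angles: np.ndarray
    s_plus: np.ndarray
    s_minus: np.ndarray
    psi: float
    convergence: ConvergenceReport | None = None

    def __post_init__(self) -> None:
        self.flip_angles = np.asarray(self.flip_angles, dtype=float)
        self.s_plus = np.asarray(self.s_plus, dtype=float)
        self.s_minus = np.asarray(self.s_minus, dtype=float)
        if not (self.flip_angles.size == self.s_plus.size == self.s_minus.size):
            raise ValueError("flip, s_plus and s_minus lengths must match")


def _default_n_pulses(tr: float, t1: float) -> int:
    return max(2000, int(math.ceil(10.0 * t1 / tr)))


def _interval_factors(intervals, dephasing_per_tr, t1, t2, d, k_cap):
    """Per-interval multiplicative factors over the full order ladder.

    Returns (transverse factor over k = -K..K, longitudinal factor over
    k = 0..K, Z_0 regrowth increment per unit m0) for each interval.
    """
    k_t = np.arange(-k_cap, k_cap + 1)
    k_l = np.arange(k_cap + 1)
    out = []
    for iv in intervals:
        e2 = math.exp(-iv.duration / t2)
        e1 = math.exp(-iv.duration / t1)
        ft = e2 * np.exp(-d * transverse_b_values(k_t, iv, dephasing_per_tr))
        fl = e1 * np.exp(-d * longitudinal_b_values(k_l, iv, dephasing_per_tr))
        out.append((ft, fl, 1.0 - e1))
    return out


def simulate_batch(
    schedule: TRSchedule,
    tissue: TissueParams,
    scheme: SpoilingScheme,
    flips: Sequence[float],
    n_pulses: int | None = None,
    window: int = 100,
    floor: float = 1e-12,
    sample: str = "post_pulse",
    return_history: bool = False,
):
    """Simulate all flip angles of one curve in a single vectorized EPG run.

    Returns ``(s_plus, s_minus, report)`` with arrays over the flip grid, or
    ``(hist_plus, hist_minus)`` complex demodulated histories of shape
    (n_pulses, n_flips) when ``return_history`` is set.
    """
    flips = np.asarray(flips, dtype=float)
    if flips.size == 0:
        raise ValueError("flip-angle list must be non-empty")
    if np.any((flips <= 0) | (flips > 180)):
        raise ValueError("flip angles must lie in (0, 180] degrees")
    if sample not in ("post_pulse", "te"):
        raise ValueError(f"unknown sampling point {sample!r}")

    intervals, te_index = schedule_to_intervals(schedule)
    dq = schedule.dephasing_per_tr
    if all(abs(q) < 1e-12 for q in dq):
        raise ValueError(
            "fully balanced schedule: RF spoiling needs a net per-TR gradient moment"
        )
    if n_pulses is None:
        n_pulses = _default_n_pulses(schedule.tr, tissue.t1)
    window = min(window, n_pulses)

    # A pathway must spend one TR transverse per order gained, so its
    # amplitude at order k is bounded by exp(-k * TR / T2): orders beyond the
    # floor cannot contribute.
    if floor > 0:
        k_decay = int(math.ceil(-math.log(floor) * tissue.t2 / schedule.tr)) + 8
        k_cap = min(n_pulses, k_decay)
    else:
        k_cap = n_pulses

    n_f = flips.size
    width = 2 * k_cap + 1
    f = np.zeros((n_f, width), dtype=complex)
    z = np.zeros((n_f, k_cap + 1), dtype=complex)
    z[:, 0] = tissue.m0

    factors = _interval_factors(
        intervals, dq, tissue.t1, tissue.t2, tissue.d, k_cap
    )
    m0 = tissue.m0

    a = np.deg2rad(flips)[:, None]
    ca2 = np.cos(a / 2) ** 2
    sa2 = np.sin(a / 2) ** 2
    sa = np.sin(a)
    ca = np.cos(a)

    sig_plus = np.empty((n_pulses, n_f))
    sig_minus = np.empty((n_pulses, n_f))
    if return_history:
        hist_plus = np.empty((n_pulses, n_f), dtype=complex)
        hist_minus = np.empty((n_pulses, n_f), dtype=complex)

    ka = 0  # active half-width of the order ladder
    center = k_cap
    for n in range(n_pulses):
        ph = math.radians(quadratic_phase(scheme, n))
        eip = complex(math.cos(ph), math.sin(ph))
        ei2p = eip * eip
        lo, hi = center - ka, center + ka + 1

        fa = f[:, lo:hi]
        za = z[:, : ka + 1]
        frev = np.conj(fa[:, ::-1])
        if ka:
            zfull = np.concatenate(
                [np.conj(za[:, 1:])[:, ::-1], za], axis=1
            )
        else:
            zfull = za
        f_new = ca2 * fa + (sa2 * ei2p) * frev + (-1j * eip) * sa * zfull
        z_new = (
            (-0.5j * np.conj(eip)) * sa * fa[:, ka:]
            + (0.5j * eip) * sa * frev[:, ka:]
            + ca * za
        )
        f[:, lo:hi] = f_new
        z[:, : ka + 1] = z_new

        demod = np.conj(eip)
        if sample == "post_pulse":
            sig_plus[n] = np.abs(f[:, center])
            if return_history:
                hist_plus[n] = f[:, center] * demod

        for i, (ft, fl, regrow) in enumerate(factors):
            f[:, lo:hi] *= ft[lo:hi]
            z[:, : ka + 1] *= fl[: ka + 1]
            z[:, 0] += regrow * m0
            if sample == "te" and i == te_index - 1:
                sig_plus[n] = np.abs(f[:, center])
                if return_history:
                    hist_plus[n] = f[:, center] * demod

        # end of TR: accumulated moment is one order quantum -> re-index.
        # numpy evaluates the overlapping right-hand side before assigning.
        if ka < k_cap:
            f[:, lo + 1 : hi + 1] = f[:, lo:hi]
            f[:, lo] = 0.0
            ka += 1
        else:  # ladder at capacity: the topmost order (below floor) is dropped
            f[:, lo + 1 : hi] = f[:, lo : hi - 1]
            f[:, lo] = 0.0
        sig_minus[n] = np.abs(f[:, center])
        if return_history:
            hist_minus[n] = f[:, center] * demod

        if floor > 0 and ka > 8 and (n & 127) == 127:
            col = np.abs(f[:, center - ka : center + ka + 1]).max(axis=0)
            colz = np.abs(z[:, : ka + 1]).max(axis=0)
            live = np.flatnonzero(
                (col[ka:] + col[ka::-1][: ka + 1] + colz) >= floor * m0
            )
            new_ka = min(int(live.max()) + 1, k_cap) if live.size else 1
            if new_ka < ka:
                f[:, center - ka : center - new_ka] = 0.0
                f[:, center + new_ka + 1 : center + ka + 1] = 0.0
                z[:, new_ka + 1 : ka + 1] = 0.0
                ka = new_ka

    tol = 1e-4 * m0
    s_plus = sig_plus[-window:].mean(axis=0)
    s_minus = sig_minus[-window:].mean(axis=0)
    residual = np.ptp(sig_plus[-window:], axis=0)
    report = ConvergenceReport(
        n_pulses=n_pulses,
        window=window,
        residual=residual,
        converged=residual <= tol,
        tolerance=tol,
    )
    if np.any(~report.converged):
        worst = float(residual.max())
        warnings.warn(
            f"pseudo steady state residual {worst:.2e} exceeds {tol:.1e} "
            f"after {n_pulses} pulses; returning windowed mean",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_history:
        return hist_plus, hist_minus
    return s_plus, s_minus, report


def steady_state_signal(
    schedule: TRSchedule,
    tissue: TissueParams,
    scheme: SpoilingScheme,
    flip: float,
    **kwargs,
) -> tuple[float, float]:
    """Pseudo-steady-state (s_plus, s_minus) magnitudes for one flip angle."""
    s_plus, s_minus, _ = simulate_batch(schedule, tissue, scheme, [flip], **kwargs)
    return float(s_plus[0]), float(s_minus[0])


def signal_curve(
    schedule: TRSchedule,
    tissue: TissueParams,
    scheme: SpoilingScheme,
    flips: Sequence[float] = DEFAULT_FLIPS,
    **kwargs,
) -> SignalCurve:
    """Steady-state signal over a flip-angle grid (one vectorized EPG run)."""
    s_plus, s_minus, report = simulate_batch(
        schedule, tissue, scheme, flips, **kwargs
    )
    return SignalCurve(
        flip_angles=np.asarray(flips, dtype=float),
        s_plus=s_plus,
        s_minus=s_minus,
        psi=scheme.psi,
        convergence=report,
    )


@dataclass
class IsochromatEnsemble:
    """Discrete ensemble of spin packets for the brute-force signal integral.

    ``thetas`` are the per-TR precession angles, uniform over (-pi, pi];
    ``mplus`` (complex Mx + i My) and ``mz`` hold one magnetization vector
    per isochromat.
    """

    thetas: np.ndarray
    mplus: np.ndarray
    mz: np.ndarray

    @classmethod
    def uniform(cls, count: int, m0: float = 1.0) -> "IsochromatEnsemble":
        if count < 2:
            raise ValueError("need at least 2 isochromats")
        thetas = -math.pi + 2.0 * math.pi * (np.arange(count) + 0.5) / count
        return cls(
            thetas=thetas,
            mplus=np.zeros(count, dtype=complex),
            mz=np.full(count, float(m0)),
        )

    @property
    def count(self) -> int:
        return self.thetas.size

    def mean_transverse(self) -> complex:
        """The discretized signal integral: the ensemble mean of M+."""
        return complex(self.mplus.mean())


def isochromat_signal(
    schedule: TRSchedule,
    tissue: TissueParams,
    scheme: SpoilingScheme,
    flip: float,
    m_isochromats: int,
    n_pulses: int,
    return_history: bool = False,
):
    """Brute-force ensemble version of the signal integral (D = 0 only).

    ``m_isochromats`` spins with per-TR precession angles theta uniformly
    spanning (-pi, pi] are rotated by the phase-cycled pulses and relaxed over
    each TR; the ensemble mean of M+ is the discretized signal integral.  The
    ensemble must be dense enough that occupied dephasing orders do not alias:
    ``m_isochromats >= 2 * n_pulses``.
    """
    if tissue.d != 0:
        raise ValueError("the isochromat oracle is defined for D = 0 only")
    if m_isochromats < max(2, 2 * n_pulses):
        raise ValueError("need m_isochromats >= 2 * n_pulses to avoid aliasing")
    if not 0 < flip <= 180:
        raise ValueError("flip must be in (0, 180] degrees")

    ens = IsochromatEnsemble.uniform(m_isochromats, m0=tissue.m0)
    rot = np.exp(1j * ens.thetas)
    e2 = math.exp(-schedule.tr / tissue.t2)
    e1 = math.exp(-schedule.tr / tissue.t1)
    arad = math.radians(flip)
    ca2, sa2 = math.cos(arad / 2) ** 2, math.sin(arad / 2) ** 2
    sa, ca = math.sin(arad), math.cos(arad)

    hist_plus = np.empty(n_pulses, dtype=complex)
    hist_minus = np.empty(n_pulses, dtype=complex)
    for n in range(n_pulses):
        ph = math.radians(quadratic_phase(scheme, n))
        eip = complex(math.cos(ph), math.sin(ph))
        mp = ca2 * ens.mplus + (sa2 * eip * eip) * np.conj(ens.mplus) \
            - 1j * eip * sa * ens.mz
        ens.mz = sa * np.imag(np.conj(eip) * ens.mplus) + ca * ens.mz
        ens.mplus = mp
        hist_plus[n] = ens.mean_transverse() * np.conj(eip)
        # free evolution over one TR: relaxation plus gradient precession
        ens.mplus = ens.mplus * (e2 * rot)
        ens.mz = e1 * ens.mz + (1.0 - e1) * tissue.m0
        hist_minus[n] = ens.mean_transverse() * np.conj(eip)
    if return_history:
        return hist_plus, hist_minus
    return float(abs(hist_plus[-1])), float(abs(hist_minus[-1]))


def curve_to_csv(
    curve: SignalCurve,
    path: str | Path,
    schedule: TRSchedule | None = None,
    tissue: TissueParams | None = None,
) -> None:
    """Write a curve as CSV plus a JSON sidecar with protocol and convergence."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("flip_deg,s_plus,s_minus,psi_deg\n")
        for a, sp, sm in zip(curve.flip_angles, curve.s_plus, curve.s_minus):
            fh.write(f"{a:g},{sp:.10g},{sm:.10g},{curve.psi:g}\n")
    meta: dict = {"psi_deg": curve.psi}
    if curve.convergence is not None:
        meta["convergence"] = {
            "n_pulses": curve.convergence.n_pulses,
            "window": curve.convergence.window,
            "max_residual": float(curve.convergence.residual.max()),
            "all_converged": bool(curve.convergence.converged.all()),
        }
    if schedule is not None:
        meta["protocol"] = {
            "tr_ms": schedule.tr,
            "te_ms": schedule.te,
            "voxel_size_mm": list(schedule.voxel_size),
            "spoil_cycles_per_voxel": list(schedule.spoil_cycles),
        }
    if tissue is not None:
        meta["tissue"] = {
            "t1_ms": tissue.t1,
            "t2_ms": tissue.t2,
            "d_mm2_per_s": tissue.d,
            "m0": tissue.m0,
        }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))
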