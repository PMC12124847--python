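"""Extended-phase-graph (EPG) states and elementary evolution operators.

The EPG formalism represents the magnetization of a voxel as discrete Fourier
configurations of the intra-voxel dephasing angle theta set up by the
unbalanced gradients of one repetition interval: transverse configurations
``F_k`` (complex Fourier coefficients of M+ = Mx + i*My) and longitudinal
configurations ``Z_k`` (coefficients of Mz, Hermitian: Z_{-k} = conj(Z_k)).
The integer order ``k`` counts multiples of the net per-TR gradient dephasing
("one configuration order"); its physical spatial frequency is
``k * dephasing_per_tr`` on each gradient axis.

Four elementary operators evolve a state set:

* :func:`rf_rotation` -- RF pulse of given flip and phase; mixes
  ``(F_k, F_{-k}*, Z_k)`` with the same unitary 3x3 matrix at every order.
* :func:`evolve_interval` -- free evolution over a piece of the repetition
  interval: T2/T1 relaxation with regrowth of ``Z_0``, plus diffusion
  attenuation ``exp(-b D)`` with the b-value of each configuration's spatial
  frequency trajectory through the interval.
* :func:`shift` -- re-indexing of the transverse ladder once the accumulated
  gradient moment is an integer number of order quanta.
* :func:`truncate` -- drop orders whose amplitude fell below a floor.

Transverse states are stored for all orders k in [-K, K]; ``F_{-k}`` is kept
explicitly and every operator maintains the conjugation bookkeeping (the state
triple at order k couples ``F_k`` with ``conj(F_{-k})``).

Diffusion b-values follow the constant/linear spatial-frequency rules: for a
transverse configuration whose per-axis frequency moves linearly from q1 to q2
over duration tau, ``b = tau * (q1^2 + q1 q2 + q2^2) / 3`` (the exact integral
of q(t)^2); a longitudinal configuration sits at constant q, ``b = tau * q^2``.
Axes contribute additively for isotropic diffusion. Durations are in ms,
frequencies in rad/mm and diffusion coefficients in mm^2/s; the ms -> s
conversion is applied inside the b-value helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .signal_engine import TissueParams

__all__ = [
    "ConfigurationStateSet",
    "EvolutionInterval",
    "rf_rotation",
    "evolve_interval",
    "shift",
    "truncate",
    "rf_mixing_matrix",
    "transverse_b_values",
    "longitudinal_b_values",
]

MS_TO_S = 1.0e-3


@dataclass(frozen=True)
class EvolutionInterval:
    """One piecewise-constant slice of the repetition interval.

    Parameters
    ----------
    duration:
        Length of the interval in ms (>= 0).
    moment:
        Gradient moment added during the interval per axis, in rad/mm.
        A gap has zero moment on all axes.
    start_offset:
        Cumulative intra-TR dephasing per axis at the start of the interval
        (rad/mm), relative to the last re-indexing point.  Needed so the
        diffusion b-value of a configuration uses its true spatial-frequency
        trajectory, not just its integer order.
    """

    duration: float
    moment: tuple[float, float] = (0.0, 0.0)
    start_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"interval duration must be >= 0, got {self.duration}")

    @property
    def is_gap(self) -> bool:
        return all(m == 0.0 for m in self.moment)


@dataclass
class ConfigurationStateSet:
    """EPG configuration amplitudes of one voxel.

    ``f`` holds the transverse configurations F_k for k in [-K, K] (index
    ``k + K``), ``z`` the longitudinal configurations Z_k for k in [0, K].
    Amplitudes are dimensionless fractions of M0.  ``dephasing_per_tr`` is the
    spatial frequency of one configuration order per axis (rad/mm).
    """

    f: np.ndarray
    z: np.ndarray
    dephasing_per_tr: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=complex)
        self.z = np.asarray(self.z, dtype=complex)
        if self.f.ndim != 1 or self.z.ndim != 1:
            raise ValueError("state arrays must be one-dimensional")
        if self.f.size != 2 * self.z.size - 1:
            raise ValueError(
                f"inconsistent state sizes: len(f)={self.f.size} must equal "
                f"2*len(z)-1={2 * self.z.size - 1}"
            )

    @classmethod
    def equilibrium(
        cls,
        m0: float = 1.0,
        max_order: int = 0,
        dephasing_per_tr: tuple[float, float] = (0.0, 0.0),
    ) -> "ConfigurationStateSet":
        """Thermal equilibrium: Z_0 = m0, everything else zero."""
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        f = np.zeros(2 * max_order + 1, dtype=complex)
        z = np.zeros(max_order + 1, dtype=complex)
        z[0] = m0
        return cls(f=f, z=z, dephasing_per_tr=dephasing_per_tr)

    @property
    def max_order(self) -> int:
        return self.z.size - 1

    @property
    def orders(self) -> np.ndarray:
        """Integer orders k = -K .. K matching the layout of ``f``."""
        k = self.max_order
        return np.arange(-k, k + 1)

    def f_at(self, k: int) -> complex:
        """Transverse amplitude F_k (0 outside the stored range)."""
        if abs(k) > self.max_order:
            return 0.0 + 0.0j
        return complex(self.f[k + self.max_order])

    def z_at(self, k: int) -> complex:
        """Longitudinal amplitude Z_k; Z_{-k} = conj(Z_k)."""
        if abs(k) > self.max_order:
            return 0.0 + 0.0j
        if k < 0:
            return complex(np.conj(self.z[-k]))
        return complex(self.z[k])

    @property
    def transverse_energy(self) -> float:
        """Sum_k |F_k|^2 -- conserved by :func:`shift`."""
        return float(np.sum(np.abs(self.f) ** 2))

    def copy(self) -> "ConfigurationStateSet":
        return ConfigurationStateSet(
            f=self.f.copy(), z=self.z.copy(), dephasing_per_tr=self.dephasing_per_tr
        )


def rf_mixing_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """3x3 unitary mixing matrix acting on (F_k, conj(F_{-k}), Z_k).

    The pulse rotates the magnetization by ``flip_deg`` about an axis in the
    transverse plane at azimuth ``phase_deg`` from x.
    """
    if not 0.0 <= flip_deg <= 180.0:
        raise ValueError(f"flip angle must be in [0, 180] degrees, got {flip_deg}")
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    ca2 = np.cos(a / 2.0) ** 2
    sa2 = np.sin(a / 2.0) ** 2
    sa = np.sin(a)
    eip = np.exp(1j * p)
    return np.array(
        [
            [ca2, eip * eip * sa2, -1j * eip * sa],
            [np.conj(eip * eip) * sa2, ca2, 1j * np.conj(eip) * sa],
            [-0.5j * np.conj(eip) * sa, 0.5j * eip * sa, np.cos(a)],
        ],
        dtype=complex,
    )


def rf_rotation(
    states: ConfigurationStateSet, flip_deg: float, phase_deg: float
) -> ConfigurationStateSet:
    """Apply an RF pulse: the same 3x3 mixing at every configuration order."""
    t = rf_mixing_matrix(flip_deg, phase_deg)
    k = states.max_order
    f = states.f
    # Full-ladder update for all k in [-K, K]; Z is extended Hermitianly.
    f_rev = np.conj(f[::-1])  # conj(F_{-k}) at index k+K
    z_full = np.empty(2 * k + 1, dtype=complex)
    z_full[k:] = states.z
    if k > 0:
        z_full[:k] = np.conj(states.z[1:])[::-1]
    f_new = t[0, 0] * f + t[0, 1] * f_rev + t[0, 2] * z_full
    z_new = t[2, 0] * f[k:] + t[2, 1] * f_rev[k:] + t[2, 2] * states.z
    return ConfigurationStateSet(
        f=f_new, z=z_new, dephasing_per_tr=states.dephasing_per_tr
    )


def transverse_b_values(
    orders: np.ndarray,
    interval: EvolutionInterval,
    dephasing_per_tr: Sequence[float],
) -> np.ndarray:
    """Diffusion b-value (s/mm^2) per transverse order for one interval.

    The spatial frequency of order k on axis a runs linearly from
    ``k*dq_a + start_offset_a`` to ``k*dq_a + start_offset_a + moment_a``
    over the interval; b is the exact integral of q(t)^2, summed over axes.
    """
    orders = np.asarray(orders, dtype=float)
    tau = interval.duration * MS_TO_S
    b = np.zeros_like(orders)
    for dq, off, mom in zip(dephasing_per_tr, interval.start_offset, interval.moment):
        q1 = orders * dq + off
        q2 = q1 + mom
        b += tau * (q1 * q1 + q1 * q2 + q2 * q2) / 3.0
    return b


def longitudinal_b_values(
    orders: np.ndarray,
    interval: EvolutionInterval,
    dephasing_per_tr: Sequence[float],
) -> np.ndarray:
    """Diffusion b-value (s/mm^2) per longitudinal order: constant q = k*dq."""
    orders = np.asarray(orders, dtype=float)
    tau = interval.duration * MS_TO_S
    b = np.zeros_like(orders)
    for dq in dephasing_per_tr:
        b += tau * (orders * dq) ** 2
    return b


def evolve_interval(
    states: ConfigurationStateSet,
    interval: EvolutionInterval,
    tissue: "TissueParams",
) -> ConfigurationStateSet:
    """Relaxation, Z_0 regrowth and diffusion attenuation over one interval.

    Transverse amplitudes decay by exp(-tau/T2), longitudinal by exp(-tau/T1)
    with regrowth of Z_0 toward m0; every amplitude is additionally attenuated
    by exp(-b D) with the per-order b-values of this interval.  Relaxation and
    diffusion are diagonal in the configuration basis, so they commute and the
    composed factor is exact for piecewise-constant gradients.
    """
    if tissue.t2 <= 0 or tissue.t1 < tissue.t2 or tissue.d < 0:
        raise ValueError("tissue must satisfy T1 >= T2 > 0 and D >= 0")
    e2 = np.exp(-interval.duration / tissue.t2)
    e1 = np.exp(-interval.duration / tissue.t1)
    bt = transverse_b_values(states.orders, interval, states.dephasing_per_tr)
    bl = longitudinal_b_values(
        np.arange(states.max_order + 1), interval, states.dephasing_per_tr
    )
    f = states.f * (e2 * np.exp(-tissue.d * bt))
    z = states.z * (e1 * np.exp(-tissue.d * bl))
    z[0] += (1.0 - e1) * tissue.m0  # b = 0 at k = 0: regrowth is not attenuated
    return ConfigurationStateSet(f=f, z=z, dephasing_per_tr=states.dephasing_per_tr)


def shift(states: ConfigurationStateSet, n_units: int) -> ConfigurationStateSet:
    """Advance transverse orders: F_k -> F_{k+n_units}; Z unaffected.

    Storage grows by |n_units| so no amplitude is lost; Sum |F_k|^2 is
    conserved exactly.  With the full ladder stored for both signs of k the
    k = 0 crossing needs no explicit conjugation: negative orders are genuine
    amplitudes, not mirror copies.
    """
    n_units = int(n_units)
    if n_units == 0:
        return states.copy()
    k_old = states.max_order
    k_new = k_old + abs(n_units)
    f = np.zeros(2 * k_new + 1, dtype=complex)
    lo = (k_new - k_old) + n_units  # new index of old k = -K after the shift
    f[lo : lo + states.f.size] = states.f
    z = np.zeros(k_new + 1, dtype=complex)
    z[: states.z.size] = states.z
    return ConfigurationStateSet(f=f, z=z, dephasing_per_tr=states.dephasing_per_tr)


def truncate(
    states: ConfigurationStateSet, amplitude_floor: float
) -> ConfigurationStateSet:
    """Drop orders whose total amplitude is below ``amplitude_floor``."""
    if amplitude_floor < 0:
        raise ValueError("amplitude_floor must be >= 0")
    if amplitude_floor == 0:
        return states.copy()
    k = states.max_order
    keep = 0
    for order in range(k, 0, -1):
        total = (
            abs(states.f[k + order])
            + abs(states.f[k - order])
            + abs(states.z[order])
        )
        if total >= amplitude_floor:
            keep = order
            break
    f = states.f[k - keep : k + keep + 1].copy()
    z = states.z[: keep + 1].copy()
    return ConfigurationStateSet(f=f, z=z, dephasing_per_tr=states.dephasing_per_tr)
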