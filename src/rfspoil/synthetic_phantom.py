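"""Synthetic phantom measurements with ROI noise and Ernst-angle normalization.

Real validation data for the signal model are ROI means of magnitude images
of liquid phantoms, acquired once per flip angle and phase difference
increment.  This module emulates that measurement chain so the comparison
pipeline can be exercised end to end without a scanner:

* a *phantom* is a named tissue parameter set (:data:`PRESETS` holds the
  characterized liquids: CuSO4-doped water, silicone oil, Gd-doped water, and
  a grey-matter-like parameter set for 3 T);
* :func:`generate_measurement` simulates the true steady-state curve and
  draws, per flip angle, an ROI of Rician-distributed voxel magnitudes
  (true signal plus complex Gaussian noise, magnitude taken) whose mean is
  the recorded value -- the magnitude operation biases the mean at low
  signal, exactly as in real magnitude images;
* :func:`normalize_at_ernst` divides each curve by its own value at the
  measured flip angle closest to the Ernst angle, mirroring how measured
  curves are anchored to the ideally spoiled amplitude (curves for different
  psi coincide there);
* :func:`compare_measured_simulated` reports per-psi residuals between a
  measurement set and simulated curves after identical normalization.

Measurement sets round-trip through a documented CSV layout; a bare
two-column (flip, signal) file is also accepted so externally exported ROI
values can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_model import SpoilingScheme, TRSchedule
from .signal_engine import DEFAULT_FLIPS, SignalCurve, TissueParams, signal_curve
from .spoiling_analysis import epsilon, ernst_angle

__all__ = [
    "PhantomSpec",
    "PRESETS",
    "MeasurementSet",
    "NormalizationError",
    "AlignmentError",
    "generate_measurement",
    "normalize_at_ernst",
    "epsilon_from_measurement",
    "compare_measured_simulated",
    "measurement_to_csv",
    "measurement_from_csv",
]


def rician_roi_mean(
    true_signal: np.ndarray,
    noise_sigma: float,
    roi_voxel_count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ROI mean of Rician voxel magnitudes for each true signal value.

    Each voxel magnitude is |s + n_r + i n_i| with independent Gaussian noise
    of standard deviation ``noise_sigma`` per channel; for s = 0 the mean
    tends to the Rayleigh mean ``noise_sigma * sqrt(pi/2)``.
    """
    true_signal = np.atleast_1d(np.asarray(true_signal, dtype=float))
    noise = rng.normal(scale=noise_sigma, size=(2, true_signal.size, roi_voxel_count))
    voxels = np.abs(true_signal[:, None] + noise[0] + 1j * noise[1])
    return voxels.mean(axis=1)


class NormalizationError(ValueError):
    """No measured flip angle close enough to the Ernst angle."""


class AlignmentError(ValueError):
    """Measurement and simulation grids do not match."""


@dataclass(frozen=True)
class PhantomSpec:
    """A named phantom: tissue parameters of one liquid or tissue mimic."""

    name: str
    tissue: TissueParams


#: Characterized phantom liquids and a grey-matter-like reference (3 T).
#: The Gd-doped water phantom's diffusion coefficient was not characterized;
#: it is stored as 0 and the preset is meant for qualitative contrast only.
PRESETS: Mapping[str, PhantomSpec] = {
    "H2O_CuSO4": PhantomSpec("H2O_CuSO4", TissueParams(t1=540.0, t2=340.0, d=1.93e-3)),
    "SiliconeOil": PhantomSpec(
        "SiliconeOil", TissueParams(t1=1290.0, t2=399.0, d=0.0055e-3)
    ),
    "H2O_Gd": PhantomSpec("H2O_Gd", TissueParams(t1=1603.0, t2=613.0, d=0.0)),
    "GreyMatter3T": PhantomSpec(
        "GreyMatter3T", TissueParams(t1=1500.0, t2=100.0, d=0.8e-3)
    ),
}


@dataclass
class MeasurementSet:
    """Per-psi ROI-mean signal curves of one phantom.

    ``signal[psi]`` is the array of ROI means over ``flips``.  ``scale[psi]``
    records the cumulative factor each curve has been divided by, so the
    absolute (un-normalized) curve can always be recovered exactly:
    ``absolute = signal * scale``.
    """

    flips: np.ndarray
    psis: tuple[float, ...]
    signal: dict[float, np.ndarray]
    roi_voxel_count: int
    noise_sigma: float
    seed: int
    normalized: bool = False
    normalization_flip: float | None = None
    scale: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flips = np.asarray(self.flips, dtype=float)
        for psi in self.psis:
            if psi not in self.scale:
                self.scale[psi] = 1.0
            if len(self.signal[psi]) != self.flips.size:
                raise ValueError("signal length must match the flip grid")

    def absolute(self, psi: float) -> np.ndarray:
        """Curve in absolute units (normalization undone)."""
        return self.signal[psi] * self.scale[psi]


def generate_measurement(
    spec: PhantomSpec,
    schemes: Sequence[SpoilingScheme],
    flips: Sequence[float],
    schedule: TRSchedule,
    noise_sigma: float = 0.005,
    roi_voxel_count: int = 500,
    seed: int = 0,
    **engine_kwargs,
) -> MeasurementSet:
    """Simulate a noisy ROI measurement of the phantom's signal curves.

    For every flip angle, ``roi_voxel_count`` voxel magnitudes are drawn as
    |s_true + n| with n complex Gaussian of per-channel standard deviation
    ``noise_sigma`` (in units of m0), and their mean is recorded -- a Rician
    ROI mean.  ``noise_sigma = 0`` reproduces the simulated curve exactly.
    Deterministic for a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if roi_voxel_count < 1:
        raise ValueError("roi_voxel_count must be >= 1")
    rng = np.random.default_rng(seed)
    flips = np.asarray(flips, dtype=float)
    signal: dict[float, np.ndarray] = {}
    for scheme in schemes:
        curve = signal_curve(schedule, spec.tissue, scheme, flips, **engine_kwargs)
        if noise_sigma == 0.0:
            signal[scheme.psi] = curve.s_plus.copy()
            continue
        signal[scheme.psi] = rician_roi_mean(
            curve.s_plus, noise_sigma, roi_voxel_count, rng
        )
    return MeasurementSet(
        flips=flips,
        psis=tuple(s.psi for s in schemes),
        signal=signal,
        roi_voxel_count=roi_voxel_count,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def normalize_at_ernst(
    ms: MeasurementSet, tr_over_t1: float, max_distance: float = 2.5
) -> MeasurementSet:
    """Divide each curve by its own value at the flip nearest the Ernst angle.

    The normalization flip is recorded and the division factor accumulates in
    ``scale`` so the absolute curve remains recoverable.  Idempotent: a
    normalized curve has value 1 at the normalization flip.
    """
    alpha_e = ernst_angle(tr_over_t1)
    idx = int(np.argmin(np.abs(ms.flips - alpha_e)))
    if abs(ms.flips[idx] - alpha_e) > max_distance:
        raise NormalizationError(
            f"no measured flip within {max_distance} deg of the Ernst angle "
            f"{alpha_e:.1f} deg"
        )
    signal = {}
    scale = {}
    for psi in ms.psis:
        ref = float(ms.signal[psi][idx])
        if ref <= 0:
            raise NormalizationError(
                f"non-positive signal at the normalization flip for psi={psi}"
            )
        signal[psi] = ms.signal[psi] / ref
        scale[psi] = ms.scale[psi] * ref
    return replace(
        ms,
        signal=signal,
        scale=scale,
        normalized=True,
        normalization_flip=float(ms.flips[idx]),
    )


def epsilon_from_measurement(
    ms: MeasurementSet, tr_over_t1: float, m0: float = 1.0
) -> dict[float, float]:
    """Epsilon per psi computed from a measurement set in absolute units."""
    out = {}
    for psi in ms.psis:
        curve = SignalCurve(
            flip_angles=ms.flips,
            s_plus=ms.absolute(psi),
            s_minus=np.zeros_like(ms.flips),
            psi=psi,
        )
        out[psi] = epsilon(curve, tr_over_t1, m0=m0)
    return out


def compare_measured_simulated(
    ms: MeasurementSet,
    simulated: Mapping[float, SignalCurve],
) -> pd.DataFrame:
    """Per-psi residuals between measurement and simulation.

    Both sides are normalized identically (each by its own value at the
    measurement's normalization flip, if set) before computing, per psi, the
    mean and maximum absolute relative residual with respect to the simulated
    curve.
    """
    rows = []
    for psi in ms.psis:
        if psi not in simulated:
            raise AlignmentError(f"no simulated curve for psi={psi}")
        sim = simulated[psi]
        if sim.flip_angles.size != ms.flips.size or np.any(
            sim.flip_angles != ms.flips
        ):
            raise AlignmentError("measurement and simulation flip grids differ")
        meas = ms.signal[psi].copy()
        ref = sim.s_plus.copy()
        if ms.normalization_flip is not None:
            idx = int(np.argmin(np.abs(ms.flips - ms.normalization_flip)))
            meas = meas / meas[idx]
            ref = ref / ref[idx]
        rel = np.abs(meas - ref) / np.abs(ref)
        rows.append(
            {
                "psi_deg": psi,
                "mean_abs_rel_residual": float(rel.mean()),
                "max_abs_rel_residual": float(rel.max()),
            }
        )
    return pd.DataFrame(rows)


def measurement_to_csv(ms: MeasurementSet, path: str | Path) -> None:
    """Write the documented long-format measurement CSV."""
    rows = []
    for psi in ms.psis:
        for flip, val in zip(ms.flips, ms.signal[psi]):
            rows.append(
                {
                    "flip_deg": flip,
                    "psi_deg": psi,
                    "signal_mean": val,
                    "n_voxels": ms.roi_voxel_count,
                    "normalized_flag": int(ms.normalized),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def measurement_from_csv(path: str | Path, psi: float | None = None) -> MeasurementSet:
    """Read a measurement CSV.

    Accepts the full layout written by :func:`measurement_to_csv` or a bare
    two-column (flip, signal) export, in which case ``psi`` labels the single
    curve (NaN if not given).
    """
    df = pd.read_csv(path)
    if "psi_deg" not in df.columns:
        if df.shape[1] < 2:
            raise ValueError("two-column (flip, signal) layout expected")
        flips = df.iloc[:, 0].to_numpy(dtype=float)
        label = float("nan") if psi is None else float(psi)
        return MeasurementSet(
            flips=flips,
            psis=(label,),
            signal={label: df.iloc[:, 1].to_numpy(dtype=float)},
            roi_voxel_count=1,
            noise_sigma=0.0,
            seed=0,
        )
    psis = tuple(sorted(df.psi_deg.unique()))
    flips = np.sort(df[df.psi_deg == psis[0]].flip_deg.unique())
    signal = {}
    for p in psis:
        sub = df[df.psi_deg == p].sort_values("flip_deg")
        if sub.shape[0] != flips.size:
            raise AlignmentError("inconsistent flip grids between psi curves")
        signal[p] = sub.signal_mean.to_numpy(dtype=float)
    normalized = bool(df.normalized_flag.iloc[0]) if "normalized_flag" in df else False
    n_voxels = int(df.n_voxels.iloc[0]) if "n_voxels" in df else 1
    return MeasurementSet(
        flips=flips,
        psis=psis,
        signal=signal,
        roi_voxel_count=n_voxels,
        noise_sigma=0.0,
        seed=0,
        normalized=normalized,
    )
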