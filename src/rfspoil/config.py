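"""YAML configuration for protocols, tissues and sweeps.

Schema (all sections optional, keys map 1:1 onto the dataclasses):

.. code-block:: yaml

    protocol:            # -> build_default_protocol(...) or explicit lobes
      tr: 20.0           # ms
      te: 4.0            # ms
      voxel_readout: 0.30            # mm
      voxel_slice: 0.78              # mm
      readout_cycles: 3.0            # spoiling cycles per voxel, readout axis
      slice_cycles: 3.76             # spoiling cycles per voxel, slice axis
      readout_bandwidth_khz: 50.0
      matrix_readout: 100
      prephaser_duration: 1.0        # ms
      spoiler_duration: 1.5          # ms
      lobes:             # optional: overrides the default layout entirely
        - {axis: readout, amplitude: -39.1, duration: 1.0, start_time: 2.0}
    tissue:
      t1: 540.0          # ms
      t2: 340.0          # ms
      d: 1.93e-3         # mm^2/s
      m0: 1.0
    sweep:               # -> SweepConfig(...)
      psis: [50.0, 115.4, 117.0, 150.0, 169.0]
      d_values: [0.0]
      tr_values: [20.0]

A preset reproducing the studied 7 T protocol ships with the package
(:func:`default_protocol_preset`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .sequence_model import GradientLobe, TRSchedule, build_default_protocol
from .signal_engine import TissueParams
from .spoiling_analysis import SweepConfig

__all__ = [
    "load_config",
    "schedule_from_config",
    "tissue_from_config",
    "sweep_from_config",
    "default_protocol_preset",
]


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML config file into a nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return cfg


def schedule_from_config(cfg: dict[str, Any]) -> TRSchedule:
    """Build a :class:`TRSchedule` from the ``protocol`` section.

    Without an explicit ``lobes`` list the default layout is generated; with
    one, the listed lobes replace it (amplitude mT/m, times ms).
    """
    proto = dict(cfg.get("protocol", cfg))
    lobes_cfg = proto.pop("lobes", None)
    if lobes_cfg is None:
        return build_default_protocol(**proto)
    base = build_default_protocol(
        **{k: v for k, v in proto.items() if k in (
            "tr", "te", "voxel_readout", "voxel_slice",
            "readout_cycles", "slice_cycles",
        )}
    )
    lobes = tuple(GradientLobe(**entry) for entry in lobes_cfg)
    return TRSchedule(
        tr=base.tr,
        te=base.te,
        lobes=lobes,
        voxel_size=base.voxel_size,
        spoil_cycles=base.spoil_cycles,
    )


def tissue_from_config(cfg: dict[str, Any]) -> TissueParams:
    return TissueParams(**cfg.get("tissue", cfg))


def sweep_from_config(cfg: dict[str, Any]) -> SweepConfig:
    section = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in cfg.get("sweep", cfg).items()
    }
    return SweepConfig(**section)


def default_protocol_preset() -> TRSchedule:
    """The bundled preset: 7 T liquid-phantom protocol (TR 20 ms, TE 4 ms,
    0.30 mm readout voxel, spoiling moments 3 and 3.76 cycles/voxel)."""
    ref = resources.files("rfspoil").joinpath("data/bruker7t_protocol.yaml")
    with resources.as_file(ref) as path:
        return schedule_from_config(load_config(path))
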