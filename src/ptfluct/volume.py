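"""Apparent protein volume from box-volume statistics.

    V_app = ⟨V_MD⟩ − N_w·⟨V_w⟩

⟨V_MD⟩ is the time-mean simulation-box volume, N_w the number of water
molecules in the box, and ⟨V_w⟩ the mean molecular volume of water from a
pure-solvent simulation at the same temperature and pressure.  V_app/N_HA
(volume per protein heavy atom) is the per-atom measure used for
cross-condition comparison.  Ions' volume contribution is not subtracted;
this biases absolute V_app slightly but cancels in ΔT/ΔP comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BlockSpec, ConditionLabel, Trajectory
from .errors import ConditionMismatchError, CoverageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolventReference:
    """Mean molecular volume of water, ⟨V_w⟩ (Å³), at a given (T, P)."""

    mean_water_volume: float  # Å³ per molecule
    temperature: float  # K
    pressure: float  # bar
    source: str = ""

    def __post_init__(self):
        if self.mean_water_volume <= 0:
            raise ValueError("mean water volume must be positive (Å³)")


@dataclass
class VolumeResult:
    mean_box_volume: float  # ⟨V_MD⟩, Å³
    n_waters: int
    v_app: float  # Å³
    v_app_per_heavy_atom: float  # Å³
    error: float  # Å³, block SEM propagated from ⟨V_MD⟩
    error_per_heavy_atom: float  # Å³


def pure_solvent_reference(
    volume_series: np.ndarray,
    n_waters: int,
    label: Optional[ConditionLabel] = None,
    source: str = "pure-solvent trajectory",
) -> SolventReference:
    """⟨V_w⟩ = mean(box volume)/N_w from a pure-solvent volume series."""
    series = np.asarray(volume_series, dtype=float)
    if series.size == 0:
        raise CoverageError("empty pure-solvent volume series")
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    if series.size == 1:
        logger.warning("single-frame solvent reference; no averaging possible")
    return SolventReference(
        mean_water_volume=float(series.mean()) / n_waters,
        temperature=label.temperature if label else float("nan"),
        pressure=label.pressure if label else float("nan"),
        source=source,
    )


def compute_vapp(
    traj: Trajectory,
    ref: SolventReference,
    blocks: BlockSpec | None = None,
    match_condition: bool = True,
) -> VolumeResult:
    """Apparent protein volume and volume per heavy atom.

    The pure-solvent reference must be for the trajectory's (T, P) state;
    set ``match_condition=False`` to skip the check for unlabeled inputs.
    """
    blocks = blocks or BlockSpec()
    if match_condition and traj.label is not None and np.isfinite(ref.temperature):
        if not (
            np.isclose(ref.temperature, traj.label.temperature)
            and np.isclose(ref.pressure, traj.label.pressure)
        ):
            raise ConditionMismatchError(
                f"solvent reference at ({ref.temperature} K, {ref.pressure} bar) "
                f"does not match trajectory condition "
                f"({traj.label.temperature} K, {traj.label.pressure} bar)"
            )
    volumes = traj.box_volumes()
    slices = blocks.slices(traj.n_frames, traj.frame_interval)
    used = volumes[: slices[-1][1]]
    block_means = np.array([volumes[s:e].mean() for s, e in slices])
    mean_v = float(used.mean())
    sem = (
        float(block_means.std(ddof=1) / np.sqrt(len(slices)))
        if len(slices) > 1
        else 0.0
    )
    n_w = traj.topology.n_waters
    n_ha = traj.topology.n_protein_heavy
    v_app = mean_v - n_w * ref.mean_water_volume
    return VolumeResult(
        mean_box_volume=mean_v,
        n_waters=n_w,
        v_app=v_app,
        v_app_per_heavy_atom=v_app / n_ha,
        error=sem,
        error_per_heavy_atom=sem / n_ha,
    )


def vapp_from_series(
    volume_series: np.ndarray,
    n_waters: int,
    n_heavy_atoms: int,
    ref: SolventReference,
    blocks: BlockSpec | None = None,
    frame_interval: float = 1.0,
) -> VolumeResult:
    """Same as :func:`compute_vapp` but from a bare box-volume series (Å³),
    for workflows where only volumes were retained."""
    blocks = blocks or BlockSpec()
    volumes = np.asarray(volume_series, dtype=float)
    if volumes.size == 0:
        raise CoverageError("empty box-volume series")
    slices = blocks.slices(volumes.size, frame_interval)
    used = volumes[: slices[-1][1]]
    block_means = np.array([volumes[s:e].mean() for s, e in slices])
    mean_v = float(used.mean())
    sem = (
        float(block_means.std(ddof=1) / np.sqrt(len(slices)))
        if len(slices) > 1
        else 0.0
    )
    v_app = mean_v - n_waters * ref.mean_water_volume
    return VolumeResult(
        mean_box_volume=mean_v,
        n_waters=n_waters,
        v_app=v_app,
        v_app_per_heavy_atom=v_app / n_heavy_atoms,
        error=sem,
        error_per_heavy_atom=sem / n_heavy_atoms,
    )
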