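"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` (usually loaded from a YAML file) fixes every cutoff of
the analysis — hydrogen-bond geometry (2.40 Å / 130°), interior-water
distances (4.00 / 3.36 Å) and sampling (100 ps), block layout (10-ns × 5),
the lifetime exclusion threshold (1 ns) and the correlation-plot filter
(2 ps) — as explicit defaults, never hard-coded downstream.

:func:`run_pipeline` executes trajectory → MSF / V_app / N_w,in / hydrogen
bonds → one :class:`~ptfluct.compare.ConditionSummary` row, writing each
stage's TSV plus a manifest recording versions, the config hash, and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .compare import ConditionSummary, Measurement, write_condition_summaries
from .core import (
    BlockSpec,
    Box,
    ConditionLabel,
    read_topology,
    read_trajectory,
)
from .errors import PtfluctError
from .fluctuations import compute_msf
from .hbonds import (
    HBondCriteria,
    detect_hbonds,
    fluctuation_lifetime_dataset,
    summarize_lifetimes,
    track_events,
)
from .interior import InteriorWaterCriteria, count_interior_waters
from .reporting import (
    write_correlation_tsv,
    write_events_tsv,
    write_interior_tsv,
    write_lifetime_summary_tsv,
    write_msf_tsv,
    write_pairs_tsv,
    write_per_residue_msf_tsv,
    write_volume_tsv,
)
from .volume import SolventReference, compute_vapp

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    topology: str = ""
    trajectory: str = ""
    trajectory_format: Optional[str] = None
    frame_interval: float = 1.0  # ps
    protein_id: str = "protein"
    temperature: float = 300.0  # K
    pressure: float = 1.0  # bar
    block_length: float = 10_000.0  # ps
    n_blocks: int = 5
    superpose: bool = True
    hbond_d_ha_max: float = 2.40  # Å
    hbond_angle_min: float = 130.0  # degrees
    hbond_gap_tolerance: int = 0  # frames
    lifetime_exclusion_ps: float = 1000.0
    correlation_min_tau_ps: float = 2.0
    interior_d_protein_max: float = 4.00  # Å
    interior_d_water_min: float = 3.36  # Å
    interior_sample_interval: float = 100.0  # ps
    solvent_reference_A3: Optional[float] = None  # ⟨V_w⟩ supplied directly
    constant_box_edge: Optional[float] = None  # Å, for box-less formats
    output_dir: str = "ptfluct_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PtfluctError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def validate(self) -> None:
        for p in (self.topology, self.trajectory):
            if p and not Path(p).exists():
                raise PtfluctError(f"configured path does not exist: {p}")
        self.blocks()  # raises on bad values
        self.hbond_criteria()
        self.interior_criteria()

    def blocks(self) -> BlockSpec:
        return BlockSpec(block_length=self.block_length, n_blocks=self.n_blocks)

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(
            d_ha_max=self.hbond_d_ha_max, angle_min=self.hbond_angle_min
        )

    def interior_criteria(self) -> InteriorWaterCriteria:
        return InteriorWaterCriteria(
            d_protein_max=self.interior_d_protein_max,
            d_water_min=self.interior_d_water_min,
            sample_interval=self.interior_sample_interval,
        )

    def label(self) -> ConditionLabel:
        return ConditionLabel(self.protein_id, self.temperature, self.pressure)


def _stage(name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except PtfluctError as exc:
        raise PtfluctError(f"stage '{name}': {exc}") from exc
    logger.info("stage %-10s done in %.2f s", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: RunConfig) -> ConditionSummary:
    """Full analysis of one condition; returns its summary row.

    Stage outputs (TSV) and a manifest land in ``config.output_dir``.  If no
    solvent reference is configured the V_app column is reported as NaN with
    a warning; other stages are unaffected.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    blocks = config.blocks()

    top = _stage("topology", read_topology, config.topology)
    constant_box = (
        Box.cubic(config.constant_box_edge) if config.constant_box_edge else None
    )
    traj = _stage(
        "trajectory",
        read_trajectory,
        top,
        config.trajectory,
        format=config.trajectory_format,
        frame_interval=config.frame_interval,
        constant_box=constant_box,
        label=config.label(),
    )
    logger.info("%d frames × %d atoms", traj.n_frames, traj.topology.n_atoms)

    msf = _stage("msf", compute_msf, traj, blocks, superpose=config.superpose)
    write_msf_tsv(msf, out / "msf_per_atom.tsv", chash)
    write_per_residue_msf_tsv(msf, out / "msf_per_residue.tsv", chash)

    per_frame = _stage("hbond-detect", detect_hbonds, traj, config.hbond_criteria())
    heavy_of = {
        a.index: a.bonded_heavy_partner
        for a in traj.topology.atoms
        if a.bonded_heavy_partner is not None
    }
    events, pairs = _stage(
        "hbond-events",
        track_events,
        per_frame,
        traj.frame_interval,
        donor_heavy_of=heavy_of,
        gap_tolerance=config.hbond_gap_tolerance,
    )
    summary = _stage(
        "hbond-summary",
        summarize_lifetimes,
        pairs,
        per_frame,
        blocks,
        frame_interval=traj.frame_interval,
        exclusion_threshold=config.lifetime_exclusion_ps,
    )
    write_events_tsv(events, traj.frame_interval, out / "hbond_events.tsv", chash)
    write_pairs_tsv(pairs, out / "hbond_pairs.tsv", chash)
    write_lifetime_summary_tsv(summary, out / "hbond_summary.tsv", chash)
    corr_rows, pearson_r = _stage(
        "correlation",
        fluctuation_lifetime_dataset,
        msf,
        pairs,
        min_tau=config.correlation_min_tau_ps,
    )
    write_correlation_tsv(corr_rows, pearson_r, out / "correlation.tsv", chash)

    if traj.topology.n_waters:
        interior = _stage(
            "interior", count_interior_waters, traj, config.interior_criteria(),
            blocks,
        )
        write_interior_tsv(
            interior, traj.frame_interval, out / "interior_waters.tsv", chash
        )
        n_w_in = Measurement(interior.n_w_in, interior.error)
    else:
        logger.warning("no waters in topology; skipping interior-water stage")
        n_w_in = Measurement(float("nan"))

    if config.solvent_reference_A3 is not None:
        ref = SolventReference(
            mean_water_volume=config.solvent_reference_A3,
            temperature=config.temperature,
            pressure=config.pressure,
            source="config",
        )
        vol = _stage("vapp", compute_vapp, traj, ref, blocks)
        write_volume_tsv(vol, out / "volume.tsv", chash)
        vapp = Measurement(vol.v_app_per_heavy_atom, vol.error_per_heavy_atom)
    else:
        logger.warning(
            "no solvent reference configured; V_app/N_HA reported as NaN"
        )
        vapp = Measurement(float("nan"))

    row = ConditionSummary(
        label=config.label(),
        msf=Measurement(msf.global_msf, msf.global_error),
        v_app_per_heavy_atom=vapp,
        n_w_in=n_w_in,
        n_hb=Measurement(summary.n_hb, summary.n_hb_error),
        tau_hb=Measurement(summary.tau_hb, summary.tau_hb_error),
    )
    write_condition_summaries([row], out / "condition_summary.tsv")

    manifest = {
        "ptfluct_version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "n_atoms": traj.topology.n_atoms,
        "n_protein_heavy": traj.topology.n_protein_heavy,
        "n_waters": traj.topology.n_waters,
        "config": yaml.safe_load(config.to_yaml()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return row
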