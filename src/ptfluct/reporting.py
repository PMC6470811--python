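"""Tab-separated output emitters.

Every table starts with ``#`` comment lines recording the producing stage
and, when available, the run-configuration hash, so outputs are traceable
to the exact settings that produced them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .fluctuations import DeltaMSFMap, MSFResult
from .hbonds import HBondEvent, LifetimeSummary, PairLifetime
from .interior import InteriorWaterResult
from .volume import VolumeResult


def _header(stage: str, config_hash: Optional[str]) -> list[str]:
    lines = [f"# ptfluct {stage}"]
    if config_hash:
        lines.append(f"# config_hash: {config_hash}")
    return lines


def write_tsv(path, comment_lines: Sequence[str], columns: Sequence[str],
              rows: Sequence[Sequence]) -> None:
    lines = list(comment_lines)
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_msf_tsv(result: MSFResult, path, config_hash: Optional[str] = None) -> None:
    """Per-atom MSF table (atom index, residue, per-block values, mean)."""
    n_blocks = result.per_atom_per_block.shape[1]
    cols = ["atom_index", "residue_index", "msf_A2"] + [
        f"block{k}_A2" for k in range(n_blocks)
    ]
    rows = []
    for i, atom in enumerate(result.atom_indices):
        rows.append(
            [int(atom), int(result.atom_residue_indices[i]),
             f"{result.per_atom_mean[i]:.6f}"]
            + [f"{v:.6f}" for v in result.per_atom_per_block[i]]
        )
    comments = _header("msf per-atom", config_hash) + [
        f"# global_msf_A2 = {result.global_msf:.6f}",
        f"# global_error_A2 = {result.global_error:.6f}",
    ]
    write_tsv(path, comments, cols, rows)


def write_per_residue_msf_tsv(
    result: MSFResult, path, config_hash: Optional[str] = None
) -> None:
    rows = [
        [int(r), n, f"{v:.6f}"]
        for r, n, v in zip(
            result.residue_indices, result.residue_names, result.per_residue_mean
        )
    ]
    write_tsv(
        path,
        _header("msf per-residue", config_hash),
        ["residue_index", "residue_name", "msf_A2"],
        rows,
    )


def write_dmsf_tsv(dmap: DeltaMSFMap, path, config_hash: Optional[str] = None) -> None:
    """Per-residue ΔMSF with the normalized color coordinate (clipped to the
    −0.5/2.0 Å² anchors)."""
    color = dmap.color_coordinate
    rows = [
        [int(r), n, f"{d:.6f}", f"{c:.6f}"]
        for r, n, d, c in zip(
            dmap.residue_indices, dmap.residue_names, dmap.delta, color
        )
    ]
    write_tsv(
        path,
        _header("delta-msf map", config_hash)
        + [f"# color anchors (A2): low={dmap.anchors[0]} mid={dmap.anchors[1]} high={dmap.anchors[2]}"],
        ["residue_index", "residue_name", "delta_msf_A2", "color_coord"],
        rows,
    )


def write_events_tsv(
    events: Sequence[HBondEvent],
    frame_interval: float,
    path,
    config_hash: Optional[str] = None,
) -> None:
    rows = [
        [
            e.donor_hydrogen,
            e.donor_heavy,
            e.acceptor,
            f"{e.start_frame * frame_interval:g}",
            f"{e.duration:g}",
            int(e.truncated),
        ]
        for e in events
    ]
    write_tsv(
        path,
        _header("hbond events", config_hash),
        ["donor_hydrogen", "donor_heavy", "acceptor", "start_ps", "duration_ps",
         "truncated"],
        rows,
    )


def write_pairs_tsv(
    pairs: Sequence[PairLifetime], path, config_hash: Optional[str] = None
) -> None:
    rows = [
        [p.donor_hydrogen, p.acceptor, p.n_events, f"{p.tau:.6f}",
         f"{p.total_time:g}"]
        for p in pairs
    ]
    write_tsv(
        path,
        _header("hbond pair lifetimes", config_hash),
        ["donor_hydrogen", "acceptor", "n_events", "tau_ps", "total_time_ps"],
        rows,
    )


def write_lifetime_summary_tsv(
    summary: LifetimeSummary, path, config_hash: Optional[str] = None
) -> None:
    comments = _header("hbond summary", config_hash)
    for pair, tau, reason in summary.excluded_pairs:
        comments.append(f"# excluded pair {pair}: tau={tau:.1f} ps ({reason})")
    write_tsv(
        path,
        comments,
        ["N_HB", "N_HB_err", "N_unique_pairs", "tau_HB_ps", "tau_HB_err_ps",
         "n_excluded"],
        [[
            f"{summary.n_hb:.4f}",
            f"{summary.n_hb_error:.4f}",
            summary.n_unique_pairs,
            f"{summary.tau_hb:.4f}",
            f"{summary.tau_hb_error:.4f}",
            len(summary.excluded_pairs),
        ]],
    )


def write_correlation_tsv(
    rows: Sequence[dict], pearson_r: float, path,
    config_hash: Optional[str] = None,
) -> None:
    write_tsv(
        path,
        _header("fluctuation-lifetime correlation", config_hash)
        + [f"# pearson_r(1/MSF, ln tau) = {pearson_r:.6f}"],
        ["acceptor", "msf_A2", "inv_msf_A-2", "tau_ps", "ln_tau"],
        [
            [r["acceptor"], f"{r['msf']:.6f}", f"{r['inv_msf']:.6f}",
             f"{r['tau']:.6f}", f"{r['ln_tau']:.6f}"]
            for r in rows
        ],
    )


def write_interior_tsv(
    result: InteriorWaterResult,
    frame_interval: float,
    path,
    config_hash: Optional[str] = None,
) -> None:
    rows = [
        [f"{f * frame_interval:g}", int(c),
         ",".join(str(int(i)) for i in ids)]
        for f, c, ids in zip(
            result.sampled_frames,
            result.per_sampled_frame_counts,
            result.interior_identities,
        )
    ]
    write_tsv(
        path,
        _header("interior waters", config_hash)
        + [f"# N_w_in = {result.n_w_in:.4f} ± {result.error:.4f}"],
        ["time_ps", "count", "interior_water_atom_indices"],
        rows,
    )


def write_volume_tsv(
    result: VolumeResult, path, config_hash: Optional[str] = None
) -> None:
    write_tsv(
        path,
        _header("apparent volume", config_hash),
        ["mean_box_volume_A3", "N_w", "V_app_A3", "Vapp_per_NHA_A3",
         "err_A3", "err_per_NHA_A3"],
        [[
            f"{result.mean_box_volume:.4f}",
            result.n_waters,
            f"{result.v_app:.4f}",
            f"{result.v_app_per_heavy_atom:.4f}",
            f"{result.error:.4f}",
            f"{result.error_per_heavy_atom:.4f}",
        ]],
    )
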