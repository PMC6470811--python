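"""Mean-square fluctuations (MSF) with block averaging.

The protein-averaged MSF is

    MSF = (1/N_HA) Σ_i ⟨Δr_i²⟩

where ⟨Δr_i²⟩ is, for each protein heavy atom i, the block average of the
variance of its position about the within-block mean position (summed over
x, y, z), computed over consecutive 10-ns blocks by default.  Errors are the
standard error of the mean over block values.

Superposition: by default each frame is least-squares fitted (Kabsch, on
protein heavy atoms) to the within-block mean structure before variances
are taken, so rigid-body tumbling does not inflate the fluctuations; two
fit iterations are used (fit to a provisional reference, rebuild the mean,
refit).  Disable with ``superpose=False`` when the input is known to carry
no rigid-body motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import BlockSpec, Trajectory
from .errors import SelectionError, ShapeError

#: Color-scale anchors for per-residue ΔMSF maps (Å²): low, mid, high.
DMSF_COLOR_ANCHORS = (-0.5, 0.0, 2.0)


@dataclass
class MSFResult:
    """Per-atom, per-residue and protein-averaged mean-square fluctuations.

    ``atom_indices`` are topology indices of the protein heavy atoms the
    rows of ``per_atom_per_block``/``per_atom_mean`` refer to.
    """

    atom_indices: np.ndarray  # (n_atoms,)
    atom_residue_indices: np.ndarray  # (n_atoms,) residue of each atom row
    per_atom_per_block: np.ndarray  # (n_atoms, n_blocks), Å²
    per_atom_mean: np.ndarray  # (n_atoms,), Å²
    global_msf: float  # Å²
    global_error: float  # Å² (SEM over block means)
    residue_indices: np.ndarray  # (n_residues,) residue index per row
    residue_names: np.ndarray
    per_residue_mean: np.ndarray  # (n_residues,), Å²

    def per_atom(self, atom_index: int) -> float:
        """⟨Δr²⟩ of one topology atom index."""
        pos = np.flatnonzero(self.atom_indices == atom_index)
        if pos.size != 1:
            raise KeyError(f"atom {atom_index} is not a protein heavy atom here")
        return float(self.per_atom_mean[pos[0]])


@dataclass
class DeltaMSFMap:
    """Per-residue MSF difference between two conditions (b − a), Å²."""

    residue_indices: np.ndarray
    residue_names: np.ndarray
    delta: np.ndarray  # Å²
    anchors: tuple = DMSF_COLOR_ANCHORS

    @property
    def color_coordinate(self) -> np.ndarray:
        """ΔMSF clipped to the [low, high] anchors and mapped to [0, 1]
        (0 = low anchor, 1 = high anchor; the mid anchor is white)."""
        low, _, high = self.anchors
        clipped = np.clip(self.delta, low, high)
        return (clipped - low) / (high - low)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |mobile·R + t − reference|²."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    r = rot.as_matrix().T  # row-vector convention: aligned = (x - mc) @ R + rc
    return r, rc - mc @ r


def _superpose_block(block: np.ndarray, fit_idx: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Least-squares superpose every frame of a block onto the within-block
    mean structure (protein heavy atoms drive the fit; all atoms move)."""
    out = block.copy()
    reference = out[0, fit_idx]
    for _ in range(n_iter):
        for f in range(out.shape[0]):
            r, t = _kabsch(out[f, fit_idx], reference)
            out[f] = out[f] @ r + t
        reference = out[:, fit_idx].mean(axis=0)
    return out


def compute_msf(
    traj: Trajectory,
    blocks: BlockSpec | None = None,
    superpose: bool = True,
) -> MSFResult:
    """Block-averaged mean-square fluctuations of protein heavy atoms.

    Raises :class:`CoverageError` if the trajectory is shorter than one block
    and :class:`SelectionError` if there are no protein heavy atoms.
    """
    blocks = blocks or BlockSpec()
    top = traj.topology
    heavy = top.protein_heavy_indices
    if heavy.size == 0:
        raise SelectionError("no protein heavy atoms in topology")
    slices = blocks.slices(traj.n_frames, traj.frame_interval)

    fit_local = np.arange(heavy.size)
    per_block = np.empty((heavy.size, len(slices)))
    for k, (start, stop) in enumerate(slices):
        block = traj.coordinates[start:stop, heavy, :]
        if superpose:
            block = _superpose_block(block, fit_local)
        mean_pos = block.mean(axis=0)
        dev = block - mean_pos[None, :, :]
        per_block[:, k] = np.einsum("fad,fad->a", dev, dev) / block.shape[0]

    per_atom_mean = per_block.mean(axis=1)
    block_global = per_block.mean(axis=0)  # per-block protein-average
    global_msf = float(block_global.mean())
    if len(slices) > 1:
        global_error = float(block_global.std(ddof=1) / np.sqrt(len(slices)))
    else:
        global_error = 0.0

    res_of_atom = top.residue_indices[heavy]
    res_idx = np.unique(res_of_atom)
    per_res = np.array(
        [per_atom_mean[res_of_atom == r].mean() for r in res_idx]
    )
    res_names = np.array(
        [top.residue_names[heavy[res_of_atom == r][0]] for r in res_idx]
    )
    return MSFResult(
        atom_indices=heavy,
        atom_residue_indices=res_of_atom,
        per_atom_per_block=per_block,
        per_atom_mean=per_atom_mean,
        global_msf=global_msf,
        global_error=global_error,
        residue_indices=res_idx,
        residue_names=res_names,
        per_residue_mean=per_res,
    )


def delta_msf_map(a: MSFResult, b: MSFResult) -> DeltaMSFMap:
    """Per-residue MSF difference map, b − a (e.g. high minus low temperature).

    The two results must cover the same residues in the same order.
    """
    if a.residue_indices.shape != b.residue_indices.shape or np.any(
        a.residue_indices != b.residue_indices
    ):
        raise ShapeError("residue structures of the two MSF results do not align")
    return DeltaMSFMap(
        residue_indices=a.residue_indices.copy(),
        residue_names=a.residue_names.copy(),
        delta=b.per_residue_mean - a.per_residue_mean,
    )
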