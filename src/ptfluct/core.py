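"""Domain types and I/O for topologies, trajectories, and periodic geometry.

Conventions used throughout the package: coordinates in Å, time in ps,
temperature in K, pressure in bar; 0-based atom/frame indices; half-open
frame ranges ``[start, stop)``.  Downstream analysis stages consume only the
types defined here, never raw file handles.

File reading and writing is delegated to MDAnalysis (PDB for topologies and
multi-model coordinates; DCD/XTC/TRR for frames); this module owns the
in-memory model and the minimum-image geometry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CoverageError,
    FormatError,
    GeometryError,
    MissingBoxError,
    ShapeError,
    TopologyError,
)

logger = logging.getLogger(__name__)

#: Residue names recognised as water.  PDB dialects vary; override via the
#: ``water_residues`` argument of :func:`read_topology`.
WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP4", "TIP4P", "WAT", "SOL", "TIP3", "SPC"})

#: Residue names treated as neither protein nor water (monatomic ions);
#: excluded from every statistic.
ION_RESIDUE_NAMES = frozenset(
    {"K", "CL", "NA", "MG", "CA", "ZN", "POT", "CLA", "SOD", "MGD", "CAL"}
)

#: Atom names of massless virtual interaction sites (four-point water models).
#: They are kept in the coordinate arrays but excluded from all atom counts
#: and geometric criteria.
VIRTUAL_SITE_NAMES = frozenset({"MW", "EPW", "EP", "LP", "LP1", "LP2", "OM"})

_HB_DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``bonded_heavy_partner`` is, for hydrogens, the index of the covalent
    heavy (donor) atom; ``None`` for heavy atoms.  Virtual sites (massless
    M/EP points of four-site water models) have ``is_virtual`` set and are
    neither heavy nor hydrogen.
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str = "A"
    is_protein: bool = False
    is_water: bool = False
    is_virtual: bool = False
    bonded_heavy_partner: Optional[int] = None

    @property
    def is_heavy(self) -> bool:
        return (not self.is_virtual) and self.element.upper() != "H"

    @property
    def is_hydrogen(self) -> bool:
        return (not self.is_virtual) and self.element.upper() == "H"


class Topology:
    """An ordered collection of :class:`Atom` with cached selection masks."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise TopologyError(
                    f"atom {i} carries index {a.index}; indices must be 0..n-1 in order"
                )
            if a.is_protein and a.is_water:
                raise TopologyError(f"atom {i} flagged both protein and water")
            if a.is_hydrogen and (a.is_protein or a.is_water):
                if a.bonded_heavy_partner is None:
                    raise TopologyError(
                        f"hydrogen atom {i} ({a.name}, residue {a.residue_name}"
                        f"{a.residue_index}) has no covalent heavy partner; "
                        "lifetime analysis requires donor hydrogens"
                    )
        names = np.array([a.name for a in self.atoms])
        elements = np.array([a.element.upper() for a in self.atoms])
        self.n_atoms = len(self.atoms)
        self.is_protein = np.array([a.is_protein for a in self.atoms], dtype=bool)
        self.is_water = np.array([a.is_water for a in self.atoms], dtype=bool)
        self.is_virtual = np.array([a.is_virtual for a in self.atoms], dtype=bool)
        self.is_heavy = (~self.is_virtual) & (elements != "H")
        self.is_hydrogen = (~self.is_virtual) & (elements == "H")
        self.elements = elements
        self.names = names
        self.residue_indices = np.array([a.residue_index for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        partner = np.full(self.n_atoms, -1, dtype=np.int64)
        for a in self.atoms:
            if a.bonded_heavy_partner is not None:
                partner[a.index] = a.bonded_heavy_partner
        self.bonded_heavy_partner = partner

    # -- selections ---------------------------------------------------------

    @property
    def protein_heavy_indices(self) -> np.ndarray:
        """Indices of protein heavy atoms (the N_HA selection)."""
        return np.flatnonzero(self.is_protein & self.is_heavy)

    @property
    def n_protein_heavy(self) -> int:
        return int(np.count_nonzero(self.is_protein & self.is_heavy))

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_water & (self.elements == "O"))

    @property
    def n_waters(self) -> int:
        """Number of water molecules (counted by oxygen atoms)."""
        return int(self.water_oxygen_indices.size)

    def donor_hydrogen_indices(self) -> np.ndarray:
        """Protein hydrogens covalently bound to a polar (N/O/S) heavy atom."""
        mask = self.is_protein & self.is_hydrogen
        idx = np.flatnonzero(mask)
        partners = self.bonded_heavy_partner[idx]
        polar = np.isin(self.elements[partners], list(_HB_DONOR_ACCEPTOR_ELEMENTS))
        return idx[polar]

    def acceptor_indices(self) -> np.ndarray:
        """Protein polar heavy atoms (N/O/S) that can accept a hydrogen bond."""
        mask = (
            self.is_protein
            & self.is_heavy
            & np.isin(self.elements, list(_HB_DONOR_ACCEPTOR_ELEMENTS))
        )
        return np.flatnonzero(mask)

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms


@dataclass(frozen=True)
class Box:
    """A triclinic periodic cell given by three lattice vectors (Å, rows)."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise GeometryError(f"box vectors must be 3x3, got {v.shape}")
        object.__setattr__(self, "vectors", v)
        if self.volume <= 1e-9:
            raise GeometryError("degenerate box: non-positive cell volume")

    @property
    def volume(self) -> float:
        """Cell volume as the scalar triple product, Å³."""
        return float(abs(np.linalg.det(self.vectors)))

    @classmethod
    def cubic(cls, edge: float) -> "Box":
        return cls(np.eye(3) * float(edge))

    @classmethod
    def rhombic_dodecahedron(cls, face_distance: float) -> "Box":
        """The rhombic dodecahedral cell with the given distance between
        opposite square faces; volume = (√2/2)·d³."""
        d = float(face_distance)
        return cls(
            np.array(
                [
                    [d, 0.0, 0.0],
                    [0.0, d, 0.0],
                    [d / 2.0, d / 2.0, d * np.sqrt(2.0) / 2.0],
                ]
            )
        )

    def to_mdanalysis_dimensions(self) -> np.ndarray:
        from MDAnalysis.lib.mdamath import triclinic_box

        return triclinic_box(*self.vectors)

    def __eq__(self, other) -> bool:
        return isinstance(other, Box) and np.allclose(self.vectors, other.vectors)


@dataclass(frozen=True)
class ConditionLabel:
    """A (protein, temperature, pressure) simulation condition."""

    protein_id: str
    temperature: float  # K
    pressure: float  # bar

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive (bar)")


@dataclass(frozen=True)
class BlockSpec:
    """Block-averaging layout: consecutive intervals of ``block_length`` ps.

    Statistics are reported as mean ± standard error over block means.
    """

    block_length: float = 10_000.0  # ps
    n_blocks: int = 5

    def __post_init__(self):
        if self.block_length <= 0:
            raise ValueError("block_length must be positive (ps)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def frames_per_block(self, frame_interval: float) -> int:
        ratio = self.block_length / frame_interval
        n = int(round(ratio))
        if abs(ratio - n) > 1e-9 or n < 1:
            raise CoverageError(
                f"block_length {self.block_length} ps is not a multiple of the "
                f"frame interval {frame_interval} ps"
            )
        return n

    def slices(self, n_frames: int, frame_interval: float) -> list[tuple[int, int]]:
        """Half-open frame ranges of the full blocks available, at most
        ``n_blocks``; trailing frames not filling a block are dropped."""
        per = self.frames_per_block(frame_interval)
        available = n_frames // per
        if available < 1:
            raise CoverageError(
                f"trajectory of {n_frames} frames does not span one full block "
                f"({per} frames)"
            )
        used = min(available, self.n_blocks)
        if used < self.n_blocks:
            logger.warning(
                "only %d of %d requested blocks available; using %d",
                available,
                self.n_blocks,
                used,
            )
        leftover = n_frames - used * per
        if leftover:
            logger.info("dropping %d trailing frames not filling a block", leftover)
        return [(k * per, (k + 1) * per) for k in range(used)]


@dataclass
class Trajectory:
    """Coordinates (frames × atoms × 3, Å) plus per-frame boxes and timing."""

    topology: Topology
    coordinates: np.ndarray
    boxes: Optional[list[Box]]
    frame_interval: float = 1.0  # ps
    label: Optional[ConditionLabel] = None
    constant_box: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ShapeError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"trajectory has {self.coordinates.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if self.boxes is not None and len(self.boxes) != self.n_frames:
            raise ShapeError(
                f"{len(self.boxes)} boxes for {self.n_frames} frames"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def duration(self) -> float:
        """Trajectory length in ps (n_frames × frame_interval)."""
        return self.n_frames * self.frame_interval

    def require_boxes(self) -> list[Box]:
        if self.boxes is None:
            raise MissingBoxError(
                "analysis requires per-frame periodic boxes but none are present; "
                "supply a constant box when reading the trajectory"
            )
        return self.boxes

    def box_volumes(self) -> np.ndarray:
        return np.array([b.volume for b in self.require_boxes()])


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

_SHIFTS27 = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def minimum_image_displacements(d: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement vectors for an array of raw displacements.

    Works for any triclinic cell: displacements are wrapped to the central
    cell in fractional coordinates, then the shortest vector is chosen among
    the 27 neighbouring images (exact for reduced cells).
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    m = box.vectors
    # Integer lattice shifts applied to the raw displacement in cartesian
    # space, so the zero-shift candidate is d itself, exactly (no fractional
    # round trip); correct for reduced cells via the 3×3×3 neighbour scan.
    n0 = np.round(d @ np.linalg.inv(m))
    cand = d[:, None, :] - (n0[:, None, :] + _SHIFTS27[None, :, :]) @ m
    norms = np.einsum("nij,nij->ni", cand, cand)
    best = np.argmin(norms, axis=1)
    return cand[np.arange(d.shape[0]), best]


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> float:
    """Distance (Å) between ``a`` and ``b`` under the minimum-image convention."""
    disp = minimum_image_displacements(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(disp[0]))


def minimum_image_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: Box
) -> np.ndarray:
    """All pairwise minimum-image distances between point sets ``a`` (n×3)
    and ``b`` (m×3); returns an (n, m) array in Å."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    d = b[None, :, :] - a[:, None, :]
    disp = minimum_image_displacements(d.reshape(-1, 3), box)
    return np.linalg.norm(disp, axis=1).reshape(a.shape[0], b.shape[0])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _guess_element(name: str) -> str:
    """Element from a PDB atom name when no element column is present."""
    stripped = name.strip()
    if not stripped:
        return ""
    # Names like "1HB2" start with a digit; hydrogens like "HG21" with H.
    core = stripped.lstrip("0123456789")
    if not core:
        return ""
    first = core[0].upper()
    if first == "H":
        return "H"
    two = core[:2].upper()
    if two in {"CL", "NA", "MG", "ZN", "FE", "BR"} and len(stripped) <= 2:
        return two.capitalize()
    return first


def read_topology(
    path,
    format: str = "pdb",
    water_residues: frozenset = WATER_RESIDUE_NAMES,
    ion_residues: frozenset = ION_RESIDUE_NAMES,
) -> Topology:
    """Read a topology from a PDB file.

    Protein/water classification comes from residue names; hydrogens are
    linked to their covalent heavy partner using CONECT records when present,
    otherwise the nearest intra-residue heavy atom within 1.2 Å.
    """
    import MDAnalysis as mda

    if format.lower() != "pdb":
        raise FormatError(f"unsupported topology format: {format}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="PDB")
        n = len(u.atoms)
    except Exception as exc:  # MDA raises assorted errors on garbage input
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    if n == 0:
        raise FormatError(f"{path} contains no atoms")

    names = [a.name for a in u.atoms]
    try:
        elements = [e if e else _guess_element(nm) for e, nm in zip(u.atoms.elements, names)]
    except Exception:
        elements = [_guess_element(nm) for nm in names]
    resnames = [a.resname.strip() for a in u.atoms]
    resids = [a.resid for a in u.atoms]
    try:
        chains = [a.chainID if a.chainID.strip() else "A" for a in u.atoms]
    except Exception:
        chains = ["A"] * n

    # Compress residue ids to 0-based consecutive indices in order of appearance.
    res_key_to_index: dict[tuple, int] = {}
    residue_index = np.empty(n, dtype=int)
    for i in range(n):
        key = (chains[i], resids[i], resnames[i])
        if key not in res_key_to_index:
            res_key_to_index[key] = len(res_key_to_index)
        residue_index[i] = res_key_to_index[key]

    upper_res = [r.upper() for r in resnames]
    is_water = np.array([r in water_residues for r in upper_res])
    is_ion = np.array([r in ion_residues for r in upper_res])
    is_protein = ~is_water & ~is_ion
    is_virtual = np.array(
        [nm.strip().upper() in VIRTUAL_SITE_NAMES for nm in names]
    )
    if is_ion.any():
        logger.info(
            "%d ion atoms treated as neither protein nor water and excluded "
            "from all statistics",
            int(is_ion.sum()),
        )
        is_protein = is_protein & ~is_ion

    # Hydrogen -> covalent heavy partner.
    partner = np.full(n, -1, dtype=int)
    bonded: dict[int, list[int]] = {}
    if hasattr(u, "bonds"):
        for b in u.bonds:
            i, j = int(b.atoms[0].index), int(b.atoms[1].index)
            bonded.setdefault(i, []).append(j)
            bonded.setdefault(j, []).append(i)
    coords = u.atoms.positions.astype(float)
    heavy_mask = (~is_virtual) & (np.array([e.upper() for e in elements]) != "H")
    for i in range(n):
        if is_virtual[i] or elements[i].upper() != "H":
            continue
        cands = [j for j in bonded.get(i, []) if heavy_mask[j]]
        if cands:
            partner[i] = cands[0]
            continue
        same_res = np.flatnonzero(heavy_mask & (residue_index == residue_index[i]))
        if same_res.size:
            dists = np.linalg.norm(coords[same_res] - coords[i], axis=1)
            k = int(np.argmin(dists))
            if dists[k] <= 1.2:
                partner[i] = int(same_res[k])
        if partner[i] < 0 and (is_protein[i] or is_water[i]):
            raise TopologyError(
                f"hydrogen atom {i} ({names[i]}, residue {resnames[i]}{resids[i]}) "
                "has no resolvable covalent heavy partner (no CONECT and no "
                "intra-residue heavy atom within 1.2 Å)"
            )

    atoms = [
        Atom(
            index=i,
            name=names[i].strip(),
            element=elements[i].strip() or _guess_element(names[i]),
            residue_index=int(residue_index[i]),
            residue_name=resnames[i],
            chain=chains[i],
            is_protein=bool(is_protein[i]),
            is_water=bool(is_water[i]),
            is_virtual=bool(is_virtual[i]),
            bonded_heavy_partner=int(partner[i]) if partner[i] >= 0 else None,
        )
        for i in range(n)
    ]
    return Topology(atoms)


def _pdb_cryst1_box(path) -> Optional[Box]:
    """The CRYST1 header cell of a PDB file, or None if absent/placeholder."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    dims = np.array(
                        [line[6:15], line[15:24], line[24:33],
                         line[33:40], line[40:47], line[47:54]],
                        dtype=float,
                    )
                    if np.allclose(dims, [1, 1, 1, 90, 90, 90]) or np.any(
                        dims[:3] <= 0
                    ):
                        return None  # PDB placeholder cell
                    return _dimensions_to_box(dims)
                if line.startswith(("MODEL", "ATOM", "HETATM")):
                    break
    except (OSError, ValueError):
        return None
    return None


def _dimensions_to_box(dim) -> Optional[Box]:
    from MDAnalysis.lib.mdamath import triclinic_vectors

    if dim is None:
        return None
    dim = np.asarray(dim, dtype=float)
    if dim.shape != (6,) or np.any(dim[:3] <= 0):
        return None
    return Box(triclinic_vectors(dim).astype(float))


def read_trajectory(
    topology: Topology,
    path,
    format: Optional[str] = None,
    frame_interval: float = 1.0,
    constant_box: Optional[Box] = None,
    label: Optional[ConditionLabel] = None,
) -> Trajectory:
    """Read coordinate frames (DCD/XTC/TRR or multi-model PDB) onto a topology.

    Formats lacking per-frame cells are accepted with a constant user-supplied
    box (a warning is logged and the trajectory flagged ``constant_box``).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            u.load_new(str(path), format=fmt)
    except (ValueError, OSError, EOFError) as exc:
        msg = str(exc)
        if "number of atoms" in msg or "Timestep" in msg or "shape" in msg:
            raise ShapeError(
                f"{path}: atom count does not match topology "
                f"({topology.n_atoms} atoms expected): {msg}"
            ) from exc
        raise FormatError(f"could not read {path} as {fmt}: {msg}") from exc

    frames = []
    boxes: list[Optional[Box]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.positions.shape[0] != topology.n_atoms:
                raise ShapeError(
                    f"frame {ts.frame} has {ts.positions.shape[0]} atoms; "
                    f"topology has {topology.n_atoms}"
                )
            frames.append(ts.positions.astype(np.float64).copy())
            boxes.append(_dimensions_to_box(ts.dimensions))
    coords = np.stack(frames)

    have_all = all(b is not None for b in boxes)
    is_constant = False
    if not have_all and fmt == "PDB":
        # Multi-model PDB carries one CRYST1 header cell; apply it to every
        # frame when the reader did not attach per-frame dimensions.
        cell = _pdb_cryst1_box(path)
        if cell is not None:
            boxes = [cell] * len(frames)
            have_all = True
            is_constant = True
            logger.debug("using the CRYST1 header cell for all frames of %s", path)
    if not have_all:
        if constant_box is not None:
            logger.warning(
                "%s carries no per-frame cell; using the supplied constant box", path
            )
            boxes = [constant_box] * len(frames)
            is_constant = True
        else:
            boxes = None  # volume analysis will raise MissingBoxError
    return Trajectory(
        topology=topology,
        coordinates=coords,
        boxes=boxes,
        frame_interval=frame_interval,
        label=label,
        constant_box=is_constant,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _to_mdanalysis(traj: Trajectory):
    """Build an MDAnalysis Universe mirroring the trajectory (for writers)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = traj.topology
    resix = top.residue_indices
    n_res = int(resix.max()) + 1 if top.n_atoms else 0
    u = mda.Universe.empty(
        top.n_atoms,
        n_residues=n_res,
        atom_resindex=resix,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(top.names))
    u.add_TopologyAttr("elements", list(top.elements))
    u.add_TopologyAttr("chainIDs", [a.chain for a in top.atoms])
    resnames = [""] * n_res
    resids = np.zeros(n_res, dtype=int)
    for a in top.atoms:
        resnames[a.residue_index] = a.residue_name
        resids[a.residue_index] = a.residue_index + 1
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    bond_pairs = [
        (a.index, a.bonded_heavy_partner)
        for a in top.atoms
        if a.bonded_heavy_partner is not None
    ]
    if bond_pairs:
        u.add_TopologyAttr("bonds", bond_pairs)
    if traj.boxes is not None:
        dims = np.stack([b.to_mdanalysis_dimensions() for b in traj.boxes])
    else:
        dims = None
    u.load_new(
        traj.coordinates.astype(np.float32),
        format=MemoryReader,
        dimensions=dims,
    )
    return u


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    """Write frames as multi-model PDB, DCD, XTC or TRR (by extension)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    u = _to_mdanalysis(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(
            str(path), n_atoms=traj.topology.n_atoms, format=fmt, multiframe=True
        ) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_topology(traj_or_top, path) -> None:
    """Write a single-frame PDB (topology plus, if available, frame 0)."""
    if isinstance(traj_or_top, Topology):
        coords = np.zeros((1, traj_or_top.n_atoms, 3))
        traj = Trajectory(traj_or_top, coords, None, frame_interval=1.0)
    else:
        traj = replace(traj_or_top, coordinates=traj_or_top.coordinates[:1],
                       boxes=None if traj_or_top.boxes is None else traj_or_top.boxes[:1])
    write_trajectory(traj, path, format="PDB")
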