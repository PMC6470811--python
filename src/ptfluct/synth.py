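"""Synthetic trajectories with known ground truth.

The generators emulate the *statistical* structure the analysis stages
assume — stationary per-atom fluctuations, two-state hydrogen-bond
occupancy with exponential dwells, waters with planted interior/exterior
status, and a fluctuating box volume — not molecular physics.  Every
generator is deterministic given its spec (which carries the seed).

Ground truths:

* Ornstein–Uhlenbeck pseudo-protein: each heavy atom relaxes toward a fixed
  site at rate ``friction`` (ps⁻¹) with stationary variance k_B·T/κ_i per
  coordinate, so the 3-D mean-square fluctuation is exactly 3·k_B·T/κ_i.
  k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹.
* Telegraph occupancy: bonded/unbonded dwells are exponential with means
  τ_on/τ_off.  Point-sampling at interval Δ makes the observed on-runs
  geometric with continuation probability
  p = π_on + (1 − π_on)·exp(−(1/τ_on + 1/τ_off)·Δ), π_on = τ_on/(τ_on+τ_off),
  so the expected observed mean run duration is Δ/(1 − p)
  (:func:`expected_observed_run_duration`).
* Solvated scene: the planted interior waters satisfy the two-distance
  interior rule by construction (with safety margins) and every other water
  violates it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Atom, Box, ConditionLabel, Topology, Trajectory
from .errors import ConstructionError

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹ (fixes the OU analytic targets).
KB_KCAL_MOL_K = 0.0019872041


# ---------------------------------------------------------------------------
# Ornstein–Uhlenbeck pseudo-protein
# ---------------------------------------------------------------------------


@dataclass
class OUProteinSpec:
    n_residues: int = 20
    atoms_per_residue: int = 5
    kappa: float | np.ndarray = 0.025  # kcal·mol⁻¹·Å⁻², per atom or scalar
    temperature: float = 279.0  # K
    friction: float = 0.2  # ps⁻¹: positional relaxation rate of the OU process
    frame_interval: float = 1.0  # ps
    n_frames: int = 10_000
    seed: int = 0
    box_edge: float = 200.0  # Å, constant cubic cell
    site_spacing: float = 6.0  # Å between anchor sites

    @property
    def n_atoms(self) -> int:
        return self.n_residues * self.atoms_per_residue

    def kappa_array(self) -> np.ndarray:
        k = np.broadcast_to(np.asarray(self.kappa, float), (self.n_atoms,)).copy()
        if np.any(k <= 0):
            raise ValueError("spring constants must be positive")
        return k

    def msf_true(self) -> np.ndarray:
        """Ground-truth 3-D MSF per atom: 3·k_B·T/κ_i (Å²)."""
        return 3.0 * KB_KCAL_MOL_K * self.temperature / self.kappa_array()


def _grid_sites(n: int, spacing: float, origin: float) -> np.ndarray:
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = np.array(
        list(itertools.product(range(side), repeat=3))[:n], dtype=float
    )
    return pts * spacing + origin


def generate_ou_protein(spec: OUProteinSpec) -> Trajectory:
    """Trajectory of independent OU heavy atoms anchored on a grid."""
    if spec.friction <= 0:
        raise ValueError("friction (relaxation rate) must be positive")
    kappa = spec.kappa_array()
    rng = np.random.default_rng(spec.seed)
    sites = _grid_sites(spec.n_atoms, spec.site_spacing, spec.box_edge / 4.0)
    var = (KB_KCAL_MOL_K * spec.temperature / kappa)[None, :, None]  # per coord
    a = np.exp(-spec.friction * spec.frame_interval)
    coords = np.empty((spec.n_frames, spec.n_atoms, 3))
    x = rng.standard_normal((1, spec.n_atoms, 3)) * np.sqrt(var)
    coords[0] = sites + x[0]
    step_sd = np.sqrt(var * (1.0 - a * a))
    for f in range(1, spec.n_frames):
        x = a * x + step_sd * rng.standard_normal((1, spec.n_atoms, 3))
        coords[f] = sites + x[0]

    atoms = []
    for i in range(spec.n_atoms):
        atoms.append(
            Atom(
                index=i,
                name=f"C{i % spec.atoms_per_residue + 1}",
                element="C",
                residue_index=i // spec.atoms_per_residue,
                residue_name="ALA",
                is_protein=True,
            )
        )
    box = Box.cubic(spec.box_edge)
    return Trajectory(
        topology=Topology(atoms),
        coordinates=coords,
        boxes=[box] * spec.n_frames,
        frame_interval=spec.frame_interval,
        label=ConditionLabel("OU-PSEUDOPROTEIN", spec.temperature, 1.0),
        constant_box=True,
    )


# ---------------------------------------------------------------------------
# Telegraph hydrogen-bond occupancy
# ---------------------------------------------------------------------------


@dataclass
class TelegraphSpec:
    tau_on: float | np.ndarray = 25.0  # ps, mean bonded dwell (per pair or scalar)
    tau_off: float | np.ndarray = 25.0  # ps, mean unbonded dwell
    n_pairs: int = 10
    duration: float = 10_000.0  # ps
    frame_interval: float = 1.0  # ps
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def tau_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        on = np.broadcast_to(np.asarray(self.tau_on, float), (self.n_pairs,)).copy()
        off = np.broadcast_to(np.asarray(self.tau_off, float), (self.n_pairs,)).copy()
        if np.any(on <= 0) or np.any(off <= 0):
            raise ValueError("dwell-time means must be positive")
        return on, off


@dataclass
class OccupancyRealization:
    """Telegraph occupancies plus the book-keeping the oracles need.

    Pair p maps to synthetic atom ids (donor heavy, donor hydrogen,
    acceptor) = (3p, 3p+1, 3p+2); the per-frame sets use
    (donor hydrogen, acceptor) tuples like the detector does.
    """

    spec: TelegraphSpec
    occupancy: np.ndarray  # (n_pairs, n_frames) bool
    pair_ids: list  # [(donor_hydrogen, acceptor), ...]
    true_events: list  # [(pair index, t_start ps, t_end ps), ...] continuous

    @property
    def per_frame_sets(self) -> list[set]:
        n_pairs, n_frames = self.occupancy.shape
        return [
            {self.pair_ids[p] for p in np.flatnonzero(self.occupancy[:, f])}
            for f in range(n_frames)
        ]

    @property
    def donor_heavy_of(self) -> dict[int, int]:
        return {h: h - 1 for (h, _a) in self.pair_ids}


def expected_observed_run_duration(
    tau_on: float, tau_off: float, frame_interval: float
) -> float:
    """Mean duration (ps) of an on-run of the telegraph process when the
    occupancy is point-sampled every ``frame_interval`` ps and a run of k
    consecutive on-frames is scored as k·Δ (discretization-corrected
    expectation for exponential dwells on a frame grid)."""
    lam = 1.0 / tau_on + 1.0 / tau_off
    pi_on = tau_on / (tau_on + tau_off)
    p_stay = pi_on + (1.0 - pi_on) * np.exp(-lam * frame_interval)
    return frame_interval / (1.0 - p_stay)


def generate_hbond_occupancy(spec: TelegraphSpec) -> OccupancyRealization:
    """Alternating exponential bonded/unbonded dwells, sampled per frame."""
    on, off = spec.tau_arrays()
    if np.any(on < spec.frame_interval):
        import warnings

        warnings.warn(
            "tau_on below the frame interval: discretization bias expected",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    t_frames = np.arange(n_frames) * spec.frame_interval
    occ = np.zeros((spec.n_pairs, n_frames), dtype=bool)
    true_events = []
    for p in range(spec.n_pairs):
        pi_on = on[p] / (on[p] + off[p])
        state = bool(rng.random() < pi_on)
        t = 0.0
        # Stationary start: the first dwell is length-biased; drawing a full
        # exponential from the renewal start is the standard equilibrium
        # construction for the *residual* dwell of a memoryless process.
        while t < spec.duration:
            dwell = rng.exponential(on[p] if state else off[p])
            t_end = t + dwell
            if state:
                true_events.append((p, t, min(t_end, spec.duration)))
                lo = int(np.ceil(t / spec.frame_interval - 1e-12))
                hi = int(np.floor(min(t_end, spec.duration - 1e-9) / spec.frame_interval + 1e-12))
                if hi >= lo:
                    occ[p, max(lo, 0) : min(hi + 1, n_frames)] = True
            t = t_end
            state = not state
    pair_ids = [(3 * p + 1, 3 * p + 2) for p in range(spec.n_pairs)]
    return OccupancyRealization(
        spec=spec, occupancy=occ, pair_ids=pair_ids, true_events=true_events
    )


def realize_geometry(
    occ: OccupancyRealization,
    spacing: float = 25.0,
    bonded_distance: float = 1.80,
    unbonded_distance: float = 5.0,
) -> Trajectory:
    """Embed an occupancy schedule in 3-D coordinates.

    Each pair becomes a (N, H, O) triple in its own residue; when bonded the
    acceptor sits collinear with D−H at H···A = ``bonded_distance`` (angle
    180°), when unbonded it is moved to ``unbonded_distance``; pairs are
    spaced far apart so no cross-pair bond can form.  The detector therefore
    reproduces the schedule frame-by-frame.
    """
    n_pairs, n_frames = occ.occupancy.shape
    origins = _grid_sites(n_pairs, spacing, spacing)
    box_edge = spacing * (int(np.ceil(n_pairs ** (1 / 3))) + 2)
    atoms = []
    for p in range(n_pairs):
        atoms.append(Atom(3 * p, "N", "N", p, "ALA", is_protein=True))
        atoms.append(
            Atom(3 * p + 1, "H", "H", p, "ALA", is_protein=True,
                 bonded_heavy_partner=3 * p)
        )
        atoms.append(Atom(3 * p + 2, "O", "O", p, "ALA", is_protein=True))
    coords = np.empty((n_frames, 3 * n_pairs, 3))
    for p in range(n_pairs):
        o = origins[p]
        coords[:, 3 * p] = o  # donor heavy
        coords[:, 3 * p + 1] = o + np.array([1.0, 0.0, 0.0])  # hydrogen
        bonded = occ.occupancy[p]
        acc_x = np.where(bonded, 1.0 + bonded_distance, 1.0 + unbonded_distance)
        coords[:, 3 * p + 2, 0] = o[0] + acc_x
        coords[:, 3 * p + 2, 1] = o[1]
        coords[:, 3 * p + 2, 2] = o[2]
    box = Box.cubic(box_edge)
    return Trajectory(
        topology=Topology(atoms),
        coordinates=coords,
        boxes=[box] * n_frames,
        frame_interval=occ.spec.frame_interval,
        label=ConditionLabel("TELEGRAPH", 300.0, 1.0),
        constant_box=True,
    )


# ---------------------------------------------------------------------------
# Solvated scene with planted interior waters
# ---------------------------------------------------------------------------


@dataclass
class SolvatedSceneSpec:
    box: Box = field(default_factory=lambda: Box.cubic(60.0))
    n_interior: int = 3
    n_exterior: int = 40
    protein_positions: Optional[np.ndarray] = None  # (n, 3) Å; default cluster
    seed: int = 0
    max_retries: int = 20_000


def generate_solvated_scene(
    spec: SolvatedSceneSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Single-frame scene in which exactly ``n_interior`` waters satisfy the
    interior rule (strictly inside the distance margins) and every other
    water fails it.  Returns the trajectory and the planted interior waters'
    oxygen atom indices."""
    from .core import minimum_image_distance_matrix

    rng = np.random.default_rng(spec.seed)
    box = spec.box
    if spec.protein_positions is None:
        center = np.full(3, box.vectors.diagonal().mean() / 2.0)
        protein = center + rng.normal(scale=2.0, size=(8, 3))
    else:
        protein = np.asarray(spec.protein_positions, float)

    def min_dist(p, pts):
        if len(pts) == 0:
            return np.inf
        return float(
            minimum_image_distance_matrix(np.atleast_2d(p), np.asarray(pts), box).min()
        )

    interior: list[np.ndarray] = []
    tries = 0
    while len(interior) < spec.n_interior:
        if tries > spec.max_retries:
            raise ConstructionError("could not place planted interior waters")
        tries += 1
        anchor = protein[rng.integers(len(protein))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + direction * rng.uniform(3.45, 3.85)
        if not 3.2 < min_dist(pos, protein) < 3.95:
            continue
        if min_dist(pos, interior) < 3.60:
            continue
        interior.append(pos)

    exterior: list[np.ndarray] = []
    lengths = np.linalg.norm(box.vectors, axis=1)
    tries = 0
    while len(exterior) < spec.n_exterior:
        if tries > spec.max_retries:
            raise ConstructionError("could not place exterior waters")
        tries += 1
        frac = rng.random(3)
        pos = frac @ box.vectors
        if min_dist(pos, protein) < 4.20:
            continue  # would pass the near-protein test
        if min_dist(pos, interior) < 3.60:
            continue  # would disqualify a planted interior water
        exterior.append(pos)

    atoms = []
    for i in range(len(protein)):
        atoms.append(Atom(i, "CA", "C", 0, "ALA", is_protein=True))
    n_p = len(protein)
    waters = interior + exterior
    for w, _pos in enumerate(waters):
        atoms.append(Atom(n_p + w, "O", "O", 1 + w, "HOH", is_water=True))
    coords = np.vstack([protein, np.asarray(waters)])[None, :, :]
    traj = Trajectory(
        topology=Topology(atoms),
        coordinates=coords,
        boxes=[box],
        frame_interval=1.0,
        label=ConditionLabel("SCENE", 300.0, 1.0),
        constant_box=True,
    )
    planted = np.arange(n_p, n_p + len(interior))
    return traj, planted


# ---------------------------------------------------------------------------
# Box-volume series
# ---------------------------------------------------------------------------


def generate_volume_series(
    mean: float, sd: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Gaussian box-volume series (Å³), deterministic per seed."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    return mean + sd * rng.standard_normal(n_frames)


def write_ground_truth(path, values: dict) -> None:
    """Key-value sidecar file consumed by the test suite and CLI users."""
    from pathlib import Path

    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path) -> dict:
    from pathlib import Path

    out = {}
    for ln in Path(path).read_text().splitlines():
        if "=" in ln:
            k, v = ln.split("=", 1)
            try:
                out[k.strip()] = float(v.strip())
            except ValueError:
                out[k.strip()] = v.strip()
    return out
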