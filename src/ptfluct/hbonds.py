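"""Geometric hydrogen bonds: detection, continuous-event lifetimes, summaries.

Definition: a donor hydrogen H (covalently bound to a protein N/O/S atom D)
is bonded to an acceptor A (a protein N/O/S heavy atom, A ≠ D) in a frame iff
the minimum-image H···A distance is strictly smaller than 2.40 Å and the
D−H···A angle is strictly larger than 130°.  Charged moieties participate on
both sides; an atom may appear in several pairs in the same frame
(bifurcated bonds count as separate pair events).

Lifetimes use the continuous-event convention rather than the decay of an
occupancy autocorrelation function: an *event* is a maximal run of
consecutive frames in which a (H, A) pair is bonded, and the pair lifetime is

    τ_ij = (1/n_ij) Σ_n t_ij(n)

the mean event duration over the pair's n_ij events.  The pair-averaged
lifetime τ_HB is the unweighted mean of τ_ij over unique pairs, excluding
pairs with τ_ij above a threshold (default 1 ns, reported by identity) whose
statistics rest on too few events; excluded pairs still count in the
simultaneous-bond population N_HB, which is block-averaged over every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    BlockSpec,
    Trajectory,
    minimum_image_displacements,
)
from .errors import (
    CoverageError,
    DegenerateSummaryError,
    SelectionError,
    TopologyError,
)

Pair = tuple[int, int]  # (donor hydrogen atom index, acceptor atom index)


@dataclass(frozen=True)
class HBondCriteria:
    d_ha_max: float = 2.40  # Å, strict upper bound on H···A distance
    angle_min: float = 130.0  # degrees, strict lower bound on D-H···A angle

    def __post_init__(self):
        if self.d_ha_max <= 0:
            raise ValueError("d_ha_max must be positive (Å)")
        if not 0 < self.angle_min < 180:
            raise ValueError("angle_min must lie in (0, 180) degrees")


@dataclass(frozen=True)
class HBondEvent:
    """One maximal run of consecutive bonded frames for a (H, A) pair."""

    donor_hydrogen: int
    donor_heavy: int
    acceptor: int
    start_frame: int
    end_frame: int  # half-open
    duration: float  # ps = (end − start) × frame_interval
    truncated: bool  # touches a trajectory boundary


@dataclass(frozen=True)
class PairLifetime:
    donor_hydrogen: int
    acceptor: int
    n_events: int
    tau: float  # ps, mean event duration
    total_time: float  # ps, Σ durations


@dataclass
class LifetimeSummary:
    n_hb: float  # mean simultaneous bond count
    n_hb_error: float  # block SEM
    n_unique_pairs: int  # N: pairs ever observed
    tau_hb: float  # ps
    tau_hb_error: float  # ps, block SEM over per-block pair means
    excluded_pairs: list = field(default_factory=list)
    # entries: (pair, tau, reason)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_hbonds_frame(
    traj: Trajectory,
    frame: int,
    crit: HBondCriteria | None = None,
    donors: Optional[np.ndarray] = None,
    acceptors: Optional[np.ndarray] = None,
) -> set[Pair]:
    """Hydrogen-bonded (donor hydrogen, acceptor) pairs in one frame."""
    crit = crit or HBondCriteria()
    top = traj.topology
    if donors is None:
        donors = top.donor_hydrogen_indices()
    if acceptors is None:
        acceptors = top.acceptor_indices()
    if donors.size == 0:
        raise TopologyError("topology has no polar protein hydrogens (donors)")
    if acceptors.size == 0:
        raise SelectionError("topology has no acceptor atoms")
    box = traj.require_boxes()[frame]
    pos = traj.coordinates[frame]
    heavy_of = top.bonded_heavy_partner

    h_pos = pos[donors]
    a_pos = pos[acceptors]
    # H -> A displacements under minimum image, all pairs
    d = a_pos[None, :, :] - h_pos[:, None, :]
    disp_ha = minimum_image_displacements(d.reshape(-1, 3), box).reshape(
        donors.size, acceptors.size, 3
    )
    dist_ha = np.linalg.norm(disp_ha, axis=2)
    cand_h, cand_a = np.nonzero(dist_ha < crit.d_ha_max)
    out: set[Pair] = set()
    if cand_h.size == 0:
        return out
    # H -> D displacements under minimum image, per donor
    d_pos = pos[heavy_of[donors]]
    disp_hd = minimum_image_displacements(d_pos - h_pos, box)
    for hi, ai in zip(cand_h, cand_a):
        h_atom = int(donors[hi])
        a_atom = int(acceptors[ai])
        if a_atom == int(heavy_of[h_atom]):
            continue  # the donor heavy atom itself cannot accept from its H
        v1 = disp_hd[hi]
        v2 = disp_ha[hi, ai]
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle > crit.angle_min:  # strict: "larger than"
            out.add((h_atom, a_atom))
    return out


def detect_hbonds(
    traj: Trajectory, crit: HBondCriteria | None = None
) -> list[set[Pair]]:
    """Per-frame bonded pair sets for the whole trajectory."""
    top = traj.topology
    donors = top.donor_hydrogen_indices()
    acceptors = top.acceptor_indices()
    return [
        detect_hbonds_frame(traj, f, crit, donors=donors, acceptors=acceptors)
        for f in range(traj.n_frames)
    ]


# ---------------------------------------------------------------------------
# Event tracking (continuous lifetimes)
# ---------------------------------------------------------------------------


def track_events(
    per_frame_sets: Sequence[set[Pair]],
    frame_interval: float = 1.0,
    donor_heavy_of: Optional[dict[int, int]] = None,
    gap_tolerance: int = 0,
) -> tuple[list[HBondEvent], list[PairLifetime]]:
    """Continuous-event list and per-pair lifetimes from per-frame pair sets.

    An event is a maximal run of consecutive bonded frames; with
    ``gap_tolerance`` g > 0, interruptions of at most g frames are bridged
    (default 0: the strict continuous reading).  Events touching either
    trajectory end are flagged truncated but included in τ_ij.
    """
    n_frames = len(per_frame_sets)
    if n_frames == 0:
        raise CoverageError("empty frame sequence")
    frames_of: dict[Pair, list[int]] = {}
    for f, pairs in enumerate(per_frame_sets):
        for p in pairs:
            frames_of.setdefault(p, []).append(f)

    events: list[HBondEvent] = []
    lifetimes: list[PairLifetime] = []
    for pair in sorted(frames_of):
        frames = frames_of[pair]
        runs: list[tuple[int, int]] = []
        start = prev = frames[0]
        for f in frames[1:]:
            if f - prev <= 1 + gap_tolerance:
                prev = f
            else:
                runs.append((start, prev + 1))
                start = prev = f
        runs.append((start, prev + 1))
        heavy = (
            donor_heavy_of.get(pair[0], -1) if donor_heavy_of is not None else -1
        )
        durations = []
        for s, e in runs:
            dur = (e - s) * frame_interval
            durations.append(dur)
            events.append(
                HBondEvent(
                    donor_hydrogen=pair[0],
                    donor_heavy=heavy,
                    acceptor=pair[1],
                    start_frame=s,
                    end_frame=e,
                    duration=dur,
                    truncated=(s == 0) or (e == n_frames),
                )
            )
        lifetimes.append(
            PairLifetime(
                donor_hydrogen=pair[0],
                acceptor=pair[1],
                n_events=len(runs),
                tau=float(np.mean(durations)),
                total_time=float(np.sum(durations)),
            )
        )
    return events, lifetimes


def summarize_lifetimes(
    pairs: Sequence[PairLifetime],
    per_frame_sets: Sequence[set[Pair]],
    blocks: BlockSpec | None = None,
    frame_interval: float = 1.0,
    exclusion_threshold: float = 1000.0,
) -> LifetimeSummary:
    """Population N_HB and pair-averaged lifetime τ_HB with the exclusion rule.

    N_HB is the block average of the per-frame bond count over every written
    frame and includes all pairs.  τ_HB averages τ_ij over unique pairs with
    τ_ij ≤ ``exclusion_threshold`` (default 1 ns); longer-lived pairs are
    excluded for lack of event statistics and reported by identity.
    """
    blocks = blocks or BlockSpec()
    n_frames = len(per_frame_sets)
    if n_frames == 0:
        raise CoverageError("empty frame sequence")
    counts = np.array([len(s) for s in per_frame_sets], dtype=float)
    try:
        slices = blocks.slices(n_frames, frame_interval)
    except CoverageError:
        slices = [(0, n_frames)]
    block_counts = np.array([counts[s:e].mean() for s, e in slices])
    n_hb = float(block_counts.mean())
    n_hb_err = (
        float(block_counts.std(ddof=1) / np.sqrt(len(slices)))
        if len(slices) > 1
        else 0.0
    )

    included = [p for p in pairs if p.tau <= exclusion_threshold]
    excluded = [
        (
            (p.donor_hydrogen, p.acceptor),
            p.tau,
            f"tau {p.tau:.1f} ps exceeds the {exclusion_threshold:.0f} ps "
            "exclusion threshold (insufficient event statistics)",
        )
        for p in pairs
        if p.tau > exclusion_threshold
    ]
    if pairs and not included:
        raise DegenerateSummaryError(
            "every hydrogen-bond pair exceeded the exclusion threshold"
        )
    tau_hb = float(np.mean([p.tau for p in included])) if included else float("nan")

    # Error on tau_HB: recompute the pair-mean within each block and take the
    # SEM over blocks (pairs absent from a block simply do not contribute).
    tau_err = 0.0
    if len(slices) > 1 and included:
        block_tau = []
        for s, e in slices:
            _, bl_pairs = track_events(per_frame_sets[s:e], frame_interval)
            vals = [p.tau for p in bl_pairs if p.tau <= exclusion_threshold]
            if vals:
                block_tau.append(np.mean(vals))
        if len(block_tau) > 1:
            bt = np.asarray(block_tau)
            tau_err = float(bt.std(ddof=1) / np.sqrt(bt.size))

    return LifetimeSummary(
        n_hb=n_hb,
        n_hb_error=n_hb_err,
        n_unique_pairs=len(pairs),
        tau_hb=tau_hb,
        tau_hb_error=tau_err,
        excluded_pairs=excluded,
    )


# ---------------------------------------------------------------------------
# Fluctuation–lifetime correlation
# ---------------------------------------------------------------------------


def fluctuation_lifetime_dataset(
    msf,
    pairs: Sequence[PairLifetime],
    min_tau: float = 2.0,
    weighting: str = "event",
):
    """Per-acceptor dataset of (1/MSF, ln τ) with its Pearson correlation.

    For each acceptor atom, τ_acceptor aggregates the lifetimes of every
    donor bonded to it: event-weighted (total bonded time / total events,
    the default) or the unweighted mean of the per-donor τ_ij.  Rows are
    kept only when τ_acceptor exceeds ``min_tau`` (default 2 ps), removing
    acceptors whose bonds never outlive the frame grid.

    Returns ``(rows, pearson_r)`` where rows is a list of dicts with keys
    ``acceptor``, ``msf``, ``inv_msf``, ``tau``, ``ln_tau``.
    """
    import warnings as _warnings

    by_acceptor: dict[int, list[PairLifetime]] = {}
    for p in pairs:
        by_acceptor.setdefault(p.acceptor, []).append(p)

    rows = []
    for acc in sorted(by_acceptor):
        plist = by_acceptor[acc]
        if weighting == "event":
            total_time = sum(p.total_time for p in plist)
            total_events = sum(p.n_events for p in plist)
            tau_acc = total_time / total_events
        elif weighting == "pair":
            tau_acc = float(np.mean([p.tau for p in plist]))
        else:
            raise ValueError(f"unknown weighting: {weighting!r}")
        if tau_acc <= min_tau:
            continue
        try:
            msf_val = msf.per_atom(acc)
        except KeyError:
            continue  # acceptor outside the MSF selection (should not happen)
        if msf_val <= 0:
            continue
        rows.append(
            {
                "acceptor": acc,
                "msf": msf_val,
                "inv_msf": 1.0 / msf_val,
                "tau": tau_acc,
                "ln_tau": float(np.log(tau_acc)),
            }
        )
    if len(rows) < 2:
        _warnings.warn(
            "fewer than two acceptors pass the lifetime filter; "
            "correlation undefined",
            stacklevel=2,
        )
        return rows, float("nan")
    inv_msf = np.array([r["inv_msf"] for r in rows])
    ln_tau = np.array([r["ln_tau"] for r in rows])
    r = float(np.corrcoef(inv_msf, ln_tau)[0, 1])
    return rows, r


def occupancy_conservation_gap(
    pairs: Sequence[PairLifetime],
    per_frame_sets: Sequence[set[Pair]],
    frame_interval: float = 1.0,
) -> float:
    """Σ n_ij·τ_ij − Δt·Σ_frames |bond set|; zero when events exactly tile
    the occupancy (a consistency check linking lifetimes to N_HB)."""
    total_event_time = sum(p.n_events * p.tau for p in pairs)
    total_occupancy = frame_interval * sum(len(s) for s in per_frame_sets)
    return float(total_event_time - total_occupancy)
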