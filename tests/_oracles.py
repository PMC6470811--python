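"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration (explicit loops,
27-image scans, run-length scans) without using the package's vectorized
implementations, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

IMAGE_SHIFTS = [
    (i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
]


def brute_min_image_distance(a, b, box_vectors) -> float:
    """Minimum over the 27 periodic images after wrapping into the cell."""
    d = np.asarray(b, float) - np.asarray(a, float)
    frac = d @ np.linalg.inv(box_vectors)
    frac = frac - np.round(frac)
    wrapped = frac @ box_vectors
    best = math.inf
    for s in IMAGE_SHIFTS:
        cand = wrapped + np.asarray(s, float) @ box_vectors
        best = min(best, float(np.linalg.norm(cand)))
    return best


def brute_hbond_pairs(
    positions, donors, donor_heavy, acceptors, box_vectors,
    d_max=2.40, angle_min=130.0,
):
    """All-triples hydrogen-bond scan: for every (H, A) pair check the
    minimum-image H···A distance and the D-H···A angle explicitly."""
    out = set()
    for h in donors:
        d_atom = donor_heavy[h]
        for a in acceptors:
            if a == d_atom:
                continue
            dist = brute_min_image_distance(positions[h], positions[a], box_vectors)
            if not dist < d_max:
                continue
            # minimum-image displacement vectors from H
            def mi_vec(p, q):
                d = np.asarray(q, float) - np.asarray(p, float)
                frac = d @ np.linalg.inv(box_vectors)
                frac = frac - np.round(frac)
                wrapped = frac @ box_vectors
                best, bv = math.inf, wrapped
                for s in IMAGE_SHIFTS:
                    cand = wrapped + np.asarray(s, float) @ box_vectors
                    n = float(np.linalg.norm(cand))
                    if n < best:
                        best, bv = n, cand
                return bv

            v_hd = mi_vec(positions[h], positions[d_atom])
            v_ha = mi_vec(positions[h], positions[a])
            cosang = np.dot(v_hd, v_ha) / (
                np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            )
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle > angle_min:
                out.add((h, a))
    return out


def brute_interior_waters(
    protein_pos, water_pos, box_vectors, d_protein_max=4.00, d_water_min=3.36
):
    """Interior-water rule by explicit double loop over atoms and images."""
    interior = []
    n_w = len(water_pos)
    for w in range(n_w):
        near = any(
            brute_min_image_distance(water_pos[w], p, box_vectors) < d_protein_max
            for p in protein_pos
        )
        if not near:
            continue
        crowded = any(
            brute_min_image_distance(water_pos[w], water_pos[v], box_vectors)
            < d_water_min
            for v in range(n_w)
            if v != w
        )
        if not crowded:
            interior.append(w)
    return interior


def run_length_events(occupancy_row):
    """Maximal runs of True in a boolean sequence: [(start, stop)), ...]."""
    runs = []
    start = None
    for i, on in enumerate(occupancy_row):
        if on and start is None:
            start = i
        elif not on and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(occupancy_row)))
    return runs


def double_loop_global_msf(per_atom_per_block):
    """Eq-style recomputation of the protein-averaged MSF by explicit loops:
    average per-atom block values over blocks, then over atoms."""
    n_atoms, n_blocks = per_atom_per_block.shape
    total = 0.0
    for i in range(n_atoms):
        acc = 0.0
        for b in range(n_blocks):
            acc += per_atom_per_block[i, b]
        total += acc / n_blocks
    return total / n_atoms
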