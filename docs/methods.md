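# Methods

`ptfluct` quantifies how temperature and pressure change the internal
dynamics of a solvated protein in MD trajectories, using five per-condition
observables and their endpoint comparisons. This note records the models,
the defaults and their units, the numerical choices, and what the synthetic
ground truth does and does not establish.

## Observables

### Mean-square fluctuations (MSF)

For each protein heavy atom *i* the trajectory is cut into consecutive
blocks (default 10 ns, 5 blocks), and within each block the fluctuation is
the variance of the atom's position about its within-block mean position,
summed over x, y, z:

    ⟨Δr_i²⟩ = block average of Var_block(r_i)      [Å²]
    MSF = (1/N_HA) Σ_i ⟨Δr_i²⟩

N_HA counts protein heavy atoms only; hydrogens, waters, ions, ligands and
virtual sites are excluded by default (the ligand selection is
configurable). Errors are the standard error of the mean over block values
(sd/√n_blocks) — the block mean ± SEM convention is used for every
block-averaged quantity in the package.

**Superposition.** By default every frame is least-squares superposed
(Kabsch, protein heavy atoms) onto the within-block mean structure before
variances are taken, with two fit iterations (fit to a provisional
reference, rebuild the mean, refit). Without this, rigid-body tumbling
dominates 10-ns fluctuations of a free protein. The reference is the
within-block mean, not a crystal structure, so each block is
self-contained. A `superpose=False` switch exists for inputs known to carry
no rigid-body motion (the OU generator below); any cross-condition
comparison must use one setting throughout.

Per-residue MSF averages ⟨Δr_i²⟩ over the heavy atoms of each residue.
Difference maps between two conditions (high − low) are exported with a
color coordinate clipped to the anchors −0.5 Å² (blue) / 0 (white) /
+2.0 Å² (red) and normalised to [0, 1]; rendering on a structure is left to
external tools.

### Apparent protein volume

    V_app = ⟨V_MD⟩ − N_w·⟨V_w⟩      [Å³]

⟨V_MD⟩ is the time-mean simulation-box volume (scalar triple product of the
cell vectors, so triclinic cells such as the rhombic dodecahedron are
exact), N_w the number of water molecules in the box, ⟨V_w⟩ the mean
molecular volume of water from a pure-solvent simulation at the same (T, P)
— supplied either as a bare number in the config or computed from a
solvent volume series. V_app/N_HA is the per-heavy-atom measure used in
comparisons. Ions' volume is *not* subtracted; this biases absolute V_app
by roughly the ionic partial volumes but cancels in ΔT/ΔP comparisons,
which is what the package is for. Surface- or Voronoi-based protein volumes
are deliberately out of scope.

### Interior waters

A water (located by its oxygen) is *inside* the protein in a frame iff its
minimum-image distance to the nearest protein heavy atom is **< 4.00 Å**
and no other water oxygen lies **< 3.36 Å** from it. Both cutoffs, the
oxygen–oxygen convention, and the sampling grid (every 100 ps) are config
defaults. Boundary semantics: "within" is a strict `<` on both tests, so a
neighbour at exactly 3.36 Å does **not** disqualify; ties are measure-zero
on real data and are pinned by explicit boundary tests. N_w,in is the mean
count over sampled frames ± block SEM.

### Hydrogen bonds and lifetimes

Donors are protein hydrogens covalently bound to N/O/S; acceptors are
protein N/O/S heavy atoms (charged moieties included); the donor's own
heavy atom is excluded as acceptor for its hydrogen. A pair is bonded in a
frame iff the minimum-image H···A distance is **< 2.40 Å** and the D−H···A
angle is **> 130°** (both strict). Bifurcated bonds count as separate pair
events. Protein–water hydrogen bonds are out of scope.

Lifetimes use the continuous-event convention: an event is a maximal run of
consecutive bonded frames (zero-frame gap tolerance by default; a
configurable tolerance exists for sensitivity analysis), and

    τ_ij = (Σ_n t_ij(n)) / n_ij

is the mean event duration of a pair. The pair-averaged lifetime τ_HB is
the unweighted mean of τ_ij over unique pairs with τ_ij at or below the
exclusion threshold (default 1 ns); longer-lived pairs have too few events
for a meaningful mean and are excluded from τ_HB but reported by identity,
and they always count toward the population N_HB, which is the
block-averaged per-frame bond count over every written frame. The
occupancy-autocorrelation lifetime was deliberately not implemented:
protein hydrogen bonds span picoseconds to tens of nanoseconds, which makes
a single correlation-decay fit impractical, and the continuous-event
measure tracks the same relative changes.

Events touching either trajectory end are flagged `truncated` and
*included* in τ_ij: at 50-ns scale, dropping them would bias long-lived
pairs downward, and the flag lets users recompute without them.

The exclusion threshold is fixed (not temperature-dependent): published
workflows sometimes apply it only at the coldest condition, and the
excluded-pair report makes that variant reproducible by hand.

### Fluctuation–lifetime correlation

Per acceptor atom, τ_acceptor pools the lifetimes of all donors bonded to
it, event-weighted (total bonded time / total events; an unweighted
per-donor mean is a switch). Acceptors with τ_acceptor ≤ 2 ps are dropped —
bonds that never outlive a couple of frame intervals carry no lifetime
signal. The exported table holds (acceptor, 1/MSF, ln τ) and the Pearson
correlation of 1/MSF with ln τ; a negative-sloped cloud (r > 0 between
1/MSF and ln τ) is the signature of shorter-lived hydrogen bonds
accompanying larger fluctuations.

### Condition comparison

`delta_table` compares the two endpoint states along one axis (T at
constant P, or P at constant T): percent changes 100·(high − low)/low for
MSF, V_app/N_HA and τ_HB, rounded half-away-from-zero to integers; N_w,in
as a signed difference to 2 decimals; N_HB as a signed integer difference.
The rounding convention was fixed by verifying it against every cell of the
published DHFR comparison tables that the shipped
`data/dhfr_condition_summaries.tsv` reproduces (all 40 cells, exactly).
Errors are propagated in quadrature and kept in the row objects but not in
the printed view, matching the published presentation.

## Synthetic ground truth

The trajectories behind the published DHFR numbers are not deposited, so
the package ships generators that emulate the *statistical* structure each
stage assumes — not molecular physics. All are deterministic given
(spec, seed).

* **OU pseudo-protein** — each heavy atom is an independent
  Ornstein–Uhlenbeck process about a fixed lattice site: relaxation rate
  `friction` (ps⁻¹, the positional decorrelation rate; default 0.2, i.e. a
  5-ps relaxation time so a 10-ns block holds ~2000 correlation times), and
  stationary variance k_B·T/κ_i per coordinate, giving the exact 3-D ground
  truth MSF_i = 3k_BT/κ_i with k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹. The
  default κ targets the ~0.65 Å² scale of a cold folded protein. Exact
  discretization (x ← a·x + √(σ²(1−a²))·ξ, a = e^(−λΔt)) keeps the target
  exact at any frame interval.
* **Telegraph occupancy** — per pair, alternating exponential
  bonded/unbonded dwells (defaults τ_on = τ_off = 25 ps, matching the
  ~25-30 ps pair lifetimes of the cold conditions), point-sampled on the
  frame grid. Sampling makes observed on-runs geometric with continuation
  probability p = π_on + (1−π_on)e^(−(1/τ_on+1/τ_off)Δ), so the expected
  observed mean run duration is Δ/(1−p) — the discretization-corrected
  target the recovery tests use (cross-checked against a brute-force
  continuous-time simulation). An optional geometric realization embeds the
  schedule as (N, H, O) triples that the detector reproduces frame-exactly.
* **Solvated scene** — plants a chosen number of waters that satisfy the
  interior rule with safety margins (3.45–3.85 Å from protein, ≥ 3.6 Å from
  other waters) and exterior waters that violate it (> 4.2 Å from protein),
  by rejection sampling with a bounded retry budget.
* **Volume series** — Gaussian box volumes (defaults 260 000 ± 200 Å³,
  the scale of a ~71 Å rhombic dodecahedral cell).

**What passing on synthetic data does not show:** the generators have no
covalent geometry, no water hydrogens, no coupling between atoms, no
pressure/temperature physics. They validate the *estimators* (block
statistics, event bookkeeping, geometric criteria, minimum-image handling),
not force fields or sampling adequacy of real MD.

## Numerical choices

* Units: Å, ps, K, bar throughout; 0-based atom/frame indices; half-open
  frame ranges.
* Minimum image: displacements are reduced by the rounded fractional
  lattice shift and the shortest vector chosen among the 27 neighbouring
  images — exact for reduced cells (verified against a brute-force image
  scan on random triclinic cells); the zero-shift candidate is the raw
  displacement itself, so short in-cell distances suffer no fractional
  round-trip error. Degenerate cells raise a geometry error.
* Angles are compared in degrees after `arccos` (clipped to [−1, 1]), so
  exactly-boundary geometries behave per the strict inequalities.
* Blocks that would be incomplete at the trajectory tail are dropped and
  logged; fewer available blocks than requested is a logged warning, not an
  error (≥ 1 block required).
* Water residue names {HOH, TIP4, TIP4P, WAT, SOL, TIP3, SPC} and monatomic
  ion names are recognised; ions are neither protein nor water and excluded
  from every statistic. TIP4P-style massless virtual sites are carried in
  the coordinate arrays but excluded from all counts and criteria.
* Hydrogen→heavy pairing uses CONECT records when present, else the nearest
  intra-residue heavy atom within 1.2 Å; an unresolvable protein/water
  hydrogen is a topology error because lifetime analysis needs donors.
* Formats without per-frame cells are accepted with a constant
  user-supplied box (logged); multi-model PDB uses its CRYST1 header cell
  for all frames.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery checks at
100 atoms × 50 000 frames (MSF), 50 pairs × 12 500 frames (~12 000 events;
lifetimes), 50 random periodic configurations per geometric oracle, and
80 acceptors (correlation) — sizes at which the analytic tolerances (5 %
per atom, 2 % global, 3 SEM) are comfortably resolvable and a full run
stays under a minute.

## Known limitations

* Superposition removes net rotation/translation per block; internal
  collective motions spanning blocks are invisible to the 10-ns MSF by
  construction.
* τ_HB depends on the frame interval through the run-length discretization;
  comparisons across trajectories must use the same interval.
* V_app inherits any barostat volume drift; the block SEM reflects
  fluctuation, not drift.
* The interior-water count is definition-sensitive near protein melting,
  where the protein surface becomes diffuse; no alternative definition is
  provided.
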