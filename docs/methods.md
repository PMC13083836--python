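# Methods

This note documents the models and procedures implemented in `qwire`, the
parameters that matter, the synthetic-data generators, and the numerical
choices made where the design was genuinely open.

## Grotthuss wire model

A proton wire is modelled as a graph whose nodes are water oxygens and the
protonatable sidechain heavy atoms of Asp (OD1, OD2), Glu (OE1, OE2),
His (ND1, NE2), Lys (NZ), Ser (OG), Thr (OG1) and Tyr (OH). Backbone
carbonyls/amides are excluded: the analysis considers sidechains and waters
only. An undirected edge joins two nodes whose distance is ≤ r_c; the
default cutoff is exactly 4.0 Å with an inclusive boundary. Hydrogens are
ignored throughout (the criterion is heavy-atom distance, not hydrogen-bond
geometry), and ligand O/N atoms can be included as nodes via a flag
(default off, since whether detergent/quinone oxygens participate in the
published networks is not stated).

A pathway segment is a pair of anchor residue sets (A, B). Anchors with
several wire atoms (His, carboxylates) count as node sets: reaching any
member connects the segment. Segments facing bulk solvent (matrix or
intermembrane space) use a `surface` anchor that matches user-flagged
surface waters, because detecting bulk exposure automatically is out of
scope. Classification is three-valued:

* **connected** — multi-source BFS finds an A→B path; the witness is a
  shortest hop-count path.
* Otherwise the graph's components are condensed; inter-component links are
  weighted by the minimal node-pair distance, and Dijkstra gives the
  minimum-total-gap-length route from A's component(s) to B's. (Which route
  "the" gaps belong to is otherwise ambiguous; the minimal-total-gap route is
  a deterministic, physically sensible choice.) Each gap on the route is
  probed:
* **open gap** — every gap admits a water-sized probe; **obstructed gap** —
  at least one does not.

### Obstruction probe

The published analysis distinguishes unobstructed from obstructed gaps
without an operational criterion (visual inspection is likely). Here the
criterion is explicit and config-exposed: sample the straight u–v line at
≤ 0.5 Å spacing; a sample point is *passable* if a probe sphere of radius
1.4 Å (a water) can be centred within 2.0 Å of the point without
overlapping the van-der-Waals sphere of any heavy atom that is not a water
and not part of the two gap-flanking residues (overlap = centre distance
< r_vdw + r_probe). The gap is open iff every point is passable. Candidate
centres are enumerated on a 0.1 Å grid inside the lateral-search sphere;
a 0.1 Å brute-force grid is kept as an independent oracle, and the two
agree in ≥ 99% of randomised trials, with disagreements confined to
near-boundary geometries. VdW radii are the Bondi element table shipped as
data (C 1.70, N 1.55, O 1.52, S 1.80 Å …), overridable via config.
Because the published verdicts were not produced by this exact criterion,
cell-by-cell reproduction of the published connectivity table is not
promised; the criterion is a stated surrogate.

Hydration numbers count distinct waters with an oxygen within 3.4 Å of any
atom of the query set. Hydrogen-bond detection pairs polar heavy atoms
(N, O) at 2.4–3.4 Å — the same window used to place waters when the
deposited models were built — and, when a donor's covalent antecedent is
resolvable (nearest same-residue heavy atom within 1.8 Å), requires an
antecedent–donor–acceptor angle ≥ 90° for at least one of the two donor
assignments.

## Path collective variables and binding modes

The pose vector v collects all distances between the Q-headgroup heavy
atoms and the Cα of channel-lining residues in NDUFS7/NDUFS2/ND1, in nm,
headgroup-major order. With N milestone vectors m_i (the study used N = 4,
representing progressive binding):

    d_i²  = mean over components of (v − m_i)²        [nm²]
    s_raw = Σ i·exp(−λ d_i²) / Σ exp(−λ d_i²)         ∈ [1, N]
    Path.S = a + b·s_raw
    Path.Z = −(1/λ)·ln Σ exp(−λ d_i²)                 [nm²]

Numerical choices: d² is the *mean* (not sum) of squared deviations, which
keeps Path.Z on the nm² scale of the published tables (config-switchable to
sum); the soft-min is evaluated with the smallest d² factored out so large
λ cannot underflow. λ defaults to 2.3 / ⟨d²_{i,i+1}⟩ (mean squared metric
distance between consecutive milestones), standard path-CV practice; the
published λ is not stated. The affine map defaults to a = 21, b = 1.25 so
that s_raw ∈ [1, 4] spans the wall interval [21, 26] of the sampling
protocol. Because the original milestone geometries and λ live in prior
work, absolute Path.S/Path.Z values of deposited structures are *not*
reproduced — only the functional form, its invariants (bounds,
monotonicity along the route, rigid-motion invariance) and the scale.

**Ring flip.** A least-squares plane is fitted to the six ring carbons
(SVD). If any named substituent (O1, O4, the two methoxy O, the 5-methyl C)
deviates from the plane by more than 0.4 Å the flip is *undefined* (bent
headgroup, as in the bacterial structures). Otherwise the state is *on* iff
the 5-methyl carbon is closer to the reactive Tyr hydroxyl oxygen than the
midpoint of the two methoxy oxygens — a geometric operationalisation of
"the Q-methyl points towards the Tyr".

**Modes.** on → I; off → J.1 (Path.S ≤ 23.40), J.2 (≤ 23.85), K.2
(> 23.85); undefined → K.1. The two thresholds are midpoints between the
printed Path.S clusters {≤23.2}, {23.6}, {24.1}; they are config-overridable
and reproduce all 13 published labels exactly.

**Superposition.** Kabsch SVD with proper-rotation sign correction; Cα
pairing by (subunit, residue number), silently dropping residues missing
from either model (≥ 3 required). Headgroup displacement aligns model B
onto model A on one subunit's Cα (default NDUFS2) and reports the distance
between ring-carbon centroids — the published shifts do not state their
measurement convention, so centroid distance is adopted and compared with a
widened tolerance.

## Well-tempered metadynamics

The engine reproduces the published biasing protocol exactly and replaces
only the dynamics (all-atom MD is out of scope) with overdamped Langevin
moves directly in CV space:

    x ← x − (Δt/γ_f)·∇(U + V_bias + W) + √(2 k_BT Δt/γ_f)·ξ

Parameters (defaults = the published protocol): kernel height h₀ =
0.6 kJ/mol; pace 500 steps (1 ps at Δt = 2 fs); widths σ = 0.4 CV units
(0.02 rad for an optional dihedral dimension); bias factor γ = 15;
T = 310 K (k_B in kJ/mol/K); half-harmonic walls 21.0 < s < 26.0 (and
−0.245 < z < −0.220 nm² in 2-D) with k = 10⁴ kJ/mol per unit². Deposited
heights follow h = h₀·exp(−V_bias/k_B ΔT), ΔT = (γ−1)T. The surrogate
friction defaults to γ_f = 25 kJ/mol·ps per unit² (≈1 ps decorrelation in
the benchmark wells); several analyses use γ_f = 5 for faster CV diffusion,
which changes only the surrogate kinetics, never the biasing protocol.
Kernel sums are evaluated exactly (no grids/splines) — with the default
pace a multi-million-step run deposits only thousands of kernels.

Estimators:

* running estimate F̂ = −(T+ΔT)/ΔT·V_bias, shifted to min 0. This carries
  the O(σ²·F″) smoothing bias of the kernel width; it preserves quadratic
  curvature exactly but cannot resolve quartic minima sharper than σ.
* reweighted histogram: post-burn-in frames weighted by exp(+V_bias/k_BT)
  under the final bias, F = −k_BT·ln ρ̂. Free of kernel smoothing.
* pooled walkers: independent seeded runs, each run's weights normalised to
  unit mass, histograms summed before the log. This is the recommended
  recovery route: averaging over walkers suppresses the ripple a single
  history-dependent bias leaves in the profile.

Observable reweighting uses final-bias weights (the standard last-bias
estimator; time-dependent estimators are out of scope), with a bootstrap
confidence interval over stride-decimated, approximately decorrelated
frames. Convergence is monitored as the maximum change of
F̂(cv) − F̂(cv_ref) between consecutive snapshots — offset-invariant, as a
free-energy-difference criterion must be.

**Benchmark.** The double-well landscape U(s) = B·(((s−c)/a)² − 1)² with
B = 10 kJ/mol, c = 23.5, a = 1 (minima 22.5/24.5 inside the walls, barrier
10 kJ/mol) is the recovery benchmark: 8 pooled walkers × 6·10⁵ steps
recover the profile on [22, 25] to within the ±1 kJ/mol convergence
criterion in a few CPU-minutes. The comparison window [22, 25] covers both
minima and the barrier while staying ≥ 2σ clear of the walls, where the
static wall potential (which the bias legitimately also compensates) would
otherwise contaminate the comparison. The running bias-formula estimate
alone plateaus near 2.3 kJ/mol on this landscape — a systematic
kernel-smoothing floor (verified against the deterministic ideal-sampling
fixed point), which is why the pooled reweighted histogram is the recovery
route.

## Synthetic fixtures

Fixtures contain only the atoms the analyses touch (a Tyr is its hydroxyl
oxygen, a water its oxygen); rotamer realism is irrelevant to the geometric
contracts under test.

* **Wire fixtures**: per-segment declared states. Water chains at 2.8 Å
  spacing (inside both the 4 Å cutoff and the 2.4–3.4 Å H-bond window);
  gaps of 5.5 Å; obstructed gaps centre a selenium pseudo-atom (vdW
  1.90 Å) on the gap line, which excludes every probe centre within
  1.3 Å of the midpoint — comfortably beyond the 0.3 Å clearance margin
  the generator enforces around every decision boundary. Coordinates are
  jittered (≤ 0.05 Å) and optionally rigidly moved. Before returning, the
  generator re-runs the full analysis *and* the independent brute-force
  oracles (all-pairs edges, dense probe grid) and refuses to emit a
  mislabelled fixture.
* **Channel fixtures**: a straight channel with Cα anchors alternating
  ±4 Å off-axis, headgroup waypoints at even fractions; milestone vectors
  are computed from the waypoint geometries, λ by the default rule. At that
  λ the soft-min cross-talk between milestones pulls s_raw at the first
  waypoint slightly above 1 (≈1.08 for the default geometry); the exact
  endpoint value is therefore not asserted, the strict monotonicity of
  s_raw with channel position is.
* **Quinol poses**: a 1.39 Å hexagonal ring with radial substituents,
  rotated so the methyl edge (on) or methoxy edge (off) faces the Tyr, or
  with the methyl bent 1 Å out of plane (undefined).
* **Landscapes**: harmonic, double-well and flat potentials with exact
  gradients (checked against finite differences).

What the fixtures do *not* emulate: real rotamer geometry, crowded protein
interiors (probe trials place 1–3 random blockers, not a packed cavity),
experimental coordinate error, or partial-occupancy waters. Passing the
fixture suite therefore demonstrates the correctness of the graph,
probe, CV and superposition machinery — not that the surrogate obstruction
criterion reproduces every published connectivity verdict on deposited
models.

## Known limitations

* The obstruction criterion is a surrogate for an unstated published
  procedure; verdicts near the probe decision boundary are parameter
  sensitive (probe radius, lateral search, grid).
* Absolute Path.S/Path.Z of deposited structures require the original
  milestone configurations; only scale and form are reproduced.
* The default pathway config fills a few central-axis anchors not named in
  the published key from the mammalian literature; confirm against the
  deposited entry before production use.
* Comparisons against deposited models need the public archive (or a local
  cache); the rest of the suite is offline by construction.
* The Langevin surrogate says nothing about the real system's kinetics;
  only the biasing protocol and its estimators are exercised.
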