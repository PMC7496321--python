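# Methods

This note documents the models, numerical choices and limitations behind
`modecross`, in the spirit of a methods appendix.

## Elastic-network model

Every heavy atom is a network node; atom pairs within a distance cutoff
(default 8 Å) are connected by identical Hookean springs (spring constant
1.0, arbitrary energy/Å² units).  The 3N×3N Hessian is assembled from the
standard anisotropic-network super-elements −k·(Δr Δrᵀ)/|Δr|² with diagonal
blocks equal to the negated row sums; it is symmetric positive semidefinite
by construction.  A connected network has exactly six zero eigenvalues
(rigid translations and rotations).  Trivial modes are removed by
thresholding eigenvalues at 1e−8 relative to the largest; any count other
than six is treated as an error (more than six means the network is
disconnected at this cutoff and the error says so), never silently
tolerated.  No mass weighting is applied: only mode shapes and the relative
eigenvalue order are consumed downstream, never physical frequencies.

Modes are unit-normalized, so amplitudes are in Å per unit mode vector.
Because eigenvector signs are arbitrary, a deterministic convention is
fixed: each mode is flipped so its largest-magnitude component is positive.
Dense eigendecomposition is used; at the fixture scales exercised here
(≲ a few hundred atoms) this is exact and fast.  For large systems a
sparse smallest-eigenpair solver can be substituted without changing any
contract.

## Unbound→bound projection

Given unbound coordinates, their retained mode matrix M (rows = modes) and
bound coordinates in one-to-one atom correspondence, the bound set is first
rigidly superposed onto the unbound frame (Kabsch SVD with reflection
correction) and the residual displacement T projected: β = (M Mᵀ)⁻¹ M T,
which reduces to βᵢ = mᵢ·T for orthonormal modes.  Both routes are
implemented and agree to 1e−9; tests keep them separate as mutual oracles.

The superposition fit uses **all atoms by default**.  This is a deliberate
choice: when T lies in the span of the (all-atom) modes, the all-atom
Kabsch covariance matrix is symmetric positive definite, the optimal
rotation is exactly the identity, and the projection recovers generating
amplitudes to machine precision.  A Cα-only fit (available via
`fit_selection="CA"`) leaves a small residual rotation that leaks into β at
the 1e−2 level on the fixtures, so it is not the default.

## Secondary structure and conservation

A reduced Kabsch–Sander assigner produces three states per residue.  Amide
hydrogens are reconstructed from backbone geometry (H placed 1 Å from N
along the preceding C=O direction; chain-initial residues cannot donate).
Backbone hydrogen bonds are scored with the electrostatic model
E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) kcal/mol, bonded when
E < −0.5; sequence neighbours (|Δi| ≤ 1) are excluded and an O–N distance
sanity bound of 5.2 Å guards against clashing reconstructions.  Helix (H)
is assigned to residues covered by two consecutive i→i+4 turns; strand (E)
to residues in parallel/antiparallel bridge ladders of at least two
residues; everything else is coil (C), mirroring the usual collapse of the
8-state alphabet to 3 states.  A hook accepts externally computed state
strings for users who want parity with a reference assigner.

Two distinct conservation statistics are used because the protocols gate on
different things:

* the **per-state rule** (amplitude search): no state's percentage may move
  by more than 10 percentage points.  The 10 % criterion is interpreted as
  absolute percentage points — the stricter, scale-free reading — and is
  configurable.
* **per-residue identity** (energy-map selection): the percentage of
  residues keeping their state letter, required ≥ 90 %.  It is measured
  against the unbound structure as read, on the raw deformed conformation.

## Pair potentials and the octree

Total energy is the sum of a distance-dependent atom-pair term over unique
pairs within a cutoff, excluding pairs in the same residue or in
sequence-adjacent residues of the same chain (the conventional near-bonded
exclusion for statistical potentials; configurable).  Two potentials ship:

* a loader for plain-text distance-binned tables (header `#bins lo hi …`,
  half-open bins, rows `TYPE_A TYPE_B e₁ e₂ …`, symmetrized on load,
  element or residue_atom typing, unknown types skipped with a counter by
  default) — the format accommodates published statistical potentials with
  15 Å / 0.5 Å binning;
* a fully specified built-in surrogate: a truncated-and-shifted 12-6 form
  E(d) = ε[(s/d)¹² − 2(s/d)⁶] − E_cut with s the sum of per-element van der
  Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å), ε = 1,
  continuous at the cutoff (default 10 Å).  It keeps the entire pipeline
  self-contained and has a closed-form minimum used in tests.

The octree partitions the padded bounding box 8-ways until leaves hold ≤ 32
atoms (capacity) or depth 12.  Pair enumeration recursively visits node
pairs, discarding any whose box–box minimum distance exceeds the cutoff,
and evaluates surviving leaf–leaf blocks vectorized; the enumerated pair
set is identical to brute force, so agreement is to floating-point
accumulation (≤ 1e−9 relative, verified across sizes 10–2000 and cutoffs
4/8/15 Å).  Leaf-pair tasks are independent and order-free, so any
scheduler may parallelize them; no concurrency mechanism is mandated or
used.  An instrumentation counter reports evaluated candidate pairs; on
uniform random clouds at fixed density it grows markedly subquadratically
(empirical exponent < 1.5 between 100 and 3000 atoms).

Normalization of sampled energies is min–max to [0, 10]: the lowest raw
value maps to 0.0 and the highest to 10.0; a constant sample set maps to
all zeros by convention.  The map is affine-invariant.

## Protocols

**Amplitude search.**  Search starts at magnitude 100 (the documented
starting extent in both directions).  A trial deforms the structure, runs
the configured minimizer, and applies the per-state rule.  Passing doubles
the magnitude (capped at 1600 = 100·2⁴ to bound the doubling phase);
failing sets the failure bound; once both bounds exist the bracket is
bisected.  The loose textual termination condition ("ranges match") is
realized as bracket width ≤ a convergence tolerance (default 1.0 amplitude
unit); the largest passing magnitude, signed by direction, is returned.
Zero deformation always passes, so an always-failing criterion converges
below 1.  The search is validated against synthetic threshold pass-rules
(pass iff a ≤ A*) for A* spanning 10–1000.

**Minimizer contract.**  Protocols accept any deterministic
structure→structure relaxation.  Two are bundled: the identity (default —
fast and sufficient for the geometric fixtures) and a bounded steepest
descent (200 steps of 0.01 Å along the normalized gradient of the surrogate
potential plus harmonic restraints holding backbone bond lengths), a
reproducible stand-in for a force-field minimization, not a physical one.

**P1** deforms each partner to its maximum extent along the lowest
nontrivial mode in both directions, yielding {Ru, R+, R−, Lu, L+, L−} and
the canonical 9-run pairing list.  Whether the unbound conformers are
minimized is a flag (default: raw as read).

**P2** applies the closed-form projection of the three lowest modes and
deforms the unbound inputs by β; no secondary-structure gating is applied
since the goal is the parsimonious unbound→bound route.  It requires the
bound complex and exists for benchmarking.

**P3** samples the 3-mode envelope on a regular grid (default 21 points per
axis; the origin is injected as an extra sample when the envelope is
asymmetric enough to push it off-grid), scores each point with the octree
route without per-point minimization (minimization belongs to the envelope
search, not the grid scan), normalizes, and selects the sample of maximum
Euclidean norm among those with normalized energy ≤ 5.0 and per-residue
conservation ≥ 90 %.  Ties break toward lower normalized energy, then
lexicographic amplitude order, making selection fully deterministic; if
nothing qualifies, the origin is returned with a fallback flag.  The
conformer labels R5/L5 reflect the ≤ 5.0 energy gate.  Energy maps export
to a PDB-like file (amplitudes as coordinates, scaled by a recorded
power-of-ten when they exceed the fixed columns; normalized energy as
B-factor) for 3-D visualization.

## CAPRI assessment

Contacts are residue pairs with any heavy-atom pair within 5 Å; interface
residues have any atom within 10 Å of the partner in the reference;
backbone means {N, CA, C, O}.  FNAT is the recovered fraction of reference
contacts; FNONNAT the fraction of model contacts that are non-native; LRMSD
the ligand backbone RMSD after superposing receptor backbones; IRMSD the
optimally-fitted backbone RMSD over reference interface residues.  Quality
uses the community thresholds with non-strict inequalities (High: fnat ≥ 0.5
and lrmsd ≤ 1.0 or irmsd ≤ 1.0; Medium: fnat ≥ 0.3 and lrmsd ≤ 5.0 or
irmsd ≤ 2.0; Acceptable: fnat ≥ 0.1 and lrmsd ≤ 10.0 or irmsd ≤ 4.0).
Residues are matched strictly by (chain, residue number, insertion code) —
inputs must be complete; no alignment fallback is attempted.  Target
difficulty from unbound–bound interface Cα RMSD: RB ≤ 1.35 Å < M ≤ 2.5 Å < D;
a helper computes that statistic from unbound/bound/partner structures.

## Synthetic fixtures

Backbones carry N, CA, C, O per residue with ideal internal coordinates
(N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; standard angles; ω = 180°)
chained from φ/ψ: helix (−57°, −47°), strand (−139°, 135°), coil
(−80°, 150°).  The hinge fixture is helix–4-residue-coil–helix; the hairpin
pairs a strand with its 180°-rotated antiparallel copy at a calibrated
offset so facing amides and carbonyls fall in hydrogen-bond range, bridged
by a 2-residue straight-line turn; the complex fixture packs two helices
(chains A/B) at contact distance.  Optional coordinate noise is seeded
i.i.d. Gaussian; every generator is deterministic for a fixed spec.

These fixtures are geometric idealizations: no side chains, no realistic
Ramachandran variation, no packing-quality interiors, and the hairpin turn
is not a stereochemically valid β-turn.  Passing tests therefore establish
the correctness of the algorithms (mode computation, projection algebra,
pair-sum equivalence, selection logic, metric geometry) — not predictive
performance on experimental structures, which additionally depends on the
pair potential used and on a real minimizer.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run on the fixtures above
(~50–100 atoms), random uniform atom clouds of 10–2000 atoms for the
octree/brute-force comparisons, 3×3×3 to 5×5×5 sampling grids, and 100
randomly generated energy maps for the selection oracle; these sizes keep
every check exact (oracle-equivalence rather than statistical) while
completing in seconds on a single core.  The default 21-point-per-axis
production grid is configurable, as are all thresholds, via `RunConfig`
(YAML + flag overrides), and every run log echoes the full configuration.

## Known limitations

* All-heavy-atom dense ENM only; no rotation–translation-block projection.
* The surrogate potential is a geometric stand-in with documented constants,
  not a fitted statistical potential; results on real proteins should use a
  supplied table.
* The reduced assigner does not reproduce full 8-state assignments
  (G/I/T/S/B are absorbed into C by construction) and π-helices are not
  detected.
* Missing residues/atoms are not modeled; incomplete inputs raise
  validation errors by design.
* Docking itself (pose generation and ranking) is explicitly out of scope;
  the manifests and conformers are the hand-off interface to any engine.
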