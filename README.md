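# modecross

Conformer generation, energy-mapped selection and pose assessment for
**protein–protein cross-docking**.

Docking servers that allow only moderate flexibility often fail when a
receptor or ligand changes backbone conformation on binding.  One remedy is
*cross-docking*: dock several alternative conformations of each partner and
keep the best pose.  `modecross` builds the machinery around that idea:

* **Elastic-network normal modes** (`modecross.enm`) — an anisotropic
  elastic network over all heavy atoms (springs within a cutoff, default
  8 Å) whose Hessian eigenvectors give collective motions; the six
  zero-frequency rigid-body modes are removed and the lowest nontrivial
  modes m₁…m_k retained as an orthonormal basis for deformation,
  x′ = x + Σᵢ βᵢ mᵢ.
* **Closed-form unbound→bound projection** — given a bound conformation,
  the amplitudes that best reproduce the observed change are the least
  squares solution β = (M Mᵀ)⁻¹ M T (βᵢ = mᵢ·T for orthonormal modes),
  where T is the displacement after rigid superposition.
* **Maximum-amplitude search** (`modecross.protocols`) — walks each mode in
  both directions starting at ±100: double on success, halve on failure,
  then bisect, where success means the (optionally minimized) conformation
  keeps every secondary-structure state (H/E/C, reduced Kabsch–Sander
  assigner in `modecross.secstruct`) within 10 percentage points of the
  starting assignment.
* **Energy-mapped sampling** — the 3-mode amplitude envelope is sampled on a
  regular grid; each point is scored with a distance-dependent pair
  potential (user-supplied distance-binned tables or a built-in 12-6
  surrogate), accelerated by an **octree** that prunes atom-pair blocks
  beyond the cutoff; scores are min–max normalized to [0, 10] and the point
  farthest from the origin with normalized energy ≤ 5 and ≥ 90 % per-residue
  secondary-structure conservation is selected.
* **Cross-docking manifests** — the protocols emit the standard pairing
  lists: P0 `(Ru):(Lu)`; P1 the nine combinations of unbound and ±extreme
  lowest-mode conformers; P2 the theoretical-best pair; P3
  `(R5):(L5), (Ru):(L5), (R5):(Lu), (Ru):(Lu)`.
* **CAPRI assessment** (`modecross.capri`) — FNAT, FNONNAT, LRMSD, IRMSD and
  the High/Medium/Acceptable/Incorrect quality classes, plus the RB/M/D
  target-difficulty classification from unbound–bound interface Cα RMSD.

The docking engine itself is out of scope: `modecross` produces and
evaluates docking *inputs and outputs*.  A synthetic fixture generator
(`modecross.fixtures`) builds ideal helices, hairpins, hinged two-segment
structures and two-chain complexes so the whole pipeline runs and is tested
without any downloads.

## Worked example

```sh
modecross fixtures --kind two_segment_hinge --n-res 10 --out rec.pdb
modecross fixtures --kind helix --n-res 14 --out lig.pdb
modecross run --protocol P3 --receptor rec.pdb --ligand lig.pdb \
    --steps 5,5,5 --out-dir p3_run
```

which prints `P3 outputs in p3_run`, and `p3_run/run_log.json` records the
selected amplitudes:

```
"R5_amplitudes": [63.28125, -82.03125, 0.390625],
"L5_amplitudes": [-35.15625, -15.234375, 0.78125]
```

i.e. the receptor conformer handed to docking sits 103 amplitude units from
the unbound origin along its two softest modes, the largest deformation
whose normalized surrogate energy stayed ≤ 5 with ≥ 90 % of residues keeping
their secondary-structure state.  The directory also contains `R5.pdb`,
`L5.pdb`, `Ru.pdb`, `Lu.pdb`, the 4-pair `manifest.tsv`, and
`energy_map_R.pdb` / `energy_map_L.pdb` — pseudo-atom files with mode
amplitudes as coordinates and normalized energy as B-factor (0.00–10.00),
viewable in any molecular graphics program.

Assessing a pose against a reference complex:

```sh
modecross assess model.pdb reference.pdb --receptor-chains A --ligand-chains B
# irmsd   lrmsd   fnat    fnonnat quality
# 0.000   0.000   1.000   0.000   High
```

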