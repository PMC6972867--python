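# Methods

This note documents the models behind flapkit, the parameters that
matter, the synthetic-data generator, and the design choices made where
the procedure was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Structure model and preparation

Structures are hierarchical heavy-atom models (chains → residues →
atoms) in Å. Hydrogens are dropped at parse time and waters stripped;
every downstream quantity (SASA, RMSF, RMSD, energies) is defined over
heavy atoms only. ALTLOC groups resolve to the highest-occupancy
conformer. Author residue numbering is preserved end-to-end and all
six-residue windows are 1-based and inclusive. Van der Waals radii come
from a fixed element table (C 1.70, N 1.55, O 1.52, S 1.80 Å).

**Secondary structure** uses Kabsch–Sander hydrogen-bond energies
(E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond if
E < −0.5) with the amide hydrogen reconstructed 1 Å from N along the
preceding carbonyl direction, then the classic n-turn and bridge
patterns. The bridge patterns are evaluated acceptor-first, matching
reference DSSP implementations; all helix classes collapse to H,
strands/bridges to E, everything else to C — three states are all the
pipeline consumes. The test suite checks ≥ 95 % per-residue agreement
with mdtraj's DSSP on the fixture set (in practice the agreement on
these idealised structures is exact).

**Disulfides** are Cys SG–SG pairs within 2.5 Å, greedily matched
nearest-first so each cysteine appears in at most one bond.

**SASA** is Shrake–Rupley with a 1.4 Å probe and 960 test points per
atom. The point lattice is a deterministic Fibonacci sphere expressed
in the molecule's principal-axis frame with third-moment sign fixing,
so per-residue areas are exactly invariant under rigid motion and runs
are bit-reproducible. A `buried_delta` mode (isolated-residue minus
in-context area) is available; the default `exposed` mode is used by
the SA filter because the filter keeps *solvent-accessible* residues.

## Fluctuation backends

Two interchangeable backends produce per-heavy-atom RMSF:

* **ensemble** — frames of a multi-model PDB are Kabsch-superposed onto
  the reference (fit selection configurable; the pipeline excludes the
  grafted window so window motion is measured relative to the
  scaffold), and RMSF is taken over the final half of the frames,
  mirroring equilibrated-tail trajectory analysis.
* **enm** — a Gaussian network model on residue (Cα) nodes. Residue
  mean-square fluctuation is proportional to the diagonal of the
  Kirchhoff pseudoinverse. Two spring models are provided:
  `uniform` (unit springs between Cα pairs within 7.5 Å — the classic
  GNM) and `contact` (spring constant = number of heavy-atom pairs of
  the two residues within 4.5 Å). The pipeline default is `contact`:
  a Cα-only network cannot see a grafted sequence (mutations never move
  Cα), which would make homo-hexapeptide profiling vacuous, whereas
  contact weighting lets side-chain packing, disulfide clamps and
  grafted bulk stiffen or soften the network.

**Calibration.** GNM fluctuations are in mode units; the selection
thresholds (1.5 / 1.0 Å) live on an MD-derived Å scale. The bridge is a
single explicit constant (Å per mode unit), computed once so that the
median residue RMSF of a *constrained reference structure* equals a
configurable target (default 0.8 Å) and then applied to every structure
in the run — one universal spring constant, mirroring how the selection
thresholds themselves are defined against hexapeptides immobilised in
antibody frameworks. The constant is recorded in every report. Per-structure
re-calibration is deliberately avoided: it would erase exactly the
between-structure contrast (linear peptide vs embedded loop, open vs
clamped) that the thresholds are meant to detect.

## Site funnel

Enumeration finds six-residue windows in coil regions flanked by
anchors (helix, strand, or disulfide-bonded cysteine). A
disulfide-bonded cysteine terminates a loop even when its own state is
coil — it is a covalent anchor, which is what makes the CLC/CLS/SLC
motif classes possible. When a flank is both strand/helix and
disulfide-bonded, the secondary-structure letter wins the motif name.
Two modes: `strict` (one site per exactly-six loop with immediately
adjacent anchors) and the default `windowed` (every 6-mer window with
an anchor within `flank_reach` = 2 intervening coil residues of each
end; an eight-residue loop between strands yields three sites).

Filters: SA keeps sites whose six residues all have SASA strictly
greater than 15 Å²; the constrained/CSA split uses mean heavy-atom
window RMSF below 1.5 / 1.0 Å. CSA sites are named
`[scaffold]-[ordinal]` from the N-terminus after filtering, and the
funnel counts (enumerated → SA → constrained → CSA → GA) are emitted
with every scan.

## Mutagenesis and RMSF profiling

`mutate_window` keeps the backbone fixed (φ/ψ are never remodelled) and
rebuilds side chains from Chemical Component Dictionary ideal-geometry
templates, oriented by (N, CA, C) superposition and relaxed by a
discrete chi1 × chi2 rotamer search (−60/180/60°, most common rotamer
first) minimising the heavy-atom clash count (clash: distance below
0.75 × summed vdW radii). No continuous minimisation — placement is
deterministic and testable. A residue whose type already matches the
target keeps its existing coordinates, which makes identity mutations
exact no-ops (and identity alanine-scan losses exactly zero). Proline
and glycine graft anywhere; proline's ring is placed rigidly.

GA profiling grafts all 20 homo-hexapeptides (A6 … Y6) into a CSA site,
re-evaluates the backend with the *run-wide* calibration, and calls the
site GA only if every one of the 20 mean-RMSF entries stays below the
constrained threshold. Profiling a site that failed CSA only warns:
GA status presupposes CSA in the selection funnel.

## Paratope extraction and the energy score

Antigen-contact residues are ligand residues with any heavy atom within
4.5 Å of the antigen. CDR boundaries are *input annotation* — numbering
schemes (Kabat/Chothia/IMGT) disagree, so the package does not impose
one. Candidate windows are all 6-mers overlapping a CDR range,
optionally restricted to windows containing a contact residue, named
`[prefix][ordinal]` N→C.

The binding score is E(complex) − E(receptor) − E(ligand) with a
simplified pairwise function: Lennard-Jones on element-level parameters
(σ/ε, Lorentz–Berthelot combination) plus Coulomb with
distance-dependent dielectric ε(r) = 4r and a coarse charge model
(±1 distributed over ionizable side-chain termini, ±0.4 backbone amide
dipole; version 1, tabulated in `flap.energy`). Pairs within one
residue or between sequence neighbours are excluded; the summation
cutoff is 12 Å. In the default single-point mode intra-molecular terms
cancel and the score reduces to the cross-interface sum, which makes
the two invariants exact: identity mutations and windows entirely
beyond the cutoff have zero loss. An optional iteration-capped
steepest-descent relaxation (200 steps, fixed step) is provided;
absolute scores are in score units and are **not** comparable to
force-field kcal/mol, so the default selection is rank mode (top-k
losses, k = 3, ties broken N-terminal-first) with an absolute-loss
threshold mode configurable.

## Synthetic-data generator

Fixtures are built from ideal backbone internal coordinates (NeRF
placement; helix −57/−47°, strand −120/+120°) with CCD template side
chains:

* **hairpin** — two 7-residue antiparallel strands and a 6-residue
  loop whose dihedrals are optimised (deterministic least squares) for
  the canonical narrow/wide H-bond register, with the loop pushed away
  from the strand tips: a *mobile* loop by construction.
* **clamped_hairpin** — same, with the loop pulled compact and the two
  loop-flanking cysteines closed into a disulfide (chi search +
  continuous refinement to SG–SG ≈ 2.04 Å): an *immobilised* loop.
* **toy_complex** — an extended 24-residue ligand with lysines at the
  designed contact positions (default a six-residue block) and serines
  elsewhere, laterally paired — like a neighbouring sheet strand, the
  geometry that lets every consecutive residue touch a partner — with a
  short acidic receptor strand whose register and approach are chosen
  by a deterministic dock so the realised heavy-atom contact set equals
  the designed one exactly.
* **ensembles** — per-residue isotropic Gaussian jitter (per-axis σ, so
  RMSF = √3·σ) with optional rigid-body noise to exercise
  superposition. Seeds are recorded in every output; identical specs
  give byte-identical PDB files.

What the generator does *not* emulate: real side-chain rotamer
statistics, correlated (physical) dynamics, solvent, crystallographic
disorder, or antibody domain architecture. Passing tests therefore
demonstrate that the pipeline's logic recovers designed ground truth
under its own model assumptions — not that the thresholds transfer
quantitatively to experimental scaffolds, which requires MD-grade
fluctuation input through the ensemble adapter.

## Numerical choices

* GNM pseudoinverse via `scipy.linalg.pinvh`; the test suite checks
  agreement with a dense eigendecomposition oracle to 1e-8 on graphs up
  to 50 nodes. Disconnected contact graphs raise an error naming the
  components.
* Kabsch superposition with SVD sign correction; RMSD symmetric to
  1e-9. An independent quaternion (Horn) oracle backs the tests.
* The hairpin loop optimiser and the complex dock are deterministic
  (fixed starts, fixed grids, bisection), so fixture geometry is a pure
  function of the spec.
* Rotamer and selection ties break first-in-order / N-terminal-first,
  making reports byte-reproducible; the report hash covers the
  scientific configuration (the output directory is excluded).
* Default problem sizes — 20-residue hairpins, a 24+5-residue complex,
  500-frame ensembles, 960 SASA points — were chosen so the entire
  fixture workflow, including 20-variant profiling, completes in tens
  of seconds on one CPU while leaving comfortable numerical margins on
  every designed contrast.

## Known limitations

* The ENM is harmonic around one conformation: it ranks rigidity, it
  does not simulate unfolding or conformational exchange, and absolute
  Å values inherit the calibration convention.
* The energy score has no solvation by default (a burial term is
  optional), no entropy, and coarse charges; only loss *rankings* are
  meaningful.
* Side-chain building uses three rotamers per chi and no backbone
  relaxation; severely buried grafts may retain clashes that MD would
  relieve (the clash count is reported, not hidden).
* The ensemble backend cannot profile in-silico mutants (it has no way
  to generate their dynamics); GA profiling therefore requires the ENM
  backend or externally supplied mutant ensembles.
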