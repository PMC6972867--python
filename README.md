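# flapkit

Desk-scale design pipeline for **FLAPs** — fluctuation-regulated
affinity proteins: small non-immunoglobulin scaffolds that carry a
structurally immobilised antigen-binding hexapeptide taken from an
antibody CDR (complementarity-determining region).

The package is for protein engineers who want to prototype and test the
*computational* half of CDR-graft design: pick scaffold positions that
will hold any grafted six-residue peptide rigid, extract the
hexapeptides that actually drive antigen binding from an
antibody–antigen complex, and combine the two into ranked graft
candidates — all on a laptop, with no molecular-dynamics cluster.

## The method

A graft-acceptor (GA) site is found by a funnel of filters over every
candidate hexapeptide window in a scaffold:

1. **loop geometry** — the window lies in a loop flanked by α-helices,
   β-strands or disulfide-bonded cysteines (motif classes SLS, HLH,
   SLC, …);
2. **solvent accessibility (SA)** — every residue's solvent-accessible
   surface area exceeds 15 Å² (Shrake–Rupley, 1.4 Å probe);
3. **constraint (CSA)** — the window's mean heavy-atom RMSF is below
   1.0 Å (with 1.5 Å as the looser "constrained" level);
4. **RMSF profiling** — the window is replaced in silico by each of the
   20 homo-hexapeptides (A6 … Y6, spanning the 6.4×10⁷ theoretical
   hexapeptide species from the smallest G6 to the bulkiest W6); the
   site is a GA site only if **every** grafted profile stays below
   1.5 Å.

Fluctuations come from a contact-weighted Gaussian network model
(residue springs weighted by heavy-atom contact counts), with the
Å-scale fixed by a single calibration constant computed once on a
constrained reference structure — or from a conformational ensemble
(multi-model PDB) when one is available.

Antigen-binding hexapeptides are found by **alanine-hexapeptide
scanning**: every 6-mer CDR window of the antibody variable domain that
touches the antigen is mutated to AAAAAA and the binding-score loss
ΔG(A6) − ΔG(wt) is recorded (simplified score: Lennard-Jones + Coulomb
with distance-dependent dielectric ε(r) = 4r). The top-scoring windows
become the grafting payloads, and each GA site × peptide combination
yields a candidate named `[site]-[peptide]` (e.g. `Sca8-1-TH3`), with
its grafted-window RMSF and heavy-atom RMSD to the source CDR
conformation.

## Worked example

The package ships a generator for synthetic fixtures with known ground
truth: a disulfide-clamped β-hairpin (immobilised loop), an open
β-hairpin (mobile loop) and a toy antibody–antigen complex with a
designed six-residue contact block.

```bash
flap fixtures --out work --seed 1
flap scan-scaffolds --config work/config.yaml
flap profile-ga     --config work/config.yaml
flap extract-cdr    --config work/config.yaml
flap design         --config work/config.yaml
```

With seed 1 this prints (stderr) and writes (`work/run/*.tsv`):

```
funnel: 2 enumerated -> 2 SA -> 2 constrained -> 1 CSA
1 GA site(s) of 1 CSA
selected CDR hexapeptides: TH5, TH6, TH7
built 3 design(s) -> work/run
```

Reading the numbers: both hairpins contribute one SLS loop site; both
are solvent-accessible and constrained (< 1.5 Å), but only the clamped
loop is CSA (mean RMSF 0.89 Å < 1.0 Å; the open loop sits at 1.18 Å).
Profiling the clamped site with all 20 homo-hexapeptides tops out at
0.95 Å, so it is called GA. In the toy complex the scan's losses rise
window by window as more of the designed contact block is mutated
away — the all-contact window `TH6` (KKKKKK) peaks at a loss of 21.5
score units — and the top three are selected. The three resulting
designs (e.g. `clamped_hairpin-1-TH6`) keep grafted-window RMSF at
0.82–0.83 Å, well inside the 1.5 Å constraint, with heavy-atom RMSDs
of 6.1–6.7 Å to the extended source conformation.

Every TSV report embeds the package version, a hash of the resolved
configuration and the backend calibration constant; identical config
and seed reproduce byte-identical reports.

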