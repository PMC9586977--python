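# foldkit

Detection and structural validation of **tandem zf-C3HC/Rsm1 domains** —
the "Pml39 fold" — with the supporting binding and oligomer biophysics.

## The problem

The BIR-like clan of Zn-binding domains comprises three Pfam families:
canonical BIR domains (PF00653), zf-C3HC (PF07967) and Rsm1 (PF08600).
All three share a CCHC zinc finger and a small set of anchor motifs,

```
Rxx(S/T)Ω ... GΩ ... C-x2-C-xn-H-x6-C-x-Ω     (canonical BIR)
Rxx(S/T)Ω ... GΩ ... C-x2-C-xn-H-x3-C-x-Ω     (zf-C3HC, Rsm1)
```

where x is any residue, Ω an aromatic, and the spacer `x_k` counts the
residues strictly between consecutive Zn ligands. The shortened His→Cys
spacer (3 vs 6) is the hallmark separating zf-C3HC/Rsm1 from canonical
BIR; the two BIR-like families are in turn separated by a long insertion
(an extra helix plus a Ser-rich segment) that only the Rsm1 module
carries between its Rxx(S/T)Ω anchor helix and its GΩ turn. A zf-C3HC
module immediately followed by an Rsm1 module packs into one integrated
domain — the Pml39 fold — the architecture shared by *S. cerevisiae*
Pml39, *S. pombe* Rsm1 and human NIPA/ZC3HC1, nuclear-basket proteins of
the nuclear pore complex. Because overall sequence identity among these
orthologs is very low, the fold is found not by alignment score but by a
**checklist of 18 conserved positions** (9 per module: the Arg anchor,
Ser/Thr at +3, the GΩ dipeptide, the four Zn ligands with
family-correct spacing, the His→Cys spacer, and the post-finger
aromatic).

foldkit implements that analysis as a tested pipeline:

* `foldkit.seq_motif` — the motif grammar: CCHC scanning with
  family-specific spacer constraints, anchor location, zf-C3HC/Rsm1
  disambiguation by insertion length, tandem-fold calling, and the
  18-point ortholog checklist.
* `foldkit.struct_geom` — coordinate-level validation: Kabsch
  superposition and RMSD, helix axes and inter-helix tilt angles
  (canonical-vs-BIR-like helix tilts of ~42° and ~26° are the fold's
  structural signature), Zn-coordination spheres, and the hydrophobic
  inter-module interface.
* `foldkit.biophys` — single-site ITC fitting (exact 1:1 mass-action
  isotherm with injection-displacement bookkeeping; ΔG = −RT ln(1/K_D),
  TΔS = ΔH − ΔG with R = 1.99 cal/(mol·K)) and SEC-MALS molecular
  weights from Debye plots (KC/Rθ vs sin²(θ/2); MW = 1/intercept;
  concentration-weighted peak averages) with oligomeric-state calling.
* `foldkit.synthetic_data` — seeded generators for every input class
  (planted motifs, ideal helices, tetrahedral Zn sites, noisy isotherms,
  MALS traces), each with a ground-truth sidecar.
* `foldkit.pipeline` / the `foldkit` CLI — end-to-end orchestration with
  a YAML config and deterministic JSON reports.

## Worked example

Generate a synthetic protein carrying a planted tandem fold, call it,
then fit a noisy synthetic titration and a two-species SEC-MALS trace:

```
$ foldkit simulate sequence --seed 11 --out demo
wrote demo.fasta (226 aa)

$ foldkit fold-call --fasta demo.fasta --out demo
synthetic_tandem_11: Pml39 fold checklist 18/18

$ foldkit simulate itc --seed 5 --noise 0.02 --out titration
$ foldkit itc fit --data titration.heats.csv --protocol titration.protocol.yaml
n = 1.021, K_D = 12.18 µM, ΔH = -9.70 kcal/mol, ΔG = -6.24 kcal/mol, TΔS = -3.46 kcal/mol

$ foldkit simulate mals --seed 4 --out sec
$ foldkit mals mw --data sec.trace.csv --peaks peaks.yaml --monomer-mw 41000
dimer: 80.0 kDa (2-mer)
monomer: 41.0 kDa (1-mer)
```

The fold call confirms a zf-C3HC module followed by an Rsm1 module with
all 18 conserved positions satisfied. The titration was generated with
K_D = 13 µM, n = 1 and ΔH = −10 kcal/mol plus 2% heat noise; the fit
recovers them within the noise, and ΔG/TΔS follow from the enforced
identities at 277.15 K. The MALS trace planted an 80 kDa dimer and a
41 kDa monomer of the same 41 kDa chain; the Debye analysis recovers
both weights and the oligomeric states.

Structure-side commands work the same way (`foldkit geom superpose`,
`geom znsites`, `geom interface`), reading PDB/mmCIF via gemmi, and
`foldkit run --config run.yaml --out DIR` chains all stages into one
deterministic report.

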