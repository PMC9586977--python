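# Methods

This note documents the models, conventions and numerical choices
behind foldkit, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Motif grammar

**Indexing and spacers.** Residue indices are 1-based, matching
author/crystallographic numbering. A spacer between ligands at i < j is
`j − i − 1` (residues strictly between them). This reproduces the
reference zinc fingers: 34 residues between C137/H172, 3 between
H172/C176, 16 between C271/H288.

**Family spacing.** The H→C3 spacer is exact and family-defining: 6 for
canonical BIR, 3 for zf-C3HC/Rsm1. Defaults for the variable spacers
are C1→C2 ∈ [1, 3] and C2→H ∈ [10, 160]. Exactly-2 for C1→C2 would be
truer to the consensus but rejects the human NIPA zf-C3HC module, whose
Cys pair (C118/C120) implies a spacer of 1; the scanner admits it and
the checklist still requires family spacing, so non-canonical spacing
is visible in the per-criterion breakdown. The C2→H ceiling of 160
admits the ~135-residue insertion of NIPA's Rsm1 module (C275→H425,
spacer 149).

**Scanning.** `scan_znf` enumerates all C/C/H/C quadruples meeting the
spacer constraints, in ascending order, without overlap filtering —
callers own that policy (the fold caller keeps the best-checklist,
smallest-c1 module per overlap group). `X` and gap characters never
match a ligand or satisfy a criterion. The scanner is checked against
exhaustive quadruple enumeration on random sequences.

**Anchors.** The Rxx(S/T) anchor is the nearest upstream Arg with
Ser/Thr at +3 within a configurable window (default 80 residues before
C1; the reference modules place it 45 and 70 residues upstream — the
exact window used in the original structure-guided analysis is not
published, so it is exposed as a parameter). An Arg lacking the +3
partner is still reported so degraded anchors are visible. The GΩ
dipeptide is the last Gly+aromatic between the Arg and C1; the closing
aromatic is the first aromatic within 3 residues after C3. Ω = {F, W, Y}
by default (His excluded), configurable. Absent anchors are result
states, not errors.

**zf-C3HC vs Rsm1.** Both have the 3-residue His→Cys spacer; the only
discriminating sequence feature is the Rsm1 module's long insertion
between its anchor helix and its GΩ turn. The classifier therefore
thresholds the Arg→Gly distance at 40 residues (the reference modules
measure 29 and 54, comfortably either side). With no Arg anchor the
C2→H spacer is compared against the same threshold — a weaker proxy,
flagged by the missing-anchor state itself.

**Module spans.** A module span runs from the Arg anchor (or C1 − 45
when absent, the reference anchor-to-finger distance) to the closing
aromatic + 11 (or C3 + 20 when absent), clamped to the sequence. The
tail of 11 reproduces the reference zf-C3HC boundary (W178 → 189); spans
are descriptive bookkeeping, not part of any decision rule except the
tandem-order requirement.

**Fold call.** Positive iff a zf-C3HC module is followed N→C by an Rsm1
module whose zinc finger starts after the zf-C3HC span ends. All known
members share this order; a reversed arrangement is reported with both
modules but not called. The 18-point checklist (9 criteria × 2 modules)
is evaluated independently per criterion; several criteria share
residues (e.g. the +3 Ser/Thr rule references the Arg), so knocking out
a shared position fails every criterion that reads it.

## Structure geometry

**Superposition.** Kabsch via SVD, with the determinant correction
forcing a proper rotation; degenerate (collinear or < 3 point) sets are
rejected because the optimum is not unique. The RMSD is cross-checked
in the tests against an independent numerical minimization over
rotation vectors.

**Helix axes.** For a helical trace the second-difference (curvature)
vectors `P[i+1] − 2P[i] + P[i−1]` lie exactly in the plane perpendicular
to the axis, so the axis is taken as their smallest principal
component, oriented N→C. This is exact for ideal helices regardless of
how few turns the trace covers; the more obvious choice — the principal
axis of the Cα cloud — is biased by ~2° for a 12-residue helix covering
3⅓ turns, which matters when the quantity of interest is a tilt angle
reported to the degree. Near-straight traces (rank-deficient curvature)
fall back to coordinate PCA. Tilt angles default to the unsigned
line–line convention, arccos|a·b| ∈ [0°, 90°]; a signed variant
(arccos(a·b), [0°, 180°]) is available, as is measuring tilts on
first-to-last-residue vectors by passing those two points — the
published tilts do not state their convention, so both are exposed.

**Module superposition.** The Cα pairing is an explicit input (TSV of
author residue numbers): the pairing behind published RMSD values is
generally not released, so reproducing or varying it must be in the
user's hands. Pairs with missing Cα are dropped with a warning;
fewer than 3 survivors is an error.

**Zn sites.** Donors are Cys Sγ and His Nδ1/Nε2 within 2.8 Å of a Zn
(a typical upper bound for Zn–S/N bonds; configurable). Ligand counts
are reported as found, not forced to 4.

**Interfaces.** All residue pairs across two disjoint spans with
minimum heavy-atom distance ≤ 4.5 Å; hydrophobicity is the fixed set
{A, V, L, I, M, F, W, Y, P}, not a numeric scale. Contacts are checked
against a brute-force all-pairs scan on synthetic structures.

**Parsing.** PDB/mmCIF via gemmi; first model only, altloc A, waters
dropped, occupancy < 0.5 atoms retained but flagged, metals listed
separately from the polymer.

## ITC

**Forward model.** Exact 1:1 mass action. Each injection is modeled as
instantaneous mixing at constant cell volume V0: dV of syringe solution
enters and dV of the mixed solution overflows, so totals update as
`M ← M·V0/(V0+dV)`, `X ← (X·V0 + Xs·dV)/(V0+dV)`. This conserves
titrant moles exactly (cell + displaced = injected, asserted to 1e-12
in the tests). The bound complex follows the quadratic root of the
mass balance with binding-site concentration n·M; the measured heat of
injection i is

    q_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2,   Q_i = ΔH·V0·[MX]_i,

the standard displacement correction for complex carried out in the
overflow. The equilibrium solve is cross-checked against an independent
root-finding oracle in free-ligand space.

**Default protocol.** 2 µL injections of 1.6 mM titrant into 350 µL of
70 µM cell species at 277.15 K. The injection count is not part of the
published protocol; 20 injections (reaching molar ratio ~2.6, well past
saturation at n = 1) is used as a standard scheme for this instrument
class. The cell species is the binding-site species — for a dimer
binding one ligand per protomer pair, the dimer concentration.

**Fit.** Levenberg–Marquardt over (n, log10 K_D, ΔH), optionally plus a
constant heat-of-dilution offset (off by default for synthetic data).
Starts: n ∈ {0.5, 1, 2} × K_D log-spaced 1e-8–1e-3 M (six decades), ΔH
seeded from the first-injection heat; best χ² wins; K_D in log space
keeps it positive and well-conditioned. ΔG = −RT ln(1/K_D) and
TΔS = ΔH − ΔG are computed from the fit, never fitted, with
R = 1.99 cal/(mol·K). At 13 µM and 277.15 K, ΔG ≈ −6.2 kcal/mol.

## SEC-MALS

Per 1-s slice, a straight line is fit to KC/Rθ vs sin²(θ/2); MW is the
reciprocal intercept; slices with non-positive intercept or zero
concentration are flagged and excluded. Peak MW is the
concentration-weighted (weight-average) mean over a window. The second
virial coefficient is neglected (dilute limit) and instrument constants
(including dn/dc) are folded into K, so only the product KC/Rθ matters —
the analysis is invariant to consistent rescaling of K and Rθ.
Oligomeric state is the nearest integer ratio to a monomer weight,
within 15% relative tolerance by default (80 kDa over a 41 kDa monomer
→ dimer at 2.4% deviation).

## Synthetic data

All generators take a mandatory seed and return a `PlantedTruth`
sidecar; identical seeds reproduce identical artifacts. Sequence
backgrounds exclude the anchor-forming letters (C, H, F, W, Y, R, G, S,
T), so the planted motif is provably the only match and recovery can be
asserted exactly; a realistic-background flag restores the full
alphabet for stress testing. Helices are ideal (rise 1.5 Å, radius
2.3 Å, 100°/residue → 3.83 Å Cα–Cα). Zn sites are exact tetrahedra
plus optional jitter. ITC noise is multiplicative Gaussian per
injection heat (0.02 = "2% heat noise"); MALS Rayleigh ratios are ideal
point-scatterer values (no angular dependence, appropriate for proteins
far below the laser wavelength) with optional multiplicative noise.

What passing tests therefore show: the grammar, geometry and fitting
machinery recover known ground truth under controlled noise. What they
do not show: robustness to real-sequence composition (anchor-like
letters everywhere), real electron-density artifacts, baseline drift or
injection-volume error in real calorimetry, or band-broadening and
inter-detector delays in real chromatography.

## Simulation sizes

The binding-recovery study uses 100 replicates at 2% noise (medians of
K_D and n); the scanner/oracle equivalence check uses 500 random
sequences up to 200 residues; Zn-site jitter stability uses 100 seeds.
These sizes give stable medians and exhaustive small-case coverage
while keeping the full suite fast.

## Known limitations

* No HMM/profile scoring: the grammar is positional, by design — the
  family's low sequence identity is the reason the checklist exists.
* Helix spans are inputs, not computed (no secondary-structure
  assignment); the published spans are the defaults in examples.
* The ITC model is strictly 1:1 single-site; no cooperative,
  multi-site or displacement formats, and no raw-thermogram baseline
  integration.
* The Debye analysis stops at the linear plot; no Zimm/Berry
  formalisms, no angular-dependence modeling for large scatterers.
* Checklist criteria are boolean; conservative substitutions (e.g.
  Lys for Arg) score as failures.
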