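# Methods

This note documents the models, conventions and numerical choices behind
`pbscore`, and what the synthetic fixtures do and do not establish about
real data.

## Scope and design stance

The package analyses the phycobilisome-core trimers of *Gracilaria
chilensis* at four levels: subunit sequences, quaternary assembly,
subunit–subunit interfaces, and chromophore geometry.  Where the original
workflow used interactive or stochastic tools (homology modelling,
docking, molecular-dynamics relaxation), `pbscore` substitutes transparent
deterministic equivalents whose behaviour is fully testable:

* homology models → **backbone threading**: aligned positions keep the
  template backbone (N, CA, C, O, CB), identical residues keep full side
  chains, substituted residues are truncated to CB, and target residues
  opposite template gaps (e.g. the PB loop) are reported as unmodeled
  rather than built.  Downstream interface and geometry measures depend
  chiefly on backbone plus conserved residues, which threading preserves
  exactly.
* docking of the core linker → **template transfer**: the target trimer
  is superposed on a homologous linker-bearing complex (chains paired by
  id over shared CA positions) and the inverse transform carries the
  template linker into the target frame as chain G.
* MD relaxation → **clash reporting** with an optional greedy relief pass
  that iteratively discards the clashing side-chain atom farthest from its
  CB; backbone atoms are never moved.

Hexamer stacking, cylinder/core assembly, disorder prediction and
excited-state spectra are out of scope.

## Assembly model

The biological unit is a trimer of αβ heterodimers generated from the
one-heterodimer asymmetric unit by the three-fold of space group P321
(operators `x,y,z`; `-y,x-y,z`; `-x+y,-x,z`, applied in the fractional
frame of the crystal cell).  Copies are labeled in (operator, chain)
order, putting α-type subunits at chains A/C/E and β-type at B/D/F; the
core linker is chain G.  Variant compositions are fixed tables:
APC = α₃β₃; APC_1 adds L_C; APC_2 substitutes αII at slot A (with L_C);
APC_3 substitutes the PB domain at A and β18 at F — neighboring
heterodimers, so the terminal emitter and β18 can exchange energy within
one trimer.  Which specific slots receive the minor subunits is not
observable from a symmetric trimer; the A (and A/F) assignment is a
convention exposed in the composition table.

Superposition is least-squares rigid (Kabsch via rotation SVD), proper
rotations enforced, RMSD computed from the actual residuals; ≥ 3
non-collinear points are required.

## Interface model

* **SASA** — Shrake–Rupley sphere sampling with a deterministic
  golden-spiral point set (default 960 points; 240 in the comparative
  report for speed), water probe 1.4 Å, Chothia-style heavy-atom radii
  (C 1.87, N 1.65, O 1.40, S 1.85 Å) pinned in `config.py`.  Quadrature
  error on convex fixtures is < 1 % at 960 points.
* **Buried area** — half the SASA lost on association,
  `(A₁ + A₂ − A₁₂)/2`, the per-side convention used for reported
  interface areas; symmetric by construction.
* **Hydrogen bonds** — heavy-atom criterion (the underlying structures
  carry no hydrogens): donor–acceptor distance ≤ 3.5 Å and
  antecedent–donor–acceptor angle ≥ 90°, with donor/acceptor chemistry
  from per-residue tables; chromophore N/O atoms count as both donor and
  acceptor with the nearest bonded heavy atom as antecedent.
* **Salt bridges** — Lys NZ / Arg NH1,NH2,NE / His ND1,NE2 versus
  Asp OD1,OD2 / Glu OE1,OE2 / C-terminal OXT at ≤ 4.0 Å, one bridge per
  residue pair at the minimum-distance atom pair.
* All distance cutoffs are **inclusive**; boundary semantics are pinned
  by fixtures placed 0.01 Å on either side of each cutoff.
* Waters are excluded by default; chromophores are counted with their
  parent chain, since subunit–chromophore burial is part of the
  trimer-level interaction surface.  N4-methyl-asparagine (MEN) is
  treated as an ASN variant.

## Chromophore model

Phycocyanobilin is an open-chain tetrapyrrole: four five-membered
N-containing rings A–D joined by methine bridges, thioether-linked to a
cysteine via ring A.  Rings are located by atom name when the standard
nomenclature (N*x*, C1*x*..C4*x*) is present, otherwise by five-cycle
detection and connectivity ordering from the thioether-bearing terminal
ring.  Per bridge X→Y the two dihedrals are, by a fixed atom convention,

* double bond: C3X–C4X–CHm–C1Y (Z if |τ| ≤ 90°, else E),
* single bond: C4X–CHm–C1Y–NY (syn if |τ| ≤ 90°, else anti),

with the torsion sign following the IUPAC convention (cross-checked
against gemmi and mdtraj).  The six-character class string concatenates
the three Z/E letters and three s/a letters; its syn/anti summary
reproduces the field's ASA/SSA nomenclature for the α-subunit and
PB-domain conformers.  The ring A–D centroid distance corroborates the
classification (anti-rich conformers are more extended).  Binding sites
collect protein residues with any heavy atom within 4.0 Å of the ligand;
the covalent cysteine is any Cys SG within 2.0 Å of a ligand carbon
(S–C bond ≈ 1.8 Å).  Mirror images flip dihedral signs but not classes;
this chirality behaviour is intentional and tested.

## Sequence conventions

Percent identity = identical columns / columns where both rows are
non-gap (the most common convention; printed alongside full precision).
Alignments are global Needleman–Wunsch with BLOSUM62, gap open 10, gap
extend 0.5 — the comparison values tolerate ±2–3 points of
alignment-parameter sensitivity.  Translation uses the standard code,
stops at the first stop codon, drops trailing partial codons, and maps
codons containing non-ACGT letters to X with a warning.  Residue
numbering is 1-based everywhere.  The PROSITE-subset scanner supports
letters, `x`, `[..]`, `{..}` and `(n)` repeats, reports overlapping hits,
and defaults to the PKC (`[ST]-x-[RK]`) and CK2 (`[ST]-x(2)-[DE]`)
phosphosite motifs.  Nearest-neighbor Tm uses the Allawi & SantaLucia
1997 table at 50 mM Na⁺, 25 nM strands.

## Synthetic fixtures: what they show

Every pipeline stage is validated against generators with planted,
recomputable truth: exact C3 assemblies; one- and two-sphere SASA
fixtures with closed-form sphere/cap areas; dimers with planted
donor–acceptor and charged pairs satisfying the criteria with margin and
decoys violating them with margin; planar-pentagon tetrapyrrole mimics
(bond length 1.4 Å, standard atom names) whose bridge dihedrals are set
by internal-coordinate construction near canonical values (0°/180° for
Z/E, ±30°/±150° for syn/anti, ±5° jitter); and homolog pairs built by
conservative (BLOSUM62-similar) substitutions plus one insertion block,
which keeps the planted alignment optimal so the planted identity is
exactly recoverable.  A heterodimer-like asymmetric unit (30-residue
pseudo-helical chains, Cys at residue 81, attached bilins, hexagonal
P321 cell) exercises the full pipeline end to end.

These fixtures pin the *semantics* of every measurement — cutoff
behaviour, symmetry handling, classification windows, report shapes —
but they are not physically realistic: no force field, idealized
geometry, uniform B-factors.  Passing them demonstrates correctness of
the computations, not the accuracy of any particular biological value;
the published sequence- and structure-level anchors are checked
separately when the original inputs are supplied under `data/paper/`
(see README), since those files are not redistributable here.

## Problem sizes and determinism

Default problem sizes (161-residue sequence pairs, 30-residue structural
chains, 960/240 SASA points, 50–100 fixture seeds) were chosen so a full
validation run completes in about a minute on one CPU while leaving every
statistic far from its tolerance.  All randomness flows from explicit
integer seeds; reruns with the same config and seed are byte-identical,
and the report echoes every parameter it was computed under.
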