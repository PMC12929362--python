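# Methods

## Problem and scope

Single-stranded RNA aptamers fold into target-recognizing 3D shapes but are
chemically fragile; converting them to single-stranded DNA analogues is
attractive only if the parent conformation survives the conversion.
`aptadna` implements that conversion as a deterministic atomic-coordinate
edit on a 3D model, together with the two descriptors conventionally used to
judge conformational preservation over molecular-dynamics trajectories —
superposition RMSD against a reference and intramolecular hydrogen-bond
counts — plus emission of a complete GROMACS simulation protocol.  Running
MD itself, secondary-structure prediction, 3D folding, and force-field
topology generation are out of scope.

## Conversion model

A ribonucleotide differs from the corresponding deoxyribonucleotide by the
2'-hydroxyl; uracil differs from thymine by the 5-methyl group.  The
conversion therefore applies, in order:

1. **2'-dehydroxylation.**  O2' (and its hydroxyl hydrogen when present) is
   deleted from every residue.  Nothing else is touched, so all retained
   coordinates are bit-identical to the input.
2. **C5 methylation of uracil.**  Any H5 is deleted and a methyl carbon C7
   is constructed from the ring heavy atoms alone: C7 sits in the best-fit
   base plane, 1.50 Å from C5, along the in-plane direction opposite the
   C4–C5–C6 bisector (the exterior position H5 occupied).  Three hydrogens
   H71/H72/H73 are added at 1.09 Å with tetrahedral geometry, staggered
   with respect to the C5–C4 bond.  Because the construction never reads
   hydrogen positions, hydrogen-free models (as produced by automated RNA
   modelling pipelines) convert identically to protonated ones; when an H5
   is present it is deleted rather than extended, which makes the result
   independent of where that hydrogen happened to be.
3. **Renaming.**  A→DA, C→DC, G→DG, U→DT; a residue still carrying O2' is
   refused (consistency guard).

The guarantee this package is built around: every atom present in both
input and output has bit-identical coordinates, so the shared-atom
superposition RMSD between parent and product is zero (to SVD round-off).
The conversion is idempotent, and it commutes with the string-level U→T
sequence map.

Geometry parameters live in `MethylGeometry` (C5–C7 bond 1.50 Å, C–H
1.09 Å, H–C–H 109.5°, ring-coplanarity warning threshold 0.15 Å).  These
are standard thymine values; nothing in the workflow constrains them, so
they are parameters rather than constants.

A `ConversionReport` records every removed/added atom and renamed residue,
plus validity findings: per-residue heavy-atom inventories against the
idealized residue templates (the 5' terminus may lack its phosphate),
absence of O2', C5–C7 within (1.3, 1.7) Å, intra-residue bond lengths
within ±0.25 Å of template values, and consecutive O3'–P distances within
(1.4, 1.9) Å.  Validation reports rather than raises; the CLI `--strict`
flag turns failures into a nonzero exit.

Residue templates (heavy-atom inventories, donor/acceptor classification,
bond lists with ideal lengths) are built at run time from the idealized
nucleotide geometry in the chemical component dictionary bundled with
biotite, not from hand-maintained tables.

### The published LN-A11 string

Strict per-residue conversion of the 60-nt A11 RNA yields a 60-nt DNA
sequence, while the published LN-A11 string is 57 nt (the CCT triplet that
positions 34–36 would produce is absent).  Whether that is a deliberate
truncation or a transcription artefact cannot be determined from the
published material; this tool never deletes residues, performs the strict
conversion, and keeps the published 57-nt string available for comparison
(`aptadna.sequences.LN_A11_DNA_PUBLISHED`).

## Trajectory descriptors

**Superposition RMSD.**  The optimal rigid superposition is the Kabsch
(SVD) solution with the determinant correction, so reflections are never
returned; weighted variants use atomic masses.  `rmsd_series` superposes
every frame onto a fixed reference over a configurable atom selection
(default: all atoms, mass-weighted — the common default of MD analysis
tools) and reports nm.  Degenerate inputs (fewer than 3 atoms, collinear
point sets) are rejected.  The implementation is cross-checked in the test
suite against an independently implemented quaternion-eigenvalue (Horn)
oracle to 1e-6 on a thousand random instances.

**Hydrogen bonds.**  Geometric criteria follow the common GROMACS
convention: donor–acceptor distance ≤ 0.35 nm and hydrogen–donor–acceptor
angle ≤ 30°, both configurable.  Donors are N/O atoms with a covalently
attached hydrogen (hydrogens are assigned to their nearest heavy atom
within 1.25 Å; heavy-atom covalent bonds are inferred below 1.85 Å);
acceptors are all N/O.  Pairs separated by at most two covalent bonds are
excluded, and triples are deduplicated.  For hydrogen-free models a clearly
labelled heavy-only proxy counts donor-capable N/O (per the residue
templates) within 0.32 nm of an acceptor with no angle term; proxy counts
are not comparable to hydrogen-aware counts and are labelled as such in
output.

**Summaries and plateaus.**  `summarize` reports the arithmetic mean and
sample SD (n−1) over frames at or after a configurable equilibration
cutoff (default 0 ns: no frames discarded).  `detect_plateau` returns the
earliest sample time from which every sliding window (default 20 ns) has
least-squares slope magnitude ≤ 0.005 nm/ns and sample SD ≤ 0.1 nm.  The
defaults are chosen so that a trajectory that stabilizes around 75 ns of a
200 ns run — the qualitative reading plateau analysis is meant to support —
is representable; they are starting points, not fitted values.  Because the
onset is reported at window granularity, a detected onset is accurate to
within one window length of the true change point.  `compare_runs`
arranges summaries into the conventional molecule × temperature grid with
H-bond mean/SD and RMSD mean/SD columns.

## Synthetic fixtures

No experimental aptamer coordinates are bundled; every structural fixture
is generated.

**Helix builder.**  Idealized monomer geometry is placed along a helical
axis (A-form 32.7°/2.81 Å per residue for RNA, B-form 36.0°/3.38 Å for
DNA, both configurable).  The monomer pose relative to the axis is solved
once per geometry by a seeded multi-start local optimization of a 6-DOF
rigid placement, with terms holding the O3'(i)–P(i+1) distance at 1.60 Å,
keeping the flanking bond angles reasonable, and repelling steric overlap
between neighbouring residues; the solution is cached and fully
deterministic.  Each base type is then attached through its own glycosidic
frame (the C1'/C2'/O4' triangle), preserving the base's internal geometry
exactly while all residues share one backbone geometry — which is what
makes the backbone-connectivity validator pass by construction.  The
fixtures are single strands with no base pairing, no sequence-dependent
structure and no thermodynamic realism: passing tests on them demonstrates
the correctness of the editing and measurement machinery, not the realism
of any folded aptamer model.

**Noise trajectories.**  Frames are the reference coordinates plus i.i.d.
Gaussian noise (σ per coordinate, seeded), optionally composed with a
per-frame rigid drift.  For N atoms with uniform weights the expected
post-fit RMSD is σ√3·√(1−6/(3N)) — the √(1−6/3N) factor accounting for the
six rigid degrees of freedom absorbed by the fit — which gives the
statistical-recovery tests a closed-form target.

**Plateau series.**  A linear ramp (default 0.02 nm/ns) to a known onset,
constant afterwards, with optional seeded Gaussian noise.

**Watson–Crick G–C pair.**  A synthetic fixture: the cytosine base is
placed against a fixed guanine by deterministic optimization so the three
canonical contacts (N4–O6 2.91 Å, N1–N3 2.95 Å, N2–O2 2.86 Å) are
coplanar with in-line hydrogens, secondary contacts held apart.  Under the
default criteria it yields exactly three hydrogen bonds.

## Protocol emission

`emit_mdp` writes GROMACS-dialect parameter files for the four stages
(steepest-descent minimization, 100 ps NVT, 100 ps NPT, 200 ns NPT
production) with PME electrostatics, 1.2 nm twin cutoffs, V-rescale
thermostat at 300 or 310 K, Parrinello–Rahman barostat at 1 atm
(1.01325 bar), CHARMM27/TIP3P labels, and step counts computed exactly as
duration ÷ timestep (2 fs default: 50,000 steps per 100 ps equilibration,
100,000,000 for 200 ns).  Coupling constants (τ_t 0.1 ps, τ_p 2.0 ps) and
the timestep are conventional rather than mandated; emitted files flag
them as assumptions in header comments.  Emission is byte-stable for
identical specs.  `emit_run_plan` writes the ordered plan (solvate →
neutralize → minimize → NVT → NPT → production per temperature → RMSD and
H-bond analysis) naming those files.

## Naming dialects and I/O

PDB v3 naming (primed sugar atoms, OP1/OP2, DA/DC/DG/DT) is canonical
internally; the legacy v2 convention (asterisks, O1P/O2P, single-letter
DNA codes) is detected on read and available on write.  The covered name
set maps bijectively; uncovered names pass through with a warning.
Alternate locations other than blank/'A' are dropped with a warning
(single-stranded aptamer models carry no alternate conformers); insertion
codes are retained.  Trajectories are read from multi-model PDB (times
from `REMARK ... TIME_NS` records when present, else the frame index) or
concatenated GRO blocks (nm → Å, title `t=` ps → ns); binary formats go
through an optional MDAnalysis adapter so the core stays dependency-light.
Coordinates are Å internally; RMSD output is nm.

## Problem sizes

The test suite and the reproduction script work at desk scale: the 60-nt
A6 helix (~1,300 atoms), 100–200-frame synthetic trajectories, 1,000
random superposition instances, and 401-point plateau series.  The
200 ns / explicit-solvent simulations the protocol files describe are not
executed anywhere in this package.

## Known limitations

- Helix fixtures are idealized single strands; they carry no hairpins,
  stacking realism or sequence-dependent structure.
- The hydrogen-bond donor inference is distance-based; exotic protonation
  states or metal coordination are not modelled.
- Only the four canonical bases are supported; modified nucleotides are
  rejected rather than approximated.
- mmCIF and topology (bond) file formats are not read; proteins pass
  through the PDB reader but have no residue templates.
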