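# aptadna

In silico conversion of single-stranded RNA aptamer 3D models into
single-stranded DNA analogues, with the molecular-dynamics descriptors used
to judge whether the parent conformation survived.

## The problem

ssRNA aptamers — short oligonucleotides selected (e.g. by Cell-SELEX
against tumour cell lines) for target binding through their 3D fold — are
chemically unstable and ribonuclease-sensitive.  Converting an aptamer to
ssDNA improves stability, but only preserves function if it preserves the
fold.  Because no direct ssDNA 3D-modelling pipeline exists, the practical
route is to edit an RNA-derived 3D model atom by atom and then verify, by
molecular dynamics, that the edited molecule keeps the parent conformation.

`aptadna` is for structural bioinformaticians running that workflow.  It
implements:

- **Conversion** (`aptadna convert`): delete the 2'-OH from every ribose
  (ribose → deoxyribose), replace the uracil H5 with a methyl group built
  from ring geometry (uracil → thymine: C7 at 1.50 Å from C5 in the base
  plane, opposite the C4–C5–C6 bisector, plus tetrahedral H71/H72/H73),
  and rename residues to DNA codes (A→DA, …, U→DT).  Every retained atom
  keeps bit-identical coordinates, so the shared-atom superposition RMSD
  between parent and product is exactly zero — conformation preservation
  by construction, audited by a JSON conversion report and chemical
  validity checks.
- **Descriptors** (`aptadna analyze`): per-frame superposition RMSD
  (weighted Kabsch,
  `RMSD = √( Σᵢ wᵢ ‖R xᵢ + t − yᵢ‖² / Σᵢ wᵢ )` minimized over proper
  rigid transforms (R, t), reported in nm) and intramolecular hydrogen-bond
  counts (geometric criteria: donor–acceptor ≤ 0.35 nm, H–donor–acceptor
  ≤ 30°), with mean ± SD summaries and plateau-onset detection.
- **Fixtures** (`aptadna fixture`): idealized single-stranded A-/B-form
  helices, seeded Gaussian-noise trajectories, and ramp-then-plateau
  series with known ground truth.
- **Protocol** (`aptadna protocol`): GROMACS .mdp files and a run plan for
  the full simulation protocol (minimization, 100 ps NVT, 100 ps NPT,
  200 ns NPT production at 300 K and 310 K, PME, 1.2 nm cutoffs,
  V-rescale + Parrinello–Rahman, CHARMM27/TIP3P) — emission only; no MD
  engine is invoked.

See `docs/methods.md` for the model, parameters and limitations.

## Worked example

Convert the published 60-nt A6 aptamer RNA sequence:

```sh
$ aptadna convert sequence "CCGCAUCGUCCCAAGCCGAUUUUGGCGAGCAGCAGACAGGUUCCGGGGCGAGCAGCAGAC"
CCGCATCGTCCCAAGCCGATTTTGGCGAGCAGCAGACAGGTTCCGGGGCGAGCAGCAGAC
```

Build an idealized A-form model of the same sequence, convert it, and
measure a noisy synthetic trajectory of the product against it:

```sh
$ aptadna fixture helix "CCGCAUCGU...GAC" -o a6.pdb
wrote 1286 atoms to a6.pdb
$ aptadna convert structure a6.pdb -o ln_a6.pdb --report report.json
removed 60 atoms, added 32, renamed 60 residues; 0 validation failures
$ aptadna fixture traj --ref ln_a6.pdb --sigma 0.4 --frames 50 --seed 11 -o traj.pdb
wrote 50 frames (seed 11) to traj.pdb
$ aptadna analyze rmsd --traj traj.pdb --ref ln_a6.pdb -o rmsd.tsv
wrote 50 frames to rmsd.tsv
$ aptadna analyze summary --series rmsd.tsv
label	units	mean	sd	n
RMSD	nm	0.069182	0.000682	50
```

Reading the numbers: the conversion removed the 60 2'-hydroxyl oxygens
(one per residue), added 32 atoms (8 methyl carbons — one per uracil —
plus their 24 hydrogens), renamed all 60 residues to DNA codes, and passed
every chemical-validity check.  The trajectory summary shows the mean
post-superposition RMSD of the 50 noisy frames: 0.4 Å of Gaussian noise
per coordinate yields ≈ 0.069 nm after the rigid-body fit, matching the
analytic expectation σ√3·√(1−6/3N) for this atom count.

The same operations are available as a library:

```python
from aptadna import build_helix, convert_structure, sequence_of
from aptadna.sequences import A6_RNA

dna, report = convert_structure(build_helix(A6_RNA))
print(sequence_of(dna))        # the LN-A6 DNA sequence
print(report.all_valid)        # True
```

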