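"""ssRNA → ssDNA conversion preserving the parent conformation.

The conversion is a sequence of three atomic-coordinate edits applied to a
single-stranded RNA model:

1. **2'-dehydroxylation** — delete the 2'-OH group (O2' and its hydroxyl
   hydrogen) from every ribose, turning it into a deoxyribose.
2. **C5 methylation of uracil** — delete the exocyclic H5 (when present) and
   build a methyl group (C7 + H71/H72/H73) at the C5 position of every
   uracil, turning the base into thymine.  The methyl carbon is constructed
   from the ring heavy atoms alone, so hydrogen-free models convert cleanly.
3. **renaming** — map residue codes to the DNA convention
   (A→DA, C→DC, G→DG, U→DT).

No retained atom moves: coordinates present in both input and output are
bit-identical, so the superposition RMSD between parent and product over
shared atoms is exactly zero.  A :class:`ConversionReport` records every
removed, added and renamed entity plus chemical-validity checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .nucleic import (
    AlphabetError,
    ConsistencyError,
    GeometryError,
    Atom,
    Residue,
    Structure,
    normalize_dialect,
)

logger = logging.getLogger("aptadna")

# O2' hydroxyl-hydrogen naming variants seen across tool chains.
_O2P_HYDROGEN_NAMES = ("HO2'", "HO2*", "2HO'", "HO'2", "H2''")
_O2P_NAMES = ("O2'", "O2*")


# --------------------------------------------------------------------------
# Parameters and report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylGeometry:
    """Geometry used to build the thymine methyl group.

    Defaults are standard thymine values: C5–C7 bond 1.50 Å, C–H 1.09 Å,
    tetrahedral H–C–H angle.  ``coplanarity_tol`` bounds how far ring atoms
    may sit from their best-fit plane before a non-planarity warning.
    """

    c5_c7_bond: float = 1.50    # Å
    c_h_bond: float = 1.09      # Å
    hch_angle: float = 109.5    # degrees
    coplanarity_tol: float = 0.15  # Å

    def __post_init__(self):
        if self.c5_c7_bond <= 0 or self.c_h_bond <= 0:
            raise ValueError("bond lengths must be positive")
        if not 90.0 < self.hch_angle < 120.0:
            raise ValueError("hch_angle must lie in (90, 120) degrees")


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    residue: str | None = None
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "passed": self.passed,
            "residue": self.residue,
            "detail": self.detail,
        }


@dataclass
class ConversionReport:
    """Ledger of one RNA→DNA conversion: edits made and validation outcomes."""

    removed_atoms: list[tuple[str, str]] = field(default_factory=list)
    added_atoms: list[tuple[str, str]] = field(default_factory=list)
    renamed_residues: list[tuple[str, str, str]] = field(default_factory=list)
    validation: list[ValidationCheck] = field(default_factory=list)

    def merge(self, other: "ConversionReport") -> None:
        self.removed_atoms.extend(other.removed_atoms)
        self.added_atoms.extend(other.added_atoms)
        self.renamed_residues.extend(other.renamed_residues)
        self.validation.extend(other.validation)

    @property
    def all_valid(self) -> bool:
        return all(c.passed for c in self.validation)

    def to_dict(self) -> dict:
        return {
            "removed": [list(t) for t in self.removed_atoms],
            "added": [list(t) for t in self.added_atoms],
            "renamed": [list(t) for t in self.renamed_residues],
            "validation": [c.to_dict() for c in self.validation],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


# --------------------------------------------------------------------------
# Residue templates (from the chemical component dictionary)
# --------------------------------------------------------------------------


def _ccd_residue(code: str):
    import biotite.structure.info as info

    return info.residue(code)


@dataclass(frozen=True)
class ResidueTemplate:
    code: str
    heavy_atoms: frozenset[str]
    donors: frozenset[str]
    acceptors: frozenset[str]
    bonds: tuple[tuple[str, str, float], ...]  # (name_a, name_b, ideal Å)


class ResidueTemplateTable:
    """Canonical heavy-atom inventories, donor/acceptor sets and bond lists.

    Built from idealized nucleotide geometry for the eight standard residues.
    The 5'-terminal cap oxygen OP3 and all hydrogens are excluded from the
    heavy-atom inventories (structures may or may not carry hydrogens).
    """

    # Backbone oxygens that carry an H only in the free-nucleotide template,
    # not in a polymer: never classified as donors.
    _NON_DONOR_BACKBONE = {"OP1", "OP2", "OP3", "O3'", "O5'"}

    def __init__(self):
        self._templates: dict[str, ResidueTemplate] = {}
        for code in ("A", "C", "G", "U", "DA", "DC", "DG", "DT"):
            self._templates[code] = self._build(code)

    @staticmethod
    def _build(code: str) -> ResidueTemplate:
        import biotite.structure.info as info

        arr = _ccd_residue(code)
        names = list(arr.atom_name)
        elements = list(arr.element)
        coords = np.asarray(arr.coord)
        keep = [
            i for i, n in enumerate(names)
            if elements[i] != "H" and n != "OP3"
        ]
        heavy = frozenset(names[i] for i in keep)

        bonded_h: dict[str, bool] = {n: False for n in names}
        bond_list = []
        raw = info.bonds_in_residue(code)
        for (a, b), _order in raw.items():
            if elements[names.index(a)] == "H":
                bonded_h[b] = True
            elif elements[names.index(b)] == "H":
                bonded_h[a] = True
            elif a != "OP3" and b != "OP3":
                d = float(
                    np.linalg.norm(coords[names.index(a)] - coords[names.index(b)])
                )
                bond_list.append((a, b, d))

        donors = frozenset(
            n for n in heavy
            if elements[names.index(n)] in ("N", "O")
            and bonded_h.get(n)
            and n not in ResidueTemplateTable._NON_DONOR_BACKBONE
        )
        acceptors = frozenset(
            n for n in heavy if elements[names.index(n)] in ("N", "O")
        )
        return ResidueTemplate(code, heavy, donors, acceptors, tuple(bond_list))

    def __getitem__(self, code: str) -> ResidueTemplate:
        return self._templates[code]

    def __contains__(self, code: str) -> bool:
        return code in self._templates

    def codes(self):
        return tuple(self._templates)


@lru_cache(maxsize=1)
def default_templates() -> ResidueTemplateTable:
    return ResidueTemplateTable()


# --------------------------------------------------------------------------
# Sequence conversion
# --------------------------------------------------------------------------


def convert_sequence(rna_seq: str) -> str:
    """Replace every uracil with thymine in an RNA sequence string.

    Whitespace is preserved; any character outside {A, C, G, U, whitespace}
    (case-insensitive) raises :class:`AlphabetError` naming its position.
    """
    out = []
    for pos, ch in enumerate(rna_seq, start=1):
        if ch.isspace() or ch.upper() in ("A", "C", "G"):
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch == "u":
            out.append("t")
        else:
            raise AlphabetError(
                f"position {pos}: character {ch!r} is not an RNA base"
            )
    return "".join(out)


# --------------------------------------------------------------------------
# Structure edits
# --------------------------------------------------------------------------


def strip_2prime_hydroxyl(s: Structure) -> tuple[Structure, ConversionReport]:
    """Delete the 2'-OH group (O2' plus its hydrogen) from every residue.

    Residues already lacking O2' are untouched (logged as already-deoxy).
    All other coordinates are bit-identical to the input.
    """
    out = s.copy()
    report = ConversionReport()
    for res in out.residues:
        had_o2 = any(res.has_atom(n) for n in _O2P_NAMES)
        if not had_o2:
            logger.info("residue %s already deoxy (no O2')", res.rid())
            continue
        doomed = set(_O2P_NAMES) | set(_O2P_HYDROGEN_NAMES)
        kept = []
        for a in res.atoms:
            if a.name in doomed:
                report.removed_atoms.append((res.rid(), a.name))
                logger.debug("removed %s from %s", a.name, res.rid())
            else:
                kept.append(a)
        res.atoms = kept
    return out, report


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (centroid, unit normal) of the least-squares plane."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


_RING_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")


def _methyl_coords(res: Residue, geom: MethylGeometry) -> np.ndarray:
    """Coordinates of C7, H71, H72, H73 for a uracil residue (4×3, Å)."""
    for name in ("C4", "C5", "C6"):
        if not res.has_atom(name):
            raise GeometryError(
                f"residue {res.rid()}: missing ring atom {name}, "
                "cannot construct methyl group"
            )
    c4 = res.atom("C4").coords
    c5 = res.atom("C5").coords
    c6 = res.atom("C6").coords

    ring_pts = np.array(
        [res.atom(n).coords for n in _RING_NAMES if res.has_atom(n)]
    )
    centroid, normal = _best_fit_plane(ring_pts)
    deviation = float(np.max(np.abs((ring_pts - centroid) @ normal)))
    if deviation > geom.coplanarity_tol:
        logger.warning(
            "residue %s: ring non-planar (%.3f Å > %.3f Å); methyl placed on "
            "best-fit plane", res.rid(), deviation, geom.coplanarity_tol,
        )

    # Exterior in-plane direction at C5: opposite the C4–C5–C6 bisector.
    u = (c4 - c5) / np.linalg.norm(c4 - c5)
    v = (c6 - c5) / np.linalg.norm(c6 - c5)
    exterior = -(u + v)
    exterior -= (exterior @ normal) * normal  # project into ring plane
    exterior /= np.linalg.norm(exterior)
    c7 = c5 + geom.c5_c7_bond * exterior

    # Methyl hydrogens: tetrahedral about C7, staggered w.r.t. the C5–C4 bond.
    z = (c7 - c5) / np.linalg.norm(c7 - c5)
    x = (c4 - c5) - ((c4 - c5) @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    theta = np.deg2rad(180.0 - geom.hch_angle)  # polar angle from +z
    hydrogens = []
    for phi_deg in (60.0, 180.0, 300.0):  # staggered: 0° would eclipse C4
        phi = np.deg2rad(phi_deg)
        direction = (
            np.cos(theta) * z
            + np.sin(theta) * (np.cos(phi) * x + np.sin(phi) * y)
        )
        hydrogens.append(c7 + geom.c_h_bond * direction)
    return np.vstack([c7, hydrogens])


def methylate_uracil(
    s: Structure, geom: MethylGeometry = MethylGeometry()
) -> tuple[Structure, ConversionReport]:
    """Replace the 5-position hydrogen of every uracil with a methyl group.

    For each uracil residue: H5 is deleted if present; C7 is placed in the
    base plane at ``geom.c5_c7_bond`` from C5 along the exterior bisector
    direction (the position H5 occupied); hydrogens H71/H72/H73 are added
    with tetrahedral geometry.  Construction uses heavy atoms only, so models
    without hydrogens convert identically.  No other atom moves.
    """
    out = s.copy()
    report = ConversionReport()
    next_serial = max((a.serial for a in out.atoms()), default=0) + 1
    for res in out.residues:
        if res.base_kind != "uracil":
            continue
        methyl = _methyl_coords(res, geom)
        if res.has_atom("H5"):
            res.atoms = [a for a in res.atoms if a.name != "H5"]
            report.removed_atoms.append((res.rid(), "H5"))
            logger.debug("removed H5 from %s", res.rid())
        c7 = Atom("C7", "C", methyl[0], next_serial)
        next_serial += 1
        # C7 sits between C5 and C6 in the conventional thymine atom order.
        i_c5 = next(i for i, a in enumerate(res.atoms) if a.name == "C5")
        res.atoms.insert(i_c5 + 1, c7)
        report.added_atoms.append((res.rid(), "C7"))
        logger.debug("added C7 to %s", res.rid())
        for name, xyz in zip(("H71", "H72", "H73"), methyl[1:]):
            res.atoms.append(Atom(name, "H", xyz, next_serial))
            next_serial += 1
            report.added_atoms.append((res.rid(), name))
            logger.debug("added %s to %s", name, res.rid())
    return out, report


_RNA_TO_DNA_CODE = {"A": "DA", "C": "DC", "G": "DG", "U": "DT", "T": "DT"}


def rename_to_dna(s: Structure) -> tuple[Structure, ConversionReport]:
    """Map residue codes to the DNA convention (A→DA, C→DC, G→DG, U→DT).

    Refuses to rename a residue that still carries O2' (a ribonucleotide).
    """
    out = s.copy()
    report = ConversionReport()
    for res in out.residues:
        if res.name in _RNA_TO_DNA_CODE:
            if any(res.has_atom(n) for n in _O2P_NAMES):
                raise ConsistencyError(
                    f"residue {res.rid()} still contains O2'; strip the "
                    "2'-hydroxyl before renaming"
                )
            new = _RNA_TO_DNA_CODE[res.name]
            report.renamed_residues.append((res.rid(), res.name, new))
            res.name = new
            if res.base_kind == "uracil":
                res.base_kind = "thymine"
    return out, report


def convert_structure(
    s: Structure, geom: MethylGeometry = MethylGeometry()
) -> tuple[Structure, ConversionReport]:
    """Full ssRNA → ssDNA conversion: strip 2'-OH, methylate uracils, rename.

    The three edits are applied in order on a pdbv3-normalized copy; every
    atom present in both input and output keeps bit-identical coordinates.
    The returned report aggregates all edits plus :func:`validate_dna`
    findings on the product.  Applying the conversion to an already-converted
    structure is the identity (empty edit lists).
    """
    work = normalize_dialect(s, "pdbv3")
    work, rep_strip = strip_2prime_hydroxyl(work)
    work, rep_methyl = methylate_uracil(work, geom)
    work, rep_rename = rename_to_dna(work)
    report = ConversionReport()
    report.merge(rep_strip)
    report.merge(rep_methyl)
    # Renames of residues that were already DNA-coded are not edits.
    report.renamed_residues = [
        t for t in rep_rename.renamed_residues if t[1] != t[2]
    ]
    report.validation = validate_dna(work, default_templates())
    return work, report


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_C5_C7_RANGE = (1.3, 1.7)   # Å
_O3_P_RANGE = (1.4, 1.9)    # Å
_BOND_TOL = 0.25            # Å


def validate_dna(
    s: Structure, templates: ResidueTemplateTable | None = None
) -> list[ValidationCheck]:
    """Chemical-validity checks for a converted ssDNA model.

    Per residue: heavy-atom inventory equals the DNA template (the 5'
    terminus may lack the phosphate group); no O2' anywhere; every DT carries
    C7 at a bonded distance from C5; intra-residue bond lengths within
    ±0.25 Å of template values.  Per chain: consecutive O3'–P distances in
    the bonded range.  Findings are returned, never raised.
    """
    templates = templates or default_templates()
    checks: list[ValidationCheck] = []
    for chain_id, residues in s.chains().items():
        for i, res in enumerate(residues):
            rid = res.rid()
            if res.name not in templates.codes():
                checks.append(ValidationCheck(
                    "known_residue", False, rid,
                    f"unknown residue code {res.name!r}",
                ))
                continue
            tpl = templates[res.name]

            heavy = res.heavy_atom_names()
            expected = set(tpl.heavy_atoms)
            ok = heavy == expected
            if not ok and i == 0:
                ok = heavy == expected - {"P", "OP1", "OP2"}
            checks.append(ValidationCheck(
                "heavy_atom_inventory", ok, rid,
                "" if ok else (
                    f"missing {sorted(expected - heavy)}, "
                    f"extra {sorted(heavy - expected)}"
                ),
            ))

            has_o2 = any(res.has_atom(n) for n in _O2P_NAMES)
            checks.append(ValidationCheck(
                "no_2prime_hydroxyl", not has_o2, rid,
                "O2' present" if has_o2 else "",
            ))

            if res.name == "DT":
                ok = False
                detail = "C7 or C5 missing"
                if res.has_atom("C7") and res.has_atom("C5"):
                    d = float(np.linalg.norm(
                        res.atom("C7").coords - res.atom("C5").coords
                    ))
                    ok = _C5_C7_RANGE[0] < d < _C5_C7_RANGE[1]
                    detail = f"d(C5,C7) = {d:.3f} Å"
                checks.append(ValidationCheck("thymine_methyl", ok, rid, detail))

            worst = 0.0
            worst_pair = None
            for a, b, ideal in tpl.bonds:
                atom_a, atom_b = res.atom(a), res.atom(b)
                if atom_a is None or atom_b is None:
                    continue
                dev = abs(
                    float(np.linalg.norm(atom_a.coords - atom_b.coords)) - ideal
                )
                if dev > worst:
                    worst, worst_pair = dev, (a, b)
            ok = worst <= _BOND_TOL
            checks.append(ValidationCheck(
                "bond_lengths", ok, rid,
                "" if ok else f"{worst_pair}: deviation {worst:.3f} Å",
            ))

            if i + 1 < len(residues):
                nxt = residues[i + 1]
                o3, p = res.atom("O3'"), nxt.atom("P")
                if o3 is not None and p is not None:
                    d = float(np.linalg.norm(o3.coords - p.coords))
                    ok = _O3_P_RANGE[0] < d < _O3_P_RANGE[1]
                    checks.append(ValidationCheck(
                        "backbone_connectivity", ok, rid,
                        f"d(O3',P next) = {d:.3f} Å",
                    ))
                else:
                    checks.append(ValidationCheck(
                        "backbone_connectivity", False, rid,
                        "O3' or next-residue P missing",
                    ))
    return checks
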