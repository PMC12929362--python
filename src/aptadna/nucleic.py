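"""Domain model and coordinate I/O for single-stranded nucleic acids.

The package's native representation is a hierarchy ``Structure`` → ``Residue``
→ ``Atom`` with Cartesian coordinates in Ångström and PDB-convention atom
names.  Two naming dialects are understood: modern PDB version 3 (primed
sugar atoms such as ``O2'``, phosphate oxygens ``OP1``/``OP2``, DNA residue
codes ``DA``/``DC``/``DG``/``DT``) and the legacy version 2 convention
(``O2*``, ``O1P``/``O2P``, single-letter DNA codes).  Trajectories are
ordered coordinate frames sharing one topology; multi-model PDB and GRO
frame series are read natively, binary formats through an optional
MDAnalysis adapter.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("aptadna")

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class AptadnaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AptadnaError):
    """A coordinate file could not be parsed (message names the line)."""


class EmptyInputError(AptadnaError):
    """A coordinate file contained no atoms."""


class FormatError(AptadnaError):
    """A structure cannot be represented in the requested output format."""


class UnknownResidueError(AptadnaError):
    """A residue code is not a recognized nucleotide."""


class AlphabetError(AptadnaError):
    """A sequence string contains characters outside the allowed alphabet."""


class GeometryError(AptadnaError):
    """Coordinates are degenerate or required atoms are missing."""


class ConsistencyError(AptadnaError):
    """An operation was applied to a structure in an inconsistent state."""


class UnitsError(AptadnaError):
    """Incompatible units were mixed in one operation."""


# --------------------------------------------------------------------------
# Constants
# --------------------------------------------------------------------------

#: Atomic masses (u) for mass-weighted superposition.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

RNA_CODES = ("A", "C", "G", "U")
DNA_CODES = ("DA", "DC", "DG", "DT")

#: residue code → base kind, across both dialects.
BASE_KIND_OF_CODE = {
    "A": "adenine",
    "DA": "adenine",
    "C": "cytosine",
    "DC": "cytosine",
    "G": "guanine",
    "DG": "guanine",
    "U": "uracil",
    "T": "thymine",  # legacy (pdbv2) DNA code
    "DT": "thymine",
}

ONE_LETTER_OF_KIND = {
    "adenine": "A",
    "cytosine": "C",
    "guanine": "G",
    "uracil": "U",
    "thymine": "T",
}

GRO_NM_TO_ANGSTROM = 10.0


def element_of_name(name: str) -> str:
    """Infer the chemical element from a PDB atom name.

    Nucleic-acid atoms are all single-letter elements; the element is the
    first alphabetic character of the name (``"OP1"`` → O, ``"H5''"`` → H).
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


# --------------------------------------------------------------------------
# Naming dialects
# --------------------------------------------------------------------------


def _v3_to_v2_atom(name: str) -> str:
    m = re.fullmatch(r"OP([123])", name)
    if m:
        return f"O{m.group(1)}P"
    return name.replace("'", "*")


def _build_atom_tables() -> tuple[dict, dict]:
    v3_names = [
        "P", "OP1", "OP2", "OP3",
        "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
        "H5'", "H5''", "H4'", "H3'", "HO3'", "H2'", "H2''", "HO2'", "H1'",
        "HO5'",
    ]
    v3_to_v2 = {n: _v3_to_v2_atom(n) for n in v3_names}
    v2_to_v3 = {v: k for k, v in v3_to_v2.items()}
    assert len(v2_to_v3) == len(v3_to_v2), "atom-name map must be a bijection"
    return v3_to_v2, v2_to_v3


_V3_TO_V2_ATOM, _V2_TO_V3_ATOM = _build_atom_tables()

# Base-ring names are identical in both dialects; they are "covered" so that
# normalization does not warn about them.
_INVARIANT_NAMES = {
    "N1", "C2", "O2", "N3", "C4", "O4", "N4", "C5", "C6", "O6", "N6",
    "N7", "C8", "N9", "N2", "C7", "H1", "H2", "H3", "H5", "H6", "H8",
    "H21", "H22", "H41", "H42", "H61", "H62", "H71", "H72", "H73",
}

_V3_TO_V2_RES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
_V2_TO_V3_RES = {v: k for k, v in _V3_TO_V2_RES.items()}


@dataclass(frozen=True)
class AtomNamingDialect:
    """One of the two PDB atom/residue naming conventions.

    ``pdbv3`` uses primes and OP1/OP2 (``O2'``); ``pdbv2`` uses asterisks and
    O1P/O2P (``O2*``) plus single-letter DNA residue codes.  The covered name
    set maps bijectively; names outside it pass through unchanged with a
    logged warning.
    """

    id: str  # "pdbv3" | "pdbv2"

    def __post_init__(self):
        if self.id not in ("pdbv3", "pdbv2"):
            raise ValueError(f"unknown dialect {self.id!r}")

    def atom_name_to(self, other: "AtomNamingDialect", name: str) -> str:
        if self.id == other.id:
            return name
        table = _V3_TO_V2_ATOM if self.id == "pdbv3" else _V2_TO_V3_ATOM
        if name in table:
            return table[name]
        if name not in _INVARIANT_NAMES:
            logger.warning(
                "atom name %r not covered by %s→%s table; passed through",
                name, self.id, other.id,
            )
        return name

    def residue_code_to(
        self, other: "AtomNamingDialect", code: str, *, is_dna: bool
    ) -> str:
        if self.id == other.id:
            return code
        if self.id == "pdbv3" and code in _V3_TO_V2_RES:
            return _V3_TO_V2_RES[code]
        if self.id == "pdbv2" and is_dna and code in _V2_TO_V3_RES:
            return _V2_TO_V3_RES[code]
        return code


PDBV3 = AtomNamingDialect("pdbv3")
PDBV2 = AtomNamingDialect("pdbv2")


def dialect_from_id(d) -> AtomNamingDialect:
    if isinstance(d, AtomNamingDialect):
        return d
    if d == "pdbv3":
        return PDBV3
    if d == "pdbv2":
        return PDBV2
    raise ValueError(f"unknown dialect {d!r}")


# --------------------------------------------------------------------------
# Hierarchy
# --------------------------------------------------------------------------


@dataclass
class Atom:
    """A single atom: PDB name, element symbol, coordinates (Å), serial."""

    name: str
    element: str
    coords: np.ndarray
    serial: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.serial < 1:
            raise ValueError(f"atom {self.name}: serial must be positive")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.serial)


@dataclass
class Residue:
    """One nucleotide: residue code, chain, sequence number, ordered atoms."""

    name: str
    chain_id: str
    seq_number: int
    atoms: list[Atom] = field(default_factory=list)
    base_kind: str | None = None
    insertion_code: str = ""

    def __post_init__(self):
        if self.base_kind is None:
            self.base_kind = BASE_KIND_OF_CODE.get(self.name)
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.rid()}: duplicate atom names {dup}"
            )

    def rid(self) -> str:
        """Short residue identifier, e.g. ``A:12``."""
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    def heavy_atom_names(self) -> set[str]:
        return {a.name for a in self.atoms if a.element != "H"}

    def copy(self) -> "Residue":
        return Residue(
            self.name, self.chain_id, self.seq_number,
            [a.copy() for a in self.atoms], self.base_kind,
            self.insertion_code,
        )


@dataclass
class Structure:
    """A nucleic-acid model: residues in file order, grouped by chain."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    dialect: AtomNamingDialect = PDBV3

    def __post_init__(self):
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials are not unique")
        for chain_id, residues in self.chains().items():
            nums = [r.seq_number for r in residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    f"chain {chain_id}: residue numbers not strictly increasing"
                )

    # -- views -------------------------------------------------------------

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All coordinates as an N×3 array (Å), in atom order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match structure")
        for a, xyz in zip(self.atoms(), coords):
            a.coords = xyz.copy()

    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(a.element, 12.011) for a in self.atoms()]
        )

    def copy(self) -> "Structure":
        return Structure(
            [r.copy() for r in self.residues], self.title, self.dialect
        )

    def renumber_serials(self) -> None:
        for i, a in enumerate(self.atoms(), start=1):
            a.serial = i


def normalize_dialect(s: Structure, target="pdbv3") -> Structure:
    """Return a copy of *s* with atom and residue names in *target* dialect."""
    target = dialect_from_id(target)
    out = s.copy()
    for res in out.residues:
        is_dna = res.base_kind == "thymine" or not res.has_atom(
            "O2'" if s.dialect.id == "pdbv3" else "O2*"
        )
        res.name = s.dialect.residue_code_to(target, res.name, is_dna=is_dna)
        for a in res.atoms:
            a.name = s.dialect.atom_name_to(target, a.name)
    out.dialect = target
    return out


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------


@dataclass
class Frame:
    """One trajectory frame: time stamp (ns) and an N×3 coordinate array (Å)."""

    time: float
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.time < 0:
            raise ValueError("frame time must be non-negative")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coords must be N×3")


@dataclass
class Trajectory:
    """Ordered frames over one topology; frame times strictly increase."""

    topology: Structure
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {i}: {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


# --------------------------------------------------------------------------
# PDB reading
# --------------------------------------------------------------------------

_TIME_REMARK = re.compile(
    r"REMARK.*?\bTIME(?:_NS)?\s*[=:]?\s*([0-9.eE+-]+)", re.IGNORECASE
)


def _parse_atom_record(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain_id = line[21]
        seq_number = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    if not element:
        element = element_of_name(name)
    return serial, name, altloc, resname, chain_id, seq_number, icode, (x, y, z), element.capitalize()


def _detect_dialect(structure_lines: list[str]) -> AtomNamingDialect:
    for line in structure_lines:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        if "*" in name or name in ("O1P", "O2P", "O3P"):
            return PDBV2
        if resname == "T":
            return PDBV2
        if resname in DNA_CODES:
            return PDBV3
    return PDBV3


def _residues_from_records(records, dialect) -> list[Residue]:
    residues: list[Residue] = []
    key = None
    for serial, name, altloc, resname, chain_id, seqnum, icode, xyz, element in records:
        this_key = (chain_id, seqnum, icode, resname)
        if this_key != key:
            residues.append(
                Residue(resname, chain_id, seqnum, [], None, icode)
            )
            key = this_key
        res = residues[-1]
        if res.has_atom(name):
            logger.warning(
                "duplicate atom %s in residue %s ignored", name, res.rid()
            )
            continue
        res.atoms.append(Atom(name, element, np.asarray(xyz), serial))
    return residues


def read_pdb(path, dialect="auto") -> Structure:
    """Read a (single-model) PDB file into a :class:`Structure`.

    ``dialect="auto"`` detects pdbv2 vs pdbv3 from residue and atom names.
    Alternate locations other than blank/'A' are dropped with a warning;
    insertion codes are retained.  Of a multi-model file only the first model
    is read (use :func:`read_trajectory` for all models).
    """
    with open(path) as fh:
        lines = fh.readlines()

    title = ""
    records = []
    atom_lines = []
    in_model = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "TITLE ":
            title = (title + " " + line[10:].strip()).strip()
        elif rec == "MODEL ":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL":
            break
        elif rec in ("ATOM  ", "HETATM"):
            parsed = _parse_atom_record(line, lineno)
            altloc = parsed[2]
            if altloc not in (" ", "A"):
                logger.warning(
                    "line %d: dropping altloc %r atom %s",
                    lineno, altloc, parsed[1],
                )
                continue
            records.append(parsed)
            atom_lines.append(line)

    if not records:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")

    if dialect == "auto":
        detected = _detect_dialect(atom_lines)
    else:
        detected = dialect_from_id(dialect)

    residues = _residues_from_records(records, detected)
    return Structure(residues, title=title, dialect=detected)


# --------------------------------------------------------------------------
# PDB writing
# --------------------------------------------------------------------------


def _format_atom_name(name: str) -> str:
    if len(name) > 4:
        raise FormatError(f"atom name {name!r} longer than 4 characters")
    # Single-letter elements start in column 14 unless the name needs 4 chars.
    if len(name) < 4:
        return f" {name:<3s}"
    return name


def _atom_line(atom: Atom, res: Residue, resname: str, name: str) -> str:
    x, y, z = atom.coords
    return (
        f"ATOM  {atom.serial:>5d} {_format_atom_name(name)} "
        f"{resname:>3s} {res.chain_id}{res.seq_number:>4d}{res.insertion_code or ' '}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def _structure_lines(s: Structure, dialect: AtomNamingDialect) -> list[str]:
    lines = []
    chains = s.chains()
    last_serial = 0
    for chain_id, residues in chains.items():
        for res in residues:
            is_dna = res.base_kind == "thymine" or not res.has_atom(
                "O2'" if s.dialect.id == "pdbv3" else "O2*"
            )
            resname = s.dialect.residue_code_to(dialect, res.name, is_dna=is_dna)
            for atom in res.atoms:
                name = s.dialect.atom_name_to(dialect, atom.name)
                lines.append(_atom_line(atom, res, resname, name))
                last_serial = atom.serial
        last = residues[-1]
        is_dna = last.base_kind == "thymine" or not last.has_atom(
            "O2'" if s.dialect.id == "pdbv3" else "O2*"
        )
        resname = s.dialect.residue_code_to(dialect, last.name, is_dna=is_dna)
        lines.append(
            f"TER   {last_serial + 1:>5d}      {resname:>3s} "
            f"{chain_id}{last.seq_number:>4d}\n"
        )
    return lines


def write_pdb(s: Structure, path, dialect="pdbv3") -> None:
    """Write *s* as a standard PDB file in the requested naming dialect."""
    if s.n_atoms == 0:
        raise EmptyInputError("refusing to write an empty structure")
    dialect = dialect_from_id(dialect)
    with open(path, "w") as fh:
        if s.title:
            fh.write(f"TITLE     {s.title}\n")
        fh.writelines(_structure_lines(s, dialect))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path, dialect="pdbv3") -> None:
    """Write a trajectory as multi-model PDB, one MODEL per frame.

    Each model carries a ``REMARK   6 TIME_NS`` record so times survive a
    round trip.
    """
    dialect = dialect_from_id(dialect)
    topo = traj.topology
    with open(path, "w") as fh:
        if topo.title:
            fh.write(f"TITLE     {topo.title}\n")
        for i, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {i:>4d}\n")
            fh.write(f"REMARK   6 TIME_NS {frame.time:.6f}\n")
            snapshot = topo.copy()
            snapshot.set_coords(frame.coords)
            fh.writelines(_structure_lines(snapshot, dialect))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Trajectory reading
# --------------------------------------------------------------------------


def _read_pdb_frames(path, n_atoms_expected: int) -> list[Frame]:
    with open(path) as fh:
        lines = fh.readlines()

    blocks: list[tuple[float | None, list]] = []
    current: list | None = None
    current_time: float | None = None
    saw_model = any(line.startswith("MODEL") for line in lines)
    if not saw_model:
        current = []
        blocks.append((None, current))
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "MODEL ":
            current = []
            current_time = None
            blocks.append((None, current))
        elif rec == "REMARK":
            m = _TIME_REMARK.search(line)
            if m and blocks:
                time_val = float(m.group(1))
                blocks[-1] = (time_val, blocks[-1][1])
        elif rec in ("ATOM  ", "HETATM") and current is not None:
            parsed = _parse_atom_record(line, lineno)
            if parsed[2] not in (" ", "A"):
                continue
            current.append(parsed[7])

    frames = []
    for i, (time_val, coords) in enumerate(blocks):
        if not coords:
            continue
        if len(coords) != n_atoms_expected:
            raise ParseError(
                f"frame {i}: {len(coords)} atoms, topology has "
                f"{n_atoms_expected}"
            )
        frames.append(
            Frame(time_val if time_val is not None else float(i), np.asarray(coords))
        )
    return frames


_GRO_TIME = re.compile(r"\bt\s*=\s*([0-9.eE+-]+)")


def _read_gro_frames(path, n_atoms_expected: int) -> list[Frame]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        title = lines[i]
        if not title.strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i + 1])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"line {i + 2}: expected GRO atom count: {exc}"
            ) from exc
        if n_atoms != n_atoms_expected:
            raise ParseError(
                f"frame {frame_index}: {n_atoms} atoms, topology has "
                f"{n_atoms_expected}"
            )
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            line = lines[i + 2 + j]
            try:
                coords[j] = (
                    float(line[20:28]), float(line[28:36]), float(line[36:44])
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"line {i + 3 + j}: malformed GRO atom line: {exc}"
                ) from exc
        m = _GRO_TIME.search(title)
        time_ns = float(m.group(1)) / 1000.0 if m else float(frame_index)
        frames.append(Frame(time_ns, coords * GRO_NM_TO_ANGSTROM))
        i += 2 + n_atoms + 1  # title, count, atoms, box line
        frame_index += 1
    return frames


def read_trajectory(topology_path, traj_path) -> Trajectory:
    """Read a trajectory from multi-model PDB or concatenated GRO blocks.

    GRO coordinates (nm) are converted to Å; GRO title times (``t=`` in ps)
    are converted to ns.  Frames lacking time stamps get their frame index as
    time.  An atom-count mismatch in any frame is a hard error naming the
    frame.
    """
    topology = read_pdb(topology_path)
    n = topology.n_atoms
    if str(traj_path).lower().endswith(".gro"):
        frames = _read_gro_frames(traj_path, n)
    else:
        frames = _read_pdb_frames(traj_path, n)
    if not frames:
        raise EmptyInputError(f"{traj_path}: no frames found")
    return Trajectory(topology, frames)


def trajectory_from_mdanalysis(topology_path, traj_path) -> Trajectory:
    """Optional adapter: read any MDAnalysis-supported format (XTC, DCD, ...).

    Requires the ``MDAnalysis`` extra; times are converted ps → ns and
    coordinates are kept in Å (MDAnalysis native units).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise AptadnaError(
            "binary trajectory formats need the optional MDAnalysis adapter"
        ) from exc
    topology = read_pdb(topology_path)
    u = mda.Universe(str(topology_path), str(traj_path))
    frames = [
        Frame(float(ts.time) / 1000.0, u.atoms.positions.astype(float).copy())
        for ts in u.trajectory
    ]
    return Trajectory(topology, frames)


# --------------------------------------------------------------------------
# Sequences
# --------------------------------------------------------------------------


def sequence_of(s: Structure) -> str:
    """5'→3' one-letter sequence (U for uracil, T for thymine, any dialect)."""
    letters = []
    for res in s.residues:
        kind = BASE_KIND_OF_CODE.get(res.name)
        if kind is None:
            raise UnknownResidueError(
                f"residue {res.rid()}: unknown residue code {res.name!r}"
            )
        letters.append(ONE_LETTER_OF_KIND[kind])
    return "".join(letters)
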