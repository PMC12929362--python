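"""Synthetic fixtures: idealized single-stranded helices, noisy trajectories
and plateau series with known ground truth.

Every generator is deterministic under a fixed seed.  The helix builder
places idealized nucleotide monomer geometry (from the chemical component
dictionary) along a helical axis with configurable twist and rise; the
monomer pose relative to the axis is solved once per geometry so that
consecutive O3'–P distances fall in the covalent-bond range.  The fixtures
are chemically plausible single strands, not folded aptamer models: they
carry no base pairing and no thermodynamic realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .analysis import TimeSeries, kabsch_superpose
from .nucleic import (
    AlphabetError,
    GeometryError,
    Atom,
    Frame,
    Residue,
    Structure,
    Trajectory,
)

logger = logging.getLogger("aptadna")

# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

_FORM_DEFAULTS = {"A": (32.7, 2.81), "B": (36.0, 3.38)}


@dataclass(frozen=True)
class HelixParams:
    """Helical placement parameters: twist (deg/residue) and rise (Å/residue).

    Defaults follow the canonical fibre geometries: A-form 32.7°/2.81 Å,
    B-form 36.0°/3.38 Å.
    """

    form: str = "A"
    twist: float | None = None
    rise: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.form not in _FORM_DEFAULTS:
            raise ValueError(f"form must be 'A' or 'B', got {self.form!r}")
        t, r = _FORM_DEFAULTS[self.form]
        if self.twist is None:
            object.__setattr__(self, "twist", t)
        if self.rise is None:
            object.__setattr__(self, "rise", r)
        if not 0 < self.twist < 60:
            raise ValueError("twist must lie in (0, 60) degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


@dataclass
class NoiseSpec:
    """Gaussian coordinate noise (σ in Å per coordinate) over n_frames.

    ``drift`` is an optional callable ``i -> (rotation 3×3, translation 3)``
    composed onto frame *i* after the noise.
    """

    sigma: float
    n_frames: int
    seed: int = 0
    drift: object = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


# --------------------------------------------------------------------------
# Template access
# --------------------------------------------------------------------------

_BACKBONE = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
             "C2'", "C1'"]
_GLYCO_FRAME = ["C1'", "C2'", "O4'"]
_SUGAR_H = ["H5'", "H5''", "H4'", "H3'", "H2'", "H2''", "HO2'", "H1'"]


def _template_atoms(code: str) -> tuple[list[str], list[str], np.ndarray]:
    """CCD ideal atoms for *code*: (names, elements, coords), OP3 group removed."""
    import biotite.structure.info as info

    arr = info.residue(code)
    names, elements, coords = [], [], []
    for n, e, c in zip(arr.atom_name, arr.element, np.asarray(arr.coord)):
        if n in ("OP3", "HOP3", "HOP2"):
            continue
        names.append(str(n))
        elements.append(str(e))
        coords.append(c)
    return names, elements, np.asarray(coords, dtype=float)


def _rigid_from_points(src: np.ndarray, dst: np.ndarray):
    rot, trans, _ = kabsch_superpose(src, dst)
    return rot, trans


# --------------------------------------------------------------------------
# Monomer pose relative to the helix axis
# --------------------------------------------------------------------------


def _symmetry_op(twist_deg: float, rise: float):
    rot = Rotation.from_euler("z", twist_deg, degrees=True).as_matrix()
    shift = np.array([0.0, 0.0, rise])
    return rot, shift

# 1-2 and 1-3 neighbours across the O3'(i)–P(i+1) linkage: not clashes.
_LINK_EXEMPT = {
    ("O3'", "P"), ("O3'", "O5'"), ("O3'", "OP1"), ("O3'", "OP2"),
    ("C3'", "P"),
}

_O3_P_TARGET = 1.60  # Å
_CLASH_MIN = 2.6     # Å


def _pose_objective(params, coords, names, sym):
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    x = coords @ rot.T + params[3:]
    s_rot, s_shift = sym
    x1 = x @ s_rot.T + s_shift          # next residue
    x2 = x1 @ s_rot.T + s_shift         # residue after next

    i_p = names.index("P")
    i_o3 = names.index("O3'")
    i_c3 = names.index("C3'")
    i_o5 = names.index("O5'")

    obj = 300.0 * (np.linalg.norm(x[i_o3] - x1[i_p]) - _O3_P_TARGET) ** 2

    # C3'–O3'–P and O3'–P–O5' angles kept near tetrahedral-ish values
    def angle(a, b, c):
        u = a - b
        v = c - b
        cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    obj += 5.0 * (angle(x[i_c3], x[i_o3], x1[i_p]) - np.deg2rad(120.0)) ** 2
    obj += 5.0 * (angle(x[i_o3], x1[i_p], x1[i_o5]) - np.deg2rad(104.0)) ** 2

    for neighbour, exempt in ((x1, True), (x2, False)):
        d = np.linalg.norm(x[:, None, :] - neighbour[None, :, :], axis=2)
        if exempt:
            for a, b in _LINK_EXEMPT:
                d[names.index(a), names.index(b)] = _CLASH_MIN
        viol = np.clip(_CLASH_MIN - d, 0.0, None)
        obj += 20.0 * float((viol ** 2).sum())
    return obj


@lru_cache(maxsize=8)
def _solve_pose(chemistry: str, twist: float, rise: float, seed: int):
    """Rigid placement of the reference monomer so helical symmetry bonds it.

    Solved by seeded multi-start local optimization of a 6-DOF pose; the
    result is cached and fully deterministic.
    """
    ref_code = "A" if chemistry == "RNA" else "DA"
    names, _elements, coords = _template_atoms(ref_code)
    heavy = [i for i, n in enumerate(names) if not n.startswith("H")]
    names_h = [names[i] for i in heavy]
    coords_h = coords[heavy] - coords[heavy].mean(axis=0)
    sym = _symmetry_op(twist, rise)

    rng = np.random.default_rng(977_003 + seed)
    best = None
    for _ in range(12):
        rotvec = rng.normal(size=3) * 2.0
        radius = rng.uniform(4.0, 11.0)
        phi = rng.uniform(0, 2 * np.pi)
        start = np.concatenate([
            rotvec,
            [radius * np.cos(phi), radius * np.sin(phi), 0.0],
        ])
        res = minimize(
            _pose_objective, start, args=(coords_h, names_h, sym),
            method="Nelder-Mead",
            options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = minimize(
        _pose_objective, best.x, args=(coords_h, names_h, sym),
        method="Nelder-Mead",
        options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-12},
    )
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    posed = coords_h @ rot.T + res.x[3:]
    s_rot, s_shift = sym
    link = float(np.linalg.norm(
        posed[names_h.index("O3'")]
        - (posed[names_h.index("P")] @ s_rot.T + s_shift)
    ))
    if not 1.4 < link < 1.9:
        raise GeometryError(
            f"could not pose {chemistry} monomer for twist={twist}, "
            f"rise={rise}: O3'–P link {link:.2f} Å"
        )
    logger.debug("posed %s monomer: O3'–P link %.3f Å", chemistry, link)
    full_rot, full_trans = _rigid_from_points(
        coords[[names.index(n) for n in names_h]], posed
    )
    posed_full = coords @ full_rot.T + full_trans
    return names, posed_full


# --------------------------------------------------------------------------
# Helix builder
# --------------------------------------------------------------------------

_RNA_LETTER_TO_CODE = {"A": "A", "C": "C", "G": "G", "U": "U"}
_DNA_LETTER_TO_CODE = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


def _posed_monomer(code: str, chemistry: str, params: HelixParams):
    """All-atom coordinates of one posed monomer of residue type *code*.

    The sugar-phosphate backbone is the posed reference backbone (identical
    for every residue of the strand); base atoms are attached through the
    code's own glycosidic frame (C1'/C2'/O4'), preserving the base's internal
    and glycosidic geometry exactly.
    """
    ref_names, ref_posed = _solve_pose(
        chemistry, params.twist, params.rise, params.seed
    )
    ref_map = dict(zip(ref_names, ref_posed))
    names, elements, coords = _template_atoms(code)
    tpl_map = dict(zip(names, coords))

    frame_src = np.array([tpl_map[n] for n in _GLYCO_FRAME])
    frame_dst = np.array([ref_map[n] for n in _GLYCO_FRAME])
    # 3-point rigid map: congruent triangles, so the fit is essentially exact.
    rot, trans, _ = kabsch_superpose(frame_src, frame_dst)

    backbone_set = set(_BACKBONE) | {"O2'"} | set(_SUGAR_H) | {"HO3'"}
    out_names, out_elements, out_coords = [], [], []
    for n, e in zip(names, elements):
        if n in backbone_set:
            if n not in ref_map:
                continue  # e.g. H2'' absent from the RNA reference
            xyz = ref_map[n]
        else:
            xyz = tpl_map[n] @ rot.T + trans
        out_names.append(n)
        out_elements.append(e)
        out_coords.append(xyz)
    return out_names, out_elements, np.asarray(out_coords)


def build_helix(
    seq: str,
    params: HelixParams | None = None,
    include_hydrogens: bool = False,
    chain_id: str = "A",
) -> Structure:
    """Build an idealized single-stranded helix for a nucleotide sequence.

    The sequence may use U (RNA) or T (DNA) but not both; DNA strands default
    to B-form, RNA strands to A-form.  Every residue carries the full
    heavy-atom inventory of its residue template (including the 5'-terminal
    phosphate); hydrogens are added on request, with the 3'-hydroxyl hydrogen
    only on the terminal residue.
    """
    seq = "".join(seq.split()).upper()
    if "U" in seq and "T" in seq:
        raise AlphabetError("sequence mixes U and T")
    chemistry = "DNA" if "T" in seq else "RNA"
    letter_map = (
        _DNA_LETTER_TO_CODE if chemistry == "DNA" else _RNA_LETTER_TO_CODE
    )
    for pos, ch in enumerate(seq, start=1):
        if ch not in letter_map:
            raise AlphabetError(
                f"position {pos}: character {ch!r} not in "
                f"{sorted(letter_map)}"
            )
    if params is None:
        params = HelixParams(form="A" if chemistry == "RNA" else "B")

    s_rot, s_shift = _symmetry_op(params.twist, params.rise)
    residues = []
    serial = 1
    n_res = len(seq)
    for i, letter in enumerate(seq):
        code = letter_map[letter]
        names, elements, coords = _posed_monomer(code, chemistry, params)
        rot_i = np.linalg.matrix_power(s_rot, i)
        xyz = coords @ rot_i.T + i * s_shift
        atoms = []
        for n, e, c in zip(names, elements, xyz):
            if e == "H":
                if not include_hydrogens:
                    continue
                if n == "HO3'" and i < n_res - 1:
                    continue  # O3' is esterified to the next phosphate
            atoms.append(Atom(n, e, c, serial))
            serial += 1
        residues.append(Residue(code, chain_id, i + 1, atoms))
    return Structure(residues, title=f"idealized ss{chemistry} helix")


# --------------------------------------------------------------------------
# Trajectories and series
# --------------------------------------------------------------------------


def make_noise_trajectory(ref: Structure, spec: NoiseSpec) -> Trajectory:
    """Frames = reference coordinates + i.i.d. Gaussian noise (σ per coordinate).

    An optional drift generator (``i -> (rotation, translation)``) composes a
    rigid transform onto each frame, giving trajectories whose superposition
    RMSD is unaffected by the drift.  Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = ref.coords()
    frames = []
    for i in range(spec.n_frames):
        coords = base + rng.normal(0.0, spec.sigma, size=base.shape)
        if spec.drift is not None:
            rot, trans = spec.drift(i)
            coords = coords @ np.asarray(rot).T + np.asarray(trans)
        frames.append(Frame(float(i), coords))
    return Trajectory(ref, frames)


def make_plateau_series(
    t_onset: float,
    total: float,
    dt: float,
    pre_slope: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic plateau",
) -> TimeSeries:
    """Linear ramp until *t_onset*, constant thereafter, plus Gaussian noise.

    Mimics an RMSD profile that stabilizes into a plateau; units are nm.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < t_onset < total:
        raise ValueError("t_onset must lie strictly inside (0, total)")
    times = np.arange(0.0, total + dt / 2, dt)
    values = pre_slope * np.minimum(times, t_onset)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.abs(values)  # RMSD-like series stays non-negative
    return TimeSeries(times, values, label, units="nm")


# --------------------------------------------------------------------------
# Watson–Crick pair fixture
# --------------------------------------------------------------------------

_WC_CONTACTS = (
    # donor residue/atom, hydrogen, acceptor residue/atom, target Å
    ("C", "N4", "H41", "G", "O6", 2.91),
    ("G", "N1", "H1", "C", "N3", 2.95),
    ("G", "N2", "H21", "C", "O2", 2.86),
)


def _base_atoms(code: str):
    names, elements, coords = _template_atoms(code)
    keep = [
        i for i, n in enumerate(names)
        if n not in _BACKBONE and n != "O2'" and n not in _SUGAR_H
        and n != "HO3'"
    ]
    return (
        [names[i] for i in keep],
        [elements[i] for i in keep],
        coords[keep],
    )


@lru_cache(maxsize=1)
def _gc_pair_geometry():
    g_names, g_elements, g_coords = _base_atoms("G")
    c_names, c_elements, c_coords = _base_atoms("C")
    gi = {n: i for i, n in enumerate(g_names)}
    ci = {n: i for i, n in enumerate(c_names)}
    g_heavy = np.array([i for i, e in enumerate(g_elements) if e != "H"])
    c_heavy = np.array([i for i, e in enumerate(c_elements) if e != "H"])

    centroid, normal = _plane(g_coords[g_heavy])

    # Contacts adjacent to the true bonds: kept apart so only the three
    # canonical bonds satisfy the geometric criteria (proper, non-mirrored
    # pairing; in the mirrored solution these collapse below 3.3 Å).
    diagonals = (("N1", "N4"), ("N2", "N3"), ("O6", "N3"))

    def objective(p):
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        c = c_coords @ rot.T + p[3:]
        obj = 0.0
        for d_res, d_name, h_name, _a_res, a_name, target in _WC_CONTACTS:
            if d_res == "C":
                d_xyz, h_xyz, a_xyz = (
                    c[ci[d_name]], c[ci[h_name]], g_coords[gi[a_name]]
                )
            else:
                d_xyz, h_xyz, a_xyz = (
                    g_coords[gi[d_name]], g_coords[gi[h_name]], c[ci[a_name]]
                )
            obj += 100.0 * (np.linalg.norm(d_xyz - a_xyz) - target) ** 2
            dh = (h_xyz - d_xyz) / np.linalg.norm(h_xyz - d_xyz)
            da = (a_xyz - d_xyz) / np.linalg.norm(a_xyz - d_xyz)
            obj += 10.0 * (1.0 - float(dh @ da))
        # glycosidic-nitrogen separation fixes the overall pair shape
        obj += 10.0 * (
            np.linalg.norm(g_coords[gi["N9"]] - c[ci["N1"]]) - 8.95
        ) ** 2
        for g_name, c_name in diagonals:
            d = np.linalg.norm(g_coords[gi[g_name]] - c[ci[c_name]])
            obj += 50.0 * max(0.0, 3.5 - d) ** 2
        obj += 2.0 * float((((c[c_heavy] - centroid) @ normal) ** 2).sum())
        d = np.linalg.norm(
            g_coords[g_heavy][:, None, :] - c[c_heavy][None, :, :], axis=2
        )
        viol = np.clip(2.8 - d, 0.0, None)
        obj += 20.0 * float((viol ** 2).sum())
        return obj

    rng = np.random.default_rng(424_242)
    best = None
    for _ in range(12):
        start = np.concatenate([
            rng.normal(size=3) * 1.5,
            centroid + rng.normal(size=3) * 4.0,
        ])
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxiter": 1500, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    best = minimize(objective, best.x, method="Nelder-Mead",
                    options={"maxiter": 6000, "fatol": 1e-12})
    rot = Rotation.from_rotvec(best.x[:3]).as_matrix()
    c_final = c_coords @ rot.T + best.x[3:]
    return (
        (g_names, g_elements, g_coords),
        (c_names, c_elements, c_final),
    )


def build_gc_pair() -> Structure:
    """Synthetic idealized Watson–Crick G–C base pair (bases only).

    Guanine is kept fixed; the cytosine base is placed by deterministic
    optimization so the three canonical donor–acceptor contacts sit at their
    standard distances, coplanar with the guanine ring, hydrogens in line.
    This is a constructed fixture, not an experimental structure.
    """
    (g_names, g_elements, g_coords), (c_names, c_elements, c_final) = (
        _gc_pair_geometry()
    )
    serial = 1
    residues = []
    for code, names, elements, coords, seq in (
        ("G", g_names, g_elements, g_coords, 1),
        ("C", c_names, c_elements, c_final, 2),
    ):
        atoms = []
        for n, e, xyz in zip(names, elements, coords):
            atoms.append(Atom(n, e, xyz, serial))
            serial += 1
        residues.append(Residue(code, "A", seq, atoms))
    return Structure(residues, title="synthetic Watson-Crick G-C pair")


def _plane(points: np.ndarray):
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]
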